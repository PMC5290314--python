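"""Synthetic proteogenomic cohorts drawn from the bilinear generative model.

The generator mirrors the model the package fits: a binary motif matrix D, a
sparse ground-truth interaction matrix W*, standard-normal protein profiles
P, and expression Y = D W* P' + Gaussian noise whose standard deviation is a
configured fraction of the empirical signal sd.  On top of the molecular
core it plants the structures every downstream stage tests for:

* binary somatic alterations at configured frequencies, each optionally
  shifting designated protein features of its carrier samples (so effects
  propagate through the full inference chain);
* a binary subgroup label with its own planted protein-feature shifts
  (differential-activity screens);
* exponential proportional-hazards survival times driven by one true TF
  activity, with independent exponential censoring;
* a categorical stage covariate independent of everything else.

``make_null_cohort`` keeps all marginals but severs the expression–protein
link (W* = 0), giving an exact null for calibration tests of every
p-value-producing stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import (
    AlterationMatrix,
    ClinicalTable,
    CohortBundle,
    ExpressionMatrix,
    MotifHitMatrix,
    ProteinMatrix,
)
from . import io as arpan_io

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "SyntheticTruth", "make_cohort", "make_null_cohort",
           "write_fixture_suite", "PRESETS"]


@dataclass
class SimulationConfig:
    """Parameters of the generative model; the defaults are the reference
    cohort used throughout the test suite."""

    n_genes: int = 1000
    n_samples: int = 100
    n_tfs: int = 40
    n_proteins: int = 25
    motif_density: float = 0.10
    w_sparsity: float = 0.30        # fraction of nonzero W* entries
    w_scale: float = 1.0            # sd of nonzero W* entries
    noise_sd_ratio: float = 0.5     # noise sd relative to empirical signal sd
    null_noise_sd: float = 1.0      # absolute noise sd when the signal is absent
    n_alterations: int = 10
    alteration_frequency: float = 0.30
    planted_alterations: int = 3    # how many alterations shift protein features
    planted_magnitude: float = 1.0  # shift added to target features of carriers
    subgroup_fraction: float = 0.5
    subgroup_targets: int = 2       # protein features shifted in the subgroup
    subgroup_magnitude: float = 1.0
    survival_coefficient: float = 1.0  # log-hazard per sd of the driving activity
    baseline_hazard: float = 0.02      # events per month
    censoring_fraction: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_samples", "n_tfs", "n_proteins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("motif_density", "w_sparsity", "alteration_frequency",
                     "subgroup_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_alterations and self.alteration_frequency * self.n_samples < 1:
            raise ValueError("alteration frequency too low: expected carriers < 1")
        if not 0 <= self.censoring_fraction < 1:
            raise ValueError("censoring_fraction must lie in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to a synthetic bundle."""

    W_star: pd.DataFrame                 # TFs x protein features
    tf_activities: pd.DataFrame          # W* P', TFs x samples
    alteration_effects: pd.DataFrame     # alteration, feature, magnitude
    subgroup_effects: pd.DataFrame       # feature, magnitude
    survival_coefficient: float
    survival_driver: str                 # regulator id driving the hazard
    config: SimulationConfig


def _draw_motifs(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    D = rng.binomial(1, cfg.motif_density, size=(cfg.n_genes, cfg.n_tfs))
    for j in range(cfg.n_tfs):  # no all-zero TF column
        if D[:, j].sum() == 0:
            D[rng.integers(cfg.n_genes), j] = 1
    return D


def make_cohort(config: SimulationConfig) -> Tuple[CohortBundle, SyntheticTruth]:
    """Draw one cohort and its ground truth; deterministic under the seed."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = pd.Index([f"g{i:04d}" for i in range(cfg.n_genes)])
    samples = pd.Index([f"s{i:03d}" for i in range(cfg.n_samples)])
    tfs = pd.Index([f"TF{i:02d}" for i in range(cfg.n_tfs)])
    feats = pd.Index([f"prot{i:02d}" for i in range(cfg.n_proteins)])

    D = _draw_motifs(rng, cfg)
    mask = rng.binomial(1, cfg.w_sparsity, size=(cfg.n_tfs, cfg.n_proteins))
    W_star = mask * rng.normal(0.0, cfg.w_scale, size=mask.shape)

    P = rng.normal(0.0, 1.0, size=(cfg.n_samples, cfg.n_proteins))

    # alterations: binary carriers; the first `planted_alterations` shift a
    # dedicated protein feature of their carriers
    alt_ids = [f"alt{i:02d}" for i in range(cfg.n_alterations)]
    calls = np.zeros((cfg.n_samples, cfg.n_alterations), dtype=int)
    effect_rows = []
    for j in range(cfg.n_alterations):
        carriers = rng.random(cfg.n_samples) < cfg.alteration_frequency
        if carriers.sum() == 0:
            carriers[rng.integers(cfg.n_samples)] = True
        calls[:, j] = carriers.astype(int)
        if j < cfg.planted_alterations:
            target = j % cfg.n_proteins
            P[carriers, target] += cfg.planted_magnitude
            effect_rows.append(
                {"alteration": alt_ids[j], "feature": feats[target],
                 "magnitude": cfg.planted_magnitude}
            )

    # subgroup with its own planted protein shifts
    subgroup = (rng.random(cfg.n_samples) < cfg.subgroup_fraction).astype(int)
    sub_rows = []
    for k in range(cfg.subgroup_targets):
        target = cfg.n_proteins - 1 - k
        P[subgroup == 1, target] += cfg.subgroup_magnitude
        sub_rows.append({"feature": feats[target], "magnitude": cfg.subgroup_magnitude})

    signal = D @ W_star @ P.T
    signal_sd = float(signal.std())
    noise_sd = cfg.noise_sd_ratio * signal_sd if signal_sd > 0 else cfg.null_noise_sd
    Y = signal + rng.normal(0.0, noise_sd, size=signal.shape)

    # survival driven by the standardized true activity of the first TF
    true_act = W_star @ P.T  # Q x M
    driver = true_act[0]
    z = (driver - driver.mean()) / driver.std() if driver.std() > 0 else np.zeros_like(driver)
    rate = cfg.baseline_hazard * np.exp(cfg.survival_coefficient * z)
    t_event = rng.exponential(1.0 / rate)
    if cfg.censoring_fraction > 0:
        c_rate = cfg.baseline_hazard * cfg.censoring_fraction / (1 - cfg.censoring_fraction)
        t_cens = rng.exponential(1.0 / c_rate, size=cfg.n_samples)
    else:
        t_cens = np.full(cfg.n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    stage = rng.choice(["I", "II", "III"], size=cfg.n_samples, p=[0.4, 0.4, 0.2])

    bundle = CohortBundle(
        expression=ExpressionMatrix(pd.DataFrame(Y, index=genes, columns=samples)),
        motifs=MotifHitMatrix(pd.DataFrame(D, index=genes, columns=tfs)),
        proteins=ProteinMatrix(pd.DataFrame(P, index=samples, columns=feats)),
        alterations=AlterationMatrix(
            pd.DataFrame(calls, index=samples, columns=alt_ids),
            pd.DataFrame({"gene": alt_ids, "kind": "mutation"}, index=alt_ids),
        ),
        clinical=ClinicalTable(
            pd.DataFrame(
                {
                    "time_months": time,
                    "event": event,
                    "covariate": stage,
                    "subgroup": subgroup,
                },
                index=samples,
            )
        ),
    )
    truth = SyntheticTruth(
        W_star=pd.DataFrame(W_star, index=tfs, columns=feats),
        tf_activities=pd.DataFrame(true_act, index=tfs, columns=samples),
        alteration_effects=pd.DataFrame(
            effect_rows, columns=["alteration", "feature", "magnitude"]
        ),
        subgroup_effects=pd.DataFrame(sub_rows, columns=["feature", "magnitude"]),
        survival_coefficient=cfg.survival_coefficient,
        survival_driver=str(tfs[0]),
        config=cfg,
    )
    return bundle, truth


def make_null_cohort(config: SimulationConfig) -> CohortBundle:
    """Same marginals but expression independent of the protein data
    (W* = 0; Y is pure noise)."""
    cfg = SimulationConfig(**{**asdict(config), "w_sparsity": 1e-12,
                              "planted_alterations": 0, "subgroup_targets": 0})
    cfg.w_scale = 0.0
    bundle, _ = make_cohort(cfg)
    return bundle


PRESETS = {
    "tiny": dict(n_genes=50, n_samples=12, n_tfs=6, n_proteins=4),
    "small": dict(n_genes=500, n_samples=60, n_tfs=20, n_proteins=12),
    "reference": dict(n_genes=1000, n_samples=100, n_tfs=40, n_proteins=25),
}


def write_fixture_suite(
    output_dir, sizes: Sequence[str] = ("tiny", "small", "reference"), base_seed: int = 0
) -> Path:
    """Emit graded synthetic cohorts with their truth bundles and a seed
    manifest; rerunning with the same seeds regenerates identical files."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for i, size in enumerate(sizes):
        if size not in PRESETS:
            raise ValueError(f"unknown preset {size!r}")
        seed = base_seed + i
        cfg = SimulationConfig(**PRESETS[size], seed=seed)
        bundle, truth = make_cohort(cfg)
        subdir = outdir / size
        arpan_io.write_bundle(bundle, subdir)
        arpan_io.write_matrix(truth.W_star, subdir / "truth_W.tsv")
        arpan_io.write_matrix(truth.tf_activities, subdir / "truth_tf_activities.tsv")
        truth.alteration_effects.to_csv(subdir / "truth_alteration_effects.tsv",
                                        sep="\t", index=False)
        manifest[size] = {"seed": seed, **PRESETS[size]}
    (outdir / "fixture_manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
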