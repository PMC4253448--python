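"""Synthetic cohort generator with full ground truth.

Emulates the study design the analysis assumes: 7 control and 7 cancer
donors, five sorted leukocyte subsets plus whole blood per donor, 1,205
miRNAs measured as 40 replicate probes each.  Planted structure:

* per-cell-type marker miRNAs (a fixed log2 boost in exactly one subset),
* disease effects (log2 shifts in cancer donors), including one universal
  miRNA deregulated in every subset — and hence, through mixing, in whole
  blood — after the oncomiR pattern,
* whole blood as a convex combination of the donor's observed subset
  profiles plus a hidden non-leukocyte component (erythrocyte/platelet/
  exosome-borne miRNAs expressed in no sorted subset),
* detection censoring: linear signals below a threshold are zeroed,
* probe-replicate expansion with multiplicative probe noise.

All randomness flows from one seed through numpy's default PCG64 generator;
identical seeds give identical cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ConfigError,
    DetectionMatrix,
    ExpressionMatrix,
    ProbeTable,
    SampleSheet,
    SUBSETS,
)

DEFAULT_MIXTURE_WEIGHTS = {"CD15": 0.55, "CD3": 0.20, "CD14": 0.08, "CD19": 0.07, "CD56": 0.05}


@dataclass
class DiseaseEffect:
    """One planted condition effect: a log2 shift in cancer donors."""

    mirna_index: int
    cell_types: tuple[str, ...]  # subsets carrying the effect
    log2_effect: float  # signed; positive = up in cancer

    @property
    def universal(self) -> bool:
        return set(self.cell_types) >= set(SUBSETS)


def default_disease_effects(n_mirna: int, universal_effect: float = 1.5,
                            per_subset: int = 4, subset_effect: float = 1.5,
                            start_index: int = 0) -> list[DiseaseEffect]:
    """One universal effect plus ``per_subset`` single-subset effects per cell
    type, alternating sign, on consecutive miRNA indices."""
    effects = [DiseaseEffect(start_index, tuple(SUBSETS), universal_effect)]
    idx = start_index + 1
    for ct in SUBSETS:
        for k in range(per_subset):
            sign = 1.0 if k % 2 == 0 else -1.0
            effects.append(DiseaseEffect(idx, (ct,), sign * subset_effect))
            idx += 1
    if idx > n_mirna:
        raise ConfigError("too many disease effects for n_mirna")
    return effects


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the emulated study's scale."""

    n_donors_per_condition: int = 7
    n_mirna: int = 1205
    n_markers_per_celltype: int = 20
    marker_effect: float = 4.0            # log2 units
    disease_effects: list[DiseaseEffect] | None = None
    universal_effect: float = 1.5         # log2 units, used when effects defaulted
    # baseline model: a miRNA is either expressed in leukocytes or silent,
    # with a thin mass near the detection limit (real miRNomes are bimodal)
    expressed_fraction: float = 0.35
    expressed_mean: float = 4.5           # log2 baseline of expressed miRNAs
    expressed_sd: float = 2.0
    unexpressed_mean: float = -1.0        # log2 baseline of silent miRNAs
    unexpressed_sd: float = 1.0
    effect_baseline: float = 8.0          # fixed baseline for disease-affected miRNAs
    marker_baseline_log2_min: float = 7.0  # markers are robustly expressed where they mark
    noise_sd: float = 0.5                 # log2 measurement noise per sample
    mixture_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE_WEIGHTS))
    hidden_n_mirna: int = 15
    hidden_profile_log2: float = 12.0     # linear signal of hidden miRNAs in WB source
    detection_threshold: float = 4.0      # linear censoring limit (log2 = 2)
    n_probe_replicates: int = 40
    probe_noise_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        w = self.mixture_weights
        if set(w) != set(SUBSETS):
            raise ConfigError(f"mixture_weights must cover exactly {SUBSETS}")
        if any(v < 0 for v in w.values()) or sum(w.values()) > 1 + 1e-12:
            raise ConfigError("mixture weights must be nonnegative and sum to <= 1")
        if self.n_markers_per_celltype * len(SUBSETS) > self.n_mirna:
            raise ConfigError("more markers requested than miRNAs available")

    @property
    def hidden_weight(self) -> float:
        return max(0.0, 1.0 - sum(self.mixture_weights.values()))


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery scoring."""

    marker_map: dict[str, list[str]]              # cell type -> marker miRNA ids
    disease_effects: pd.DataFrame                 # mirna_id, cell_types, log2_effect
    universal_mirna: str | None
    mixture_weights: dict[str, dict[str, float]]  # donor -> cell type -> weight
    hidden_weight: float
    hidden_mirnas: list[str]
    hidden_profile: pd.Series                     # linear signal per hidden miRNA
    detection_mask: pd.DataFrame                  # bool, pre-censoring truth
    seed: int

    def expected_specific(self, condition: str) -> dict[str, set[str]]:
        """Cell-type-specific miRNAs a perfect analysis should report.

        In controls these are the planted markers; in the cancer condition,
        miRNAs deregulated in exactly one subset are additionally cell-type-
        specific there.
        """
        expected = {ct: set(ids) for ct, ids in self.marker_map.items()}
        if condition == "cancer":
            for _, row in self.disease_effects.iterrows():
                cts = row["cell_types"]
                if len(cts) == 1:
                    expected[cts[0]].add(row["mirna_id"])
        return expected


def _mirna_ids(n: int) -> list[str]:
    return [f"syn-miR-{i:04d}" for i in range(n)]


def generate_cohort(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, SampleSheet, SyntheticTruth]:
    """Generate a full cohort: linear expression matrix, sample sheet, truth.

    Subset signal (log2): per-miRNA baseline + marker boost + disease shift +
    N(0, noise_sd).  Whole blood (linear): convex mix of the donor's observed
    subset profiles plus the hidden component, with its own multiplicative
    noise.  Finally, linear values below ``detection_threshold`` are censored
    to 0.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_mirna
    ids = _mirna_ids(n)

    effects = cfg.disease_effects
    if effects is None:
        effects = default_disease_effects(n, universal_effect=cfg.universal_effect)
    used = {e.mirna_index for e in effects}

    # hidden-component miRNAs: silent in every sorted subset
    free = [i for i in range(n) if i not in used]
    hidden_idx = list(rng.choice(free, size=cfg.hidden_n_mirna, replace=False))
    used |= set(hidden_idx)

    # markers: disjoint blocks per cell type, drawn from the remaining miRNAs
    free = np.array([i for i in range(n) if i not in used])
    marker_idx = rng.choice(free, size=cfg.n_markers_per_celltype * len(SUBSETS), replace=False)
    marker_map_idx = {
        ct: sorted(marker_idx[k * cfg.n_markers_per_celltype:(k + 1) * cfg.n_markers_per_celltype])
        for k, ct in enumerate(SUBSETS)
    }

    expressed = rng.random(n) < cfg.expressed_fraction
    baseline = np.where(
        expressed,
        rng.normal(cfg.expressed_mean, cfg.expressed_sd, size=n),
        rng.normal(cfg.unexpressed_mean, cfg.unexpressed_sd, size=n),
    )
    for e in effects:
        baseline[e.mirna_index] = cfg.effect_baseline
    # cell-type markers are, by definition, well expressed in leukocytes:
    # keep their baselines clear of the detection limit so censoring cannot
    # turn a planted marker into a bimodal on/off signal
    baseline[marker_idx] = np.maximum(baseline[marker_idx], cfg.marker_baseline_log2_min)
    baseline[hidden_idx] = 0.0  # linear 1: censored everywhere in the subsets

    effect_by_ct = {ct: np.zeros(n) for ct in SUBSETS}
    for e in effects:
        for ct in e.cell_types:
            effect_by_ct[ct][e.mirna_index] += e.log2_effect
    marker_boost = {ct: np.zeros(n) for ct in SUBSETS}
    for ct, idx in marker_map_idx.items():
        marker_boost[ct][idx] = cfg.marker_effect

    hidden_profile = np.zeros(n)
    hidden_profile[hidden_idx] = 2.0 ** cfg.hidden_profile_log2

    donors = [(f"ctrl{i + 1}", "control") for i in range(cfg.n_donors_per_condition)] + \
             [(f"case{i + 1}", "cancer") for i in range(cfg.n_donors_per_condition)]

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    weights_by_donor: dict[str, dict[str, float]] = {}
    for donor, condition in donors:
        subset_linear = {}
        for ct in SUBSETS:
            log2_val = baseline + marker_boost[ct]
            if condition == "cancer":
                log2_val = log2_val + effect_by_ct[ct]
            log2_val = log2_val + rng.normal(0.0, cfg.noise_sd, size=n)
            subset_linear[ct] = 2.0 ** log2_val
            subset_linear[ct][hidden_idx] = 2.0 ** rng.normal(0.0, cfg.noise_sd, size=len(hidden_idx))
            sid = f"{donor}_{ct}"
            columns[sid] = subset_linear[ct]
            sheet_rows.append({"sample_id": sid, "donor_id": donor,
                               "cell_type": ct, "condition": condition})
        w = dict(cfg.mixture_weights)
        weights_by_donor[donor] = w
        wb = sum(w[ct] * subset_linear[ct] for ct in SUBSETS) + cfg.hidden_weight * hidden_profile
        wb = wb * 2.0 ** rng.normal(0.0, cfg.noise_sd, size=n)
        sid = f"{donor}_WB"
        columns[sid] = wb
        sheet_rows.append({"sample_id": sid, "donor_id": donor,
                           "cell_type": "WB", "condition": condition})

    values = pd.DataFrame(columns, index=ids)
    detection_mask = values >= cfg.detection_threshold
    values = values.where(detection_mask, 0.0)

    matrix = ExpressionMatrix(values, scale="linear")
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    truth = SyntheticTruth(
        marker_map={ct: [ids[i] for i in idx] for ct, idx in marker_map_idx.items()},
        disease_effects=pd.DataFrame(
            [{"mirna_id": ids[e.mirna_index], "cell_types": tuple(e.cell_types),
              "log2_effect": e.log2_effect} for e in effects]),
        universal_mirna=next((ids[e.mirna_index] for e in effects if e.universal), None),
        mixture_weights=weights_by_donor,
        hidden_weight=cfg.hidden_weight,
        hidden_mirnas=[ids[i] for i in sorted(hidden_idx)],
        hidden_profile=pd.Series(hidden_profile[sorted(hidden_idx)],
                                 index=[ids[i] for i in sorted(hidden_idx)]),
        detection_mask=detection_mask,
        seed=cfg.seed,
    )
    return matrix, sheet, truth


def null_cohort(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, SampleSheet, SyntheticTruth]:
    """Same cohort structure with every planted effect zeroed."""
    null_cfg = SyntheticConfig(**{**cfg.__dict__,
                                  "marker_effect": 0.0,
                                  "disease_effects": [],
                                  "n_markers_per_celltype": 0})
    return generate_cohort(null_cfg)


def expand_to_probes(m: ExpressionMatrix, cfg: SyntheticConfig,
                     rng: np.random.Generator | None = None) -> ProbeTable:
    """Split each (miRNA, sample) value into replicate probe signals.

    Probes get multiplicative noise with coefficient of variation
    ``probe_noise_cv`` and are renormalized so their sum reproduces the
    original value exactly; aggregation is thus the exact inverse.
    """
    if m.scale != "linear":
        raise ConfigError("expand_to_probes expects a linear-scale matrix")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    r = cfg.n_probe_replicates
    n_mir, n_smp = m.shape
    vals = m.values.to_numpy(dtype=float)
    if cfg.probe_noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.probe_noise_cv ** 2))
        noise = rng.lognormal(0.0, sigma, size=(n_mir, n_smp, r))
    else:
        noise = np.ones((n_mir, n_smp, r))
    shares = noise / noise.sum(axis=2, keepdims=True)
    probes = vals[:, :, None] * shares

    mirnas = np.repeat(m.mirna_ids, n_smp * r)
    samples = np.tile(np.repeat(m.sample_ids, r), n_mir)
    probe_ids = np.tile(np.arange(r), n_mir * n_smp)
    records = pd.DataFrame({
        "probe_id": [f"{mid}_p{k:02d}" for mid, k in zip(mirnas, probe_ids)],
        "mirna_id": mirnas,
        "sample_id": samples,
        "signal": probes.reshape(-1),
    })
    return ProbeTable(records)


def generate_annotations(mirna_ids: list[str], seed: int = 0,
                         n_genes: int = 1500, n_pathways: int = 25,
                         targets_per_mirna: tuple[int, int] = (5, 30),
                         pathway_size: tuple[int, int] = (30, 80),
                         ) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Synthetic miRNA->target map and pathway gene sets.

    A stand-in for validated-target and pathway databases (which the analysis
    always takes as input files); random memberships, no biological meaning.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"GENE{i:04d}" for i in range(n_genes)])
    target_map = {}
    for mid in mirna_ids:
        k = int(rng.integers(targets_per_mirna[0], targets_per_mirna[1] + 1))
        target_map[mid] = set(rng.choice(genes, size=k, replace=False))
    pathways = {}
    for j in range(n_pathways):
        k = int(rng.integers(pathway_size[0], pathway_size[1] + 1))
        pathways[f"synthetic_pathway_{j:02d}"] = set(rng.choice(genes, size=k, replace=False))
    return target_map, pathways
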