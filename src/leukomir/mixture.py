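"""Whole blood as a function of the sorted subsets, per donor.

Whole blood physically mixes the leukocyte subsets with other compartments
(erythrocytes, platelets, exosomes).  Per donor, this module regresses the
whole-blood expression vector on the five subset vectors across miRNAs
(OLS by default, optionally nonnegative least squares), reports per-subset
Pearson correlations with whole blood, and flags presence/absence
discordance: miRNAs seen in every whole-blood sample but no subset sample and
vice versa — the footprint of compartments the sorting never captured.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import (
    ConfigError,
    DetectionMatrix,
    ExpressionMatrix,
    SampleSheet,
    SUBSETS,
)


@dataclass
class MixtureFit:
    """Per-donor linear model of whole blood on subset expression."""

    donor: str
    coefficients: dict[str, float]
    intercept: float
    r_squared: float
    residuals: pd.Series  # per-miRNA
    mode: str = "ols"
    rank_deficient: bool = False
    n_mirna: int = 0


def fit_wholeblood_model(m: ExpressionMatrix, sheet: SampleSheet, donor: str,
                         mode: str = "ols", intercept: bool = True,
                         detection: DetectionMatrix | None = None) -> MixtureFit:
    """Least-squares fit of a donor's whole-blood vector on their subset
    vectors, observations = miRNAs.

    Rows undetected in every one of the donor's samples are excluded (they are
    structurally zero on both sides).  ``mode="nnls"`` constrains the subset
    coefficients to be nonnegative.  A rank-deficient design (duplicate subset
    profiles) is flagged and the minimum-norm solution returned.
    """
    if mode not in ("ols", "nnls"):
        raise ConfigError(f"mode must be 'ols' or 'nnls', got {mode!r}")
    wb = sheet.samples(cell_type="WB", donor=donor)
    if not wb:
        raise ConfigError(f"donor {donor} has no whole-blood sample")
    subset_samples = {ct: sheet.samples(cell_type=ct, donor=donor) for ct in SUBSETS}
    subset_samples = {ct: s[0] for ct, s in subset_samples.items() if s}
    if len(subset_samples) < 2:
        raise ConfigError(f"donor {donor} has fewer than 2 subset samples")

    y = m.values[wb[0]].to_numpy(dtype=float)
    cts = sorted(subset_samples)
    X = m.values[[subset_samples[ct] for ct in cts]].to_numpy(dtype=float)

    keep = np.ones(len(y), dtype=bool)
    if detection is not None:
        donor_cols = [wb[0]] + [subset_samples[ct] for ct in cts]
        keep = detection.values[donor_cols].any(axis=1).to_numpy()
    y, X = y[keep], X[keep]
    mirna_index = m.values.index[keep]

    if intercept:
        design = np.column_stack([np.ones(len(y)), X])
    else:
        design = X
    rank = np.linalg.matrix_rank(design)
    rank_deficient = rank < design.shape[1]

    if mode == "ols":
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    else:
        beta, _ = optimize.nnls(design, y) if not intercept else _nnls_with_free_intercept(design, y)

    fitted = design @ beta
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    if intercept:
        b0, coefs = float(beta[0]), beta[1:]
    else:
        b0, coefs = 0.0, beta
    return MixtureFit(
        donor=donor,
        coefficients={ct: float(c) for ct, c in zip(cts, coefs)},
        intercept=b0,
        r_squared=r2,
        residuals=pd.Series(resid, index=mirna_index),
        mode=mode,
        rank_deficient=rank_deficient,
        n_mirna=len(y),
    )


def _nnls_with_free_intercept(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """NNLS on the subset coefficients with an unconstrained intercept.

    Handled by splitting the intercept into a positive and a negative part so
    plain NNLS applies.
    """
    aug = np.column_stack([design, -design[:, :1]])
    beta_aug, rnorm = optimize.nnls(aug, y)
    beta = beta_aug[:-1].copy()
    beta[0] -= beta_aug[-1]
    return beta, rnorm


def subset_wb_correlation(m: ExpressionMatrix, sheet: SampleSheet,
                          detection: DetectionMatrix | None = None) -> pd.DataFrame:
    """Pearson rho between each subset's vector and whole blood, per donor.

    Returns a DataFrame with columns donor, cell_type, rho (NaN when either
    vector has zero variance), restricted to miRNAs detected in at least one
    of the pair when a detection matrix is given.
    """
    rows = []
    for donor in sheet.donors:
        wb = sheet.samples(cell_type="WB", donor=donor)
        if not wb:
            continue
        for ct in SUBSETS:
            ss = sheet.samples(cell_type=ct, donor=donor)
            if not ss:
                continue
            x = m.values[ss[0]].to_numpy(dtype=float)
            y = m.values[wb[0]].to_numpy(dtype=float)
            if detection is not None:
                keep = detection.values[[ss[0], wb[0]]].any(axis=1).to_numpy()
                x, y = x[keep], y[keep]
            if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
                rho = np.nan
            else:
                rho = float(stats.pearsonr(x, y).statistic)
            rows.append({"donor": donor, "cell_type": ct, "rho": rho})
    return pd.DataFrame(rows, columns=["donor", "cell_type", "rho"])


@dataclass
class PresenceDiscordance:
    """miRNAs whose detection pattern splits whole blood from the subsets."""

    wb_only: set[str]
    subset_only: set[str]
    subset_fraction: float = 0.90
    condition: str = ""

    def __post_init__(self) -> None:
        if self.wb_only & self.subset_only:
            raise ConfigError("wb_only and subset_only must be disjoint")


def presence_discordance(d: DetectionMatrix, sheet: SampleSheet, condition: str,
                         subset_fraction: float = 0.90) -> PresenceDiscordance:
    """Presence/absence discordance between whole blood and the subsets.

    wb_only: detected in ALL whole-blood samples of the condition and in NO
    subset sample.  subset_only: detected in more than ``subset_fraction`` of
    all subset samples and in NO whole-blood sample.
    """
    if not 0 < subset_fraction <= 1:
        raise ConfigError("subset_fraction must be in (0, 1]")
    wb_samples = sheet.samples(cell_type="WB", condition=condition)
    if not wb_samples:
        raise ConfigError(f"no whole-blood samples in condition {condition!r}")
    subset_samples = [s for ct in SUBSETS for s in sheet.samples(cell_type=ct, condition=condition)]
    if not subset_samples:
        raise ConfigError(f"no subset samples in condition {condition!r}")
    det = d.values
    wb_all = det.loc[:, wb_samples].all(axis=1)
    wb_none = ~det.loc[:, wb_samples].any(axis=1)
    sub_frac = det.loc[:, subset_samples].mean(axis=1)
    sub_none = ~det.loc[:, subset_samples].any(axis=1)
    return PresenceDiscordance(
        wb_only=set(det.index[wb_all & sub_none]),
        subset_only=set(det.index[(sub_frac > subset_fraction) & wb_none]),
        subset_fraction=subset_fraction,
        condition=condition,
    )
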