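"""Two-group differential miRNA expression.

Per-miRNA independent two-tailed t tests (Welch by default) with
Benjamini-Hochberg FDR adjustment, the raw-p + detection candidate filter
used for condition contrasts, and the union report that tabulates deregulated
miRNAs across several contrasts with per-miRNA overlap counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ConfigError, DetectionMatrix, ExpressionMatrix, IntegrityError

_TINY_P = np.finfo(float).tiny


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min(1, min_{j: p_(j) >= p_(i)} p_(j) * n / rank(j)); monotone in
    the raw p-values and >= them elementwise.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ConfigError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ConfigError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty(n)
    adj[order] = adj_sorted
    return adj


@dataclass
class DEResult:
    """Per-miRNA statistics for one two-group contrast (group b vs group a)."""

    table: pd.DataFrame  # index: mirna ids; columns: mean_a, mean_b, t_stat,
    #                      df, raw_p, adj_p, direction, detected_all_a, detected_all_b
    group_a: str = "a"
    group_b: str = "b"
    zero_variance_flagged: list[str] = field(default_factory=list)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.table.index)

    def significant(self, alpha: float = 0.05, adjusted: bool = True) -> pd.DataFrame:
        col = "adj_p" if adjusted else "raw_p"
        return self.table[self.table[col] < alpha]


def _welch_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch t over matrix rows; returns (t, df, p)."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = np.full(t.shape, np.nan)
    ok = np.isfinite(t) & np.isfinite(df) & (df > 0)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    return t, df, p


def _student_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    df = float(na + nb - 2)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = np.full(t.shape, np.nan)
    ok = np.isfinite(t)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df)
    return t, np.full(t.shape, df), p


def two_group_t_test(m: ExpressionMatrix, samples_a: list[str], samples_b: list[str],
                     detection: DetectionMatrix | None = None,
                     equal_var: bool = False,
                     group_a: str = "a", group_b: str = "b") -> DEResult:
    """Independent two-tailed t test per miRNA, group b versus group a.

    Welch's unequal-variance form is the default; ``equal_var=True`` selects
    the pooled-variance Student form.  Rows where both groups are constant get
    t=0, p=1 if the constants agree, and p = machine minimum (flagged) if they
    differ — the test statistic is undefined there but the evidence for a
    difference is unbounded.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ConfigError("each group needs >= 2 samples")
    if set(samples_a) & set(samples_b):
        raise ConfigError("groups must be disjoint")
    a = m.subset_samples(samples_a).values.to_numpy(dtype=float)
    b = m.subset_samples(samples_b).values.to_numpy(dtype=float)
    t, df, p = (_student_rows if equal_var else _welch_rows)(a, b)

    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    both_const = (va == 0) & (vb == 0)
    flagged_mask = both_const & (ma != mb)
    t = np.where(both_const & (ma == mb), 0.0, t)
    p = np.where(both_const & (ma == mb), 1.0, p)
    p = np.where(flagged_mask, _TINY_P, p)
    t = np.where(flagged_mask, np.where(mb > ma, np.inf, -np.inf), t)
    df = np.where(both_const, 0.0, df)
    # one group constant, the other not: Welch formula is defined; nothing to fix
    p = np.nan_to_num(p, nan=1.0)

    direction = np.where(mb > ma, "up_in_b", np.where(mb < ma, "down_in_b", "none"))
    table = pd.DataFrame(
        {
            "mean_a": ma,
            "mean_b": mb,
            "t_stat": t,
            "df": df,
            "raw_p": p,
            "adj_p": bh_adjust(p),
            "direction": direction,
        },
        index=m.values.index,
    )
    if detection is not None:
        if not detection.aligned_with(m):
            det = detection.values.reindex(index=m.values.index)
        else:
            det = detection.values
        table["detected_all_a"] = det.loc[:, samples_a].all(axis=1).to_numpy()
        table["detected_all_b"] = det.loc[:, samples_b].all(axis=1).to_numpy()
    else:
        table["detected_all_a"] = True
        table["detected_all_b"] = True
    return DEResult(table=table, group_a=group_a, group_b=group_b,
                    zero_variance_flagged=list(table.index[flagged_mask]))


def select_candidates(de: DEResult, raw_alpha: float = 0.05) -> pd.DataFrame:
    """Deregulation candidates: raw p below ``raw_alpha`` AND detected in every
    sample of at least one group.

    This is the reporting filter used for condition contrasts when the
    BH-adjusted values clear nothing at the study's sample size.
    """
    t = de.table
    mask = (t["raw_p"] < raw_alpha) & (t["detected_all_a"] | t["detected_all_b"])
    return t.loc[mask, ["raw_p", "adj_p", "direction"]].copy()


def build_union_report(contrast_selected: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Tabulate selected miRNAs across contrasts.

    Rows are the union of all selected miRNAs, one raw-p column per contrast
    (NaN where not selected), an ``overlaps`` column counting the contrasts in
    which each miRNA appears, sorted by overlap count (desc) then miRNA id,
    and a final ``total`` row with per-contrast selection sizes.
    """
    if not contrast_selected:
        raise ConfigError("union report needs >= 1 contrast")
    contrasts = list(contrast_selected)
    all_ids = sorted(set().union(*(set(sel.index) for sel in contrast_selected.values())))
    report = pd.DataFrame(index=all_ids, columns=contrasts, dtype=float)
    for name, sel in contrast_selected.items():
        if len(sel):
            report.loc[sel.index, name] = sel["raw_p"].to_numpy()
    report["overlaps"] = report[contrasts].notna().sum(axis=1).astype(float)
    order = np.lexsort((np.asarray(report.index), -report["overlaps"].to_numpy()))
    report = report.iloc[order]
    total = {c: float(len(contrast_selected[c])) for c in contrasts}
    total["overlaps"] = np.nan
    report.loc["total"] = pd.Series(total)
    return report
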