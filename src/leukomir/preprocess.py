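"""Probe aggregation, quantile normalization, log2 transform and detection.

The preprocessing order follows standard miRNA microarray practice: replicate
probe signals are summed to one expression value per miRNA and sample,
quantile normalization aligns the sample distributions on the linear scale,
and a log2 transform (with a floor so undetected signals map to the scale
origin) produces the values all downstream statistics run on.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    ConfigError,
    DetectionMatrix,
    ExpressionMatrix,
    IntegrityError,
    ProbeTable,
    SampleSheet,
)


def aggregate_probes(pt: ProbeTable) -> tuple[ExpressionMatrix, DetectionMatrix | None]:
    """Sum replicate probe signals to one value per (miRNA, sample).

    A (miRNA, sample) combination absent from the table gets value 0 and, if a
    vendor detection flag is present, detected=False.  Returns the linear-scale
    matrix and, when the table carries a detection flag, a DetectionMatrix in
    which a miRNA counts as detected if any of its probes is flagged; without a
    flag, detection is deferred to :func:`call_detection`.
    """
    if len(pt) == 0:
        raise IntegrityError("probe table is empty")
    summed = pt.records.pivot_table(index="mirna_id", columns="sample_id",
                                    values="signal", aggfunc="sum", fill_value=0.0)
    summed = summed.sort_index()
    summed.columns.name = None
    summed.index.name = None
    m = ExpressionMatrix(summed.astype(float), scale="linear")
    det = None
    if pt.has_detection_flag:
        flags = pt.records.pivot_table(index="mirna_id", columns="sample_id",
                                       values="detected", aggfunc="any", fill_value=False)
        flags = flags.reindex(index=summed.index, columns=summed.columns, fill_value=False)
        flags.columns.name = None
        flags.index.name = None
        det = DetectionMatrix(flags)
    return m, det


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the across-sample mean distribution of order
    statistics.

    Tied values within a sample receive the mean of the target order
    statistics over their tied ranks, the behaviour of the de-facto standard
    implementation used with these arrays.
    """
    if m.shape[1] < 2:
        raise ConfigError("quantile normalization needs >= 2 samples")
    x = m.values.to_numpy(dtype=float)
    n = x.shape[0]
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        ranked = np.empty(n)
        ranked[order] = target
        # average target values over runs of tied input values
        s = pd.Series(ranked).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(df, scale=m.scale)


def log2_transform(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """value -> log2(max(value, floor)); floor 1.0 keeps undetected (0) at 0."""
    if m.scale != "linear":
        raise ConfigError("log2_transform expects a linear-scale matrix")
    if floor <= 0:
        raise ConfigError("floor must be positive")
    df = np.log2(m.values.clip(lower=floor))
    return ExpressionMatrix(df, scale="log2")


def call_detection(m: ExpressionMatrix, threshold: float = 0.0) -> DetectionMatrix:
    """detected(m, s) iff linear signal strictly exceeds ``threshold``."""
    if m.scale != "linear":
        raise ConfigError("call_detection expects a linear-scale matrix")
    if threshold < 0:
        raise ConfigError("detection threshold must be >= 0")
    return DetectionMatrix(m.values > threshold)


@dataclass
class DetectionSummary:
    n_any: int
    n_all: int
    ids_any: list[str]
    ids_all: list[str]


def detection_summary(d: DetectionMatrix, sample_ids: list[str]) -> DetectionSummary:
    """Count miRNAs detected in at least one / in every selected sample."""
    if not sample_ids:
        raise ConfigError("detection_summary needs a non-empty sample group")
    missing = [s for s in sample_ids if s not in d.values.columns]
    if missing:
        raise IntegrityError(f"samples not in detection matrix: {missing[:5]}")
    sub = d.values.loc[:, sample_ids]
    any_mask = sub.any(axis=1)
    all_mask = sub.all(axis=1)
    return DetectionSummary(
        n_any=int(any_mask.sum()),
        n_all=int(all_mask.sum()),
        ids_any=list(sub.index[any_mask]),
        ids_all=list(sub.index[all_mask]),
    )


def normalize_and_log(m: ExpressionMatrix, sheet: SampleSheet | None = None,
                      scope: str = "all", floor: float = 1.0) -> ExpressionMatrix:
    """Quantile-normalize then log2-transform.

    scope="all" normalizes every array together (subsets and whole blood in
    one batch, matching a single joint cluster map); scope="per_cell_type"
    normalizes each cell type's arrays separately.
    """
    if scope == "all":
        return log2_transform(quantile_normalize(m), floor=floor)
    if scope == "per_cell_type":
        if sheet is None:
            raise ConfigError("per_cell_type scope requires a sample sheet")
        pieces = []
        for ct in sorted(set(sheet.table["cell_type"])):
            ids = [s for s in sheet.samples(cell_type=ct) if s in m.values.columns]
            if ids:
                pieces.append(quantile_normalize(m.subset_samples(ids)).values)
        joined = pd.concat(pieces, axis=1).loc[:, m.sample_ids]
        return log2_transform(ExpressionMatrix(joined, scale="linear"), floor=floor)
    raise ConfigError(f"unknown normalization scope {scope!r}")
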