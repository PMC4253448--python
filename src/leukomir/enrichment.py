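"""Hypergeometric over-representation of miRNA target genes in pathways.

The query set is the union of validated target genes of a miRNA set (e.g. one
cell type's specific miRNAs); the reference universe is the union of targets
of every miRNA on the array, supplied as a file — never a hard-coded genome.
The test is one-sided (over-representation only), BH-adjusted across the
pathways of one query, with a coverage filter for reporting: keep pathways
containing at least a given fraction of the query's target genes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust
from .types import ConfigError


@dataclass
class TargetCollection:
    genes: set[str]
    n_unmapped: int
    unmapped: list[str]


def collect_targets(mirnas: set[str] | list[str], target_map: dict[str, set[str]]) -> TargetCollection:
    """Union of validated targets of the given miRNAs; unmapped ids counted."""
    genes: set[str] = set()
    unmapped = []
    for mir in sorted(set(mirnas)):
        if mir in target_map:
            genes |= target_map[mir]
        else:
            unmapped.append(mir)
    return TargetCollection(genes=genes, n_unmapped=len(unmapped), unmapped=unmapped)


def ora_hypergeometric(targets: set[str], universe: set[str],
                       pathways: dict[str, set[str]]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway.

    Genes outside the universe are dropped (the drop count is recorded in the
    frame's ``attrs``).  raw_p = P(X >= overlap) for X hypergeometric with
    population ``|universe|``, successes ``|pathway ∩ universe|`` and draws
    ``|targets ∩ universe|``; BH across pathways.
    """
    if not universe:
        raise ConfigError("reference universe must be non-empty")
    dropped = len(set(targets) - universe)
    targets_in = set(targets) & universe
    n_universe = len(universe)
    n_targets = len(targets_in)
    rows = []
    for name in sorted(pathways):
        pw = pathways[name] & universe
        k = len(pw & targets_in)
        # upper tail P(X >= k); survival function is P(X > k-1)
        raw_p = float(stats.hypergeom.sf(k - 1, n_universe, len(pw), n_targets)) if n_targets else 1.0
        rows.append({
            "pathway": name,
            "overlap_count": k,
            "pathway_size": len(pw),
            "target_set_size": n_targets,
            "universe_size": n_universe,
            "raw_p": min(raw_p, 1.0),
            "coverage_fraction": k / n_targets if n_targets else 0.0,
            "overlap_genes": ";".join(sorted(pw & targets_in)),
        })
    res = pd.DataFrame(rows).set_index("pathway")
    res["adj_p"] = bh_adjust(res["raw_p"].to_numpy()) if len(res) else []
    res.attrs["n_dropped_targets"] = dropped
    return res


def filter_by_coverage(res: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Keep pathways containing at least ``fraction`` of the query's target
    genes (inclusive boundary)."""
    if not 0 < fraction <= 1:
        raise ConfigError("fraction must be in (0, 1]")
    out = res[res["coverage_fraction"] >= fraction].copy()
    out.attrs.update(res.attrs)
    return out
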