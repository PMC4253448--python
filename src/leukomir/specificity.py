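"""Cell-type-specific miRNA sets from all pairwise subset contrasts.

The core procedure: within one condition, t-test every unordered pair of the
five sorted subsets (10 contrasts, each BH-adjusted on its own), take as a
cell type's candidates the miRNAs significant in *all four* of its pairwise
comparisons, then remove any miRNA claimed by more than one cell type so the
final five sets are mutually disjoint ("disjointification").

Also here: the grouped contrasts along the lineage / line-of-defense /
function axes, and the partition of two significant sets into exclusive and
shared (same- or opposite-direction) members used for the condition-overlap
accounting.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .differential import DEResult, two_group_t_test
from .types import (
    CellTypeOntology,
    ConfigError,
    DetectionMatrix,
    ExpressionMatrix,
    IntegrityError,
    SampleSheet,
    SUBSETS,
)


@dataclass
class MarkerSetCollection:
    """Candidate and final (disjoint) cell-type-specific miRNA sets."""

    candidate_sets: dict[str, set[str]]
    specific_sets: dict[str, set[str]]
    condition: str = ""
    removed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for c, s in self.specific_sets.items():
            if not s.issubset(self.candidate_sets.get(c, set())):
                raise IntegrityError(f"specific set for {c} not within its candidates")
        cells = list(self.specific_sets)
        for c1, c2 in combinations(cells, 2):
            overlap = self.specific_sets[c1] & self.specific_sets[c2]
            if overlap:
                raise IntegrityError(f"specific sets {c1}/{c2} overlap: {sorted(overlap)[:5]}")


@dataclass
class ContrastOverlap:
    """Partition of two directed significant sets."""

    exclusive_a: set[str]
    exclusive_b: set[str]
    shared_same_direction: set[str]
    shared_opposite_direction: set[str]
    label_a: str = "a"
    label_b: str = "b"


def pairwise_cell_tests(m: ExpressionMatrix, sheet: SampleSheet, condition: str,
                        cell_types: tuple[str, ...] = SUBSETS,
                        equal_var: bool = False) -> dict[tuple[str, str], DEResult]:
    """t-test every unordered pair of sorted subsets within one condition.

    Whole blood never participates.  Each pair's p-values are BH-adjusted
    within that pair's own test family.
    """
    cts = sorted(set(cell_types) - {"WB"})
    for ct in cts:
        if not sheet.samples(cell_type=ct, condition=condition):
            raise ConfigError(f"no {condition} samples for cell type {ct}")
    results: dict[tuple[str, str], DEResult] = {}
    for ca, cb in combinations(cts, 2):
        sa = sheet.samples(cell_type=ca, condition=condition)
        sb = sheet.samples(cell_type=cb, condition=condition)
        results[(ca, cb)] = two_group_t_test(m, sa, sb, equal_var=equal_var,
                                             group_a=ca, group_b=cb)
    return results


def derive_specific_sets(pairwise: dict[tuple[str, str], DEResult],
                         adj_alpha: float = 0.05,
                         condition: str = "",
                         strict_direction: bool = False) -> MarkerSetCollection:
    """Candidates per cell type, then disjointification.

    candidate_sets[c] = miRNAs with BH-adjusted p < ``adj_alpha`` in every
    pairwise comparison involving c (optionally also with a consistent
    direction relative to c when ``strict_direction``);
    specific_sets[c] = candidates of c minus candidates of any other cell type.
    """
    cells = sorted({c for pair in pairwise for c in pair})
    expected = set(combinations(cells, 2))
    have = {tuple(sorted(p)) for p in pairwise}
    missing = expected - have
    if missing:
        raise ConfigError(f"pairwise map incomplete; missing pairs: {sorted(missing)}")

    candidate_sets: dict[str, set[str]] = {}
    for c in cells:
        sets_c = []
        for pair, de in pairwise.items():
            if c not in pair:
                continue
            sig = de.table[de.table["adj_p"] < adj_alpha]
            if strict_direction:
                # keep direction "up in c" consistently: c may be group a or b
                want = "up_in_b" if de.group_b == c else "down_in_b"
                up = set(sig.index[sig["direction"] == want])
                down = set(sig.index[sig["direction"] ==
                                     ("down_in_b" if want == "up_in_b" else "up_in_b")])
                sets_c.append({"up": up, "down": down})
            else:
                sets_c.append(set(sig.index))
        if strict_direction:
            up_all = set.intersection(*(s["up"] for s in sets_c))
            down_all = set.intersection(*(s["down"] for s in sets_c))
            candidate_sets[c] = up_all | down_all
        else:
            candidate_sets[c] = set.intersection(*sets_c) if sets_c else set()

    specific_sets: dict[str, set[str]] = {}
    removed: set[str] = set()
    for c in cells:
        others = set().union(*(candidate_sets[o] for o in cells if o != c))
        specific_sets[c] = candidate_sets[c] - others
        removed |= candidate_sets[c] & others
    return MarkerSetCollection(candidate_sets=candidate_sets, specific_sets=specific_sets,
                               condition=condition, removed=removed)


def group_contrast(m: ExpressionMatrix, sheet: SampleSheet, ontology: CellTypeOntology,
                   axis: str, condition: str, detection: DetectionMatrix,
                   adj_alpha: float = 0.05, equal_var: bool = False) -> DEResult:
    """Contrast two biological groupings of the subsets within one condition.

    The tested universe is restricted to miRNAs detected in every sample of at
    least one side; significance is BH-adjusted p < ``adj_alpha`` on that
    universe.  The returned DEResult covers the universe; use
    ``.significant()`` for the reported set.
    """
    side_a_cts, side_b_cts = ontology.sides(axis)
    samples_a = [s for ct in side_a_cts for s in sheet.samples(cell_type=ct, condition=condition)]
    samples_b = [s for ct in side_b_cts for s in sheet.samples(cell_type=ct, condition=condition)]
    if not samples_a or not samples_b:
        raise ConfigError(f"axis {axis}: empty side within condition {condition}")
    det = detection.values
    all_a = det.loc[:, samples_a].all(axis=1)
    all_b = det.loc[:, samples_b].all(axis=1)
    universe = det.index[all_a | all_b]
    sub = ExpressionMatrix(m.values.loc[universe], scale=m.scale)
    la, lb = ontology.SIDE_LABELS[axis]
    de = two_group_t_test(sub, samples_a, samples_b, detection=None,
                          equal_var=equal_var, group_a=la, group_b=lb)
    de.table["detected_all_a"] = all_a.loc[universe].to_numpy()
    de.table["detected_all_b"] = all_b.loc[universe].to_numpy()
    return de


def condition_overlap(sig_a: pd.Series, sig_b: pd.Series,
                      label_a: str = "a", label_b: str = "b") -> ContrastOverlap:
    """Partition two significant sets with directions into exclusive /
    shared-same-direction / shared-opposite-direction members.

    ``sig_a`` and ``sig_b`` map miRNA id -> direction string.
    """
    for s in (sig_a, sig_b):
        if s.isna().any():
            raise ConfigError("every member needs a direction")
    set_a, set_b = set(sig_a.index), set(sig_b.index)
    shared = set_a & set_b
    same = {x for x in shared if sig_a[x] == sig_b[x]}
    return ContrastOverlap(
        exclusive_a=set_a - set_b,
        exclusive_b=set_b - set_a,
        shared_same_direction=same,
        shared_opposite_direction=shared - same,
        label_a=label_a,
        label_b=label_b,
    )


def marker_sets_to_frame(collections: dict[str, MarkerSetCollection]) -> pd.DataFrame:
    """Flatten marker collections to one row per (miRNA, cell type, condition)."""
    rows = []
    for condition, coll in collections.items():
        for ct, cands in coll.candidate_sets.items():
            for mir in sorted(cands):
                rows.append({
                    "mirna_id": mir, "cell_type": ct, "condition": condition,
                    "status": "specific" if mir in coll.specific_sets[ct] else "candidate_removed",
                })
    return pd.DataFrame(rows, columns=["mirna_id", "cell_type", "condition", "status"])
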