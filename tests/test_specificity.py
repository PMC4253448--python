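"""Pairwise cell-type tests, disjoint specific sets, grouped contrasts."""
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from leukomir.differential import DEResult
from leukomir.preprocess import call_detection, log2_transform, normalize_and_log
from leukomir.specificity import (
    condition_overlap,
    derive_specific_sets,
    group_contrast,
    pairwise_cell_tests,
)
from leukomir.types import (
    CellTypeOntology,
    ConfigError,
    ExpressionMatrix,
    IntegrityError,
    SampleSheet,
)

from conftest import toy_matrix


def make_cohort(cell_types, n_per=3, n_mirna=10, effects=None, sd=0.3, seed=0):
    """Tiny cohort: one condition, ``n_per`` donors per cell type; ``effects``
    maps (mirna_index, cell_type) -> log2 shift."""
    rng = np.random.default_rng(seed)
    cols, rows = {}, []
    for ct in cell_types:
        for d in range(n_per):
            base = np.full(n_mirna, 5.0)
            for (mi, ect), delta in (effects or {}).items():
                if ect == ct:
                    base[mi] += delta
            sid = f"d{d}_{ct}"
            cols[sid] = base + rng.normal(0, sd, n_mirna)
            rows.append({"sample_id": sid, "donor_id": f"d{d}", "cell_type": ct,
                         "condition": "control"})
    m = ExpressionMatrix(pd.DataFrame(cols, index=[f"m{i}" for i in range(n_mirna)]),
                         scale="log2")
    return m, SampleSheet(pd.DataFrame(rows))


class TestPairwiseCellTests:
    def test_ten_pairs_for_five_cell_types(self, default_processed):
        log2m, _, sheet, _ = default_processed
        pw = pairwise_cell_tests(log2m, sheet, "control")
        assert len(pw) == 10
        assert all(tuple(sorted(p)) == p for p in pw)

    def test_three_cell_types_give_three_pairs(self):
        m, sheet = make_cohort(["CD3", "CD14", "CD19"])
        pw = pairwise_cell_tests(m, sheet, "control",
                                 cell_types=("CD3", "CD14", "CD19"))
        assert set(pw) == {("CD14", "CD19"), ("CD14", "CD3"), ("CD19", "CD3")}

    def test_planted_marker_significant_only_in_its_pairs(self):
        m, sheet = make_cohort(["CD3", "CD14", "CD19"], n_per=5,
                               effects={(0, "CD3"): 4.0}, seed=1)
        pw = pairwise_cell_tests(m, sheet, "control",
                                 cell_types=("CD3", "CD14", "CD19"))
        for pair, de in pw.items():
            sig = de.table.loc["m0", "adj_p"] < 0.05
            assert sig == ("CD3" in pair)

    def test_missing_cell_type_named(self):
        m, sheet = make_cohort(["CD3", "CD14"])
        with pytest.raises(ConfigError, match="CD19"):
            pairwise_cell_tests(m, sheet, "control",
                                cell_types=("CD3", "CD14", "CD19"))


def fake_pairwise(cells, sig_map):
    """Build DEResults where sig_map[(pair)][mirna] = (adj_p, direction)."""
    out = {}
    for pair in combinations(sorted(cells), 2):
        entries = sig_map.get(pair, {})
        ids = sorted({m for p in sig_map.values() for m in p})
        table = pd.DataFrame({
            "adj_p": [entries.get(m, (1.0, "none"))[0] for m in ids],
            "raw_p": [entries.get(m, (1.0, "none"))[0] for m in ids],
            "direction": [entries.get(m, (1.0, "none"))[1] for m in ids],
            "mean_a": 0.0, "mean_b": 0.0, "t_stat": 0.0, "df": 1.0,
            "detected_all_a": True, "detected_all_b": True}, index=ids)
        out[pair] = DEResult(table=table, group_a=pair[0], group_b=pair[1])
    return out


class TestDeriveSpecificSets:
    def test_marker_high_in_one_type_only(self):
        # m1 high only in X: X-Y and X-Z significant, Y-Z not
        pw = fake_pairwise("XYZ", {("X", "Y"): {"m1": (0.01, "down_in_b")},
                                   ("X", "Z"): {"m1": (0.01, "down_in_b")}})
        coll = derive_specific_sets(pw)
        assert coll.specific_sets == {"X": {"m1"}, "Y": set(), "Z": set()}

    def test_graded_means_removed_from_all(self):
        # m2 significant in every pairwise test -> candidate everywhere,
        # removed everywhere
        pw = fake_pairwise("XYZ", {p: {"m2": (0.001, "up_in_b")}
                                   for p in [("X", "Y"), ("X", "Z"), ("Y", "Z")]})
        coll = derive_specific_sets(pw)
        assert all(s == set() for s in coll.specific_sets.values())
        assert all(coll.candidate_sets[c] == {"m2"} for c in "XYZ")
        assert coll.removed == {"m2"}

    def test_nothing_significant(self):
        pw = fake_pairwise("XYZ", {("X", "Y"): {"m1": (0.9, "none")}})
        coll = derive_specific_sets(pw)
        assert all(s == set() for s in coll.specific_sets.values())

    def test_incomplete_pair_map_rejected(self):
        pw = fake_pairwise("XYZ", {})
        del pw[("X", "Y")]
        with pytest.raises(ConfigError, match="X.*Y"):
            derive_specific_sets(pw)

    def test_disjointness_on_random_instances(self, rng):
        cells = list("ABCDE")
        for _ in range(200):
            sig = {}
            for pair in combinations(cells, 2):
                sig[pair] = {f"m{i}": (float(rng.choice([0.01, 0.5])),
                                       str(rng.choice(["up_in_b", "down_in_b"])))
                             for i in range(8)}
            coll = derive_specific_sets(fake_pairwise(cells, sig))
            for c1, c2 in combinations(cells, 2):
                assert not (coll.specific_sets[c1] & coll.specific_sets[c2])
            # oracle: literal definition
            for c in cells:
                cand = None
                for pair in combinations(cells, 2):
                    if c not in pair:
                        continue
                    s = {m for m, (p, _) in sig[pair].items() if p < 0.05}
                    cand = s if cand is None else cand & s
                assert coll.candidate_sets[c] == cand

    def test_alpha_monotonicity(self, rng):
        cells = list("ABC")
        sig = {pair: {f"m{i}": (float(rng.random()), "up_in_b") for i in range(20)}
               for pair in combinations(cells, 2)}
        pw = fake_pairwise(cells, sig)
        loose = derive_specific_sets(pw, adj_alpha=0.2)
        tight = derive_specific_sets(pw, adj_alpha=0.05)
        for c in cells:
            assert tight.candidate_sets[c] <= loose.candidate_sets[c]

    def test_boundary_alpha_excluded(self):
        pw = fake_pairwise("XY", {("X", "Y"): {"m1": (0.05, "up_in_b")}})
        coll = derive_specific_sets(pw, adj_alpha=0.05)
        assert coll.candidate_sets["X"] == set()

    def test_relabeling_symmetry(self):
        sig = {("X", "Y"): {"m1": (0.01, "down_in_b")},
               ("X", "Z"): {"m1": (0.01, "down_in_b")}}
        coll = derive_specific_sets(fake_pairwise("XYZ", sig))
        relabel = {"X": "Q", "Y": "R", "Z": "S"}
        sig2 = {tuple(sorted((relabel[a], relabel[b]))): v for (a, b), v in sig.items()}
        coll2 = derive_specific_sets(fake_pairwise("QRS", sig2))
        assert coll2.specific_sets == {relabel[c]: s
                                       for c, s in coll.specific_sets.items()}


class TestGroupContrast:
    def test_lineage_sides(self):
        ont = CellTypeOntology()
        assert ont.sides("lineage") == (["CD14", "CD15"], ["CD19", "CD3", "CD56"])
        assert ont.sides("defense") == (["CD14", "CD15", "CD56"], ["CD19", "CD3"])
        assert ont.sides("function") == (["CD14", "CD19"], ["CD3", "CD56"])
        with pytest.raises(ConfigError):
            ont.sides("size")

    def test_null_rarely_has_significant_mirnas(self):
        # BH bounds the probability of any false discovery under the global
        # null by about alpha; allow one unlucky seed in five
        from leukomir.simulate import SyntheticConfig, null_cohort
        seeds_with_hits = 0
        for seed in range(5):
            m, sheet, _ = null_cohort(SyntheticConfig(n_mirna=500, seed=10 + seed))
            log2m = normalize_and_log(m, sheet)
            det = call_detection(m, 0.0)
            de = group_contrast(log2m, sheet, CellTypeOntology(), "lineage",
                                "control", det)
            seeds_with_hits += int(len(de.significant(0.05)) > 0)
        assert seeds_with_hits <= 1

    def test_planted_lineage_effect_recovered(self):
        from leukomir.simulate import SyntheticConfig, generate_cohort
        cfg = SyntheticConfig(n_mirna=400, n_markers_per_celltype=0,
                              hidden_n_mirna=0, seed=5)
        m, sheet, truth = generate_cohort(cfg)
        # plant a myeloid-vs-lymphoid difference on 20 well-expressed miRNAs
        log2m = normalize_and_log(m, sheet)
        planted = list(log2m.values.index[:20])
        myeloid = [s for ct in ("CD14", "CD15") for s in sheet.samples(cell_type=ct)]
        vals = log2m.values.copy()
        vals.loc[planted, myeloid] += 3.0
        vals.loc[planted] += 8.0  # keep the rows detection-qualified
        m2 = ExpressionMatrix(vals, scale="log2")
        det = call_detection(ExpressionMatrix(2.0 ** vals, scale="linear"), 0.0)
        de = group_contrast(m2, sheet, CellTypeOntology(), "lineage", "control", det)
        recovered = set(de.significant(0.05).index) & set(planted)
        assert len(recovered) >= 18


class TestConditionOverlap:
    def test_study_scale_arithmetic(self, rng):
        # |A|=75, |B|=64, 60 shared in the same direction, none opposite
        shared = [f"s{i}" for i in range(60)]
        only_a = [f"a{i}" for i in range(15)]
        only_b = [f"b{i}" for i in range(4)]
        sig_a = pd.Series("up_in_b", index=shared + only_a)
        sig_b = pd.Series("up_in_b", index=shared + only_b)
        ov = condition_overlap(sig_a, sig_b)
        assert (len(ov.exclusive_a), len(ov.exclusive_b)) == (15, 4)
        assert len(ov.shared_same_direction) == 60
        assert not ov.shared_opposite_direction

    def test_identical_sets(self):
        s = pd.Series(["up_in_b", "down_in_b"], index=["x", "y"])
        ov = condition_overlap(s, s.copy())
        assert not ov.exclusive_a and not ov.exclusive_b
        assert ov.shared_same_direction == {"x", "y"}

    def test_partition_matches_bruteforce(self, rng):
        for _ in range(200):
            ids = [f"m{i}" for i in range(20)]
            a = {i: str(rng.choice(["up_in_b", "down_in_b"]))
                 for i in ids if rng.random() < 0.5}
            b = {i: str(rng.choice(["up_in_b", "down_in_b"]))
                 for i in ids if rng.random() < 0.5}
            ov = condition_overlap(pd.Series(a, dtype=object), pd.Series(b, dtype=object))
            parts = [ov.exclusive_a, ov.exclusive_b, ov.shared_same_direction,
                     ov.shared_opposite_direction]
            assert set().union(*parts) == set(a) | set(b)
            assert sum(len(p) for p in parts) == len(set(a) | set(b))
            assert ov.exclusive_a == set(a) - set(b)
            assert ov.shared_same_direction == {i for i in set(a) & set(b)
                                                if a[i] == b[i]}
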