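"""Cell-type-specific miRNA sets and the lineage/defense/function contrasts.

Within each condition: all 10 pairwise subset t tests, candidates significant
in every comparison of a cell type, disjointification, and scoring against
the planted markers.  Then the three grouped contrasts (myeloid vs lymphoid,
innate vs adaptive, APC vs cytotoxic) with condition-overlap Venn counts.
"""
import json

import pandas as pd

from _shared import COHORT, RESULTS, load_processed
from leukomir.specificity import (
    condition_overlap,
    derive_specific_sets,
    group_contrast,
    marker_sets_to_frame,
    pairwise_cell_tests,
)
from leukomir.types import CellTypeOntology

OUT = RESULTS / "markers"


def main() -> None:
    _, sheet, detection, log2m = load_processed()
    truth = json.loads((COHORT / "truth.json").read_text())
    OUT.mkdir(parents=True, exist_ok=True)

    collections = {}
    for cond in ("control", "cancer"):
        pw = pairwise_cell_tests(log2m, sheet, cond)
        collections[cond] = derive_specific_sets(pw, condition=cond)
    marker_sets_to_frame(collections).to_csv(OUT / "marker_sets.tsv", sep="\t",
                                             index=False)
    for cond, coll in collections.items():
        sizes = {ct: len(s) for ct, s in sorted(coll.specific_sets.items())}
        print(f"{cond}: specific-set sizes {json.dumps(sizes)}, "
              f"{len(coll.removed)} removed by disjointification")
    planted = {ct: set(ids) for ct, ids in truth["marker_map"].items()}
    got = collections["control"].specific_sets
    tp = sum(len(got[ct] & planted[ct]) for ct in planted)
    print(f"control condition vs planted markers: recall "
          f"{tp / sum(len(v) for v in planted.values()):.3f}, precision "
          f"{tp / max(1, sum(len(v) for v in got.values())):.3f}")

    ontology = CellTypeOntology()
    rows = []
    for axis in CellTypeOntology.AXES:
        sig = {}
        for cond in ("control", "cancer"):
            de = group_contrast(log2m, sheet, ontology, axis, cond, detection)
            sig[cond] = de.significant(0.05)["direction"]
        ov = condition_overlap(sig["cancer"], sig["control"],
                               label_a="cancer", label_b="control")
        rows.append({"axis": axis, "n_cancer": len(sig["cancer"]),
                     "n_control": len(sig["control"]),
                     "shared_same": len(ov.shared_same_direction),
                     "shared_opposite": len(ov.shared_opposite_direction),
                     "cancer_only": len(ov.exclusive_a),
                     "control_only": len(ov.exclusive_b)})
    venn = pd.DataFrame(rows)
    venn.to_csv(OUT / "group_contrast_venn.tsv", sep="\t", index=False)
    print(venn.to_string(index=False))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
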