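"""Control-vs-cancer contrasts per cell type and the cross-contrast union.

BH-adjusted significance clears nothing at n=7 per group, so the report uses
the fallback filter: raw p < 0.05 plus detection in every sample of at least
one group.  The union table lists each selected miRNA's raw p per contrast
and in how many contrasts it appears.
"""
import json

from _shared import RESULTS, load_processed
from leukomir.differential import build_union_report, select_candidates, two_group_t_test
from leukomir.types import CELL_TYPES

OUT = RESULTS / "differential"


def main() -> None:
    _, sheet, detection, log2m = load_processed()
    OUT.mkdir(parents=True, exist_ok=True)
    selected = {}
    n_adj_sig = {}
    for ct in CELL_TYPES:
        de = two_group_t_test(
            log2m, sheet.samples(cell_type=ct, condition="control"),
            sheet.samples(cell_type=ct, condition="cancer"),
            detection=detection, group_a="control", group_b="cancer")
        de.table.to_csv(OUT / f"de_{ct}.tsv", sep="\t")
        n_adj_sig[ct] = int((de.table["adj_p"] < 0.05).sum())
        selected[ct] = select_candidates(de)
    union = build_union_report(selected)
    union.to_csv(OUT / "union_report.tsv", sep="\t")

    print("BH-significant miRNAs per contrast:", json.dumps(n_adj_sig))
    print("raw-p + detection candidates per contrast:",
          json.dumps({ct: len(s) for ct, s in selected.items()}))
    body = union.drop(index="total")
    top = body[body["overlaps"] == body["overlaps"].max()]
    print(f"deregulated in the most contrasts ({int(body['overlaps'].max())}): "
          f"{', '.join(top.index)}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
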