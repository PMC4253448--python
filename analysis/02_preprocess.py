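"""Detection summaries and the normalized log2 expression matrix.

How many of the 1,205 miRNAs are seen per cell type — in at least one sample
and in every sample — and how many are never detected anywhere.
"""
import pandas as pd

from _shared import RESULTS, load_processed
from leukomir import io
from leukomir.preprocess import detection_summary
from leukomir.types import CELL_TYPES

OUT = RESULTS / "preprocess"


def main() -> None:
    matrix, sheet, detection, log2m = load_processed()
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_expression_matrix(log2m, OUT / "expression_log2_normalized.tsv")

    rows = []
    for ct in CELL_TYPES:
        for cond in ("control", "cancer"):
            ids = sheet.samples(cell_type=ct, condition=cond)
            s = detection_summary(detection, ids)
            rows.append({"cell_type": ct, "condition": cond,
                         "n_any": s.n_any, "n_all": s.n_all})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "detection_summary.tsv", sep="\t", index=False)

    never = matrix.shape[0] - detection_summary(detection, matrix.sample_ids).n_any
    print(f"{never} of {matrix.shape[0]} miRNAs never detected in any sample")
    sub = table[table["cell_type"] != "WB"]
    print(f"per subset, detected in >=1 sample: {sub['n_any'].min()}-{sub['n_any'].max()}; "
          f"in all samples: {sub['n_all'].min()}-{sub['n_all'].max()}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
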