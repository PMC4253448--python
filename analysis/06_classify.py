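"""Condition classification per cell type: leaky vs leakage-safe LOOCV.

Linear SVM, leave-one-out.  ``as_published`` selects features (deregulated
miRNAs) on all samples before cross-validation — the protocol behind the
original accuracy table, reproduced deliberately; ``nested`` re-selects
inside each training fold and is the honest estimate.
"""
import pandas as pd

from _shared import RESULTS, load_processed
from leukomir.classify import classification_table, loocv_svm
from leukomir.types import CELL_TYPES

OUT = RESULTS / "classification"


def main() -> None:
    _, sheet, detection, log2m = load_processed()
    OUT.mkdir(parents=True, exist_ok=True)
    reports = []
    for mode in ("as_published", "nested"):
        for ct in CELL_TYPES:
            reports.append(loocv_svm(log2m, sheet, ct, mode=mode,
                                     detection=detection))
    table = classification_table(reports)
    table.to_csv(OUT / "classification.tsv", sep="\t")
    wide = table.reset_index().pivot(index="contrast", columns="mode",
                                     values="accuracy_mean")
    print(wide.round(4).to_string())
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
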