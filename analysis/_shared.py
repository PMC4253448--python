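"""Shared loading for the analysis scripts: cohort files -> processed objects."""
from pathlib import Path

from leukomir import io
from leukomir.preprocess import call_detection, normalize_and_log

RESULTS = Path(__file__).resolve().parents[1] / "results"
COHORT = RESULTS / "cohort"


def load_processed():
    """Linear matrix, sheet, detection calls and normalized log2 matrix."""
    if not (COHORT / "expression_linear.tsv").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    matrix = io.read_expression_matrix(COHORT / "expression_linear.tsv")
    sheet = io.read_sample_sheet(COHORT / "sample_sheet.tsv")
    detection = call_detection(matrix, threshold=0.0)
    log2m = normalize_and_log(matrix, sheet)
    return matrix, sheet, detection, log2m
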