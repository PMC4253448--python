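"""Generate the synthetic study cohort used by all downstream analyses.

7 control and 7 lung-cancer donors; per donor the five sorted leukocyte
subsets plus whole blood; 1,205 miRNAs with planted cell-type markers, a
universally deregulated oncomiR-like miRNA, whole-blood mixing and a hidden
non-leukocyte component.  Writes the linear expression matrix, sample sheet
and ground truth under results/cohort/.
"""
import json
from pathlib import Path

from leukomir import io
from leukomir.simulate import SyntheticConfig, generate_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 1


def main() -> None:
    cfg = SyntheticConfig(seed=SEED)
    matrix, sheet, truth = generate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_expression_matrix(matrix, OUT / "expression_linear.tsv")
    io.write_sample_sheet(sheet, OUT / "sample_sheet.tsv")
    (OUT / "truth.json").write_text(json.dumps({
        "seed": truth.seed,
        "marker_map": truth.marker_map,
        "universal_mirna": truth.universal_mirna,
        "hidden_mirnas": truth.hidden_mirnas,
        "hidden_weight": truth.hidden_weight,
        "mixture_weights": truth.mixture_weights,
        "disease_effects": truth.disease_effects.assign(
            cell_types=truth.disease_effects["cell_types"].map(list)
        ).to_dict(orient="records"),
    }, indent=2))
    print(f"cohort: {matrix.shape[0]} miRNAs x {matrix.shape[1]} samples "
          f"({len(sheet.donors)} donors), seed {SEED}")
    print(f"planted: {sum(len(v) for v in truth.marker_map.values())} markers, "
          f"{len(truth.disease_effects)} disease effects "
          f"(universal: {truth.universal_mirna}), "
          f"{len(truth.hidden_mirnas)} hidden-component miRNAs "
          f"(weight {truth.hidden_weight:.2f})")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
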