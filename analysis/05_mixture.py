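"""Whole blood as a linear function of the sorted subsets, per donor.

Per-donor OLS of the whole-blood log2 vector on the five subset vectors,
subset-vs-WB Pearson correlations, and presence/absence discordance — the
miRNAs whole blood shows that no sorted subset does (the hidden-compartment
footprint) and vice versa.
"""
import json

import pandas as pd

from _shared import COHORT, RESULTS, load_processed
from leukomir.mixture import (
    fit_wholeblood_model,
    presence_discordance,
    subset_wb_correlation,
)

OUT = RESULTS / "mixture"


def main() -> None:
    _, sheet, detection, log2m = load_processed()
    truth = json.loads((COHORT / "truth.json").read_text())
    OUT.mkdir(parents=True, exist_ok=True)

    fits = []
    for donor in sheet.donors:
        fit = fit_wholeblood_model(log2m, sheet, donor, detection=detection)
        fits.append({"donor": donor, "r_squared": fit.r_squared,
                     "intercept": fit.intercept, **fit.coefficients})
    fits = pd.DataFrame(fits)
    fits.to_csv(OUT / "mixture_fits.tsv", sep="\t", index=False)
    print(f"log2-scale OLS R^2 across donors: "
          f"{fits['r_squared'].min():.3f}-{fits['r_squared'].max():.3f} "
          "(log-scale fits are only approximate: mixing is linear in raw signal)")

    rho = subset_wb_correlation(log2m, sheet, detection=detection)
    rho.to_csv(OUT / "wb_correlations.tsv", sep="\t", index=False)
    print(f"subset-vs-WB Pearson rho band: "
          f"{rho['rho'].min():.2f} <= rho <= {rho['rho'].max():.2f}")

    rows = []
    hidden = set(truth["hidden_mirnas"])
    for cond in ("control", "cancer"):
        disc = presence_discordance(detection, sheet, cond)
        rows += [{"condition": cond, "kind": "wb_only", "mirna_id": m}
                 for m in sorted(disc.wb_only)]
        rows += [{"condition": cond, "kind": "subset_only", "mirna_id": m}
                 for m in sorted(disc.subset_only)]
        rec = len(disc.wb_only & hidden) / len(hidden)
        print(f"{cond}: {len(disc.wb_only)} miRNAs in all WB but no subset "
              f"sample (hidden-component recall {rec:.2f}); "
              f"{len(disc.subset_only)} in >90% of subsets but no WB sample")
    pd.DataFrame(rows, columns=["condition", "kind", "mirna_id"]).to_csv(
        OUT / "presence_discordance.tsv", sep="\t", index=False)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
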