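"""Unsupervised structure: top-variance miRNAs + complete-linkage clustering.

The 50 highest-variance miRNAs should cluster the sorted subsets perfectly by
cell type, and whole blood — a mixture plus hidden compartments — should sit
on its own branch when included.
"""
from _shared import RESULTS, load_processed
from leukomir.cluster import cluster_purity, hierarchical_cluster, top_variance_features
from leukomir.types import ExpressionMatrix, SUBSETS

OUT = RESULTS / "clustering"


def main() -> None:
    _, sheet, _, log2m = load_processed()
    OUT.mkdir(parents=True, exist_ok=True)
    feats = top_variance_features(log2m, 50)
    (OUT / "top50_mirnas.txt").write_text("\n".join(feats) + "\n")
    labels = dict(zip(sheet.table["sample_id"], sheet.table["cell_type"]))

    sub_ids = [s for ct in SUBSETS for s in sheet.samples(cell_type=ct)]
    dend = hierarchical_cluster(
        ExpressionMatrix(log2m.values.loc[feats, sub_ids], scale="log2"),
        axis="samples")
    (OUT / "subset_tree.nwk").write_text(dend.to_newick())
    purity = cluster_purity(dend, labels, 5)
    print(f"subset samples, 5-cluster cut: cell-type purity {purity:.3f}")

    dend_all = hierarchical_cluster(
        ExpressionMatrix(log2m.values.loc[feats], scale="log2"), axis="samples")
    (OUT / "all_samples_tree.nwk").write_text(dend_all.to_newick())
    cut2 = dend_all.cut(2)
    wb = set(sheet.samples(cell_type="WB"))
    wb_cl = {cut2[s] for s in wb}
    separate = len(wb_cl) == 1 and wb_cl.isdisjoint(
        {cut2[s] for s in cut2.index if s not in wb})
    print(f"all samples, 2-way cut: whole blood forms its own branch: {separate}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
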