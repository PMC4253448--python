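"""End-to-end orchestration: simulate/load -> preprocess -> differential ->
markers -> mixture -> classification -> clustering -> enrichment.

``run_pipeline`` is deterministic given the config and seed; the JSON summary
it writes records the config hash, the seed and every headline count so each
narrative number of the analysis has a named counterpart.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .classify import classification_table, loocv_svm
from .cluster import cluster_purity, hierarchical_cluster, top_variance_features
from .differential import build_union_report, select_candidates, two_group_t_test
from .enrichment import collect_targets, filter_by_coverage, ora_hypergeometric
from .mixture import fit_wholeblood_model, presence_discordance, subset_wb_correlation
from .preprocess import call_detection, detection_summary, normalize_and_log
from .specificity import (
    condition_overlap,
    derive_specific_sets,
    group_contrast,
    marker_sets_to_frame,
    pairwise_cell_tests,
)
from .simulate import SyntheticConfig, generate_annotations, generate_cohort
from .types import (
    CellTypeOntology,
    CELL_TYPES,
    ConfigError,
    SUBSETS,
)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the emulated study where it
    states a value (alpha 0.05, top-k 50, 20 LOOCV repetitions, 10%% ORA
    coverage)."""

    # inputs: either file paths or a synthetic cohort
    matrix_path: str | None = None
    sample_sheet_path: str | None = None
    target_map_path: str | None = None
    gmt_path: str | None = None
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    use_synthetic: bool = True
    # preprocessing
    detection_threshold: float = 0.0
    log2_floor: float = 1.0
    normalize_scope: str = "all"
    # statistics
    raw_alpha: float = 0.05
    adj_alpha: float = 0.05
    equal_var: bool = False
    # classification
    classify_mode: str = "as_published"
    n_repeats: int = 20
    # clustering
    top_k: int = 50
    linkage: str = "complete"
    # mixture
    mixture_mode: str = "ols"
    subset_fraction: float = 0.90
    # enrichment
    coverage_fraction: float = 0.10
    seed: int = 0
    out_dir: str = "results/pipeline"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``cfg.out_dir``.

    Returns the JSON summary as a dict.  Any stage failure aborts with the
    stage name prefixed to the error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": []}

    def stage(name):
        summary["stages"].append(name)
        return name

    # ---- inputs -----------------------------------------------------------
    stage("input")
    truth = None
    try:
        if cfg.use_synthetic:
            syn = SyntheticConfig(**{"seed": cfg.seed, **cfg.synthetic})
            matrix, sheet, truth = generate_cohort(syn)
        else:
            if not (cfg.matrix_path and cfg.sample_sheet_path):
                raise ConfigError("matrix_path and sample_sheet_path required "
                                  "when use_synthetic is false")
            matrix = io.read_expression_matrix(cfg.matrix_path)
            sheet = io.read_sample_sheet(cfg.sample_sheet_path)
        sheet.check_covers(matrix)
        if cfg.target_map_path and cfg.gmt_path:
            target_map = io.read_target_map(cfg.target_map_path)
            pathways = io.read_gmt(cfg.gmt_path)
        else:
            target_map, pathways = generate_annotations(matrix.mirna_ids, seed=cfg.seed)
    except Exception as exc:
        raise RuntimeError(f"stage 'input' failed: {exc}") from exc

    # ---- preprocess -------------------------------------------------------
    stage("preprocess")
    detection = call_detection(matrix, threshold=cfg.detection_threshold)
    log2m = normalize_and_log(matrix, sheet, scope=cfg.normalize_scope, floor=cfg.log2_floor)

    det_rows = []
    for ct in CELL_TYPES:
        for cond in ("control", "cancer"):
            ids = sheet.samples(cell_type=ct, condition=cond)
            if not ids:
                continue
            s = detection_summary(detection, ids)
            det_rows.append({"cell_type": ct, "condition": cond,
                             "n_any": s.n_any, "n_all": s.n_all})
    det_table = pd.DataFrame(det_rows)
    det_table.to_csv(out / "detection_summary.tsv", sep="\t", index=False)
    never = detection_summary(detection, matrix.sample_ids)
    summary["n_mirna"] = matrix.shape[0]
    summary["n_samples"] = matrix.shape[1]
    summary["n_never_detected"] = matrix.shape[0] - never.n_any
    summary["detection"] = det_rows

    # ---- condition contrasts + union report -------------------------------
    stage("differential")
    selected = {}
    for ct in CELL_TYPES:
        ctrl = sheet.samples(cell_type=ct, condition="control")
        canc = sheet.samples(cell_type=ct, condition="cancer")
        if len(ctrl) < 2 or len(canc) < 2:
            continue
        de = two_group_t_test(log2m, ctrl, canc, detection=detection,
                              equal_var=cfg.equal_var, group_a="control", group_b="cancer")
        de.table.to_csv(out / f"de_{ct}.tsv", sep="\t")
        selected[ct] = select_candidates(de, raw_alpha=cfg.raw_alpha)
    union = build_union_report(selected)
    union.to_csv(out / "union_report.tsv", sep="\t")
    summary["n_selected_per_contrast"] = {ct: int(len(s)) for ct, s in selected.items()}
    full_overlap = union.index[(union["overlaps"] == len(selected))].tolist()
    summary["mirnas_deregulated_in_all_contrasts"] = [x for x in full_overlap if x != "total"]

    # ---- cell-type-specific sets + grouped contrasts ----------------------
    stage("specificity")
    ontology = CellTypeOntology()
    collections = {}
    for cond in ("control", "cancer"):
        pairwise = pairwise_cell_tests(log2m, sheet, cond, equal_var=cfg.equal_var)
        collections[cond] = derive_specific_sets(pairwise, adj_alpha=cfg.adj_alpha,
                                                 condition=cond)
    marker_sets_to_frame(collections).to_csv(out / "marker_sets.tsv", sep="\t", index=False)
    summary["specific_set_sizes"] = {
        cond: {ct: len(s) for ct, s in coll.specific_sets.items()}
        for cond, coll in collections.items()}

    overlaps = {}
    for axis in CellTypeOntology.AXES:
        sig = {}
        for cond in ("control", "cancer"):
            de = group_contrast(log2m, sheet, ontology, axis, cond, detection,
                                adj_alpha=cfg.adj_alpha, equal_var=cfg.equal_var)
            sig[cond] = de.significant(cfg.adj_alpha)["direction"]
        ov = condition_overlap(sig["cancer"], sig["control"],
                               label_a="cancer", label_b="control")
        overlaps[axis] = {
            "n_cancer": len(sig["cancer"]), "n_control": len(sig["control"]),
            "shared_same_direction": len(ov.shared_same_direction),
            "shared_opposite_direction": len(ov.shared_opposite_direction),
            "exclusive_cancer": len(ov.exclusive_a),
            "exclusive_control": len(ov.exclusive_b),
        }
    summary["group_contrast_overlaps"] = overlaps

    # ---- whole-blood mixture ----------------------------------------------
    stage("mixture")
    fits = []
    for donor in sheet.donors:
        try:
            fit = fit_wholeblood_model(log2m, sheet, donor, mode=cfg.mixture_mode,
                                       detection=detection)
        except ConfigError:
            continue
        fits.append({"donor": donor, "r_squared": fit.r_squared,
                     "intercept": fit.intercept, **fit.coefficients})
    pd.DataFrame(fits).to_csv(out / "mixture_fits.tsv", sep="\t", index=False)
    rho = subset_wb_correlation(log2m, sheet, detection=detection)
    rho.to_csv(out / "wb_correlations.tsv", sep="\t", index=False)
    summary["rho_band"] = [float(rho["rho"].min()), float(rho["rho"].max())]
    disc_rows = []
    for cond in ("control", "cancer"):
        disc = presence_discordance(detection, sheet, cond,
                                    subset_fraction=cfg.subset_fraction)
        summary[f"wb_only_{cond}"] = sorted(disc.wb_only)
        summary[f"subset_only_{cond}"] = sorted(disc.subset_only)
        for mir in sorted(disc.wb_only):
            disc_rows.append({"condition": cond, "kind": "wb_only", "mirna_id": mir})
        for mir in sorted(disc.subset_only):
            disc_rows.append({"condition": cond, "kind": "subset_only", "mirna_id": mir})
    pd.DataFrame(disc_rows, columns=["condition", "kind", "mirna_id"]).to_csv(
        out / "presence_discordance.tsv", sep="\t", index=False)

    # ---- classification ----------------------------------------------------
    stage("classify")
    reports = []
    for ct in CELL_TYPES:
        try:
            reports.append(loocv_svm(log2m, sheet, ct, mode=cfg.classify_mode,
                                     detection=detection, raw_alpha=cfg.raw_alpha,
                                     n_repeats=cfg.n_repeats))
        except ConfigError:
            continue
    cls_table = classification_table(reports)
    cls_table.to_csv(out / "classification.tsv", sep="\t")
    summary["classification"] = {
        r.contrast: {"accuracy": r.accuracy_mean, "sensitivity": r.sensitivity_mean,
                     "specificity": r.specificity_mean} for r in reports}

    # ---- clustering --------------------------------------------------------
    stage("cluster")
    feats = top_variance_features(log2m, min(cfg.top_k, log2m.shape[0]))
    sub_samples = [s for ct in SUBSETS for s in sheet.samples(cell_type=ct)]
    dend_subsets = hierarchical_cluster(_restrict(log2m, feats, sub_samples),
                                        axis="samples", method=cfg.linkage)
    ct_labels = dict(zip(sheet.table["sample_id"], sheet.table["cell_type"]))
    purity_subsets = cluster_purity(dend_subsets, ct_labels, n_clusters=len(SUBSETS))
    dend_all = hierarchical_cluster(_restrict(log2m, feats, log2m.sample_ids),
                                    axis="samples", method=cfg.linkage)
    purity_all = cluster_purity(dend_all, ct_labels, n_clusters=len(CELL_TYPES))
    wb_ids = set(sheet.samples(cell_type="WB"))
    if wb_ids:
        cut2 = dend_all.cut(2)
        wb_clusters = {cut2[s] for s in wb_ids}
        other_clusters = {cut2[s] for s in cut2.index if s not in wb_ids}
        wb_branch = len(wb_clusters) == 1 and wb_clusters.isdisjoint(other_clusters)
    else:
        wb_branch = False
    summary["cluster_purity_subsets"] = purity_subsets
    summary["cluster_purity_all"] = purity_all
    summary["wb_separate_branch"] = wb_branch
    (out / "sample_tree.nwk").write_text(dend_all.to_newick())

    # ---- enrichment --------------------------------------------------------
    stage("enrichment")
    universe = collect_targets(set(matrix.mirna_ids), target_map).genes
    ora_counts = {}
    ora_frames = []
    for cond, coll in collections.items():
        for ct, mirnas in coll.specific_sets.items():
            if not mirnas:
                continue
            targets = collect_targets(mirnas, target_map).genes
            if not targets:
                continue
            res = ora_hypergeometric(targets, universe, pathways)
            kept = filter_by_coverage(res, cfg.coverage_fraction)
            kept = kept.assign(cell_type=ct, condition=cond)
            ora_frames.append(kept)
            ora_counts[f"{cond}:{ct}"] = int((kept["adj_p"] < cfg.adj_alpha).sum())
    if ora_frames:
        pd.concat(ora_frames).to_csv(out / "ora_results.tsv", sep="\t")
    summary["ora_significant_pathways"] = ora_counts

    # ---- truth-based recovery (synthetic runs only) ------------------------
    if truth is not None:
        stage("recovery")
        rec = {}
        expected = truth.expected_specific("control")
        found = collections["control"].specific_sets
        prec, recall = _precision_recall(found, expected)
        rec["marker_precision_control"] = prec
        rec["marker_recall_control"] = recall
        if truth.universal_mirna:
            hits = sum(truth.universal_mirna in s.index for s in selected.values())
            rec["universal_mirna_contrast_hits"] = int(hits)
            rec["universal_mirna_n_contrasts"] = len(selected)
        wb_only = set(summary["wb_only_control"])
        hidden = set(truth.hidden_mirnas)
        rec["hidden_recall"] = len(wb_only & hidden) / len(hidden) if hidden else float("nan")
        summary["recovery"] = rec

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary


def _restrict(m, mirna_ids, sample_ids):
    from .types import ExpressionMatrix
    return ExpressionMatrix(m.values.loc[mirna_ids, sample_ids].copy(), scale=m.scale)


def _precision_recall(found: dict[str, set[str]], expected: dict[str, set[str]]
                      ) -> tuple[float, float]:
    """Micro-averaged precision/recall of per-cell-type sets against truth."""
    tp = sum(len(found.get(ct, set()) & exp) for ct, exp in expected.items())
    n_found = sum(len(s) for s in found.values())
    n_exp = sum(len(s) for s in expected.values())
    precision = tp / n_found if n_found else float("nan")
    recall = tp / n_exp if n_exp else float("nan")
    return precision, recall
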