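"""One-command pipeline: matrix in, every stage's table out.

Stage order: (optional log2 transform) -> TcB + gene shift -> abacus
ordering -> stratification -> between-group DE for each configured pair ->
TcB-gene correlation screen -> (with a GMT) enrichment of the significant
high-vs-low genes and higher-order collapsing -> (with metadata) paired
shift classification or longitudinal course, depending on the number of
timepoints. Stages whose inputs are absent are skipped and logged; the
resolved configuration is written next to the outputs.
"""

from __future__ import annotations

import json
import logging
import os

import pandas as pd

from . import correlation as corr
from . import differential as de
from . import enrichment as enr
from . import io, stratify, trajectory, transform
from .config import RunConfig

log = logging.getLogger("tcburden")


def run_pipeline(
    config: RunConfig,
    matrix_path: str,
    out_dir: str,
    meta_path: str | None = None,
    gmt_path: str | None = None,
    catmap_path: str | None = None,
) -> dict:
    """Run every applicable stage; returns the output manifest (also written
    as ``manifest.json`` in ``out_dir``)."""
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"outputs": [], "skipped": [], "stages": {}}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(out_dir, name)
        io.write_table(df, path)
        manifest["outputs"].append(name)

    matrix = io.read_expression_matrix(matrix_path, scale=config.scale, orientation=config.orientation)
    log.info("loaded matrix: %d genes x %d samples (scale=%s)", matrix.n_genes, matrix.n_samples, matrix.scale)
    if matrix.scale == "raw":
        matrix = transform.log2_transform(matrix, pseudocount=config.pseudocount)
        log.info("log2-transformed with pseudocount %g", config.pseudocount)

    tcb = transform.compute_tcb(matrix, degenerate=config.degenerate)
    emit("tcb.tsv", tcb)
    gene_shift = transform.compute_gene_shift(matrix, degenerate=config.degenerate)
    emit("gene_shift.tsv", gene_shift)
    ordered = transform.abacus_order(matrix, tcb, gene_shift)
    io.write_expression_matrix(ordered, os.path.join(out_dir, "ordered_matrix.tsv"))
    manifest["outputs"].append("ordered_matrix.tsv")

    bands = config.bands_tuples()
    groups = stratify.assign_tcb_groups(tcb, bands=bands)
    emit("groups.tsv", groups)
    counts = stratify.group_counts(groups)
    manifest["stages"]["stratify"] = counts
    log.info("group counts: %s", counts)

    de_matrix = matrix
    if config.gene_shift_mode == "per_value":
        de_matrix = transform.median_shift_per_gene(matrix, degenerate=config.degenerate)
        log.info("per-value gene-shift mode: DE on min-max transformed matrix (fc threshold 0.25)")
    sig_high_low: list[str] = []
    for a, b in config.de_pairs:
        if counts.get(a, 0) < stratify.MIN_GROUP_SIZE or counts.get(b, 0) < stratify.MIN_GROUP_SIZE:
            manifest["skipped"].append(f"de_{b}_vs_{a}: group too small")
            log.info("skipping DE %s vs %s (group < %d)", b, a, stratify.MIN_GROUP_SIZE)
            continue
        table = de.between_group_de(
            de_matrix, groups, pair=(a, b), test=config.de_test,
            fc_threshold=config.de_fc, p_threshold=config.de_p, fdr_threshold=config.de_fdr,
        )
        emit(f"de_{b}_vs_{a}.tsv", table)
        n_sig = int(table["significant"].sum())
        manifest["stages"][f"de_{b}_vs_{a}"] = {"tested": len(table), "significant": n_sig}
        log.info("DE %s vs %s: %d genes tested, %d significant", b, a, len(table), n_sig)
        if (a, b) == ("low", "high") or (a, b) == ["low", "high"]:
            sig_high_low = table.loc[table["significant"], "gene_id"].tolist()

    records = corr.tcb_gene_correlation(matrix, tcb)
    records = corr.select_top_correlated(
        records, r_pos=config.corr_r_pos, r_neg=config.corr_r_neg,
        p_max=config.corr_p_max, top_n=config.corr_top_n,
    )
    emit("corr.tsv", records)
    pos, neg = corr.top_gene_lists(records)
    manifest["stages"]["correlation"] = {"positive_top": len(pos), "negative_top": len(neg)}

    if gmt_path:
        sets = io.read_gmt(gmt_path)
        if catmap_path:
            sets.category_map = io.read_category_map(catmap_path)
        if sig_high_low:
            enrich = enr.hypergeometric_enrichment(
                sig_high_low, matrix.gene_ids, sets,
                p_max=config.enrich_p_max, fdr_max=config.enrich_fdr_max,
                name_blacklist=tuple(config.enrich_blacklist),
            )
            emit("enrich.tsv", enrich)
            manifest["stages"]["enrichment"] = {"sets_tested": len(enrich),
                                                "significant": int(enrich["significant"].sum())}
        else:
            manifest["skipped"].append("enrichment: no significant high-vs-low genes")
        if sets.category_map:
            try:
                summary = enr.collapse_to_higher_order(matrix, sets, groups)
                ho = summary.group_medians.reset_index()
                emit("higher_order.tsv", ho)
                emit("higher_order_sample_means.tsv", summary.sample_means.reset_index())
            except Exception as exc:  # noqa: BLE001 - stage is optional
                manifest["skipped"].append(f"higher_order: {exc}")
    else:
        manifest["skipped"].append("enrichment: no GMT supplied")

    if meta_path:
        metadata = io.read_sample_table(meta_path, timepoint_order=config.timepoint_order or None)
        n_tp = len(metadata.timepoint_order)
        if n_tp == 2:
            shifts = trajectory.paired_tcb_shift(tcb, metadata, bands=bands)
            emit("shifts.tsv", shifts)
            manifest["stages"]["paired_shift"] = {
                "subjects": len(shifts), "shifted": int(shifts["shifted"].sum())}
            if gmt_path:
                sets = io.read_gmt(gmt_path)
                if catmap_path:
                    sets.category_map = io.read_category_map(catmap_path)
                if sets.category_map:
                    fc = trajectory.directional_foldchange(matrix, metadata, shifts, sets)
                    emit("directional_fc.tsv", fc)
        elif n_tp > 2:
            course, density = trajectory.longitudinal_course(
                matrix, metadata, grid_size=config.kde_grid_size,
                bandwidth=config.kde_bandwidth, degenerate=config.degenerate,
            )
            emit("course.tsv", course)
            emit("gene_shift_density.tsv", density)
            manifest["stages"]["longitudinal"] = {"subjects": course["subject_id"].nunique()}
    else:
        manifest["skipped"].append("trajectory: no metadata supplied")

    config.to_yaml(os.path.join(out_dir, "run_config.yaml"))
    manifest["outputs"].append("run_config.yaml")
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
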