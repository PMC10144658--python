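"""End-to-end orchestration: from count + metadata tables to result TSVs.

Stages: sample intersection -> rarefaction -> alpha diversity -> clr /
Aitchison beta diversity -> genus filter -> co-abundance network and
coops -> parameter de-duplication -> association screens (alpha, beta,
coop balances, per-rank clr taxa) with BH-FDR per parameter group x
feature family -> nearest-balance cross-validation for factors linked to
beta diversity. All randomness derives from ``config.seed``; the same
config and inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .associations import (
    alpha_assoc,
    attach_fdr,
    coop_balance_assoc,
    dedup_parameters,
    permutation_beta_test,
    taxon_clr_assoc,
)
from .composition import (
    aitchison_distance,
    chao1,
    clr_transform,
    pcoa_biplot,
    rarefy,
    shannon,
)
from .coop_network import filter_genera, infer_network, louvain_coops
from .datatypes import AnalysisConfig, AssociationResult, CountTable, SampleMetadata
from .io import (
    aggregate_to_rank,
    available_ranks,
    intersect_samples,
    read_count_table,
    read_metadata,
)
from .nb import cross_validated_balance

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in results]
    cols = ["feature", "feature_type", "factor", "parameter_group",
            "statistic", "r2", "p", "q", "n"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(
    config: AnalysisConfig,
    count_path: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path,
    count_format: str = "tsv",
    group_spec: dict[str, str] | None = None,
    nb_factors: list[str] | str = "auto",
) -> dict:
    """Run the full analysis and write result tables under ``out_dir``.

    ``nb_factors``: "auto" runs nearest-balance cross-validation for every
    parameter whose beta-diversity FDR falls below ``config.fdr_alpha``;
    a list names the factors explicitly.

    Returns a summary dict (also written as ``run_log.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = read_count_table(count_path, format=count_format)
    meta = read_metadata(metadata_path, group_spec)
    return run_pipeline_objects(config, counts, meta, out, nb_factors=nb_factors)


def run_pipeline_objects(
    config: AnalysisConfig,
    counts: CountTable,
    meta: SampleMetadata,
    out: Path | None = None,
    nb_factors: list[str] | str = "auto",
) -> dict:
    if out is not None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
    n_before = len(counts.sample_ids) + len(meta.sample_ids)
    counts, meta = intersect_samples(counts, meta)
    n_dropped = n_before - 2 * len(counts.sample_ids)

    # --- diversity ------------------------------------------------------
    rarefied = rarefy(counts, config.rarefaction_depth, seed=config.seed)
    depth = int(rarefied.sample_sums()[0])
    div = shannon(rarefied, rarefaction_depth=depth)
    div.metrics["chao1"] = chao1(rarefied, rarefaction_depth=depth).metrics["chao1"]
    clr_all = clr_transform(rarefied, config.pseudocount)
    dist = aitchison_distance(clr_all)
    ordination = pcoa_biplot(dist, clr_all)

    # --- network & coops ------------------------------------------------
    filtered = filter_genera(rarefied, config.min_reads, config.min_samples)
    clr_filtered = clr_transform(filtered, config.pseudocount)
    graph = infer_network(clr_filtered, config)
    rel = filtered.counts / filtered.sample_sums()[:, None]
    mean_abund = dict(zip(filtered.taxon_ids, rel.mean(axis=0)))
    coops = louvain_coops(graph, mean_abund, config)

    # --- per-rank tables for the taxon clr screen -----------------------
    rank_clr = {}
    for rank in available_ranks(rarefied):
        agg = aggregate_to_rank(rarefied, rank)
        if len(agg.taxon_ids) >= 2:
            rank_clr[rank] = clr_transform(agg, config.pseudocount)

    # --- parameter screens ----------------------------------------------
    screens = {
        g: dedup_parameters(meta, g, config.dedup_rho) for g in meta.groups
    }
    results: list[AssociationResult] = []
    group_series = meta.group_label.astype(str)

    def run_factor(factor: pd.Series, fname: str, pgroup: str) -> None:
        for metric in ("shannon", "chao1"):
            results.append(alpha_assoc(div, factor, metric, fname, pgroup))
        results.append(
            permutation_beta_test(
                dist, factor, config.n_permutations, config.seed, fname, pgroup
            )
        )
        results.extend(
            coop_balance_assoc(clr_filtered, coops, factor, fname, pgroup)
        )
        for rank in sorted(rank_clr):
            results.extend(
                taxon_clr_assoc(rank_clr[rank], factor, fname, pgroup, rank)
            )

    # study-group comparison (categorical)
    if group_series.nunique() > 1:
        run_factor(group_series, "group", "study_design")
    for g in sorted(screens):
        for p in screens[g].retained:
            try:
                run_factor(meta.parameters[p], p, g)
            except ValueError as e:
                logger.warning("factor %s skipped: %s", p, e)
    attach_fdr(results)
    res_df = _results_frame(results)

    # --- nearest balance -------------------------------------------------
    if nb_factors == "auto":
        beta_hits = res_df[
            (res_df.feature_type == "beta")
            & (res_df.parameter_group != "study_design")
            & (res_df.q < config.fdr_alpha)
        ]
        nb_list = sorted(beta_hits.factor.unique())
    else:
        nb_list = list(nb_factors)
    nb_results = {}
    for fname in nb_list:
        if fname not in meta.parameters.columns:
            logger.warning("nearest-balance factor %r not in metadata; skipped", fname)
            continue
        rb = cross_validated_balance(
            clr_filtered, meta.parameters[fname], config, fname
        )
        nb_results[fname] = rb

    # --- outputs ----------------------------------------------------------
    summary = {
        "package_version": __version__,
        "config": config.to_dict(),
        "n_samples": len(counts.sample_ids),
        "n_dropped_unmatched": n_dropped,
        "rarefaction_depth": depth,
        "n_genera_filtered": len(filtered.taxon_ids),
        "coops": {k: sorted(v) for k, v in coops.communities.items()},
        "n_singletons": len(coops.singletons),
        "network_lambda": graph.graph.get("lambda"),
        "dedup": {
            g: {"retained": s.retained, "dropped": s.dropped}
            for g, s in screens.items()
        },
        "nb_factors": sorted(nb_results),
        "nb_empty": sorted(f for f, rb in nb_results.items() if rb.is_empty),
    }
    if out is not None:
        _write_tsv(
            div.metrics.reset_index(names="sample_id"), out / "alpha_diversity.tsv"
        )
        for ftype, fname in (
            ("alpha", "alpha_associations.tsv"),
            ("beta", "beta_associations.tsv"),
            ("taxon_clr", "taxon_clr_associations.tsv"),
        ):
            _write_tsv(
                res_df[res_df.feature_type == ftype], out / fname
            )
        coop_df = res_df[res_df.feature_type == "coop"].rename(
            columns={"feature": "coop", "statistic": "coefficient", "q": "FDR"}
        )[["coop", "factor", "parameter_group", "coefficient", "p", "FDR", "n"]]
        _write_tsv(coop_df, out / "coop_balance_associations.tsv")
        edges = pd.DataFrame(
            [
                {"genus_a": a, "genus_b": b, "stability": w}
                for a, b, w in sorted(graph.edges.data("stability"))
            ],
            columns=["genus_a", "genus_b", "stability"],
        )
        _write_tsv(edges, out / "network_edges.tsv")
        coop_members = pd.DataFrame(
            [
                {"coop": k, "genus": g}
                for k in coops.coop_names
                for g in sorted(coops.communities[k])
            ],
            columns=["coop", "genus"],
        )
        _write_tsv(coop_members, out / "coop_membership.tsv")
        coords = pd.DataFrame(
            ordination.coordinates,
            columns=[f"PCo{i + 1}" for i in range(ordination.coordinates.shape[1])],
        )
        coords.insert(0, "sample_id", ordination.sample_ids)
        _write_tsv(coords, out / "pcoa_coordinates.tsv")
        for fname, rb in sorted(nb_results.items()):
            _write_tsv(
                rb.membership_table(), out / f"nearest_balance_{fname}.tsv"
            )
        (out / "run_log.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        _write_tsv(res_df, out / "all_associations.tsv")
    summary["results"] = res_df
    summary["nearest_balances"] = nb_results
    summary["ordination"] = ordination
    summary["coop_partition"] = coops
    return summary
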