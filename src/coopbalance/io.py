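"""Readers and writers for count tables (TSV, BIOM v1 JSON) and metadata.

TSV dialect: taxa as rows, samples as columns, first column the taxon id,
optional last column ``lineage`` holding either "k__...;p__...;..." QIIME-style
prefixed ranks or a plain semicolon-delimited kingdom-to-species path.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import RANKS, CountTable, SampleMetadata, ValidationError

logger = logging.getLogger(__name__)

_PREFIX_TO_RANK = {
    "k": "kingdom", "d": "kingdom", "p": "phylum", "c": "class",
    "o": "order", "f": "family", "g": "genus", "s": "species",
}
_UNCLASSIFIED = {"", "unclassified", "na", "none", "__"}


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a lineage string into a rank -> clade-name map.

    Handles "k__Bacteria; p__Firmicutes" prefixed tokens and plain
    semicolon paths (assigned to ranks in kingdom..species order). Empty or
    "unclassified" tokens are dropped, leaving the rank absent.
    """
    out: dict[str, str] = {}
    tokens = [t.strip() for t in str(lineage).split(";")]
    prefixed = any(len(t) > 2 and t[1:3] == "__" for t in tokens if t)
    for i, tok in enumerate(tokens):
        if not tok:
            continue
        if prefixed:
            if len(tok) > 1 and tok[1:3] == "__":
                rank = _PREFIX_TO_RANK.get(tok[0].lower())
                name = tok[3:].strip()
            else:
                continue
        else:
            rank = RANKS[i] if i < len(RANKS) else None
            name = tok
        if rank and name.lower() not in _UNCLASSIFIED:
            out[rank] = name
    return out


def format_lineage(lineage: Mapping[str, str]) -> str:
    parts = []
    for rank in RANKS:
        if rank in lineage:
            prefix = "k" if rank == "kingdom" else rank[0]
            parts.append(f"{prefix}__{lineage[rank]}")
    return ";".join(parts)


# ---------------------------------------------------------------------------
# count tables


def read_count_table(path: str | Path, format: str = "tsv") -> CountTable:
    """Read a taxon-count table from ``tsv`` or ``biom-json``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_counts_tsv(path)
    if format == "biom-json":
        return _read_counts_biom(path)
    raise ValueError(f"unknown count-table format: {format!r}")


def _read_counts_tsv(path: Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    lineages: dict[str, dict[str, str]] = {}
    if df.columns.size and df.columns[-1].lower() == "lineage":
        lineages = {
            str(t): parse_lineage(v) if pd.notna(v) else {}
            for t, v in df.iloc[:, -1].items()
        }
        df = df.iloc[:, :-1]
    taxon_ids = [str(t) for t in df.index]
    sample_ids = [str(s) for s in df.columns]
    try:
        counts = df.to_numpy(dtype=float)
    except ValueError:
        for t, row in df.iterrows():
            for s, v in row.items():
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"non-numeric count {v!r} at taxon {t!r}, sample {s!r}"
                    ) from None
        raise
    # taxa are rows on disk; in memory samples are rows
    return CountTable(sample_ids, taxon_ids, counts.T, lineages)


def write_count_table(t: CountTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(t.counts.T, index=t.taxon_ids, columns=t.sample_ids)
        df.index.name = "taxon_id"
        df["lineage"] = [format_lineage(t.lineages[tax]) for tax in t.taxon_ids]
        df.to_csv(path, sep="\t")
    elif format == "biom-json":
        rows_idx, cols_idx = np.nonzero(t.counts.T)
        data = [
            [int(r), int(c), int(t.counts.T[r, c])]
            for r, c in zip(rows_idx.tolist(), cols_idx.tolist())
        ]
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "coopbalance",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [len(t.taxon_ids), len(t.sample_ids)],
            "rows": [
                {
                    "id": tax,
                    "metadata": {
                        "taxonomy": [t.lineages[tax].get(r, "") for r in RANKS]
                    },
                }
                for tax in t.taxon_ids
            ],
            "columns": [{"id": s, "metadata": None} for s in t.sample_ids],
            "data": data,
        }
        path.write_text(json.dumps(doc))
    else:
        raise ValueError(f"unknown count-table format: {format!r}")


def _read_counts_biom(path: Path) -> CountTable:
    doc = json.loads(Path(path).read_text())
    n_taxa, n_samples = doc["shape"]
    taxon_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    counts = np.zeros((n_samples, n_taxa), dtype=np.int64)
    if doc.get("matrix_type") == "dense":
        counts = np.asarray(doc["data"], dtype=np.int64).T
    else:
        for r, c, v in doc["data"]:
            counts[int(c), int(r)] = int(v)
    lineages = {}
    for r in doc["rows"]:
        meta = r.get("metadata") or {}
        taxonomy = meta.get("taxonomy") or []
        lineages[str(r["id"])] = {
            rank: name
            for rank, name in zip(RANKS, taxonomy)
            if name and str(name).lower() not in _UNCLASSIFIED
        }
    return CountTable(sample_ids, taxon_ids, counts, lineages)


# ---------------------------------------------------------------------------
# metadata


def read_metadata(
    path: str | Path,
    group_spec: Mapping[str, str] | None = None,
    group_column: str = "group",
) -> SampleMetadata:
    """Read a tab-separated sample metadata table.

    One row per sample (first column = sample id); ``group_column`` holds
    the categorical label; every other column is coerced to float with
    empty/"NA" as missing. ``group_spec`` maps parameter names to parameter
    groups; unmapped parameters land in "ungrouped" with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""], dtype=str)
    df.index = df.index.astype(str)
    group_spec = dict(group_spec or {})
    if group_column in df.columns:
        group_label = df[group_column].astype(str)
        df = df.drop(columns=[group_column])
    else:
        group_label = pd.Series("all", index=df.index)
    params = df.apply(pd.to_numeric, errors="coerce").astype(float)
    missing_from_file = sorted(set(group_spec) - set(params.columns))
    for p in missing_from_file:
        logger.warning("parameter %r in group_spec but absent from %s; skipped", p, path)
        group_spec.pop(p)
    unmapped = sorted(set(params.columns) - set(group_spec))
    if unmapped:
        logger.warning("parameters without group mapping assigned 'ungrouped': %s", unmapped)
    return SampleMetadata(
        list(df.index),
        group_label,
        params,
        {p: group_spec.get(p, "ungrouped") for p in params.columns},
    )


def write_metadata(m: SampleMetadata, path: str | Path, group_column: str = "group") -> None:
    df = m.parameters.copy()
    df.insert(0, group_column, m.group_label)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def write_group_spec(m: SampleMetadata, path: str | Path) -> None:
    Path(path).write_text(json.dumps(m.parameter_groups, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# rank aggregation


def aggregate_to_rank(t: CountTable, rank: str) -> CountTable:
    """Sum counts of taxa sharing the lineage prefix down to ``rank``.

    Taxa unclassified at ``rank`` are pooled under their deepest classified
    ancestor as ``unclassified_<ancestor>``; per-sample totals are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank)
    groups: dict[tuple, list[int]] = {}
    group_lineage: dict[tuple, dict[str, str]] = {}
    group_name: dict[tuple, str] = {}
    for j, tax in enumerate(t.taxon_ids):
        lin = t.lineages[tax]
        prefix = tuple(lin.get(r, None) for r in RANKS[: depth + 1])
        if prefix[-1] is None:
            # pool under deepest classified ancestor
            classified = [lin[r] for r in RANKS[: depth + 1] if lin.get(r)]
            anchor = classified[-1] if classified else "root"
            prefix = tuple(classified) + ("__unclassified__",)
            name = f"unclassified_{anchor}"
            lineage = {r: lin[r] for r in RANKS[: depth + 1] if lin.get(r)}
        else:
            name = prefix[-1]
            lineage = {
                r: v for r, v in zip(RANKS[: depth + 1], prefix) if v is not None
            }
        groups.setdefault(prefix, []).append(j)
        group_lineage[prefix] = lineage
        group_name[prefix] = name
    # disambiguate same name under different higher lineages
    names_seen: dict[str, int] = {}
    ordered = sorted(groups, key=lambda k: tuple(x or "" for x in k))
    out_ids, out_cols, out_lineages = [], [], {}
    for key in ordered:
        base = group_name[key]
        n_prev = names_seen.get(base, 0)
        names_seen[base] = n_prev + 1
        name = base if n_prev == 0 else f"{base}_{n_prev + 1}"
        out_ids.append(name)
        out_cols.append(t.counts[:, groups[key]].sum(axis=1))
        out_lineages[name] = group_lineage[key]
    counts = np.column_stack(out_cols) if out_cols else np.zeros((len(t.sample_ids), 0), int)
    return CountTable(list(t.sample_ids), out_ids, counts, out_lineages)


def available_ranks(t: CountTable) -> list[str]:
    """Ranks at which at least one taxon is classified, coarse to fine."""
    present = set()
    for lin in t.lineages.values():
        present.update(lin)
    return [r for r in RANKS if r in present]


def intersect_samples(
    t: CountTable, m: SampleMetadata
) -> tuple[CountTable, SampleMetadata]:
    """Restrict both tables to shared samples, sorted by id (order-stable)."""
    shared = sorted(set(t.sample_ids) & set(m.sample_ids))
    if not shared:
        raise ValidationError("no samples shared between counts and metadata")
    dropped = (len(t.sample_ids) - len(shared)) + (len(m.sample_ids) - len(shared))
    if dropped:
        logger.info("dropped %d samples present in only one input", dropped)
    return t.select_samples(shared), m.select_samples(shared)
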