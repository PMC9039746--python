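"""Readers, writers, and the standard OTU-table cleaning rules.

File formats are deliberately plain: tab-separated tables with one header
row (OTU table, taxonomy, metadata) and newick for trees.  Writers mirror
readers so that write -> parse round-trips are exact.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .datatypes import (
    LINEAGE_RANKS,
    OtuTable,
    Phylogeny,
    SalinetError,
    SampleMetadata,
    TaxonomyTable,
)

#: Lineage labels whose OTUs are removed outright (multicellular animals
#: and land plants are not part of the microeukaryotic community).
EXCLUDED_LINEAGES = ("metazoa", "streptophyta")


def _check_header_duplicates(path: str | Path) -> list[str]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    body = header[1:]
    dups = sorted({h for h in body if body.count(h) > 1})
    if dups:
        raise SalinetError(f"duplicate column ids in {path}: {dups}")
    return header


def parse_otu_table(path: str | Path, orientation: str = "otus_as_rows") -> OtuTable:
    """Read a tab-separated abundance table.

    ``orientation`` declares what the rows are: ``"otus_as_rows"`` (the
    common amplicon convention, default) or ``"samples_as_rows"``.  The
    returned table is always samples x OTUs.  Orientation is never
    auto-detected; silent transposition is worse than an explicit flag.
    """
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise SalinetError(f"unknown orientation {orientation!r}")
    _check_header_duplicates(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise SalinetError(f"duplicate row ids in {path}: {dups}")
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad][0]
            raise SalinetError(f"non-numeric cell in {path} at row {row!r}, column {col!r}")
        if converted.isna().any():
            row = raw.index[converted.isna()][0]
            raise SalinetError(f"missing cell in {path} at row {row!r}, column {col!r}")
        numeric[col] = converted
    if orientation == "otus_as_rows":
        numeric = numeric.T
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return OtuTable(numeric)


def write_otu_table(table: OtuTable, path: str | Path, orientation: str = "otus_as_rows") -> None:
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise SalinetError(f"unknown orientation {orientation!r}")
    out = table.counts.T if orientation == "otus_as_rows" else table.counts
    label = "otu_id" if orientation == "otus_as_rows" else "sample_id"
    out.to_csv(path, sep="\t", index_label=label)


def parse_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a taxonomy TSV with columns otu_id, lineage, functional_group.

    ``lineage`` is semicolon-delimited, kingdom to genus; short lineages
    are right-padded with ``"unclassified"``.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("otu_id", "lineage", "functional_group"):
        if col not in raw.columns:
            raise SalinetError(f"taxonomy file {path} missing column {col!r}")
    rows = {}
    for _, rec in raw.iterrows():
        parts = [p.strip() for p in str(rec["lineage"]).split(";")]
        parts = (parts + ["unclassified"] * len(LINEAGE_RANKS))[: len(LINEAGE_RANKS)]
        rows[rec["otu_id"]] = {
            **dict(zip(LINEAGE_RANKS, parts)),
            "functional_group": rec["functional_group"],
        }
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.index.name = "otu_id"
    return TaxonomyTable(data)


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "otu_id": taxonomy.data.index,
            "lineage": taxonomy.lineage_strings().to_numpy(),
            "functional_group": taxonomy.data["functional_group"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def parse_metadata(path: str | Path) -> SampleMetadata:
    """Read per-sample metadata; first column is the sample id."""
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    return SampleMetadata(raw)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.data.to_csv(path, sep="\t", index_label="sample_id")


def parse_tree(path: str | Path) -> Phylogeny:
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return Phylogeny(tree)


def write_tree(phylogeny: Phylogeny, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            phylogeny.tree.as_string(
                schema="newick", suppress_rooting=True, unquoted_underscores=True
            )
        )


def filter_otus(table: OtuTable, taxonomy: TaxonomyTable, min_occupancy: int = 2) -> OtuTable:
    """Apply the standard amplicon cleaning rules.

    Removes OTUs present (count > 0) in fewer than ``min_occupancy``
    samples (singleton-sample OTUs inflate diversity) and OTUs whose
    lineage contains Metazoa or Streptophyta at any rank
    (case-insensitive substring match).  Samples are never dropped.
    """
    taxonomy.require_covers(table.otu_ids)
    occupancy = table.occupancy()
    lineages = taxonomy.lineage_strings().str.lower()
    keep = []
    for otu in table.otu_ids:
        if occupancy[otu] < min_occupancy:
            continue
        lineage = lineages[otu]
        if any(label in lineage for label in EXCLUDED_LINEAGES):
            continue
        keep.append(otu)
    return table.select_otus(keep)


def percent(part: float, whole: float, decimals: int = 2) -> float:
    """Percentage ``100 * part / whole`` rounded to ``decimals`` places."""
    if whole == 0:
        raise SalinetError("zero denominator in percentage")
    return round(100.0 * part / whole, decimals)


def group_composition_summary(
    table: OtuTable, taxonomy: TaxonomyTable, total_sequences: int | None = None
) -> pd.DataFrame:
    """Per-functional-group OTU and sequence counts with percentages.

    OTU percentages use the table's total OTU count as denominator
    (unassigned OTUs stay in the denominator); sequence percentages use
    ``total_sequences`` (defaults to the table's grand total, but the
    total high-quality sequence count may be passed when the table has
    been filtered).
    """
    taxonomy.require_covers(table.otu_ids)
    if total_sequences is None:
        total_sequences = int(table.counts.to_numpy().sum())
    total_otus = table.n_otus
    if total_otus == 0 or total_sequences == 0:
        raise SalinetError("empty table: zero denominator in composition summary")
    groups = taxonomy.data.loc[table.otu_ids, "functional_group"]
    seq_totals = table.counts.sum(axis=0)
    rows = []
    for group in sorted(groups.unique()):
        otus = groups.index[groups == group]
        n_seq = int(seq_totals[otus].sum())
        rows.append(
            {
                "group": group,
                "otu_count": len(otus),
                "otu_pct": percent(len(otus), total_otus),
                "seq_count": n_seq,
                "seq_pct": percent(n_seq, total_sequences),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def warn(message: str) -> None:
    warnings.warn(message, UserWarning, stacklevel=2)
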