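"""Readers and writers for the package's tabular formats.

Supported formats: GMT gene-set collections, tab-delimited assay matrices
(first column = measure name, remaining columns = patient IDs), the patient
metadata table (mandatory ``ID`` and ``STATUS`` columns, extra columns kept
as clinical variables), genomic interval tables (1-based closed internally;
BED accepted at the boundary and converted), square gene-interaction
matrices, and the edge-list serialization defined in
:mod:`psnet.similarity`.

All readers reject malformed rows with the offending line/row number rather
than silently coercing them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .dataset import CLINICAL_LAYER, PatientDataset, ValidationError, dedupe_patients

__all__ = [
    "GmtFilterParams",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "read_intervals",
    "write_intervals",
    "map_intervals_to_sets",
    "events_by_patient",
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "load_dataset",
    "read_interaction_network",
]


@dataclass
class GmtFilterParams:
    """Gene-set size filter applied at read time (sizes after within-set
    deduplication)."""

    min_size: int = 10
    max_size: int = 200

    def __post_init__(self) -> None:
        if self.min_size > self.max_size:
            raise ValidationError("min_size must be <= max_size", field="min_size")


@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, genes)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def as_dict(self) -> dict[str, list[str]]:
        return {nm: genes for nm, (_, genes) in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


def read_gmt(
    path, filter: GmtFilterParams | None = None
) -> tuple[GeneSetCollection, dict[str, int]]:
    """Parse a GMT file; returns the collection and a filter report.

    Each line is ``name <TAB> description <TAB> gene1 <TAB> gene2 ...``.
    Genes are deduplicated within a set (first occurrence kept); sets whose
    deduplicated size falls outside ``[min_size, max_size]`` are dropped.
    The report holds ``read`` / ``kept`` / ``excluded`` counts.
    """
    filter = filter or GmtFilterParams()
    coll = GeneSetCollection()
    seen: set[str] = set()
    n_read = n_kept = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{ln}: GMT line has {len(parts)} field(s); need >= 3",
                    field="gmt",
                )
            name, desc = parts[0], parts[1]
            if name in seen:
                raise ValidationError(
                    f"{path}:{ln}: duplicate set name {name!r}", field="gmt"
                )
            seen.add(name)
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            n_read += 1
            if filter.min_size <= len(genes) <= filter.max_size:
                coll.sets[name] = (desc, genes)
                n_kept += 1
    return coll, {"read": n_read, "kept": n_kept, "excluded": n_read - n_kept}


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in coll.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


_INTERVAL_COLS = ["chrom", "start", "end", "patient", "genes"]


def read_intervals(path, dialect: str = "onebased_closed") -> pd.DataFrame:
    """Read a genomic event table into 1-based closed coordinates.

    The tabular dialect expects a header with columns chrom/start/end and
    optionally patient and genes (comma-separated symbols); common aliases
    (``seqnames``, ``ID``, ``Gene_symbols``) are accepted.  The ``bed``
    dialect is headerless BED3+ with optional 4th (patient) and 5th (genes)
    columns, converted from 0-based half-open to 1-based closed.
    """
    if dialect not in ("onebased_closed", "bed"):
        raise ValidationError(f"unknown dialect {dialect!r}", field="dialect")
    if dialect == "bed":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] < 3:
            raise ValidationError("BED needs at least 3 columns", field="bed")
        df = df.iloc[:, :5]
        df.columns = _INTERVAL_COLS[: df.shape[1]]
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        alias = {"seqnames": "chrom", "ID": "patient", "id": "patient",
                 "Gene_symbols": "genes", "gene": "genes"}
        df = df.rename(columns=alias)
        missing = [c for c in ("chrom", "start", "end") if c not in df.columns]
        if missing:
            raise ValidationError(f"missing columns {missing}", field="intervals")
    for c in _INTERVAL_COLS:
        if c not in df.columns:
            df[c] = ""
    out_rows = []
    for i, row in df.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"row {i + 1}: malformed coordinates "
                f"({row['start']!r}, {row['end']!r})",
                field="intervals",
            )
        if dialect == "bed":
            start += 1  # 0-based half-open -> 1-based closed
        if not str(row["chrom"]):
            raise ValidationError(f"row {i + 1}: empty chrom", field="intervals")
        if start > end:
            raise ValidationError(
                f"row {i + 1}: start {start} > end {end}", field="intervals"
            )
        out_rows.append(
            {
                "chrom": str(row["chrom"]),
                "start": start,
                "end": end,
                "patient": str(row["patient"]) if pd.notna(row["patient"]) else "",
                "genes": str(row["genes"]) if pd.notna(row["genes"]) else "",
            }
        )
    return pd.DataFrame(out_rows, columns=_INTERVAL_COLS)


def write_intervals(df: pd.DataFrame, path, dialect: str = "onebased_closed") -> None:
    out = df.copy()
    if dialect == "bed":
        out["start"] = out["start"].astype(int) - 1
        out.to_csv(path, sep="\t", header=False, index=False)
    else:
        out.to_csv(path, sep="\t", index=False)


def map_intervals_to_sets(
    intervals: pd.DataFrame,
    gene_extents: pd.DataFrame,
    sets: GeneSetCollection | Mapping[str, list[str]],
) -> dict[str, dict[str, int]]:
    """Per-patient event counts per gene set.

    ``gene_extents`` holds one row per gene (columns chrom/start/end plus a
    ``gene`` column or the gene name in ``genes``).  An interval hits a gene
    when they overlap by >= 1 base on the same chromosome (closed-interval
    arithmetic, strand ignored); a patient has an event in a set when any of
    their intervals hits any of the set's covered genes.  Set genes without
    extents are ignored with a warning.
    """
    import warnings

    set_map = sets.as_dict() if isinstance(sets, GeneSetCollection) else dict(sets)
    gene_col = "gene" if "gene" in gene_extents.columns else "genes"
    trees: dict[str, IntervalTree] = {}
    covered: set[str] = set()
    for _, row in gene_extents.iterrows():
        g = str(row[gene_col])
        covered.add(g)
        # closed [s, e] -> half-open [s, e+1) for the tree
        trees.setdefault(str(row["chrom"]), IntervalTree()).addi(
            int(row["start"]), int(row["end"]) + 1, g
        )
    uncovered = {g for genes in set_map.values() for g in genes} - covered
    if uncovered:
        warnings.warn(
            f"{len(uncovered)} gene(s) in sets have no extent and are ignored "
            f"(e.g. {sorted(uncovered)[0]!r})"
        )
    gene_to_sets: dict[str, list[str]] = {}
    for nm, genes in set_map.items():
        for g in genes:
            gene_to_sets.setdefault(g, []).append(nm)

    counts: dict[str, dict[str, int]] = {}
    for _, row in intervals.iterrows():
        pat = str(row["patient"])
        tree = trees.get(str(row["chrom"]))
        if tree is None:
            counts.setdefault(pat, {})
            continue
        hits = tree.overlap(int(row["start"]), int(row["end"]) + 1)
        pat_counts = counts.setdefault(pat, {})
        hit_sets = {nm for iv in hits for nm in gene_to_sets.get(iv.data, ())}
        for nm in hit_sets:
            pat_counts[nm] = pat_counts.get(nm, 0) + 1
    return counts


def events_by_patient(intervals: pd.DataFrame) -> dict[str, set[str]]:
    """Collapse an interval table to patient -> set of annotated gene symbols."""
    out: dict[str, set[str]] = {}
    for _, row in intervals.iterrows():
        genes = {g for g in str(row["genes"]).replace(";", ",").split(",") if g}
        out.setdefault(str(row["patient"]), set()).update(genes)
    return out


def read_matrix(path) -> pd.DataFrame:
    """Tab-delimited assay matrix: first column = measure name, header =
    patient IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.map(str)
    df.index = df.index.map(str)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Patient metadata table with mandatory ID and STATUS columns."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ID", "STATUS"):
        if col not in meta.columns:
            raise ValidationError(f"metadata is missing column {col!r}", field=col)
    return meta


def load_dataset(
    meta_path, assay_paths: Mapping[str, str], dedupe: bool = False
) -> PatientDataset:
    """Assemble a :class:`PatientDataset` from files.

    Extra metadata columns become rows of the reserved ``clinical`` layer
    (numeric coercion; non-numeric columns are dropped with a warning).
    """
    import warnings

    meta = read_metadata(meta_path)
    if dedupe:
        meta = dedupe_patients(meta)
    ids = meta["ID"].tolist()
    labels = dict(zip(meta["ID"], meta["STATUS"]))
    assays = {name: read_matrix(p) for name, p in assay_paths.items()}
    extra = [c for c in meta.columns if c not in ("ID", "STATUS")]
    if extra:
        clin = {}
        for c in extra:
            vals = pd.to_numeric(meta[c], errors="coerce")
            if vals.notna().sum() == 0:
                warnings.warn(f"clinical column {c!r} is non-numeric; dropped")
                continue
            clin[c] = vals.to_numpy()
        if clin:
            assays[CLINICAL_LAYER] = pd.DataFrame(clin, index=ids).T
    return PatientDataset(ids=ids, labels=labels, assays=assays)


def read_interaction_network(path) -> pd.DataFrame:
    """Square binary gene x gene matrix with header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if list(df.index) != list(df.columns):
        raise ValidationError(
            "interaction network row and column names differ", field="net"
        )
    return df
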