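"""Count-table, taxonomy and metadata I/O plus rank aggregation.

Count tables are plain TSV (a "classic BIOM-like" dialect): first header
cell ``#SampleID`` when samples are rows, ``#TaxonID`` when taxa are rows.
Taxonomy maps are two-column TSV with QIIME-style lineage strings
(``k__Bacteria;p__...;g__Burkholderia``). Metadata is TSV with one row per
sequenced replicate and the measured wood covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
_RANK_PREFIX = {"k": "kingdom", "p": "phylum", "c": "class",
                "o": "order", "f": "family", "g": "genus"}
UNCLASSIFIED = "unclassified"

#: Metadata columns required when pairing with a count table.
METADATA_COLUMNS = ("wood_density", "pH", "moisture", "c_n_ratio",
                    "ergosterol", "replicate_of")


class TableFormatError(ValueError):
    """Raised for malformed count tables, taxonomy files or metadata."""


@dataclass
class CountMatrix:
    """Samples x taxa table of non-negative integer counts.

    Attributes
    ----------
    data
        DataFrame with unique sample ids as the index and unique taxon
        ids as the columns; every cell a non-negative integer.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate taxon ids: {dups}")
        if not all(np.issubdtype(dt, np.integer) for dt in df.dtypes):
            raise TableFormatError("counts must be integers")
        if (df.to_numpy() < 0).any():
            raise TableFormatError("negative counts are not allowed")
        self.data = df.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def relative_abundances(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        totals = self.data.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total reads: {empty}")
        return self.data.div(totals, axis=0)

    def select_samples(self, sample_ids) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return CountMatrix(self.data.loc[list(sample_ids)].copy())

    def drop_empty_taxa(self) -> "CountMatrix":
        keep = self.data.columns[self.data.sum(axis=0) > 0]
        return CountMatrix(self.data[keep].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class TaxonomyMap:
    """Mapping from taxon id to a rank-labeled lineage.

    ``lineages[taxon_id][rank]`` is the name at that rank or
    ``"unclassified"``. Lineages are prefix-consistent: once a rank is
    unclassified every finer rank is unclassified too.
    """

    lineages: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, lin in self.lineages.items():
            extra = set(lin) - set(RANKS)
            if extra:
                raise TableFormatError(
                    f"taxon {tid!r}: unsupported rank labels {sorted(extra)}")
            full = {r: lin.get(r, UNCLASSIFIED) or UNCLASSIFIED for r in RANKS}
            seen_unclassified = False
            for r in RANKS:
                if full[r] == UNCLASSIFIED:
                    seen_unclassified = True
                elif seen_unclassified:
                    # enforce prefix consistency by truncating
                    full[r] = UNCLASSIFIED
            self.lineages[tid] = full

    def name_at(self, taxon_id: str, rank: str) -> str:
        return self.lineages[taxon_id][rank]

    def kingdom_of(self, taxon_id: str) -> str:
        return self.lineages[taxon_id]["kingdom"]

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.lineages


@dataclass
class SampleMetadata:
    """Per-replicate wood covariates and replicate grouping.

    One row per sequenced replicate; ``replicate_of`` names the parent
    wood sample the replicate was drilled from. Units: wood_density in
    g/cm^3, moisture in % of dry mass, ergosterol in mg/kg.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise TableFormatError(f"metadata missing columns: {missing}")
        if df.index.has_duplicates:
            raise TableFormatError("duplicate sample ids in metadata")
        if (df["wood_density"] <= 0).any():
            raise TableFormatError("wood_density must be > 0")
        if (df["moisture"] < 0).any():
            raise TableFormatError("moisture must be >= 0")
        if (df["c_n_ratio"] <= 0).any():
            raise TableFormatError("c_n_ratio must be > 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def require_samples(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise TableFormatError(
                f"samples without metadata rows: {missing}")

    def parents(self) -> dict[str, list[str]]:
        """Parent wood-sample id -> list of replicate sample ids."""
        out: dict[str, list[str]] = {}
        for sid, parent in self.data["replicate_of"].items():
            out.setdefault(parent, []).append(sid)
        return out

    def parent_covariates(self) -> pd.DataFrame:
        """Numeric covariates averaged over the replicates of each parent."""
        num = self.data.drop(columns=["replicate_of"]).select_dtypes("number")
        return num.groupby(self.data["replicate_of"]).mean()


# ---------------------------------------------------------------------------
# I/O

def read_count_table(path, orientation: str = "samples_as_rows") -> CountMatrix:
    """Read a TSV count table.

    Parameters
    ----------
    path
        TSV file; first row and first column are headers.
    orientation
        ``"samples_as_rows"`` or ``"samples_as_columns"``; declares which
        axis of the file holds samples.

    Empty cells are read as 0. Non-integer or negative cells raise
    :class:`TableFormatError` naming the offending row and column.
    """
    if orientation not in ("samples_as_rows", "samples_as_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({c for c in header if header.count(c) > 1})
        # pandas would silently rename these to "x.1"
        raise TableFormatError(f"duplicate ids in header of {path}: {dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False, comment=None)
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dups = sorted(raw.index[raw.index.duplicated()].unique())
        raise TableFormatError(
            f"duplicate ids in first column of {path}: {dups}")
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=np.int64)
    for col in raw.columns:
        for row in raw.index:
            cell = raw.at[row, col].strip()
            if cell == "":
                val = 0
            else:
                try:
                    val = int(cell)
                except ValueError:
                    raise TableFormatError(
                        f"non-integer count {cell!r} at row {row!r}, "
                        f"column {col!r} in {path}") from None
                if val < 0:
                    raise TableFormatError(
                        f"negative count {val} at row {row!r}, "
                        f"column {col!r} in {path}")
            parsed.at[row, col] = val
    parsed = parsed.astype(np.int64)
    if orientation == "samples_as_columns":
        parsed = parsed.T
    return CountMatrix(parsed)


def write_count_table(cm: CountMatrix, path,
                      orientation: str = "samples_as_rows") -> None:
    """Write a count table as TSV, inverse of :func:`read_count_table`."""
    if orientation == "samples_as_rows":
        df, label = cm.data, "#SampleID"
    elif orientation == "samples_as_columns":
        df, label = cm.data.T, "#TaxonID"
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = df.copy()
    df.index.name = label
    df.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyMap:
    """Read a two-column TSV of taxon id and QIIME-style lineage string."""
    lineages: dict[str, dict[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise TableFormatError(
                    f"{path}:{ln}: expected 2 tab-separated fields")
            tid, lineage = parts
            if tid in lineages:
                raise TableFormatError(f"{path}:{ln}: duplicate taxon {tid!r}")
            lineages[tid] = parse_lineage(lineage)
    return TaxonomyMap(lineages)


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse ``k__Bacteria;p__Acidobacteria;...`` into a rank dict."""
    out: dict[str, str] = {}
    for token in lineage.split(";"):
        token = token.strip()
        if not token:
            continue
        if len(token) < 3 or token[1:3] != "__":
            raise TableFormatError(f"malformed lineage token {token!r}")
        prefix = token[0]
        if prefix not in _RANK_PREFIX:
            raise TableFormatError(f"unknown rank prefix {token!r}")
        name = token[3:].strip()
        out[_RANK_PREFIX[prefix]] = name if name else UNCLASSIFIED
    return out


def format_lineage(lin: dict[str, str]) -> str:
    parts = []
    for rank in RANKS:
        prefix = rank[0]
        name = lin.get(rank, UNCLASSIFIED)
        parts.append(f"{prefix}__{'' if name == UNCLASSIFIED else name}")
    return ";".join(parts)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid, lin in tax.lineages.items():
            fh.write(f"{tid}\t{format_lineage(lin)}\n")


def read_metadata(path) -> SampleMetadata:
    """Read a metadata TSV indexed by replicate sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.data.copy()
    df.index.name = "#SampleID"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Aggregation

def aggregate_taxa(cm: CountMatrix, tax: TaxonomyMap, rank: str) -> CountMatrix:
    """Sum counts of taxa sharing a name at ``rank``.

    Taxa unclassified at ``rank`` are pooled into one
    ``"<kingdom>;unclassified@<rank>"`` taxon per kingdom so per-sample
    totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unsupported rank {rank!r}; choose from {RANKS}")
    missing = [t for t in cm.taxon_ids if t not in tax]
    if missing:
        raise KeyError(f"taxa missing from taxonomy map: {missing}")
    labels = []
    for tid in cm.taxon_ids:
        name = tax.name_at(tid, rank)
        if name == UNCLASSIFIED:
            labels.append(f"{tax.kingdom_of(tid)};unclassified@{rank}")
        else:
            labels.append(name)
    grouped = cm.data.T.groupby(pd.Index(labels, name=rank), sort=True).sum().T
    return CountMatrix(grouped)


def average_replicates(cm: CountMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Average replicate relative abundances per parent wood sample.

    Each replicate's counts are converted to relative abundances
    (count / replicate total); replicates of the same parent are then
    averaged arithmetically. Output rows (parents) sum to 1. Parents all
    of whose replicates are missing from ``cm`` are dropped with a
    logged warning.
    """
    meta.require_samples(cm.sample_ids)
    rel = cm.relative_abundances()
    parents = meta.parents()
    rows = {}
    for parent, reps in sorted(parents.items()):
        present = [r for r in reps if r in rel.index]
        if not present:
            logger.warning("parent %s has no replicates in the count table; "
                           "excluded", parent)
            continue
        rows[parent] = rel.loc[present].mean(axis=0)
    if not rows:
        raise ValueError("no parent has any replicate in the count table")
    return pd.DataFrame(rows).T.rename_axis(index="parent")
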