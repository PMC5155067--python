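"""Typed readers and writers for every file the pipeline touches.

All genomic coordinates are 1-based inclusive, as in GFF3; gene length is
``end - start + 1``.  Tables are tab-separated UTF-8 with a header row;
lines starting with ``#`` are comments.  Lineages are semicolon-joined rank
labels ordered domain → kingdom → phylum → class → order → family → genus →
species, truncated at the deepest assigned rank (no internal gaps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import skbio

logger = logging.getLogger(__name__)

RANKS = ("domain", "kingdom", "phylum", "class", "order", "family", "genus", "species")

HITS_COLUMNS = (
    "gene_id", "subject_id", "pct_identity", "aln_len",
    "evalue", "query_coverage", "lineage",
)


class ValidationError(ValueError):
    """A record violates a structural invariant (bad coordinates, negative count...)."""


class SchemaError(ValueError):
    """A table is missing required columns."""


@dataclass(frozen=True, order=True)
class Lineage:
    """Ranked taxonomy path, domain → species, truncated at the deepest assigned rank."""

    ranks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.ranks) > len(RANKS):
            raise ValidationError(f"lineage deeper than {len(RANKS)} ranks: {self.ranks}")
        if any(not r for r in self.ranks):
            raise ValidationError(f"empty rank label inside lineage {self.ranks} "
                                  "(an absent rank implies all lower ranks absent)")

    @classmethod
    def from_string(cls, s: str) -> "Lineage":
        s = s.strip()
        if not s:
            return cls(())
        return cls(tuple(part.strip() for part in s.split(";")))

    def __str__(self) -> str:
        return ";".join(self.ranks)

    def __len__(self) -> int:
        return len(self.ranks)

    @property
    def domain(self) -> str | None:
        return self.ranks[0] if self.ranks else None

    def at_rank(self, rank: str) -> str | None:
        """Label at a named rank, or None if unassigned at that depth."""
        i = RANKS.index(rank)
        return self.ranks[i] if i < len(self.ranks) else None

    def truncate(self, rank: str) -> "Lineage":
        """Lineage cut at (and including) the named rank."""
        return Lineage(self.ranks[: RANKS.index(rank) + 1])


@dataclass(frozen=True)
class GeneRecord:
    """One predicted CDS: coordinates on its scaffold, carrier of the RPKM length."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}")
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class BestHit:
    """A gene's closest reference protein with its lineage and alignment stats."""

    gene_id: str
    subject_id: str
    lineage: Lineage
    pct_identity: float
    evalue: float
    query_coverage: float
    aln_len: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValidationError(f"hit {self.gene_id}->{self.subject_id}: "
                                  f"pct_identity {self.pct_identity} outside [0,100]")
        if not (0.0 <= self.query_coverage <= 100.0):
            raise ValidationError(f"hit {self.gene_id}->{self.subject_id}: "
                                  f"query_coverage {self.query_coverage} outside [0,100]")
        if self.evalue < 0:
            raise ValidationError(f"hit {self.gene_id}->{self.subject_id}: negative evalue")


@dataclass
class CountTable:
    """Gene x sample raw read counts plus per-sample library sizes.

    ``library_sizes`` defaults to the per-sample column sums (the denominator
    used when normalising without access to the original alignments); callers
    may supply externally measured totals instead.  Library size is not
    required to bound the column sum.
    """

    counts: pd.DataFrame  # index gene_id, columns sample ids, int
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            bad = self.counts.index[(self.counts < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative counts for genes {bad[:5]}")
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate gene ids in count table")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = pd.Series(self.library_sizes).reindex(self.counts.columns)
            if self.library_sizes.isna().any() or (self.library_sizes <= 0).any():
                raise ValidationError("library sizes must be positive for every sample")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path: str | Path) -> dict[str, GeneRecord]:
    """Read CDS features from a GFF3 file into GeneRecords keyed by gene id.

    Coordinates are kept 1-based inclusive as written.  Duplicate gene ids
    are rejected; a coordinate inversion names the offending line.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        logger.warning("GFF file %s is empty", path)
        return {}
    try:
        db = gffutils.create_db(
            text, ":memory:", from_string=True,
            merge_strategy="error", keep_order=True,
        )
    except Exception as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    records: dict[str, GeneRecord] = {}
    for feat in db.features_of_type("CDS"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in records:
            raise ValidationError(f"duplicate gene id {gene_id!r} in {path}")
        if feat.end < feat.start:
            raise ValidationError(
                f"{path}: feature {gene_id!r} has end {feat.end} < start {feat.start}")
        records[gene_id] = GeneRecord(
            gene_id=gene_id, scaffold_id=feat.seqid,
            start=feat.start, end=feat.end,
            strand=feat.strand if feat.strand in {"+", "-"} else "+",
        )
    return records


def write_gff(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write GeneRecords as GFF3 CDS features (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.scaffold_id}\tbinquant\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0"
                f"\tID={g.gene_id}\n")


# ---------------------------------------------------------------------------
# Tabular files


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def read_hits(path: str | Path, best_only: bool = True) -> dict[str, BestHit]:
    """Read a tabular homology-hit file into per-gene closest hits.

    When several rows share a gene id, only the closest hit is retained:
    lowest E-value, ties broken by higher identity, then lexicographic
    subject id.  Set ``best_only=False`` to get every hit
    (returns gene_id -> list of BestHit instead).
    """
    df = _read_tsv(path, HITS_COLUMNS)
    hits: dict[str, list[BestHit]] = {}
    for row in df.itertuples(index=False):
        hit = BestHit(
            gene_id=row.gene_id,
            subject_id=row.subject_id,
            lineage=Lineage.from_string(row.lineage if isinstance(row.lineage, str) else ""),
            pct_identity=float(row.pct_identity),
            evalue=float(row.evalue),
            query_coverage=float(row.query_coverage),
            aln_len=int(float(row.aln_len)),
        )
        hits.setdefault(hit.gene_id, []).append(hit)
    if not best_only:
        return hits  # type: ignore[return-value]
    return {g: best_hit(hs) for g, hs in hits.items()}


def best_hit(hits: Sequence[BestHit]) -> BestHit:
    """Closest hit: lowest E-value, then highest identity, then subject id."""
    return min(hits, key=lambda h: (h.evalue, -h.pct_identity, h.subject_id))


def write_hits(hits: Iterable[BestHit], path: str | Path) -> None:
    rows = [
        (h.gene_id, h.subject_id, f"{h.pct_identity:.2f}", h.aln_len,
         f"{h.evalue:.3e}", f"{h.query_coverage:.2f}", str(h.lineage))
        for h in hits
    ]
    pd.DataFrame(rows, columns=list(HITS_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, library_sizes: Mapping[str, float] | None = None) -> CountTable:
    """Read a gene x sample count TSV (column ``gene_id`` + one column per sample)."""
    df = _read_tsv(path, ["gene_id"])
    df = df.set_index("gene_id")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene ids {dups[:5]}")
    try:
        counts = df.astype(np.int64)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-integer count value ({exc})") from exc
    if (counts.values < 0).any():
        raise ValidationError(f"{path}: negative count values present")
    sizes = pd.Series(library_sizes) if library_sizes is not None else None
    return CountTable(counts=counts, library_sizes=sizes)


def write_counts(table: CountTable, path: str | Path) -> None:
    table.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_table(path: str | Path, index_col: str) -> pd.DataFrame:
    """Generic numeric table keyed by one id column (coverages, OTUs, ...)."""
    df = _read_tsv(path, [index_col]).set_index(index_col)
    return df.apply(pd.to_numeric)


def read_scaffold_bins(path: str | Path) -> dict[str, str]:
    """Scaffold -> bin membership from a two-column TSV."""
    df = _read_tsv(path, ["scaffold_id", "bin_id"])
    return dict(zip(df["scaffold_id"], df["bin_id"]))


def read_gene_map(path: str | Path, key: str, value: str) -> dict[str, str]:
    df = _read_tsv(path, [key, value])
    return dict(zip(df[key], df[value]))


# ---------------------------------------------------------------------------
# Trees


def write_newick(tree: skbio.TreeNode, path: str | Path) -> None:
    """Serialise a tree to newick with branch lengths."""
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")
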