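"""RPKM normalisation and transcription aggregation.

RPKM (reads per kilobase of gene per million mapped reads) for gene *g* in
sample *s* is

    RPKM = 1e9 * count / (length_bp * library_size)

with the library size defaulting to the per-sample column sum of
gene-assigned counts.  Genome (bin) expression is the sum of member-gene
RPKM; eukaryotic bins and scaffolds labelled "eukaryotes", "cellular
organisms" or "unassigned" are excluded from prokaryotic totals, while
"unclassified bacteria" stays in.  Top-k transcriber shares and per-bin
top-gene percentages follow directly.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from binquant.io import CountTable, GeneRecord
from binquant.taxonomy import EXCLUDED_LABELS

#: sentinel group for genes absent from the grouping map
UNGROUPED = "__ungrouped__"


def compute_rpkm(counts: CountTable, genes: Mapping[str, GeneRecord]) -> pd.DataFrame:
    """Gene x sample RPKM from raw counts and gene lengths.

    Every counted gene must have a gene record carrying its length; offenders
    are listed in the error.  Zero count gives exactly zero RPKM.
    """
    missing = [g for g in counts.gene_ids if g not in genes]
    if missing:
        raise KeyError(
            f"{len(missing)} genes in the count table have no gene model; "
            f"first offenders: {missing[:10]}")
    lengths = np.array([genes[g].length for g in counts.gene_ids], dtype=float)
    lib = counts.library_sizes.to_numpy(dtype=float)
    rpkm = 1e9 * counts.counts.to_numpy(dtype=float) / (lengths[:, None] * lib[None, :])
    return pd.DataFrame(rpkm, index=counts.counts.index, columns=counts.counts.columns)


def aggregate(
    rpkm: pd.DataFrame,
    grouping: Mapping[str, str],
    excluded_groups: set[str] | frozenset[str] = frozenset(),
) -> tuple[pd.DataFrame, pd.Series]:
    """Sum RPKM per group and sample.

    ``grouping`` maps gene id -> group (bin id, phylum, enzyme class, or an
    unbinned label); genes absent from the map land in the ``__ungrouped__``
    sentinel group.  Returns (group x sample matrix, boolean Series marking
    groups included in prokaryotic totals).  Excluded are the named
    ``excluded_groups`` (e.g. eukaryote bins) plus the standard excluded
    labels; the sentinel group is always excluded.
    """
    groups = pd.Series([grouping.get(g, UNGROUPED) for g in rpkm.index], index=rpkm.index)
    agg = rpkm.groupby(groups).sum()
    agg = agg.sort_index()
    excluded = set(excluded_groups) | set(EXCLUDED_LABELS) | {UNGROUPED}
    included = pd.Series([g not in excluded for g in agg.index], index=agg.index)
    return agg, included


def top_k_share(
    bin_expr: pd.DataFrame,
    included: pd.Series,
    sample: str,
    k: int = 5,
    denominator: str = "all_prokaryotic",
) -> float | None:
    """Percent of prokaryotic transcription carried by the k top bins.

    ``denominator`` selects what counts as the prokaryotic total:
    ``"all_prokaryotic"`` (default) sums every included group — binned plus
    unbinned prokaryotic labels; ``"binned_only"`` restricts both the ranking
    and the total to groups whose id does not mark an unbinned pool.  Ties at
    rank k are broken by group id.  An all-zero sample reports None.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if denominator not in {"all_prokaryotic", "binned_only"}:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    expr = bin_expr.loc[included, sample]
    if denominator == "binned_only":
        expr = expr[[not str(i).startswith("unbinned:") and str(i) != "unclassified bacteria"
                     for i in expr.index]]
    total = float(expr.sum())
    if total <= 0:
        return None
    ranked = expr.iloc[np.lexsort((expr.index.astype(str), -expr.to_numpy()))]
    return 100.0 * float(ranked.iloc[:k].sum()) / total


def top_genes_in_bin(
    rpkm: pd.DataFrame,
    gene_to_bin: Mapping[str, str],
    bin_id: str,
    sample: str,
    n: int = 5,
) -> list[tuple[str, float]]:
    """Most-transcribed genes of one bin with their percent of bin transcription.

    Percent is 100 x gene RPKM / the bin's summed RPKM in that sample.  A
    zero-total bin yields an empty list.
    """
    members = [g for g in rpkm.index if gene_to_bin.get(g) == bin_id]
    col = rpkm.loc[members, sample]
    total = float(col.sum())
    if total <= 0:
        return []
    ranked = col.sort_values(ascending=False, kind="mergesort")
    return [(g, 100.0 * float(v) / total) for g, v in ranked.iloc[:n].items()]


def phylum_grouping(
    gene_to_bin: Mapping[str, str],
    bin_phylum: Mapping[str, str],
    scaffold_labels: Mapping[str, str] | None = None,
    gene_to_scaffold: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Gene -> phylum map combining binned genes and LCA-labelled unbinned genes."""
    out: dict[str, str] = {}
    for gene, b in gene_to_bin.items():
        if b in bin_phylum:
            out[gene] = bin_phylum[b]
    if scaffold_labels and gene_to_scaffold:
        for gene, scaf in gene_to_scaffold.items():
            if gene in out:
                continue
            label = scaffold_labels.get(scaf)
            if label is not None:
                out[gene] = label
    return out


__all__ = [
    "compute_rpkm", "aggregate", "top_k_share", "top_genes_in_bin",
    "phylum_grouping", "UNGROUPED",
]
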