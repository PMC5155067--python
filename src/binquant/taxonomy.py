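"""Taxonomy assignment for genome bins and unbinned scaffolds.

Bins are labelled by majority vote over the full lineages of their genes'
closest reference hits, with the averaged amino-acid identity (AAI) taken
over the genes that voted for the winner.  Unbinned scaffolds get a
lowest-common-ancestor (LCA) label computed over the high-scoring subset of
their hits, with the conventional exclusion vocabulary: labels "eukaryotes",
"cellular organisms" and "unassigned" are excluded from downstream
transcript accounting, while "unclassified bacteria" (hits agreeing only at
the Bacteria domain) stays in.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from binquant.io import BestHit, Lineage, RANKS

EXCLUDED_LABELS = frozenset({"eukaryotes", "cellular organisms", "unassigned"})
UNCLASSIFIED_BACTERIA = "unclassified bacteria"

#: Floor applied to E-values before taking -log10 as the LCA score proxy.
MIN_EVALUE = 1e-180


@dataclass(frozen=True)
class BinTaxonomy:
    """Voting result for one genome bin.

    ``vote_fraction`` is winner votes / genes with hits; ``mean_aai`` averages
    percent identity over winner-voting genes only and is None for a hitless
    bin.  ``is_eukaryote`` marks bins excluded from transcript accounting.
    """

    bin_id: str
    lineage: Lineage | None
    vote_fraction: float | None
    mean_aai: float | None
    n_genes: int
    is_eukaryote: bool = False

    @property
    def label(self) -> str:
        return str(self.lineage) if self.lineage is not None else "unassigned"


@dataclass(frozen=True)
class ScaffoldLabel:
    """LCA label for one unbinned scaffold.

    ``label`` is either a semicolon-joined lineage or one of the special
    labels; ``include_in_transcriptomics`` is False exactly for the excluded
    vocabulary ("eukaryotes", "cellular organisms", "unassigned").
    """

    scaffold_id: str
    label: str
    lineage: Lineage | None = None

    @property
    def include_in_transcriptomics(self) -> bool:
        return self.label not in EXCLUDED_LABELS


def vote_bin_taxonomy(bin_id: str, hits: Sequence[BestHit]) -> BinTaxonomy:
    """Assign a bin the most frequent closest-hit lineage.

    The vote is over full lineage strings (species level when available);
    ties are broken by higher mean identity among the tied lineages, then
    lexicographically.  Genes without hits do not vote.
    """
    if not hits:
        return BinTaxonomy(bin_id=bin_id, lineage=None, vote_fraction=None,
                           mean_aai=None, n_genes=0)
    votes = Counter(h.lineage for h in hits)
    top = max(votes.values())
    tied = [lin for lin, n in votes.items() if n == top]
    if len(tied) > 1:
        def mean_ident(lin: Lineage) -> float:
            vals = [h.pct_identity for h in hits if h.lineage == lin]
            return sum(vals) / len(vals)
        tied.sort(key=lambda lin: (-mean_ident(lin), str(lin)))
    winner = tied[0]
    winner_idents = [h.pct_identity for h in hits if h.lineage == winner]
    return BinTaxonomy(
        bin_id=bin_id,
        lineage=winner,
        vote_fraction=top / len(hits),
        mean_aai=sum(winner_idents) / len(winner_idents),
        n_genes=len(hits),
        is_eukaryote=(winner.domain == "Eukaryota"),
    )


def lineage_lca(lineages: Sequence[Lineage]) -> Lineage:
    """Deepest rank prefix shared by all lineages (rank-by-rank intersection)."""
    if not lineages:
        return Lineage(())
    shared: list[str] = []
    for depth in range(min(len(lin) for lin in lineages)):
        labels = {lin.ranks[depth] for lin in lineages}
        if len(labels) != 1:
            break
        shared.append(labels.pop())
    return Lineage(tuple(shared))


def _score(hit: BestHit) -> float:
    return -math.log10(max(hit.evalue, MIN_EVALUE))


def lca_assign(scaffold_id: str, hits: Sequence[BestHit],
               top_percent: float = 10.0) -> ScaffoldLabel:
    """Label a scaffold by the LCA of its high-scoring hits.

    Hits scoring within ``top_percent`` percent of the best hit (score proxy:
    -log10 E-value) participate.  An LCA that bottoms out exactly at the
    Bacteria domain becomes "unclassified bacteria"; one above the domain rank
    becomes "cellular organisms"; a eukaryotic LCA becomes "eukaryotes"; no
    hits means "unassigned".
    """
    if not (0.0 < top_percent <= 100.0):
        raise ValueError(f"top_percent must be in (0, 100], got {top_percent}")
    if not hits:
        return ScaffoldLabel(scaffold_id=scaffold_id, label="unassigned")
    best = max(_score(h) for h in hits)
    window = abs(best) * top_percent / 100.0
    retained = [h for h in hits if _score(h) >= best - window]
    lca = lineage_lca([h.lineage for h in retained])
    if len(lca) == 0:
        # hits disagree even at the domain rank (or carry empty lineages)
        return ScaffoldLabel(scaffold_id=scaffold_id, label="cellular organisms")
    if lca.domain == "Eukaryota":
        return ScaffoldLabel(scaffold_id=scaffold_id, label="eukaryotes", lineage=lca)
    if lca.domain == "Bacteria" and len(lca) == 1:
        return ScaffoldLabel(scaffold_id=scaffold_id, label=UNCLASSIFIED_BACTERIA,
                             lineage=lca)
    return ScaffoldLabel(scaffold_id=scaffold_id, label=str(lca), lineage=lca)


def report_rank(tax: BinTaxonomy, rank: str) -> str | None:
    """Bin label truncated to a requested rank (e.g. phylum for phylum plots)."""
    if tax.lineage is None:
        return None
    return tax.lineage.at_rank(rank)


__all__ = [
    "BinTaxonomy", "ScaffoldLabel", "EXCLUDED_LABELS", "UNCLASSIFIED_BACTERIA",
    "vote_bin_taxonomy", "lca_assign", "lineage_lca", "report_rank", "RANKS",
]
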