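"""Community ecology metrics and the abundance distance tree.

Alpha diversity follows the vegan conventions: Shannon diversity H with the
natural logarithm, richness S as the number of taxa with positive abundance,
and Pielou's evenness J = H / ln S.  Singletons — taxa whose total count
across the whole dataset is one — are removed before diversity calculation
to reduce variability.  The community distance tree clusters samples by
UPGMA on Bray-Curtis distances between per-sample relative abundances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import skbio
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform


def remove_singletons(table: pd.DataFrame) -> pd.DataFrame:
    """Drop taxa whose total count across all samples is <= 1.

    A taxon with one read in each of two samples (total 2) is retained; the
    convention is global, not per-sample.  Requires integer counts.
    """
    if table.empty:
        return table
    if not np.allclose(table.to_numpy(dtype=float) % 1, 0):
        raise ValueError("singleton removal expects integer counts")
    return table.loc[table.sum(axis=1) > 1]


def shannon(abundances: "pd.Series | np.ndarray") -> float:
    """Shannon diversity H = -sum p_i ln p_i over taxa with positive abundance."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("at least one positive abundance required")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def richness(abundances: "pd.Series | np.ndarray") -> int:
    """Number of taxa with positive abundance."""
    x = np.asarray(abundances, dtype=float)
    return int((x > 0).sum())


def pielou(h: float, s: int) -> float | None:
    """Pielou's evenness J = H / ln S; undefined (None) for S < 2."""
    if s < 2:
        return None
    return h / np.log(s)


def diversity_report(table: pd.DataFrame, drop_singletons: bool = True) -> pd.DataFrame:
    """Per-sample S, H and J for an OTU/bin count table (taxa x samples)."""
    if drop_singletons:
        table = remove_singletons(table)
    rows = []
    for sample in table.columns:
        col = table[sample]
        s = richness(col)
        h = shannon(col) if s > 0 else np.nan
        j = pielou(h, s) if s >= 2 else np.nan
        rows.append({"sample": sample, "richness": s, "shannon": h,
                     "pielou": np.nan if j is None else j})
    return pd.DataFrame(rows).set_index("sample")


def bray_curtis_matrix(table: pd.DataFrame, relative: bool = True) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances between samples (columns of the table)."""
    mat = table.to_numpy(dtype=float).T
    if relative:
        totals = mat.sum(axis=1, keepdims=True)
        if (totals <= 0).any():
            raise ValueError("every sample needs a positive total abundance")
        mat = mat / totals
    dm = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(dm, index=table.columns, columns=table.columns)


def distance_tree(
    table: pd.DataFrame,
    relative: bool = True,
    metric: str = "braycurtis",
    method: str = "average",
) -> skbio.TreeNode:
    """UPGMA tree of samples from pairwise abundance distances.

    Columns are samples; abundances are converted to per-sample relative
    abundances by default.  Ties (e.g. identical samples at distance zero)
    are resolved by input order, which scipy's agglomeration makes
    deterministic.  Returns a skbio TreeNode with branch lengths.
    """
    if table.shape[1] < 2:
        raise ValueError("at least two samples required for a distance tree")
    mat = table.to_numpy(dtype=float).T
    if relative:
        mat = mat / mat.sum(axis=1, keepdims=True)
    condensed = pdist(mat, metric=metric)
    z = linkage(condensed, method=method)
    tree = skbio.TreeNode.from_linkage_matrix(z, [str(c) for c in table.columns])
    # from_linkage_matrix stores cumulative heights; convert nothing — branch
    # lengths are already per-edge.  Root length is meaningless; zero it.
    tree.length = None
    return tree


__all__ = [
    "remove_singletons", "shannon", "richness", "pielou",
    "diversity_report", "bray_curtis_matrix", "distance_tree",
]
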