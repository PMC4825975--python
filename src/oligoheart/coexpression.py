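"""Weighted gene-coexpression modules from a developmental expression atlas.

Counts are normalized to log1p counts-per-million, transcripts collapsed to
one row per gene by connectivity, and modules built from a soft-thresholded
correlation network via topological-overlap dissimilarity and average-
linkage clustering.  Module eigengenes (first principal component of the
standardized module expression) are correlated against tissue-of-origin
indicators; the module most correlated with the atrioventricular-canal
analog tissue is the one intersected with inheritance-model genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class CoexpressionModule:
    name: str
    members: tuple  # gene ids, sorted
    eigengene: np.ndarray  # one value per library
    tissue_correlations: pd.Series | None = None
    best_tissue: str | None = None


def normalize_and_collapse(counts: pd.DataFrame, transcript_gene_map: pd.Series | None = None) -> pd.DataFrame:
    """Library-size normalize (CPM, log1p) and collapse transcripts to genes.

    When several transcripts map to one gene, the transcript with the
    highest connectivity (sum of absolute Pearson correlations with every
    other row) represents the gene; ties break to the lexicographically
    smallest transcript id.
    """
    counts = counts.astype(float)
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    libsize = counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"all-zero library: {list(zero.index)}")
    cpm = counts / libsize * 1e6
    logcpm = np.log1p(cpm)
    if transcript_gene_map is None:
        return logcpm

    X = logcpm.values
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X)
    corr[np.isnan(corr)] = 0.0
    connectivity = np.abs(corr).sum(axis=1) - 1.0
    conn = pd.Series(connectivity, index=logcpm.index)
    conn[sd == 0] = -np.inf  # constant rows carry no usable signal

    genes = transcript_gene_map.reindex(logcpm.index)
    if genes.isna().any():
        missing = list(logcpm.index[genes.isna()])
        raise ValueError(f"transcripts without gene mapping: {missing[:5]}")
    keep = []
    for gene, grp in conn.groupby(genes):
        # max connectivity, ties to smallest transcript id
        best = grp.sort_index().idxmax()
        keep.append((gene, best))
    keep.sort()
    collapsed = logcpm.loc[[t for _, t in keep]]
    collapsed.index = [g for g, _ in keep]
    return collapsed


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix of a weighted adjacency."""
    A = adjacency.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (L + A) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def _eigengene(X: np.ndarray) -> np.ndarray:
    """First right singular vector of the row-standardized module matrix,
    unit-normalized, sign fixed to correlate positively with the module
    mean profile."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    _, _, Vt = np.linalg.svd(Z, full_matrices=False)
    e = Vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    return e / np.linalg.norm(e)


def build_modules(
    matrix: pd.DataFrame,
    soft_power: int = 6,
    min_module_size: int = 10,
    cut_height_frac: float = 0.99,
):
    """Detect coexpression modules.

    Adjacency a_ij = |cor(i,j)|^soft_power, topological-overlap
    dissimilarity, average-linkage clustering, cut at ``cut_height_frac``
    of the tallest merge (a fixed-height analog of dynamic tree cutting).
    Modules smaller than ``min_module_size`` fall into an unassigned pool.

    Returns ``(modules, assignment)``: a list of CoexpressionModule ordered
    by decreasing size, and a gene -> module-name Series (including
    ``unassigned``).
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 libraries")
    if soft_power < 1:
        raise ValueError("soft_power must be >= 1")
    X = matrix.values
    sd = X.std(axis=1)
    if (sd == 0).any():
        log.warning("dropping %d constant gene rows", int((sd == 0).sum()))
        matrix = matrix.loc[sd > 0]
        X = matrix.values
    genes = matrix.index.to_numpy()
    n = len(genes)
    assignment = pd.Series(UNASSIGNED, index=matrix.index, name="module")
    if n == 0:
        return [], assignment

    corr = np.corrcoef(X)
    A = np.abs(corr) ** soft_power
    diss = 1.0 - topological_overlap(A)
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2
    Z = linkage(squareform(diss, checks=False), method="average")
    max_h = Z[:, 2].max() if len(Z) else 0.0
    labels = fcluster(Z, t=cut_height_frac * max_h, criterion="distance")

    modules = []
    for lab in np.unique(labels):
        members = genes[labels == lab]
        if len(members) < min_module_size:
            continue
        order = np.argsort(members)
        members = members[order]
        sub = matrix.loc[members].values
        modules.append(
            CoexpressionModule(
                name="",
                members=tuple(members),
                eigengene=_eigengene(sub),
            )
        )
    modules.sort(key=lambda m: (-len(m.members), m.members))
    for i, m in enumerate(modules, start=1):
        m.name = f"M{i:02d}"
        assignment.loc[list(m.members)] = m.name
    return modules, assignment


def module_tissue_correlation(modules, tissue_design: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with per-tissue
    indicator vectors; records the best tissue on each module.

    ``tissue_design`` maps library -> tissue label, in library order of the
    expression matrix the modules were built from.
    """
    tissues = sorted(tissue_design.unique())
    rows = {}
    for m in modules:
        e = m.eigengene
        corrs = {}
        for t in tissues:
            ind = (tissue_design.values == t).astype(float)
            if ind.std() == 0 or e.std() == 0:
                corrs[t] = np.nan  # undefined-variance guard
            else:
                corrs[t] = float(np.corrcoef(e, ind)[0, 1])
        s = pd.Series(corrs)
        m.tissue_correlations = s
        # unsigned networks admit anticorrelated members, so the eigengene
        # sign is not informative for assignment: strongest |correlation| wins
        m.best_tissue = s.abs().idxmax() if s.notna().any() else None
        rows[m.name] = s
    return pd.DataFrame(rows).T


def intersect_module_with_events(module: CoexpressionModule, events: pd.DataFrame, mode_filter: str | None = None):
    """Genes present both in the module and in the inheritance events.

    ``mode_filter`` restricts events to one inheritance class (the primary
    analysis uses de novo events only).
    """
    if mode_filter is not None:
        events = events[events["mode"] == mode_filter]
    event_genes = set(events["gene"])
    return sorted(event_genes & set(module.members))


def top_k_genes(matrix: pd.DataFrame, k: int) -> list:
    """Top-k genes of a second expression matrix by mean expression, used to
    augment a gene list with highly expressed genes from another dataset."""
    means = matrix.mean(axis=1)
    return list(means.sort_values(ascending=False, kind="stable").index[:k])


def augment_gene_list(genes, matrix: pd.DataFrame, k: int) -> list:
    """Union of a gene list with the top-k most expressed genes of ``matrix``."""
    return sorted(set(genes) | set(top_k_genes(matrix, k)))
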