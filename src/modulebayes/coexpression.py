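"""Weighted coexpression network construction and module detection.

The gene-gene similarity is the absolute Pearson correlation across samples,
soft-thresholded by a power beta chosen so that the network connectivity
distribution approximates scale-free topology. Pairwise adjacency is then
augmented with shared-neighbour structure (unsigned topological overlap),
and genes are partitioned by average-linkage hierarchical clustering on
1 - TOM. Clusters below the size floor fall into module 0 (unassigned).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "SoftThresholdScan",
    "ModuleAssignment",
    "similarity",
    "adjacency",
    "scale_free_fit",
    "pick_soft_threshold",
    "topological_overlap",
    "detect_modules",
    "merge_close_modules",
]


@dataclass
class SoftThresholdScan:
    """Result of scanning candidate soft-threshold powers.

    ``fit_indices[i]`` is the signed scale-free fit index -sign(slope)*R^2
    for ``powers[i]``; ``chosen_beta`` is the smallest power whose fit
    reaches the cut, or the argmax (with ``converged=False``) if none does.
    """

    powers: list[int]
    fit_indices: list[float]
    mean_connectivities: list[float]
    chosen_beta: int
    rsq_cut: float
    converged: bool = True


@dataclass
class ModuleAssignment:
    """Per-gene module index; 0 marks unassigned ('grey') genes."""

    labels: pd.Series  # gene_id -> module index

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in self.labels.unique() if m != 0)

    @property
    def sizes(self) -> dict[int, int]:
        counts = self.labels.value_counts()
        return {int(m): int(counts[m]) for m in self.module_ids}

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def similarity(x: pd.DataFrame) -> pd.DataFrame:
    """Absolute Pearson correlation between genes (rows) of ``x``.

    Genes with zero variance get similarity 0 to every other gene (logged);
    the diagonal is 1.
    """
    if x.shape[1] < 3:
        raise ValueError("at least 3 samples are required for correlations")
    vals = x.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    zero = sd == 0
    if zero.any():
        logger.warning("%d zero-variance genes get similarity 0", int(zero.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.corrcoef(vals)
    c = np.atleast_2d(c)
    c[~np.isfinite(c)] = 0.0
    s = np.clip(np.abs(c), 0.0, 1.0)
    np.fill_diagonal(s, 1.0)
    return pd.DataFrame(s, index=x.index, columns=x.index)


def adjacency(x: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Soft-thresholded adjacency |cor|^beta with a zero diagonal."""
    a = similarity(x) ** beta
    np.fill_diagonal(a.values, 0.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index of a connectivity vector.

    Connectivities are binned into ``n_bins`` equal-width bins; log10 bin
    frequency is regressed on log10 mean bin connectivity over non-empty
    bins, and the index is -sign(slope) * R^2 (so a decreasing, well-fit
    log-log relation scores near +1). Degenerate distributions score 0.
    """
    k = np.asarray(k, dtype=float)
    if k.size < 2 or k.max() == k.min():
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    kmean = np.zeros(n_bins)
    for b in range(n_bins):
        if freq[b] > 0:
            kmean[b] = k[idx == b].mean()
    mask = (freq > 0) & (kmean > 0)
    if mask.sum() < 2:
        return 0.0
    lx = np.log10(kmean[mask])
    ly = np.log10(freq[mask])
    if np.allclose(lx, lx[0]):
        return 0.0
    res = stats.linregress(lx, ly)
    return float(-np.sign(res.slope) * res.rvalue**2)


def pick_soft_threshold(
    x: pd.DataFrame,
    powers: tuple[int, ...] = tuple(range(1, 21)),
    rsq_cut: float = 0.85,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Choose the smallest power whose network is approximately scale-free.

    For each candidate beta, the similarity is raised to beta (diagonal
    zeroed), connectivity k_i = sum_j a_ij is computed, and the scale-free
    fit index is evaluated. The smallest beta with fit >= ``rsq_cut`` wins;
    if none qualifies, the argmax is returned with ``converged=False``.
    """
    if x.shape[0] < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} genes")
    s = similarity(x).to_numpy()
    fits, means = [], []
    for beta in powers:
        a = s**beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        fits.append(scale_free_fit(k, n_bins=n_bins))
        means.append(float(k.mean()))
    chosen = None
    for beta, fit in zip(powers, fits):
        if fit >= rsq_cut:
            chosen = beta
            break
    converged = chosen is not None
    if chosen is None:
        chosen = powers[int(np.argmax(fits))]
        logger.warning(
            "no power reached scale-free fit %.2f; using argmax beta=%d (fit %.3f)",
            rsq_cut,
            chosen,
            max(fits),
        )
    return SoftThresholdScan(
        powers=list(powers),
        fit_indices=fits,
        mean_connectivities=means,
        chosen_beta=int(chosen),
        rsq_cut=rsq_cut,
        converged=converged,
    )


def topological_overlap(adj) -> pd.DataFrame | np.ndarray:
    """Unsigned topological overlap matrix of an adjacency matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_u a_iu a_uj and TOM_ii = 1. Requires a symmetric adjacency
    with zero diagonal and entries in [0, 1].
    """
    index = adj.index if isinstance(adj, pd.DataFrame) else None
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    L = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    assert np.all(denom > 0), "TOM denominator must be positive"
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    if index is not None:
        return pd.DataFrame(tom, index=index, columns=index)
    return tom


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 20,
    cut_height: float = 0.99,
) -> ModuleAssignment:
    """Partition genes by average-linkage clustering on 1 - TOM.

    The dendrogram is cut at ``cut_height`` times the maximum merge height;
    flat clusters smaller than ``min_module_size`` become module 0, and the
    survivors are renumbered 1..M by decreasing size (ties by first gene
    position, so the labelling is deterministic).
    """
    genes = list(tom.index)
    n = len(genes)
    if n < 2:
        return ModuleAssignment(pd.Series(0, index=pd.Index(genes), dtype=int))
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    Z = linkage(squareform(diss, checks=False), method="average")
    hmax = Z[:, 2].max()
    flat = fcluster(Z, t=cut_height * hmax, criterion="distance")
    labels = pd.Series(0, index=pd.Index(genes), dtype=int)
    clusters: dict[int, list[int]] = {}
    for pos, c in enumerate(flat):
        clusters.setdefault(int(c), []).append(pos)
    survivors = [
        (c, members)
        for c, members in clusters.items()
        if len(members) >= min_module_size
    ]
    if not survivors:
        logger.warning("no cluster reached min_module_size=%d; all module 0",
                       min_module_size)
        return ModuleAssignment(labels)
    survivors.sort(key=lambda cm: (-len(cm[1]), min(cm[1])))
    for new_id, (_, members) in enumerate(survivors, start=1):
        labels.iloc[members] = new_id
    return ModuleAssignment(labels)


def merge_close_modules(
    x: pd.DataFrame,
    modules: ModuleAssignment,
    merge_cut: float = 0.15,
) -> ModuleAssignment:
    """Merge modules whose provisional eigengenes are nearly identical.

    Pairs of modules with eigengene dissimilarity 1 - cor below
    ``merge_cut`` are merged (closest pair first), iterating until stable;
    surviving modules are renumbered by decreasing size. ``merge_cut=0``
    returns the assignment unchanged.
    """
    from .eigengenes import compute_eigengenes

    if merge_cut <= 0:
        return modules
    labels = modules.labels.copy()
    merged_any = False
    while True:
        current = ModuleAssignment(labels)
        ids = current.module_ids
        if len(ids) < 2:
            break
        _, eig = compute_eigengenes(x, current, labels=None)
        corr = np.corrcoef(eig.to_numpy().T)
        diss = 1.0 - corr
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut:
            break
        keep, drop = sorted((ids[i], ids[j]))
        logger.info("merging module %d into module %d (dissimilarity %.3f)",
                    drop, keep, diss[i, j])
        labels[labels == drop] = keep
        merged_any = True
    if not merged_any:
        return modules
    # renumber by decreasing size, deterministic on ties
    current = ModuleAssignment(labels)
    order = sorted(
        current.module_ids,
        key=lambda m: (-current.sizes[m], labels.index.get_indexer(current.genes_in(m)).min()),
    )
    remap = {old: new for new, old in enumerate(order, start=1)}
    new_labels = labels.map(lambda m: remap.get(int(m), 0))
    return ModuleAssignment(new_labels.astype(int))
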