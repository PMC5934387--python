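"""Synthetic expression data with the structure the method assumes.

A Gaussian latent-factor generator: each module has one factor per sample
whose mean shifts between disease classes by that module's effect size; a
gene in the module is its factor scaled to a target gene-factor correlation
plus independent noise. Probe-level replication with multi-mapping and a
per-gene affine "platform" transform emulate, respectively, microarray
probe annotation and a change of expression-profiling technology.

Defaults are the desk-scale study conditions used throughout the test
suite: 10 modules of 30 genes (two carrying a class shift of d = 2), 100
unstructured noise genes, gene-factor correlation 0.85, and 150 samples
per class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticTruth",
    "generate_expression",
    "generate_from_truth",
    "generate_probe_level",
    "platform_transform",
]

DEFAULT_MODULE_SIZES = (30,) * 10
DEFAULT_EFFECT_SIZES = {1: 2.0, 2: 2.0}


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset; sufficient to draw more samples."""

    module_sizes: list[int]
    membership: pd.Series          # gene_id -> module (0 = noise gene)
    loadings: pd.Series            # gene_id -> gene-factor correlation
    effect_sizes: dict[int, float] # module -> class shift of the factor mean
    within_cor: float
    n_pos: int
    n_neg: int
    seed: int

    @property
    def effect_modules(self) -> list[int]:
        return sorted(m for m, d in self.effect_sizes.items() if d != 0)

    def to_dict(self) -> dict:
        return {
            "module_sizes": [int(s) for s in self.module_sizes],
            "membership": {g: int(m) for g, m in self.membership.items()},
            "loadings": {g: float(l) for g, l in self.loadings.items()},
            "effect_sizes": {str(m): float(d) for m, d in self.effect_sizes.items()},
            "within_cor": float(self.within_cor),
            "n_pos": int(self.n_pos),
            "n_neg": int(self.n_neg),
            "seed": int(self.seed),
        }


def generate_from_truth(
    truth: SyntheticTruth, n_pos: int, n_neg: int, seed: int, prefix: str = "s"
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw fresh samples from an existing ground truth."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    sample_ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    genes = list(truth.membership.index)
    values = np.empty((len(genes), n))
    n_modules = len(truth.module_sizes)
    factors = {}
    for m in range(1, n_modules + 1):
        d = truth.effect_sizes.get(m, 0.0)
        factors[m] = rng.normal(labels * d, 1.0)
    for gi, g in enumerate(genes):
        m = int(truth.membership[g])
        if m == 0:
            values[gi] = rng.normal(0.0, 1.0, size=n)
        else:
            lam = float(truth.loadings[g])
            noise_sd = math.sqrt(max(1.0 - lam * lam, 0.0))
            values[gi] = lam * factors[m] + rng.normal(0.0, noise_sd, size=n)
    x = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    return x, pd.Series(labels, index=sample_ids, name="label")


def generate_expression(
    n_pos: int = 150,
    n_neg: int = 150,
    module_sizes=DEFAULT_MODULE_SIZES,
    n_noise_genes: int = 100,
    within_cor: float = 0.85,
    effect_sizes: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Modular latent-factor expression matrix with class-linked modules.

    Per module m the latent factor is N(label * d_m, 1) per sample; a gene
    in m equals lambda * factor + noise with lambda = ``within_cor`` so the
    population gene-factor correlation matches. Noise genes are pure N(0,1).
    Returns (genes x samples matrix, labels, truth).
    """
    if not 0 < within_cor < 1:
        raise ValueError("within_cor must be in (0, 1)")
    if any(s < 2 for s in module_sizes):
        raise ValueError("module sizes must be >= 2")
    if effect_sizes is None:
        effect_sizes = dict(DEFAULT_EFFECT_SIZES)
    membership: dict[str, int] = {}
    loadings: dict[str, float] = {}
    gi = 0
    for m, size in enumerate(module_sizes, start=1):
        for _ in range(size):
            gi += 1
            g = f"g{gi:05d}"
            membership[g] = m
            loadings[g] = within_cor
    for _ in range(n_noise_genes):
        gi += 1
        g = f"g{gi:05d}"
        membership[g] = 0
        loadings[g] = 0.0
    truth = SyntheticTruth(
        module_sizes=list(module_sizes),
        membership=pd.Series(membership, name="module"),
        loadings=pd.Series(loadings, name="loading"),
        effect_sizes={int(m): float(d) for m, d in effect_sizes.items()},
        within_cor=float(within_cor),
        n_pos=int(n_pos),
        n_neg=int(n_neg),
        seed=int(seed),
    )
    x, labels = generate_from_truth(truth, n_pos, n_neg, seed)
    return x, labels, truth


def generate_probe_level(
    x: pd.DataFrame,
    probes_per_gene: int | tuple[int, int] = (1, 3),
    multimap_fraction: float = 0.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a gene matrix to probes with optional multi-mapping.

    Each gene is replicated into 1-3 probes (uniform over the given range,
    or exactly ``probes_per_gene`` if an int) with independent Gaussian
    measurement noise; a ``multimap_fraction`` of probes is additionally
    mapped to one other random gene. Returns (probe matrix, probe map with
    columns probe_id/gene_id).
    """
    if not 0 <= multimap_fraction <= 1:
        raise ValueError("multimap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(x.index)
    rows = []
    mapping = []
    for g in genes:
        if isinstance(probes_per_gene, int):
            n_p = probes_per_gene
        else:
            n_p = int(rng.integers(probes_per_gene[0], probes_per_gene[1] + 1))
        for j in range(n_p):
            pid = f"{g}_p{j + 1}"
            rows.append((pid, x.loc[g].to_numpy() + rng.normal(0, noise_sd, x.shape[1])))
            mapping.append((pid, g))
            if len(genes) > 1 and rng.random() < multimap_fraction:
                other = genes[int(rng.integers(len(genes)))]
                while other == g:
                    other = genes[int(rng.integers(len(genes)))]
                mapping.append((pid, other))
    probes = pd.DataFrame(
        {pid: vals for pid, vals in rows}, index=x.columns
    ).T
    probes.index.name = "probe_id"
    probe_map = pd.DataFrame(mapping, columns=["probe_id", "gene_id"])
    return probes, probe_map


def platform_transform(
    x: pd.DataFrame,
    seed: int = 0,
    noise_sd: float = 0.0,
    dropout: float = 0.0,
    slope_range: tuple[float, float] = (0.5, 2.0),
    offset_range: tuple[float, float] = (-2.0, 2.0),
) -> pd.DataFrame:
    """Monotone per-gene platform change: y = a_g x + b_g + noise.

    a_g ~ U(slope_range), b_g ~ U(offset_range), noise ~ N(0, noise_sd); a
    ``dropout`` fraction of genes is removed entirely (genes not measured
    on the new platform).
    """
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    vals = x.to_numpy(dtype=float)
    a = rng.uniform(*slope_range, size=(x.shape[0], 1))
    b = rng.uniform(*offset_range, size=(x.shape[0], 1))
    y = a * vals + b
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    out = pd.DataFrame(y, index=x.index, columns=x.columns)
    if dropout > 0:
        n_drop = int(round(dropout * x.shape[0]))
        drop = rng.choice(x.shape[0], size=n_drop, replace=False)
        out = out.drop(index=x.index[drop])
    return out
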