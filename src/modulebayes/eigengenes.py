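"""Module eigengenes: class-balanced first principal components.

An eigengene summarises a gene module as one value per sample: the first
principal component of the module's standardized expression submatrix. To
stop the larger disease class from dominating the component, samples are
oversampled to near-equal class representation before the weights are
estimated; eigengene values are then evaluated on the original samples.
Because genes are z-scored, a trained eigengene can be projected onto a
dataset from a different platform (any per-gene affine change of scale is
absorbed), which is the mechanism behind cross-platform prediction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import ModuleAssignment
from .preprocess import adjust_pvalues

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleWeights",
    "EigengeneModel",
    "balance_classes",
    "compute_eigengenes",
    "project_eigengenes",
    "eigengene_differential_test",
]


@dataclass
class ModuleWeights:
    """Unit-norm gene weights plus training standardization for one module."""

    genes: list[str]
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "weights": [float(w) for w in self.weights],
            "means": [float(m) for m in self.means],
            "sds": [float(s) for s in self.sds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModuleWeights":
        return cls(
            genes=list(d["genes"]),
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
        )


@dataclass
class EigengeneModel:
    """Trained eigengene weights for every module, keyed by module index."""

    modules: dict[int, ModuleWeights]
    factors: dict[int, int] | None = None

    @property
    def module_names(self) -> list[str]:
        return [f"M{m}" for m in sorted(self.modules)]

    def to_dict(self) -> dict:
        return {
            "modules": {str(m): w.to_dict() for m, w in self.modules.items()},
            "factors": (
                {str(c): int(f) for c, f in self.factors.items()}
                if self.factors
                else None
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EigengeneModel":
        return cls(
            modules={int(m): ModuleWeights.from_dict(w) for m, w in d["modules"].items()},
            factors=(
                {int(c): int(f) for c, f in d["factors"].items()}
                if d.get("factors")
                else None
            ),
        )


def balance_classes(
    sample_ids,
    labels: pd.Series,
    factors: dict[int, int] | None = None,
    f_ref: int = 9,
) -> tuple[list[int], dict[int, int]]:
    """Oversample both classes to near-equal representation.

    When ``factors`` is omitted, the largest class is repeated ``f_ref``
    times and each other class c is repeated round(f_ref * n_ref / n_c)
    times (reproducing factors 9 and 11 for class sizes 202 and 164).

    Returns the expanded list of positional sample indices (input order,
    repeats contiguous) and the per-class factors used.
    """
    sample_ids = list(sample_ids)
    lab = labels.reindex(sample_ids)
    if lab.isna().any():
        raise ValueError("labels missing for some samples")
    counts = lab.value_counts()
    if len(counts) != 2:
        raise ValueError("exactly two non-empty classes are required")
    if factors is None:
        ref_class = counts.idxmax()
        n_ref = int(counts[ref_class])
        factors = {}
        for c, n_c in counts.items():
            factors[int(c)] = (
                int(f_ref)
                if c == ref_class
                else int(math.floor(f_ref * n_ref / n_c + 0.5))
            )
    factors = {int(c): int(f) for c, f in factors.items()}
    if any(f < 1 for f in factors.values()):
        raise ValueError("oversampling factors must be >= 1")
    expanded: list[int] = []
    lab_arr = lab.to_numpy()
    for i in range(len(sample_ids)):
        expanded.extend([i] * factors[int(lab_arr[i])])
    return expanded, factors


def compute_eigengenes(
    x: pd.DataFrame,
    modules: ModuleAssignment,
    labels: pd.Series | None = None,
    factors: dict[int, int] | None = None,
    f_ref: int = 9,
) -> tuple[EigengeneModel, pd.DataFrame]:
    """First principal component of each module's standardized submatrix.

    Weights are estimated on the class-balanced (oversampled) expansion
    when ``labels`` are given; eigengene values are always evaluated on the
    original samples as z_m(s) = sum_g w_m[g] (x[g,s] - mean_g) / sd_g.
    The component sign is flipped so the eigengene correlates positively
    with the module's mean standardized expression.
    """
    ids = modules.module_ids
    if not ids:
        raise ValueError("no non-grey modules to summarise")
    if labels is not None:
        expanded, used_factors = balance_classes(x.columns, labels, factors, f_ref)
    else:
        expanded, used_factors = list(range(x.shape[1])), None

    model_modules: dict[int, ModuleWeights] = {}
    columns: dict[str, np.ndarray] = {}
    for m in ids:
        genes = modules.genes_in(m)
        missing = [g for g in genes if g not in x.index]
        if missing:
            raise ValueError(f"module {m} genes missing from matrix: {missing[:5]}")
        sub_full = x.loc[genes].to_numpy(dtype=float)
        sub = sub_full[:, expanded]
        means = sub.mean(axis=1)
        sds = sub.std(axis=1)
        keep = sds > 1e-12 * np.maximum(1.0, np.abs(means))
        if not keep.all():
            logger.warning(
                "module %d: dropping %d zero-variance genes", m, int((~keep).sum())
            )
        if not keep.any():
            logger.warning("module %d: all genes zero-variance; skipped", m)
            continue
        genes = [g for g, k in zip(genes, keep) if k]
        sub, sub_full = sub[keep], sub_full[keep]
        means, sds = means[keep], sds[keep]
        if len(genes) == 1:
            w = np.array([1.0])
        else:
            z = ((sub - means[:, None]) / sds[:, None]).T  # expanded samples x genes
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            w = vt[0]
            score = z @ w
            ref = z.mean(axis=1)
            if score.std() > 0 and ref.std() > 0:
                if np.corrcoef(score, ref)[0, 1] < 0:
                    w = -w
        z_orig = ((sub_full - means[:, None]) / sds[:, None]).T
        columns[f"M{m}"] = z_orig @ w
        model_modules[m] = ModuleWeights(
            genes=genes, weights=w, means=means, sds=sds
        )

    eig = pd.DataFrame(columns, index=x.columns)
    eig = eig[[f"M{m}" for m in sorted(model_modules)]]
    return EigengeneModel(modules=model_modules, factors=used_factors), eig


def project_eigengenes(model: EigengeneModel, y: pd.DataFrame) -> pd.DataFrame:
    """Project trained eigengenes onto a new dataset ``y``.

    For each module, weights are restricted to the genes present in ``y``
    and renormalized to unit norm; the shared genes are z-scored *within*
    ``y`` (no training statistics are applied), which makes the projection
    invariant to per-gene affine transforms of the new platform. Modules
    sharing no genes with ``y`` yield a zero column with a warning.
    """
    columns: dict[str, np.ndarray] = {}
    any_shared = False
    for m in sorted(model.modules):
        mw = model.modules[m]
        pos = [i for i, g in enumerate(mw.genes) if g in y.index]
        name = f"M{m}"
        if pos:
            sub = y.loc[[mw.genes[i] for i in pos]].to_numpy(dtype=float)
            sds = sub.std(axis=1)
            ok = sds > 1e-12 * np.maximum(1.0, np.abs(sub.mean(axis=1)))
            pos = [p for p, k in zip(pos, ok) if k]
            sub = sub[ok]
        if not pos:
            logger.warning("module %d shares no usable genes with new data", m)
            columns[name] = np.zeros(y.shape[1])
            continue
        any_shared = True
        w = mw.weights[pos]
        w = w / np.linalg.norm(w)
        means = sub.mean(axis=1)
        sds = sub.std(axis=1)
        z = ((sub - means[:, None]) / sds[:, None]).T
        columns[name] = z @ w
    if not any_shared:
        raise ValueError("new dataset shares no genes with any module")
    return pd.DataFrame(columns, index=y.columns)[
        [f"M{m}" for m in sorted(model.modules)]
    ]


def eigengene_differential_test(
    eig: pd.DataFrame, labels: pd.Series, adjust: str = "bh"
) -> pd.DataFrame:
    """Welch two-sample t-test per eigengene, with adjusted p-values."""
    lab = labels.reindex(eig.index)
    if lab.isna().any():
        raise ValueError("labels missing for some samples")
    classes = np.unique(lab.to_numpy())
    if classes.size != 2:
        raise ValueError("exactly two classes are required")
    pos = eig.loc[lab == classes.max()].to_numpy(dtype=float)
    neg = eig.loc[lab == classes.min()].to_numpy(dtype=float)
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise ValueError("each class needs at least 2 samples")
    t, p = stats.ttest_ind(pos, neg, axis=0, equal_var=False)
    p = np.nan_to_num(np.asarray(p, dtype=float), nan=1.0)
    return pd.DataFrame(
        {
            "t_statistic": np.nan_to_num(np.asarray(t, dtype=float), nan=0.0),
            "p_value": p,
            "adjusted_p_value": adjust_pvalues(p, method=adjust),
        },
        index=eig.columns,
    )
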