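"""Probe-level differential screening and collapsing to one probe per gene.

Microarray expression arrives as a probes x samples matrix in which several
probes may interrogate the same gene and some probes hit more than one gene.
This module ranks probes by differential expression between the two disease
classes (moderated or Welch two-sample t), keeps the most discriminative
fraction, removes multi-mapped probes, and picks the lowest-p probe as each
gene's single representative.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "moderated_t_test",
    "adjust_pvalues",
    "filter_top_fraction",
    "select_gene_representatives",
]


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def _fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Estimate (d0, s0_sq) of the scaled inverse-chi-square variance prior.

    Method of moments on log sample variances: the excess spread of
    log(s^2) beyond trigamma(d/2) identifies the prior degrees of freedom
    through the trigamma function; the centre identifies the prior variance.
    A non-positive excess yields an infinite-d0 (fully shrunk) prior.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return math.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    ev = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if ev > 0:
        d0 = 2.0 * _trigamma_inverse(ev)
        s0_sq = float(
            np.exp(np.mean(e) + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
        )
    else:
        d0 = math.inf
        s0_sq = float(np.exp(np.mean(e)))
    return d0, s0_sq


def _split_classes(
    x: pd.DataFrame, labels: pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    labels = labels.reindex(x.columns)
    if labels.isna().any():
        missing = list(x.columns[labels.isna()])
        raise ValueError(f"labels missing for samples: {missing[:5]}")
    lab = labels.to_numpy()
    classes = np.unique(lab)
    if classes.size < 2:
        raise ValueError("labels required: both classes must be present")
    if classes.size > 2:
        raise ValueError(f"expected binary labels, got classes {classes}")
    pos = x.to_numpy(dtype=float)[:, lab == classes.max()]
    neg = x.to_numpy(dtype=float)[:, lab == classes.min()]
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise ValueError("each class needs at least 2 samples")
    return pos, neg


def moderated_t_test(
    x: pd.DataFrame,
    labels: pd.Series,
    method: str = "moderated",
    d0: float | None = None,
    s0_sq: float | None = None,
    adjust: str = "bh",
) -> pd.DataFrame:
    """Two-sample differential test per feature (row) of ``x``.

    Parameters
    ----------
    x : DataFrame, features x samples, log-scale expression.
    labels : per-sample binary class (1 = positive, 0 = negative).
    method : "moderated" for the empirical-Bayes shrunken pooled-variance t,
        "welch" for the plain unequal-variance t.
    d0, s0_sq : optional overrides of the variance-prior hyperparameters
        (moderated mode only). ``d0=0`` recovers the ordinary pooled t.
    adjust : multiple-testing adjustment for the reported
        ``adjusted_p_value`` column ("bh", "bonferroni" or "none").

    Returns
    -------
    DataFrame indexed like ``x`` with columns ``t_statistic``, ``p_value``,
    ``adjusted_p_value`` and ``df``; the fitted hyperparameters are stored in
    ``result.attrs["d0"]`` / ``result.attrs["s0_sq"]``.

    Features with zero variance in both classes are reported as t = 0, p = 1.
    """
    pos, neg = _split_classes(x, labels)
    n1, n0 = pos.shape[1], neg.shape[1]
    m1, m0 = pos.mean(axis=1), neg.mean(axis=1)
    v1 = pos.var(axis=1, ddof=1)
    v0 = neg.var(axis=1, ddof=1)
    diff = m1 - m0
    degenerate = (v1 == 0) & (v0 == 0)

    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = v1 / n1 + v0 / n0
            t = diff / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        attrs = {"d0": None, "s0_sq": None, "method": "welch"}
    elif method == "moderated":
        d = float(n1 + n0 - 2)
        s2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / d
        if d0 is None or s0_sq is None:
            d0_fit, s0_fit = _fit_variance_prior(s2, d)
            d0 = d0_fit if d0 is None else d0
            s0_sq = s0_fit if s0_sq is None else s0_sq
        if math.isinf(d0):
            s_tilde = np.full_like(s2, s0_sq)
            df = np.full(s2.shape, np.inf)
        else:
            s_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
            df = np.full(s2.shape, d + d0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(s_tilde * (1.0 / n1 + 1.0 / n0))
            t = diff / se
        zero_se = se == 0
        t[zero_se] = np.sign(diff[zero_se]) * np.inf
        t[zero_se & (diff == 0)] = 0.0
        if math.isinf(d0):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df)
        p[zero_se & (diff == 0)] = 1.0
        attrs = {"d0": d0, "s0_sq": s0_sq, "method": "moderated"}
    else:
        raise ValueError(f"unknown method {method!r}")

    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    p = np.clip(p, 0.0, 1.0)
    out = pd.DataFrame(
        {
            "t_statistic": t,
            "p_value": p,
            "adjusted_p_value": adjust_pvalues(p, method=adjust),
            "df": df,
        },
        index=x.index,
    )
    out.attrs.update(attrs)
    return out


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment of a p-value vector.

    ``bh`` is Benjamini-Hochberg step-up (monotone, capped at 1);
    ``bonferroni`` and ``none`` are also available.
    """
    arr = np.asarray(p, dtype=float)
    if arr.size and np.isnan(arr).any():
        raise ValueError("p-values contain NaN")
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr.copy()
    if method == "none":
        return arr.copy()
    if method == "bonferroni":
        return np.minimum(arr * arr.size, 1.0)
    if method == "bh":
        return multipletests(arr, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def filter_top_fraction(
    x: pd.DataFrame, stats_df: pd.DataFrame, fraction: float
) -> pd.DataFrame:
    """Keep the ``ceil(fraction * P)`` features with smallest p-values.

    Ties at the cutoff are broken by feature id (lexicographic), and the
    original row order of the survivors is preserved.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if set(stats_df.index) != set(x.index) or len(stats_df) != len(x):
        raise ValueError("differential statistics do not match matrix features")
    n_keep = math.ceil(fraction * len(x))
    order = sorted(x.index, key=lambda pid: (stats_df.at[pid, "p_value"], str(pid)))
    keep = set(order[:n_keep])
    return x.loc[[pid for pid in x.index if pid in keep]]


def select_gene_representatives(
    x: pd.DataFrame, probe_map: pd.DataFrame, stats_df: pd.DataFrame
) -> pd.DataFrame:
    """Collapse probes to one representative probe per gene.

    Probes mapped to more than one gene are excluded first; unmapped probes
    are dropped (count logged). For each gene the surviving probe with the
    smallest p-value (ties by probe id) becomes that gene's row; the output
    is keyed by gene id.
    """
    pm = probe_map[["probe_id", "gene_id"]].drop_duplicates()
    gene_counts = pm.groupby("probe_id")["gene_id"].nunique()
    multi = set(gene_counts[gene_counts > 1].index)
    mapped = set(pm["probe_id"])
    n_multi = sum(1 for pid in x.index if pid in multi)
    n_unmapped = sum(1 for pid in x.index if pid not in mapped)
    if n_multi:
        logger.info("excluded %d multi-mapped probes", n_multi)
    if n_unmapped:
        logger.info("dropped %d unmapped probes", n_unmapped)

    usable = pm[pm["probe_id"].isin(set(x.index) - multi)]
    reps: dict[str, str] = {}
    for gene, grp in usable.groupby("gene_id"):
        probes = sorted(
            grp["probe_id"], key=lambda pid: (stats_df.at[pid, "p_value"], str(pid))
        )
        reps[str(gene)] = probes[0]
    if not reps:
        raise ValueError("no mappable probes")
    genes = sorted(reps)
    out = x.loc[[reps[g] for g in genes]].copy()
    out.index = pd.Index(genes, name="gene_id")
    return out
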