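"""Discrete Bayesian networks over eigengenes with a binary Effect node.

Eigengenes are discretized into three levels by Hartemink's pairwise
mutual-information method, structures are learned by hill climbing on the
BDe(u) score under a blacklist forbidding outgoing Effect arcs, bootstrap
replicates are averaged into a consensus DAG, and conditional probability
tables are fitted as Dirichlet posterior means. Because Effect has no
children, its Markov blanket is exactly its parents, so exact prediction is
a CPT lookup; likelihood-weighting inference is provided as well and agrees
with the lookup.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "DiscreteData",
    "DiscretizationModel",
    "BNModel",
    "ArcStrengthTable",
    "HillClimbResult",
    "hartemink_discretize",
    "bde_score",
    "hill_climb",
    "bootstrap_structures",
    "consensus_network",
    "fit_parameters",
    "is_acyclic",
    "topological_order",
]

DAGType = dict[str, frozenset]


# ---------------------------------------------------------------------------
# discrete data container


class DiscreteData:
    """Complete discrete dataset: integer levels per node, declared arities."""

    def __init__(self, frame: pd.DataFrame, arities: dict[str, int] | None = None):
        self.frame = frame
        self.names: list[str] = [str(c) for c in frame.columns]
        self.values = frame.to_numpy(dtype=np.int64)
        if np.any(self.values < 0):
            raise ValueError("discrete levels must be non-negative integers")
        observed = {n: int(self.values[:, j].max()) + 1 if len(frame) else 1
                    for j, n in enumerate(self.names)}
        if arities is None:
            arities = observed
        for n in self.names:
            if observed[n] > arities.get(n, 0):
                raise ValueError(f"node {n}: observed level exceeds declared arity")
        self.arities = {n: int(arities[n]) for n in self.names}
        self._idx = {n: j for j, n in enumerate(self.names)}

    def __len__(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self._idx[name]]

    def subset_rows(self, rows: np.ndarray) -> "DiscreteData":
        sub = DiscreteData.__new__(DiscreteData)
        sub.frame = self.frame.iloc[rows]
        sub.names = self.names
        sub.values = self.values[rows]
        sub.arities = self.arities
        sub._idx = self._idx
        return sub


# ---------------------------------------------------------------------------
# DAG helpers


def topological_order(dag: DAGType) -> list[str]:
    """Kahn topological sort; raises on cycles."""
    indeg = {n: len(ps) for n, ps in dag.items()}
    children: dict[str, list[str]] = {n: [] for n in dag}
    for n, ps in dag.items():
        for p in ps:
            children[p].append(n)
    queue = sorted(n for n, d in indeg.items() if d == 0)
    order = []
    while queue:
        n = queue.pop(0)
        order.append(n)
        added = False
        for c in children[n]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
                added = True
        if added:
            queue.sort()
    if len(order) != len(dag):
        raise ValueError("graph contains a cycle")
    return order


def is_acyclic(dag: DAGType) -> bool:
    try:
        topological_order(dag)
        return True
    except ValueError:
        return False


def dag_arcs(dag: DAGType) -> set[tuple[str, str]]:
    return {(p, n) for n, ps in dag.items() for p in ps}


def _has_path(children: dict[str, set], src: str, dst: str) -> bool:
    """Directed path src -> ... -> dst over a children map."""
    stack = [src]
    seen = set()
    while stack:
        n = stack.pop()
        if n == dst:
            return True
        if n in seen:
            continue
        seen.add(n)
        stack.extend(children[n])
    return False


# ---------------------------------------------------------------------------
# Hartemink discretization


@dataclass
class DiscretizationModel:
    """Per-variable cut points (z-scale) learned by Hartemink's method.

    ``transform`` z-scores each variable *within the supplied data* and
    replays the cuts, so a per-variable affine change of scale in new data
    does not change the discrete output.
    """

    variables: list[str]
    cuts: dict[str, np.ndarray]
    means: dict[str, float]
    sds: dict[str, float]
    levels: int
    ibreaks: int

    def transform(self, e: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for v in self.variables:
            vals = e[v].to_numpy(dtype=float)
            sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
            if sd == 0:
                z = np.zeros_like(vals)
            else:
                z = (vals - vals.mean()) / sd
            lev = np.searchsorted(self.cuts[v], z, side="right")
            out[v] = np.clip(lev, 0, self.levels - 1)
        return pd.DataFrame(out, index=e.index)[self.variables]

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "cuts": {v: [float(c) for c in self.cuts[v]] for v in self.variables},
            "means": {v: float(self.means[v]) for v in self.variables},
            "sds": {v: float(self.sds[v]) for v in self.variables},
            "levels": int(self.levels),
            "ibreaks": int(self.ibreaks),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscretizationModel":
        return cls(
            variables=list(d["variables"]),
            cuts={v: np.asarray(c, dtype=float) for v, c in d["cuts"].items()},
            means={v: float(m) for v, m in d["means"].items()},
            sds={v: float(s) for v, s in d["sds"].items()},
            levels=int(d["levels"]),
            ibreaks=int(d["ibreaks"]),
        )


def _mutual_information(a: np.ndarray, b: np.ndarray, ra: int, rb: int) -> float:
    n = a.size
    joint = np.bincount(a * rb + b, minlength=ra * rb).reshape(ra, rb) / n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    outer = pa[:, None] * pb[None, :]
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def _initial_bins(z: np.ndarray, ibreaks: int) -> np.ndarray:
    """Rank-based quantile binning of z into at most ``ibreaks`` levels.

    Assignment depends only on the rank distribution, so any strictly
    monotone transform of the input yields the same bins. When there are at
    most ``ibreaks`` distinct values, each value keeps its own bin.
    """
    u, inv = np.unique(z, return_inverse=True)
    m = u.size
    if m <= ibreaks:
        return inv
    cnt = np.bincount(inv)
    cum = np.cumsum(cnt)
    mid = (cum - cnt / 2.0) / z.size  # empirical CDF at each distinct value
    bins_of_value = np.minimum((mid * ibreaks).astype(int), ibreaks - 1)
    # compress to consecutive occupied labels
    occupied = np.unique(bins_of_value)
    remap = {b: i for i, b in enumerate(occupied)}
    bins_of_value = np.array([remap[b] for b in bins_of_value])
    return bins_of_value[inv]


def hartemink_discretize(
    e: pd.DataFrame,
    levels: int = 3,
    ibreaks: int = 20,
    extra: pd.DataFrame | None = None,
) -> tuple[DiscretizationModel, pd.DataFrame]:
    """Multivariate information-preserving discretization.

    Each variable is z-scored and quantile-binned into (up to) ``ibreaks``
    levels; then, cycling over variables in fixed column order, the pair of
    adjacent levels whose collapse loses the least total pairwise mutual
    information with the other variables is merged, until every variable
    has at most ``levels`` levels. Cut points (z-scale) are recorded so the
    mapping can be replayed on new data.

    ``extra`` may carry already-discrete variables (e.g. the binary class
    node): they participate in the mutual-information totals — so merges
    keep level boundaries that carry information about them — but are never
    merged themselves and are not part of the returned mapping.

    Constant variables are assigned the middle level with a warning.
    """
    variables = [str(c) for c in e.columns]
    n = len(e)
    zmat: dict[str, np.ndarray] = {}
    disc: dict[str, np.ndarray] = {}
    cut_values: dict[str, list[float]] = {}
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    middle = min(levels - 1, levels // 2)
    for v in variables:
        vals = e[v].to_numpy(dtype=float)
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        means[v], sds[v] = mu, sd
        if sd == 0:
            logger.warning("variable %s is constant; assigned middle level", v)
            zmat[v] = np.zeros(n)
            disc[v] = np.full(n, middle, dtype=np.int64)
            cuts = [-math.inf] * middle + [math.inf] * (levels - 1 - middle)
            cut_values[v] = cuts
            continue
        z = (vals - mu) / sd
        zmat[v] = z
        bins = _initial_bins(z, ibreaks)
        disc[v] = bins.astype(np.int64)
        nbin = int(bins.max()) + 1
        cuts = []
        for b in range(nbin - 1):
            lo = z[bins == b].max()
            hi = z[bins == b + 1].min()
            cuts.append(float((lo + hi) / 2.0))
        cut_values[v] = cuts

    others: dict[str, np.ndarray] = dict(disc)
    if extra is not None:
        for c in extra.columns:
            others[str(c)] = extra[c].to_numpy(dtype=np.int64)

    mergeable = [v for v in variables if len(cut_values[v]) + 1 > levels]
    while mergeable:
        for v in list(mergeable):
            nlev = len(cut_values[v]) + 1
            if nlev <= levels:
                mergeable.remove(v)
                continue
            dv = disc[v]
            best_cut, best_total = None, -math.inf
            for c in range(nlev - 1):
                merged = dv - (dv > c)
                total = 0.0
                for u, du in others.items():
                    if u == v:
                        continue
                    total += _mutual_information(
                        merged, du, nlev - 1, int(du.max()) + 1
                    )
                if total > best_total + 1e-12:
                    best_total, best_cut = total, c
            disc[v] = dv - (dv > best_cut)
            del cut_values[v][best_cut]
            others[v] = disc[v]
            if len(cut_values[v]) + 1 <= levels:
                mergeable.remove(v)

    model = DiscretizationModel(
        variables=variables,
        cuts={v: np.asarray(cut_values[v], dtype=float) for v in variables},
        means=means,
        sds=sds,
        levels=levels,
        ibreaks=ibreaks,
    )
    frame = pd.DataFrame({v: disc[v] for v in variables}, index=e.index)[variables]
    return model, frame


# ---------------------------------------------------------------------------
# BDe scoring


def _family_score(
    values: np.ndarray,
    arity_arr: np.ndarray,
    child: int,
    parents: tuple[int, ...],
    iss: float,
) -> float:
    """BDeu log marginal-likelihood contribution of one node family."""
    n = values.shape[0]
    r = int(arity_arr[child])
    q = 1
    codes = np.zeros(n, dtype=np.int64)
    for p in parents:
        codes = codes * arity_arr[p] + values[:, p]
        q *= int(arity_arr[p])
    a_ijk = iss / (r * q)
    a_ij = iss / q
    if q * r <= 200_000:
        counts = np.bincount(codes * r + values[:, child], minlength=q * r)
        counts = counts.reshape(q, r)
        nij = counts.sum(axis=1)
        seen = nij > 0
        term = float(
            np.sum(gammaln(a_ij) - gammaln(a_ij + nij[seen]))
            + np.sum(gammaln(a_ijk + counts[seen]) - gammaln(a_ijk))
        )
        return term
    # sparse path for huge parent-state spaces: unseen configs contribute 0
    joint, jcnt = np.unique(codes * r + values[:, child], return_counts=True)
    cfg = joint // r
    ucfg, start = np.unique(cfg, return_index=True)
    nij = np.add.reduceat(jcnt, start)
    return float(
        np.sum(gammaln(a_ij) - gammaln(a_ij + nij))
        + np.sum(gammaln(a_ijk + jcnt) - gammaln(a_ijk))
    )


def bde_score(dag: DAGType, data: DiscreteData, iss: float = 1.0) -> float:
    """BDe(u) log score of a DAG: sum of per-family marginal likelihoods.

    Uses a uniform Dirichlet prior with imaginary sample size ``iss``
    spread over the joint parent-child states, which makes Markov-equivalent
    DAGs score identically.
    """
    if not is_acyclic(dag):
        raise ValueError("graph contains a cycle")
    arity_arr = np.array([data.arities[n] for n in data.names], dtype=np.int64)
    total = 0.0
    for node, parents in dag.items():
        child = data._idx[node]
        pidx = tuple(sorted(data._idx[p] for p in parents))
        total += _family_score(data.values, arity_arr, child, pidx, iss)
    return total


# ---------------------------------------------------------------------------
# structure search


@dataclass
class HillClimbResult:
    dag: DAGType
    score: float


class _Climber:
    def __init__(self, data: DiscreteData, blacklist, iss: float, tol: float):
        self.data = data
        self.nodes = sorted(data.names)
        self.blacklist = {(str(u), str(v)) for u, v in blacklist}
        self.iss = iss
        self.tol = tol
        self.arity_arr = np.array(
            [data.arities[n] for n in data.names], dtype=np.int64
        )
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def family(self, node: str, parents: frozenset) -> float:
        key = (node, tuple(sorted(parents)))
        val = self._cache.get(key)
        if val is None:
            child = self.data._idx[node]
            pidx = tuple(sorted(self.data._idx[p] for p in parents))
            val = _family_score(self.data.values, self.arity_arr, child, pidx, self.iss)
            self._cache[key] = val
        return val

    def total(self, parents: dict[str, set]) -> float:
        return sum(self.family(n, frozenset(ps)) for n, ps in parents.items())

    def _children(self, parents: dict[str, set]) -> dict[str, set]:
        ch: dict[str, set] = {n: set() for n in self.nodes}
        for n, ps in parents.items():
            for p in ps:
                ch[p].add(n)
        return ch

    def candidate_moves(self, parents: dict[str, set]):
        """Valid moves in lexicographic (operation, from, to) order."""
        children = self._children(parents)
        moves = []
        for u in self.nodes:
            for v in self.nodes:
                if u == v:
                    continue
                if u not in parents[v] and (u, v) not in self.blacklist:
                    if not _has_path(children, v, u):
                        moves.append(("add", u, v))
        for u in self.nodes:
            for v in self.nodes:
                if u != v and u in parents[v]:
                    moves.append(("delete", u, v))
        for u in self.nodes:
            for v in self.nodes:
                if u == v or u not in parents[v]:
                    continue
                if (v, u) in self.blacklist:
                    continue
                children[u].discard(v)
                ok = not _has_path(children, u, v)
                children[u].add(v)
                if ok:
                    moves.append(("reverse", u, v))
        return moves

    def delta(self, parents: dict[str, set], move) -> float:
        op, u, v = move
        pv = frozenset(parents[v])
        if op == "add":
            return self.family(v, pv | {u}) - self.family(v, pv)
        if op == "delete":
            return self.family(v, pv - {u}) - self.family(v, pv)
        pu = frozenset(parents[u])
        return (
            self.family(v, pv - {u})
            - self.family(v, pv)
            + self.family(u, pu | {v})
            - self.family(u, pu)
        )

    def apply(self, parents: dict[str, set], move) -> None:
        op, u, v = move
        if op == "add":
            parents[v].add(u)
        elif op == "delete":
            parents[v].discard(u)
        else:
            parents[v].discard(u)
            parents[u].add(v)

    def climb(self, start: dict[str, set]) -> tuple[dict[str, set], float]:
        parents = {n: set(ps) for n, ps in start.items()}
        score = self.total(parents)
        while True:
            best_move, best_delta = None, self.tol
            for move in self.candidate_moves(parents):
                d = self.delta(parents, move)
                if d > best_delta:
                    best_move, best_delta = move, d
            if best_move is None:
                return parents, score
            self.apply(parents, best_move)
            score += best_delta


def hill_climb(
    data: DiscreteData,
    blacklist=(),
    iss: float = 1.0,
    tol: float = 1e-8,
    restarts: int = 0,
    perturb: int = 2,
    seed: int | None = None,
) -> HillClimbResult:
    """Greedy BDe hill climbing from the empty DAG.

    Each step evaluates every single-arc addition, deletion and reversal
    that keeps the graph acyclic and respects the blacklist, and applies the
    best strictly improving move (ties broken by lexicographic
    (operation, from, to) order). With ``restarts`` > 0 the local optimum is
    perturbed by ``perturb`` random valid arc changes and re-climbed,
    keeping the best-scoring result.
    """
    climber = _Climber(data, blacklist, iss, tol)
    empty = {n: set() for n in climber.nodes}
    best_parents, best_score = climber.climb(empty)
    if restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            parents = {n: set(ps) for n, ps in best_parents.items()}
            for _ in range(perturb):
                moves = climber.candidate_moves(parents)
                if not moves:
                    break
                climber.apply(parents, moves[rng.integers(len(moves))])
            cand_parents, cand_score = climber.climb(parents)
            if cand_score > best_score + tol:
                best_parents, best_score = cand_parents, cand_score
    dag = {n: frozenset(ps) for n, ps in best_parents.items()}
    return HillClimbResult(dag=dag, score=best_score)


def bootstrap_structures(
    data: DiscreteData,
    R: int = 500,
    blacklist=(),
    iss: float = 1.0,
    tol: float = 1e-8,
    restarts: int = 0,
    seed: int | None = None,
) -> list[tuple[DAGType, float]]:
    """Learn ``R`` structures on bootstrap resamples of the rows.

    Each replicate draws n rows with replacement and hill-climbs on the
    replicate; the learned DAG is then re-scored on the FULL dataset so the
    replicate scores are comparable. Reproducible given ``seed``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(data)
    out: list[tuple[DAGType, float]] = []
    for _ in range(R):
        rows = rng.integers(0, n, size=n)
        sub = data.subset_rows(rows)
        sub_seed = int(rng.integers(2**31)) if restarts > 0 else None
        res = hill_climb(
            sub, blacklist=blacklist, iss=iss, tol=tol,
            restarts=restarts, seed=sub_seed,
        )
        out.append((res.dag, bde_score(res.dag, data, iss=iss)))
    return out


@dataclass
class ArcStrengthTable:
    """Directed arc strengths over the retained bootstrap networks."""

    strengths: dict[tuple[str, str], float]
    n_retained: int
    scores: list[float]


def consensus_network(
    boot: list[tuple[DAGType, float]],
    top_fraction: float = 1.0 / 3.0,
    strength_threshold: float = 0.5,
    blacklist=(),
) -> tuple[DAGType, ArcStrengthTable]:
    """Average the highest-scoring bootstrap structures into one DAG.

    The ``ceil(R * top_fraction)`` best-scoring networks are retained (score
    ties resolved in favour of earlier replicates); each directed arc's
    strength is the fraction of retained networks containing it. Arcs with
    strength >= ``strength_threshold`` are inserted in decreasing strength
    order, skipping (with a log message) any insertion that would create a
    cycle or violate the blacklist.
    """
    R = len(boot)
    if R < 3:
        raise ValueError("need at least 3 bootstrap networks")
    n_keep = math.ceil(R * top_fraction)
    if n_keep < 1:
        raise ValueError("retained set is empty")
    scores = np.array([s for _, s in boot], dtype=float)
    order = np.argsort(-scores, kind="stable")[:n_keep]
    retained = [boot[i] for i in order]
    nodes = sorted(retained[0][0].keys())
    counts: dict[tuple[str, str], int] = {}
    for dag, _ in retained:
        for arc in dag_arcs(dag):
            counts[arc] = counts.get(arc, 0) + 1
    strengths = {arc: c / n_keep for arc, c in counts.items()}
    bl = {(str(u), str(v)) for u, v in blacklist}
    consensus: DAGType = {n: frozenset() for n in nodes}
    mutable = {n: set() for n in nodes}
    for arc in sorted(strengths, key=lambda a: (-strengths[a], a)):
        if strengths[arc] < strength_threshold:
            break
        u, v = arc
        if arc in bl:
            logger.info("consensus: skipping blacklisted arc %s->%s", u, v)
            continue
        mutable[v].add(u)
        if not is_acyclic({n: frozenset(ps) for n, ps in mutable.items()}):
            mutable[v].discard(u)
            logger.info("consensus: skipping cycle-creating arc %s->%s", u, v)
    consensus = {n: frozenset(ps) for n, ps in mutable.items()}
    return consensus, ArcStrengthTable(
        strengths=strengths, n_retained=n_keep, scores=[float(s) for s in scores]
    )


# ---------------------------------------------------------------------------
# parameters and inference


@dataclass
class BNModel:
    """Fitted discrete Bayesian network.

    ``cpts[node]`` has shape (arity, q) where q is the number of parent
    configurations; configurations are indexed mixed-radix over the parents
    sorted lexicographically, the first parent being the most significant
    digit. All entries are strictly positive (Dirichlet smoothing).
    """

    nodes: list[str]
    parents: dict[str, tuple[str, ...]]
    arities: dict[str, int]
    cpts: dict[str, np.ndarray]
    iss: float = 1.0
    effect: str = "Effect"

    def dag(self) -> DAGType:
        return {n: frozenset(self.parents[n]) for n in self.nodes}

    def parent_config_index(self, node: str, assignment: dict[str, int]) -> int:
        j = 0
        for p in self.parents[node]:
            try:
                val = assignment[p]
            except KeyError:
                raise ValueError(f"missing value for parent {p!r} of {node!r}")
            r = self.arities[p]
            if not 0 <= val < r:
                raise ValueError(f"value {val} out of range for {p!r}")
            j = j * r + val
        return j

    def predict_effect_exact(
        self, evidence: dict[str, int], warn_on_tie: bool = True
    ) -> tuple[int, np.ndarray]:
        """Read the Effect CPT row for the observed parent configuration.

        Returns (most probable class, posterior vector). An exact tie
        resolves to class 0 with a warning (suppressible for batch callers
        that aggregate their own tie counts).
        """
        j = self.parent_config_index(self.effect, evidence)
        post = self.cpts[self.effect][:, j].copy()
        best = int(np.argmax(post))
        if np.sum(post == post.max()) > 1:
            if warn_on_tie:
                logger.warning("tied Effect posterior; predicting class 0")
            best = 0
        return best, post

    def predict_effect_lw(
        self,
        evidence: dict[str, int],
        n_particles: int = 500,
        seed: int | None = None,
    ) -> tuple[int, np.ndarray]:
        """Likelihood-weighting estimate of the Effect posterior.

        Evidence must cover every non-Effect node. Each particle samples
        the unobserved nodes from their CPTs in topological order and is
        weighted by the likelihood of the evidence nodes given their
        parents; the posterior is the normalized weighted count.
        """
        missing = [n for n in self.nodes if n != self.effect and n not in evidence]
        if missing:
            raise ValueError(f"evidence must cover all non-Effect nodes; missing {missing}")
        rng = np.random.default_rng(seed)
        order = topological_order(self.dag())
        r_eff = self.arities[self.effect]
        weights = np.zeros(r_eff, dtype=float)
        for _ in range(n_particles):
            assign = dict(evidence)
            w = 1.0
            for node in order:
                j = self.parent_config_index(node, assign)
                probs = self.cpts[node][:, j]
                if node in evidence:
                    w *= probs[evidence[node]]
                else:
                    assign[node] = int(rng.choice(self.arities[node], p=probs / probs.sum()))
            weights[assign[self.effect]] += w
        assert weights.sum() > 0, "all particle weights vanished"
        post = weights / weights.sum()
        best = int(np.argmax(post))
        if np.sum(post == post.max()) > 1:
            best = 0
        return best, post

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "parents": {n: list(self.parents[n]) for n in self.nodes},
            "arities": {n: int(self.arities[n]) for n in self.nodes},
            "cpts": {n: self.cpts[n].tolist() for n in self.nodes},
            "iss": float(self.iss),
            "effect": self.effect,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BNModel":
        return cls(
            nodes=list(d["nodes"]),
            parents={n: tuple(p) for n, p in d["parents"].items()},
            arities={n: int(a) for n, a in d["arities"].items()},
            cpts={n: np.asarray(c, dtype=float) for n, c in d["cpts"].items()},
            iss=float(d["iss"]),
            effect=d.get("effect", "Effect"),
        )


def fit_parameters(
    dag: DAGType, data: DiscreteData, iss: float = 1.0, effect: str = "Effect"
) -> BNModel:
    """Fit CPTs as Dirichlet posterior means (N_ijk + a_ijk)/(N_ij + a_ij).

    Parent configurations never observed fall back to the uniform prior.
    """
    if not is_acyclic(dag):
        raise ValueError("graph contains a cycle")
    nodes = sorted(dag.keys())
    parents = {n: tuple(sorted(dag[n])) for n in nodes}
    cpts: dict[str, np.ndarray] = {}
    for node in nodes:
        r = data.arities[node]
        q = 1
        codes = np.zeros(len(data), dtype=np.int64)
        for p in parents[node]:
            codes = codes * data.arities[p] + data.column(p)
            q *= data.arities[p]
        counts = np.bincount(codes * r + data.column(node), minlength=q * r)
        counts = counts.reshape(q, r).T.astype(float)  # (r, q)
        a_ijk = iss / (r * q)
        a_ij = iss / q
        cpts[node] = (counts + a_ijk) / (counts.sum(axis=0, keepdims=True) + a_ij)
    return BNModel(
        nodes=nodes, parents=parents, arities=dict(data.arities),
        cpts=cpts, iss=iss, effect=effect,
    )
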