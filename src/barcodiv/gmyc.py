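"""Single-threshold generalized mixed Yule-coalescent (GMYC) delimitation.

The model places a threshold time ``T`` on an ultrametric tree: branching
events older than ``T`` belong to a generalized Yule (diversification)
process, events younger than ``T`` to generalized coalescent processes
running independently inside each cluster (a cluster is the set of tips
subtended by a branch crossing ``T``).  With ``n_div`` diversification
lineages and ``n_j`` lineages inside cluster ``j`` alive on an inter-event
interval, the total branching rate on that interval is

    lambda = b_div * n_div**p_div + b_coal * sum_j (n_j*(n_j-1))**p_coal

and the log-likelihood is the broken-exponential sum ``log lambda - lambda*x``
over the waiting intervals between successive branching events.  The rate is
piecewise constant and switches class at ``T``; each event's density uses the
rate of the interval on its tipward side, which is the exact likelihood of
the corresponding inhomogeneous pure-birth process read backward in time.

The fit maximizes this likelihood over the four rate parameters at every
candidate threshold (midpoints between distinct branching times), compares
the winner against a one-process null by a 3-df likelihood-ratio test, and
scores entities by Akaike weights over the candidate-threshold model set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import dendropy
from scipy.optimize import minimize
from scipy.stats import chi2

from .trees import is_ultrametric, node_ages

__all__ = [
    "EntityPartition", "GmycFit", "CandidateFit", "NodeSupport",
    "branching_times", "entities_at_threshold", "mixed_loglik",
    "fit_null", "fit_single_threshold", "aic_entity_supports",
    "select_st_vs_mm",
]

P_BOUNDS = (0.0, 3.0)
LOG_B_BOUNDS = (-30.0, 30.0)


# ---------------------------------------------------------------------------
# partitions

@dataclass
class EntityPartition:
    """Tip partition induced by a threshold: clusters plus singletons."""

    assignment: dict[str, str]            # tip label -> entity id
    entities: dict[str, frozenset[str]]   # entity id -> tip set

    @property
    def entity_count(self) -> int:
        return len(self.entities)

    @property
    def cluster_count(self) -> int:
        return sum(1 for tips in self.entities.values() if len(tips) >= 2)

    def entity_of(self, tip: str) -> str:
        return self.assignment[tip]

    def tip_sets(self) -> set[frozenset[str]]:
        return set(self.entities.values())

    @classmethod
    def from_assignment(cls, assignment: dict[str, str]) -> "EntityPartition":
        ents: dict[str, set[str]] = {}
        for tip, eid in assignment.items():
            ents.setdefault(eid, set()).add(tip)
        return cls(assignment=dict(assignment),
                   entities={e: frozenset(t) for e, t in ents.items()})


def branching_times(tree: dendropy.Tree, rel_tol: float = 1e-6) -> np.ndarray:
    """Internal-node ages (time before present), sorted descending from the root."""
    ages = node_ages(tree, rel_tol=rel_tol)
    times = sorted((ages[n] for n in tree.preorder_internal_node_iter()),
                   reverse=True)
    return np.array(times, dtype=float)


def entities_at_threshold(tree: dendropy.Tree, T: float,
                          rel_tol: float = 1e-6) -> EntityPartition:
    """One entity per branch crossing time ``T``: its descendant tips."""
    ages = node_ages(tree, rel_tol=rel_tol)
    root_age = ages[tree.seed_node]
    if not (0.0 < T < root_age):
        raise ValueError(f"threshold {T} outside (0, root height {root_age})")
    assignment: dict[str, str] = {}
    entities: dict[str, frozenset[str]] = {}
    k = 0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        child_age = ages[node]
        if ages[parent] > T >= child_age:
            k += 1
            eid = f"E{k:04d}"
            if node.is_leaf():
                tips = frozenset([node.taxon.label])
            else:
                tips = frozenset(l.taxon.label for l in node.leaf_iter())
            entities[eid] = tips
            for t in tips:
                assignment[t] = eid
    return EntityPartition(assignment=assignment, entities=entities)


# ---------------------------------------------------------------------------
# likelihood machinery

@dataclass
class _IntervalData:
    """Piecewise-constant rate structure of a tree for one threshold."""

    seg_x: np.ndarray        # (S,) segment lengths, tipward to rootward
    seg_ndiv: np.ndarray     # (S,) diversification lineage counts (0 below T)
    coal_pairs: np.ndarray   # (S, J) n_j*(n_j-1) per cluster, 0 above T
    event_seg: np.ndarray    # (E,) segment index on the tipward side of each event


def _interval_data(tree: dendropy.Tree, T: float | None,
                   rel_tol: float = 1e-6) -> _IntervalData:
    ages = node_ages(tree, rel_tol=rel_tol)
    internal = list(tree.preorder_internal_node_iter())
    event_ages = np.array([ages[n] for n in internal], dtype=float)
    root_age = ages[tree.seed_node]

    points = set(np.round(event_ages, 15)) | {0.0}
    if T is not None and 0.0 < T < root_age:
        points.add(round(T, 15))
    bps = np.array(sorted(points))            # ascending, 0 .. root age
    lo, hi = bps[:-1], bps[1:]
    mids = 0.5 * (lo + hi)
    S = len(mids)

    # total lineages alive on each segment
    total = 1 + np.array([(event_ages > m).sum() for m in mids])

    if T is None:
        seg_ndiv = total
        coal_pairs = np.zeros((S, 0), dtype=float)
    else:
        below = mids < T
        # clusters = branches crossing T; a crossing branch remains a
        # diversification lineage below T until it ends at the cluster MRCA
        clusters: list[list[float]] = []      # per cluster: internal node ages within
        mrca_ages: list[float] = []
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                continue
            if ages[parent] > T >= ages[node]:
                mrca_ages.append(ages[node])
                if node.is_leaf():
                    clusters.append([])
                else:
                    sub = [ages[n] for n in node.preorder_iter()
                           if not n.is_leaf()]
                    clusters.append(sub)
        mrca = np.array(mrca_ages, dtype=float)
        ndiv_below = np.array([(mrca <= m).sum() for m in mids])
        seg_ndiv = np.where(below, ndiv_below, total)
        J = len(clusters)
        counts = np.zeros((S, J), dtype=float)
        for j, sub_ages in enumerate(clusters):
            sub = np.array(sub_ages, dtype=float)
            top = mrca[j]
            for s in np.nonzero(below)[0]:
                if mids[s] < top:
                    counts[s, j] = 1 + (sub > mids[s]).sum()
        coal_pairs = counts * (counts - 1.0)

    # each event pairs with the segment whose rootward endpoint is its age
    hi_round = np.round(hi, 15)
    seg_index = {h: i for i, h in enumerate(hi_round)}
    event_seg = np.array([seg_index[a] for a in np.round(event_ages, 15)],
                         dtype=int)
    return _IntervalData(seg_x=hi - lo, seg_ndiv=seg_ndiv.astype(float),
                         coal_pairs=coal_pairs, event_seg=event_seg)


def _loglik(data: _IntervalData, b_div: float, p_div: float,
            b_coal: float, p_coal: float) -> float:
    with np.errstate(over="ignore", invalid="ignore"):
        ndiv = data.seg_ndiv
        div_term = np.where(ndiv > 0, ndiv ** p_div, 0.0)
        cp = data.coal_pairs
        if cp.shape[1]:
            coal_term = np.where(cp > 0, cp ** p_coal, 0.0).sum(axis=1)
        else:
            coal_term = 0.0
        lam = b_div * div_term + b_coal * coal_term
    lam_ev = lam[data.event_seg]
    if np.any(lam_ev <= 0) or not np.all(np.isfinite(lam)):
        return -np.inf
    return float(np.log(lam_ev).sum() - (lam * data.seg_x).sum())


def mixed_loglik(tree: dendropy.Tree, T: float, b_div: float, p_div: float,
                 b_coal: float, p_coal: float) -> float:
    """GMYC mixed-model log-likelihood at explicit parameter values."""
    if b_div <= 0 or b_coal <= 0:
        raise ValueError("rate scales must be positive")
    for p in (p_div, p_coal):
        if not P_BOUNDS[0] <= p <= P_BOUNDS[1]:
            raise ValueError(f"exponent {p} outside {P_BOUNDS}")
    if np.isnan(logl := _loglik(_interval_data(tree, T), b_div, p_div,
                                b_coal, p_coal)):
        raise ValueError("non-finite likelihood intermediate")
    return logl


def _optimize_mixed(data: _IntervalData, height: float) -> tuple[np.ndarray, float]:
    """Deterministic multi-start maximization over (log b_div, p_div, log b_coal, p_coal)."""
    def nll(x):
        return -_loglik(data, np.exp(x[0]), x[1], np.exp(x[2]), x[3])

    bounds = [LOG_B_BOUNDS, P_BOUNDS, LOG_B_BOUNDS, P_BOUNDS]
    best_x, best_f = None, np.inf
    for b0 in (0.1, 1.0, 10.0):
        x0 = np.array([np.log(b0 / height), 1.0, np.log(b0 / height), 1.0])
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError("mixed-model optimization failed at all starts")
    return best_x, -best_f


@dataclass
class CandidateFit:
    """Fitted mixed model at one candidate threshold."""

    threshold: float
    b_div: float
    p_div: float
    b_coal: float
    p_coal: float
    logL: float
    aic: float
    partition: EntityPartition


@dataclass
class GmycFit:
    """Maximum-likelihood single-threshold GMYC fit with its candidate set."""

    threshold: float
    b_div: float
    p_div: float
    b_coal: float
    p_coal: float
    logL: float
    n_params: int
    aic: float
    partition: EntityPartition
    null_logL: float
    null_aic: float
    lr_stat: float
    lr_p_value: float
    candidates: list[CandidateFit] = field(default_factory=list)

    def report(self) -> dict:
        return {
            "threshold": self.threshold,
            "b_div": self.b_div, "p_div": self.p_div,
            "b_coal": self.b_coal, "p_coal": self.p_coal,
            "logL": self.logL, "aic": self.aic, "n_params": self.n_params,
            "null_logL": self.null_logL, "null_aic": self.null_aic,
            "lr_stat": self.lr_stat, "lr_p_value": self.lr_p_value,
            "entity_count": self.partition.entity_count,
            "cluster_count": self.partition.cluster_count,
        }


def fit_null(tree: dendropy.Tree) -> tuple[float, float, float, float]:
    """One generalized branching process over the whole tree.

    Returns ``(b, p, logL, aic)`` with ``aic = 2*2 - 2*logL``.
    """
    if sum(1 for _ in tree.leaf_node_iter()) < 3:
        raise ValueError("null model needs >= 3 tips")
    data = _interval_data(tree, None)
    height = float(branching_times(tree)[0])

    def nll(x):
        lam_scale, p = np.exp(x[0]), x[1]
        with np.errstate(over="ignore"):
            lam = lam_scale * data.seg_ndiv ** p
        if not np.all(np.isfinite(lam)):
            return np.inf
        return float((lam * data.seg_x).sum()
                     - np.log(lam[data.event_seg]).sum())

    best_x, best_f = None, np.inf
    for b0 in (0.1, 1.0, 10.0):
        res = minimize(nll, np.array([np.log(b0 / height), 1.0]),
                       method="L-BFGS-B", bounds=[LOG_B_BOUNDS, P_BOUNDS])
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError("null-model optimization failed")
    b, p = float(np.exp(best_x[0])), float(best_x[1])
    logL = -best_f
    return b, p, logL, 2 * 2 - 2 * logL


def candidate_thresholds(tree: dendropy.Tree) -> np.ndarray:
    """Midpoints between consecutive distinct branching times, plus one
    between the youngest internal node and the tips."""
    times = np.unique(branching_times(tree))[::-1]   # distinct, descending
    mids = 0.5 * (times[:-1] + times[1:])
    return np.append(mids, times[-1] / 2.0)


def fit_single_threshold(tree: dendropy.Tree, n_params: int = 5) -> GmycFit:
    """Maximum-likelihood single-threshold GMYC fit.

    Every candidate threshold is fitted and retained (the candidate set is
    what Akaike-weight supports and the multimodel average are computed
    from); the threshold itself counts as a parameter by default (k=5).
    """
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < 4:
        raise ValueError("single-threshold fit needs >= 4 tips")
    height = float(branching_times(tree)[0])
    cands: list[CandidateFit] = []
    for T in candidate_thresholds(tree):
        data = _interval_data(tree, float(T))
        try:
            x, logL = _optimize_mixed(data, height)
        except RuntimeError:
            continue
        cands.append(CandidateFit(
            threshold=float(T),
            b_div=float(np.exp(x[0])), p_div=float(x[1]),
            b_coal=float(np.exp(x[2])), p_coal=float(x[3]),
            logL=logL, aic=2 * n_params - 2 * logL,
            partition=entities_at_threshold(tree, float(T)),
        ))
    if not cands:
        raise RuntimeError("optimization failed at every candidate threshold")
    best = max(cands, key=lambda c: c.logL)
    _, _, null_logL, null_aic = fit_null(tree)
    lr = 2.0 * (best.logL - null_logL)
    return GmycFit(
        threshold=best.threshold,
        b_div=best.b_div, p_div=best.p_div,
        b_coal=best.b_coal, p_coal=best.p_coal,
        logL=best.logL, n_params=n_params, aic=best.aic,
        partition=best.partition,
        null_logL=null_logL, null_aic=null_aic,
        lr_stat=lr, lr_p_value=float(chi2.sf(max(lr, 0.0), df=3)),
        candidates=cands,
    )


# ---------------------------------------------------------------------------
# Akaike-weight supports and multimodel averaging

@dataclass
class NodeSupport:
    """Akaike-weight support per entity (tip set)."""

    st_supports: dict[frozenset[str], float]
    mm_supports: dict[frozenset[str], float]
    weights: list[float]

    def support_of(self, tips: frozenset[str]) -> float:
        return self.mm_supports.get(tips, self.st_supports.get(tips, 0.0))


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def aic_entity_supports(fit: GmycFit, floor: float = 0.01) -> NodeSupport:
    """Sum of Akaike weights of candidate models containing each entity.

    ST supports cover the entities of the maximum-likelihood partition; MM
    supports cover every entity whose weight sum exceeds ``floor``.
    """
    aics = np.array([c.aic for c in fit.candidates])
    w = akaike_weights(aics)
    tally: dict[frozenset[str], float] = {}
    for wk, cand in zip(w, fit.candidates):
        for tips in cand.partition.tip_sets():
            tally[tips] = tally.get(tips, 0.0) + float(wk)
    st = {tips: min(tally.get(tips, 0.0), 1.0)
          for tips in fit.partition.tip_sets()}
    mm = {tips: min(s, 1.0) for tips, s in tally.items() if s >= floor}
    return NodeSupport(st_supports=st, mm_supports=mm, weights=list(map(float, w)))


def select_st_vs_mm(fit: GmycFit) -> dict:
    """Compare the ML single-threshold model against the weight-averaged set.

    Reports both AIC conventions; the lower score is selected, with ST
    preferred on ties.  Downstream classification uses the selected
    partition (identical in both cases: the multimodel variant changes
    supports, not the point partition).
    """
    aics = np.array([c.aic for c in fit.candidates])
    w = akaike_weights(aics)
    st_aic = float(fit.aic)
    mm_aic = float((w * aics).sum())
    selected = "ST" if st_aic <= mm_aic else "MM"
    return {"st_aic": st_aic, "mm_aic": mm_aic, "selected": selected}
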