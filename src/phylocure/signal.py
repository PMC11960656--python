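"""Pagel's lambda for a binary trait by maximum likelihood.

The trait follows a two-state symmetric Markov model (equal forward and
backward rate q, stationary root frequencies (1/2, 1/2)), fitted on
lambda-transformed trees: internal branches are multiplied by lambda while
terminal branches are stretched so every tip keeps its original root-to-tip
height. lambda = 1 leaves the tree unchanged; lambda = 0 collapses it to a
star, i.e. no phylogenetic structure. The likelihood is maximized jointly
over (lambda, q) per tree, and signal across a tree ensemble is summarized
by the median and 2.5/97.5 percentiles of the per-tree estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .phylo import PhylogenyEnsemble, is_ultrametric, tip_heights

__all__ = [
    "SignalEstimate",
    "lambda_transform",
    "mk_loglik",
    "fit_lambda",
    "aggregate_signal",
    "simulate_binary_trait",
]


@dataclass
class SignalEstimate:
    lambdas: np.ndarray  # per-tree ML estimates
    rates: np.ndarray
    median: float
    ci_low: float  # 2.5 percentile across trees
    ci_high: float  # 97.5 percentile


def lambda_transform(
    tree: dendropy.Tree, lam: float, ultrametric_tol: float = 1e-6
) -> dendropy.Tree:
    """Pagel lambda branch-length transform (tip heights preserved).

    Requires an ultrametric tree within ``ultrametric_tol`` relative spread
    of root-to-tip heights.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if not is_ultrametric(tree, ultrametric_tol):
        raise ValueError("lambda transform requires an ultrametric tree")
    out = tree.clone(depth=1)
    heights = tip_heights(out)
    # depth of each internal node from the root, on the original tree
    depth = {id(out.seed_node): 0.0}
    for node in out.preorder_node_iter():
        if node.parent_node is None:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (
            node.edge.length or 0.0
        )
    for node in out.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.is_leaf():
            node.edge.length = heights[node.taxon.label] - lam * depth[
                id(node.parent_node)
            ]
        else:
            node.edge.length = lam * node.edge.length
    return out


def _prob_same(q: float, t: float) -> float:
    """Transition probability of remaining in the same state."""
    return 0.5 * (1.0 + np.exp(-2.0 * q * t))


def mk_loglik(tree: dendropy.Tree, tip_states: dict[str, int], q: float) -> float:
    """Felsenstein pruning log-likelihood, symmetric 2-state model.

    ``tip_states`` maps tip label to 0/1 (or to a length-2 probability pair
    for uncertain tips). Root state weighted by the (1/2, 1/2) equilibrium.
    """
    if q <= 0:
        raise ValueError("rate q must be positive")
    logscale = 0.0
    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            st = tip_states[node.taxon.label]
            if np.ndim(st) == 0:
                vec = np.zeros(2)
                vec[int(st)] = 1.0
            else:
                vec = np.asarray(st, dtype=float)
            partials[id(node)] = vec
            continue
        vec = np.ones(2)
        for child in node.child_nodes():
            ps = _prob_same(q, child.edge.length or 0.0)
            P = np.array([[ps, 1.0 - ps], [1.0 - ps, ps]])
            vec = vec * (P @ partials.pop(id(child)))
        norm = vec.sum()
        if norm <= 0:
            return -np.inf
        logscale += np.log(norm)
        partials[id(node)] = vec / norm
    root = partials[id(tree.seed_node)]
    return float(logscale + np.log(0.5 * root.sum()))


def fit_lambda(
    tree: dendropy.Tree,
    tip_states: dict[str, int],
    n_starts: int = 5,
) -> tuple[float, float, float]:
    """Joint ML fit of (lambda, q); returns (lambda_hat, q_hat, loglik).

    Bounded multi-start quasi-Newton search over (logit lambda, log q),
    with the boundary values lambda in {0, 1} also profiled over q; among
    near-ties the smaller lambda wins. All-same-state tips are degenerate
    (lambda unidentified); a warning is emitted and lambda_hat = 0 reported.
    """
    states = np.array(
        [tip_states[l.taxon.label] for l in tree.leaf_node_iter()]
    )
    if states.ndim == 1 and len(set(states.tolist())) < 2:
        warnings.warn(
            "degenerate trait (all tips share one state); "
            "lambda is unidentified",
            UserWarning,
            stacklevel=2,
        )
        return 0.0, np.nan, np.nan

    cache: dict[float, dendropy.Tree] = {}

    def transformed(lam: float) -> dendropy.Tree:
        key = round(float(lam), 12)
        if key not in cache:
            if len(cache) > 64:
                cache.clear()
            cache[key] = lambda_transform(tree, key)
        return cache[key]

    def negll(x) -> float:
        lam = float(expit(x[0]))
        q = float(np.exp(x[1]))
        return -mk_loglik(transformed(lam), tip_states, q)

    height = max(tip_heights(tree).values())
    q0 = 1.0 / height
    starts = [
        (logit(l0), np.log(q0 * m))
        for l0, m in [(0.05, 1.0), (0.3, 1.0), (0.5, 3.0), (0.7, 1.0),
                      (0.95, 1.0)][:n_starts]
    ]
    candidates = []
    for x0 in starts:
        res = minimize(
            negll,
            x0=np.array(x0),
            method="L-BFGS-B",
            bounds=[(-9.0, 9.0), (np.log(q0) - 8.0, np.log(q0) + 8.0)],
        )
        candidates.append((float(expit(res.x[0])), float(np.exp(res.x[1])),
                           -float(res.fun)))
    # profile the boundaries lambda = 0, 1 exactly
    for lam_b in (0.0, 1.0):
        tr = transformed(lam_b)

        def neg_q(y):
            return -mk_loglik(tr, tip_states, float(np.exp(y[0])))

        res = minimize(
            neg_q,
            x0=np.array([np.log(q0)]),
            method="L-BFGS-B",
            bounds=[(np.log(q0) - 8.0, np.log(q0) + 8.0)],
        )
        candidates.append((lam_b, float(np.exp(res.x[0])), -float(res.fun)))
    best_ll = max(c[2] for c in candidates)
    near = [c for c in candidates if c[2] >= best_ll - 1e-6]
    lam_hat, q_hat, ll = min(near, key=lambda c: c[0])  # ties: smaller lambda
    return lam_hat, q_hat, ll


def aggregate_signal(
    lambdas, rates=None
) -> SignalEstimate:
    """Median and 2.5/97.5 percentiles of per-tree lambda estimates."""
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("need at least one per-tree estimate")
    rates = (
        np.asarray(rates, dtype=float)
        if rates is not None
        else np.full_like(lambdas, np.nan)
    )
    lo, med, hi = np.percentile(lambdas, [2.5, 50.0, 97.5])
    return SignalEstimate(
        lambdas=lambdas,
        rates=rates,
        median=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
    )


def estimate_signal(
    ensemble: PhylogenyEnsemble, tip_states: dict[str, int],
    n_trees: int | None = None,
) -> SignalEstimate:
    """fit_lambda on each ensemble tree, aggregated across trees."""
    trees = ensemble.trees if n_trees is None else ensemble.trees[:n_trees]
    lams, qs = [], []
    for tree in trees:
        lam, q, _ = fit_lambda(tree, tip_states)
        lams.append(lam)
        qs.append(q)
    return aggregate_signal(lams, qs)


def simulate_binary_trait(
    tree: dendropy.Tree, q: float, seed: int | np.random.Generator
) -> dict[str, int]:
    """Forward-simulate the symmetric 2-state model down the tree."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    state = {id(tree.seed_node): int(rng.uniform() < 0.5)}
    tips = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            ps = _prob_same(q, node.edge.length or 0.0)
            parent = state[id(node.parent_node)]
            same = rng.uniform() < ps
            state[id(node)] = parent if same else 1 - parent
        if node.is_leaf():
            tips[node.taxon.label] = state[id(node)]
    return tips
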