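"""Ancestral state reconstruction under the threshold model.

A latent continuous liability evolves along the tree as a stationary
Ornstein-Uhlenbeck process; the binary state of a node is the sign of its
liability (positive = tool use). Stationarity makes the joint liability of
all nodes multivariate normal with covariance exp(-a * Dn), where Dn holds
node-to-node patristic distances and a is the mean-reversion rate. The
stationary variance is fixed to 1 — threshold models are scale-free — and a
carries a half-Normal(0, 1) prior.

Inference is Gibbs sampling: tip liabilities are updated one at a time from
their truncated-normal full conditionals (the truncation side set by the
tip's currently imputed state), internal liabilities are redrawn jointly
from their exact multivariate-normal conditional, and a is slice-sampled
periodically. Uncertain tips (e.g. survival-cure posterior medians used as
state probabilities) are re-imputed from their Bernoulli probabilities at
every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtr, ndtri

from .data import normalize_species_id
from .phylo import PhylogenyEnsemble, mrca_node, node_distance_matrix

__all__ = [
    "AsrConfig",
    "AsrResult",
    "asr_sample",
    "genus_mrca_table",
]


@dataclass
class AsrConfig:
    n_iter: int = 50_000
    burn_frac: float = 0.2
    n_retained: int = 1_000
    a_update_interval: int = 10
    fix_a: float | None = None  # fix the OU rate (used by exact-oracle checks)
    rhat_threshold: float = 1.05


def _truncnorm(mu: float, sd: float, positive: bool, rng) -> float:
    """Draw from N(mu, sd^2) truncated to x > 0 (or x < 0)."""
    if not positive:
        return -_truncnorm(-mu, sd, True, rng)
    alpha = -mu / sd  # lower bound in standard units
    if alpha < 6.0:
        lo = ndtr(alpha)
        u = rng.uniform(lo, 1.0)
        u = min(u, 1.0 - 1e-16)
        return mu + sd * ndtri(u)
    # deep tail: Robert's exponential rejection on the standard scale
    while True:
        lam = 0.5 * (alpha + np.sqrt(alpha * alpha + 4.0))
        x = alpha + rng.exponential(1.0 / lam)
        if rng.uniform() <= np.exp(-0.5 * (x - lam) ** 2):
            return mu + sd * x


@dataclass
class AsrResult:
    nodes: list  # internal nodes, preorder
    node_probs: np.ndarray  # posterior P(state 1) per internal node
    draws: np.ndarray  # retained sign indicators, draws x internal nodes
    a_draws: np.ndarray
    tree: dendropy.Tree

    def prob_at(self, node) -> float:
        for i, nd in enumerate(self.nodes):
            if nd is node:
                return float(self.node_probs[i])
        raise KeyError("node is not an internal node of this reconstruction")

    def draws_at(self, node) -> np.ndarray:
        for i, nd in enumerate(self.nodes):
            if nd is node:
                return self.draws[:, i]
        raise KeyError("node is not an internal node of this reconstruction")


def asr_sample(
    tree: dendropy.Tree,
    tip_state_probs: dict[str, float],
    config: AsrConfig | None = None,
    seed: int = 0,
) -> AsrResult:
    """Posterior state probabilities for every internal node.

    ``tip_state_probs`` maps tip label to the probability of the positive
    (tool-use) state; hard codings use 0.0 / 1.0. Reproducible from seed.
    """
    config = config or AsrConfig()
    rng = np.random.default_rng(seed)
    nodes, Dn = node_distance_matrix(tree)
    is_tip = np.array([nd.is_leaf() for nd in nodes])
    tips = np.where(is_tip)[0]
    internal = np.where(~is_tip)[0]
    labels = [nodes[i].taxon.label for i in tips]
    missing = [l for l in labels if l not in tip_state_probs]
    if missing:
        raise KeyError(f"tips without state probabilities: {missing}")
    q1 = np.array([float(tip_state_probs[l]) for l in labels])
    if np.any((q1 < 0) | (q1 > 1)):
        raise ValueError("tip state probabilities must lie in [0, 1]")

    n = len(nodes)
    a = config.fix_a if config.fix_a is not None else 1.0

    state = {"Lam": None, "cho_II": None, "B": None}

    def set_rate(a_val: float) -> None:
        Sigma = np.exp(-a_val * Dn)
        cho = cho_factor(Sigma, lower=True)
        Lam = cho_solve(cho, np.eye(n))
        Lam_II = Lam[np.ix_(internal, internal)]
        state["Lam"] = Lam
        state["logdet_sigma"] = 2.0 * np.sum(np.log(np.diag(cho[0])))
        state["cho_II"] = cho_factor(Lam_II, lower=True)
        state["L_II"] = np.linalg.cholesky(Lam_II)
        state["Lam_IT"] = Lam[np.ix_(internal, tips)]

    def liability_logpdf(a_val: float, x: np.ndarray) -> float:
        Sigma = np.exp(-a_val * Dn)
        try:
            cho = cho_factor(Sigma, lower=True)
        except np.linalg.LinAlgError:
            return -np.inf
        quad = x @ cho_solve(cho, x)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        return -0.5 * (quad + logdet)

    set_rate(a)
    x = rng.standard_normal(n) * 0.1
    s = rng.uniform(size=len(tips)) < q1  # imputed tip states
    for j, i in enumerate(tips):
        x[i] = abs(x[i]) if s[j] else -abs(x[i])

    burn = int(config.burn_frac * config.n_iter)
    keep_every = max(1, (config.n_iter - burn) // config.n_retained)
    draws, a_draws = [], []
    for it in range(config.n_iter):
        # impute tip states from their probabilities
        s = rng.uniform(size=len(tips)) < q1
        # tip liabilities: truncated-normal full conditionals, sequential
        Lam = state["Lam"]
        for j, i in enumerate(tips):
            lam_ii = Lam[i, i]
            r = Lam[i] @ x - lam_ii * x[i]
            mu = -r / lam_ii
            sd = 1.0 / np.sqrt(lam_ii)
            x[i] = _truncnorm(mu, sd, bool(s[j]), rng)
        # internal liabilities: exact joint conditional given the tips
        rhs = -(state["Lam_IT"] @ x[tips])
        mean_I = cho_solve(state["cho_II"], rhs)
        noise = solve_triangular(
            state["L_II"], rng.standard_normal(len(internal)),
            lower=True, trans="T",
        )
        x[internal] = mean_I + noise
        # OU rate: slice sample log a under the half-Normal(0,1) prior
        if config.fix_a is None and it % config.a_update_interval == 0:
            from .inference import _slice_update

            def f_loga(la):
                av = np.exp(la)
                # half-Normal prior + log-scale Jacobian
                return liability_logpdf(av, x) - 0.5 * av * av + la

            la, _ = _slice_update(np.log(a), f_loga, f_loga(np.log(a)), rng)
            a = float(np.exp(la))
            set_rate(a)
        if it >= burn and (it - burn) % keep_every == 0:
            draws.append((x[internal] > 0.0).astype(np.int8))
            a_draws.append(a)
    draws = np.array(draws)
    return AsrResult(
        nodes=[nodes[i] for i in internal],
        node_probs=draws.mean(axis=0),
        draws=draws,
        a_draws=np.array(a_draws),
        tree=tree,
    )


def _genus_of(label: str) -> str:
    return label.split()[0]


def genus_mrca_table(
    ensemble: PhylogenyEnsemble,
    codings: dict[str, dict[str, float]],
    genera: list[str],
    config: AsrConfig | None = None,
    seed: int = 0,
    n_trees: int | None = None,
) -> pd.DataFrame:
    """Tool-use probability at genus MRCAs, per coding, pooled over trees.

    ``codings`` maps a coding name (e.g. pre, post, cure) to per-tip
    probabilities of the tool-use state. For each genus the MRCA of its
    sampled species is located on every tree; the pooled probability is the
    mean across trees of the per-tree posterior probabilities, with a 95%
    interval from batch means of the pooled draws (10 batches per tree),
    which mixes within-tree MCMC uncertainty with across-tree variation.
    """
    config = config or AsrConfig()
    trees = ensemble.trees if n_trees is None else ensemble.trees[:n_trees]
    seeds = np.random.SeedSequence(seed).generate_state(
        len(trees) * len(codings)
    )
    rows = []
    genus_members: dict[str, list[str]] = {}
    for label in sorted(ensemble.tip_labels):
        genus_members.setdefault(_genus_of(label), []).append(label)
    for g in genera:
        if len(genus_members.get(g, [])) < 2:
            raise ValueError(
                f"genus {g!r} has fewer than 2 sampled species on the trees"
            )
    si = 0
    for coding_name, tip_probs in codings.items():
        batch_means: dict[str, list[float]] = {g: [] for g in genera}
        per_tree: dict[str, list[float]] = {g: [] for g in genera}
        for tree in trees:
            res = asr_sample(
                tree, tip_probs, config, seed=int(seeds[si] % 2**31)
            )
            si += 1
            for g in genera:
                node = mrca_node(tree, genus_members[g])
                d = res.draws_at(node)
                per_tree[g].append(float(d.mean()))
                for chunk in np.array_split(d, 10):
                    if len(chunk):
                        batch_means[g].append(float(chunk.mean()))
        for g in genera:
            pooled = np.array(batch_means[g])
            lo, hi = np.percentile(pooled, [2.5, 97.5])
            rows.append(
                {
                    "genus": g,
                    "coding": coding_name,
                    "probability": float(np.mean(per_tree[g])),
                    "ci95_low": float(lo),
                    "ci95_high": float(hi),
                    "n_trees": len(trees),
                }
            )
    return pd.DataFrame(rows)
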