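"""Synthetic data with exactly the generative structure the model assumes.

The generator composes: a unit-height Yule tree; feeding strategy and
encephalization quotient covariates; a multivariate-normal species effect
with OU kernel covariance on patristic distances; the logistic cure
submodel; and two independent censored-exponential detection channels with
per-species lognormal effort budgets. Budgets exist only to create
censoring — the fitted model conditions on observed effort and never models
them.

Defaults emulate the parrot study's conditions: ~70% feeding generalists,
EQ centered near 1.5, a tool-use prevalence of roughly one species in five,
literature efforts on the scale of tens of papers and video efforts on the
scale of hundreds of hits.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .data import ChannelObservation, Dataset, SpeciesRecord, save_traits
from .model import ModelParameters, phylo_kernel
from .phylo import (
    DistanceMatrix,
    PhylogenyEnsemble,
    patristic_distances,
    simulate_yule_tree,
)
from . import phylo as _phylo

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_tree",
    "simulate_species_effects",
    "simulate_covariates",
    "simulate_observations",
    "generate_dataset",
]


@dataclass
class SimConfig:
    """Generative parameters; defaults are the package's study conditions."""

    n_species: int = 100
    n_trees: int = 1
    generalist_fraction: float = 0.7
    eq_mean: float = 1.5
    eq_sd: float = 0.5
    # non-tool-use (cure) logit scale: alpha + beta*EQ + k
    alpha_generalist: float = 1.0
    alpha_specialist: float = 1.3
    beta: float = -1.1
    eta_sq: float = 1.0
    rho_sq: float = 5.0
    gamma_lit: float = float(np.log(20.0))
    gamma_vid: float = float(np.log(500.0))
    # lognormal effort budgets per channel (median, log-scale sigma)
    budget_lit_median: float = 30.0
    budget_lit_sigma: float = 1.5
    budget_vid_median: float = 1000.0
    budget_vid_sigma: float = 1.5
    shared_cure: bool = False
    integerize_efforts: bool = False
    # brain/body masses are back-filled from EQ for a fixed body mass so the
    # trait CSV stays self-consistent (EQ = brain / (0.12 * body^(2/3)))
    body_mass: float = 300.0


@dataclass
class SyntheticTruth:
    """Generating parameters and latent indicators for recovery tests."""

    params: ModelParameters
    p: np.ndarray  # true cure probabilities
    cured_lit: np.ndarray  # latent cure indicator, literature channel
    cured_vid: np.ndarray
    budgets_lit: np.ndarray
    budgets_vid: np.ndarray
    config: SimConfig

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "params": {
                "gamma_lit": self.params.gamma_lit,
                "gamma_vid": self.params.gamma_vid,
                "alpha": self.params.alpha.tolist(),
                "beta": self.params.beta,
                "k": self.params.k.tolist(),
                "eta_sq": self.params.eta_sq,
                "rho_sq": self.params.rho_sq,
            },
            "p": self.p.tolist(),
            "cured_lit": self.cured_lit.astype(int).tolist(),
            "cured_vid": self.cured_vid.astype(int).tolist(),
            "budgets_lit": self.budgets_lit.tolist(),
            "budgets_vid": self.budgets_vid.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def simulate_tree(n_tips: int, seed: int):
    """Unit-height Yule tree with tips sp_0001...; see phylo module."""
    return simulate_yule_tree(n_tips, seed)


def simulate_species_effects(
    D: DistanceMatrix | np.ndarray,
    eta_sq: float,
    rho_sq: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One draw k ~ MVN(0, eta_sq * exp(-rho_sq * D)) via Cholesky."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    km = phylo_kernel(D, eta_sq, rho_sq)
    n = km.K.shape[0]
    return km.L @ rng.standard_normal(n)


def simulate_covariates(
    n: int,
    generalist_fraction: float,
    eq_mean: float,
    eq_sd: float,
    seed: int | np.random.Generator,
):
    """Feeding strategy (Bernoulli) and EQ (zero-truncated Normal)."""
    if not 0.0 <= generalist_fraction <= 1.0:
        raise ValueError("generalist_fraction must be in [0, 1]")
    if eq_sd <= 0:
        raise ValueError("eq_sd must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    feeding_index = (rng.uniform(size=n) >= generalist_fraction).astype(int)
    eq = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        eq[todo] = rng.normal(eq_mean, eq_sd, size=todo.sum())
        todo = eq <= 0.0
    return feeding_index, eq


def simulate_observations(
    p: np.ndarray,
    gamma_lit: float,
    gamma_vid: float,
    budgets_lit: np.ndarray,
    budgets_vid: np.ndarray,
    seed: int | np.random.Generator,
    shared_cure: bool = False,
):
    """Two-channel censored detection records for given cure probabilities.

    Per channel: a latent cure indicator ~ Bernoulli(p) (shared across
    channels if ``shared_cure``); susceptible species draw a discovery
    effort E ~ Exponential(rate exp(-gamma)) and are detected iff E falls
    within their budget C, recording effort E; otherwise (or if cured) the
    record is censored at effort C.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("cure probabilities must lie strictly in (0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = p.shape[0]
    cured_lit = rng.uniform(size=n) < p
    cured_vid = cured_lit if shared_cure else rng.uniform(size=n) < p
    out = []
    for cured, gamma, budgets in (
        (cured_lit, gamma_lit, budgets_lit),
        (cured_vid, gamma_vid, budgets_vid),
    ):
        scale = np.exp(gamma)  # mean of the exponential discovery effort
        E = rng.exponential(scale, size=n)
        detected = (~cured) & (E <= budgets)
        effort = np.where(detected, E, budgets)
        out.append((detected, effort))
    (lit_det, lit_eff), (vid_det, vid_eff) = out
    return lit_det, lit_eff, vid_det, vid_eff, cured_lit, cured_vid


def _mass_from_eq(eq: float, body_mass: float) -> float:
    return eq * 0.12 * body_mass ** (2.0 / 3.0)


def generate_dataset(
    config: SimConfig | None = None,
    seed: int = 0,
    out_dir=None,
):
    """Compose the simulators into a (Dataset, PhylogenyEnsemble, truth).

    If ``out_dir`` is given, writes ``traits.csv``, ``trees.nwk`` and
    ``truth.json`` so the fitting pipeline consumes synthetic data exactly
    like real data. Byte-identical outputs for identical seeds.
    """
    from scipy.special import expit

    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    tree_seeds = np.random.SeedSequence(seed).generate_state(
        config.n_trees + 1
    )
    trees = [
        simulate_yule_tree(config.n_species, int(ts % 2**31))
        for ts in tree_seeds[: config.n_trees]
    ]
    ensemble = PhylogenyEnsemble(trees) if config.n_trees == 1 else _relabel(
        trees
    )
    data_tree = ensemble.trees[0]
    D = patristic_distances(data_tree)
    labels = list(D.labels)

    feeding_index, eq = simulate_covariates(
        config.n_species,
        config.generalist_fraction,
        config.eq_mean,
        config.eq_sd,
        rng,
    )
    k = simulate_species_effects(D, config.eta_sq, config.rho_sq, rng)
    alpha = np.array([config.alpha_generalist, config.alpha_specialist])
    lin = alpha[feeding_index] + config.beta * eq + k
    p = expit(lin)

    budgets_lit = rng.lognormal(
        np.log(config.budget_lit_median), config.budget_lit_sigma,
        config.n_species,
    )
    budgets_vid = rng.lognormal(
        np.log(config.budget_vid_median), config.budget_vid_sigma,
        config.n_species,
    )
    lit_det, lit_eff, vid_det, vid_eff, cured_lit, cured_vid = (
        simulate_observations(
            p,
            config.gamma_lit,
            config.gamma_vid,
            budgets_lit,
            budgets_vid,
            rng,
            config.shared_cure,
        )
    )
    if config.integerize_efforts:
        lit_eff = np.ceil(lit_eff)
        vid_eff = np.ceil(vid_eff)

    from .data import compute_eq

    records = []
    for i, sid in enumerate(labels):
        brain = _mass_from_eq(eq[i], config.body_mass)
        records.append(
            SpeciesRecord(
                species_id=sid,
                feeding=SpeciesRecord.FEEDING_LEVELS[feeding_index[i]],
                brain_mass=brain,
                body_mass=config.body_mass,
                eq=compute_eq(brain, config.body_mass),
                literature=ChannelObservation(
                    bool(lit_det[i]), float(lit_eff[i])
                ),
                video=ChannelObservation(bool(vid_det[i]), float(vid_eff[i])),
            )
        )
    dataset = Dataset(records, provenance=f"synthetic seed={seed}")
    truth = SyntheticTruth(
        params=ModelParameters(
            gamma_lit=config.gamma_lit,
            gamma_vid=config.gamma_vid,
            alpha=alpha,
            beta=config.beta,
            k=k,
            eta_sq=config.eta_sq,
            rho_sq=config.rho_sq,
        ),
        p=p,
        cured_lit=cured_lit,
        cured_vid=cured_vid,
        budgets_lit=budgets_lit,
        budgets_vid=budgets_vid,
        config=config,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_traits(dataset, out_dir / "traits.csv")
        _phylo.save_trees(ensemble, out_dir / "trees.nwk")
        truth.to_json(out_dir / "truth.json")
    return dataset, ensemble, truth


def _relabel(trees) -> PhylogenyEnsemble:
    # independent Yule trees already share the sp_xxxx label set
    return PhylogenyEnsemble(trees)
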