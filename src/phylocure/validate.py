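"""Model validation: ROC/AUC, leave-one-species-out CV, parameter recovery."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import Dataset
from .inference import (
    FitConfig,
    PosteriorDraws,
    rank_species,
    sample_posterior,
)
from .phylo import PhylogenyEnsemble
from .simulate import SimConfig, generate_dataset

__all__ = [
    "classification_auc",
    "loo_species_cv",
    "parameter_recovery",
    "LooReport",
    "RecoveryReport",
]


def classification_auc(scores, labels) -> float:
    """Rank-based AUC: P(random positive outranks random negative), ties 1/2.

    Equivalent to the normalized Mann-Whitney U statistic. Raises when either
    class is empty.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both a positive and a negative class")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2 wins
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class LooReport:
    per_species: pd.DataFrame  # species, heldout_median, threshold, success
    success_rate: float
    baseline_rate: float
    n_success: int
    n_heldout: int
    skipped: list


def loo_species_cv(
    dataset: Dataset,
    ensemble: PhylogenyEnsemble,
    fit_config: FitConfig | None = None,
    seed: int = 0,
    full_draws: PosteriorDraws | None = None,
) -> LooReport:
    """Leave-one-species-out cross-validation of known tool users.

    For each in-tree species with evidence, the model is refitted with that
    species' detections set to absent in both channels (efforts kept as
    censoring times). The held-out species succeeds when its refitted median
    tool-use probability falls within the closed range [min, max] of the
    OTHER tool users' medians from the full-data fit — since those medians
    are at most ~1, the binding edge is the minimum. The baseline rate is
    the fraction of never-evidence species inside the same range in the
    full-data fit.
    """
    fit_config = fit_config or FitConfig()
    if full_draws is None:
        full_draws = sample_posterior(dataset, ensemble, fit_config, seed)
    full_rank = rank_species(full_draws).set_index("species")
    in_tree = dataset.subset_in_tree()
    users = [r.species_id for r in in_tree if r.any_evidence]
    skipped = [
        r.species_id
        for r in dataset
        if r.any_evidence and not r.in_tree
    ]
    if len(users) < 2:
        raise ValueError("need at least two in-tree species with evidence")

    rows = []
    for i, sid in enumerate(users):
        others = [s for s in users if s != sid]
        lo = float(full_rank.loc[others, "median"].min())
        hi = float(full_rank.loc[others, "median"].max())
        reduced = dataset.with_species_suppressed(sid)
        draws = sample_posterior(reduced, ensemble, fit_config, seed + 1 + i)
        med = float(
            rank_species(draws).set_index("species").loc[sid, "median"]
        )
        rows.append(
            {
                "species": sid,
                "heldout_median": med,
                "range_low": lo,
                "range_high": hi,
                "success": bool(lo <= med <= hi),
            }
        )
    per_species = pd.DataFrame(rows)
    n_success = int(per_species["success"].sum())

    users_lo = float(full_rank.loc[users, "median"].min())
    users_hi = float(full_rank.loc[users, "median"].max())
    no_evidence = [r.species_id for r in in_tree if not r.any_evidence]
    if no_evidence:
        meds = full_rank.loc[no_evidence, "median"]
        baseline = float(((meds >= users_lo) & (meds <= users_hi)).mean())
    else:
        baseline = float("nan")
    return LooReport(
        per_species=per_species,
        success_rate=n_success / len(users),
        baseline_rate=baseline,
        n_success=n_success,
        n_heldout=len(users),
        skipped=skipped,
    )


@dataclass
class RecoveryReport:
    per_replicate: pd.DataFrame  # replicate, parameter, truth, median, ...
    summary: pd.DataFrame  # parameter, bias, rmse, coverage
    n_failed: int


RECOVERY_PARAMS = [
    "gamma_lit",
    "gamma_vid",
    "alpha_generalist",
    "alpha_specialist",
    "beta",
    "eta_sq",
    "rho_sq",
]


def parameter_recovery(
    generator_config: SimConfig | None = None,
    fit_config: FitConfig | None = None,
    n_replicates: int = 20,
    seed: int = 0,
    ci_level: float = 0.90,
) -> RecoveryReport:
    """Fit the model to simulated datasets with known parameters.

    Per replicate: generate a dataset from ``generator_config``, sample the
    posterior, and record each parameter's posterior median, bias and
    whether the equal-tailed ``ci_level`` interval covers the truth.
    Replicates whose sampler fails are recorded, excluded and counted.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    generator_config = generator_config or SimConfig()
    fit_config = fit_config or FitConfig()
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    rep_seeds = np.random.SeedSequence(seed).generate_state(2 * n_replicates)
    rows = []
    n_failed = 0
    for rep in range(n_replicates):
        dataset, ensemble, truth = generate_dataset(
            generator_config, int(rep_seeds[2 * rep] % 2**31)
        )
        truths = {
            "gamma_lit": truth.params.gamma_lit,
            "gamma_vid": truth.params.gamma_vid,
            "alpha_generalist": truth.params.alpha[0],
            "alpha_specialist": truth.params.alpha[1],
            "beta": truth.params.beta,
            "eta_sq": truth.params.eta_sq,
            "rho_sq": truth.params.rho_sq,
        }
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                draws = sample_posterior(
                    dataset,
                    ensemble,
                    fit_config,
                    int(rep_seeds[2 * rep + 1] % 2**31),
                )
        except Exception:  # sampler failure: recorded and excluded
            n_failed += 1
            continue
        for name in RECOVERY_PARAMS:
            vals = draws.df[name].to_numpy()
            lo, med, hi = np.quantile(vals, [lo_q, 0.5, hi_q])
            rows.append(
                {
                    "replicate": rep,
                    "parameter": name,
                    "truth": truths[name],
                    "median": float(med),
                    "bias": float(med - truths[name]),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "covered": bool(lo <= truths[name] <= hi),
                }
            )
    per_replicate = pd.DataFrame(rows)
    summary = (
        per_replicate.groupby("parameter")
        .agg(
            bias=("bias", "mean"),
            rmse=("bias", lambda b: float(np.sqrt(np.mean(np.square(b))))),
            coverage=("covered", "mean"),
            n=("bias", "size"),
        )
        .reset_index()
    )
    return RecoveryReport(
        per_replicate=per_replicate, summary=summary, n_failed=n_failed
    )
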