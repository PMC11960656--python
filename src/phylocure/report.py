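"""Assemble the headline estimands into a machine-readable study report."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset
from .inference import (
    PosteriorDraws,
    expected_discovery_effort,
    rank_species,
    sum_undetected,
)

__all__ = ["StudyReport", "build_report", "DEFAULT_TOTAL_EXTANT"]

#: External taxonomy constant: number of extant parrot species.
DEFAULT_TOTAL_EXTANT = 398
DEFAULT_TOP_N = 10


@dataclass
class StudyReport:
    ranking: pd.DataFrame
    top_candidates: list[str]
    undetected_count: dict  # median + 95% CI of the sum of probabilities
    prevalence_range: tuple[float, float]  # (low, high) fractions
    effects: dict  # tool-use-scale EQ slope and feeding difference
    discovery_effort: dict
    asr_table: pd.DataFrame | None
    n_known: int
    total_extant: int

    def to_dict(self) -> dict:
        return {
            "n_known": self.n_known,
            "total_extant": self.total_extant,
            "undetected_count": {
                k: v
                for k, v in self.undetected_count.items()
                if k != "draws"
            },
            "prevalence_range": list(self.prevalence_range),
            "top_candidates": self.top_candidates,
            "effects": self.effects,
            "discovery_effort": self.discovery_effort,
            "ranking": self.ranking.to_dict(orient="records"),
            "asr_table": (
                None
                if self.asr_table is None
                else self.asr_table.to_dict(orient="records")
            ),
        }


def _summary(x: np.ndarray) -> dict:
    lo, q25, med, q75, hi = np.quantile(x, [0.025, 0.25, 0.5, 0.75, 0.975])
    return {
        "median": float(med),
        "q025": float(lo),
        "q25": float(q25),
        "q75": float(q75),
        "q975": float(hi),
    }


def build_report(
    draws: PosteriorDraws,
    dataset: Dataset,
    asr_table: pd.DataFrame | None = None,
    total_extant_species: int = DEFAULT_TOTAL_EXTANT,
    top_n: int = DEFAULT_TOP_N,
) -> StudyReport:
    """Compose the posterior summaries into one deterministic report.

    Covariate effects are reported on the tool-use scale: the EQ slope is
    the negated cure-scale slope (a positive value means bigger-brained
    species are more likely tool users), and the feeding effect is the
    generalist-minus-specialist log-odds difference of tool use.
    """
    ranking = rank_species(draws)
    candidates = ranking[~ranking["evidence"]]
    if top_n > len(candidates):
        warnings.warn(
            f"top_n={top_n} exceeds the {len(candidates)} candidate species;"
            " clipping",
            UserWarning,
            stacklevel=2,
        )
        top_n = len(candidates)
    top = candidates["species"].head(top_n).tolist()

    und = sum_undetected(draws)
    n_known = int(sum(draws.evidence.values()))
    prevalence = (
        (n_known + und["ci95_low"]) / total_extant_species,
        (n_known + und["ci95_high"]) / total_extant_species,
    )

    beta_tool = -draws.df["beta"].to_numpy()
    # alpha on the cure (non-tool-use) logit scale; the tool-use-scale
    # generalist advantage is alpha_specialist - alpha_generalist
    feed_diff_tool = (
        draws.df["alpha_specialist"].to_numpy()
        - draws.df["alpha_generalist"].to_numpy()
    )
    effects = {
        "eq_slope_tool_scale": _summary(beta_tool),
        "generalist_minus_specialist_tool_scale": _summary(feed_diff_tool),
    }
    return StudyReport(
        ranking=ranking,
        top_candidates=top,
        undetected_count={
            k: v for k, v in und.items() if k != "draws"
        },
        prevalence_range=prevalence,
        effects=effects,
        discovery_effort=expected_discovery_effort(draws),
        asr_table=asr_table,
        n_known=n_known,
        total_extant=total_extant_species,
    )
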