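"""Species-level data model for two-channel censored detection records.

Each species carries covariates (feeding strategy, brain and body mass,
encephalization quotient) and one detection record per observation channel:
a binary "detected yet?" flag and a continuous research-effort count (papers
published for the literature channel, platform search hits for the video
channel). Effort is the censoring clock of the survival-cure model, so it is
stored as a non-negative real, not an integer: the video channel's coding
interpolates hit counts linearly in time and is naturally fractional.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ChannelObservation",
    "SpeciesRecord",
    "Dataset",
    "MergedEvidence",
    "compute_eq",
    "code_literature_effort",
    "code_video_effort",
    "merge_evidence",
    "normalize_species_id",
    "load_traits",
    "save_traits",
    "YOUTUBE_INCEPTION",
]

#: Default platform inception date for the video channel (YouTube founding).
YOUTUBE_INCEPTION = _dt.date(2005, 2, 14)

EQ_SCALING = 0.12  # allometric constant in EQ = brain / (0.12 * body^(2/3))


def normalize_species_id(name: str) -> str:
    """Normalize a Latin binomial to canonical 'Genus species' form.

    Case-folds, converts underscores to spaces, collapses whitespace, and
    capitalizes the genus. Matching elsewhere is exact on this normal form;
    no fuzzy matching is ever attempted.
    """
    parts = name.strip().replace("_", " ").split()
    if not parts:
        raise ValueError("empty species name")
    parts = [p.lower() for p in parts]
    parts[0] = parts[0].capitalize()
    return " ".join(parts)


def compute_eq(brain_mass: float, body_mass: float) -> float:
    """Encephalization quotient: brain_mass / (0.12 * body_mass**(2/3)).

    Both masses in grams; the result is dimensionless. Raises ``ValueError``
    for non-positive masses.
    """
    if not (brain_mass > 0) or not (body_mass > 0):
        raise ValueError(
            f"masses must be positive, got brain={brain_mass}, body={body_mass}"
        )
    return brain_mass / (EQ_SCALING * body_mass ** (2.0 / 3.0))


def code_literature_effort(
    total_papers: float, first_detection_index: int | None = None
) -> float:
    """Research effort for the literature channel.

    If the behavior was detected, effort is the number of papers up to and
    including the first paper reporting it; otherwise the total number of
    papers published to date.
    """
    if total_papers < 0:
        raise ValueError("paper count must be non-negative")
    if first_detection_index is None:
        return float(total_papers)
    if first_detection_index < 1 or first_detection_index > total_papers:
        raise ValueError(
            f"detection index {first_detection_index} outside 1..{total_papers}"
        )
    return float(first_detection_index)


def code_video_effort(
    current_hits: float,
    first_tool_video_date: _dt.date | None = None,
    query_date: _dt.date | None = None,
    platform_inception_date: _dt.date = YOUTUBE_INCEPTION,
) -> float:
    """Research effort for the video channel.

    Undetected species keep their current hit count. For detected species the
    hit count at the date of the first relevant video is estimated by linear
    interpolation between the platform's inception (zero hits) and the query
    date (current hits).
    """
    if current_hits < 0:
        raise ValueError("hit count must be non-negative")
    if first_tool_video_date is None:
        return float(current_hits)
    if query_date is None:
        raise ValueError("query_date required when a detection date is given")
    if not (platform_inception_date <= first_tool_video_date <= query_date):
        raise ValueError(
            "dates must satisfy inception <= first detection <= query"
        )
    span = (query_date - platform_inception_date).days
    if span == 0:
        return float(current_hits)
    elapsed = (first_tool_video_date - platform_inception_date).days
    return float(current_hits) * elapsed / span


@dataclass(frozen=True)
class ChannelObservation:
    """One channel's detection record: flag plus censoring effort."""

    detected: bool
    effort: float

    def __post_init__(self) -> None:
        if self.effort < 0:
            raise ValueError("effort must be non-negative")
        if self.detected and self.effort == 0:
            raise ValueError("detected species must have positive effort")


@dataclass(frozen=True)
class SpeciesRecord:
    species_id: str
    feeding: str  # "generalist" or "specialist"
    brain_mass: float
    body_mass: float
    eq: float
    literature: ChannelObservation
    video: ChannelObservation
    in_tree: bool = True
    proxy_for: str | None = None

    FEEDING_LEVELS = ("generalist", "specialist")

    def __post_init__(self) -> None:
        if self.feeding not in self.FEEDING_LEVELS:
            raise ValueError(f"unknown feeding level {self.feeding!r}")
        expected = compute_eq(self.brain_mass, self.body_mass)
        if not np.isclose(self.eq, expected, rtol=1e-9, atol=0.0):
            raise ValueError(
                f"{self.species_id}: eq={self.eq} inconsistent with masses "
                f"(expected {expected})"
            )

    @property
    def feeding_index(self) -> int:
        """0 for generalist, 1 for specialist (index coding of intercepts)."""
        return self.FEEDING_LEVELS.index(self.feeding)

    @property
    def any_evidence(self) -> bool:
        return self.literature.detected or self.video.detected


@dataclass
class Dataset:
    """Ordered species collection; the order is the canonical model index."""

    records: list[SpeciesRecord]
    channel_names: tuple[str, str] = ("literature", "video")
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.species_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate species ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species_ids(self) -> list[str]:
        return [r.species_id for r in self.records]

    def subset_in_tree(self) -> "Dataset":
        return Dataset(
            [r for r in self.records if r.in_tree],
            self.channel_names,
            self.provenance,
        )

    def reorder(self, species_ids: list[str]) -> "Dataset":
        by_id = {r.species_id: r for r in self.records}
        missing = [s for s in species_ids if s not in by_id]
        if missing:
            raise KeyError(f"species not in dataset: {missing}")
        return Dataset(
            [by_id[s] for s in species_ids], self.channel_names, self.provenance
        )

    def with_species_suppressed(self, species_id: str) -> "Dataset":
        """Copy with one species' detections zeroed in both channels.

        The recorded efforts are retained as censoring times; this is the
        leave-one-species-out perturbation used in cross-validation.
        """
        out = []
        found = False
        for r in self.records:
            if r.species_id == species_id:
                found = True
                r = replace(
                    r,
                    literature=ChannelObservation(False, r.literature.effort),
                    video=ChannelObservation(False, r.video.effort),
                )
            out.append(r)
        if not found:
            raise KeyError(species_id)
        return Dataset(out, self.channel_names, self.provenance)


@dataclass(frozen=True)
class MergedEvidence:
    union: frozenset
    n_lit: int
    n_vid: int
    n_overlap: int

    @property
    def n_union(self) -> int:
        return len(self.union)


def merge_evidence(literature_species: set, video_species: set) -> MergedEvidence:
    """Combine per-channel tool-use evidence into a union status.

    Species ids are normalized before comparison; a species counts as an
    evidence-positive tool user if either channel reports it.
    """
    bad: list[str] = []

    def _norm(items) -> frozenset:
        out = set()
        for s in items:
            try:
                out.add(normalize_species_id(s))
            except ValueError:
                bad.append(repr(s))
        return frozenset(out)

    lit = _norm(literature_species)
    vid = _norm(video_species)
    if bad:
        raise ValueError(f"unnormalizable species ids: {bad}")
    return MergedEvidence(
        union=lit | vid,
        n_lit=len(lit),
        n_vid=len(vid),
        n_overlap=len(lit & vid),
    )


TRAIT_COLUMNS = [
    "species",
    "feeding",
    "brain_g",
    "body_g",
    "lit_detected",
    "lit_effort",
    "vid_detected",
    "vid_effort",
]


def save_traits(dataset: Dataset, path) -> None:
    """Write the trait table as CSV (booleans as 0/1, full float precision)."""
    rows = []
    for r in dataset:
        rows.append(
            {
                "species": r.species_id,
                "feeding": r.feeding,
                "brain_g": repr(float(r.brain_mass)),
                "body_g": repr(float(r.body_mass)),
                "lit_detected": int(r.literature.detected),
                "lit_effort": repr(float(r.literature.effort)),
                "vid_detected": int(r.video.detected),
                "vid_effort": repr(float(r.video.effort)),
                "proxy_for": r.proxy_for or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_traits(path, tree_tip_labels: set[str] | None = None) -> Dataset:
    """Read a trait CSV into a Dataset, recomputing EQ from the masses.

    If ``tree_tip_labels`` is given, species absent from it are retained with
    ``in_tree=False`` (they are excluded from model fitting downstream).
    """
    df = pd.read_csv(
        path,
        dtype={"proxy_for": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    if tree_tip_labels is not None:
        tree_tip_labels = {normalize_species_id(t) for t in tree_tip_labels}
    records = []
    for row in df.itertuples(index=False):
        sid = normalize_species_id(row.species)
        brain, body = float(row.brain_g), float(row.body_g)
        records.append(
            SpeciesRecord(
                species_id=sid,
                feeding=str(row.feeding),
                brain_mass=brain,
                body_mass=body,
                eq=compute_eq(brain, body),
                literature=ChannelObservation(
                    bool(int(row.lit_detected)), float(row.lit_effort)
                ),
                video=ChannelObservation(
                    bool(int(row.vid_detected)), float(row.vid_effort)
                ),
                in_tree=(
                    True if tree_tip_labels is None else sid in tree_tip_labels
                ),
                proxy_for=(
                    normalize_species_id(row.proxy_for)
                    if getattr(row, "proxy_for", "")
                    else None
                ),
            )
        )
    return Dataset(records, provenance=f"loaded from {path}")
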