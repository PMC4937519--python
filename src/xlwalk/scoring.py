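"""Crosslink-based model scoring.

The matched and non-accessible crosslink score (MNXL) evaluates a candidate
model against an experimentally observed crosslink set.  Each crosslink whose
surface distance can be computed on the model is a *matched* crosslink: if
its SASD is within the maximum bound (33 Å by default) it contributes the
normal probability density of that distance under the empirical distribution
of crosslinked-lysine SASDs; beyond the bound it contributes a flat −0.1
penalty.  A crosslink with no computable SASD on the model (buried endpoint
or no solvent path) is a *non-accessible* crosslink and also receives a flat
−0.1 penalty.  Higher MNXL is better.

The comparison scores are the number of violations (NoV), the sum of
violation distances (SoVD), and NoV plus the non-accessible count; for all
three, lower is better.  Ensemble scores are min–max normalized to [0, 1]
with 0 assigned to the best model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .sasd_search import MEASURED, PairKey, SASDResult, canonical_pair
from .structures_io import CrosslinkDataset, NormalParams

__all__ = [
    "ScoringConfig", "CrosslinkClassification", "ScoreReport",
    "classify_crosslinks", "score_matched", "score_mnxl", "score_nov",
    "score_sovd", "score_nov_nonacc", "normalize_ensemble", "score_model",
]


def normal_density(distance: float, params: NormalParams) -> float:
    return float(norm.pdf(distance, loc=params.mu, scale=params.sigma))


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the crosslink scores.

    ``cutoff`` is the maximum bound in Å beyond which a measured crosslink is
    a violation.  ``penalty_violating`` / ``penalty_nonaccessible`` default to
    the shared flat −0.1.  ``distribution`` holds the mu/sigma of the matched
    score's normal density; ``density`` is pluggable (e.g. for log-density).
    """

    cutoff: float = 33.0
    penalty_violating: float = -0.1
    penalty_nonaccessible: float = -0.1
    distribution: NormalParams | None = None
    distance_mode: str = "sasd"   # sasd | euclidean_surface | euclidean_all
    density: Callable[[float, NormalParams], float] = normal_density

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.penalty_violating > 0 or self.penalty_nonaccessible > 0:
            raise ValueError("penalties must be <= 0")

    def with_cutoff(self, cutoff: float) -> "ScoringConfig":
        return replace(self, cutoff=cutoff)


@dataclass
class CrosslinkClassification:
    """Partition of the observed crosslinks evaluable on one model."""

    matched_ok: list[tuple[PairKey, float]] = field(default_factory=list)
    matched_violating: list[tuple[PairKey, float]] = field(default_factory=list)
    nonaccessible: list[PairKey] = field(default_factory=list)

    @property
    def matched_count(self) -> int:
        return len(self.matched_ok) + len(self.matched_violating)

    @property
    def violating_count(self) -> int:
        return len(self.matched_violating)

    @property
    def nonaccessible_count(self) -> int:
        return len(self.nonaccessible)


@dataclass
class ScoreReport:
    """All scores of one model against one crosslink dataset."""

    model: str
    raw_mnxl: float
    nov: int
    sovd: float
    nov_plus_nonaccessible: int
    matched_count: int
    violating_count: int
    nonaccessible_count: int
    normalized: float | None = None   # filled at ensemble level


def classify_crosslinks(ms_dataset: CrosslinkDataset,
                        model_distances: SASDResult,
                        config: ScoringConfig) -> CrosslinkClassification:
    """Place each observed crosslink in matched-ok / violating / non-accessible.

    A measured distance ≤ cutoff is matched-ok (the boundary itself is not
    penalized); > cutoff is violating; an unmeasurable pair (non-accessible
    endpoint or no solvent path) is non-accessible.  In ``euclidean_all``
    mode every pair is measured so the non-accessible list is empty by
    construction.
    """
    cls = CrosslinkClassification()
    for rec in ms_dataset:
        pair = canonical_pair(rec.a, rec.b)
        res = model_distances.pairs.get(pair)
        if res is None:
            raise KeyError(
                f"crosslink {pair} has no distance on the model; models and "
                f"dataset must share residue numbering")
        if res.status == MEASURED:
            if res.distance <= config.cutoff:
                cls.matched_ok.append((pair, res.distance))
            else:
                cls.matched_violating.append((pair, res.distance))
        else:
            cls.nonaccessible.append(pair)
    return cls


def score_matched(distance: float, config: ScoringConfig) -> float:
    """Score of a single matched crosslink.

    Within the cutoff: the normal density of the distance under the fitted
    SASD distribution.  Beyond the cutoff: the flat violation penalty.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if distance > config.cutoff:
        return config.penalty_violating
    if config.distribution is None:
        raise ValueError("ScoringConfig.distribution (mu/sigma) is required "
                         "for the matched score")
    return config.density(distance, config.distribution)


def score_mnxl(classification: CrosslinkClassification,
               config: ScoringConfig) -> float:
    """Raw MNXL: sum of matched scores plus non-accessible penalties."""
    total = 0.0
    for _, d in classification.matched_ok:
        total += score_matched(d, config)
    total += config.penalty_violating * len(classification.matched_violating)
    total += config.penalty_nonaccessible * len(classification.nonaccessible)
    return total


def score_nov(classification: CrosslinkClassification) -> int:
    """Number of violations: crosslinks whose distance exceeds the cutoff."""
    return classification.violating_count


def score_sovd(classification: CrosslinkClassification,
               config: ScoringConfig) -> float:
    """Sum of violation distances: total excess over the cutoff."""
    return float(sum(d - config.cutoff
                     for _, d in classification.matched_violating))


def score_nov_nonacc(classification: CrosslinkClassification) -> int:
    """NoV augmented with the non-accessible crosslink count."""
    return classification.violating_count + classification.nonaccessible_count


def score_model(name: str, ms_dataset: CrosslinkDataset,
                model_distances: SASDResult,
                config: ScoringConfig) -> ScoreReport:
    cls = classify_crosslinks(ms_dataset, model_distances, config)
    return ScoreReport(
        model=name,
        raw_mnxl=score_mnxl(cls, config),
        nov=score_nov(cls),
        sovd=score_sovd(cls, config),
        nov_plus_nonaccessible=score_nov_nonacc(cls),
        matched_count=cls.matched_count,
        violating_count=cls.violating_count,
        nonaccessible_count=cls.nonaccessible_count,
    )


def normalize_ensemble(raw_scores: Sequence[float],
                       orientation: str = "higher_better") -> np.ndarray:
    """Min–max normalize ensemble scores to [0, 1], best model → 0.

    ``orientation`` states whether a larger raw score means a better model
    (MNXL) or a worse one (NoV, SoVD).  An all-equal ensemble maps to all
    zeros.
    """
    raw = np.asarray(raw_scores, dtype=float)
    if raw.size == 0:
        raise ValueError("empty ensemble")
    if orientation not in ("higher_better", "lower_better"):
        raise ValueError("orientation must be higher_better or lower_better")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    if orientation == "higher_better":
        return (hi - raw) / (hi - lo)
    return (raw - lo) / (hi - lo)
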