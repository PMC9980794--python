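"""Validation of the literature ranking: LOOCV, retrospective slicing, ROC/AUC.

Each training drug is held out in turn, added to the candidate pool, and
re-ranked against the remaining training set; its 1-based rank among the
``n_neg`` candidates feeds a rank-based ROC curve.

The ROC uses the pairwise (Mann-Whitney) construction: a held-out positive
with mid-rank ``r`` among ``n_neg + 1`` pooled entities receives the pseudo-
score ``n_neg + 1 - r`` (the number of candidates it beats, with half credit
for ties), while the candidate slots occupy scores ``j - 1/2`` for
``j = 1..n_neg``.  Sweeping a threshold over the pooled scores yields a
stepwise ROC whose trapezoidal area equals the closed-form concordance AUC

    AUC = sum_i (n_neg + 1 - r_i) / (P * n_neg)

exactly, including tie half-credit.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError
from .literature_ranking import (
    EntityCorpus,
    RankingConfig,
    TextFingerprint,
    _training_prototype,
    filter_candidates,
    fingerprint_entities,
)

__all__ = [
    "HeldOutRank",
    "ValidationResult",
    "loocv",
    "retrospective_slice",
    "roc_auc",
    "concordance_auc",
]


@dataclass(frozen=True)
class HeldOutRank:
    """Rank of one held-out positive among 1 + n_neg pooled entities.

    ``rank`` may be half-integral under the mid-rank tie convention.
    """

    entity_id: str
    rank: float
    n_neg: int

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= self.n_neg + 1:
            raise ValidationError(
                f"rank {self.rank} outside [1, {self.n_neg + 1}] for "
                f"{self.entity_id!r}"
            )


@dataclass(frozen=True)
class ValidationResult:
    held_out: tuple[HeldOutRank, ...]
    roc_points: tuple[tuple[float, float], ...]
    auc: float


def _midrank(score: float, other_scores: Sequence[float]) -> float:
    greater = sum(1 for s in other_scores if s > score)
    equal = sum(1 for s in other_scores if s == score)
    return greater + equal / 2.0 + 1.0


def _score_against(
    fps: dict[str, TextFingerprint],
    training_ids: Sequence[str],
    candidate_ids: Sequence[str],
    config: RankingConfig,
) -> dict[str, float]:
    training_fps = [fps[t] for t in training_ids]
    if config.similarity_aggregation == "centroid":
        proto = _training_prototype(training_fps)
        return {c: fps[c].cosine(proto) for c in candidate_ids}
    return {
        c: sum(fps[c].cosine(t) for t in training_fps) / len(training_fps)
        for c in candidate_ids
    }


def loocv(
    corpus: EntityCorpus,
    training_ids: Sequence[str],
    config: RankingConfig,
) -> list[HeldOutRank]:
    """Hold out each positive in turn and rank it among the candidates.

    The held-out drug is subject to the same abstract-count filter as every
    candidate; a positive failing it is an error (it could never be
    recovered, so its fold is meaningless).
    """
    training_ids = list(training_ids)
    if len(training_ids) < 2:
        raise ValidationError("LOOCV needs at least 2 training entities")
    for p in training_ids:
        if corpus.n_documents(p, config.year_cutoff) < config.min_abstracts:
            raise ValidationError(
                f"held-out positive {p!r} fails the min-abstract filter"
            )
    candidates = [c for c in filter_candidates(corpus, config) if c not in training_ids]
    # E and df are identical in every fold (the pooled entity set does not
    # change when one positive moves to the candidate side), so fingerprints
    # are computed once.
    fps = fingerprint_entities(corpus, training_ids + candidates, config)
    out = []
    for p in training_ids:
        rest = [t for t in training_ids if t != p]
        scores = _score_against(fps, rest, candidates + [p], config)
        p_score = scores.pop(p)
        rank = _midrank(p_score, list(scores.values()))
        out.append(HeldOutRank(p, rank, n_neg=len(candidates)))
    return out


def retrospective_slice(
    corpus: EntityCorpus,
    year_cutoff: int,
    held_out_id: str,
    config: RankingConfig,
) -> HeldOutRank:
    """Time-sliced hold-out: drop post-cutoff documents everywhere, move one
    training drug to the candidate pool, and rank it.
    """
    if corpus.roles.get(held_out_id) != "training":
        raise ValidationError(f"{held_out_id!r} is not in the training set")
    if corpus.n_documents(held_out_id, year_cutoff) == 0:
        raise ValidationError(
            f"held-out entity {held_out_id!r} has no documents published on or "
            f"before {year_cutoff}"
        )
    sliced = RankingConfig(
        min_abstracts=config.min_abstracts,
        weighting=config.weighting,
        similarity_aggregation=config.similarity_aggregation,
        year_cutoff=year_cutoff,
    )
    training = [t for t in corpus.training_ids if t != held_out_id]
    if not training:
        raise ValidationError("no training entities left after holding out")
    candidates = [c for c in filter_candidates(corpus, sliced) if c not in corpus.training_ids]
    fps = fingerprint_entities(corpus, training + candidates + [held_out_id], sliced)
    scores = _score_against(fps, training, candidates + [held_out_id], sliced)
    p_score = scores.pop(held_out_id)
    return HeldOutRank(held_out_id, _midrank(p_score, list(scores.values())), len(candidates))


def concordance_auc(held_out: Sequence[HeldOutRank]) -> float:
    """Closed-form pairwise AUC: mean fraction of candidates each positive beats."""
    if not held_out:
        raise ValidationError("empty held-out list")
    n_neg = held_out[0].n_neg
    if any(h.n_neg != n_neg for h in held_out):
        raise ValidationError("held-out ranks computed against different n_neg")
    return sum(n_neg + 1 - h.rank for h in held_out) / (len(held_out) * n_neg)


def roc_auc(held_out: Sequence[HeldOutRank]) -> ValidationResult:
    """ROC curve and trapezoidal AUC over the pooled rank pseudo-scores.

    The curve is anchored at (0,0) and (1,1); tied positive/candidate scores
    produce diagonal segments whose trapezoids realize mid-rank half-credit,
    so the area equals :func:`concordance_auc` to machine precision.
    """
    if not held_out:
        raise ValidationError("empty held-out list")
    n_neg = held_out[0].n_neg
    if any(h.n_neg != n_neg for h in held_out):
        raise ValidationError("held-out ranks computed against different n_neg")
    n_pos = len(held_out)
    pos_scores = np.array([n_neg + 1 - h.rank for h in held_out], dtype=float)
    neg_scores = np.arange(1, n_neg + 1, dtype=float) - 0.5
    thresholds = np.unique(np.concatenate([pos_scores, neg_scores]))[::-1]
    points = [(0.0, 0.0)]
    tp = fp = 0.0
    for thr in thresholds:
        tp += float(np.sum(pos_scores == thr))
        fp += float(np.sum(neg_scores == thr))
        points.append((fp / n_neg, tp / n_pos))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return ValidationResult(tuple(held_out), tuple(points), auc)
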