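"""Literature-similarity drug ranking.

Each drug entity is represented by a *text fingerprint*: an L2-normalized
TF-IDF vector over the tokens of its pooled abstracts.  Candidate entities
are scored by cosine similarity to the training set (by default against the
unit-normalized training centroid) and ranked from most to least similar.

The fingerprint scheme is fixed so that rankings are reproducible:

* lowercase, tokenize on non-alphanumeric boundaries;
* drop tokens shorter than 3 characters and a frozen English stopword list;
* ``tf``  = raw term count over the entity's surviving documents pooled;
* ``idf`` = ln((1 + E) / (1 + df)) + 1, with ``E`` the number of
  fingerprinted entities and ``df`` the number of them containing the term;
* weight = tf * idf, then L2 normalization.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._stopwords import STOPWORDS
from .errors import ConfigError, CurationError, FingerprintError, RankingError

__all__ = [
    "Document",
    "EntityCorpus",
    "RankingConfig",
    "TextFingerprint",
    "SimilarityRanking",
    "tokenize",
    "curate_training_set",
    "filter_candidates",
    "build_fingerprint",
    "fingerprint_entities",
    "similarity_score",
    "rank_candidates",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")

TRAINING = "training"
CANDIDATE = "candidate"


def _raw_tokens(text: str) -> list[str]:
    """Lowercased alphanumeric tokens, no length/stopword filtering."""
    return _TOKEN_RE.findall(text.lower())


def tokenize(text: str) -> list[str]:
    """Fingerprint tokens: lowercased, length >= 3, stopwords removed."""
    return [t for t in _raw_tokens(text) if len(t) >= 3 and t not in STOPWORDS]


@dataclass(frozen=True)
class Document:
    year: int
    text: str


@dataclass
class EntityCorpus:
    """Per-entity bag of dated abstracts with a training/candidate role.

    ``entities`` maps entity_id -> list of documents; ``roles`` maps
    entity_id -> ``"training"`` or ``"candidate"``.
    """

    entities: dict[str, list[Document]]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for eid, docs in self.entities.items():
            for d in docs:
                if not d.text:
                    raise ConfigError(f"entity {eid!r} contains an empty document")
        for eid, role in self.roles.items():
            if role not in (TRAINING, CANDIDATE):
                raise ConfigError(f"unknown role {role!r} for entity {eid!r}")
            if eid not in self.entities:
                raise ConfigError(f"role given for unknown entity {eid!r}")

    @property
    def training_ids(self) -> list[str]:
        return [e for e in self.entities if self.roles.get(e) == TRAINING]

    @property
    def candidate_ids(self) -> list[str]:
        return [e for e in self.entities if self.roles.get(e, CANDIDATE) == CANDIDATE]

    def documents(self, entity_id: str, year_cutoff: int | None = None) -> list[Document]:
        docs = self.entities[entity_id]
        if year_cutoff is None:
            return list(docs)
        return [d for d in docs if d.year <= year_cutoff]

    def n_documents(self, entity_id: str, year_cutoff: int | None = None) -> int:
        return len(self.documents(entity_id, year_cutoff))


@dataclass(frozen=True)
class RankingConfig:
    """Knobs of the ranking pipeline.

    ``min_abstracts`` implements the candidate-inclusion filter (entities
    with fewer published abstracts are dropped); ``year_cutoff`` restricts
    every entity to documents published up to and including that year, for
    retrospective analyses.
    """

    min_abstracts: int = 5
    weighting: str = "tfidf"
    similarity_aggregation: str = "centroid"
    year_cutoff: int | None = None

    def __post_init__(self) -> None:
        if self.min_abstracts < 1:
            raise ConfigError("min_abstracts must be >= 1")
        if self.weighting != "tfidf":
            raise ConfigError(f"unknown weighting scheme {self.weighting!r}")
        if self.similarity_aggregation not in ("centroid", "mean_pairwise"):
            raise ConfigError(
                f"unknown similarity_aggregation {self.similarity_aggregation!r}"
            )


@dataclass(frozen=True)
class TextFingerprint:
    """Sparse unit-norm term-weight vector for one entity."""

    entity_id: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise FingerprintError(f"empty fingerprint for entity {self.entity_id!r}")
        norm = math.sqrt(sum(w * w for w in self.weights.values()))
        if abs(norm - 1.0) > 1e-9:
            raise FingerprintError(
                f"fingerprint for {self.entity_id!r} is not unit-norm (|w|={norm})"
            )

    def cosine(self, other: "TextFingerprint") -> float:
        return _dot(self.weights, other.weights)


@dataclass(frozen=True)
class SimilarityRanking:
    """Rank-ordered candidate list: (entity_id, score, 1-based rank)."""

    entries: tuple[tuple[str, float, int], ...]

    @property
    def n_candidates(self) -> int:
        return len(self.entries)

    def rank_of(self, entity_id: str) -> int:
        for eid, _, rank in self.entries:
            if eid == entity_id:
                return rank
        raise KeyError(entity_id)

    def score_of(self, entity_id: str) -> float:
        for eid, score, _ in self.entries:
            if eid == entity_id:
                return score
        raise KeyError(entity_id)


def _dot(a: Mapping[str, float], b: Mapping[str, float]) -> float:
    if len(b) < len(a):
        a, b = b, a
    return sum(w * b.get(t, 0.0) for t, w in a.items())


def _normalize(weights: Mapping[str, float]) -> dict[str, float]:
    norm = math.sqrt(sum(w * w for w in weights.values()))
    if norm == 0.0:
        raise FingerprintError("cannot normalize a zero vector")
    return {t: w / norm for t, w in weights.items()}


# ---------------------------------------------------------------------------
# pipeline stages


def curate_training_set(
    candidate_positives: Sequence[str],
    exclusion_terms: Sequence[str],
    corpus: EntityCorpus,
) -> list[str]:
    """Drop positives whose literature mentions any exclusion term.

    Matching is case-insensitive on whole tokens; multi-word terms must
    appear as a contiguous token sequence in a single document.  Input
    order is preserved.
    """
    for eid in candidate_positives:
        if eid not in corpus.entities:
            raise ConfigError(f"candidate positive {eid!r} not present in corpus")
    patterns = [tuple(_raw_tokens(term)) for term in exclusion_terms]
    patterns = [p for p in patterns if p]

    def tainted(eid: str) -> bool:
        for doc in corpus.entities[eid]:
            toks = _raw_tokens(doc.text)
            for pat in patterns:
                n = len(pat)
                if any(tuple(toks[i : i + n]) == pat for i in range(len(toks) - n + 1)):
                    return True
        return False

    kept = [eid for eid in candidate_positives if not tainted(eid)]
    if not kept:
        raise CurationError("training set empty after curation")
    return kept


def filter_candidates(corpus: EntityCorpus, config: RankingConfig) -> list[str]:
    """Candidate entities with at least ``min_abstracts`` surviving documents.

    The year cutoff (if any) is applied before counting.  Training entities
    are never filtered here.
    """
    return [
        eid
        for eid in corpus.candidate_ids
        if corpus.n_documents(eid, config.year_cutoff) >= config.min_abstracts
    ]


def _term_counts(corpus: EntityCorpus, entity_id: str, config: RankingConfig) -> Counter:
    docs = corpus.documents(entity_id, config.year_cutoff)
    if not docs:
        raise FingerprintError(
            f"entity {entity_id!r} has no documents surviving the year cutoff"
        )
    counts: Counter = Counter()
    for d in docs:
        counts.update(tokenize(d.text))
    if not counts:
        raise FingerprintError(f"empty fingerprint for entity {entity_id!r}")
    return counts


def fingerprint_entities(
    corpus: EntityCorpus,
    entity_ids: Sequence[str],
    config: RankingConfig,
) -> dict[str, TextFingerprint]:
    """TF-IDF fingerprints for ``entity_ids``, which also define E and df."""
    counts = {eid: _term_counts(corpus, eid, config) for eid in entity_ids}
    n_entities = len(counts)
    df: Counter = Counter()
    for c in counts.values():
        df.update(c.keys())
    idf = {t: math.log((1 + n_entities) / (1 + d)) + 1.0 for t, d in df.items()}
    out = {}
    for eid, c in counts.items():
        out[eid] = TextFingerprint(eid, _normalize({t: n * idf[t] for t, n in c.items()}))
    return out


def build_fingerprint(
    entity_id: str, corpus: EntityCorpus, config: RankingConfig
) -> TextFingerprint:
    """Fingerprint one entity against the corpus-wide document frequencies.

    The IDF reference set is the set of entities that would be fingerprinted
    by :func:`rank_candidates`: all training entities plus candidates that
    survive the abstract-count filter (plus ``entity_id`` itself if it would
    otherwise be filtered out).
    """
    universe = list(corpus.training_ids) + filter_candidates(corpus, config)
    if entity_id not in universe:
        universe.append(entity_id)
    return fingerprint_entities(corpus, universe, config)[entity_id]


def _training_prototype(training: Sequence[TextFingerprint]) -> TextFingerprint:
    acc: Counter = Counter()
    for fp in training:
        for t, w in fp.weights.items():
            acc[t] += w
    return TextFingerprint("__centroid__", _normalize(acc))


def similarity_score(
    candidate: TextFingerprint,
    training: Sequence[TextFingerprint],
    config: RankingConfig,
) -> float:
    """Similarity of one candidate to the training set.

    ``centroid`` mode: cosine to the unit-normalized mean of the training
    fingerprints.  ``mean_pairwise`` mode: arithmetic mean of the cosines to
    each training fingerprint.
    """
    if not training:
        raise RankingError("empty training fingerprint list")
    if config.similarity_aggregation == "centroid":
        return candidate.cosine(_training_prototype(training))
    return sum(candidate.cosine(fp) for fp in training) / len(training)


def rank_candidates(
    corpus: EntityCorpus,
    training_ids: Sequence[str],
    config: RankingConfig,
    exclusion_terms: Sequence[str] = (),
) -> SimilarityRanking:
    """Full pipeline: curate, filter, fingerprint, score, sort.

    Candidates also appearing in the training set are removed before
    ranking.  Ties are broken by ascending entity_id, so the ranking is
    invariant to candidate input order.
    """
    training_ids = list(training_ids)
    if exclusion_terms:
        training_ids = curate_training_set(training_ids, exclusion_terms, corpus)
    candidates = [c for c in filter_candidates(corpus, config) if c not in training_ids]
    if not candidates:
        raise RankingError("no candidates survive filtering")
    fps = fingerprint_entities(corpus, training_ids + candidates, config)
    training_fps = [fps[t] for t in training_ids]
    if config.similarity_aggregation == "centroid":
        proto = _training_prototype(training_fps)
        scores = {c: fps[c].cosine(proto) for c in candidates}
    else:
        scores = {
            c: sum(fps[c].cosine(t) for t in training_fps) / len(training_fps)
            for c in candidates
        }
    ordered = sorted(candidates, key=lambda c: (-scores[c], c))
    entries = tuple((c, scores[c], i + 1) for i, c in enumerate(ordered))
    return SimilarityRanking(entries)
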