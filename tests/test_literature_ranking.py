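"""Fingerprinting, curation, filtering and similarity ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoscreen.errors import CurationError, FingerprintError, RankingError
from mitoscreen.literature_ranking import (
    RankingConfig,
    TextFingerprint,
    build_fingerprint,
    curate_training_set,
    fingerprint_entities,
    filter_candidates,
    rank_candidates,
    similarity_score,
    tokenize,
)
from mitoscreen.synthetic_data import CorpusSimConfig, gen_corpus

from conftest import make_corpus


class TestTokenize:
    def test_lowercases_splits_and_drops_short_and_stopwords(self):
        assert tokenize("The PINK1/Parkin pathway, and CCCP!") == [
            "pink1",
            "parkin",
            "pathway",
            "cccp",
        ]

    def test_all_stopword_text_yields_nothing(self):
        assert tokenize("the and of to") == []


class TestCuration:
    def test_empty_exclusion_list_is_a_noop(self, toy_corpus):
        ids = ["drugA", "drugB"]
        assert curate_training_set(ids, [], toy_corpus) == ids

    def test_matching_abstract_excludes_positive(self):
        corpus = make_corpus(
            {
                "good": [(2010, "induces mitophagy strongly")],
                "bad": [(2010, "triggers Apoptosis in neurons")],
                "also_bad": [(2011, "causes mitochondrial damage quickly")],
            }
        )
        terms = ["apoptosis", "depolarization", "mitochondrial damage"]
        kept = curate_training_set(["good", "bad", "also_bad"], terms, corpus)
        assert kept == ["good"]

    def test_multiword_term_requires_contiguous_tokens(self):
        corpus = make_corpus(
            {"x": [(2010, "mitochondrial biogenesis prevents damage")]}
        )
        # both words present but not adjacent -> not excluded
        assert curate_training_set(["x"], ["mitochondrial damage"], corpus) == ["x"]

    def test_seven_of_nine_retained(self):
        docs = {f"p{i}": [(2010, "benign mitophagy text")] for i in range(9)}
        docs["p3"] = [(2010, "this one mentions apoptosis")]
        docs["p7"] = [(2010, "linked to depolarization events")]
        corpus = make_corpus(docs)
        kept = curate_training_set(
            list(docs), ["apoptosis", "depolarization"], corpus
        )
        assert len(kept) == 7 and "p3" not in kept and "p7" not in kept

    def test_empty_result_raises(self):
        corpus = make_corpus({"x": [(2010, "apoptosis study")]})
        with pytest.raises(CurationError, match="empty after curation"):
            curate_training_set(["x"], ["apoptosis"], corpus)


class TestFilterCandidates:
    def test_boundary_at_min_abstracts(self):
        corpus = make_corpus(
            {
                "A": [(2010, f"text {i}") for i in range(4)],
                "B": [(2010, f"text {i}") for i in range(5)],
                "C": [(2010, f"text {i}") for i in range(12)],
            }
        )
        assert filter_candidates(corpus, RankingConfig(min_abstracts=5)) == ["B", "C"]

    def test_min_one_retains_everything(self, toy_corpus):
        cfg = RankingConfig(min_abstracts=1)
        assert filter_candidates(toy_corpus, cfg) == ["drugA", "drugB", "drugC"]

    def test_year_cutoff_counts_only_surviving_documents(self):
        docs = [(2012, "a"), (2013, "b"), (2014, "c"), (2015, "d"), (2016, "e"), (2017, "f")]
        corpus = make_corpus({"D": docs})
        assert filter_candidates(corpus, RankingConfig(min_abstracts=5)) == ["D"]
        sliced = RankingConfig(min_abstracts=5, year_cutoff=2014)
        assert filter_candidates(corpus, sliced) == []

    def test_training_entities_never_filtered(self):
        corpus = make_corpus({"t": [(2010, "single doc")]}, training=["t"])
        assert filter_candidates(corpus, RankingConfig(min_abstracts=5)) == []
        assert corpus.training_ids == ["t"]


class TestFingerprints:
    def test_identical_text_gives_identical_fingerprints(self, permissive_config):
        corpus = make_corpus(
            {
                "a": [(2010, "alpha beta gamma")],
                "b": [(2011, "alpha beta gamma")],
                "c": [(2012, "delta epsilon")],
            }
        )
        fps = fingerprint_entities(corpus, ["a", "b", "c"], permissive_config)
        assert fps["a"].weights == fps["b"].weights
        assert fps["a"].cosine(fps["b"]) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_vocabularies_are_orthogonal(self, permissive_config):
        corpus = make_corpus(
            {"a": [(2010, "alpha beta")], "b": [(2011, "gamma delta")]}
        )
        fps = fingerprint_entities(corpus, ["a", "b"], permissive_config)
        assert fps["a"].cosine(fps["b"]) == 0.0

    def test_weights_match_hand_computed_tfidf(self, toy_corpus, permissive_config):
        """Independent hand computation of tf, idf and L2 norm on the toy corpus."""
        fps = fingerprint_entities(
            toy_corpus, ["drugA", "drugB", "drugC"], permissive_config
        )
        # drugA tokens: kinase x2, inhibitor, mitophagy, assay; E=3
        # df: kinase 2, inhibitor 2, mitophagy 1, assay 1
        idf2 = math.log(4 / 3) + 1
        idf1 = math.log(4 / 2) + 1
        raw = {
            "kinase": 2 * idf2,
            "inhibitor": 1 * idf2,
            "mitophagy": 1 * idf1,
            "assay": 1 * idf1,
        }
        norm = math.sqrt(sum(v * v for v in raw.values()))
        for term, w in raw.items():
            assert fps["drugA"].weights[term] == pytest.approx(w / norm, abs=1e-9)

    def test_matches_sklearn_tfidf_oracle(self, permissive_config):
        """Cross-check the full scheme against scikit-learn's TfidfVectorizer."""
        pytest.importorskip("sklearn")
        from sklearn.feature_extraction.text import TfidfVectorizer

        corpus = make_corpus(
            {
                "a": [(2010, "kinase kinase mitophagy flux assay")],
                "b": [(2011, "kinase receptor binding"), (2012, "receptor agonist")],
                "c": [(2013, "zebrafish larvae kinase screen")],
            }
        )
        ids = ["a", "b", "c"]
        fps = fingerprint_entities(corpus, ids, permissive_config)
        joined = [" ".join(d.text for d in corpus.entities[e]) for e in ids]
        vec = TfidfVectorizer(tokenizer=tokenize, lowercase=False, token_pattern=None)
        mat = vec.fit_transform(joined).toarray()
        vocab = vec.get_feature_names_out()
        for i, eid in enumerate(ids):
            for j, term in enumerate(vocab):
                assert fps[eid].weights.get(term, 0.0) == pytest.approx(
                    mat[i, j], abs=1e-12
                )

    def test_duplicating_document_set_leaves_fingerprint_unchanged(
        self, permissive_config
    ):
        base = {"a": [(2010, "alpha beta beta")], "b": [(2011, "gamma alpha")]}
        doubled = {e: docs + docs for e, docs in base.items()}
        fp1 = fingerprint_entities(make_corpus(base), ["a", "b"], permissive_config)
        fp2 = fingerprint_entities(make_corpus(doubled), ["a", "b"], permissive_config)
        for e in base:
            for t, w in fp1[e].weights.items():
                assert fp2[e].weights[t] == pytest.approx(w, abs=1e-12)

    def test_errors_on_empty_or_stopword_only_text(self, permissive_config):
        corpus = make_corpus({"a": [(2010, "the and")], "b": [(2010, "alpha")]})
        with pytest.raises(FingerprintError, match="empty fingerprint"):
            fingerprint_entities(corpus, ["a", "b"], permissive_config)
        late = RankingConfig(min_abstracts=1, year_cutoff=1990)
        with pytest.raises(FingerprintError, match="no documents"):
            fingerprint_entities(corpus, ["b"], late)

    def test_build_fingerprint_single_entity(self, toy_corpus, permissive_config):
        fp = build_fingerprint("drugA", toy_corpus, permissive_config)
        assert fp.entity_id == "drugA"
        norm = math.sqrt(sum(w * w for w in fp.weights.values()))
        assert norm == pytest.approx(1.0, abs=1e-9)


def _unit_fp(eid, **weights):
    norm = math.sqrt(sum(w * w for w in weights.values()))
    return TextFingerprint(eid, {t: w / norm for t, w in weights.items()})


class TestSimilarityScore:
    @pytest.mark.parametrize("mode", ["centroid", "mean_pairwise"])
    def test_identical_fingerprints_score_one(self, mode):
        fp = _unit_fp("x", alpha=1.0, beta=2.0)
        cfg = RankingConfig(similarity_aggregation=mode)
        assert similarity_score(fp, [fp, fp], cfg) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("mode", ["centroid", "mean_pairwise"])
    def test_orthogonal_scores_zero(self, mode):
        cand = _unit_fp("c", alpha=1.0)
        train = [_unit_fp("t1", beta=1.0), _unit_fp("t2", gamma=1.0)]
        cfg = RankingConfig(similarity_aggregation=mode)
        assert similarity_score(cand, train, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_mean_pairwise_averages_and_centroid_matches_vector_sum_oracle(self):
        # cos(c,u)=0.6, cos(c,v)=0.8 by construction in 2-D term space
        cand = _unit_fp("c", x=1.0)
        u = _unit_fp("u", x=0.6, y=0.8)
        v = _unit_fp("v", x=0.8, y=0.6)
        cfg = RankingConfig(similarity_aggregation="mean_pairwise")
        assert similarity_score(cand, [u, v], cfg) == pytest.approx(0.7, abs=1e-12)
        # centroid oracle: normalize(u+v) then dot with candidate
        s = np.array([0.6 + 0.8, 0.8 + 0.6])
        expected = (s / np.linalg.norm(s))[0]
        cfg2 = RankingConfig(similarity_aggregation="centroid")
        assert similarity_score(cand, [u, v], cfg2) == pytest.approx(
            expected, abs=1e-12
        )

    def test_empty_training_list_raises(self):
        with pytest.raises(RankingError):
            similarity_score(_unit_fp("c", x=1.0), [], RankingConfig())


class TestRankCandidates:
    def test_single_candidate_gets_rank_one(self, permissive_config):
        corpus = make_corpus(
            {"t": [(2010, "alpha beta")], "c": [(2010, "unrelated words")]},
            training=["t"],
        )
        ranking = rank_candidates(corpus, ["t"], permissive_config)
        assert ranking.entries == ((
            "c",
            ranking.score_of("c"),
            1,
        ),)

    def test_document_order_within_entities_is_irrelevant(self, permissive_config):
        docs = {
            "t": [(2010, "alpha beta"), (2011, "alpha gamma")],
            "c1": [(2010, "alpha delta"), (2011, "beta beta")],
            "c2": [(2012, "gamma gamma")],
        }
        flipped = {e: list(reversed(d)) for e, d in docs.items()}
        r1 = rank_candidates(make_corpus(docs, ["t"]), ["t"], permissive_config)
        r2 = rank_candidates(make_corpus(flipped, ["t"]), ["t"], permissive_config)
        assert r1.entries == r2.entries

    def test_scores_non_increasing_ranks_permutation_scores_in_unit_interval(self):
        corpus, truth = gen_corpus(
            CorpusSimConfig(n_decoys=20, vocab_size=150, docs_per_entity_range=(5, 8),
                            doc_length_range=(20, 50), seed=7)
        )
        ranking = rank_candidates(corpus, list(truth.planted_enhancers), RankingConfig())
        scores = [s for _, s, _ in ranking.entries]
        ranks = [r for _, _, r in ranking.entries]
        assert ranks == list(range(1, len(ranks) + 1))
        assert all(a >= b for a, b in zip(scores, scores[1:]))
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_candidates_in_training_set_are_removed(self, permissive_config):
        corpus = make_corpus(
            {
                "t": [(2010, "alpha beta")],
                "c": [(2010, "alpha gamma")],
            }
        )  # both default to candidate role
        ranking = rank_candidates(corpus, ["t"], permissive_config)
        assert [e for e, _, _ in ranking.entries] == ["c"]

    def test_planted_signal_decoys_dominate_top_ranks(self):
        """Decoys carrying the training topic rise to the top of the ranking."""
        wins = 0
        n_rep = 50
        for seed in range(n_rep):
            corpus, truth = gen_corpus(
                CorpusSimConfig(
                    n_positives=12, n_decoys=50, vocab_size=300, n_signal_terms=10,
                    docs_per_entity_range=(10, 10), doc_length_range=(40, 80),
                    signal_weight=0.8, seed=seed,
                )
            )
            planted = list(truth.planted_enhancers)
            training, planted_decoys = planted[:7], planted[7:]
            for eid in planted_decoys:  # relabel 5 positives as candidates
                corpus.roles[eid] = "candidate"
            ranking = rank_candidates(corpus, training, RankingConfig())
            top10 = [e for e, _, r in ranking.entries if r <= 10]
            if all(e in top10 for e in planted_decoys):
                wins += 1
        assert wins >= 0.9 * n_rep

    @given(st.permutations(["c1", "c2", "c3", "c4"]))
    @settings(max_examples=20, deadline=None)
    def test_ranking_invariant_to_candidate_input_order(self, order):
        docs = {
            "t": [(2010, "alpha beta gamma")],
            "c1": [(2010, "alpha beta")],
            "c2": [(2010, "alpha noise")],
            "c3": [(2010, "beta gamma gamma")],
            "c4": [(2010, "unrelated stuff")],
        }
        entity_order = ["t"] + list(order)
        corpus = make_corpus({e: docs[e] for e in entity_order}, training=["t"])
        ranking = rank_candidates(corpus, ["t"], RankingConfig(min_abstracts=1))
        baseline = rank_candidates(
            make_corpus(docs, training=["t"]), ["t"], RankingConfig(min_abstracts=1)
        )
        assert ranking.entries == baseline.entries
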