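import inspect

import numpy as np
import pytest

from notecast.cohort import SplitAssignment, extract_window
from notecast.embed import (
    EmbeddingMatrix,
    apply_bigrams,
    bigram_score,
    build_training_corpus,
    build_vocabulary,
    detect_bigrams,
    keep_probability,
    load_embeddings,
    save_embeddings,
    sgns_pair_loss_and_grad,
    train_sgns,
)


class TestVocabulary:
    def test_counts_and_total_computed_before_filtering(self):
        vocab = build_vocabulary([["a", "a", "a"], ["b", "b"]], min_count=3)
        assert vocab.tokens == ["a"]
        assert vocab.total == 5
        assert vocab.frequencies().tolist() == [3 / 5]

    def test_min_count_one_keeps_everything(self):
        vocab = build_vocabulary([["a", "b"], ["c"]], min_count=1)
        assert set(vocab.tokens) == {"a", "b", "c"}

    def test_count_exactly_at_threshold_is_retained(self):
        vocab = build_vocabulary([["x"] * 3 + ["y"] * 2], min_count=3)
        assert "x" in vocab and "y" not in vocab

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([])


class TestBigrams:
    def test_score_matches_hand_arithmetic(self):
        # corpus of 20 tokens; pair (a,b) occurs 4 times, a occurs 6, b occurs 5
        note = "a b c a b d a b e f a b g a c b h a b".split() + ["i"]
        counts = {"ab": 5, "a": 6, "b": 5}  # recount: 'a b' adjacent 5 times
        n_ab = sum(1 for x, y in zip(note, note[1:]) if (x, y) == ("a", "b"))
        expected = (n_ab - 1.0) * len(note) / (note.count("a") * note.count("b"))
        assert bigram_score(n_ab, note.count("a"), note.count("b"),
                            len(note), 1.0) == pytest.approx(expected, rel=1e-12)

    def test_frequent_adjacent_pair_is_merged(self):
        corpus = [["colorectaal", "carcinoom", "x%d" % i] for i in range(20)]
        corpus += [[f"w{i}{j}" for j in range(5)] for i in range(200)]  # background
        merged, bigrams = detect_bigrams(corpus, delta=5.0, threshold=10.0)
        assert ("colorectaal", "carcinoom") in bigrams
        assert all(note[0] == "colorectaal_carcinoom" for note in merged[:20])

    def test_large_discount_blocks_all_merges(self):
        corpus = [["a", "b"]] * 10
        merged, bigrams = detect_bigrams(corpus, delta=10.0, threshold=0.0)
        assert bigrams == frozenset()
        assert merged == corpus

    def test_greedy_merge_is_non_overlapping(self):
        assert apply_bigrams(["a", "b", "b"], {("a", "b"), ("b", "b")}) == ["a_b", "b"]


class TestKeepProbability:
    def test_boundary_frequency_always_kept(self):
        assert keep_probability(1e-5, t=1e-5) == 1.0

    def test_four_times_threshold_kept_half_the_time(self):
        assert keep_probability(4e-5, t=1e-5) == pytest.approx(0.5)

    def test_monotone_non_increasing_in_frequency(self):
        grid = np.logspace(-6, 0, 40)
        probs = keep_probability(grid, t=1e-4)
        assert np.all(np.diff(probs) <= 1e-15)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            keep_probability(0.0)


class TestSgns:
    def test_analytic_gradient_matches_central_differences(self, rng):
        d, k = 8, 3
        w = rng.normal(size=d)
        c_pos = rng.normal(size=d)
        c_negs = rng.normal(size=(k, d))
        loss, gw, gc, gn = sgns_pair_loss_and_grad(w, c_pos, c_negs)
        eps = 1e-6

        def num_grad(arr, setter):
            g = np.zeros_like(arr)
            flat = arr.ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                lp = sgns_pair_loss_and_grad(w, c_pos, c_negs)[0]
                flat[i] = orig - eps
                lm = sgns_pair_loss_and_grad(w, c_pos, c_negs)[0]
                flat[i] = orig
                g.ravel()[i] = (lp - lm) / (2 * eps)
            return g

        for analytic, arr in ((gw, w), (gc, c_pos), (gn, c_negs)):
            numeric = num_grad(arr, None)
            rel = np.abs(analytic - numeric) / np.maximum(np.abs(numeric), 1e-8)
            assert rel.max() < 1e-5

    @staticmethod
    def _block_corpus(rng, n_sentences=800, length=6):
        blocks = [[f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)]]
        corpus = []
        for _ in range(n_sentences):
            block = blocks[int(rng.random() < 0.5)]
            corpus.append([block[i] for i in rng.integers(0, 5, length)])
        return corpus, blocks

    def test_co_occurrence_blocks_recovered_in_cosine_structure(self, rng):
        corpus, blocks = self._block_corpus(rng)
        emb = train_sgns(corpus, d=16, window=3, k_neg=5, t=1.0, min_count=1,
                         epochs=5, seed=4)

        def cos(a, b):
            va, vb = emb.vector(a), emb.vector(b)
            return va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))

        within = np.mean([cos(a, b) for blk in blocks
                          for a in blk for b in blk if a != b])
        between = np.mean([cos(a, b) for a in blocks[0] for b in blocks[1]])
        assert within > between
        # tokens sharing contexts sit closer than tokens from disjoint contexts
        assert cos("a0", "a1") > cos("a0", "b0")

    def test_final_epoch_loss_below_first(self, rng):
        corpus, _ = self._block_corpus(rng, n_sentences=300)  # ~1800 tokens
        emb = train_sgns(corpus, d=12, window=3, epochs=4, t=1.0, min_count=1, seed=2)
        assert emb.epoch_losses[-1] < emb.epoch_losses[0]

    def test_training_is_deterministic_given_seed(self):
        corpus = [["x", "y", "z", "x", "y"]] * 50
        a = train_sgns(corpus, d=6, epochs=2, t=1.0, min_count=1, seed=9)
        b = train_sgns(corpus, d=6, epochs=2, t=1.0, min_count=1, seed=9)
        assert np.array_equal(a.W, b.W) and np.array_equal(a.C, b.C)

    def test_degenerate_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            train_sgns([["solo"] * 10], d=4, min_count=1)

    def test_default_hyperparameters_match_study_settings(self):
        sig = inspect.signature(train_sgns)
        defaults = {k: v.default for k, v in sig.parameters.items()}
        assert (defaults["d"], defaults["window"], defaults["k_neg"]) == (300, 5, 5)
        assert defaults["t"] == 1e-5 and defaults["min_count"] == 3


class TestTrainingCorpus:
    @staticmethod
    def _setup():
        import datetime as dt

        from notecast.records import Consultation, PatientRecord

        anchor = dt.date(2010, 1, 1)
        off = dt.timedelta(days=300)

        def win(pid, text):
            rec = PatientRecord(pid, dt.date(1950, 1, 1), "female",
                                [Consultation(anchor - off, [], text)])
            return extract_window(rec, 0, anchor)

        windows = [win("tr1", "moe en duizelig"), win("te1", "uniektoken hier")]
        split = SplitAssignment({"tr1": "train", "te1": "test"}, seed=0)
        under = [
            __import__("notecast.records", fromlist=["PatientRecord"]).PatientRecord(
                "u1", dt.date(1995, 1, 1), "male",
                [Consultation(anchor - off, [], "jong persoon")],
            )
        ]
        return windows, split, under

    def test_test_split_tokens_never_reach_the_vocabulary(self):
        windows, split, under = self._setup()
        corpus = build_training_corpus(windows, split, under)
        vocab = build_vocabulary(corpus, min_count=1)
        assert "uniektoken" not in vocab
        assert "moe" in vocab and "jong" in vocab

    def test_empty_under_age_pool_reduces_to_training_notes(self):
        windows, split, _ = self._setup()
        assert build_training_corpus(windows, split, []) == [["moe", "en", "duizelig"]]

    def test_corpus_token_count_is_sum_of_cleaned_note_lengths(self):
        windows, split, under = self._setup()
        corpus = build_training_corpus(windows, split, under)
        assert sum(len(n) for n in corpus) == 3 + 2


def test_embedding_roundtrip_through_text_format(tmp_path, rng):
    emb = EmbeddingMatrix(
        tokens=["aa", "bb"],
        W=rng.normal(size=(2, 4)),
        C=np.zeros((2, 4)),
        params={"d": 4},
        bigrams=frozenset({("aa", "bb")}),
        epoch_losses=[1.0, 0.5],
    )
    path = tmp_path / "emb.txt"
    save_embeddings(emb, path)
    back = load_embeddings(path)
    assert back.tokens == emb.tokens
    np.testing.assert_allclose(back.W, emb.W)
    assert back.bigrams == emb.bigrams
    assert back.params["d"] == 4
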