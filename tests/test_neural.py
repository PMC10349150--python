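"""Precursor classifier and cleavage tagger: encoding, CRF, training."""

from itertools import product

import numpy as np
import pytest

from ripptide.nn import (Bgc2orfSpec, CleavageTagger, DataSplit, Orf2coreSpec,
                         PrecursorClassifier, crossval, encode_sequence,
                         train_bgc2orf, train_orf2core, PAD_ID)
from ripptide.nn.crf import (crf_viterbi, position_marginals,
                             transition_marginals)
from ripptide.nn.training import load_model, save_model, split_data

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _rand_seq(rng, n):
    return "".join(rng.choice(AA, size=n))


def _classifier_data(rng, n_per_class=100, length=24, motif="WWGCCK"):
    pos, neg = [], []
    for _ in range(n_per_class):
        s = _rand_seq(rng, length)
        i = int(rng.integers(0, length - len(motif)))
        pos.append(s[:i] + motif + s[i + len(motif):])
        neg.append(_rand_seq(rng, length))
    return pos + neg, [1] * n_per_class + [0] * n_per_class


def _tagger_data(rng, n=60):
    seqs, cores = [], []
    for _ in range(n):
        lead = _rand_seq(rng, int(rng.integers(4, 9))) + "GGDW"
        core = _rand_seq(rng, int(rng.integers(5, 9)))
        foll = "KKPY" + _rand_seq(rng, int(rng.integers(4, 9)))
        seqs.append(lead + core + foll)
        cores.append((len(lead), len(lead) + len(core)))
    return seqs, cores


_TINY_CLS = dict(pad_len=24, embed_size=10, conv_filters=16, hidden_size=12)
_TINY_TAG = dict(pad_len=32, embed_size=8, conv_filters=8, hidden_size=12)


class TestEncodeSequence:
    def test_padding(self):
        ids = encode_sequence("ACD" * 50, pad_len=200)
        assert len(ids) == 200
        assert (ids[150:] == PAD_ID).all() and (ids[:150] != PAD_ID).all()

    def test_exact_length_no_padding(self):
        ids = encode_sequence("A" * 200, pad_len=200)
        assert (ids != PAD_ID).all()

    def test_truncation_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            ids = encode_sequence("A" * 250, pad_len=200)
        assert len(ids) == 200

    def test_non_amino_acid_rejected(self):
        with pytest.raises(ValueError, match="position 1"):
            encode_sequence("AZB")


class TestViterbi:
    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            L, K = 3, 5
            emis = rng.normal(size=(L, K))
            trans = rng.normal(size=(K, K))
            best, best_path = -np.inf, None
            for path in product(range(K), repeat=L):
                s = sum(emis[t, y] for t, y in enumerate(path)) + \
                    sum(trans[a, b] for a, b in zip(path, path[1:]))
                if s > best + 1e-12 or (abs(s - best) <= 1e-12
                                        and path < best_path):
                    best, best_path = s, path
            assert tuple(crf_viterbi(emis, trans)) == best_path

    def test_all_equal_scores_ties_to_lowest_label(self):
        emis = np.zeros((4, 5))
        trans = np.zeros((5, 5))
        assert crf_viterbi(emis, trans) == [0, 0, 0, 0]

    def test_forbidden_transitions_never_used(self):
        rng = np.random.default_rng(8)
        emis = rng.normal(size=(6, 5))
        trans = rng.normal(size=(5, 5))
        trans[2, 4] = trans[0, 3] = -1e9
        path = crf_viterbi(emis, trans)
        for a, b in zip(path, path[1:]):
            assert (a, b) not in {(2, 4), (0, 3)}

    def test_decoded_beats_random_paths(self):
        rng = np.random.default_rng(12)
        emis = rng.normal(size=(10, 5))
        trans = rng.normal(size=(5, 5))

        def score(path):
            return sum(emis[t, y] for t, y in enumerate(path)) + \
                sum(trans[a, b] for a, b in zip(path, path[1:]))

        best = score(crf_viterbi(emis, trans))
        for _ in range(1000):
            assert score(rng.integers(0, 5, size=10)) <= best + 1e-9


class TestMarginals:
    def test_position_marginals_sum_to_one(self):
        rng = np.random.default_rng(5)
        emis = rng.normal(size=(7, 5))
        trans = rng.normal(size=(5, 5))
        pm = position_marginals(emis, trans)
        assert np.allclose(pm.sum(axis=1), 1.0, atol=1e-6)

    def test_transition_marginals_match_enumeration(self):
        rng = np.random.default_rng(6)
        L, K = 4, 3
        emis = rng.normal(size=(L, K))
        trans = rng.normal(size=(K, K))
        # brute-force joint P(y_t=a, y_{t+1}=b)
        weights = {}
        for path in product(range(K), repeat=L):
            s = sum(emis[t, y] for t, y in enumerate(path)) + \
                sum(trans[a, b] for a, b in zip(path, path[1:]))
            weights[path] = np.exp(s)
        Z = sum(weights.values())
        m = transition_marginals(emis, trans, 0, 1)
        for t in range(L - 1):
            expected = sum(w for p, w in weights.items()
                           if p[t] == 0 and p[t + 1] == 1) / Z
            assert m[t] == pytest.approx(expected, rel=1e-9)


class TestClassifier:
    def test_fresh_model_probability_range(self):
        model = PrecursorClassifier(Bgc2orfSpec(**_TINY_CLS), seed=1)
        p = model.predict_proba(["ACDEF", "GHIKLMNP"])
        assert ((p >= 0) & (p <= 1)).all()

    def test_cutoff_boundary_is_positive(self):
        model = PrecursorClassifier(Bgc2orfSpec(**_TINY_CLS), seed=1)
        assert model.classify(0.5) is True
        assert model.classify(0.4999) is False

    def test_overfits_tiny_balanced_set(self):
        rng = np.random.default_rng(7)
        seqs, labels = _classifier_data(rng, n_per_class=20)
        spec = Bgc2orfSpec(max_epochs=200, patience=200, **_TINY_CLS)
        # train on everything: capacity check, not generalization
        n = len(seqs)
        res = train_bgc2orf(seqs, labels, spec=spec, seed=0,
                            partitions=(np.arange(n), np.arange(0),
                                        np.arange(0)))
        assert res.metrics["train_accuracy"] == 1.0

    def test_separable_motif_data_generalizes(self):
        rng = np.random.default_rng(7)
        seqs, labels = _classifier_data(rng, n_per_class=100)
        spec = Bgc2orfSpec(max_epochs=150, patience=40, **_TINY_CLS)
        res = train_bgc2orf(seqs, labels, spec=spec, seed=0)
        assert res.metrics["test_accuracy"] > 0.95

    def test_rebalancing_matches_class_counts(self):
        rng = np.random.default_rng(1)
        seqs, labels = _classifier_data(rng, n_per_class=30)
        seqs += [_rand_seq(rng, 24) for _ in range(60)]   # extra negatives
        labels += [0] * 60
        spec = Bgc2orfSpec(max_epochs=1, patience=1, **_TINY_CLS)
        res = train_bgc2orf(seqs, labels, spec=spec, seed=0)
        assert res.metrics["n_train_pos"] == res.metrics["n_train_neg"]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        seqs, labels = _classifier_data(rng, n_per_class=12, length=16)
        spec = Bgc2orfSpec(pad_len=16, embed_size=6, conv_filters=4,
                           hidden_size=6, max_epochs=5, patience=5)
        a = train_bgc2orf(seqs, labels, spec=spec, seed=3)
        b = train_bgc2orf(seqs, labels, spec=spec, seed=3)
        assert a.metrics == b.metrics

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_bgc2orf(["AAA", "CCC"], [1, 1])


class TestTagger:
    def test_decode_cores_respects_k_squared(self):
        model = CleavageTagger(Orf2coreSpec(**_TINY_TAG), seed=0)
        seq = "MKAQDLLSEEAGDWTIKVNQCD"
        assert len(model.decode_cores(seq, k=1)) <= 1
        assert len(model.decode_cores(seq, k=5)) <= 25

    def test_decode_cores_start_before_end(self):
        model = CleavageTagger(Orf2coreSpec(**_TINY_TAG), seed=0)
        for start, end, _ in model.decode_cores("MKAQDLLSEEAGDWTIKV", k=5):
            assert 0 < start < end

    def test_hand_set_emissions_recover_interval(self):
        """Emission peaks at the cleavage transitions pin the core."""
        model = CleavageTagger(Orf2coreSpec(**_TINY_TAG), seed=0)
        L = 30
        emis = np.zeros((L, 5))
        emis[0, 0] = 5.0            # <start>
        emis[1:10, 1] = 5.0         # <before>
        emis[10:20, 2] = 5.0        # <core>
        emis[20:L - 1, 3] = 5.0     # <after>
        emis[L - 1, 4] = 5.0        # <end>
        trans = np.zeros((5, 5))
        path = crf_viterbi(emis, trans)
        assert path[10:20] == [2] * 10 and 2 not in path[:10] + path[20:]
        m_n = transition_marginals(emis, trans, 1, 2)
        m_c = transition_marginals(emis, trans, 2, 3)
        assert int(np.argmax(m_n)) + 1 == 10
        assert int(np.argmax(m_c)) + 1 == 20

    def test_trained_tagger_recovers_cores_top_k2(self):
        rng = np.random.default_rng(7)
        seqs, cores = _tagger_data(rng, n=60)
        spec = Orf2coreSpec(max_epochs=80, patience=20, **_TINY_TAG)
        res = train_orf2core(seqs, cores, spec=spec, seed=0)
        hits = sum(
            any(a == cs and b == ce for a, b, _ in res.model.decode_cores(s, k=5))
            for s, (cs, ce) in zip(seqs, cores))
        assert hits / len(seqs) >= 0.8

    def test_checkpoint_roundtrip(self, tmp_path):
        model = CleavageTagger(Orf2coreSpec(**_TINY_TAG), seed=4)
        path = tmp_path / "tagger.npz"
        save_model(model, path)
        back = load_model(path)
        seq = "MKAQDLLSEEAGDWTIKVNQCD"
        assert back.decode(seq) == model.decode(seq)


class TestSplitsAndCrossval:
    def test_split_proportions_and_disjoint(self):
        rng = np.random.default_rng(0)
        tr, va, te = split_data(100, DataSplit(), rng)
        assert len(tr) == 81 and len(va) == 9 and len(te) == 10
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            DataSplit(train=0.5, validation=0.2, test=0.2)

    def test_folds_partition_data(self):
        rng = np.random.default_rng(2)
        seqs, labels = _classifier_data(rng, n_per_class=15, length=16)
        spec = Bgc2orfSpec(pad_len=16, embed_size=6, conv_filters=4,
                           hidden_size=6, max_epochs=2, patience=2)
        out = crossval(train_bgc2orf, (seqs, labels), folds=5, seed=1,
                       spec=spec)
        tested = [i for fold in out["test_partition"] for i in fold]
        assert sorted(tested) == list(range(len(seqs)))
        assert len(out["fold_accuracies"]) == 5

    def test_same_seed_same_folds(self):
        rng = np.random.default_rng(2)
        seqs, labels = _classifier_data(rng, n_per_class=12, length=16)
        spec = Bgc2orfSpec(pad_len=16, embed_size=6, conv_filters=4,
                           hidden_size=6, max_epochs=2, patience=2)
        a = crossval(train_bgc2orf, (seqs, labels), folds=4, seed=5, spec=spec)
        b = crossval(train_bgc2orf, (seqs, labels), folds=4, seed=5, spec=spec)
        assert a["test_partition"] == b["test_partition"]
        assert a["fold_accuracies"] == b["fold_accuracies"]

    def test_too_few_examples_rejected(self):
        with pytest.raises(ValueError):
            crossval(train_bgc2orf, (["AAA"] * 6, [1, 1, 1, 0, 0, 0]), folds=10)

    def test_planted_motif_crossval_accuracy(self):
        rng = np.random.default_rng(11)
        seqs, labels = _classifier_data(rng, n_per_class=50)
        spec = Bgc2orfSpec(max_epochs=120, patience=30, **_TINY_CLS)
        out = crossval(train_bgc2orf, (seqs, labels), folds=5, seed=0,
                       spec=spec)
        assert out["mean_accuracy"] > 0.9
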