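"""Catalog construction, NMF signature extraction, background adjustment."""

import numpy as np
import pandas as pd
import pytest

from canpancan.contexts import CHANNEL_LABELS
from canpancan.signatures import (
    adjust_background,
    attribute_mutations,
    build_catalog,
    cosine_similarity,
    extract_signatures,
    match_signatures,
    s1_screen,
)
from canpancan.simulate import default_signatures, simulate_catalog


def _mutation_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "channel"])


class TestCatalog:
    def test_empty_input_zero_matrix(self):
        cat, n = build_catalog(_mutation_table([]), tumor_ids=["t1"])
        assert cat.to_numpy().sum() == 0 and n == 0

    def test_identical_mutations_single_channel(self):
        cat, _ = build_catalog(_mutation_table([("t1", 17)] * 10))
        assert cat.loc["t1"].sum() == 10
        assert cat.iloc[0, 17] == 10

    def test_conservation_and_unclassifiable_counted(self):
        rows = [("t1", 3), ("t1", -1), ("t2", 90), ("t2", 3)]
        cat, n = build_catalog(_mutation_table(rows))
        assert cat.to_numpy().sum() == 3
        assert n == 1
        assert list(cat.columns) == list(CHANNEL_LABELS)


class TestExtraction:
    def test_three_signature_recovery(self):
        sigs = default_signatures(3)
        cat, _ = simulate_catalog(sigs, n_tumors=80, muts_per_tumor=300, seed=2)
        ss = extract_signatures(cat, n_iterations=8, rank_range=(1, 4), seed=2)
        assert ss.selected_rank == 3
        for truth_sig in sigs:
            assert max(cosine_similarity(s, truth_sig)
                       for s in ss.signatures) >= 0.9

    def test_single_signature_rank_one(self):
        sigs = default_signatures(1)
        cat, _ = simulate_catalog(sigs, n_tumors=30, muts_per_tumor=200, seed=3)
        ss = extract_signatures(cat, n_iterations=6, rank_range=(1, 3), seed=3)
        assert ss.selected_rank == 1
        assert cosine_similarity(ss.signatures[0], sigs[0]) >= 0.99

    def test_deterministic_given_seed(self):
        sigs = default_signatures(2)
        cat, _ = simulate_catalog(sigs, n_tumors=20, muts_per_tumor=150, seed=4)
        a = extract_signatures(cat, n_iterations=4, rank_range=(1, 3), seed=9)
        b = extract_signatures(cat, n_iterations=4, rank_range=(1, 3), seed=9)
        np.testing.assert_array_equal(a.signatures, b.signatures)
        np.testing.assert_array_equal(a.exposures, b.exposures)
        assert a.rank_votes == b.rank_votes

    def test_normalization_and_reconstruction(self):
        sigs = default_signatures(2)
        cat, _ = simulate_catalog(sigs, n_tumors=25, muts_per_tumor=200, seed=5)
        ss = extract_signatures(cat, n_iterations=4, rank_range=(2, 2), seed=5)
        np.testing.assert_allclose(ss.signatures.sum(axis=1), 1.0, atol=1e-9)
        assert (ss.exposures >= 0).all()
        recon = ss.exposures @ ss.signatures
        totals = cat.to_numpy().sum(axis=1)
        np.testing.assert_allclose(recon.sum(axis=1), totals, rtol=0.05)

    def test_degenerate_catalog_rejected(self):
        cat = pd.DataFrame(np.zeros((3, 96)), columns=list(CHANNEL_LABELS))
        with pytest.raises(ValueError):
            extract_signatures(cat, n_iterations=2, rank_range=(1, 2), seed=0)


class TestBackgroundAdjustment:
    def _uniform(self):
        return np.full(32, 1 / 32)

    def test_identity_when_backgrounds_match(self):
        sig = default_signatures(1)[0]
        out = adjust_background(sig, self._uniform(), self._uniform())
        np.testing.assert_allclose(out, sig, atol=1e-12)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        sig = rng.random(96)
        sig /= sig.sum()
        src = rng.dirichlet(np.ones(32))
        tgt = rng.dirichlet(np.ones(32))
        back = adjust_background(adjust_background(sig, src, tgt), tgt, src)
        np.testing.assert_allclose(back, sig, atol=1e-12)

    def test_doubling_target_frequency_doubles_prenormalized_weight(self):
        # two-context toy: channels of one trinucleotide vs the rest
        sig = np.full(96, 1 / 96)
        src = self._uniform()
        tgt = src.copy()
        tgt[0] *= 2  # trinucleotide ACA (channels with A_C_A context, C-centered)
        tgt /= tgt.sum()
        out = adjust_background(sig, src, tgt)
        # channels 0 (A[C>A]A), 16+0 (A[C>G]A), 32+0 (A[C>T]A) share ACA
        ratio = out[0] / out[1]
        base = sig[0] / sig[1]
        assert ratio == pytest.approx(2 * base * (src[1] / src[1]), rel=1e-9)

    def test_zero_source_with_support_rejected(self):
        sig = np.full(96, 1 / 96)
        src = self._uniform()
        src[0] = 0.0
        with pytest.raises(ValueError):
            adjust_background(sig, src / src.sum(), self._uniform())

    def test_uniform_backgrounds_preserve_channel_order(self):
        rng = np.random.default_rng(1)
        sig = rng.random(96)
        sig /= sig.sum()
        out = adjust_background(sig, self._uniform(), self._uniform())
        assert (np.argsort(out) == np.argsort(sig)).all()


class TestCosine:
    def test_identical_vectors(self):
        v = np.arange(1.0, 97.0)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = np.zeros(96)
        b = np.zeros(96)
        a[:48], b[48:] = 1, 1
        assert cosine_similarity(a, b) == 0.0

    def test_hand_example(self):
        a = np.zeros(4)
        b = np.zeros(4)
        a[0] = 1
        b[0] = b[1] = 1
        assert cosine_similarity(a, b) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(96), np.ones(96))

    def test_match_signatures_picks_best(self):
        sigs = default_signatures(3)
        res = match_signatures(sigs, sigs, ["s0", "s1", "s2"])
        assert list(res["best_match"]) == ["s0", "s1", "s2"]
        assert (res["cosine"] >= 0.999).all()


class TestS1Screen:
    def test_threshold_boundary(self):
        presence = pd.DataFrame({"m1": [True] * 10}, index=[f"t{i}" for i in
                                                            range(10)])
        s1 = pd.Series([15] * 5 + [14] * 5, index=presence.index)
        res = s1_screen(presence, s1)
        assert res.loc[0, "n_high"] == 5  # >= 15 is S1-high, 14 is not

    def test_strong_association_is_hit(self):
        tumors = [f"h{i}" for i in range(10)] + [f"l{i}" for i in range(100)]
        presence = pd.DataFrame(
            {"m1": [True] * 10 + [False] * 100,
             "m2": [False, True] * 55}, index=tumors)
        s1 = pd.Series([20] * 10 + [0] * 100, index=tumors)
        res = s1_screen(presence, s1).set_index("mutation")
        assert bool(res.loc["m1", "hit"])
        assert not bool(res.loc["m2", "hit"])

    def test_rare_mutation_excluded(self):
        tumors = [f"t{i}" for i in range(30)]
        presence = pd.DataFrame({"m1": [True] * 4 + [False] * 26}, index=tumors)
        s1 = pd.Series([20] * 15 + [0] * 15, index=tumors)
        assert s1_screen(presence, s1).empty

    def test_no_s1_high_empty(self):
        presence = pd.DataFrame({"m1": [True] * 10},
                                index=[f"t{i}" for i in range(10)])
        s1 = pd.Series(0, index=presence.index)
        assert s1_screen(presence, s1).empty


def test_attribution_max_posterior():
    from canpancan.signatures import SignatureSet

    sigs = np.zeros((2, 96))
    sigs[0, :48] = 1 / 48   # signature 0 lives in the first half
    sigs[1, 48:] = 1 / 48
    ss = SignatureSet(signatures=sigs, exposures=np.array([[10.0, 1.0]]),
                      tumor_ids=["t1"], selected_rank=2, rank_votes={2: 1})
    m = pd.DataFrame({"sample_id": ["t1", "t1", "t1"],
                      "channel": [3, 60, -1]})
    out = attribute_mutations(m, ss)
    assert list(out) == [0, 1, -1]
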