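"""Synthetic cohort generator: forced counts, truth conservation, distributions."""

import numpy as np
import pandas as pd
import pytest

from canpancan.contexts import CHANNEL_LABELS
from canpancan.simulate import (
    BreedSpec,
    SimConfig,
    default_signatures,
    simulate_annotation,
    simulate_catalog,
    simulate_cna,
    simulate_germline,
    simulate_somatic,
)


def _cfg(**kw):
    base = dict(seed=7, breeds=[BreedSpec("A"), BreedSpec("B")],
                n_dogs_per_breed=10, n_shared_sites=100,
                n_specific_per_breed=10)
    base.update(kw)
    return SimConfig(**base)


class TestGermline:
    def test_sample_counts_forced_by_config(self, small_cohort):
        roles = small_cohort.samples["role"].value_counts()
        assert roles["normal"] == 20 and roles["tumor"] == 20
        assert small_cohort.truth.swapped_case_ids == []

    def test_n_swaps_recorded_exactly(self):
        c = simulate_germline(_cfg(n_swaps=3))
        assert len(c.truth.swapped_case_ids) == 3

    def test_carrier_fraction_one_makes_all_dogs_carriers(self):
        cfg = _cfg(breeds=[BreedSpec("A", carrier_fraction=1.0),
                           BreedSpec("B", carrier_fraction=1.0)])
        c = simulate_germline(cfg)
        spec = c.sites[c.sites["kind"] == "breed_specific"]
        labels = c.truth.breed_of_dog.set_index("dog_id")["breed"]
        for site, b in zip(spec["site_id"], spec["breed"]):
            dogs = labels.index[labels == b]
            # every dog of the breed carries the site (VAF from a het/hom dose)
            assert (c.vaf.loc[dogs, site] > 0).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            _cfg(breeds=[])
        with pytest.raises(ValueError):
            _cfg(n_swaps=20)  # >= number of cases
        with pytest.raises(ValueError):
            _cfg(n_swaps=1)
        with pytest.raises(ValueError):
            _cfg(tumor_types={"T": -0.5})

    def test_reproducible_given_seed(self):
        a = simulate_germline(_cfg())
        b = simulate_germline(_cfg())
        pd.testing.assert_frame_equal(a.calls, b.calls)
        pd.testing.assert_frame_equal(a.vaf, b.vaf)

    def test_tumor_inherits_most_normal_sites(self, small_cohort):
        calls = small_cohort.calls
        for case in small_cohort.samples["case_id"].unique()[:5]:
            n = set(map(tuple, calls[(calls.case_id == case) & (calls.role == "normal")]
                        [["chrom", "pos"]].itertuples(index=False, name=None)))
            t = set(map(tuple, calls[(calls.case_id == case) & (calls.role == "tumor")]
                        [["chrom", "pos"]].itertuples(index=False, name=None)))
            assert len(n & t) / len(n) > 0.95


class TestSomatic:
    def test_poisson_burden_and_dispersion(self):
        # many tumors of one type: mean ~ rate*mb, variance/mean in [0.8, 1.2]
        cfg = _cfg(breeds=[BreedSpec("A")], n_dogs_per_breed=1000,
                   tumor_types={"T": 0.7}, tp53_mut_fraction=0.0,
                   artifact_rates={"frozen": 0.0, "FFPE": 0.0})
        _, truth = simulate_somatic(cfg)
        counts = truth.tumors["true_mutations"].to_numpy()
        lam = 0.7 * cfg.callable_mb
        assert counts.mean() == pytest.approx(lam, rel=0.05)
        assert 0.8 < counts.var() / counts.mean() < 1.2

    def test_tp53_effect_doubles_expected_burden(self):
        cfg = _cfg(breeds=[BreedSpec("A")], n_dogs_per_breed=600,
                   tumor_types={"T": 0.7}, tp53_effect=2.0, tp53_mut_fraction=0.5,
                   artifact_rates={"frozen": 0.0, "FFPE": 0.0})
        _, truth = simulate_somatic(cfg)
        t = truth.tumors
        m = t.loc[t.tp53_mutant, "true_mutations"].mean()
        w = t.loc[~t.tp53_mutant, "true_mutations"].mean()
        assert m / w == pytest.approx(2.0, rel=0.1)

    def test_artifact_rate_monte_carlo_mean(self):
        cfg = _cfg(breeds=[BreedSpec("A")], n_dogs_per_breed=1000,
                   tumor_types={"T": 0.1}, artifact_rates={"frozen": 50.0,
                                                           "FFPE": 50.0})
        _, truth = simulate_somatic(cfg)
        counts = truth.tumors["injected_artifacts"].to_numpy()
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 50.0) < 3 * se

    def test_single_signature_catalog_converges_to_generator(self):
        sig = default_signatures(1)[0]
        cfg = _cfg(breeds=[BreedSpec("A")], n_dogs_per_breed=400,
                   tumor_types={"T": 1.5}, signatures=sig[None, :],
                   signature_mix={"T": [1.0]},
                   artifact_rates={"frozen": 0.0, "FFPE": 0.0})
        cand, _ = simulate_somatic(cfg)
        freq = np.bincount(cand["true_channel"], minlength=96).astype(float)
        cos = freq @ sig / (np.linalg.norm(freq) * np.linalg.norm(sig))
        assert cos >= 0.99

    def test_artifact_classes_and_orientation_asymmetry(self):
        cfg = _cfg(artifact_rates={"frozen": 30.0, "FFPE": 30.0})
        cand, _ = simulate_somatic(cfg)
        art = cand[cand.is_artifact]
        assert set(art.loc[art.preservation == "FFPE", "ref"]) <= {"C"}
        assert set(art.loc[art.preservation == "frozen", "ref"]) <= {"G"}
        frac = art["f1r2_alt"] / (art["f1r2_alt"] + art["f2r1_alt"])
        assert (frac >= 0.75).mean() > 0.95  # binomial jitter around >=0.9

    def test_conservation_candidates_equal_truth_totals(self):
        cand, truth = simulate_somatic(_cfg())
        t = truth.tumors
        assert len(cand) == int((t.true_mutations + t.injected_artifacts).sum())


class TestAnnotation:
    def test_problematic_count_forced(self):
        _, _, truth = simulate_annotation(_cfg(), n_genes=100, n_problematic=10,
                                          n_retrogenes=0)
        assert int(truth.genes["problematic"].sum()) == 10

    def test_retrogene_parents_exist(self):
        genes, _, truth = simulate_annotation(_cfg(), n_genes=80,
                                              n_problematic=5, n_retrogenes=3)
        retro = truth.genes[truth.genes["retrogene"]]
        assert len(retro) == 3
        assert set(retro["parent_gene"]) <= set(genes["gene_id"])

    def test_intervals_valid(self):
        genes, exons, _ = simulate_annotation(_cfg())
        assert (genes["start"] < genes["end"]).all()
        assert (exons["start"] < exons["end"]).all()


class TestCNA:
    def test_zero_noise_bins_equal_segment_means(self):
        bins, truth = simulate_cna(_cfg(), n_tumors=2, noise_sd=0.0)
        for case, grp in bins.groupby("case_id"):
            segs = truth.cna_segments[truth.cna_segments.case_id == case]
            x = grp["log2_ratio"].to_numpy()
            for s in segs.itertuples(index=False):
                assert np.allclose(x[s.bin_start:s.bin_end], s.true_mean)

    def test_truth_segments_tile_without_overlap(self):
        _, truth = simulate_cna(_cfg(), n_tumors=3, n_bins=200)
        for _, segs in truth.cna_segments.groupby("case_id"):
            s = segs.sort_values("bin_start")
            assert s["bin_start"].iloc[0] == 0
            assert s["bin_end"].iloc[-1] == 200
            assert (s["bin_end"].to_numpy()[:-1]
                    == s["bin_start"].to_numpy()[1:]).all()


def test_simulate_catalog_counts_and_exposures():
    sigs = default_signatures(3)
    cat, w = simulate_catalog(sigs, n_tumors=20, muts_per_tumor=100, seed=1)
    assert cat.shape == (20, 96)
    assert list(cat.columns) == list(CHANNEL_LABELS)
    np.testing.assert_allclose(w.sum(axis=1), 1.0)
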