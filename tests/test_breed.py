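"""Breed-specific variant discovery and breed assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from canpancan import breed
from canpancan.simulate import simulate_holdout_dogs


class TestClassifySite:
    @pytest.mark.parametrize("vaf,depth,expected", [
        (0.19, 50, "reference"),
        (0.20, 10, "non-reference"),
        (0.9, 9, "ND"),
        (0.0, 10, "reference"),
    ])
    def test_three_way_rule(self, vaf, depth, expected):
        assert breed.classify_site(vaf, depth) == expected

    def test_invalid_vaf_rejected(self):
        with pytest.raises(ValueError):
            breed.classify_site(1.2, 50)
        with pytest.raises(ValueError):
            breed.classify_site(0.5, -1)

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(1)
        vaf = pd.DataFrame(rng.random((6, 8)))
        depth = pd.DataFrame(rng.integers(0, 40, size=(6, 8)))
        states = breed.classify_matrix(vaf, depth)
        for i, j in itertools.product(range(6), range(8)):
            assert states.iat[i, j] == breed.classify_site(vaf.iat[i, j],
                                                           depth.iat[i, j])


class TestNDFilter:
    def test_boundary_exactly_20_percent_retained(self):
        states = pd.DataFrame({"s1": ["ND"] * 2 + ["reference"] * 8,
                               "s2": ["ND"] * 3 + ["reference"] * 7})
        assert breed.filter_sites_by_nd(states) == ["s1"]

    def test_no_nd_keeps_everything(self):
        states = pd.DataFrame({"s1": ["reference"] * 5,
                               "s2": ["non-reference"] * 5})
        assert breed.filter_sites_by_nd(states) == ["s1", "s2"]


def _states(rows, site="s1"):
    """rows: list of (breed, state); builds a 1-site state matrix + labels."""
    labels = pd.Series([b for b, _ in rows],
                       index=[f"d{i}" for i in range(len(rows))])
    states = pd.DataFrame({site: [s for _, s in rows]}, index=labels.index)
    return states, labels


class TestBreedUnique:
    def test_passes_all_three_rules(self):
        rows = ([("B", "non-reference")] * 6 + [("B", "reference")] * 6
                + [("C", "reference")] * 12)
        states, labels = _states(rows)
        out = breed.discover_breed_unique(states, labels)
        assert list(out["breed"]) == ["B"]

    def test_fails_count_and_fraction(self):
        rows = ([("B", "non-reference")] * 4 + [("B", "reference")] * 8
                + [("C", "reference")] * 12)
        states, labels = _states(rows)
        assert breed.discover_breed_unique(states, labels).empty

    def test_covered_nonreference_in_other_breed_vetoes(self):
        rows = ([("B", "non-reference")] * 10 + [("B", "reference")] * 2
                + [("C", "reference")] * 11 + [("C", "non-reference")])
        states, labels = _states(rows)
        assert breed.discover_breed_unique(states, labels).empty

    def test_nd_dog_in_other_breed_does_not_veto(self):
        rows = ([("B", "non-reference")] * 10 + [("B", "reference")] * 2
                + [("C", "reference")] * 11 + [("C", "ND")])
        states, labels = _states(rows)
        assert list(breed.discover_breed_unique(states, labels)["breed"]) == ["B"]

    def test_small_breeds_ignored(self):
        rows = [("B", "non-reference")] * 9 + [("C", "reference")] * 12
        states, labels = _states(rows)  # B has only 9 dogs (< 10)
        assert breed.discover_breed_unique(states, labels).empty


class TestBreedEnriched:
    def test_clear_enrichment_wins_all_pairs(self):
        rows = ([("A", "non-reference")] * 10 + [("B", "reference")] * 10
                + [("C", "reference")] * 10)
        states, labels = _states(rows)
        out = breed.discover_breed_enriched(states, labels)
        assert list(out["breed"]) == ["A"]
        # pairwise p for 10/10 vs 0/10 is 1/C(20,10)
        assert hypergeom.pmf(10, 20, 10, 10) == pytest.approx(1 / 184756)

    def test_two_enriched_breeds_cancel(self):
        rows = ([("A", "non-reference")] * 10 + [("B", "non-reference")] * 10
                + [("C", "reference")] * 10)
        states, labels = _states(rows)
        assert breed.discover_breed_enriched(states, labels).empty

    def test_identical_counts_nothing_enriched(self):
        rows = ([("A", "non-reference")] * 5 + [("A", "reference")] * 5
                + [("B", "non-reference")] * 5 + [("B", "reference")] * 5)
        states, labels = _states(rows)
        assert breed.discover_breed_enriched(states, labels).empty


def brute_force_unique(states, labels):
    """Direct re-check of the three breed-unique criteria per site."""
    eligible = [b for b, n in labels.value_counts().items() if n >= 10]
    hits = []
    for site in states.columns:
        for b in eligible:
            mine = states.loc[labels == b, site]
            others = states.loc[labels.isin([x for x in eligible if x != b]), site]
            n_nonref = (mine == "non-reference").sum()
            if (n_nonref >= 5 and n_nonref / len(mine) >= 0.4
                    and not (others == "non-reference").any()):
                hits.append((site, b))
    return sorted(hits)


def test_discovery_matches_brute_force(small_cohort, breed_labels):
    states = breed.classify_matrix(small_cohort.vaf, small_cohort.depth)
    states = states[breed.filter_sites_by_nd(states)]
    out = breed.discover_breed_unique(states, breed_labels)
    assert sorted(zip(out["site_id"], out["breed"])) == \
        brute_force_unique(states, breed_labels)


@pytest.fixture(scope="module")
def panel_and_cohort(small_cohort, breed_labels):
    panel = breed.discover_panel(small_cohort.vaf, small_cohort.depth,
                                 breed_labels)
    return panel, small_cohort, breed_labels


class TestAssignment:
    def test_discovery_dogs_validated(self, panel_and_cohort):
        panel, cohort, labels = panel_and_cohort
        res, _, _ = breed.assign_breeds(cohort.vaf, cohort.depth, panel,
                                        labels, seed=1)
        outcomes = pd.Series([a.outcome for a in res])
        # on this small panel a couple of atypical dogs may stay unknown,
        # but no dog is ever assigned to the wrong breed
        assert (outcomes == "validated").mean() >= 0.9
        assert (outcomes == "corrected").sum() == 0

    def test_poor_coverage_not_evaluable(self, panel_and_cohort):
        panel, cohort, labels = panel_and_cohort
        depth = cohort.depth.copy()
        dog = depth.index[0]
        sites = list(panel["site_id"])
        # push 25% of this dog's panel sites below callable depth
        depth.loc[dog, sites[: int(0.25 * len(sites)) + 1]] = 5
        res, _, _ = breed.assign_breeds(cohort.vaf, depth, panel, labels, seed=1)
        byid = {a.dog_id: a for a in res}
        assert byid[dog].outcome == "not_evaluable"

    def test_deterministic_given_seed(self, panel_and_cohort):
        panel, cohort, labels = panel_and_cohort
        r1, _, _ = breed.assign_breeds(cohort.vaf, cohort.depth, panel, labels,
                                       seed=5)
        r2, _, _ = breed.assign_breeds(cohort.vaf, cohort.depth, panel, labels,
                                       seed=5)
        assert [(a.dog_id, a.outcome, a.assigned) for a in r1] == \
            [(a.dog_id, a.outcome, a.assigned) for a in r2]

    def test_holdouts_predicted_and_mixed_unknown(self, panel_and_cohort,
                                                  small_config):
        panel, cohort, labels = panel_and_cohort
        hv, hd, _ = simulate_holdout_dogs(small_config, cohort.sites,
                                          n_per_breed=3, n_mixed=4)
        vaf = pd.concat([cohort.vaf, hv])
        depth = pd.concat([cohort.depth, hd])
        lab = pd.concat([labels, pd.Series(index=hv.index, dtype=object)])
        res, _, _ = breed.assign_breeds(vaf, depth, panel, lab, seed=2)
        hold = [a for a in res if a.dog_id.startswith("holdout")]
        mixed = [a for a in res if a.dog_id.startswith("mixed")]
        assert all(a.outcome == "predicted"
                   and a.assigned == a.dog_id.split("_")[1] for a in hold)
        assert all(a.outcome == "unknown" for a in mixed)

    def test_empty_panel_rejected(self, panel_and_cohort):
        _, cohort, labels = panel_and_cohort
        empty = pd.DataFrame(columns=["site_id", "breed", "mode"])
        with pytest.raises(ValueError):
            breed.assign_breeds(cohort.vaf, cohort.depth, empty, labels)
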