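"""Problematic genes, TMB computation and TMB association screens."""

import numpy as np
import pandas as pd
import pytest

from canpancan.burden import (
    compare_tmb_groups,
    compute_tmb,
    flag_problematic_genes,
    gene_tmb_association,
    hypermutation_class,
    normalize_tmb,
    pathway_alteration_matrix,
)
from canpancan.simulate import SimConfig, simulate_annotation


def _annotation(rows):
    """rows: (gene_id, name, chrom, exon intervals)."""
    genes, exons = [], []
    for gid, name, chrom, exs in rows:
        genes.append((gid, name, chrom, "+", exs[0][0], exs[-1][1]))
        for i, (s, e) in enumerate(exs):
            exons.append((gid, i + 1, chrom, s, e))
    return (pd.DataFrame(genes, columns=["gene_id", "gene_name", "chrom",
                                         "strand", "start", "end"]),
            pd.DataFrame(exons, columns=["gene_id", "exon_number", "chrom",
                                         "start", "end"]))


class TestProblematicGenes:
    def test_id_only_single_exon_is_problematic(self):
        genes, exons = _annotation([
            ("ENSCAFG00000000001", "", "chr1", [(100, 400)]),
            ("ENSCAFG00000000002", "TP53", "chr1", [(1000, 1400)]),
            ("ENSCAFG00000000003", "", "chr1", [(2000, 2200), (2400, 2600)]),
        ])
        calls = flag_problematic_genes(genes, exons)
        assert [c.gene_id for c in calls] == ["ENSCAFG00000000001"]
        assert set(calls[0].reasons) == {"id_only", "single_exon"}

    def test_named_single_exon_not_problematic(self):
        genes, exons = _annotation([("g1", "MYC", "chr1", [(0, 500)])])
        assert flag_problematic_genes(genes, exons) == []

    def test_mitochondrial_genes_excluded(self):
        genes, exons = _annotation([("g1", "", "chrM", [(0, 500)])])
        assert flag_problematic_genes(genes, exons) == []

    def test_retrogene_matched_to_parent_from_simulator_truth(self):
        cfg = SimConfig(seed=3)
        genes, exons, truth = simulate_annotation(cfg, n_genes=60,
                                                  n_problematic=6,
                                                  n_retrogenes=3)
        calls = {c.gene_id: c for c in flag_problematic_genes(genes, exons)}
        tg = truth.genes.set_index("gene_id")
        flagged_truth = set(tg.index[tg["problematic"]])
        assert set(calls) == flagged_truth
        for gid, row in tg[tg["retrogene"]].iterrows():
            assert calls[gid].retrogene
            assert calls[gid].parent_gene == row["parent_gene"]
        for gid in flagged_truth - set(tg.index[tg["retrogene"]]):
            assert not calls[gid].retrogene


def _mutations(case_counts, gene="GENE1"):
    rows = []
    for case, n in case_counts.items():
        for i in range(n):
            rows.append((case, f"{case}_T", "chr1", 1000 + i, "C", "T", gene))
    return pd.DataFrame(rows, columns=["case_id", "sample_id", "chrom", "pos",
                                       "ref", "alt", "gene"])


class TestTMB:
    def test_formula(self):
        m = _mutations({"c1": 15})
        cb = pd.Series({"c1": 30_000_000})
        out = compute_tmb(m, cb)
        assert out.loc[0, "tmb"] == pytest.approx(0.5)

    def test_zero_mutations(self):
        out = compute_tmb(_mutations({}), pd.Series({"c1": 1e6}))
        assert out.loc[0, "tmb"] == 0.0

    @pytest.mark.parametrize("tmb,cls", [
        (10.5, "hyper"), (10.0, "normal"), (150.0, "ultra"), (0.4, "normal"),
    ])
    def test_hypermutation_classes(self, tmb, cls):
        assert hypermutation_class(tmb) == cls

    def test_duplicates_and_order_invariance(self):
        m = _mutations({"c1": 10})
        dup = pd.concat([m, m.iloc[:3]]).sample(frac=1, random_state=0)
        cb = pd.Series({"c1": 1e6})
        assert compute_tmb(dup, cb).loc[0, "mutation_count"] == 10

    def test_problematic_exclusion_never_increases_tmb(self):
        m = pd.concat([_mutations({"c1": 5}, "GENE1"),
                       _mutations({"c1": 4}, "BADGENE")])
        cb = pd.Series({"c1": 1e6})
        full = compute_tmb(m, cb).loc[0, "tmb"]
        excl = compute_tmb(m, cb, {"BADGENE"}).loc[0, "tmb"]
        assert excl <= full
        assert excl == pytest.approx(5.0)

    def test_zero_callable_rejected(self):
        with pytest.raises(ValueError):
            compute_tmb(_mutations({"c1": 1}), pd.Series({"c1": 0}))


class TestNormalize:
    def test_median_case_is_one(self):
        b = pd.DataFrame({"case_id": ["a", "b", "c"], "tmb": [1.0, 2.0, 3.0]})
        tt = pd.Series({"a": "T", "b": "T", "c": "T"})
        out = normalize_tmb(b, tt)
        assert out.loc["b"] == pytest.approx(1.0)
        assert out.loc["c"] == pytest.approx(1.5)

    def test_single_case_type_normalizes_to_one(self):
        b = pd.DataFrame({"case_id": ["a"], "tmb": [0.77]})
        out = normalize_tmb(b, pd.Series({"a": "T"}))
        assert out.loc["a"] == pytest.approx(1.0)

    def test_zero_median_gives_nan(self):
        b = pd.DataFrame({"case_id": ["a", "b"], "tmb": [0.0, 0.0]})
        out = normalize_tmb(b, pd.Series({"a": "T", "b": "T"}))
        assert out.isna().all()


class TestGroupComparison:
    def test_identical_groups(self):
        out = compare_tmb_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["p"] == pytest.approx(1.0)
        assert out["fold"] == pytest.approx(1.0)

    def test_small_groups_flagged(self):
        out = compare_tmb_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert out["below_size_rule"]

    def test_separated_groups_detected_with_expected_fold(self):
        rng = np.random.default_rng(2)
        hi = rng.lognormal(0.0, 0.3, size=100)       # median ~ 1.0
        lo = rng.lognormal(np.log(0.4), 0.3, size=100)  # median ~ 0.4
        out = compare_tmb_groups(hi, lo)
        assert out["p"] < 1e-6
        assert out["fold"] == pytest.approx(2.5, rel=0.15)

    def test_zero_median_denominator_infinite_fold(self):
        out = compare_tmb_groups([1.0] * 6, [0.0] * 6)
        assert np.isinf(out["fold"])


class TestAssociation:
    def _setup(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        cases = [f"c{i}" for i in range(n)]
        mut = rng.random(n) < 0.5
        tmb = np.where(mut, rng.lognormal(np.log(0.8), 0.2, n),
                       rng.lognormal(np.log(0.4), 0.2, n))
        burdens = pd.DataFrame({"case_id": cases, "tmb": tmb})
        ind = pd.DataFrame({"DRIVER": mut,
                            "RARE": np.zeros(n, dtype=bool)}, index=cases)
        ind.iloc[:4, 1] = True  # RARE mutated in only 4 tumors
        scope = pd.Series("OSA", index=cases)
        return burdens, ind, scope

    def test_driver_detected_and_rare_gene_skipped(self):
        burdens, ind, scope = self._setup()
        res = gene_tmb_association(burdens, ind, scope)
        assert list(res["gene"]) == ["DRIVER"]  # RARE (<5 tumors) not tested
        row = res.iloc[0]
        assert row["p"] < 1e-4 and row["fold"] == pytest.approx(2.0, rel=0.2)
        assert row["strong"]

    def test_s1_high_tumors_excluded(self):
        burdens, ind, scope = self._setup()
        s1 = pd.Series(20, index=burdens["case_id"])  # everything S1-high
        res = gene_tmb_association(burdens, ind, scope, s1_counts=s1)
        assert res.empty

    def test_null_gene_type_i_error_calibrated(self):
        # indicator independent of TMB: rejection rate ~5% over replicates
        rng = np.random.default_rng(7)
        n, reps = 60, 400
        tmb = rng.lognormal(0, 0.4, size=n)
        cases = [f"c{i}" for i in range(n)]
        burdens = pd.DataFrame({"case_id": cases, "tmb": tmb})
        scope = pd.Series("T", index=cases)
        hits = 0
        tested = 0
        for _ in range(reps):
            ind = pd.DataFrame({"G": rng.random(n) < 0.3}, index=cases)
            res = gene_tmb_association(burdens, ind, scope)
            if len(res):
                tested += 1
                hits += res.iloc[0]["p"] < 0.05
        rate = hits / tested
        se = np.sqrt(0.05 * 0.95 / tested)
        assert abs(rate - 0.05) < 3 * se

    def test_breed_scope_requires_tumor_type(self):
        burdens, ind, scope = self._setup()
        with pytest.raises(ValueError):
            gene_tmb_association(burdens, ind, scope, scope_kind="breed")


def test_pathway_matrix_single_member_reduces_to_gene():
    ind = pd.DataFrame({"A": [True, False], "B": [False, True]},
                       index=["s1", "s2"])
    pw = pathway_alteration_matrix(ind, {"P1": ["A"], "P2": ["A", "B"]})
    assert list(pw["P1"]) == list(ind["A"])
    assert list(pw["P2"]) == [True, True]
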