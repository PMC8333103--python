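"""Benchmark experiments exercising each pipeline stage against ground truth.

Each function simulates the stated cohort conditions with the synthetic
generator, runs the corresponding pipeline stage, and measures recovery
against the truth tables. They are used by the acceptance checks, the
numbered analysis drivers and the test suite; all randomness derives from the
single seed argument through named child streams.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import breed, burden, cna, filters, power, qc, signatures
from ._streams import child_rng, child_seed
from .simulate import (
    BreedSpec,
    SimConfig,
    default_signatures,
    simulate_catalog,
    simulate_cna,
    simulate_germline,
    simulate_holdout_dogs,
    simulate_somatic,
)
from .stats import bh_adjust, fisher_exact, wilcoxon_rank_sum

__all__ = [
    "swap_recovery_experiment",
    "breed_recovery_experiment",
    "filter_operating_characteristics",
    "tmb_recovery_experiment",
    "kernel_oracle_checks",
    "power_calibration_experiment",
    "signature_recovery_experiment",
    "segmentation_experiment",
]


# ---------------------------------------------------------------- pairing ---

def swap_recovery_experiment(seed: int = 0, n_seeds: int = 20,
                             n_cases: int = 60, n_swaps: int = 5) -> dict:
    """Tumor-normal swap recovery on 60-case cohorts across repeated seeds.

    Within-dog germline sharing is 99% and cross-dog sharing stays below 40%
    (population carrier frequencies 0.10-0.40 at shared sites). A run counts
    as exact when the flagged cases equal the injected swaps with no extras.
    """
    exact = 0
    flagged_total, truth_total = 0, 0
    for k in range(n_seeds):
        cfg = SimConfig(seed=child_seed(seed, f"swap{k}"),
                        breeds=[BreedSpec("A"), BreedSpec("B")],
                        n_dogs_per_breed=n_cases // 2, n_shared_sites=300,
                        n_specific_per_breed=20, n_swaps=n_swaps)
        cohort = simulate_germline(cfg)
        res = qc.pairing_concordance(cohort.calls)
        flagged = sorted(res.loc[res["flag"] == "mispaired", "case_id"])
        exact += flagged == cohort.truth.swapped_case_ids
        flagged_total += len(flagged)
        truth_total += n_swaps
    return {
        "exact_runs": exact, "n_seeds": n_seeds,
        "exact_fraction": exact / n_seeds,
        "flagged_total": flagged_total, "truth_total": truth_total,
        "n_cases": n_cases,
    }


# ------------------------------------------------------------------ breed ---

def breed_recovery_experiment(seed: int = 0, n_breeds: int = 8,
                              dogs_per_breed: int = 15,
                              sites_per_breed: int = 30,
                              holdout_per_breed: int = 5,
                              n_mixed: int = 10) -> dict:
    """Panel discovery and assignment accuracy on an 8-breed cohort.

    Carrier fraction 0.8, negative-binomial depth with mean 60; held-out
    pure-breed dogs must be predicted to their true breed and mixed-ancestry
    dogs (half-weight VAFs from two breeds) must stay unknown.
    """
    cfg = SimConfig(seed=child_seed(seed, "breed"),
                    breeds=[BreedSpec(f"B{i}", 0.8) for i in range(n_breeds)],
                    n_dogs_per_breed=dogs_per_breed, n_shared_sites=400,
                    n_specific_per_breed=sites_per_breed,
                    depth_model=(60.0, 3.0))
    cohort = simulate_germline(cfg)
    labels = pd.Series(cohort.truth.breed_of_dog.set_index("dog_id")["breed"])
    panel = breed.discover_panel(cohort.vaf, cohort.depth, labels)
    truth_sites = cohort.sites.loc[cohort.sites["kind"] == "breed_specific",
                                   "site_id"]
    recovery = len(set(panel["site_id"]) & set(truth_sites)) / len(truth_sites)

    hv, hd, _ = simulate_holdout_dogs(cfg, cohort.sites,
                                      n_per_breed=holdout_per_breed,
                                      n_mixed=n_mixed)
    vaf = pd.concat([cohort.vaf, hv])
    depth = pd.concat([cohort.depth, hd])
    lab = pd.concat([labels, pd.Series(index=hv.index, dtype=object)])
    res, _, _ = breed.assign_breeds(vaf, depth, panel, lab, seed=seed)
    hold = [a for a in res if a.dog_id.startswith("holdout")]
    mixed = [a for a in res if a.dog_id.startswith("mixed")]
    correct = sum(a.outcome == "predicted"
                  and a.assigned == a.dog_id.split("_")[1] for a in hold)
    unknown = sum(a.outcome == "unknown" for a in mixed)
    return {
        "panel_recovery": recovery, "panel_sites": len(panel),
        "truth_sites": len(truth_sites),
        "holdout_accuracy": correct / len(hold), "n_holdout": len(hold),
        "mixed_unknown_rate": unknown / len(mixed), "n_mixed": len(mixed),
    }


# ---------------------------------------------------------------- filters ---

def filter_operating_characteristics(seed: int = 0,
                                     min_candidates: int = 10_000) -> dict:
    """Orientation-filter sensitivity/specificity on a large candidate pool.

    The orientation Fisher test (p <= 0.05) is scored alone: sensitivity on
    injected orientation-biased artifacts, removal rate on symmetric true
    mutations. The class-routed cutoff filter is checked exhaustively against
    a brute-force restatement of the >=4-read / >=5%-mutant rule.
    """
    n_dogs = max(10, int(np.ceil(min_candidates / 2 / 75)))
    cfg = SimConfig(seed=child_seed(seed, "filters"),
                    breeds=[BreedSpec("A"), BreedSpec("B")],
                    n_dogs_per_breed=n_dogs, tumor_types={"T": 1.5},
                    artifact_rates={"frozen": 30.0, "FFPE": 30.0})
    cand, _ = simulate_somatic(cfg)
    p = np.array([
        filters.orientation_bias_test(r.f1r2_ref, r.f1r2_alt,
                                      r.f2r1_ref, r.f2r1_alt)
        for r in cand.itertuples(index=False)
    ])
    art = cand["is_artifact"].to_numpy()
    sens = float((p[art] <= 0.05).mean())
    true_removal = float((p[~art] <= 0.05).mean())

    agree = 0
    total = 0
    for f1r, f1a, f2r, f2a in itertools.product(range(6), repeat=4):
        got = filters.orientation_cutoff_filter(f1r, f1a, f2r, f2a,
                                                "C", "T", "FFPE")
        want = all((r + a) >= 4 and a >= 0.05 * (r + a)
                   for r, a in ((f1r, f1a), (f2r, f2a)))
        agree += got == want
        total += 1
    return {
        "n_candidates": len(cand), "n_artifacts": int(art.sum()),
        "fisher_artifact_sensitivity": sens,
        "fisher_true_mutation_removal": true_removal,
        "cutoff_brute_force_agreement": agree / total,
    }


# -------------------------------------------------------------------- tmb ---

def tmb_recovery_experiment(seed: int = 0, tumors_per_type: int = 100,
                            null_replicates: int = 1000) -> dict:
    """TMB recovery and the TP53-proxy association screen.

    Two tumor types with true rates 0.4 and 1.0 mutations/Mb, tp53_effect 2,
    100 tumors per type. Checks that stratum TMB medians fall inside the
    order-statistic 95% band implied by the Poisson truth (Bonferroni-
    adjusted across the four strata so the band is a joint 95% statement),
    that the screen ranks the TP53 proxy first per type with fold ~2, and
    that a null gene's rejection rate at p < 0.05 is calibrated.
    """
    cfg = SimConfig(seed=child_seed(seed, "tmb"),
                    breeds=[BreedSpec("A"), BreedSpec("B")],
                    n_dogs_per_breed=tumors_per_type,
                    tumor_types={"TMB_L": 0.4, "TMB_H": 1.0},
                    tp53_effect=2.0, tp53_mut_fraction=0.5,
                    artifact_rates={"frozen": 0.0, "FFPE": 0.0})
    cand, truth = simulate_somatic(cfg)
    callable_bases = pd.Series(cfg.callable_mb * 1e6, index=cfg.case_ids)
    burdens = burden.compute_tmb(cand, callable_bases)
    tt = truth.tumors.set_index("case_id")

    strata_in_band = 0
    strata = []
    n_strata = 2 * len(cfg.tumor_types)
    # Monte-Carlo band of the sample median under the Poisson truth (the ppf
    # grid cannot represent the half-integer medians of even-n samples);
    # Bonferroni-adjusted quantiles make the band a joint 95% statement
    band_rng = child_rng(seed, "tmb-band")
    q_lo, q_hi = 0.025 / n_strata, 1 - 0.025 / n_strata
    for ttype, rate in cfg.tumor_types.items():
        for mut in (False, True):
            sel = burdens[(burdens["case_id"].map(tt["tumor_type"]) == ttype)
                          & (burdens["case_id"].map(tt["tp53_mutant"]) == mut)]
            lam = rate * cfg.callable_mb * (cfg.tp53_effect if mut else 1.0)
            n = len(sel)
            med_null = np.median(band_rng.poisson(lam, size=(4000, n)), axis=1)
            lo = np.quantile(med_null, q_lo) / cfg.callable_mb
            hi = np.quantile(med_null, q_hi) / cfg.callable_mb
            med = float(sel["tmb"].median())
            inside = lo <= med <= hi
            strata_in_band += inside
            strata.append({"type": ttype, "tp53": mut, "median": med,
                           "band": (float(lo), float(hi)), "n": n})

    indicator = pd.crosstab(cand["case_id"], cand["gene"]).astype(bool)
    indicator = indicator.drop(columns=[""], errors="ignore")
    assoc = burden.gene_tmb_association(burdens, indicator, tt["tumor_type"])
    tp53_first = True
    tp53_p, tp53_fold = [], []
    for scope, grp in assoc.groupby("scope"):
        top = grp.sort_values("p").iloc[0]
        tp53_first &= top["gene"] == "TP53"
        row = grp.set_index("gene").loc["TP53"]
        tp53_p.append(float(row["p"]))
        tp53_fold.append(float(row["fold"]))

    # type-I error of the screen on a gene independent of TMB
    rng = child_rng(seed, "tmb-null")
    one_type = burdens[burdens["case_id"].map(tt["tumor_type"]) == "TMB_L"]
    vals = one_type["tmb"].to_numpy()
    hits = 0
    tested = 0
    for _ in range(null_replicates):
        mut = rng.random(len(vals)) < 0.3
        if mut.sum() < 5 or (~mut).sum() < 1:
            continue
        tested += 1
        hits += wilcoxon_rank_sum(vals[mut], vals[~mut]) < 0.05
    null_rate = hits / tested
    return {
        "strata_in_band": strata_in_band, "n_strata": len(strata),
        "strata": strata,
        "tp53_ranked_first": bool(tp53_first),
        "tp53_max_p": max(tp53_p), "tp53_folds": tp53_fold,
        "null_rejection_rate": null_rate,
        "null_se": float(np.sqrt(0.05 * 0.95 / tested)),
        "null_replicates": tested,
    }


# ---------------------------------------------------------------- kernels ---

def _fisher_two_sided_enum(a, b, c, d):
    row1, col1, n = a + b, a + c, a + b + c + d
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    probs = {k: sps.hypergeom.pmf(k, n, col1, row1) for k in support}
    return sum(p for p in probs.values() if p <= probs[a] * (1 + 1e-9))


def _bh_brute(p):
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def _ranksum_enum(x, y):
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n1 = len(x)
    obs = ranks[:n1].sum()
    mean = n1 * (len(pooled) + 1) / 2
    stats = np.array([ranks[list(c)].sum() for c in
                      itertools.combinations(range(len(pooled)), n1)])
    return float(np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-9))


def kernel_oracle_checks(seed: int = 0, n_bh_vectors: int = 1000,
                         fisher_total: int = 16) -> dict:
    """Fisher, BH and exact-Wilcoxon kernels against brute-force oracles."""
    fisher_err, n_tables = 0.0, 0
    for n in range(2, fisher_total + 1):
        for a, b, c in itertools.product(range(n + 1), repeat=3):
            d = n - a - b - c
            if d < 0 or min(a + b, c + d, a + c, b + d) == 0:
                continue
            n_tables += 1
            fisher_err = max(fisher_err, abs(
                fisher_exact([[a, b], [c, d]])
                - _fisher_two_sided_enum(a, b, c, d)))

    rng = child_rng(seed, "kernels")
    bh_err = 0.0
    for _ in range(n_bh_vectors):
        p = rng.random(int(rng.integers(1, 50)))
        bh_err = max(bh_err, float(np.max(np.abs(bh_adjust(p) - _bh_brute(p)))))

    wilcoxon_err = 0.0
    for _ in range(20):
        x = rng.normal(size=int(rng.integers(3, 9)))
        y = rng.normal(size=int(rng.integers(3, 9)))
        wilcoxon_err = max(wilcoxon_err,
                           abs(wilcoxon_rank_sum(x, y) - _ranksum_enum(x, y)))
    return {
        "fisher_max_abs_error": fisher_err, "fisher_tables_checked": n_tables,
        "bh_max_abs_error": bh_err, "bh_vectors_checked": n_bh_vectors,
        "wilcoxon_max_abs_error": wilcoxon_err,
    }


# ------------------------------------------------------------------ power ---

def power_calibration_experiment(seed: int = 0) -> dict:
    """Closed-form binomial power, cap rule, and simulator calibration."""
    binom_err = 0.0
    for p in (0.05, 0.10, 0.15, 0.20):
        for n in range(1, 61):
            binom_err = max(binom_err, abs(
                power.binomial_detection_power(p, n) - (1 - (1 - p) ** n)))

    cap = power.construct_prevalences(0.6, 2.0)

    fisher_null = power.fisher_power_sim(power.PowerConfig(
        n1=50, n2=50, p2=0.1, odds_ratio=1.0, reps=10_000,
        seed=child_seed(seed, "fp-null")))
    wil_null = power.wilcoxon_power_sim(power.PowerConfig(
        n1=30, n2=30, effect_size=0.0, wilcoxon_reps=10_000,
        seed=child_seed(seed, "wp-null")))
    fisher_500 = power.fisher_power_sim(power.PowerConfig(
        n1=50, n2=50, p2=0.1, odds_ratio=2.0, reps=500,
        seed=child_seed(seed, "fp-500")))
    fisher_oracle = power.fisher_power_sim(power.PowerConfig(
        n1=50, n2=50, p2=0.1, odds_ratio=2.0, reps=100_000,
        seed=child_seed(seed, "fp-oracle")))
    wil_effect = power.wilcoxon_power_sim(power.PowerConfig(
        n1=30, n2=30, effect_size=0.93, wilcoxon_reps=10_000,
        seed=child_seed(seed, "wp-093")))
    wil_oracle = power.wilcoxon_power_sim(power.PowerConfig(
        n1=30, n2=30, effect_size=0.93, wilcoxon_reps=100_000,
        seed=child_seed(seed, "wp-oracle")))
    return {
        "binomial_max_abs_error": binom_err,
        "cap_rule": cap,
        "fisher_null_power": fisher_null["power"],
        "fisher_null_se": fisher_null["se"],
        "wilcoxon_null_power": wil_null["power"],
        "wilcoxon_null_se": wil_null["se"],
        "fisher_power_500": fisher_500["power"],
        "fisher_power_oracle": fisher_oracle["power"],
        "fisher_oracle_se": fisher_oracle["se"],
        "wilcoxon_power_093": wil_effect["power"],
        "wilcoxon_power_oracle": wil_oracle["power"],
        "wilcoxon_oracle_se": wil_oracle["se"],
    }


# ------------------------------------------------------------- signatures ---

def signature_recovery_experiment(seed: int = 0, n_tumors: int = 200,
                                  muts_per_tumor: int = 500,
                                  n_iterations: int = 40) -> dict:
    """Signature extraction on catalogs from three known signatures.

    Also round-trips a background adjustment and checks S1-high calling
    against a brute-force per-mutation posterior count.
    """
    truth_sigs = default_signatures(3)
    catalog, _ = simulate_catalog(truth_sigs, n_tumors=n_tumors,
                                  muts_per_tumor=muts_per_tumor,
                                  seed=child_seed(seed, "sig-cat"))
    ss = signatures.extract_signatures(catalog, n_iterations=n_iterations,
                                       rank_range=(1, 5),
                                       seed=child_seed(seed, "sig-nmf"))
    cosines = [max(signatures.cosine_similarity(s, t) for s in ss.signatures)
               for t in truth_sigs]

    rng = child_rng(seed, "sig-bg")
    sig = truth_sigs[0]
    src = rng.dirichlet(np.ones(32))
    tgt = rng.dirichlet(np.ones(32))
    back = signatures.adjust_background(
        signatures.adjust_background(sig, src, tgt), tgt, src)
    roundtrip_err = float(np.max(np.abs(back - sig)))

    # S1-high via max-posterior attribution vs a brute-force recount
    cfg = SimConfig(seed=child_seed(seed, "sig-cohort"),
                    breeds=[BreedSpec("A")], n_dogs_per_breed=60,
                    tumor_types={"T": 1.0}, signatures=truth_sigs,
                    signature_mix={"T": [0.6, 0.2, 0.2]},
                    artifact_rates={"frozen": 0.0, "FFPE": 0.0})
    cand, _ = simulate_somatic(cfg)
    cand = cand.rename(columns={"true_channel": "channel"})
    cat2, _ = signatures.build_catalog(cand)
    ss2 = signatures.extract_signatures(cat2, n_iterations=6, rank_range=(3, 3),
                                        seed=child_seed(seed, "sig-nmf2"))
    attributed = signatures.attribute_mutations(cand, ss2)
    s1_index = 0  # call the first extracted signature "S1"
    s1_counts = attributed.groupby(cand["sample_id"]).apply(
        lambda s: int((s == s1_index).sum()))
    high = set(s1_counts.index[s1_counts >= 15])
    brute = {}
    pos = {t: i for i, t in enumerate(ss2.tumor_ids)}
    for sid, ch in zip(cand["sample_id"], cand["channel"]):
        post = ss2.exposures[pos[sid]] * ss2.signatures[:, int(ch)]
        brute[sid] = brute.get(sid, 0) + (int(np.argmax(post)) == s1_index)
    brute_high = {s for s, n in brute.items() if n >= 15}
    return {
        "modal_rank": ss.selected_rank,
        "rank_votes": ss.rank_votes,
        "vote_fraction": ss.rank_votes.get(ss.selected_rank, 0) / n_iterations,
        "min_recovery_cosine": min(cosines),
        "adjustment_roundtrip_error": roundtrip_err,
        "s1_high_matches_brute_force": high == brute_high,
        "n_s1_high": len(high),
    }


# -------------------------------------------------------------------- cna ---

def segmentation_experiment(seed: int = 0, n_tumors: int = 12,
                            noise_sd: float = 0.2,
                            permutations: int = 10_000) -> dict:
    """Segmentation and gene-call accuracy on 50-bin true segments.

    Gene calls are scored on genes lying fully inside one truth segment:
    sensitivity over genes in |mean|>1 segments, specificity over genes in
    neutral segments. A zero-noise track must be segmented exactly.
    """
    cfg_zero = cna.SegmenterConfig(permutations=permutations)
    x = np.concatenate([np.zeros(50), np.full(50, 1.5), np.zeros(50)])
    segs = cna.segment_track(x, cfg_zero, seed=child_seed(seed, "cna-zero"))
    zero_noise_exact = (list(segs["bin_start"]) == [0, 50, 100]
                        and list(segs["class"]) == ["neutral", "amp",
                                                    "neutral"])

    sim = SimConfig(seed=child_seed(seed, "cna-sim"))
    bin_size = 10_000
    bins, truth = simulate_cna(sim, n_tumors=n_tumors, n_bins=300,
                               bin_size=bin_size, noise_sd=noise_sd,
                               n_segments=6)
    tp = fn = tn = fp = 0
    for case, grp in bins.groupby("case_id"):
        segs = cna.segment_track(grp["log2_ratio"].to_numpy(), cfg_zero,
                                 seed=child_seed(seed, f"cna-{case}"))
        segs = segs.assign(start=segs["bin_start"] * bin_size,
                           end=segs["bin_end"] * bin_size)
        ts = truth.cna_segments[truth.cna_segments["case_id"] == case]
        genes = []
        for t in ts.itertuples(index=False):
            # genes fully inside the truth segment, 5 bins wide
            for gstart in range(t.bin_start, t.bin_end - 5, 10):
                genes.append((f"{case}_{gstart}", gstart * bin_size,
                              (gstart + 5) * bin_size, t.true_class))
        gene_df = pd.DataFrame(genes, columns=["gene_id", "start", "end",
                                               "truth"])
        calls = cna.call_cna_genes(segs, gene_df).set_index("gene_id")
        for g in gene_df.itertuples(index=False):
            got = calls.loc[g.gene_id, "class"]
            if g.truth in ("amp", "del"):
                tp += got == g.truth
                fn += got != g.truth
            else:
                tn += got == "neutral"
                fp += got != "neutral"
    return {
        "zero_noise_exact": bool(zero_noise_exact),
        "gene_call_sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "gene_call_specificity": tn / (tn + fp) if tn + fp else np.nan,
        "n_cna_genes": tp + fn, "n_neutral_genes": tn + fp,
        "n_tumors": n_tumors,
    }
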