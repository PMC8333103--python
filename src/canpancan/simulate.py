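"""Synthetic cohort generator with full ground truth.

Emulates the structure of a multi-study canine tumor/normal exome cohort at
the variant level: breed-structured germline variation, within-dog
tumor/normal germline sharing with injectable sample swaps, signature-driven
somatic mutations whose burden depends on tumor type and TP53 status,
orientation-biased sequencing artifacts (FFPE C>T deamination and oxoG G>T
classes), gene annotations containing problematic/retrogene entries, and
segmental copy number tracks. Every simulated entity is recorded in a truth
table so each downstream stage can be scored against known labels.

All randomness flows from one integer seed through named child streams
(:mod:`canpancan._streams`), so the output of one stage never depends on
whether another stage ran first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._streams import child_rng
from .contexts import BASES, CHANNEL_LABELS, channel_index, revcomp

__all__ = [
    "BreedSpec",
    "SimConfig",
    "TruthTables",
    "GermlineCohort",
    "default_signatures",
    "simulate_germline",
    "simulate_somatic",
    "simulate_annotation",
    "simulate_cna",
    "simulate_qc_metrics",
]


@dataclass(frozen=True)
class BreedSpec:
    """A breed and the carrier probability at its breed-specific sites."""

    name: str
    carrier_fraction: float = 0.8

    def __post_init__(self):
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError(f"carrier_fraction must be in [0,1]: {self.carrier_fraction}")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Rates are per-tumor expectations; ``tumor_types`` maps type name to its
    baseline somatic mutation rate in mutations per callable megabase.
    ``signature_mix`` maps tumor type to mixing weights over the rows of
    ``signatures`` (defaults to three synthetic signatures with distinct
    channel support). ``artifact_rates`` is the expected number of injected
    orientation-biased artifacts per tumor, keyed by preservation class.
    """

    seed: int = 0
    breeds: list = field(default_factory=lambda: [BreedSpec("BreedA"), BreedSpec("BreedB")])
    n_dogs_per_breed: int = 10
    n_shared_sites: int = 400
    n_specific_per_breed: int = 30
    tumor_types: dict = field(default_factory=lambda: {"TMB_L": 0.4, "TMB_H": 1.0})
    tp53_effect: float = 2.0
    tp53_mut_fraction: float = 0.5
    callable_mb: float = 30.0
    signature_mix: dict | None = None
    signatures: np.ndarray | None = None
    artifact_rates: dict = field(default_factory=lambda: {"frozen": 20.0, "FFPE": 50.0})
    ffpe_fraction: float = 0.5
    n_swaps: int = 0
    depth_model: tuple = (60.0, 3.0)  # (mean, dispersion) of the truncated NB
    germline_sharing: float = 0.99
    tumor_noise_sites: float = 3.0
    shared_freq_range: tuple = (0.10, 0.40)
    het_fraction: float = 0.7
    n_mixed_dogs: int = 0  # mixed-ancestry hold-outs (half weight from two breeds)

    def __post_init__(self):
        if not self.breeds:
            raise ValueError("at least one breed is required")
        if self.n_dogs_per_breed <= 0:
            raise ValueError("n_dogs_per_breed must be positive")
        for k in ("n_shared_sites", "n_specific_per_breed"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be nonnegative")
        for t, r in self.tumor_types.items():
            if r < 0:
                raise ValueError(f"negative mutation rate for tumor type {t!r}")
        if self.tp53_effect <= 0 or self.callable_mb <= 0:
            raise ValueError("tp53_effect and callable_mb must be positive")
        for k, v in self.artifact_rates.items():
            if v < 0:
                raise ValueError(f"negative artifact rate for class {k!r}")
        n_cases = len(self.breeds) * self.n_dogs_per_breed
        if self.n_swaps >= n_cases:
            raise ValueError(f"n_swaps ({self.n_swaps}) must be < number of cases ({n_cases})")
        if self.n_swaps == 1:
            raise ValueError("n_swaps=1 cannot mispair any case (a swap needs >=2 cases)")
        if self.signatures is None:
            self.signatures = default_signatures()
        self.signatures = np.asarray(self.signatures, dtype=float)
        if self.signatures.ndim != 2 or self.signatures.shape[1] != 96:
            raise ValueError("signatures must be an (n_signatures, 96) matrix")
        if self.signature_mix is None:
            k = self.signatures.shape[0]
            self.signature_mix = {
                t: np.full(k, 1.0 / k) for t in self.tumor_types
            }
        for t, w in self.signature_mix.items():
            w = np.asarray(w, dtype=float)
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"signature weights for {t!r} must sum to 1")
            self.signature_mix[t] = w

    @property
    def case_ids(self) -> list:
        return [
            f"{b.name}_{i:03d}" for b in self.breeds for i in range(self.n_dogs_per_breed)
        ]


@dataclass
class TruthTables:
    """Ground truth for a simulated cohort; one row per simulated entity."""

    breed_of_dog: pd.DataFrame | None = None
    swapped_case_ids: list = field(default_factory=list)
    site_labels: pd.DataFrame | None = None
    tumors: pd.DataFrame | None = None          # per-tumor burden/exposure truth
    mutation_labels: pd.DataFrame | None = None  # per-candidate artifact truth
    genes: pd.DataFrame | None = None            # problematic/retrogene truth
    cna_segments: pd.DataFrame | None = None


@dataclass
class GermlineCohort:
    samples: pd.DataFrame     # sample_id, case_id, dog_id, role, breed
    calls: pd.DataFrame       # long table of called variants per sample
    sites: pd.DataFrame       # site_id, chrom, pos, ref, alt, kind, breed
    vaf: pd.DataFrame         # dogs x sites observed VAF in the normal sample
    depth: pd.DataFrame       # dogs x sites read depth in the normal sample
    truth: TruthTables


def default_signatures(n: int = 3) -> np.ndarray:
    """Three synthetic 96-channel signatures with nearly disjoint support.

    Channel blocks mimic the qualitative shapes of real exposure processes
    (a C>T-dominated, a C>A-dominated and a T>C/T>G-dominated process) while
    staying synthetic; the within-block ripple breaks symmetry so factor
    recovery is identifiable.
    """
    if not 1 <= n <= 3:
        raise ValueError("1 to 3 default signatures are defined")
    blocks = [range(32, 48), range(0, 16), range(64, 96)]  # C>T, C>A, T>C+T>G
    sigs = np.zeros((n, 96))
    for i in range(n):
        idx = np.fromiter(blocks[i], dtype=int)
        w = 1.0 + 0.5 * np.sin(np.arange(idx.size) * 1.3 + i)
        sigs[i, idx] = w / w.sum()
    return sigs


def _draw_depth(rng: np.random.Generator, size, mean: float, dispersion: float) -> np.ndarray:
    """Negative-binomial depths truncated below at 1."""
    p = dispersion / (dispersion + mean)
    d = rng.negative_binomial(dispersion, p, size=size)
    return np.maximum(d, 1)


def _unique_positions(rng: np.random.Generator, n: int, lo: int, hi: int) -> np.ndarray:
    """n distinct integer positions in [lo, hi) without materializing the range."""
    out = np.unique(rng.integers(lo, hi, size=max(2 * n, 16)))
    while out.size < n:
        out = np.unique(np.concatenate([out, rng.integers(lo, hi, size=n)]))
    return rng.permutation(out)[:n]


def _random_alleles(rng: np.random.Generator, n: int):
    ref = rng.choice(list(BASES), size=n)
    shift = rng.integers(1, 4, size=n)
    alt = np.array([BASES[(BASES.index(r) + s) % 4] for r, s in zip(ref, shift)])
    return ref, alt


def simulate_germline(config: SimConfig) -> GermlineCohort:
    """Simulate per-sample germline variant sets for every dog.

    Each dog contributes one normal and one tumor sample; the tumor carries a
    ``germline_sharing`` fraction of the normal's variants plus a small number
    of tumor-private noise sites. ``n_swaps`` tumors are reassigned to the
    wrong cases by a cyclic permutation, and those case ids are recorded in
    the truth table.
    """
    rng = child_rng(config.seed, "germline")
    breeds = config.breeds
    dogs, dog_breed = [], []
    for b in breeds:
        for i in range(config.n_dogs_per_breed):
            dogs.append(f"{b.name}_{i:03d}")
            dog_breed.append(b.name)
    n_dogs = len(dogs)

    # --- site roster: cohort-shared + breed-specific, all on one synthetic chrom
    n_specific = config.n_specific_per_breed * len(breeds)
    n_sites = config.n_shared_sites + n_specific
    pos = np.sort(_unique_positions(rng, n_sites, 1_000, 50_000_000))
    ref, alt = _random_alleles(rng, n_sites)
    kind = np.array(
        ["shared"] * config.n_shared_sites + ["breed_specific"] * n_specific, dtype=object
    )
    site_breed = np.array(
        [""] * config.n_shared_sites
        + [b.name for b in breeds for _ in range(config.n_specific_per_breed)],
        dtype=object,
    )
    lo, hi = config.shared_freq_range
    freq = np.where(
        kind == "shared",
        rng.uniform(lo, hi, size=n_sites),
        np.array([
            next(bb.carrier_fraction for bb in breeds if bb.name == sb) if sb else 0.0
            for sb in site_breed
        ]),
    )
    sites = pd.DataFrame(
        {
            "site_id": [f"s{j:05d}" for j in range(n_sites)],
            "chrom": "chr1",
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "kind": kind,
            "breed": site_breed,
            "pop_freq": freq,
        }
    )

    # --- carrier matrix: shared sites by population frequency, specific sites
    # by the breed's carrier fraction and only within the breed
    u = rng.random((n_dogs, n_sites))
    carrier = u < freq[None, :]
    for j in range(n_sites):
        if kind[j] == "breed_specific":
            not_breed = np.array([db != site_breed[j] for db in dog_breed])
            carrier[not_breed, j] = False
    genotype_vaf = np.where(
        rng.random((n_dogs, n_sites)) < config.het_fraction, 0.5, 1.0
    )

    mean, disp = config.depth_model
    depth_n = _draw_depth(rng, (n_dogs, n_sites), mean, disp)
    alt_n = rng.binomial(depth_n, np.where(carrier, genotype_vaf, 0.0))
    vaf_n = alt_n / depth_n

    # --- per-sample call tables (a call exists only where the variant is carried)
    tumor_share = carrier & (rng.random((n_dogs, n_sites)) < config.germline_sharing)
    depth_t = _draw_depth(rng, (n_dogs, n_sites), mean, disp)
    alt_t = np.maximum(  # a called variant has at least one supporting read
        rng.binomial(depth_t, genotype_vaf), 1)

    # --- tumor swap: cyclic permutation of the chosen cases' tumor content
    case_order = list(dogs)
    swapped = []
    if config.n_swaps >= 2:
        chosen = sorted(rng.choice(n_dogs, size=config.n_swaps, replace=False).tolist())
        perm = {case_order[chosen[i]]: case_order[chosen[(i + 1) % len(chosen)]]
                for i in range(len(chosen))}
        swapped = [case_order[c] for c in chosen]
    else:
        perm = {}

    dog_index = {dg: i for i, dg in enumerate(dogs)}
    frames = []
    d_idx, j_idx = np.nonzero(carrier)
    frames.append(pd.DataFrame({
        "sample_id": [f"{dogs[d]}_N" for d in d_idx],
        "case_id": [dogs[d] for d in d_idx],
        "dog_id": [dogs[d] for d in d_idx],
        "role": "normal",
        "breed": [dog_breed[d] for d in d_idx],
        "chrom": "chr1", "pos": pos[j_idx], "ref": ref[j_idx], "alt": alt[j_idx],
        "depth": depth_n[d_idx, j_idx], "alt_depth": alt_n[d_idx, j_idx],
    }))
    for case in case_order:
        source = perm.get(case, case)  # tumor labeled `case` holds `source`'s germline
        d_src = dog_index[source]
        j = np.flatnonzero(tumor_share[d_src])
        breed_lbl = dog_breed[dog_index[case]]
        frames.append(pd.DataFrame({
            "sample_id": f"{case}_T", "case_id": case, "dog_id": source,
            "role": "tumor", "breed": breed_lbl,
            "chrom": "chr1", "pos": pos[j], "ref": ref[j], "alt": alt[j],
            "depth": depth_t[d_src, j], "alt_depth": alt_t[d_src, j],
        }))
        n_noise = rng.poisson(config.tumor_noise_sites)
        if n_noise:
            noise_pos = _unique_positions(rng, n_noise, 60_000_000, 90_000_000)
            dep = _draw_depth(rng, n_noise, mean, disp)
            frames.append(pd.DataFrame({
                "sample_id": f"{case}_T", "case_id": case, "dog_id": source,
                "role": "tumor", "breed": breed_lbl,
                "chrom": "chr2", "pos": noise_pos, "ref": "C", "alt": "T",
                "depth": dep, "alt_depth": np.maximum(rng.binomial(dep, 0.4), 1),
            }))

    calls = pd.concat(frames, ignore_index=True)
    calls["vaf"] = calls["alt_depth"] / calls["depth"]

    samples = (
        calls[["sample_id", "case_id", "dog_id", "role", "breed"]]
        .drop_duplicates("sample_id")
        .reset_index(drop=True)
    )

    truth = TruthTables(
        breed_of_dog=pd.DataFrame({"dog_id": dogs, "breed": dog_breed}),
        swapped_case_ids=sorted(swapped),
        site_labels=sites.copy(),
    )
    vaf_df = pd.DataFrame(vaf_n, index=dogs, columns=sites["site_id"])
    depth_df = pd.DataFrame(depth_n, index=dogs, columns=sites["site_id"])
    return GermlineCohort(samples, calls, sites, vaf_df, depth_df, truth)


def simulate_holdout_dogs(config: SimConfig, sites: pd.DataFrame, n_per_breed: int,
                          n_mixed: int = 0):
    """Extra dogs not in the discovery cohort, for breed prediction tests.

    Pure-breed hold-outs draw carriers like discovery dogs; mixed-ancestry
    dogs carry each of two breeds' specific sites at half the carrier
    fraction and at half the allelic dose (expected VAF ~0.25), emulating F1
    crosses whose panel profile matches no single breed.
    """
    rng = child_rng(config.seed, "holdout")
    mean, disp = config.depth_model
    n_sites = len(sites)
    freq = sites["pop_freq"].to_numpy()
    kind = sites["kind"].to_numpy()
    site_breed = sites["breed"].to_numpy()
    rows, labels = [], []

    def _draw(dog_id, carrier_p, dose):
        carrier = rng.random(n_sites) < carrier_p
        gvaf = np.where(rng.random(n_sites) < config.het_fraction, 0.5, 1.0) * dose
        dep = _draw_depth(rng, n_sites, mean, disp)
        a = rng.binomial(dep, np.where(carrier, np.minimum(gvaf, 1.0), 0.0))
        rows.append((a / dep, dep))
        labels.append(dog_id)

    for b in config.breeds:
        for i in range(n_per_breed):
            carrier_p = np.where(
                kind == "shared", freq,
                np.where(site_breed == b.name, b.carrier_fraction, 0.0),
            )
            _draw(f"holdout_{b.name}_{i:02d}", carrier_p, 1.0)
    breed_names = [b.name for b in config.breeds]
    for i in range(n_mixed):
        b1, b2 = rng.choice(len(breed_names), size=2, replace=False)
        cf1 = config.breeds[b1].carrier_fraction
        cf2 = config.breeds[b2].carrier_fraction
        carrier_p = np.where(
            kind == "shared", freq,
            np.where(site_breed == breed_names[b1], cf1,
                     np.where(site_breed == breed_names[b2], cf2, 0.0)),
        )
        _draw(f"mixed_{i:02d}", carrier_p, 0.5)

    vaf = pd.DataFrame([r[0] for r in rows], index=labels, columns=sites["site_id"])
    depth = pd.DataFrame([r[1] for r in rows], index=labels, columns=sites["site_id"])
    true_breed = pd.Series(
        [d.split("_")[1] if d.startswith("holdout") else "mixed" for d in labels],
        index=labels, name="breed",
    )
    return vaf, depth, true_breed


def _context_for_channel(rng: np.random.Generator, ch: int):
    """Pick (ref, alt, 5', 3') on a random strand consistent with channel ch."""
    label = CHANNEL_LABELS[ch]
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    if rng.random() < 0.5:  # emit on the purine strand half the time
        ref, alt = revcomp(ref), revcomp(alt)
        five, three = revcomp(three), revcomp(five)
    return ref, alt, five, three


def simulate_somatic(config: SimConfig, gene_pool: list | None = None) -> tuple:
    """Simulate somatic candidate calls for every tumor.

    True mutation counts are Poisson with mean ``rate x callable_mb`` times
    ``tp53_effect`` for TP53-mutant tumors; channels are drawn from the tumor
    type's signature mixture, and read orientations of true mutations are
    symmetric. Injected artifacts are C>T (FFPE tumors) or G>T (frozen, oxoG
    class) with low MAF and >=90% of mutant reads in one orientation class.

    Returns (candidates DataFrame, TruthTables with ``tumors`` and
    ``mutation_labels`` filled).
    """
    rng = child_rng(config.seed, "somatic")
    cases = config.case_ids
    types = list(config.tumor_types)
    mean, disp = config.depth_model
    if gene_pool is None:
        gene_pool = [f"GENE{i:04d}" for i in range(200)]
    gene_pool = [g for g in gene_pool if g != "TP53"]

    tumor_rows, cand_rows = [], []
    sig = config.signatures
    for i, case in enumerate(cases):
        ttype = types[i % len(types)]
        rate = config.tumor_types[ttype]
        preservation = "FFPE" if rng.random() < config.ffpe_fraction else "frozen"
        tp53 = rng.random() < config.tp53_mut_fraction
        lam = rate * config.callable_mb * (config.tp53_effect if tp53 else 1.0)
        n_true = rng.poisson(lam)
        mix = config.signature_mix[ttype]
        p_channel = mix @ sig
        p_channel = p_channel / p_channel.sum()
        n_art = rng.poisson(config.artifact_rates.get(preservation, 0.0))

        exposures = mix * n_true
        tumor_rows.append((case, f"{case}_T", ttype, preservation, tp53, n_true, n_art,
                           *exposures))

        channels = rng.choice(96, size=n_true, p=p_channel)
        positions = _unique_positions(rng, n_true + n_art, 1, 90_000_000)
        # one guaranteed TP53 mutation in TP53-mutant tumors; others random genes
        genes = list(rng.choice(gene_pool, size=n_true))
        if tp53 and n_true > 0:
            genes[0] = "TP53"
        for k in range(n_true):
            ref, alt, five, three = _context_for_channel(rng, int(channels[k]))
            dep = int(_draw_depth(rng, None, mean, disp))
            maf = rng.uniform(0.2, 0.6)
            nalt = max(1, int(rng.binomial(dep, maf)))
            nref = dep - nalt
            f1r2_alt = int(rng.binomial(nalt, 0.5))
            f1r2_ref = int(rng.binomial(nref, 0.5))
            cand_rows.append(
                (case, f"{case}_T", "chr3", int(positions[k]), ref, alt,
                 f1r2_ref, f1r2_alt, nref - f1r2_ref, nalt - f1r2_alt,
                 five + ref + three, preservation, genes[k],
                 False, "", int(channels[k]))
            )
        for k in range(n_art):
            if preservation == "FFPE":
                ref, alt, art_class = "C", "T", "ffpe_CtoT"
            else:
                ref, alt, art_class = "G", "T", "oxoG_GtoT"
            five, three = rng.choice(list(BASES)), rng.choice(list(BASES))
            nalt = 5 + int(rng.poisson(25))
            maf = rng.uniform(0.02, 0.06)
            nref = int(np.ceil(nalt * (1 - maf) / maf))
            orient_frac = rng.uniform(0.9, 1.0)
            f1r2_alt = int(rng.binomial(nalt, orient_frac))
            f1r2_ref = int(rng.binomial(nref, 0.5))
            cand_rows.append(
                (case, f"{case}_T", "chr3", int(positions[n_true + k]), ref, alt,
                 f1r2_ref, f1r2_alt, nref - f1r2_ref, nalt - f1r2_alt,
                 five + ref + three, preservation, "",
                 True, art_class, -1)
            )

    candidates = pd.DataFrame(
        cand_rows,
        columns=["case_id", "sample_id", "chrom", "pos", "ref", "alt",
                 "f1r2_ref", "f1r2_alt", "f2r1_ref", "f2r1_alt",
                 "context", "preservation", "gene",
                 "is_artifact", "artifact_class", "true_channel"],
    )
    candidates["depth"] = (
        candidates[["f1r2_ref", "f1r2_alt", "f2r1_ref", "f2r1_alt"]].sum(axis=1)
    )
    candidates["alt_depth"] = candidates["f1r2_alt"] + candidates["f2r1_alt"]
    candidates["maf"] = candidates["alt_depth"] / candidates["depth"]

    sig_cols = [f"exposure_{i}" for i in range(sig.shape[0])]
    tumors = pd.DataFrame(
        tumor_rows,
        columns=["case_id", "sample_id", "tumor_type", "preservation", "tp53_mutant",
                 "true_mutations", "injected_artifacts", *sig_cols],
    )
    truth = TruthTables(
        tumors=tumors,
        mutation_labels=candidates[
            ["sample_id", "chrom", "pos", "is_artifact", "artifact_class", "true_channel"]
        ].copy(),
    )
    return candidates, truth


def simulate_annotation(config: SimConfig, n_genes: int = 100,
                        n_problematic: int = 10, n_retrogenes: int = 3) -> tuple:
    """Simulate gene models with problematic-gene and retrogene ground truth.

    Emits named multi-exon genes, unnamed (Ensembl-ID-only) single-exon
    genes, single-exon genes WITH a symbol (not problematic), and retrogenes:
    ID-only single-exon entries whose exon is an intronless copy of a named
    parent gene, annotated over the parent locus so coordinate overlap stands
    in for sequence homology. Internal coordinates are 0-based half-open.

    Returns (genes DataFrame, exons DataFrame, TruthTables with ``genes``).
    """
    if n_problematic + n_retrogenes > n_genes:
        raise ValueError("more problematic genes than genes requested")
    rng = child_rng(config.seed, "annotation")
    n_named = n_genes - n_problematic - n_retrogenes
    n_named_single = max(1, n_named // 10)  # named single-exon genes: not problematic
    gene_rows, exon_rows, truth_rows = [], [], []
    cursor = {"chr1": 10_000, "chr2": 10_000}
    parents = []

    def _place(chrom, length):
        start = cursor[chrom]
        cursor[chrom] += length + int(rng.integers(5_000, 20_000))
        return start

    gid = 0
    for i in range(n_named):
        gid += 1
        gene_id = f"ENSCAFG{gid:011d}"
        name = f"GENE{gid:04d}" if i > 0 else "TP53"
        chrom = "chr1" if i % 2 == 0 else "chr2"
        if i < n_named_single:
            n_ex, intron_hi = 1, 0
        else:
            n_ex, intron_hi = int(rng.integers(3, 9)), 2000
        # parents reserved for retrogenes get dense exons so the intronless
        # copy is covered >=80% by the parent's exon union
        dense = len(parents) < n_retrogenes and n_ex > 1
        exon_lens = rng.integers(100, 300, size=n_ex)
        introns = (rng.integers(10, 50, size=max(n_ex - 1, 0)) if dense
                   else rng.integers(200, intron_hi + 201, size=max(n_ex - 1, 0)))
        length = int(exon_lens.sum() + (introns.sum() if n_ex > 1 else 0))
        start = _place(chrom, length)
        p = start
        for e in range(n_ex):
            exon_rows.append((gene_id, e + 1, chrom, p, p + int(exon_lens[e])))
            p += int(exon_lens[e]) + (int(introns[e]) if e < n_ex - 1 else 0)
        gene_rows.append((gene_id, name, chrom, "+", start, start + length))
        truth_rows.append((gene_id, name, False, False, ""))
        if dense:
            parents.append((gene_id, chrom, start, start + length))

    for r in range(n_retrogenes):
        gid += 1
        gene_id = f"ENSCAFG{gid:011d}"
        parent_id, chrom, pstart, pend = parents[r % len(parents)]
        gene_rows.append((gene_id, "", chrom, "+", pstart, pend))
        exon_rows.append((gene_id, 1, chrom, pstart, pend))
        truth_rows.append((gene_id, "", True, True, parent_id))

    for i in range(n_problematic):
        gid += 1
        gene_id = f"ENSCAFG{gid:011d}"
        chrom = "chr2"
        length = int(rng.integers(200, 800))
        start = _place(chrom, length)
        gene_rows.append((gene_id, "", chrom, "+", start, start + length))
        exon_rows.append((gene_id, 1, chrom, start, start + length))
        truth_rows.append((gene_id, "", True, False, ""))

    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "gene_name", "chrom", "strand", "start", "end"]
    )
    exons = pd.DataFrame(
        exon_rows, columns=["gene_id", "exon_number", "chrom", "start", "end"]
    )
    truth = TruthTables(
        genes=pd.DataFrame(
            truth_rows,
            columns=["gene_id", "gene_name", "problematic", "retrogene", "parent_gene"],
        )
    )
    return genes, exons, truth


def simulate_cna(config: SimConfig, n_tumors: int | None = None, n_bins: int = 300,
                 bin_size: int = 10_000, noise_sd: float = 0.2,
                 n_segments: int = 6) -> tuple:
    """Simulate per-tumor binned log2(T/N) tracks with true segments.

    True segments tile the binned genome without overlap; roughly a third are
    amplifications/deletions with |mean| in (1, 2], a third shallow events
    with |mean| ~0.5 and the rest neutral. Bin values are the segment mean
    plus N(0, noise_sd) noise.

    Returns (bins DataFrame, TruthTables with ``cna_segments``).
    """
    rng = child_rng(config.seed, "cna")
    cases = config.case_ids if n_tumors is None else [f"case_{i:03d}" for i in range(n_tumors)]
    bin_rows, seg_rows = [], []
    for case in cases:
        cuts = np.sort(rng.choice(np.arange(10, n_bins - 10), size=n_segments - 1,
                                  replace=False))
        bounds = np.concatenate([[0], cuts, [n_bins]])
        values = np.empty(n_bins)
        for s in range(n_segments):
            b0, b1 = int(bounds[s]), int(bounds[s + 1])
            u = rng.random()
            if u < 0.2:
                m = rng.uniform(1.1, 2.0)
            elif u < 0.4:
                m = -rng.uniform(1.1, 2.0)
            elif u < 0.6:
                m = rng.choice([-1, 1]) * rng.uniform(0.3, 0.6)
            else:
                m = 0.0
            values[b0:b1] = m
            cls = "amp" if m > 1 else ("del" if m < -1 else "neutral")
            seg_rows.append((case, "chr1", b0 * bin_size, b1 * bin_size, b0, b1, m, cls))
        noisy = values + rng.normal(0.0, noise_sd, size=n_bins)
        for b in range(n_bins):
            bin_rows.append((case, "chr1", b * bin_size, (b + 1) * bin_size, noisy[b]))
    bins = pd.DataFrame(bin_rows, columns=["case_id", "chrom", "start", "end", "log2_ratio"])
    truth = TruthTables(
        cna_segments=pd.DataFrame(
            seg_rows,
            columns=["case_id", "chrom", "start", "end", "bin_start", "bin_end",
                     "true_mean", "true_class"],
        )
    )
    return bins, truth


def simulate_catalog(signatures: np.ndarray, n_tumors: int, muts_per_tumor: float,
                     seed: int = 0, alpha: float = 1.0) -> tuple:
    """Tumor x 96 catalog drawn from known signatures with Dirichlet exposures.

    Each tumor's exposure weights are Dirichlet(alpha) over the signature
    rows and its mutation count Poisson(muts_per_tumor); channel counts are
    multinomial under the mixed channel distribution. Returns (catalog
    DataFrame, true exposure weight matrix).
    """
    sig = np.asarray(signatures, dtype=float)
    rng = child_rng(seed, "catalog")
    k = sig.shape[0]
    weights = rng.dirichlet(np.full(k, alpha), size=n_tumors)
    counts = np.zeros((n_tumors, 96), dtype=np.int64)
    for t in range(n_tumors):
        n = rng.poisson(muts_per_tumor)
        p = weights[t] @ sig
        counts[t] = rng.multinomial(n, p / p.sum())
    catalog = pd.DataFrame(counts, index=[f"tumor_{t:03d}" for t in range(n_tumors)],
                           columns=list(CHANNEL_LABELS))
    return catalog, weights


def simulate_qc_metrics(config: SimConfig, n_fail: int = 0) -> pd.DataFrame:
    """Per-sample sequencing metrics, with ``n_fail`` samples pushed below a gate."""
    rng = child_rng(config.seed, "qc")
    rows = []
    sample_ids = [f"{c}_{r}" for c in config.case_ids for r in ("N", "T")]
    fail_idx = set(rng.choice(len(sample_ids), size=n_fail, replace=False).tolist()) \
        if n_fail else set()
    for i, s in enumerate(sample_ids):
        read_pairs = int(rng.lognormal(np.log(5.5e7), 0.3))
        mapping_rate = rng.beta(40, 4)
        mapq30_rate = rng.beta(30, 5)
        target_rate = rng.beta(20, 20)
        coverage = rng.uniform(40, 120)
        if i in fail_idx:
            gate = rng.integers(4)
            if gate == 0:
                read_pairs = int(rng.uniform(1e6, 4.9e6))
            elif gate == 1:
                mapping_rate = rng.uniform(0.2, 0.59)
            elif gate == 2:
                target_rate = rng.uniform(0.05, 0.29)
            else:
                coverage = rng.uniform(5, 29)
        rows.append((s, read_pairs, mapping_rate, mapq30_rate, target_rate, coverage,
                     i in fail_idx))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "total_read_pairs", "mapping_rate", "mapq30_rate",
                 "target_rate", "mean_cds_coverage", "truth_fail"],
    )
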