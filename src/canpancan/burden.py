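"""Problematic-gene identification, tumor mutational burden, and TMB screens.

TMB = (somatic base substitutions + small indels in CDS) / (callable CDS
bases in millions), with mutations in problematic genes excluded. Problematic
genes are annotation entries that both lack a gene symbol (Ensembl-ID-only)
and consist of a single exon; a subset are retrogenes, intronless copies of a
named multi-exon parent. Hypermutation is TMB > 10, ultra-hypermutation
TMB > 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import wilcoxon_rank_sum

__all__ = [
    "ProblematicGeneCall",
    "flag_problematic_genes",
    "compute_tmb",
    "hypermutation_class",
    "compare_tmb_groups",
    "normalize_tmb",
    "gene_tmb_association",
    "pathway_alteration_matrix",
]

HYPER_TMB = 10.0
ULTRA_TMB = 100.0
MIN_MUTANT_TUMORS = 5       # a gene needs >= 5 mutant tumors in scope to be tested
RETRO_COVER_FRAC = 0.8      # exon-union coverage for retrogene parent matching
S1_HIGH_MIN = 15            # tumors with >= this many S1 mutations are S1-high


@dataclass(frozen=True)
class ProblematicGeneCall:
    gene_id: str
    reasons: tuple          # subset of ("id_only", "single_exon")
    retrogene: bool
    parent_gene: str | None


def _union_length(intervals) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _overlap_length(intervals, start, end) -> int:
    clipped = [(max(s, start), min(e, end)) for s, e in intervals
               if min(e, end) > max(s, start)]
    return _union_length(clipped)


def flag_problematic_genes(genes: pd.DataFrame, exons: pd.DataFrame) -> list:
    """Identify problematic genes and retrogenes from a gene annotation.

    ``genes`` needs columns gene_id, gene_name, chrom, start, end;
    ``exons`` needs gene_id, chrom, start, end (0-based half-open).
    Mitochondrial genes (chrom chrM/MT) are excluded up front. A gene is
    problematic iff it is both ID-only (empty/NaN name) and single-exon.
    A problematic gene is a retrogene when its exon is covered >=80% by the
    exon union of a single named multi-exon gene (coordinate overlap as a
    rule-based stand-in for sequence homology); the best-covering parent is
    reported.
    """
    for col in ("gene_id", "gene_name", "chrom", "start", "end"):
        if col not in genes.columns:
            raise ValueError(f"gene table lacks column {col!r}")
    g = genes[~genes["chrom"].isin(["chrM", "MT", "M"])].copy()
    exon_count = exons.groupby("gene_id").size()
    exons_by_gene = {gid: list(zip(grp["start"], grp["end"]))
                     for gid, grp in exons.groupby("gene_id")}
    named = g["gene_name"].notna() & (g["gene_name"].astype(str).str.strip() != "")
    multi_named = g[named & (g["gene_id"].map(exon_count).fillna(0) > 1)]
    parents_by_chrom = {
        ch: list(zip(grp["gene_id"], [exons_by_gene[i] for i in grp["gene_id"]]))
        for ch, grp in multi_named.groupby("chrom")
    }

    calls = []
    for row in g.itertuples(index=False):
        reasons = []
        is_id_only = not (isinstance(row.gene_name, str) and row.gene_name.strip())
        n_ex = int(exon_count.get(row.gene_id, 0))
        if n_ex == 0:
            raise ValueError(f"gene {row.gene_id!r} has no exon records")
        if is_id_only:
            reasons.append("id_only")
        if n_ex == 1:
            reasons.append("single_exon")
        if not (is_id_only and n_ex == 1):
            continue
        ex_s, ex_e = exons_by_gene[row.gene_id][0]
        exon_len = ex_e - ex_s
        best_cov, best_parent = 0.0, None
        for pid, p_exons in parents_by_chrom.get(row.chrom, []):
            cov = _overlap_length(p_exons, ex_s, ex_e) / exon_len
            if cov > best_cov:
                best_cov, best_parent = cov, pid
        is_retro = best_cov >= RETRO_COVER_FRAC
        calls.append(ProblematicGeneCall(
            row.gene_id, tuple(reasons), is_retro,
            best_parent if is_retro else None,
        ))
    return calls


def hypermutation_class(tmb: float) -> str:
    if tmb > ULTRA_TMB:
        return "ultra"
    if tmb > HYPER_TMB:
        return "hyper"
    return "normal"


def compute_tmb(mutations: pd.DataFrame, callable_bases: pd.Series,
                problematic_genes: set | None = None) -> pd.DataFrame:
    """Per-case TMB from a filtered CDS mutation table.

    ``mutations`` needs case_id, chrom, pos plus optionally ``gene`` (used
    for problematic exclusion) and ``sample_id``; duplicate records (same
    sample and locus) are dropped before counting. ``callable_bases`` maps
    case_id to callable CDS bases. Cases with zero mutations still appear
    with TMB 0.
    """
    if (callable_bases <= 0).any():
        bad = callable_bases.index[callable_bases <= 0].tolist()
        raise ValueError(f"non-positive callable bases for cases: {bad}")
    problematic_genes = problematic_genes or set()
    m = mutations.drop_duplicates(
        [c for c in ("sample_id", "case_id", "chrom", "pos", "ref", "alt")
         if c in mutations.columns]
    )
    if "gene" in m.columns:
        m = m[~m["gene"].isin(problematic_genes)]
    counts = m.groupby("case_id").size()
    rows = []
    for case, cb in callable_bases.items():
        n = int(counts.get(case, 0))
        tmb = n / (cb / 1e6)
        rows.append((case, n, float(cb), tmb, hypermutation_class(tmb)))
    return pd.DataFrame(rows, columns=["case_id", "mutation_count",
                                       "callable_bases", "tmb", "hypermutation"])


def normalize_tmb(burdens: pd.DataFrame, tumor_type: pd.Series) -> pd.Series:
    """TMB divided by the case's tumor-type median TMB.

    Cases of a type with median 0 are returned as NaN (excluded downstream).
    """
    tt = burdens["case_id"].map(tumor_type)
    med = burdens.groupby(tt.values)["tmb"].median()
    out = burdens["tmb"] / tt.map(med).to_numpy()
    out[~np.isfinite(out)] = np.nan
    return pd.Series(out.to_numpy(), index=burdens["case_id"], name="normalized_tmb")


def compare_tmb_groups(values_a, values_b, min_group: int = 5) -> dict:
    """Two-sided Wilcoxon comparison of two TMB groups with median fold change.

    Returns p, median fold (A over B; inf when B's median is 0), group sizes
    and ``below_size_rule`` when either group has fewer than ``min_group``
    members (still computed, but flagged).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    p = wilcoxon_rank_sum(a, b)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    fold = np.inf if med_b == 0 else med_a / med_b
    return {
        "p": p, "fold": fold, "median_a": med_a, "median_b": med_b,
        "n_a": a.size, "n_b": b.size,
        "below_size_rule": a.size < min_group or b.size < min_group,
    }


def gene_tmb_association(burdens: pd.DataFrame, gene_indicator: pd.DataFrame,
                         scope_labels: pd.Series, scope_kind: str = "tumor_type",
                         tumor_type: pd.Series | None = None,
                         s1_counts: pd.Series | None = None,
                         exclude_cases: set | None = None) -> pd.DataFrame:
    """Wilcoxon screen for genes whose mutation status tracks TMB.

    Within each scope (tumor type or breed), genes mutated in >=5 tumors of
    the scope are tested mutant vs wild type. Tumor-type scopes use raw TMB;
    breed scopes use TMB normalized by tumor-type median (``tumor_type``
    required). S1-high tumors (>= 15 S1-attributed mutations, via
    ``s1_counts``) and cases in ``exclude_cases`` (e.g. unclassified tumor
    type) are excluded from the analysis. ``strong`` marks p < 0.05 with
    median fold > 1.5.
    """
    if scope_kind not in ("tumor_type", "breed"):
        raise ValueError(f"unknown scope kind {scope_kind!r}")
    b = burdens.set_index("case_id")
    drop = set(exclude_cases or set())
    if s1_counts is not None:
        drop |= set(s1_counts.index[s1_counts >= S1_HIGH_MIN])
    keep = [c for c in b.index if c not in drop and c in gene_indicator.index]
    b = b.loc[keep]
    if scope_kind == "breed":
        if tumor_type is None:
            raise ValueError("breed-scope association requires tumor_type labels")
        values = normalize_tmb(b.reset_index(), tumor_type)
    else:
        values = pd.Series(b["tmb"].to_numpy(), index=b.index)
    ind = gene_indicator.loc[keep]
    rows = []
    for scope in sorted(pd.unique(scope_labels.loc[keep])):
        in_scope = [c for c in keep if scope_labels.loc[c] == scope]
        if len(in_scope) < 2:
            continue
        v = values.loc[in_scope]
        sub = ind.loc[in_scope]
        for gene in sub.columns:
            mut = sub[gene].astype(bool)
            if int(mut.sum()) < MIN_MUTANT_TUMORS or int((~mut).sum()) == 0:
                continue
            vm, vw = v[mut.to_numpy()].dropna(), v[(~mut).to_numpy()].dropna()
            if vm.empty or vw.empty:
                continue
            p = wilcoxon_rank_sum(vm, vw)
            med_w = float(vw.median())
            fold = np.inf if med_w == 0 else float(vm.median()) / med_w
            rows.append((gene, scope, int(mut.sum()), int((~mut).sum()), p, fold,
                         p < 0.05 and fold > 1.5))
    return pd.DataFrame(rows, columns=["gene", "scope", "n_mutant", "n_wildtype",
                                       "p", "fold", "strong"])


def pathway_alteration_matrix(gene_indicator: pd.DataFrame,
                              gene_sets: dict) -> pd.DataFrame:
    """Collapse a sample x gene indicator to sample x pathway by any-member OR."""
    cols = {}
    for pw, members in gene_sets.items():
        present = [g for g in members if g in gene_indicator.columns]
        cols[pw] = (gene_indicator[present].astype(bool).any(axis=1)
                    if present else pd.Series(False, index=gene_indicator.index))
    return pd.DataFrame(cols, index=gene_indicator.index)
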