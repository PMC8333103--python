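"""Recurrence and enrichment statistics over alteration tables.

All hypotheses are Fisher exact tests on 2x2 count tables with
Benjamini-Hochberg correction applied within each (entity class x scope)
family. Enrichment scores are signed -log10(q): positive for enrichment of
the alteration in the scope relative to the rest of the cohort, negative for
depletion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_exact, odds_ratio_haldane

__all__ = [
    "bh_adjust",
    "maf_outlier_test",
    "recurrent_entity_test",
    "enrichment_scores",
    "cross_species_compare",
]

SCORE_CAP = 300.0


def maf_outlier_test(mutations: pd.DataFrame) -> pd.DataFrame:
    """Per-mutation test for significantly higher MAF within its tumor.

    For each mutation of each tumor, a one-sided Fisher exact test compares
    its mutant/wild-type read counts against the pooled counts of the
    remaining mutations of the same tumor (direction: higher focal MAF).
    Requires columns sample_id (or case_id), alt_depth, depth. Mutations in
    single-mutation tumors are flagged ``not_testable`` with p = NaN.
    """
    key = "sample_id" if "sample_id" in mutations.columns else "case_id"
    out = mutations.copy()
    out["maf_outlier_p"] = np.nan
    out["maf_testable"] = False
    for _, grp in mutations.groupby(key, sort=False):
        if len(grp) < 2:
            continue
        alt = grp["alt_depth"].to_numpy(dtype=np.int64)
        ref = grp["depth"].to_numpy(dtype=np.int64) - alt
        tot_alt, tot_ref = alt.sum(), ref.sum()
        for i, idx in enumerate(grp.index):
            p = fisher_exact(
                [[alt[i], ref[i]], [tot_alt - alt[i], tot_ref - ref[i]]],
                alternative="greater",
            )
            out.loc[idx, "maf_outlier_p"] = p
            out.loc[idx, "maf_testable"] = True
    return out


def recurrent_entity_test(altered: pd.Series, background_altered: int,
                          background_total: int, n_scope: int) -> pd.DataFrame:
    """Fisher recurrence test of each entity against a background rate.

    ``altered`` maps entity to the number of altered samples among the
    ``n_scope`` samples of the scope; the background is given as pooled
    altered/total counts (e.g. all MAF-significant mutations for the
    mutation-level analysis, or genes harboring significant mutations for
    the gene-level analysis). Returns entity, counts, p and BH q.
    """
    if background_total <= 0:
        raise ValueError("empty background for recurrence test")
    rows = []
    for entity, k in altered.items():
        k = int(k)
        p = 1.0 if k == 0 else fisher_exact(
            [[k, n_scope - k],
             [background_altered, background_total - background_altered]],
            alternative="greater",
        )
        rows.append((entity, k, n_scope, p))
    df = pd.DataFrame(rows, columns=["entity", "n_altered", "n_scope", "p"])
    df["q"] = bh_adjust(df["p"]) if len(df) else []
    return df


def enrichment_scores(indicator: pd.DataFrame, scope_labels: pd.Series,
                      cap: float = SCORE_CAP) -> pd.DataFrame:
    """Signed enrichment scores of each entity in each scope vs the rest.

    ``indicator`` is a boolean sample x entity matrix; ``scope_labels`` maps
    sample to tumor type or breed. For each scope, each entity's altered vs
    wild-type counts inside the scope are compared to the remaining samples
    (two-sided Fisher), q values are BH-adjusted across entities within the
    scope, and the score is -log10(q) signed by the odds direction (ties at
    odds ratio 1 take the positive sign). Scores are capped at ``cap``.
    Returns a long table: scope, entity, counts, p, q, odds_ratio, score.
    """
    ind = indicator.astype(bool)
    rows = []
    for scope in sorted(pd.unique(scope_labels)):
        members = scope_labels.index[scope_labels == scope]
        inside = ind.loc[ind.index.isin(members)]
        outside = ind.loc[~ind.index.isin(members)]
        if inside.empty or outside.empty:
            continue
        ps, ors, counts = [], [], []
        for entity in ind.columns:
            a, b = int(inside[entity].sum()), int((~inside[entity]).sum())
            c, d = int(outside[entity].sum()), int((~outside[entity]).sum())
            ps.append(fisher_exact([[a, b], [c, d]]))
            ors.append(odds_ratio_haldane([[a, b], [c, d]]))
            counts.append((a, b, c, d))
        qs = bh_adjust(ps)
        for entity, p, q, orr, (a, b, c, d) in zip(ind.columns, ps, qs, ors, counts):
            with np.errstate(divide="ignore"):
                mag = min(-np.log10(q) if q > 0 else np.inf, cap)
            score = mag if orr >= 1 else -mag
            rows.append((scope, entity, a, b, c, d, p, q, orr, score))
    return pd.DataFrame(rows, columns=["scope", "entity", "altered_in", "wild_in",
                                       "altered_out", "wild_out", "p", "q",
                                       "odds_ratio", "score"])


def cross_species_compare(dog: pd.DataFrame, human: pd.DataFrame,
                          q_cutoff: float = 0.05, min_fold: float = 2.0) -> pd.DataFrame:
    """Compare per-entity alteration recurrence between species.

    ``dog`` and ``human`` are indexed by entity with columns ``altered`` and
    ``total``. Entities present in both with positive totals are tested by
    two-sided Fisher exact, BH-corrected across entities; an entity is
    ``different`` iff q < 0.05 AND the alteration-frequency ratio is >= 2 in
    either direction, else ``shared``. Entities with a zero total are skipped.
    """
    common = [e for e in dog.index if e in human.index]
    rows, skipped = [], []
    for e in common:
        ad, td = int(dog.loc[e, "altered"]), int(dog.loc[e, "total"])
        ah, th = int(human.loc[e, "altered"]), int(human.loc[e, "total"])
        if td == 0 or th == 0:
            skipped.append(e)
            continue
        p = fisher_exact([[ad, td - ad], [ah, th - ah]])
        fd, fh = ad / td, ah / th
        if fd == 0 and fh == 0:
            fold = 1.0
        elif min(fd, fh) == 0:
            fold = np.inf
        else:
            fold = max(fd / fh, fh / fd)
        rows.append((e, ad, td, ah, th, fd, fh, fold, p))
    df = pd.DataFrame(rows, columns=["entity", "dog_altered", "dog_total",
                                     "human_altered", "human_total",
                                     "dog_freq", "human_freq", "fold", "p"])
    df["q"] = bh_adjust(df["p"]) if len(df) else []
    if len(df):
        df["call"] = np.where((df["q"] < q_cutoff) & (df["fold"] >= min_fold),
                              "different", "shared")
    else:
        df["call"] = []
    df.attrs["skipped_entities"] = skipped
    return df
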