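"""Sequencing QC gates, coverage-randomness scoring, tumor-normal pairing checks.

Pairing verification relies on germline concordance: the tumor and normal of
the same dog must share more germline variants than either shares with any
other dog in the same study. The shared fraction between tumor i and normal j
is F[i,j] = S[i,j] / min(T_i, N_j) where T, N are variant-set sizes and S the
intersection size; case i is flagged mispaired when its self fraction falls
below its best non-self fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "QCThresholds",
    "apply_qc_gates",
    "coverage_rmse",
    "pairing_concordance",
]


@dataclass(frozen=True)
class QCThresholds:
    """QC gates; a sample fails when strictly below any threshold."""

    min_read_pairs: float = 5_000_000
    min_mapping_rate: float = 0.60
    min_target_rate: float = 0.30
    min_mean_coverage: float = 30.0

    def __post_init__(self):
        for f in ("min_read_pairs", "min_mapping_rate", "min_target_rate",
                  "min_mean_coverage"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


_GATES = {
    "total_read_pairs": "min_read_pairs",
    "mapping_rate": "min_mapping_rate",
    "target_rate": "min_target_rate",
    "mean_cds_coverage": "min_mean_coverage",
}


def apply_qc_gates(metrics: pd.DataFrame,
                   thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Gate samples on sequencing metrics.

    Returns one row per sample with ``status`` pass/fail/not_evaluable and
    ``failed_criteria`` listing each violated gate. A missing (NaN or absent)
    metric makes the sample not evaluable rather than silently passing.
    """
    rows = []
    for _, m in metrics.iterrows():
        failed, missing = [], []
        for col, thr_name in _GATES.items():
            thr = getattr(thresholds, thr_name)
            v = m.get(col, np.nan)
            if pd.isna(v):
                missing.append(col)
            elif v < thr:  # gates are strict: a value exactly at threshold passes
                failed.append(col)
        status = ("not_evaluable" if missing
                  else ("fail" if failed else "pass"))
        rows.append((m["sample_id"], status, ";".join(failed), ";".join(missing)))
    return pd.DataFrame(rows, columns=["sample_id", "status", "failed_criteria",
                                       "missing_metrics"])


def coverage_rmse(histogram: pd.DataFrame, quantile: float = 0.999) -> float:
    """RMSE between the empirical depth distribution and Poisson(mean depth).

    ``histogram`` has columns ``depth`` and ``bases``. Both distributions are
    expressed as probabilities per depth value over depths 0 through the
    ``quantile`` point of whichever distribution reaches further; the score
    measures how far coverage departs from the randomness of Poisson
    sampling (0 = perfectly Poisson-like).
    """
    depth = np.asarray(histogram["depth"], dtype=np.int64)
    bases = np.asarray(histogram["bases"], dtype=float)
    total = bases.sum()
    if len(depth) == 0 or total <= 0:
        raise ValueError("coverage histogram is empty")
    if (bases < 0).any() or (depth < 0).any():
        raise ValueError("negative histogram entries")
    lam = float((depth * bases).sum() / total)
    top = int(max(depth.max(), sps.poisson.ppf(quantile, lam)))
    support = np.arange(top + 1)
    empirical = np.zeros(top + 1)
    np.add.at(empirical, depth[depth <= top], bases[depth <= top])
    empirical /= total
    theoretical = sps.poisson.pmf(support, lam)
    return float(np.sqrt(np.mean((empirical - theoretical) ** 2)))


def _variant_sets(calls: pd.DataFrame, shared_prefilter: bool) -> dict:
    """Per-sample sets of (chrom, pos, ref, alt) germline keys.

    With ``shared_prefilter`` (default in :func:`pairing_concordance`), only
    variants detected in both the tumor and normal of at least one case are
    kept, discarding private call noise before concordance is measured.
    """
    key_cols = ["chrom", "pos", "ref", "alt"]
    df = calls
    if shared_prefilter:
        per_case = df.drop_duplicates(["case_id", "role", *key_cols])
        counts = per_case.groupby(["case_id", *key_cols], sort=False)["role"].nunique()
        good = set(counts[counts == 2].reset_index()[key_cols].itertuples(index=False,
                                                                          name=None))
        keys = list(zip(df["chrom"], df["pos"], df["ref"], df["alt"]))
        df = df[[k in good for k in keys]]
    out = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        out[sid] = set(zip(grp["chrom"], grp["pos"], grp["ref"], grp["alt"]))
    return out


def pairing_concordance(calls: pd.DataFrame, study: pd.Series | None = None,
                        shared_prefilter: bool = True) -> pd.DataFrame:
    """Verify tumor-normal pairings from germline variant sharing.

    ``calls`` is a long table with columns sample_id, case_id, role
    (normal/tumor), chrom, pos, ref, alt. ``study`` optionally maps case_id
    to a study label; comparisons never cross studies. Returns one row per
    case with Self, Best nonself, their difference, the best-matching other
    case, and ``flag`` True when Self - Best nonself < 0. Studies with a
    single case get flag ``not_evaluable``.
    """
    sets = _variant_sets(calls, shared_prefilter)
    cases = calls.drop_duplicates("case_id")["case_id"].tolist()
    if study is None:
        study = pd.Series("all", index=cases)
    results = []
    for st in pd.unique(study.loc[cases]):
        st_cases = [c for c in cases if study.loc[c] == st]
        tumors = {c: sets.get(f"{c}_T", None) for c in st_cases}
        normals = {c: sets.get(f"{c}_N", None) for c in st_cases}
        for c in st_cases:
            tset = _lookup(sets, calls, c, "tumor") if tumors[c] is None else tumors[c]
            nset = _lookup(sets, calls, c, "normal") if normals[c] is None else normals[c]
            tumors[c], normals[c] = tset, nset

        def F(ci, cj):
            t, n = tumors[ci], normals[cj]
            denom = min(len(t), len(n))
            return len(t & n) / denom if denom else 0.0

        for ci in st_cases:
            self_f = F(ci, ci)
            best, best_case = -np.inf, ""
            for cj in st_cases:
                if cj == ci:
                    continue
                f = max(F(ci, cj), F(cj, ci))
                if f > best:
                    best, best_case = f, cj
            if not np.isfinite(best):  # single-case study
                results.append((st, ci, self_f, np.nan, np.nan, "", "not_evaluable"))
            else:
                diff = self_f - best
                results.append((st, ci, self_f, best, diff, best_case,
                                "mispaired" if diff < 0 else "ok"))
    return pd.DataFrame(
        results,
        columns=["study", "case_id", "self", "best_nonself", "difference",
                 "best_nonself_case", "flag"],
    )


def _lookup(sets: dict, calls: pd.DataFrame, case: str, role: str) -> set:
    sid = calls.loc[(calls["case_id"] == case) & (calls["role"] == role), "sample_id"]
    if sid.empty:
        raise ValueError(f"case {case!r} lacks a {role} sample")
    return sets.get(sid.iloc[0], set())
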