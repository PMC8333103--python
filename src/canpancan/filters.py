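"""Post-calling somatic mutation filters.

Order of application in :func:`run_filters`: germline hard filters are a
separate entry point for germline VCF records; somatic candidates flow
through known-germline subtraction, the depth/MAF ladder, the orientation
Fisher test (read-pair strand bias, p <= 0.05 drops the call) and the
class-routed orientation cutoff filter (>=4 reads and >=5% mutant in EACH of
F1R2 and F2R1 for oxoG-prone G>T/C>A calls in frozen tumors of routed
studies and deamination-prone C>T/G>A calls in FFPE tumors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .contexts import channel_index, channel_label

__all__ = [
    "FilterConfig",
    "hard_filter_germline_calls",
    "subtract_known_germline",
    "five_step_filter",
    "orientation_bias_test",
    "orientation_cutoff_filter",
    "classify_96",
    "run_filters",
]

# substitutions (on the reported strand) routed to the cutoff filter
OXOG_SUBS = {("G", "T"), ("C", "A")}
FFPE_SUBS = {("C", "T"), ("G", "A")}


@dataclass
class FilterConfig:
    """Thresholds for the somatic filter chain.

    The depth/MAF ladder generalizes a published multi-step coverage/MAF
    screen; every threshold is explicit so a study can reproduce or disable
    individual steps. Normal-sample steps apply only when normal counts are
    present in the input.
    """

    min_mutant_reads: int = 3
    min_maf: float = 0.05
    min_tumor_depth: int = 8
    min_normal_depth: int = 6
    max_normal_mutant_reads: int = 1
    low_depth: int = 20
    low_depth_min_maf: float = 0.10
    orientation_p_cutoff: float = 0.05
    orientation_min_total: int = 4
    orientation_min_mutant_frac: float = 0.05
    orientation_sidedness: str = "two-sided"
    # preservation classes whose frozen tumors get the oxoG cutoff routing
    oxog_routed_studies: tuple = ("all",)

    def __post_init__(self):
        for f in ("min_mutant_reads", "min_tumor_depth", "min_normal_depth",
                  "low_depth", "orientation_min_total"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        for f in ("min_maf", "low_depth_min_maf", "orientation_p_cutoff",
                  "orientation_min_mutant_frac"):
            if not 0 < getattr(self, f) <= 1:
                raise ValueError(f"{f} must be in (0, 1]")


def hard_filter_germline_calls(records: pd.DataFrame) -> pd.DataFrame:
    """Hard-filter germline variant records on FS, QD and DP annotations.

    Drops a record iff FS > 30.0, QD < 2.0 or DP < 10. Records missing any of
    the three annotations are dropped with reason ``unannotated``
    (conservative). Returns the input with a ``filter_reason`` column; retained
    records have an empty reason.
    """
    for col in ("FS", "QD", "DP"):
        if col not in records.columns:
            raise ValueError(f"records lack required annotation column {col!r}")
    fs, qd, dp = records["FS"], records["QD"], records["DP"]
    reason = np.full(len(records), "", dtype=object)
    missing = fs.isna() | qd.isna() | dp.isna()
    reason[missing.to_numpy()] = "unannotated"
    with np.errstate(invalid="ignore"):
        reason[(~missing & (fs > 30.0)).to_numpy()] = "FS>30"
        reason[(~missing & (qd < 2.0)).to_numpy()] = "QD<2"
        reason[(~missing & (dp < 10)).to_numpy()] = "DP<10"
    out = records.copy()
    out["filter_reason"] = reason
    return out


def subtract_known_germline(candidates: pd.DataFrame,
                            known_sites: set) -> pd.DataFrame:
    """Remove candidates matching a known germline (chrom, pos, ref, alt) key."""
    if not known_sites:
        return candidates.copy()
    keys = list(zip(candidates["chrom"], candidates["pos"],
                    candidates["ref"], candidates["alt"]))
    keep = np.array([k not in known_sites for k in keys])
    return candidates[keep].copy()


def five_step_filter(depth: int, mutant: int, config: FilterConfig = FilterConfig(),
                     normal_depth: int | None = None,
                     normal_mutant: int | None = None) -> tuple:
    """Depth/MAF ladder on one candidate; returns (keep, rejecting step or "")."""
    if depth <= 0:
        return False, "no coverage"
    maf = mutant / depth
    if mutant < config.min_mutant_reads:
        return False, "mutant_reads"
    if maf < config.min_maf:
        return False, "maf"
    if depth < config.min_tumor_depth:
        return False, "tumor_depth"
    if normal_depth is not None and normal_depth < config.min_normal_depth:
        return False, "normal_depth"
    if normal_mutant is not None and normal_mutant > config.max_normal_mutant_reads:
        return False, "normal_mutant"
    if depth < config.low_depth and maf < config.low_depth_min_maf:
        return False, "low_depth_maf"
    return True, ""


def orientation_bias_test(f1r2_ref: int, f1r2_alt: int, f2r1_ref: int,
                          f2r1_alt: int, alternative: str = "two-sided") -> float:
    """Fisher exact p for read-orientation bias of the mutant allele.

    The table is [[f1r2_ref, f1r2_alt], [f2r1_ref, f2r1_alt]]; a genuine
    mutation supports both orientations symmetrically, while oxidative and
    deamination damage loads mutant reads onto one orientation. An all-zero
    table is uninformative and returns p = 1.
    """
    table = np.array([[f1r2_ref, f1r2_alt], [f2r1_ref, f2r1_alt]], dtype=np.int64)
    if (table < 0).any():
        raise ValueError("negative orientation counts")
    if table.sum() == 0:
        return 1.0
    return float(sps.fisher_exact(table, alternative=alternative)[1])


def _is_routed(ref: str, alt: str, preservation: str, study: str,
               config: FilterConfig) -> bool:
    sub = (ref.upper(), alt.upper())
    if preservation == "FFPE" and sub in FFPE_SUBS:
        return True
    routed = ("all" in config.oxog_routed_studies or study in config.oxog_routed_studies)
    if preservation == "frozen" and routed and sub in OXOG_SUBS:
        return True
    return False


def orientation_cutoff_filter(f1r2_ref: int, f1r2_alt: int, f2r1_ref: int,
                              f2r1_alt: int, ref: str, alt: str,
                              preservation: str, study: str = "all",
                              config: FilterConfig = FilterConfig()) -> bool:
    """Keep/drop decision of the class-routed per-orientation cutoff filter.

    Routed candidates (oxoG-prone substitutions in frozen tumors of routed
    studies; deamination-prone substitutions in FFPE tumors) must show, in
    EACH orientation class, total reads >= 4 of which >= 5% are mutant.
    Unrouted candidates always pass.
    """
    if not _is_routed(ref, alt, preservation, study, config):
        return True
    for r, a in ((f1r2_ref, f1r2_alt), (f2r1_ref, f2r1_alt)):
        total = r + a
        if total < config.orientation_min_total:
            return False
        if a / total < config.orientation_min_mutant_frac:
            return False
    return True


def classify_96(ref: str, alt: str, context: str) -> int:
    """96-channel index of a substitution given its trinucleotide context.

    ``context`` is the reference trinucleotide centered on the mutated base,
    on the reported strand. Raises ValueError for indels or ambiguous bases.
    """
    if len(context) != 3:
        raise ValueError(f"context must be a trinucleotide: {context!r}")
    if context[1].upper() != ref.upper():
        raise ValueError(f"context center {context[1]!r} does not match ref {ref!r}")
    return channel_index(ref, alt, context[0], context[2])


def run_filters(candidates: pd.DataFrame, known_sites: set | None = None,
                config: FilterConfig = FilterConfig()) -> tuple:
    """Full somatic filter chain on a candidate table.

    Indels (ref or alt longer than 1 base) bypass the orientation filters and
    the 96-class annotation; they are subject only to germline subtraction
    and the depth/MAF ladder. Returns (survivors DataFrame with a ``channel``
    column, rejection log DataFrame with per-candidate reason).
    """
    df = subtract_known_germline(candidates, known_sites or set())
    n_known_dropped = len(candidates) - len(df)
    reasons = []
    keep_mask = np.ones(len(df), dtype=bool)
    channels = np.full(len(df), -1, dtype=int)
    for i, row in enumerate(df.itertuples(index=False)):
        nd = getattr(row, "normal_depth", None)
        nm = getattr(row, "normal_mutant", None)
        nd = None if nd is None or pd.isna(nd) else int(nd)
        nm = None if nm is None or pd.isna(nm) else int(nm)
        keep, step = five_step_filter(int(row.depth), int(row.alt_depth), config, nd, nm)
        if not keep:
            keep_mask[i] = False
            reasons.append(f"ladder:{step}")
            continue
        is_indel = len(str(row.ref)) != 1 or len(str(row.alt)) != 1
        if not is_indel:
            p = orientation_bias_test(row.f1r2_ref, row.f1r2_alt,
                                      row.f2r1_ref, row.f2r1_alt,
                                      config.orientation_sidedness)
            if p <= config.orientation_p_cutoff:
                keep_mask[i] = False
                reasons.append("orientation_bias")
                continue
            if not orientation_cutoff_filter(
                    row.f1r2_ref, row.f1r2_alt, row.f2r1_ref, row.f2r1_alt,
                    row.ref, row.alt, row.preservation,
                    getattr(row, "study", "all"), config):
                keep_mask[i] = False
                reasons.append("orientation_cutoff")
                continue
            try:
                channels[i] = classify_96(row.ref, row.alt, row.context)
            except ValueError:
                channels[i] = -1
        reasons.append("")
    out = df[keep_mask].copy()
    out["channel"] = channels[keep_mask]
    out["channel_label"] = [channel_label(c) if c >= 0 else "" for c in out["channel"]]
    log = df[~keep_mask].copy()
    log["reject_reason"] = [r for r in reasons if r]
    log.attrs["n_known_germline_dropped"] = n_known_dropped
    return out, log
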