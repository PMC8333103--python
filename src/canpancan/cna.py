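"""Copy number analysis: segmentation, CNA gene calls, per-tumor Z-tests.

Tumor/normal log2 ratio tracks are segmented by recursive binary
segmentation: within each interval the maximal standardized mean-shift over
all split points is compared to its permutation null; the interval is split
where the shift is maximal when the permutation p is at or below the
configured significance level. Segments with |mean log2(T/N)| > 1 are called
amplifications/deletions and any-overlap transfers the call to genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._streams import child_rng
from .stats import bh_adjust

__all__ = [
    "SegmenterConfig",
    "segment_track",
    "call_cna_genes",
    "gene_ztest",
    "mean_center",
]

CNA_LOG2_THRESHOLD = 1.0


@dataclass(frozen=True)
class SegmenterConfig:
    """Changepoint significance and permutation count of the segmenter.

    ``secondary_min_mean`` etc. mirror the parameters of an external
    secondary segmenter whose segment files can be supplied for two-caller
    concordance; they are bookkeeping here, not a reimplementation.
    """

    alpha: float = 0.01
    permutations: int = 10_000
    min_width: int = 1
    secondary_w: int = 6
    secondary_k: int = 1000
    secondary_min_mean: float = 0.4
    secondary_q: float = 0.01

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.permutations < 1 or self.min_width < 1:
            raise ValueError("permutations and min_width must be >= 1")


def _max_shift(x: np.ndarray) -> tuple:
    """Max standardized mean-shift statistic and its split index.

    For split k, stat = |mean(x[:k]) - mean(x[k:])| / sqrt(1/k + 1/(n-k));
    scale-free under permutation so no variance estimate is needed.
    """
    n = x.size
    cs = np.cumsum(x)
    k = np.arange(1, n)
    mean_l = cs[:-1] / k
    mean_r = (cs[-1] - cs[:-1]) / (n - k)
    stat = np.abs(mean_l - mean_r) / np.sqrt(1.0 / k + 1.0 / (n - k))
    i = int(np.argmax(stat))
    return float(stat[i]), i + 1


def _max_shift_rows(X: np.ndarray) -> np.ndarray:
    n = X.shape[1]
    cs = np.cumsum(X, axis=1)
    k = np.arange(1, n)
    mean_l = cs[:, :-1] / k
    mean_r = (cs[:, -1:] - cs[:, :-1]) / (n - k)
    stat = np.abs(mean_l - mean_r) / np.sqrt(1.0 / k + 1.0 / (n - k))
    return stat.max(axis=1)


def segment_track(values, config: SegmenterConfig = SegmenterConfig(),
                  seed: int = 0) -> pd.DataFrame:
    """Segment a binned log2-ratio track into mean-constant segments.

    Returns a table with bin_start, bin_end (half-open bin indices), n_bins,
    mean and class (amp / del / neutral at |mean| > 1). An all-identical
    track yields one segment. Deterministic given seed and config.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        if x.size == 0:
            raise ValueError("empty track")
        return _segments_frame([(0, 1)], x)
    if not np.isfinite(x).all():
        raise ValueError("non-finite log ratios")
    rng = child_rng(seed, "cna-segment")
    bounds = []

    def recurse(lo, hi):
        n = hi - lo
        if n < 2 * config.min_width or np.ptp(x[lo:hi]) == 0:
            bounds.append((lo, hi))
            return
        obs, split = _max_shift(x[lo:hi])
        perms = rng.permuted(np.tile(x[lo:hi], (config.permutations, 1)), axis=1)
        null = _max_shift_rows(perms)
        p = (1 + int((null >= obs).sum())) / (config.permutations + 1)
        if p <= config.alpha:
            recurse(lo, lo + split)
            recurse(lo + split, hi)
        else:
            bounds.append((lo, hi))

    recurse(0, x.size)
    return _segments_frame(sorted(bounds), x)


def _segments_frame(bounds, x) -> pd.DataFrame:
    rows = []
    for lo, hi in bounds:
        m = float(np.mean(x[lo:hi]))
        cls = ("amp" if m > CNA_LOG2_THRESHOLD
               else "del" if m < -CNA_LOG2_THRESHOLD else "neutral")
        rows.append((lo, hi, hi - lo, m, cls))
    return pd.DataFrame(rows, columns=["bin_start", "bin_end", "n_bins", "mean",
                                       "class"])


def call_cna_genes(segments: pd.DataFrame, genes: pd.DataFrame,
                   secondary: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene CNA class from segment overlap (>=1 bp, shared coordinates).

    ``segments`` needs start, end, class; ``genes`` needs gene_id, start, end
    (and chrom if segments carry chrom). A gene overlapping both amp and del
    segments is reported as ``conflict``. When a ``secondary`` segment table
    from another segmenter is given, a non-neutral call is kept only if the
    secondary source supports the same class (two-caller concordance);
    otherwise calls carry a ``single_source`` flag.
    """
    def classify(seg_df):
        out = {}
        use_chrom = "chrom" in seg_df.columns and "chrom" in genes.columns
        for g in genes.itertuples(index=False):
            segs = seg_df
            if use_chrom:
                segs = seg_df[seg_df["chrom"] == g.chrom]
            hit = segs[(segs["start"] < g.end) & (segs["end"] > g.start)]
            classes = set(hit["class"]) - {"neutral"}
            if {"amp", "del"} <= classes:
                out[g.gene_id] = "conflict"
            elif classes:
                out[g.gene_id] = classes.pop()
            else:
                out[g.gene_id] = "neutral"
        return out

    primary = classify(segments)
    if secondary is None:
        return pd.DataFrame(
            {"gene_id": list(primary), "class": list(primary.values()),
             "single_source": True}
        )
    second = classify(secondary)
    rows = []
    for gid, cls in primary.items():
        if cls in ("amp", "del") and second.get(gid) != cls:
            rows.append((gid, "neutral", False))
        else:
            rows.append((gid, cls, False))
    return pd.DataFrame(rows, columns=["gene_id", "class", "single_source"])


def mean_center(values) -> np.ndarray:
    """Linear shift of a log2-ratio track so its genome-wide mean is 0."""
    x = np.asarray(values, dtype=float)
    return x - x.mean()


def gene_ztest(gene_means: pd.Series, q_cutoff: float = 0.01) -> pd.DataFrame:
    """Per-gene Z-tests of mean log2 ratio within one tumor.

    The null is the within-tumor empirical distribution of per-gene mean log
    ratios: z = (gene - mean) / sd over all genes; two-sided normal p; BH
    across genes; amp/del called by sign at q <= ``q_cutoff``. Requires >=10
    genes; with zero variance no calls are made.
    """
    x = gene_means.astype(float)
    if len(x) < 10:
        raise ValueError("gene Z-tests need >= 10 genes in the tumor")
    sd = float(x.std(ddof=1))
    if sd == 0:
        return pd.DataFrame({"gene_id": x.index, "z": 0.0, "p": 1.0, "q": 1.0,
                             "call": "neutral"})
    z = (x - x.mean()) / sd
    p = 2 * sps.norm.sf(np.abs(z))
    q = bh_adjust(p)
    call = np.where(q <= q_cutoff, np.where(z > 0, "amp", "del"), "neutral")
    return pd.DataFrame({"gene_id": x.index, "z": z.to_numpy(), "p": p, "q": q,
                         "call": call})
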