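"""Breed-specific germline variant discovery and breed assignment.

A site's state in a dog is reference (VAF < 0.2), non-reference (VAF >= 0.2)
or ND (not determined, depth < 10). Breed-unique variants are non-reference
in >=5 dogs and >=40% of dogs of one breed while reference in every
sufficiently covered dog of every other breed; breed-enriched variants win a
one-sided Fisher test against every other breed at p <= 0.1, with no second
breed doing the same. Dogs are then validated/predicted by hierarchical
clustering of their VAF profiles over the combined panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from functools import lru_cache

from ._streams import child_rng
from .stats import fisher_exact


@lru_cache(maxsize=1 << 20)
def _fisher_greater(a: int, b: int, c: int, d: int) -> float:
    # dog counts are small and repeat across sites; caching makes the
    # all-pairs enrichment scan cheap
    return fisher_exact([[a, b], [c, d]], alternative="greater")

__all__ = [
    "classify_site",
    "classify_matrix",
    "filter_sites_by_nd",
    "discover_breed_unique",
    "discover_breed_enriched",
    "discover_panel",
    "assign_breeds",
    "BreedAssignment",
]

REF, NONREF, ND = "reference", "non-reference", "ND"

MIN_DEPTH = 10          # below this a site is ND
NONREF_VAF = 0.2        # VAF at or above this is non-reference
MIN_BREED_DOGS = 10     # breeds with fewer dogs are not used for discovery
MIN_CARRIERS = 5        # breed-unique rule (1)
MIN_CARRIER_FRAC = 0.4  # breed-unique rule (2)
ENRICH_P = 0.1          # breed-enriched pairwise threshold
ND_EXCLUDE_FRAC = 0.2   # sites ND in > this fraction of samples are dropped
ELIGIBLE_COVERED = 0.8  # dog must cover > this fraction of panel sites
ADMIX_VAF = NONREF_VAF / 2  # mean VAF at a second breed's sites above this blocks assignment


def classify_site(vaf: float, depth: int) -> str:
    """Three-way site state for one dog: reference / non-reference / ND."""
    if depth < 0:
        raise ValueError("negative depth")
    if depth < MIN_DEPTH:
        return ND
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"VAF out of [0,1]: {vaf}")
    return NONREF if vaf >= NONREF_VAF else REF


def classify_matrix(vaf: pd.DataFrame, depth: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`classify_site` over a dogs x sites matrix."""
    if (depth.to_numpy() < 0).any():
        raise ValueError("negative depth")
    covered = depth.to_numpy() >= MIN_DEPTH
    v = vaf.to_numpy()
    if ((v < 0) | (v > 1))[covered].any():
        raise ValueError("VAF out of [0,1]")
    state = np.where(covered, np.where(v >= NONREF_VAF, NONREF, REF), ND)
    return pd.DataFrame(state, index=vaf.index, columns=vaf.columns)


def filter_sites_by_nd(states: pd.DataFrame) -> list:
    """Sites retained after excluding those ND in >20% of samples."""
    nd_frac = (states == ND).mean(axis=0)
    return list(states.columns[nd_frac <= ND_EXCLUDE_FRAC])


def _eligible_breeds(labels: pd.Series) -> list:
    counts = labels.value_counts()
    return sorted(counts.index[counts >= MIN_BREED_DOGS])


def discover_breed_unique(states: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Breed-unique sites: >=5 and >=40% non-reference dogs of one breed, and
    reference in every covered dog of every other (eligible) breed."""
    breeds = _eligible_breeds(labels)
    rows = []
    eligible_dogs = labels.index[labels.isin(breeds)]
    st = states.loc[eligible_dogs]
    lab = labels.loc[eligible_dogs]
    for b in breeds:
        mine = st[lab == b]
        others = st[lab != b]
        n_carrier = (mine == NONREF).sum(axis=0)
        frac = n_carrier / len(mine)
        clean = ~(others == NONREF).any(axis=0)  # ND dogs cannot veto
        ok = (n_carrier >= MIN_CARRIERS) & (frac >= MIN_CARRIER_FRAC) & clean
        for site in st.columns[ok]:
            rows.append((site, b, "unique", int(n_carrier[site]), float(frac[site])))
    return pd.DataFrame(rows, columns=["site_id", "breed", "mode", "n_nonref",
                                       "frac_nonref"])


def discover_breed_enriched(states: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Breed-enriched sites by pairwise one-sided Fisher tests on dog counts.

    Breed A wins a site when its non-reference odds beat every other breed at
    p <= 0.1 and no other breed does the same. ND dogs are excluded from each
    2x2 table.
    """
    breeds = _eligible_breeds(labels)
    if len(breeds) < 2:
        return pd.DataFrame(columns=["site_id", "breed", "mode", "n_nonref",
                                     "frac_nonref"])
    rows = []
    nonref = {b: (states[labels == b] == NONREF).sum(axis=0) for b in breeds}
    refc = {b: (states[labels == b] == REF).sum(axis=0) for b in breeds}
    for site in states.columns:
        winners = []
        for a in breeds:
            beat_all = True
            for b in breeds:
                if b == a:
                    continue
                if _fisher_greater(int(nonref[a][site]), int(refc[a][site]),
                                   int(nonref[b][site]), int(refc[b][site])) > ENRICH_P:
                    beat_all = False
                    break
            if beat_all:
                winners.append(a)
        if len(winners) == 1:
            a = winners[0]
            tot = nonref[a][site] + refc[a][site]
            rows.append((site, a, "enriched", int(nonref[a][site]),
                         float(nonref[a][site] / tot) if tot else np.nan))
    return pd.DataFrame(rows, columns=["site_id", "breed", "mode", "n_nonref",
                                       "frac_nonref"])


def discover_panel(vaf: pd.DataFrame, depth: pd.DataFrame,
                   labels: pd.Series) -> pd.DataFrame:
    """Full discovery: classify, ND-filter, union of unique + enriched sites.

    Sites found by both rules keep the ``unique`` annotation.
    """
    states = classify_matrix(vaf, depth)
    keep = filter_sites_by_nd(states)
    states = states[keep]
    uniq = discover_breed_unique(states, labels)
    enr = discover_breed_enriched(states, labels)
    panel = pd.concat([uniq, enr], ignore_index=True)
    return panel.drop_duplicates("site_id", keep="first").reset_index(drop=True)


def _admixed(dog: str, assigned: str, vaf: pd.DataFrame, covered: pd.DataFrame,
             panel: pd.DataFrame) -> bool:
    """True when the dog shows systematic non-reference VAF at sites specific
    to a breed other than the assigned one.

    Panel sites are reference in other breeds by construction, so a dog whose
    covered mean VAF at a second breed's sites reaches half the non-reference
    cutoff cannot be a pure member of the assigned breed (mixed ancestry).
    """
    site_breed = panel.set_index("site_id")["breed"]
    for other in site_breed.unique():
        if other == assigned:
            continue
        sites = [s for s in site_breed.index[site_breed == other] if s in vaf.columns]
        if not sites:
            continue
        cov = covered.loc[dog, sites]
        if cov.sum() == 0:
            continue
        if float(vaf.loc[dog, sites][cov].mean()) >= ADMIX_VAF:
            return True
    return False


@dataclass(frozen=True)
class BreedAssignment:
    dog_id: str
    provided: str | None
    outcome: str          # validated | corrected | predicted | unknown | not_evaluable
    assigned: str | None  # concrete breed for validated/corrected/predicted
    covered_fraction: float


def _valid_cut(cut_heights, Z, ref_breed):
    """Find the smallest cut height where every reference breed owns a cluster.

    A breed B owns a cluster when the cluster holding most of B's reference
    dogs contains >=80% of them and B's dogs are >=80% of the reference dogs
    in it (query dogs never enter the denominators). Returns (cluster
    labels, breed -> cluster id) or None if no cut is valid.
    """
    all_ref = np.concatenate(list(ref_breed.values()))
    for h in cut_heights:
        cl = fcluster(Z, t=h, criterion="distance")
        owner = {}
        ok = True
        for b, idxs in ref_breed.items():
            counts = pd.Series(cl[idxs]).value_counts()
            top_cluster = counts.index[0]
            in_top = int(counts.iloc[0])
            n_ref_in_cluster = int((cl[all_ref] == top_cluster).sum())
            if (in_top / len(idxs) < 0.8
                    or in_top / n_ref_in_cluster < 0.8
                    or top_cluster in owner.values()):
                ok = False
                break
            owner[b] = top_cluster
        if ok:
            return cl, owner
    return None


def assign_breeds(vaf: pd.DataFrame, depth: pd.DataFrame, panel: pd.DataFrame,
                  labels: pd.Series, seed: int = 0,
                  linkage_method: str = "average") -> tuple:
    """Validate/predict breeds by hierarchical clustering over panel sites.

    ``labels`` gives the provided breed per dog (NaN/None/"" for dogs whose
    breed is to be predicted); dogs with a label in an eligible breed act as
    the reference blocks. A dog must cover >80% of panel sites at depth >=10
    to be evaluable; uncovered sites receive a random uniform(0,1) VAF from a
    stream seeded by ``seed``. Returns (list of BreedAssignment, linkage
    matrix, dog order).
    """
    if panel.empty:
        raise ValueError("empty breed panel")
    sites = [s for s in panel["site_id"] if s in vaf.columns]
    if not sites:
        raise ValueError("no panel site present in the VAF matrix")
    v = vaf[sites].copy()
    d = depth[sites]
    covered = (d >= MIN_DEPTH)
    cov_frac = covered.mean(axis=1)
    eligible = cov_frac > ELIGIBLE_COVERED

    rng = child_rng(seed, "breed-assign")
    imput = rng.random(v.shape)
    arr = np.where(covered.to_numpy(), v.to_numpy(), imput)

    dogs = list(v.index)
    elig_dogs = [dg for dg in dogs if eligible.loc[dg]]
    idx_of = {dg: i for i, dg in enumerate(elig_dogs)}
    X = arr[[dogs.index(dg) for dg in elig_dogs]]

    provided = {dg: (labels.get(dg) if labels is not None else None) for dg in dogs}
    provided = {dg: (p if isinstance(p, str) and p else None)
                for dg, p in provided.items()}
    ref_breed = {}
    for dg, p in provided.items():
        if p is not None and dg in idx_of:
            ref_breed.setdefault(p, []).append(idx_of[dg])
    # reference blocks come only from breeds represented by >=2 labeled dogs
    ref_breed = {b: np.array(ix) for b, ix in ref_breed.items() if len(ix) >= 2}
    if not ref_breed:
        raise ValueError("no reference breed block with >=2 labeled dogs")

    Z = linkage(X, method=linkage_method, metric="euclidean")
    heights = np.unique(Z[:, 2])
    cut = _valid_cut(np.concatenate([heights, [heights[-1] + 1]]), Z, ref_breed)
    assignments = []
    cl, owner = (cut if cut is not None else (None, {}))
    cluster_breed = {c: b for b, c in owner.items()}
    # reference-block geometry for rescuing queries that merge just above the
    # cut: centroid and within-block radius of each owned breed block
    centroids, radii = {}, {}
    if cl is not None:
        for b, c in owner.items():
            block = [i for i in ref_breed[b] if cl[i] == c]
            cen = X[block].mean(axis=0)
            centroids[b] = cen
            radii[b] = float(np.linalg.norm(X[block] - cen, axis=1).max())
    for dg in dogs:
        p = provided[dg]
        if dg not in idx_of:
            assignments.append(BreedAssignment(dg, p, "not_evaluable", None,
                                               float(cov_frac.loc[dg])))
            continue
        if cl is None:
            assignments.append(BreedAssignment(dg, p, "unknown", None,
                                               float(cov_frac.loc[dg])))
            continue
        assigned = cluster_breed.get(cl[idx_of[dg]])
        if assigned is None and centroids:
            # a dog merging just above the cut still belongs to a block when it
            # lies within that block's own radius (10% slack) of the centroid
            dists = {b: float(np.linalg.norm(X[idx_of[dg]] - cen))
                     for b, cen in centroids.items()}
            near = min(dists, key=dists.get)
            if dists[near] <= 1.3 * radii[near]:
                assigned = near
        if assigned is not None and _admixed(dg, assigned, v, covered, panel):
            assigned = None  # systematic non-reference VAF at a second breed's sites
        if assigned is None:
            outcome, final = "unknown", None
        elif p is None:
            outcome, final = "predicted", assigned
        elif p == assigned:
            outcome, final = "validated", assigned
        else:
            outcome, final = "corrected", assigned
        assignments.append(BreedAssignment(dg, p, outcome, final,
                                           float(cov_frac.loc[dg])))
    return assignments, Z, elig_dogs
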