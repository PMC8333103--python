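"""96-channel mutation catalogs and mutational-signature analysis.

Signatures are extracted by repeated seeded NMF (multiplicative updates,
KL divergence): each of ``n_iterations`` runs fits every rank in the range
and votes for the rank minimizing a BIC-style penalized loss; the modal rank
across runs is selected and the best-loss run at that rank supplies the
final signatures and exposures. Signatures from different territories
(exome vs genome) are compared after reweighting each channel by the ratio
of target to source trinucleotide frequencies; similarity is cosine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from ._streams import child_seed
from .contexts import CHANNEL_LABELS, TRINUCLEOTIDES, channel_trinucleotide_index
from .stats import bh_adjust, fisher_exact

__all__ = [
    "SignatureSet",
    "build_catalog",
    "extract_signatures",
    "adjust_background",
    "cosine_similarity",
    "match_signatures",
    "attribute_mutations",
    "s1_screen",
]

S1_HIGH_MIN = 15
RECURRENT_MIN_TUMORS = 5


@dataclass
class SignatureSet:
    signatures: np.ndarray              # (k, 96), rows sum to 1
    exposures: np.ndarray               # (n_tumors, k), nonnegative
    tumor_ids: list
    selected_rank: int
    rank_votes: dict                    # rank -> number of runs voting for it
    run_losses: pd.DataFrame = field(default=None, repr=False)


def build_catalog(mutations: pd.DataFrame, tumor_ids: list | None = None) -> tuple:
    """Tumor x 96 channel-count catalog from a filtered mutation table.

    ``mutations`` needs sample_id (or case_id) and ``channel`` (from the
    filter stage; -1 marks unclassifiable records, which are excluded and
    counted). Returns (catalog DataFrame indexed by tumor with the 96
    channel labels as columns, number of unclassifiable mutations).
    """
    key = "sample_id" if "sample_id" in mutations.columns else "case_id"
    ok = mutations["channel"] >= 0
    n_unclassifiable = int((~ok).sum())
    m = mutations[ok]
    if tumor_ids is None:
        tumor_ids = sorted(mutations[key].unique())
    cat = np.zeros((len(tumor_ids), 96), dtype=np.int64)
    pos = {t: i for i, t in enumerate(tumor_ids)}
    for t, ch in zip(m[key], m["channel"]):
        if t in pos:
            cat[pos[t], int(ch)] += 1
    return pd.DataFrame(cat, index=tumor_ids, columns=list(CHANNEL_LABELS)), \
        n_unclassifiable


def _penalized_loss(kl: float, rank: int, n: int, m: int, total: float) -> float:
    # BIC-style: 2*KL plus parameter count times log(total mutation count)
    return 2.0 * kl + rank * (n + m) * np.log(max(total, 2.0))


def extract_signatures(catalog: pd.DataFrame, n_iterations: int = 40,
                       rank_range: tuple = (1, 5), seed: int = 0,
                       max_iter: int = 600) -> SignatureSet:
    """Repeated-NMF signature extraction with modal rank selection."""
    X = catalog.to_numpy(dtype=float)
    keep = X.sum(axis=1) > 0
    if keep.sum() < 2:
        raise ValueError("need >= 2 tumors with nonzero mutation counts")
    Xf = X[keep]
    n, m = Xf.shape
    total = Xf.sum()
    ranks = list(range(rank_range[0], rank_range[1] + 1))
    votes: dict = {}
    records = []
    fits = {}
    for run in range(n_iterations):
        best_rank, best_score = None, np.inf
        for r in ranks:
            if r > min(n, m):
                continue
            rs = child_seed(seed, f"nmf-run{run}-rank{r}")
            model = NMF(n_components=r, init="random", solver="mu",
                        beta_loss="kullback-leibler", max_iter=max_iter,
                        random_state=rs, tol=1e-6)
            with warnings.catch_warnings():
                # a fixed iteration budget per run is intentional
                warnings.simplefilter("ignore", ConvergenceWarning)
                W = model.fit_transform(Xf)
            kl = float(model.reconstruction_err_) ** 2 / 2.0  # err_ = sqrt(2*KL)
            score = _penalized_loss(kl, r, n, m, total)
            records.append((run, r, kl, score))
            fits[(run, r)] = (W, model.components_, kl)
            if score < best_score:
                best_rank, best_score = r, score
        votes[best_rank] = votes.get(best_rank, 0) + 1
    selected = max(votes, key=lambda r: (votes[r], -r))
    best_run = min((k for k in fits if k[1] == selected), key=lambda k: fits[k][2])
    W, H, _ = fits[best_run]
    scale = H.sum(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    signatures = H / scale
    exposures_kept = W * scale.T
    exposures = np.zeros((len(catalog), selected))
    exposures[keep] = exposures_kept
    return SignatureSet(
        signatures=signatures, exposures=exposures,
        tumor_ids=list(catalog.index), selected_rank=selected, rank_votes=votes,
        run_losses=pd.DataFrame(records, columns=["run", "rank", "kl", "score"]),
    )


def _trinuc_of_channels() -> np.ndarray:
    return np.array([channel_trinucleotide_index(i) for i in range(96)])


def adjust_background(signature: np.ndarray, source: np.ndarray,
                      target: np.ndarray) -> np.ndarray:
    """Reweight a 96-channel signature from one trinucleotide territory to another.

    ``source`` and ``target`` are 32-vector pyrimidine-collapsed trinucleotide
    frequencies (order :data:`~canpancan.contexts.TRINUCLEOTIDES`). Each
    channel is multiplied by target/source of its reference trinucleotide and
    the result renormalized to sum 1.
    """
    sig = np.asarray(signature, dtype=float)
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if sig.shape != (96,) or src.shape != (32,) or tgt.shape != (32,):
        raise ValueError("expected a 96-channel signature and 32-entry backgrounds")
    tri = _trinuc_of_channels()
    if np.any((src[tri] == 0) & (sig > 0)):
        bad = [TRINUCLEOTIDES[t] for t in np.unique(tri[(src[tri] == 0) & (sig > 0)])]
        raise ValueError(f"zero source frequency under nonzero channels: {bad}")
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(sig > 0, sig * tgt[tri] / src[tri], 0.0)
    s = w.sum()
    if s == 0:
        raise ValueError("signature vanished under adjustment")
    return w / s


def background_from_sequences(sequences) -> np.ndarray:
    """32-entry pyrimidine-collapsed trinucleotide frequencies of a territory.

    ``sequences`` is an iterable of uppercase DNA strings (e.g. extracted CDS
    or genome intervals); both strands are counted by collapsing
    purine-centered trinucleotides onto their reverse complement.
    """
    from .contexts import revcomp

    counts = np.zeros(32)
    index = {t: i for i, t in enumerate(TRINUCLEOTIDES)}
    for seq in sequences:
        s = seq.upper()
        for i in range(len(s) - 2):
            tri = s[i:i + 3]
            if tri in index:
                counts[index[tri]] += 1
            else:
                rc = revcomp(tri)
                if rc in index:
                    counts[index[rc]] += 1
    if counts.sum() == 0:
        raise ValueError("no counted trinucleotides")
    return counts / counts.sum()


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity of a zero vector is undefined")
    return float(a @ b / (na * nb))


def match_signatures(query: np.ndarray, reference: np.ndarray,
                     reference_names: list | None = None) -> pd.DataFrame:
    """Best cosine match of each query signature against a reference set."""
    q = np.atleast_2d(np.asarray(query, dtype=float))
    r = np.atleast_2d(np.asarray(reference, dtype=float))
    names = reference_names or [f"ref_{i}" for i in range(r.shape[0])]
    rows = []
    for i, sig in enumerate(q):
        sims = [cosine_similarity(sig, ref) for ref in r]
        j = int(np.argmax(sims))
        rows.append((i, names[j], sims[j]))
    return pd.DataFrame(rows, columns=["query", "best_match", "cosine"])


def attribute_mutations(mutations: pd.DataFrame, sigset: SignatureSet) -> pd.Series:
    """Maximum-posterior signature index per mutation.

    For a mutation of tumor t in channel c, the posterior over signatures is
    proportional to exposure[t, k] * signature[k, c]; each mutation takes the
    argmax. Unclassifiable mutations (channel < 0) get -1.
    """
    key = "sample_id" if "sample_id" in mutations.columns else "case_id"
    pos = {t: i for i, t in enumerate(sigset.tumor_ids)}
    out = np.full(len(mutations), -1, dtype=int)
    ch = mutations["channel"].to_numpy()
    tid = mutations[key].to_numpy()
    for i in range(len(mutations)):
        if ch[i] < 0 or tid[i] not in pos:
            continue
        t = pos[tid[i]]
        post = sigset.exposures[t] * sigset.signatures[:, int(ch[i])]
        if post.sum() == 0:
            continue
        out[i] = int(np.argmax(post))
    return pd.Series(out, index=mutations.index, name="signature")


def s1_screen(presence: pd.DataFrame, s1_counts: pd.Series,
              fdr: float = 0.1) -> pd.DataFrame:
    """Screen recurrent mutations for association with S1-high status.

    ``presence`` is a boolean tumor x mutation matrix of candidate
    mutations; only candidates present in >= 5 tumors are tested.
    ``s1_counts`` maps tumor to its S1-attributed mutation count; tumors
    with >= 15 are S1-high. Each candidate gets a two-sided Fisher exact
    test of presence in S1-high vs S1-low tumors, BH correction, and a
    ``hit`` flag at q <= ``fdr``. With no S1-high tumor the result is empty.
    """
    high = s1_counts >= S1_HIGH_MIN
    high = high.reindex(presence.index).fillna(False).astype(bool)
    if not high.any():
        return pd.DataFrame(columns=["mutation", "n_high", "n_low", "p", "q", "hit"])
    rows = []
    n_high, n_low = int(high.sum()), int((~high).sum())
    for mut in presence.columns:
        pres = presence[mut].astype(bool)
        if int(pres.sum()) < RECURRENT_MIN_TUMORS:
            continue
        a = int((pres & high).sum())
        c = int((pres & ~high).sum())
        p = fisher_exact([[a, n_high - a], [c, n_low - c]])
        rows.append((mut, a, c, p))
    df = pd.DataFrame(rows, columns=["mutation", "n_high", "n_low", "p"])
    df["q"] = bh_adjust(df["p"]) if len(df) else []
    df["hit"] = df["q"] <= fdr if len(df) else []
    return df
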