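"""Inter-CAP transition statistics with surrogate permutation testing.

Transition counts are pooled over a group's subjects (consecutive-frame
pairs within each scan only).  Persistence is the self-transition
fraction of each CAP's outgoing transitions; p_ij is normalized over
non-self transitions only.  The null is built from surrogate sequences
obtained by independently permuting each subject's label sequence, and
the same counting/normalization code path serves observed and surrogate
data.  Permutation p-values use the add-one convention
p = (1 + #{surrogate >= observed}) / (1 + n_surrogates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cap_stats import bh_fdr

__all__ = [
    "TransitionTable",
    "SurrogateEnsemble",
    "count_transitions",
    "persistence_probabilities",
    "transition_probabilities",
    "surrogate_null",
    "pair_significance",
    "directionality_test",
    "intergroup_difference_test",
    "analyze_group",
]

log = logging.getLogger(__name__)


def count_transitions(sequences, K: int) -> np.ndarray:
    """Pooled K x K counts of consecutive (i, j) label pairs.

    ``sequences`` is an iterable of 1-based label arrays, one per
    subject-scan; pairs never span scan boundaries.
    """
    counts = np.zeros((K, K), dtype=np.int64)
    for seq in sequences:
        seq = np.asarray(seq, dtype=int)
        if seq.size == 0:
            raise ValueError("empty label sequence")
        if seq.min() < 1 or seq.max() > K:
            raise ValueError(f"labels outside [1..{K}]")
        if seq.size < 2:
            continue
        idx = (seq[:-1] - 1) * K + (seq[1:] - 1)
        counts += np.bincount(idx, minlength=K * K).reshape(K, K)
    return counts


def persistence_probabilities(counts: np.ndarray) -> np.ndarray:
    """persistence_i = counts(i,i) / all outgoing transitions of i.

    Accepts stacked count arrays of shape (..., K, K) so the same code
    path serves observed data and whole surrogate ensembles.
    """
    counts = np.asarray(counts, dtype=float)
    row = counts.sum(axis=-1)
    diag = np.diagonal(counts, axis1=-2, axis2=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(row > 0, diag / np.where(row > 0, row, 1.0), np.nan)
    return out


def transition_probabilities(counts: np.ndarray) -> np.ndarray:
    """p_ij = counts(i,j) / non-self outgoing transitions of i (diag NaN).

    Accepts stacked count arrays of shape (..., K, K); rows with no
    non-self transitions come back as NaN.
    """
    counts = np.asarray(counts, dtype=float)
    K = counts.shape[-1]
    eye = np.eye(K, dtype=bool)
    offdiag = np.where(eye, 0.0, counts)
    row = offdiag.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(
            (row > 0)[..., None], offdiag / np.where(row > 0, row, 1.0)[..., None],
            np.nan,
        )
    p = np.where(eye, np.nan, p)
    return p


@dataclass
class SurrogateEnsemble:
    """Per-surrogate pooled transition summaries for one group."""

    trans: np.ndarray        # (S, K, K) p_ij per surrogate, diag NaN
    persistence: np.ndarray  # (S, K)
    n_surrogates: int
    seed: int


def _pooled_counts_batch(perms_by_subject: list[np.ndarray], K: int) -> np.ndarray:
    """Pooled (S, K, K) counts from per-subject (S, T) permuted sequences."""
    S = perms_by_subject[0].shape[0]
    counts = np.zeros((S, K * K), dtype=np.int64)
    offsets = np.arange(S)[:, None] * (K * K)
    for a in perms_by_subject:
        idx = (a[:, :-1] - 1) * K + (a[:, 1:] - 1)
        flat = (idx + offsets).ravel()
        counts += np.bincount(flat, minlength=S * K * K).reshape(S, K * K)
    return counts.reshape(S, K, K)


def surrogate_null(
    sequences,
    K: int,
    n_surrogates: int = 10_000,
    seed: int = 0,
    batch: int = 2_000,
) -> SurrogateEnsemble:
    """Build the label-permutation null ensemble for one group.

    Each surrogate independently permutes every subject's full label
    sequence (preserving its multiset and length), then recomputes the
    group-pooled persistence and p_ij through the observed-data code path.
    """
    if n_surrogates < 100:
        log.warning("n_surrogates=%d gives coarse p-value resolution",
                    n_surrogates)
    seqs = [np.asarray(s, dtype=int) for s in sequences]
    rng = np.random.default_rng(seed)
    trans = np.empty((n_surrogates, K, K))
    pers = np.empty((n_surrogates, K))
    done = 0
    while done < n_surrogates:
        S = min(batch, n_surrogates - done)
        perms = [rng.permuted(np.broadcast_to(s, (S, s.size)), axis=1)
                 for s in seqs]
        counts = _pooled_counts_batch(perms, K)
        trans[done:done + S] = transition_probabilities(counts)
        pers[done:done + S] = persistence_probabilities(counts)
        done += S
    return SurrogateEnsemble(trans=trans, persistence=pers,
                             n_surrogates=n_surrogates, seed=seed)


def _perm_p_greater(observed: float, surrogate: np.ndarray) -> float:
    """Add-one one-sided permutation p for 'surrogate >= observed'."""
    surrogate = surrogate[np.isfinite(surrogate)]
    n = surrogate.size
    return (1.0 + (surrogate >= observed).sum()) / (1.0 + n)


def pair_significance(
    observed: np.ndarray, ensemble: SurrogateEnsemble, q: float = 0.05
) -> pd.DataFrame:
    """Permutation significance of every ordered non-self CAP pair.

    One row per ordered pair (i, j), i != j, with the raw permutation p,
    the BH-FDR adjusted p over all K(K-1) pairs, and the q-level verdict.
    Pairs with an undefined observed probability are skipped.
    """
    K = observed.shape[0]
    rows = []
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            obs = observed[i, j]
            if not np.isfinite(obs):
                log.warning("skipping pair (%d,%d): observed p_ij undefined",
                            i + 1, j + 1)
                continue
            p = _perm_p_greater(obs, ensemble.trans[:, i, j])
            rows.append({"i": i + 1, "j": j + 1, "p_ij": obs, "p_raw": p})
    df = pd.DataFrame(rows)
    if df.empty:
        df["p_fdr"] = []
        df["significant"] = []
        return df
    reject, p_adj = bh_fdr(df.p_raw.to_numpy(), alpha=q)
    df["p_fdr"] = p_adj
    df["significant"] = reject
    return df


def directionality_test(
    observed: np.ndarray,
    ensemble: SurrogateEnsemble,
    significance: pd.DataFrame,
    q: float = 0.05,
) -> pd.DataFrame:
    """Test p_ij vs p_ji for pairs significant in at least one direction.

    Each eligible unordered pair is tested once, with the row oriented so
    the observed difference d = p_ij - p_ji is >= 0.  Because the
    preferred direction is read off the data, the permutation p-value is
    two-sided in |d| (a one-sided test in the observed direction would
    double the type-I rate); the orientation of the row annotates the
    preferred direction.
    """
    sig = significance[significance.significant]
    eligible = {tuple(sorted((r.i, r.j))) for r in sig.itertuples()}
    rows = []
    for i, j in sorted(eligible):
        d_obs = observed[i - 1, j - 1] - observed[j - 1, i - 1]
        if not np.isfinite(d_obs):
            continue
        if d_obs < 0:
            i, j = j, i
            d_obs = -d_obs
        d_surr = ensemble.trans[:, i - 1, j - 1] - ensemble.trans[:, j - 1, i - 1]
        p = _perm_p_greater(d_obs, np.abs(d_surr))
        rows.append({"i": i, "j": j, "d": d_obs, "p_raw": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["i", "j", "d", "p_raw", "p_fdr", "significant"])
    reject, p_adj = bh_fdr(df.p_raw.to_numpy(), alpha=q)
    df["p_fdr"] = p_adj
    df["significant"] = reject
    return df


def intergroup_difference_test(
    observed_a: np.ndarray,
    observed_b: np.ndarray,
    ensemble_a: SurrogateEnsemble,
    ensemble_b: SurrogateEnsemble,
    significance_a: pd.DataFrame,
    significance_b: pd.DataFrame,
    persistence_a: np.ndarray | None = None,
    persistence_b: np.ndarray | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Two-sided permutation test of group differences in p_ij (and
    persistence).

    Eligible pairs are those significant in at least one group.  The
    surrogate difference distribution pairs the s-th surrogate of each
    group.  Persistence differences are tested for every CAP.  FDR is
    applied over all tested hypotheses.
    """
    S = min(ensemble_a.n_surrogates, ensemble_b.n_surrogates)
    sig_pairs = set()
    for df in (significance_a, significance_b):
        sig_pairs |= {(r.i, r.j) for r in df[df.significant].itertuples()}
    rows = []
    for i, j in sorted(sig_pairs):
        d_obs = observed_a[i - 1, j - 1] - observed_b[i - 1, j - 1]
        if not np.isfinite(d_obs):
            continue
        d_surr = (ensemble_a.trans[:S, i - 1, j - 1]
                  - ensemble_b.trans[:S, i - 1, j - 1])
        p = _perm_p_greater(abs(d_obs), np.abs(d_surr))
        rows.append({"kind": "transition", "i": i, "j": j,
                     "delta": d_obs, "p_raw": p})
    if persistence_a is not None and persistence_b is not None:
        K = persistence_a.size
        for k in range(K):
            d_obs = persistence_a[k] - persistence_b[k]
            if not np.isfinite(d_obs):
                continue
            d_surr = (ensemble_a.persistence[:S, k]
                      - ensemble_b.persistence[:S, k])
            p = _perm_p_greater(abs(d_obs), np.abs(d_surr))
            rows.append({"kind": "persistence", "i": k + 1, "j": k + 1,
                         "delta": d_obs, "p_raw": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["kind", "i", "j", "delta", "p_raw", "p_fdr", "significant"])
    reject, p_adj = bh_fdr(df.p_raw.to_numpy(), alpha=q)
    df["p_fdr"] = p_adj
    df["significant"] = reject
    return df


@dataclass
class TransitionTable:
    """Full per-group transition analysis."""

    K: int
    counts: np.ndarray
    persistence: np.ndarray
    trans: np.ndarray
    significance: pd.DataFrame
    directionality: pd.DataFrame
    ensemble: SurrogateEnsemble | None = None


def analyze_group(
    sequences,
    K: int,
    n_surrogates: int = 10_000,
    seed: int = 0,
    q: float = 0.05,
) -> TransitionTable:
    """Observed + surrogate transition analysis for one group of scans."""
    seqs = [np.asarray(s, dtype=int) for s in sequences]
    counts = count_transitions(seqs, K)
    pers = persistence_probabilities(counts)
    trans = transition_probabilities(counts)
    ens = surrogate_null(seqs, K, n_surrogates=n_surrogates, seed=seed)
    sig = pair_significance(trans, ens, q=q)
    direction = directionality_test(trans, ens, sig, q=q)
    return TransitionTable(
        K=K, counts=counts, persistence=pers, trans=trans,
        significance=sig, directionality=direction, ensemble=ens,
    )
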