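"""Spatial and temporal CAP statistics.

Spatial: per-CAP one-sample T maps (Bonferroni p < 0.01), voxel-wise
two-way ANOVA (age x genotype) with interaction-dropping, post-hoc
genotype contrasts under BH-FDR plus an in-plane minimum-cluster-extent
rule.  Temporal: occurrence percentage and mean duration per subject-scan
with a mixed (repeated-measures) two-way ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TMap",
    "AnovaMaps",
    "bh_fdr",
    "one_sample_t_map",
    "subject_level_maps",
    "voxelwise_two_way_anova",
    "cluster_filter",
    "posthoc_cluster_correct",
    "occurrence_percentage",
    "mean_duration",
    "temporal_metrics_table",
    "mixed_anova_2x2",
    "rm_anova_temporal",
]

log = logging.getLogger(__name__)


def bh_fdr(pvals: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up. Returns (reject mask, adjusted p)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject, p_adj


# ---------------------------------------------------------------------------
# spatial statistics

@dataclass
class TMap:
    """Per-voxel one-sample T statistics for one CAP in one frame group."""

    t: np.ndarray
    p: np.ndarray
    df: int
    sig_pos: np.ndarray   # Bonferroni-significant activations
    sig_neg: np.ndarray   # Bonferroni-significant deactivations
    alpha: float = 0.01

    @property
    def significant(self) -> np.ndarray:
        return self.sig_pos | self.sig_neg


def one_sample_t_map(cap_frames: np.ndarray, alpha: float = 0.01) -> TMap:
    """Two-tailed one-sample T-test of each voxel's mean against zero.

    Bonferroni correction across the mask voxels of this map.  Voxels with
    zero variance across frames have undefined T and are marked
    non-significant (logged).
    """
    X = np.atleast_2d(np.asarray(cap_frames, dtype=float))
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 frames for a one-sample T map")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("%d zero-variance voxels in one-sample T map marked "
                    "non-significant", degenerate.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.nan, mu / (sd / np.sqrt(n)))
    df = n - 1
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, p)
    thresh = alpha / m  # Bonferroni over mask voxels
    sig = p < thresh
    return TMap(t=t, p=p, df=df, sig_pos=sig & (t > 0), sig_neg=sig & (t < 0),
                alpha=alpha)


def subject_level_maps(
    labels: np.ndarray,
    frames: np.ndarray,
    provenance: pd.DataFrame,
    manifest: pd.DataFrame,
    K: int,
) -> pd.DataFrame:
    """Subject-level spatial observation per CAP: the mean unthresholded
    z-map over the subject's frames assigned to that CAP.

    Returns a tidy frame with one row per (subject, cap) carrying the map
    in the ``"map"`` column; subject-cap combinations with no frames are
    omitted (logged).
    """
    rows = []
    meta = manifest.set_index("subject_id")
    for sid, idx in provenance.groupby("subject_id").indices.items():
        sub_labels = labels[idx]
        sub_frames = frames[idx]
        for k in range(1, K + 1):
            sel = sub_labels == k
            if not sel.any():
                log.warning("subject %s has no frames in CAP %d", sid, k)
                continue
            rows.append({
                "subject_id": sid,
                "genotype": meta.loc[sid, "genotype"],
                "age": meta.loc[sid, "age"],
                "cap": k,
                "map": sub_frames[sel].mean(axis=0),
            })
    return pd.DataFrame(rows)


def _sse(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of OLS fits of every column of Y on X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ beta
    return (R**2).sum(axis=0)


@dataclass
class AnovaMaps:
    """Voxel-wise two-way ANOVA results for one CAP."""

    p_interaction: np.ndarray
    p_age: np.ndarray
    p_genotype: np.ndarray
    interaction_retained: np.ndarray       # p_interaction <= alpha
    alpha: float = 0.05
    # filled by posthoc_cluster_correct, keyed by age
    posthoc_t: dict[str, np.ndarray] = field(default_factory=dict)
    posthoc_p_fdr: dict[str, np.ndarray] = field(default_factory=dict)
    cluster_mask: dict[str, np.ndarray] = field(default_factory=dict)


def voxelwise_two_way_anova(
    subject_maps: pd.DataFrame, cap: int, alpha: float = 0.05
) -> AnovaMaps:
    """Fit age x genotype models at every voxel for one CAP.

    If the interaction is not significant (p > alpha) it is dropped and
    main effects come from the additive model (Type II tests); otherwise
    the voxel is marked interaction-significant and main-effect p-values
    are reported from the full model's Type II tests as well.
    """
    df = subject_maps[subject_maps.cap == cap]
    if df.empty:
        raise ValueError(f"no subject maps for CAP {cap}")
    Y = np.vstack(df["map"].to_numpy())  # (n_obs, m)
    n, m = Y.shape
    a = (df.age == df.age.unique()[0]).to_numpy().astype(float)
    g = (df.genotype == df.genotype.unique()[0]).to_numpy().astype(float)
    one = np.ones(n)
    X_full = np.column_stack([one, a, g, a * g])
    X_add = np.column_stack([one, a, g])
    X_age = np.column_stack([one, a])
    X_gen = np.column_stack([one, g])

    sse_full = _sse(X_full, Y)
    sse_add = _sse(X_add, Y)
    sse_age = _sse(X_age, Y)   # genotype omitted
    sse_gen = _sse(X_gen, Y)   # age omitted

    def f_test(sse_r, sse_f, df_num, df_den):
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((sse_r - sse_f) / df_num) / (sse_f / df_den)
        p = stats.f.sf(F, df_num, df_den)  # F = inf (exact separation) -> p = 0
        return np.where(np.isnan(F), 1.0, p)  # 0/0: no variance, no evidence

    p_int = f_test(sse_add, sse_full, 1, n - 4)
    # Type II main effects from the additive model
    p_age = f_test(sse_gen, sse_add, 1, n - 3)
    p_gen = f_test(sse_age, sse_add, 1, n - 3)

    return AnovaMaps(
        p_interaction=p_int,
        p_age=p_age,
        p_genotype=p_gen,
        interaction_retained=p_int <= alpha,
        alpha=alpha,
    )


def cluster_filter(
    sig_mask: np.ndarray,
    coords: np.ndarray,
    shape: tuple[int, int, int],
    min_cluster: int = 10,
    slice_axis: int = 2,
) -> np.ndarray:
    """Keep only voxels in within-slice 8-connected blobs of >= min_cluster.

    ``sig_mask`` is a boolean vector over mask voxels; connectivity is
    evaluated per plane orthogonal to ``slice_axis`` (in-plane rule).
    """
    vol = np.zeros(tuple(shape), dtype=bool)
    x, y, z = np.asarray(coords).T
    vol[x, y, z] = np.asarray(sig_mask, dtype=bool)
    keep_vol = np.zeros_like(vol)
    structure = np.ones((3, 3), dtype=bool)  # 8-connectivity in plane
    for s in range(vol.shape[slice_axis]):
        plane = np.take(vol, s, axis=slice_axis)
        lab, n_lab = ndimage.label(plane, structure=structure)
        if not n_lab:
            continue
        sizes = np.bincount(lab.ravel())
        good = np.isin(lab, np.flatnonzero(sizes >= min_cluster)[1:]) & plane
        idx = [slice(None)] * 3
        idx[slice_axis] = s
        keep_vol[tuple(idx)] = good
    return keep_vol[x, y, z]


def posthoc_cluster_correct(
    anova: AnovaMaps,
    subject_maps: pd.DataFrame,
    cap: int,
    group_sig: np.ndarray,
    coords: np.ndarray,
    shape: tuple[int, int, int],
    min_cluster: int = 10,
    q: float = 0.05,
) -> AnovaMaps:
    """Genotype contrasts at each age on interaction-significant voxels.

    Voxels tested: interaction-significant AND one-sample-significant in
    at least one group (``group_sig``).  Per age, WT-vs-TG two-sample
    T-tests, BH-FDR across tested voxels, then the in-plane
    ``min_cluster`` extent rule.
    """
    eligible = anova.interaction_retained & np.asarray(group_sig, dtype=bool)
    df = subject_maps[subject_maps.cap == cap]
    m = len(eligible)
    for age in sorted(df.age.unique()):
        t_full = np.full(m, np.nan)
        p_fdr_full = np.full(m, np.nan)
        mask_full = np.zeros(m, dtype=bool)
        if eligible.any():
            sub = df[df.age == age]
            wt = np.vstack(sub[sub.genotype == "WT"]["map"].to_numpy())
            tg = np.vstack(sub[sub.genotype == "TG"]["map"].to_numpy())
            tt = stats.ttest_ind(wt[:, eligible], tg[:, eligible], axis=0)
            reject, p_adj = bh_fdr(tt.pvalue, alpha=q)
            t_full[eligible] = tt.statistic
            p_fdr_full[eligible] = p_adj
            fdr_mask = np.zeros(m, dtype=bool)
            fdr_mask[np.flatnonzero(eligible)[reject]] = True
            mask_full = cluster_filter(fdr_mask, coords, shape, min_cluster)
        anova.posthoc_t[age] = t_full
        anova.posthoc_p_fdr[age] = p_fdr_full
        anova.cluster_mask[age] = mask_full
    return anova


# ---------------------------------------------------------------------------
# temporal metrics

def occurrence_percentage(labels: np.ndarray, K: int) -> np.ndarray:
    """Percentage of the scan's frames spent in each CAP; sums to 100."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    counts = np.bincount(labels - 1, minlength=K)[:K]
    return 100.0 * counts / labels.size


def mean_duration(labels: np.ndarray, K: int) -> np.ndarray:
    """Mean maximal-run length per CAP, in frames.

    Runs touching the scan boundary count as ordinary runs; a CAP that
    never occurs gets NaN.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    change = np.flatnonzero(np.diff(labels) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [labels.size - 1]])
    run_labels = labels[starts]
    run_lens = ends - starts + 1
    out = np.full(K, np.nan)
    for k in range(1, K + 1):
        sel = run_labels == k
        if sel.any():
            out[k - 1] = run_lens[sel].mean()
    return out


def temporal_metrics_table(
    sequences: dict[str, np.ndarray], manifest: pd.DataFrame, K: int
) -> pd.DataFrame:
    """Tidy per subject x CAP metrics (occurrence_pct, duration)."""
    meta = manifest.set_index("subject_id")
    rows = []
    for sid, seq in sequences.items():
        occ = occurrence_percentage(seq, K)
        dur = mean_duration(seq, K)
        for k in range(K):
            rows.append({
                "subject_id": sid,
                "genotype": meta.loc[sid, "genotype"],
                "age": meta.loc[sid, "age"],
                "cap": k + 1,
                "occurrence_pct": occ[k],
                "duration": dur[k],
            })
    return pd.DataFrame(rows)


def mixed_anova_2x2(
    df: pd.DataFrame,
    dv: str,
    subject: str = "animal_id",
    within: str = "age",
    between: str = "genotype",
    alpha: float = 0.05,
) -> dict:
    """Two-way mixed (repeated-measures) ANOVA for a 2 x 2 design.

    With two within-subject levels the classical mixed ANOVA reduces
    exactly to t-tests: the within effect is a paired t on the level
    difference, the interaction a two-sample t on that difference between
    groups, and the between effect a two-sample t on subject means
    (F = t^2 with matching dfs).  Subjects missing a level are excluded.
    """
    wide = df.pivot_table(index=[subject, between], columns=within, values=dv)
    n_before = wide.shape[0]
    wide = wide.dropna()
    if wide.shape[0] < n_before:
        log.warning("excluded %d subjects missing a %s level",
                    n_before - wide.shape[0], within)
    levels = sorted(wide.columns)
    if len(levels) != 2:
        raise ValueError("exactly two within-subject levels required")
    groups = wide.index.get_level_values(between)
    glabels = sorted(set(groups))
    if len(glabels) != 2:
        raise ValueError("exactly two between-subject groups required")
    diff = (wide[levels[1]] - wide[levels[0]]).to_numpy()
    mean_ = wide.mean(axis=1).to_numpy()
    in_g0 = np.asarray(groups == glabels[0])

    def _safe(t, p):
        # degenerate (zero-variance) data carries no evidence of an effect
        return (0.0, 1.0) if not np.isfinite(p) else (float(t), float(p))

    # within (age) effect: grand mean of the level difference against the
    # interaction-removed (group-centered pooled) within error
    n1, n2 = in_g0.sum(), (~in_g0).sum()
    d1, d2 = diff[in_g0], diff[~in_g0]
    ss_err = ((d1 - d1.mean()) ** 2).sum() + ((d2 - d2.mean()) ** 2).sum()
    df_err = n1 + n2 - 2
    sp = np.sqrt(ss_err / df_err) if df_err > 0 else 0.0
    if sp > 0:
        t_w = diff.mean() / (sp / np.sqrt(n1 + n2))
        t_within, p_within = _safe(t_w, 2 * stats.t.sf(abs(t_w), df_err))
    else:
        t_within, p_within = 0.0, 1.0
    t_int, p_int = _safe(*stats.ttest_ind(d1, d2))
    t_between, p_between = _safe(*stats.ttest_ind(mean_[in_g0], mean_[~in_g0]))

    interaction_retained = bool(p_int <= alpha)
    result = {
        within: {"F": t_within**2, "p": p_within},
        between: {"F": t_between**2, "p": p_between},
        "interaction": {"F": t_int**2, "p": p_int,
                        "retained": interaction_retained},
    }

    # post-hoc contrasts: per-age genotype and per-genotype age comparisons
    posthocs = []
    for lev in levels:
        a = wide.loc[in_g0, lev].to_numpy()
        b = wide.loc[~in_g0, lev].to_numpy()
        t, p = _safe(*stats.ttest_ind(a, b))
        posthocs.append({"contrast": f"{glabels[0]}-vs-{glabels[1]}@{lev}",
                         "t": t, "p": p})
    for gi, glab in enumerate(glabels):
        sel = in_g0 if gi == 0 else ~in_g0
        t, p = _safe(*stats.ttest_1samp(diff[sel], 0.0))
        posthocs.append({"contrast": f"{levels[0]}-vs-{levels[1]}@{glab}",
                         "t": t, "p": p})
    result["posthocs"] = posthocs
    return result


def rm_anova_temporal(
    metrics: pd.DataFrame,
    subject: str = "animal_id",
    alpha: float = 0.05,
    q: float = 0.05,
) -> pd.DataFrame:
    """Mixed two-way ANOVA per CAP and metric with FDR-corrected post-hocs.

    Post-hoc p-values are BH-adjusted within each metric across all CAPs
    and contrasts.  Interaction is dropped (flagged) when p > alpha.
    """
    rows = []
    for metric in ("occurrence_pct", "duration"):
        for cap, df_cap in metrics.groupby("cap"):
            res = mixed_anova_2x2(df_cap, dv=metric, subject=subject, alpha=alpha)
            base = {"metric": metric, "cap": cap}
            rows.append({**base, "effect": "age", **res["age"]})
            rows.append({**base, "effect": "genotype", **res["genotype"]})
            rows.append({**base, "effect": "interaction", **res["interaction"]})
            for ph in res["posthocs"]:
                rows.append({**base, "effect": f"posthoc:{ph['contrast']}",
                             "F": ph["t"] ** 2, "p": ph["p"]})
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for metric in ("occurrence_pct", "duration"):
        sel = out.effect.str.startswith("posthoc:") & (out.metric == metric)
        if sel.any():
            _, p_adj = bh_fdr(out.loc[sel, "p"].to_numpy(), alpha=q)
            out.loc[sel, "p_fdr"] = p_adj
    return out
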