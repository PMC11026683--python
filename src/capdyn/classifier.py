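"""Leakage-controlled classification of genotype-age groups from CAP features.

Every iteration re-derives the CAPs from the training subjects only
(reference centroids, significant-voxel unions), assigns each subject's
frames to those reference CAPs, builds spatial or temporal features, fits
a regularized multinomial logistic regression and scores the held-out
subjects.  A chance baseline shuffles the training labels within the same
split.  Splits are performed at the animal level so an animal scanned at
both ages never straddles train and test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .cap_stats import mean_duration, occurrence_percentage, one_sample_t_map
from .extraction import CapMapSet, cluster_frames, compute_cap_maps, correlation_distance

__all__ = [
    "ClassificationResult",
    "split_stratified",
    "derive_training_caps",
    "assign_frames_to_reference",
    "build_features",
    "train_eval",
]

log = logging.getLogger(__name__)


def split_stratified(
    units: pd.DataFrame,
    train_frac: float = 0.8,
    seed: int = 0,
    class_col: str = "class",
    unit_col: str = "animal_id",
) -> tuple[list[str], list[str]]:
    """Stratified unit-level split: round(train_frac * n) per class in
    training, with at least one unit on each side.

    ``units`` has one row per split unit (animal) with its class label.
    """
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls, grp in units.groupby(class_col, sort=True):
        ids = sorted(grp[unit_col].astype(str))
        n = len(ids)
        if n < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 units")
        n_train = int(round(train_frac * n))
        n_train = min(max(n_train, 1), n - 1)  # keep both sides nonempty
        perm = rng.permutation(n)
        train.extend(ids[k] for k in perm[:n_train])
        test.extend(ids[k] for k in perm[n_train:])
    return sorted(train), sorted(test)


@dataclass
class TrainingReference:
    """Everything derived from the training subjects only."""

    centroids: np.ndarray                       # (K, m) reference CAP centroids
    cap_maps: CapMapSet
    group_sig: dict[str, np.ndarray]            # cell -> (K, m) bool
    sig_union: np.ndarray                       # (K, m) union over cells
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None


def derive_training_caps(
    thresholded: dict[str, np.ndarray],
    unthresholded: dict[str, np.ndarray],
    manifest: pd.DataFrame,
    train_ids: list[str],
    K: int,
    seed: int = 0,
    n_restarts: int = 3,
    alpha: float = 0.01,
) -> TrainingReference:
    """Re-run CAP extraction on the training frames only.

    Returns reference centroids, training group-level CAP maps and the
    per-CAP one-sample-significance masks (Bonferroni ``alpha``) used for
    spatial feature selection.
    """
    train_subjects = [s for s in manifest.subject_id if s in set(train_ids)]
    if not train_subjects:
        raise ValueError("no training subjects found in manifest")
    frames = np.vstack([thresholded[s] for s in train_subjects])
    raw = np.vstack([unthresholded[s] for s in train_subjects])
    prov = pd.DataFrame({
        "subject_id": np.repeat(
            train_subjects, [thresholded[s].shape[0] for s in train_subjects]
        ),
    })
    part = cluster_frames(frames, K, seed=seed, n_restarts=n_restarts,
                          provenance=prov)
    maps = compute_cap_maps(part, raw, manifest)

    meta = manifest.set_index("subject_id")
    cells = np.array([
        f"{meta.loc[s, 'genotype']}-{meta.loc[s, 'age']}"
        for s in prov.subject_id
    ])
    group_sig: dict[str, np.ndarray] = {}
    for cell in sorted(set(cells)):
        sig = np.zeros((K, raw.shape[1]), dtype=bool)
        in_cell = cells == cell
        for k in range(K):
            sel = in_cell & (part.labels == k + 1)
            if sel.sum() >= 3:
                sig[k] = one_sample_t_map(raw[sel], alpha=alpha).significant
        group_sig[cell] = sig
    sig_union = np.zeros((K, raw.shape[1]), dtype=bool)
    for sig in group_sig.values():
        sig_union |= sig
    return TrainingReference(
        centroids=part.centroids, cap_maps=maps,
        group_sig=group_sig, sig_union=sig_union,
    )


def assign_frames_to_reference(
    frames: np.ndarray, centroids: np.ndarray
) -> np.ndarray:
    """Assign each (thresholded) frame to the nearest reference centroid.

    Correlation distance; ties break to the lowest CAP index.  Degenerate
    (zero-variance) frames get label 0 ("unclassified") and are excluded
    from downstream metrics.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    if centroids.shape[1] != frames.shape[1]:
        raise ValueError("centroid dimension does not match frame length")
    labels = np.zeros(frames.shape[0], dtype=int)
    ok = frames.var(axis=1) > 0
    if not ok.all():
        log.warning("%d degenerate frames left unclassified", (~ok).sum())
    if ok.any():
        dist = correlation_distance(frames[ok], centroids)
        labels[ok] = np.argmin(dist, axis=1) + 1  # argmin takes lowest index on ties
    return labels


def build_features(
    subject_ids: list[str],
    thresholded: dict[str, np.ndarray],
    unthresholded: dict[str, np.ndarray],
    reference: TrainingReference,
    mode: str = "spatial",
) -> np.ndarray:
    """Per-subject feature vectors against a training-derived reference.

    spatial: concatenation over CAPs of the subject's mean unthresholded
    z-values on the union of voxels significant in >= 1 training group.
    temporal: occurrence percentage and mean duration per CAP.
    """
    K = reference.centroids.shape[0]
    feats = []
    for sid in subject_ids:
        labels = assign_frames_to_reference(thresholded[sid], reference.centroids)
        raw = unthresholded[sid]
        if mode == "spatial":
            vec = []
            for k in range(K):
                sel = labels == k + 1
                voxels = reference.sig_union[k]
                if sel.any():
                    vec.append(raw[sel].mean(axis=0)[voxels])
                else:
                    vec.append(np.zeros(voxels.sum()))
            feats.append(np.concatenate(vec))
        elif mode == "temporal":
            classified = labels[labels > 0]
            occ = occurrence_percentage(classified, K)
            dur = mean_duration(classified, K)
            feats.append(np.concatenate([occ, np.nan_to_num(dur)]))
        else:
            raise ValueError(f"unknown feature mode {mode!r}")
    return np.vstack(feats)


@dataclass
class ClassificationResult:
    classes: list[str]
    accuracies: np.ndarray          # per-iteration test accuracy
    chance_accuracies: np.ndarray   # same splits, shuffled training labels
    confusion: np.ndarray           # pooled, row-normalized proportions
    confusion_counts: np.ndarray
    wilcoxon_p: float
    n_iter: int
    flagged_iterations: list[int] = field(default_factory=list)


def _fit_predict(Xtr, ytr, Xte, mu, sd, C: float = 1.0):
    Z = (Xtr - mu) / sd
    clf = LogisticRegression(C=C, max_iter=2000)  # default ridge penalty
    clf.fit(Z, ytr)
    return clf.predict((Xte - mu) / sd), clf.n_iter_


def train_eval(
    manifest: pd.DataFrame,
    thresholded: dict[str, np.ndarray],
    unthresholded: dict[str, np.ndarray],
    K: int,
    mode: str = "spatial",
    classes: int = 4,
    age: str | None = None,
    n_iter: int = 50,
    seed: int = 0,
    C: float = 1.0,
    kmeans_restarts: int = 3,
) -> ClassificationResult:
    """Iterated stratified split -> training-only CAP derivation ->
    feature construction -> regularized MLR -> test accuracy, with a
    shuffled-label chance baseline on the same splits.

    ``classes=4`` predicts genotype-age cells over the full cohort;
    ``classes=2`` predicts genotype within one ``age``.
    """
    df = manifest.copy()
    if "animal_id" not in df.columns:
        df["animal_id"] = df["subject_id"]
    if classes == 4:
        df["class"] = df.genotype + "-" + df.age
        unit_class = "genotype"  # animals span ages; stratify on genotype
    elif classes == 2:
        if age is None:
            raise ValueError("2-class mode requires an age")
        df = df[df.age == age].reset_index(drop=True)
        df["class"] = df.genotype
        unit_class = "genotype"
    else:
        raise ValueError("classes must be 2 or 4")
    class_names = sorted(df["class"].unique())
    cls_index = {c: i for i, c in enumerate(class_names)}
    units = df[["animal_id", unit_class]].drop_duplicates().rename(
        columns={unit_class: "class"})

    rng_root = np.random.SeedSequence(seed)
    accs = np.empty(n_iter)
    chance = np.empty(n_iter)
    counts = np.zeros((len(class_names), len(class_names)), dtype=int)
    flagged: list[int] = []
    for it, child in enumerate(rng_root.spawn(n_iter)):
        it_seed = int(child.generate_state(1)[0] % (2**31))
        train_units, test_units = split_stratified(units, seed=it_seed)
        train_ids = df[df.animal_id.isin(train_units)].subject_id.tolist()
        test_ids = df[df.animal_id.isin(test_units)].subject_id.tolist()

        ref = derive_training_caps(
            thresholded, unthresholded, df, train_ids, K,
            seed=it_seed, n_restarts=kmeans_restarts,
        )
        Xtr = build_features(train_ids, thresholded, unthresholded, ref, mode)
        Xte = build_features(test_ids, thresholded, unthresholded, ref, mode)
        ytr = df.set_index("subject_id").loc[train_ids, "class"].to_numpy()
        yte = df.set_index("subject_id").loc[test_ids, "class"].to_numpy()

        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        pred, niter_fit = _fit_predict(Xtr, ytr, Xte, mu, sd, C=C)
        if np.any(niter_fit >= 2000):
            flagged.append(it)
            log.warning("iteration %d: MLR did not converge", it)
        accs[it] = float(np.mean(pred == yte))
        for true, p in zip(yte, pred):
            counts[cls_index[true], cls_index[p]] += 1

        # chance baseline: permute the class labels over the whole cohort
        # within the same split, so under a true null the data run and the
        # chance run are exchangeable (train on shuffled training labels,
        # score against the shuffled test labels)
        shuffler = np.random.default_rng(it_seed + 1)
        y_all = np.concatenate([ytr, yte])
        y_all_shuf = shuffler.permutation(y_all)
        ytr_shuf, yte_shuf = y_all_shuf[:len(ytr)], y_all_shuf[len(ytr):]
        pred0, _ = _fit_predict(Xtr, ytr_shuf, Xte, mu, sd, C=C)
        chance[it] = float(np.mean(pred0 == yte_shuf))

    diffs = accs - chance
    if np.allclose(diffs, 0):
        wilcoxon_p = 1.0
    else:
        wilcoxon_p = float(stats.wilcoxon(accs, chance).pvalue)
    row_sums = counts.sum(axis=1, keepdims=True).astype(float)
    row_sums[row_sums == 0] = 1.0
    return ClassificationResult(
        classes=class_names,
        accuracies=accs,
        chance_accuracies=chance,
        confusion=counts / row_sums,
        confusion_counts=counts,
        wilcoxon_p=wilcoxon_p,
        n_iter=n_iter,
        flagged_iterations=flagged,
    )
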