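"""End-to-end run orchestration: condition -> extract -> stats -> classify
-> transitions -> report, driven by a single YAML config with recorded
seeds and a config hash embedded in every CSV artifact."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cap_stats, classifier, extraction, transitions
from .conditioning import ConditioningConfig, condition, zscore_voxels
from .core import VoxelTimeSeries, load_mask, load_scan, map_to_volume, read_manifest

__all__ = ["RunConfig", "run_pipeline", "make_report"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    manifest: str = ""
    mask: str = ""
    out_dir: str = "capdyn_run"
    conditioning: str = "zscore"          # "full" | "zscore" | "none"
    k_range: tuple[int, int] = (2, 9)
    top_pct: float = 10.0
    bottom_pct: float = 5.0
    gain_threshold: float = 0.005
    elbow_mode: str = "all_subsequent"
    n_restarts: int = 5
    seed: int = 0
    n_surrogates: int = 1000
    classify_iters: int = 10
    classify_modes: tuple[str, ...] = ("spatial", "temporal")
    min_cluster: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        return cfg

    def digest(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # run location must not change analysis identity
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# capdyn config={cfg.digest()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def _load_cohort(cfg: RunConfig):
    manifest = read_manifest(cfg.manifest)
    mask_vol, coords = load_mask(cfg.mask)
    scans = {}
    for row in manifest.itertuples():
        scans[row.subject_id] = load_scan(
            row.path, coords, mask_vol.shape,
            subject_id=row.subject_id, genotype=row.genotype, age=row.age,
        )
    return manifest, mask_vol, coords, scans


def _condition_all(scans: dict[str, VoxelTimeSeries], mode: str):
    out = {}
    for sid, scan in scans.items():
        if mode == "full":
            conditioned, _ = condition(scan)
        elif mode == "zscore":
            conditioned, _ = zscore_voxels(scan)
        elif mode == "none":
            conditioned = scan
        else:
            raise ValueError(f"unknown conditioning mode {mode!r}")
        out[sid] = conditioned
    return out


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Reruns with the same config produce identical CSV outputs.
    """
    for p in (cfg.manifest, cfg.mask):
        if not Path(p).exists():
            raise FileNotFoundError(f"required input missing: {p}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        filename=out / "run.log", level=logging.INFO, force=True,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    log.info("run start: config %s seed %d", cfg.digest(), cfg.seed)

    manifest, mask_vol, coords, scans = _load_cohort(cfg)
    conditioned = _condition_all(scans, cfg.conditioning)

    # --- extraction ------------------------------------------------------
    subject_ids = manifest.subject_id.tolist()
    raw_frames = {s: conditioned[s].data.T for s in subject_ids}  # (T, m)
    thresh_frames = {
        s: extraction.threshold_frames(raw_frames[s], cfg.top_pct, cfg.bottom_pct)
        for s in subject_ids
    }
    all_raw = np.vstack([raw_frames[s] for s in subject_ids])
    all_thresh = np.vstack([thresh_frames[s] for s in subject_ids])
    prov = pd.DataFrame({
        "subject_id": np.repeat(
            subject_ids, [raw_frames[s].shape[0] for s in subject_ids]),
        "frame": np.concatenate(
            [np.arange(raw_frames[s].shape[0]) for s in subject_ids]),
    })
    curve = extraction.variance_curve(
        all_thresh, cfg.k_range, seed=cfg.seed, n_restarts=cfg.n_restarts,
        gain_threshold=cfg.gain_threshold, elbow_mode=cfg.elbow_mode,
        provenance=prov,
    )
    K = curve.elbow_K
    log.info("elbow selected K=%d", K)
    part = curve.partitions[K]
    maps = extraction.compute_cap_maps(part, all_raw, manifest)
    maps = extraction.pair_and_order_caps(maps)

    _write_csv(curve.to_frame(), out / "variance_curve.csv", cfg)
    labels_df = prov.assign(cap=part.labels)
    _write_csv(labels_df, out / "frame_labels.csv", cfg)
    _write_csv(
        pd.DataFrame({
            "cap": np.arange(1, K + 1),
            "occurrence_pct": maps.occurrence_pct,
            "display_rank": [int(np.flatnonzero(maps.order == k + 1)[0]) + 1
                             for k in range(K)],
        }),
        out / "cap_summary.csv", cfg,
    )
    try:
        import nibabel as nib
        for k in range(K):
            vol = map_to_volume(maps.cohort_maps[k], coords, mask_vol.shape)
            nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)),
                     str(out / f"cap{k + 1:02d}_mean.nii.gz"))
    except Exception as exc:  # map export is best-effort
        log.warning("could not write CAP NIfTI maps: %s", exc)

    # --- spatial + temporal statistics -----------------------------------
    t_rows = []
    tmaps = {}
    for k in range(K):
        tmap = cap_stats.one_sample_t_map(all_raw[part.labels == k + 1])
        tmaps[k + 1] = tmap
        t_rows.append({"cap": k + 1, "df": tmap.df,
                       "n_sig_pos": int(tmap.sig_pos.sum()),
                       "n_sig_neg": int(tmap.sig_neg.sum())})
    _write_csv(pd.DataFrame(t_rows), out / "tmap_summary.csv", cfg)

    smaps = cap_stats.subject_level_maps(part.labels, all_raw, prov, manifest, K)
    anova_rows = []
    two_cells = manifest.genotype.nunique() == 2 and manifest.age.nunique() == 2
    if two_cells:
        group_sig_union = {
            k + 1: np.zeros(all_raw.shape[1], dtype=bool) for k in range(K)}
        meta_cells = prov.merge(manifest, on="subject_id")
        cells = meta_cells.genotype + "-" + meta_cells.age
        for cell in cells.unique():
            for k in range(K):
                sel = (cells == cell).to_numpy() & (part.labels == k + 1)
                if sel.sum() >= 3:
                    group_sig_union[k + 1] |= cap_stats.one_sample_t_map(
                        all_raw[sel]).significant
        for k in range(1, K + 1):
            anova = cap_stats.voxelwise_two_way_anova(smaps, k)
            anova = cap_stats.posthoc_cluster_correct(
                anova, smaps, k, group_sig_union[k], coords, mask_vol.shape,
                min_cluster=cfg.min_cluster)
            for age_label, mask in anova.cluster_mask.items():
                anova_rows.append({
                    "cap": k, "age": age_label,
                    "n_interaction_voxels": int(anova.interaction_retained.sum()),
                    "n_surviving_voxels": int(mask.sum()),
                })
        _write_csv(pd.DataFrame(anova_rows), out / "anova_summary.csv", cfg)

    sequences = {
        sid: part.labels[(prov.subject_id == sid).to_numpy()]
        for sid in subject_ids
    }
    metrics = cap_stats.temporal_metrics_table(sequences, manifest, K)
    _write_csv(metrics, out / "temporal_metrics.csv", cfg)
    if two_cells and "animal_id" in manifest.columns:
        merged = metrics.merge(manifest[["subject_id", "animal_id"]],
                               on="subject_id")
        try:
            rm = cap_stats.rm_anova_temporal(merged)
            _write_csv(rm, out / "temporal_anova.csv", cfg)
        except ValueError as exc:
            log.warning("temporal ANOVA skipped: %s", exc)

    # --- classification ---------------------------------------------------
    cls_rows = []
    units = manifest.assign(
        unit=manifest.animal_id if "animal_id" in manifest.columns
        else manifest.subject_id)
    enough_units = units.groupby("genotype").unit.nunique().min() >= 2
    if not enough_units:
        log.warning("classification skipped: fewer than 2 animals per genotype")
    if two_cells and cfg.classify_iters > 0 and enough_units:
        for mode in cfg.classify_modes:
            res = classifier.train_eval(
                manifest, thresh_frames, raw_frames, K, mode=mode,
                classes=4, n_iter=cfg.classify_iters, seed=cfg.seed,
            )
            cls_rows.append({"problem": "4-class", "mode": mode,
                             "mean_accuracy": res.accuracies.mean(),
                             "mean_chance": res.chance_accuracies.mean(),
                             "wilcoxon_p": res.wilcoxon_p})
            _write_csv(
                pd.DataFrame(res.confusion, index=res.classes,
                             columns=res.classes).reset_index(names="true"),
                out / f"confusion_4class_{mode}.csv", cfg)
        _write_csv(pd.DataFrame(cls_rows), out / "classification.csv", cfg)

    # --- transitions ------------------------------------------------------
    tables = {}
    edge_rows = []
    cell_labels = manifest.genotype + "-" + manifest.age
    for ci, cell in enumerate(sorted(cell_labels.unique())):
        sids = manifest.subject_id[cell_labels == cell]
        tab = transitions.analyze_group(
            [sequences[s] for s in sids], K,
            n_surrogates=cfg.n_surrogates, seed=cfg.seed + 1000 + ci,
        )
        tables[cell] = tab
        sig = tab.significance
        directional = {(r.i, r.j) for r in tab.directionality.itertuples()
                       if r.significant}
        for r in sig.itertuples():
            edge_rows.append({
                "group": cell, "i": r.i, "j": r.j, "p_ij": r.p_ij,
                "p_fdr": r.p_fdr, "significant": bool(r.significant),
                "directional": (r.i, r.j) in directional,
            })
    _write_csv(pd.DataFrame(edge_rows), out / "transition_edges.csv", cfg)

    inter_rows = []
    for age_label in sorted(manifest.age.unique()):
        cells = [f"{g}-{age_label}" for g in ("WT", "TG")]
        if not all(c in tables for c in cells):
            continue
        a, b = tables[cells[0]], tables[cells[1]]
        diff = transitions.intergroup_difference_test(
            a.trans, b.trans, a.ensemble, b.ensemble,
            a.significance, b.significance, a.persistence, b.persistence)
        diff.insert(0, "age", age_label)
        inter_rows.append(diff)
    if inter_rows:
        _write_csv(pd.concat(inter_rows, ignore_index=True),
                   out / "transition_group_differences.csv", cfg)

    state = {
        "config": asdict(cfg), "config_hash": cfg.digest(), "K": int(K),
        "elbow_K": int(curve.elbow_K),
        "cap_pairs": [list(map(int, p)) for p in maps.pairs],
        "pair_correlations": [float(c) for c in maps.pair_corrs],
    }
    (out / "run_summary.json").write_text(json.dumps(state, indent=2))
    log.info("run complete")
    return out


def make_report(run_dir: str | Path) -> Path:
    """Render summary figures from a completed run directory."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    report_dir = run_dir / "report"
    report_dir.mkdir(exist_ok=True)
    warnings: list[str] = []

    summary = json.loads((run_dir / "run_summary.json").read_text())

    curve = pd.read_csv(run_dir / "variance_curve.csv", comment="#")
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].plot(curve.K, curve.EV, "o-")
    axes[0].axvline(summary["elbow_K"], ls="--", c="m")
    axes[0].set_xlabel("number of clusters K")
    axes[0].set_ylabel("explained variance")
    axes[1].plot(curve.K, 100 * curve.fractional_gain, "o-")
    axes[1].axhline(0.5, ls="--", c="k")
    axes[1].set_xlabel("K")
    axes[1].set_ylabel("fractional EV gain (%)")
    fig.tight_layout()
    fig.savefig(report_dir / "variance_curve.png", dpi=120)
    plt.close(fig)

    metrics_path = run_dir / "temporal_metrics.csv"
    if metrics_path.exists():
        metrics = pd.read_csv(metrics_path, comment="#")
        fig, axes = plt.subplots(1, 2, figsize=(10, 3.5))
        for ax, col in zip(axes, ("occurrence_pct", "duration")):
            for (g, a), grp in metrics.groupby(["genotype", "age"]):
                ax.scatter(grp.cap + {"WT": -0.15, "TG": 0.15}[g]
                           + {"4M": 0.0, "6M": 0.07}.get(a, 0.0),
                           grp[col], s=8, label=f"{g} {a}", alpha=0.6)
            ax.set_xlabel("CAP")
            ax.set_ylabel(col)
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(report_dir / "temporal_metrics.png", dpi=120)
        plt.close(fig)

    edges_path = run_dir / "transition_edges.csv"
    n_sig_edges = 0
    if edges_path.exists():
        edges = pd.read_csv(edges_path, comment="#")
        K = summary["K"]
        groups = sorted(edges.group.unique())
        fig, axes = plt.subplots(1, max(len(groups), 1),
                                 figsize=(3.2 * max(len(groups), 1), 3.2))
        axes = np.atleast_1d(axes)
        for ax, g in zip(axes, groups):
            M = np.full((K, K), np.nan)
            sub = edges[edges.group == g]
            for r in sub.itertuples():
                M[r.i - 1, r.j - 1] = r.p_ij
            im = ax.imshow(M, cmap="viridis", vmin=0, vmax=np.nanmax(M))
            for r in sub.itertuples():
                if r.significant:
                    n_sig_edges += 1
                    ax.text(r.j - 1, r.i - 1, "*", ha="center", va="center",
                            color="w", fontsize=11)
                if r.directional:
                    ax.plot(r.j - 1, r.i - 1, "o", mfc="none", mec="r", ms=12)
            ax.set_title(g, fontsize=9)
            ax.set_xlabel("to CAP")
            ax.set_ylabel("from CAP")
        fig.colorbar(im, ax=axes.tolist(), shrink=0.8)
        fig.savefig(report_dir / "transition_matrices.png", dpi=120)
        plt.close(fig)
        if n_sig_edges == 0:
            warnings.append("no significant transitions: schematic is empty")

    pairs = summary.get("cap_pairs", [])
    lines = [
        "# capdyn run report",
        f"config hash: {summary['config_hash']}",
        f"selected K (elbow): {summary['elbow_K']}",
        f"CAP/anti-CAP pairs: {pairs}",
        f"pair correlations: {summary.get('pair_correlations', [])}",
        f"significant transition edges: {n_sig_edges}",
    ]
    lines += [f"WARNING: {w}" for w in warnings]
    (report_dir / "report.md").write_text("\n".join(lines) + "\n")
    return report_dir
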