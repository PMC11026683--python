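"""Synthetic cohort generator with known ground truth.

Subject scans are built from a small set of spatial co-activation
topographies driven by a subject-level Markov state sequence, plus
Gaussian noise and optional per-group effects (amplitude scaling on voxel
subsets, transition-matrix overrides).  Everything downstream of the
generator can therefore be tested against planted truth without any
external data.

Signals are produced directly on the z-scale ("conditioned" space) by
default; ``raw_mode`` adds a nonzero mean, slow drift and an out-of-band
sinusoid so the conditioning chain can be exercised too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import VoxelTimeSeries, save_scan

__all__ = [
    "StateSpec",
    "MarkovSpec",
    "AmplitudeEffect",
    "CohortDesign",
    "GroundTruth",
    "make_state_spec",
    "make_markov_spec",
    "generate_state_sequence",
    "generate_subject_scan",
    "generate_cohort",
]

GENOTYPES = ("WT", "TG")
AGES = ("4M", "6M")


def cell_key(genotype: str, age: str) -> str:
    return f"{genotype}-{age}"


@dataclass
class StateSpec:
    """Planted co-activation states.

    ``patterns`` is ``(n_states, m)``; each row has zero mean over mask
    voxels.  ``amplitudes`` maps a cell key (or ``"default"``) to a
    per-state scalar gain.  ``anti_pairs`` lists 1-based state index pairs
    whose patterns are exact sign-flipped copies.
    """

    patterns: np.ndarray
    amplitudes: dict[str, np.ndarray] = field(default_factory=dict)
    anti_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        if "default" not in self.amplitudes:
            self.amplitudes["default"] = np.ones(self.n_states)
        for k, v in self.amplitudes.items():
            self.amplitudes[k] = np.asarray(v, dtype=float)

    @property
    def n_states(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    def amplitude(self, cell: str) -> np.ndarray:
        return self.amplitudes.get(cell, self.amplitudes["default"])


@dataclass
class MarkovSpec:
    """Row-stochastic transition matrix over states, with its stationary law."""

    trans: np.ndarray

    def __post_init__(self) -> None:
        self.trans = np.atleast_2d(np.asarray(self.trans, dtype=float))
        n = self.trans.shape[0]
        if self.trans.shape != (n, n):
            raise ValueError("transition matrix must be square")
        if np.any(self.trans < 0):
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(self.trans.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.trans.shape[0]

    @property
    def stationary(self) -> np.ndarray:
        """Stationary distribution (left eigenvector for eigenvalue 1)."""
        vals, vecs = np.linalg.eig(self.trans.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class AmplitudeEffect:
    """Multiplicative amplitude change on a voxel subset for one cell."""

    genotype: str
    age: str
    voxels: np.ndarray  # voxel row indices within the mask
    factor: float
    states: list[int] | None = None  # 1-based state indices; None = all

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)


@dataclass
class CohortDesign:
    """Layout of the synthetic cohort."""

    n_per_cell: int = 2
    n_frames: int = 980
    n_states: int = 6
    grid_shape: tuple[int, int, int] = (10, 10, 5)
    noise_sd: float = 0.3
    persistence: float = 0.85
    tr_seconds: float = 0.6
    amplitude_effects: list[AmplitudeEffect] = field(default_factory=list)
    markov_overrides: dict[str, MarkovSpec] = field(default_factory=dict)
    raw_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 50:
            raise ValueError("n_frames must be >= 50")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_per_cell < 1:
            raise ValueError("each cell needs at least one subject")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass
class GroundTruth:
    """Everything planted: states, chains, sequences, seeds."""

    states: StateSpec
    markov: dict[str, MarkovSpec]
    sequences: dict[str, np.ndarray]  # subject_id -> 1-based state sequence
    subject_cells: dict[str, str]
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "patterns": self.states.patterns.tolist(),
            "amplitudes": {k: v.tolist() for k, v in self.states.amplitudes.items()},
            "anti_pairs": [list(p) for p in self.states.anti_pairs],
            "markov": {k: m.trans.tolist() for k, m in self.markov.items()},
            "sequences": {k: v.tolist() for k, v in self.sequences.items()},
            "subject_cells": dict(self.subject_cells),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        states = StateSpec(
            patterns=np.asarray(d["patterns"]),
            amplitudes={k: np.asarray(v) for k, v in d["amplitudes"].items()},
            anti_pairs=[tuple(p) for p in d["anti_pairs"]],
        )
        return cls(
            states=states,
            markov={k: MarkovSpec(np.asarray(m)) for k, m in d["markov"].items()},
            sequences={k: np.asarray(v, dtype=int) for k, v in d["sequences"].items()},
            subject_cells=d["subject_cells"],
            seed=d["seed"],
        )


def make_state_spec(
    n_states: int,
    n_voxels: int,
    seed: int = 0,
    pattern_scale: float = 1.0,
) -> StateSpec:
    """Draw random anti-paired topographies.

    States come in consecutive pairs ``(1, 2), (3, 4), ...``: the even
    member of each pair is the exact negative of the odd one, so the
    planted anti-correlation is -1 by construction.  An odd trailing state
    is left unpaired.  Patterns are zero-mean, unit-sd over mask voxels.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    rng = np.random.default_rng(seed)
    patterns = np.empty((n_states, n_voxels))
    anti_pairs: list[tuple[int, int]] = []
    for i in range(0, n_states - 1, 2):
        p = rng.normal(size=n_voxels)
        p -= p.mean()
        p /= p.std()
        patterns[i] = p * pattern_scale
        patterns[i + 1] = -p * pattern_scale
        anti_pairs.append((i + 1, i + 2))
    if n_states % 2 == 1:
        p = rng.normal(size=n_voxels)
        p -= p.mean()
        p /= p.std()
        patterns[-1] = p * pattern_scale
    return StateSpec(patterns=patterns, anti_pairs=anti_pairs)


def make_markov_spec(n_states: int, persistence: float = 0.85) -> MarkovSpec:
    """Uniform-off-diagonal chain with the given self-transition probability."""
    if not 0 <= persistence <= 1:
        raise ValueError("persistence must lie in [0, 1]")
    off = (1.0 - persistence) / (n_states - 1)
    trans = np.full((n_states, n_states), off)
    np.fill_diagonal(trans, persistence)
    return MarkovSpec(trans)


def generate_state_sequence(
    markov: MarkovSpec, n_frames: int, seed: int
) -> np.ndarray:
    """Sample a 1-based state sequence, starting from the stationary law."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    n = markov.n_states
    seq = np.empty(n_frames, dtype=int)
    cum0 = np.cumsum(markov.stationary)
    seq[0] = np.searchsorted(cum0, rng.random(), side="right")
    cum = np.cumsum(markov.trans, axis=1)
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        seq[t] = np.searchsorted(cum[seq[t - 1]], u[t - 1], side="right")
    return np.minimum(seq, n - 1) + 1


def generate_subject_scan(
    states: StateSpec,
    sequence: np.ndarray,
    cell: str,
    noise_sd: float,
    seed: int,
    *,
    voxel_coords: np.ndarray | None = None,
    mask_shape: tuple[int, int, int] | None = None,
    tr_seconds: float = 0.6,
    raw_mode: bool = False,
    **meta,
) -> VoxelTimeSeries:
    """Render one scan: frame t = amplitude(cell, s_t) * pattern(s_t) + noise."""
    sequence = np.asarray(sequence, dtype=int)
    if sequence.size == 0:
        raise ValueError("sequence must be nonempty")
    m = states.n_voxels
    if voxel_coords is None:
        # degenerate line geometry for tests that ignore space
        voxel_coords = np.column_stack(
            [np.arange(m), np.zeros(m, int), np.zeros(m, int)]
        )
        mask_shape = (m, 1, 1)
    if voxel_coords.shape[0] != m:
        raise ValueError("pattern length does not match mask size")
    rng = np.random.default_rng(seed)
    amp = states.amplitude(cell)
    gains = amp[sequence - 1]  # (T,)
    data = states.patterns[sequence - 1].T * gains  # (m, T)
    if noise_sd > 0:
        data = data + rng.normal(scale=noise_sd, size=data.shape)
    if raw_mode:
        T = sequence.size
        t = np.arange(T) * tr_seconds
        base = rng.normal(loc=100.0, scale=5.0, size=(m, 1))
        drift = rng.normal(scale=0.002, size=(m, 1)) * (t - t.mean()) ** 2
        hum = 0.5 * np.sin(2 * np.pi * 0.4 * t)  # outside the 0.01-0.2 Hz band
        data = data + base + drift + hum
    return VoxelTimeSeries(
        data=data,
        voxel_coords=voxel_coords,
        mask_shape=tuple(mask_shape),
        tr_seconds=tr_seconds,
        **meta,
    )


def _apply_effects(states: StateSpec, design: CohortDesign, cell: str) -> StateSpec:
    """Per-cell pattern set with amplitude effects baked in."""
    genotype, age = cell.split("-")
    patterns = states.patterns.copy()
    for eff in design.amplitude_effects:
        if eff.genotype != genotype or eff.age != age:
            continue
        idx = list(range(states.n_states)) if eff.states is None else [
            s - 1 for s in eff.states
        ]
        for s in idx:
            patterns[s, eff.voxels] *= eff.factor
    return StateSpec(
        patterns=patterns,
        amplitudes={k: v.copy() for k, v in states.amplitudes.items()},
        anti_pairs=list(states.anti_pairs),
    )


def generate_cohort(
    design: CohortDesign,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, VoxelTimeSeries], GroundTruth]:
    """Build (and optionally write) the full synthetic cohort.

    Returns the manifest, the in-memory scans keyed by subject id, and the
    planted ground truth.  When ``out_dir`` is given, 4-D NIfTI scans, the
    binary mask, ``manifest.csv`` and ``ground_truth.json`` are written.
    """
    m = design.n_voxels
    states = make_state_spec(design.n_states, m, seed=design.seed)
    base_markov = make_markov_spec(design.n_states, design.persistence)

    shape = design.grid_shape
    coords = np.column_stack(np.nonzero(np.ones(shape, dtype=bool)))

    markov: dict[str, MarkovSpec] = {}
    sequences: dict[str, np.ndarray] = {}
    subject_cells: dict[str, str] = {}
    scans: dict[str, VoxelTimeSeries] = {}
    rows = []
    sub_idx = 0
    for genotype in GENOTYPES:
        for age in AGES:
            cell = cell_key(genotype, age)
            chain = design.markov_overrides.get(cell, base_markov)
            markov[cell] = chain
            cell_states = _apply_effects(states, design, cell)
            for i in range(design.n_per_cell):
                sid = f"sub-{sub_idx:03d}"
                # stable per-subject seeds derived from the design seed
                seq_seed = design.seed * 100003 + sub_idx * 2
                scan_seed = design.seed * 100003 + sub_idx * 2 + 1
                seq = generate_state_sequence(chain, design.n_frames, seq_seed)
                scan = generate_subject_scan(
                    cell_states,
                    seq,
                    cell,
                    design.noise_sd,
                    scan_seed,
                    voxel_coords=coords,
                    mask_shape=shape,
                    tr_seconds=design.tr_seconds,
                    raw_mode=design.raw_mode,
                    subject_id=sid,
                    genotype=genotype,
                    age=age,
                )
                sequences[sid] = seq
                subject_cells[sid] = cell
                scans[sid] = scan
                rows.append(
                    {
                        "subject_id": sid,
                        "animal_id": f"{genotype}{i:03d}",  # same animal at both ages
                        "genotype": genotype,
                        "age": age,
                        "path": f"{sid}.nii.gz",
                    }
                )
                sub_idx += 1

    manifest = pd.DataFrame(rows)
    truth = GroundTruth(
        states=states,
        markov=markov,
        sequences=sequences,
        subject_cells=subject_cells,
        seed=design.seed,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import nibabel as nib

        mask_img = nib.Nifti1Image(np.ones(shape, dtype=np.uint8), np.eye(4))
        nib.save(mask_img, str(out / "mask.nii.gz"))
        for sid, scan in scans.items():
            save_scan(scan, out / f"{sid}.nii.gz")
        manifest = manifest.assign(
            path=[str(out / f"{sid}.nii.gz") for sid in manifest.subject_id]
        )
        manifest.to_csv(out / "manifest.csv", index=False)
        truth.to_json(out / "ground_truth.json")

    return manifest, scans, truth
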