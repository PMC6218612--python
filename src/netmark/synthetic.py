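"""Synthetic multi-subject, multi-session voxel-level BOLD-like datasets.

Emulates the statistical structure the downstream pipeline assumes:
temporally autocorrelated latent signals shared within spatially
contiguous regions, correlated across regions by a specified coupling
matrix, with a group difference planted as a coupling delta on chosen
region pairs, and paired sessions with session-specific coupling state.

Generation starts at the "preprocessed voxel time series" level; scanner
physics, motion and physiological noise are out of scope.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "VoxelDataset",
    "GroundTruth",
    "default_coupling",
    "generate_cohort",
    "generate_session_pair",
    "write_dataset",
    "read_dataset",
    "write_metadata_csv",
]

#: face-neighbor (6-connectivity) offsets on the voxel grid
NEIGHBOR_OFFSETS_6 = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=int,
)

PSD_TOL = 1e-10


def default_coupling(n_regions: int, background: float = 0.2) -> np.ndarray:
    """Default latent coupling matrix: unit diagonal, uniform weak positive
    background correlation between regions (a rough stand-in for the global
    signal shared across resting-state networks)."""
    c = np.full((n_regions, n_regions), float(background))
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the acquisition the pipeline was designed around:
    177 time points at TR = 2 s per scan. Region-pair couplings are
    lag-zero correlations of the latent signals; ``planted_effects`` adds
    deltas to the patient group only (region labels are 1-based).
    """

    grid_dims: tuple[int, int, int] = (6, 6, 6)
    n_true_regions: int = 4
    n_timepoints: int = 177
    tr_seconds: float = 2.0
    n_controls: int = 10
    n_patients: int = 10
    ar_coefficient: float = 0.5
    base_coupling: np.ndarray | None = None
    planted_effects: list[tuple[int, int, float]] = field(default_factory=list)
    voxel_noise_sd: float = 1.0
    session_state_sd: float = 0.1
    seed: int = 0

    def resolved_coupling(self) -> np.ndarray:
        if self.base_coupling is None:
            return default_coupling(self.n_true_regions)
        return np.asarray(self.base_coupling, dtype=float)

    def patient_coupling(self) -> np.ndarray:
        """Base coupling with planted deltas applied; raises if any delta
        breaks positive semidefiniteness (silent projection would distort
        the planted effect size)."""
        c = self.resolved_coupling().copy()
        for a, b, delta in self.planted_effects:
            i, j = a - 1, b - 1
            c[i, j] += delta
            c[j, i] += delta
            if np.linalg.eigvalsh(c).min() < -PSD_TOL:
                raise ValueError(
                    f"planted effect on region pair ({a}, {b}) with delta "
                    f"{delta:+g} makes the coupling matrix non-positive-"
                    "semidefinite"
                )
            if np.abs(c[i, j]) > 1 + 1e-12:
                raise ValueError(
                    f"planted effect on region pair ({a}, {b}) pushes the "
                    f"coupling outside [-1, 1] (got {c[i, j]:g})"
                )
        return c

    def validate(self) -> None:
        if any(d <= 0 for d in self.grid_dims) or len(self.grid_dims) != 3:
            raise ValueError("grid_dims must be a positive integer triple")
        n_vox = int(np.prod(self.grid_dims))
        if not 1 <= self.n_true_regions <= n_vox:
            raise ValueError("n_true_regions must be in [1, n_voxels]")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not -1 < self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in (-1, 1)")
        if self.voxel_noise_sd <= 0 or self.session_state_sd < 0:
            raise ValueError("noise standard deviations must be positive")
        c = self.resolved_coupling()
        k = self.n_true_regions
        if c.shape != (k, k):
            raise ValueError("base_coupling must be n_true_regions square")
        if not np.allclose(c, c.T):
            raise ValueError("base_coupling must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("base_coupling must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -PSD_TOL:
            raise ValueError("base_coupling is not positive semidefinite")
        for a, b, _ in self.planted_effects:
            if not (1 <= a <= k and 1 <= b <= k) or a == b:
                raise ValueError(f"planted pair ({a}, {b}) is not a valid region pair")
        self.patient_coupling()  # raises on infeasible deltas


@dataclass
class VoxelDataset:
    """One subject-session scan: a T x N voxel time-series matrix plus the
    integer 3D coordinate of each voxel column."""

    subject_id: str
    session_id: str
    group_label: str  # "control" | "patient"
    coords: np.ndarray  # (N, 3) int
    series: np.ndarray  # (T, N) float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.series = np.asarray(self.series, dtype=float)
        if self.series.shape[1] != self.coords.shape[0]:
            raise ValueError("series column count must equal number of coords")
        if len({tuple(c) for c in self.coords}) != len(self.coords):
            raise ValueError("voxel coords must be unique")
        if self.group_label not in ("control", "patient"):
            raise ValueError("group_label must be 'control' or 'patient'")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.series.shape[1]


@dataclass
class GroundTruth:
    """True generative structure: region label (1-based) per voxel and the
    planted coupling deltas."""

    voxel_region_labels: np.ndarray
    planted_pairs: list[tuple[int, int, float]]


# ---------------------------------------------------------------------------
# region growing


def _grow_regions(grid_dims: tuple[int, int, int], n_regions: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Partition the full grid into contiguous regions by competitive
    breadth-first accretion from random seed voxels (6-connectivity)."""
    dims = np.asarray(grid_dims)
    n_vox = int(dims.prod())
    labels = np.zeros(n_vox, dtype=int)

    def idx(c):
        return int(np.ravel_multi_index(c, grid_dims))

    seeds = rng.choice(n_vox, size=n_regions, replace=False)
    frontiers: list[list[int]] = []
    for r, s in enumerate(seeds, start=1):
        labels[s] = r
        frontiers.append([int(s)])
    coords_all = np.stack(np.unravel_index(np.arange(n_vox), grid_dims), axis=1)
    n_assigned = n_regions
    while n_assigned < n_vox:
        progressed = False
        order = rng.permutation(n_regions)
        for r in order:
            frontier = frontiers[r]
            # claim one unassigned neighbor of this region, if any
            while frontier:
                v = frontier[0]
                nbrs = coords_all[v] + NEIGHBOR_OFFSETS_6
                ok = np.all((nbrs >= 0) & (nbrs < dims), axis=1)
                cand = [idx(c) for c in nbrs[ok] if labels[idx(c)] == 0]
                if not cand:
                    frontier.pop(0)
                    continue
                v_new = cand[int(rng.integers(len(cand)))]
                labels[v_new] = r + 1
                frontier.append(v_new)
                n_assigned += 1
                progressed = True
                break
        if not progressed:  # pragma: no cover - grid is connected
            raise RuntimeError("region growing stalled")
    return labels


# ---------------------------------------------------------------------------
# latent signals


def _ar1_innovation_scale(phi: float) -> float:
    # innovation sd that yields a unit-variance stationary AR(1)
    return float(np.sqrt(1.0 - phi * phi))


def _draw_latents(coupling: np.ndarray, phi: float, n_t: int,
                  rng: np.random.Generator) -> np.ndarray:
    """T x R latent signals: unit-variance AR(1) columns with lag-zero
    correlation matrix `coupling` (matrix square root mixing preserves the
    lag-1 autocorrelation phi)."""
    r = coupling.shape[0]
    sd = _ar1_innovation_scale(phi)
    z = np.empty((n_t, r))
    z[0] = rng.standard_normal(r)  # stationary start (unit variance)
    eps = rng.standard_normal((n_t - 1, r)) * sd
    for t in range(1, n_t):
        z[t] = phi * z[t - 1] + eps[t - 1]
    # symmetric PSD square root (Cholesky fails on singular couplings)
    w, v = np.linalg.eigh(coupling)
    w = np.clip(w, 0.0, None)
    root = v @ (np.sqrt(w)[:, None] * v.T)
    return z @ root.T


def _subject_rng(seed: int, subject_id: str, session_id: str) -> np.random.Generator:
    tag = zlib.crc32(f"{subject_id}/{session_id}".encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, tag]))


def _make_dataset(config: SyntheticConfig, labels: np.ndarray,
                  coupling: np.ndarray, subject_id: str, session_id: str,
                  group: str) -> VoxelDataset:
    rng = _subject_rng(config.seed, subject_id, session_id)
    lat = _draw_latents(coupling, config.ar_coefficient, config.n_timepoints, rng)
    series = lat[:, labels - 1] + rng.standard_normal(
        (config.n_timepoints, labels.size)) * config.voxel_noise_sd
    coords = np.stack(np.unravel_index(np.arange(labels.size), config.grid_dims),
                      axis=1)
    return VoxelDataset(subject_id, session_id, group, coords, series)


def generate_cohort(config: SyntheticConfig) -> tuple[list[VoxelDataset], GroundTruth]:
    """Generate one scan per subject plus the generative ground truth.

    Controls share ``base_coupling``; patients get ``base_coupling`` with
    the planted deltas. Deterministic given the config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0]))
    labels = _grow_regions(config.grid_dims, config.n_true_regions, rng)
    c_control = config.resolved_coupling()
    c_patient = config.patient_coupling()
    datasets = []
    for i in range(config.n_controls):
        sid = f"con{i + 1:03d}"
        datasets.append(_make_dataset(config, labels, c_control, sid, "ses-01",
                                      "control"))
    for i in range(config.n_patients):
        sid = f"pat{i + 1:03d}"
        datasets.append(_make_dataset(config, labels, c_patient, sid, "ses-01",
                                      "patient"))
    truth = GroundTruth(labels, list(config.planted_effects))
    return datasets, truth


def _nearest_correlation(c: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix by clipping
    eigenvalues at zero and renormalizing the diagonal."""
    w, v = np.linalg.eigh((c + c.T) / 2.0)
    w = np.clip(w, 1e-8, None)
    m = v @ (w[:, None] * v.T)
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return np.clip(m, -1.0, 1.0)


def session_coupling(config: SyntheticConfig, group: str, subject_id: str,
                     session_id: str) -> np.ndarray:
    """Coupling matrix in effect for a given subject-session: the group
    coupling perturbed by session-state noise (second and later sessions),
    re-projected to a valid correlation matrix."""
    base = (config.patient_coupling() if group == "patient"
            else config.resolved_coupling())
    if session_id == "ses-01" or config.session_state_sd == 0:
        return base if session_id == "ses-01" else base.copy()
    rng = _subject_rng(config.seed ^ 0x5E55, subject_id, session_id)
    k = base.shape[0]
    noise = rng.standard_normal((k, k)) * config.session_state_sd
    noise = (noise + noise.T) / 2.0
    np.fill_diagonal(noise, 0.0)
    return _nearest_correlation(base + noise)


def generate_session_pair(config: SyntheticConfig,
                          subject: VoxelDataset) -> VoxelDataset:
    """Second-session scan for an existing subject: same group couplings
    perturbed by session-state noise, latent signals re-drawn."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0]))
    labels = _grow_regions(config.grid_dims, config.n_true_regions, rng)
    session_id = "ses-02"
    coupling = session_coupling(config, subject.group_label, subject.subject_id,
                                session_id)
    return _make_dataset(config, labels, coupling, subject.subject_id, session_id,
                         subject.group_label)


# ---------------------------------------------------------------------------
# serialization


def write_dataset(path: str, dataset: VoxelDataset) -> None:
    """Write a dataset as a 4D NIfTI volume plus a JSON sidecar.

    ``path`` is a prefix: ``<path>.nii`` holds the 4D image (voxels placed
    at their grid coordinates; the affine is identity at 1 mm isotropic)
    and ``<path>.json`` holds metadata and the column order of coords.
    """
    coords = dataset.coords
    dims = coords.max(axis=0) + 1
    vol = np.zeros((*dims, dataset.n_timepoints), dtype=np.float64)
    vol[coords[:, 0], coords[:, 1], coords[:, 2], :] = dataset.series.T
    nib.save(nib.Nifti1Image(vol, np.eye(4)), f"{path}.nii")
    meta = {
        "subject_id": dataset.subject_id,
        "session_id": dataset.session_id,
        "group": dataset.group_label,
        "n_timepoints": int(dataset.n_timepoints),
        "coords": coords.tolist(),
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(meta, fh)


def read_dataset(path: str) -> VoxelDataset:
    """Inverse of :func:`write_dataset`; raises ``ValueError`` naming the
    missing or inconsistent field on malformed input."""
    try:
        with open(f"{path}.json") as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed sidecar JSON at {path}.json: {exc}") from exc
    for key in ("subject_id", "session_id", "group", "n_timepoints", "coords"):
        if key not in meta:
            raise ValueError(f"sidecar missing required field '{key}'")
    img = nib.load(f"{path}.nii")
    vol = np.asarray(img.dataobj, dtype=float)
    coords = np.asarray(meta["coords"], dtype=int)
    if vol.ndim != 4:
        raise ValueError("field 'image': expected a 4D volume")
    if vol.shape[3] != meta["n_timepoints"]:
        raise ValueError("field 'n_timepoints': does not match image 4th axis")
    series = vol[coords[:, 0], coords[:, 1], coords[:, 2], :].T
    return VoxelDataset(meta["subject_id"], meta["session_id"], meta["group"],
                        coords, series)


def write_metadata_csv(datasets: list[VoxelDataset], path: str,
                       scores: dict[str, dict[str, float]] | None = None) -> None:
    """Subject metadata table (subject_id, session_id, group, optional
    sans/saps symptom scores)."""
    rows = []
    for d in datasets:
        row = {"subject_id": d.subject_id, "session_id": d.session_id,
               "group": d.group_label}
        if scores and d.subject_id in scores:
            row.update(scores[d.subject_id])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
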