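"""Synthetic corticostriatal connectivity and voxelwise contrast maps.

Stands in for tractography and fMRI GLM outputs: a cohort shares one voxel
lattice (a connected blob emulating a striatal region of interest) and one
smooth connectivity archetype per cortical target; each subject's streamline
counts are Poisson draws around the archetype scaled by per-target lognormal
jitter.  Contrast maps are built as the generative converse of the
structure-function regression:

    y = lambda_c * z(C_z @ w) + lambda_g * z(g) + N(0, noise_sd),

where C_z is the column-z-scored connectivity, w the planted target weights
and g a group-consistent smooth spatial map, optionally followed by Gaussian
smoothing on the lattice.  The planted ground truth is retained for
recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .structure_function import zscore

DEFAULT_CONTRASTS = ("hand_vs_foot", "reward", "expected_value")

_NEIGHBORS = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                       [0, -1, 0], [0, 0, 1], [0, 0, -1]])


@dataclass
class VoxelLattice:
    """Integer 3-D coordinates of a connected voxel blob (6-neighborhood)."""

    coords: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    def pairwise_sq_distances(self) -> np.ndarray:
        d = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sum(d.astype(float) ** 2, axis=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, columns=["x", "y", "z"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VoxelLattice":
        return cls(coords=df[["x", "y", "z"]].to_numpy(dtype=np.int64))


def make_region_geometry(n_voxels: int, seed=None) -> VoxelLattice:
    """Grow a connected blob from the origin by uniform random accretion."""
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    rng = np.random.default_rng(seed)
    blob = {(0, 0, 0)}
    frontier = {tuple(n) for n in _NEIGHBORS}
    while len(blob) < n_voxels:
        candidates = sorted(frontier)
        pick = candidates[rng.integers(len(candidates))]
        frontier.discard(pick)
        blob.add(pick)
        for off in _NEIGHBORS:
            nb = (pick[0] + off[0], pick[1] + off[1], pick[2] + off[2])
            if nb not in blob:
                frontier.add(nb)
    return VoxelLattice(coords=np.array(sorted(blob), dtype=np.int64))


@dataclass
class ConnectivityMatrix:
    """Streamline counts [n_voxels x n_targets] with target names."""

    counts: np.ndarray
    target_names: list

    def __post_init__(self):
        if self.counts.shape[1] != len(self.target_names):
            raise ValueError("target_names length must match columns")
        if np.any(self.counts < 0):
            raise ValueError("streamline counts must be nonnegative")

    @property
    def n_voxels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_targets(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, columns=self.target_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConnectivityMatrix":
        df = pd.read_csv(path)
        return cls(counts=df.to_numpy(), target_names=list(df.columns))


def default_target_names(n_targets: int) -> list:
    """Generic cortical parcel labels, mirroring a bilateral parcellation."""
    half = n_targets // 2
    names = [f"lh_parcel_{i + 1:03d}" for i in range(half)]
    names += [f"rh_parcel_{i + 1:03d}" for i in range(n_targets - half)]
    return names


def _bump_field(lattice: VoxelLattice, rng, length_scale: float,
                n_bumps: int = 3) -> np.ndarray:
    """Smooth nonnegative field: mixture of Gaussian bumps on the lattice."""
    centers = lattice.coords[rng.integers(lattice.n_voxels, size=n_bumps)]
    amps = rng.lognormal(mean=0.0, sigma=0.5, size=n_bumps)
    d2 = np.sum((lattice.coords[:, None, :].astype(float)
                 - centers[None, :, :].astype(float)) ** 2, axis=2)
    return (amps[None, :] * np.exp(-d2 / (2.0 * length_scale ** 2))).sum(axis=1)


def connectivity_archetype(lattice: VoxelLattice, n_targets: int = 148,
                           mean_count: float = 50.0,
                           spatial_scale: float = 3.0, seed=None,
                           n_bumps: int = 3, target_scale_sd: float = 0.5,
                           n_empty: int = 0) -> np.ndarray:
    """Cohort-level expected streamline counts [n_voxels x n_targets].

    Each target's field is a Gaussian-bump mixture with length scale
    ``spatial_scale`` (voxels), scaled so its voxel mean is a lognormal
    multiple of ``mean_count``.  ``n_empty`` trailing-random targets are
    zeroed, emulating parcels missing in some subjects ("empty ROIs").
    """
    if mean_count <= 0:
        raise ValueError("mean_count must be positive")
    rng = np.random.default_rng(seed)
    arch = np.empty((lattice.n_voxels, n_targets))
    for j in range(n_targets):
        f = _bump_field(lattice, rng, spatial_scale, n_bumps)
        f = f / max(f.mean(), 1e-12)
        arch[:, j] = f * mean_count * rng.lognormal(0.0, target_scale_sd)
    if n_empty > 0:
        empty = rng.choice(n_targets, size=n_empty, replace=False)
        arch[:, empty] = 0.0
    return arch


def generate_connectivity(lattice: VoxelLattice, n_targets: int = 148,
                          mean_count: float = 50.0,
                          spatial_scale: float = 3.0,
                          subject_jitter_sd: float = 0.3, seed=None,
                          *, archetype: np.ndarray | None = None,
                          cohort_seed=None, target_names=None,
                          exact_mean: bool = False,
                          n_empty: int = 0) -> ConnectivityMatrix:
    """One subject's streamline-count matrix around the cohort archetype.

    The archetype is shared across subjects (pass ``archetype`` or a common
    ``cohort_seed``); the subject matrix is Poisson around archetype x
    per-target mean-one lognormal jitter.  ``exact_mean=True`` (debug)
    returns the noiseless expected counts instead of Poisson draws.
    """
    rng = np.random.default_rng(seed)
    if archetype is None:
        archetype = connectivity_archetype(
            lattice, n_targets, mean_count, spatial_scale,
            seed=cohort_seed if cohort_seed is not None else seed,
            n_empty=n_empty)
    n_targets = archetype.shape[1]
    if target_names is None:
        target_names = default_target_names(n_targets)
    if subject_jitter_sd > 0 and not exact_mean:
        jitter = rng.lognormal(-subject_jitter_sd ** 2 / 2.0,
                               subject_jitter_sd, size=n_targets)
    else:
        jitter = np.ones(n_targets)
    lam = archetype * jitter[None, :]
    counts = lam if exact_mean else rng.poisson(lam).astype(np.int64)
    return ConnectivityMatrix(counts=counts, target_names=list(target_names))


def smooth_on_lattice(values: np.ndarray, lattice: VoxelLattice,
                      fwhm: float, d2: np.ndarray | None = None) -> np.ndarray:
    """Gaussian smoothing on an irregular lattice, FWHM in voxel units."""
    if fwhm <= 0:
        return np.asarray(values, dtype=float)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if d2 is None:
        d2 = lattice.pairwise_sq_distances()
    w = np.exp(-d2 / (2.0 * sigma ** 2))
    return (w @ np.asarray(values, dtype=float)) / w.sum(axis=1)


@dataclass
class ContrastMap:
    """Voxelwise contrast (GLM-beta scale) values on the cohort lattice."""

    name: str
    values: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("contrast values must be finite")


def generate_contrast_maps(connectivity: ConnectivityMatrix,
                           true_weights: np.ndarray,
                           group_map: np.ndarray,
                           lambda_c: float = 1.0, lambda_g: float = 0.5,
                           noise_sd: float = 0.3, smooth_fwhm: float = 0.0,
                           seed=None, lattice: VoxelLattice | None = None,
                           d2: np.ndarray | None = None,
                           name: str = "contrast") -> ContrastMap:
    """Contrast map = connectivity-driven + group-consistent + noise.

    The connectivity component is C_z @ w with C_z the column-z-scored
    counts; both planted components are standardized before mixing so the
    lambdas are on a common unit-variance scale.  Optional lattice-domain
    Gaussian smoothing (FWHM in voxels) is applied last.
    """
    counts = connectivity.counts.astype(float)
    cz = np.column_stack([zscore(counts[:, j])
                          for j in range(counts.shape[1])])
    signal = cz @ np.asarray(true_weights, dtype=float)
    y = lambda_c * zscore(signal) + lambda_g * zscore(group_map)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    if smooth_fwhm > 0:
        if lattice is None and d2 is None:
            raise ValueError("smoothing needs the lattice or its distances")
        y = smooth_on_lattice(y, lattice, smooth_fwhm, d2=d2)
    return ContrastMap(name=name, values=y)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Generative settings for a synthetic cohort.

    Defaults mirror the emulated study: 24 subjects, 148 cortical targets,
    three contrasts, ~50 expected streamlines per voxel-target (a per-target
    share of 10k streamlines seeded per voxel), 6 mm FWHM smoothing = 4
    voxels at 1.5 mm.
    """

    n_subjects: int = 24
    n_voxels: int = 500
    n_targets: int = 148
    contrasts: tuple = DEFAULT_CONTRASTS
    mean_count: float = 50.0
    spatial_scale: float = 3.0
    subject_jitter_sd: float = 0.3
    lambda_c: float = 1.0
    lambda_g: float = 0.5
    noise_sd: float = 0.3
    smooth_fwhm: float = 4.0
    n_empty_targets: int = 2
    region: str = "synthetic_striatum"

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_voxels < 2 or self.n_targets < 1:
            raise ValueError("need n_voxels >= 2 and n_targets >= 1")
        self.contrasts = tuple(self.contrasts)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrasts"] = list(self.contrasts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)


@dataclass
class SubjectData:
    connectivity: ConnectivityMatrix
    contrasts: dict


@dataclass
class SyntheticCohort:
    lattice: VoxelLattice
    subjects: list
    true_weights: dict
    group_maps: dict
    config: CohortConfig
    metadata: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def observed(self, contrast: str) -> list:
        return [s.contrasts[contrast].values for s in self.subjects]

    def connectivities(self) -> list:
        return [s.connectivity for s in self.subjects]


def generate_cohort(config: CohortConfig, seed=None) -> SyntheticCohort:
    """Full synthetic cohort with planted structure-function ground truth."""
    ss = np.random.SeedSequence(seed)
    s_lat, s_arch, s_truth, s_subj = ss.spawn(4)
    lattice = make_region_geometry(config.n_voxels, seed=s_lat)
    archetype = connectivity_archetype(
        lattice, config.n_targets, config.mean_count, config.spatial_scale,
        seed=s_arch, n_empty=config.n_empty_targets)
    d2 = lattice.pairwise_sq_distances()
    names = default_target_names(config.n_targets)

    rng_truth = np.random.default_rng(s_truth)
    true_weights, group_maps = {}, {}
    for c in config.contrasts:
        true_weights[c] = rng_truth.standard_normal(config.n_targets)
        group_maps[c] = _bump_field(lattice, rng_truth,
                                    2.0 * config.spatial_scale, n_bumps=5)

    subjects = []
    for i, child in enumerate(s_subj.spawn(config.n_subjects)):
        conn_seed, map_seed = child.spawn(2)
        conn = generate_connectivity(
            lattice, subject_jitter_sd=config.subject_jitter_sd,
            seed=conn_seed, archetype=archetype, target_names=names)
        contrast_rng = np.random.default_rng(map_seed)
        contrasts = {}
        for c in config.contrasts:
            contrasts[c] = generate_contrast_maps(
                conn, true_weights[c], group_maps[c],
                lambda_c=config.lambda_c, lambda_g=config.lambda_g,
                noise_sd=config.noise_sd, smooth_fwhm=config.smooth_fwhm,
                seed=contrast_rng, lattice=lattice, d2=d2, name=c)
        subjects.append(SubjectData(connectivity=conn, contrasts=contrasts))

    meta = {"null_link": config.lambda_c == 0.0, "seed": seed}
    return SyntheticCohort(lattice=lattice, subjects=subjects,
                           true_weights=true_weights, group_maps=group_maps,
                           config=config, metadata=meta)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_cohort(cohort: SyntheticCohort, path) -> None:
    """Serialize a cohort as a directory of CSV/JSON/YAML files."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.lattice.to_frame().to_csv(path / "lattice.csv", index=False)
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)
    gt = {"true_weights": {c: w.tolist()
                           for c, w in cohort.true_weights.items()},
          "group_maps": {c: g.tolist() for c, g in cohort.group_maps.items()},
          "metadata": cohort.metadata}
    with open(path / "ground_truth.json", "w") as fh:
        json.dump(gt, fh)
    for i, sub in enumerate(cohort.subjects):
        sub_dir = path / f"sub-{i + 1:02d}"
        sub_dir.mkdir(exist_ok=True)
        sub.connectivity.to_csv(sub_dir / "connectivity.csv")
        for c, cmap in sub.contrasts.items():
            pd.DataFrame({"value": cmap.values}).to_csv(
                sub_dir / f"contrast_{c}.csv", index=False)


def load_cohort(path) -> SyntheticCohort:
    path = Path(path)
    lattice = VoxelLattice.from_frame(pd.read_csv(path / "lattice.csv"))
    with open(path / "config.yaml") as fh:
        config = CohortConfig.from_dict(yaml.safe_load(fh))
    with open(path / "ground_truth.json") as fh:
        gt = json.load(fh)
    subjects = []
    for i in range(config.n_subjects):
        sub_dir = path / f"sub-{i + 1:02d}"
        conn = ConnectivityMatrix.from_csv(sub_dir / "connectivity.csv")
        contrasts = {}
        for c in config.contrasts:
            vals = pd.read_csv(sub_dir / f"contrast_{c}.csv")["value"]
            contrasts[c] = ContrastMap(name=c, values=vals.to_numpy(float))
        subjects.append(SubjectData(connectivity=conn, contrasts=contrasts))
    return SyntheticCohort(
        lattice=lattice, subjects=subjects,
        true_weights={c: np.array(w) for c, w in gt["true_weights"].items()},
        group_maps={c: np.array(g) for c, g in gt["group_maps"].items()},
        config=config, metadata=gt["metadata"])


# ---------------------------------------------------------------------------
# real-data import/export (NIfTI)
# ---------------------------------------------------------------------------

def extract_voxel_values(image_path, mask_path):
    """Voxel values of a NIfTI volume inside a binary NIfTI mask.

    Returns (coords, values): 0-based integer voxel coordinates ordered with
    x varying fastest, and the corresponding image values.
    """
    import nibabel as nib

    img = np.asanyarray(nib.load(str(image_path)).dataobj)
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    zyx = np.argwhere(np.transpose(mask, (2, 1, 0)))
    coords = zyx[:, ::-1].astype(np.int64)
    values = img[coords[:, 0], coords[:, 1], coords[:, 2]].astype(float)
    return coords, values


def values_to_nifti(values, coords, reference_path, out_path) -> None:
    """Write a voxel-value vector back into a reference volume's grid."""
    import nibabel as nib

    ref = nib.load(str(reference_path))
    vol = np.zeros(ref.shape[:3], dtype=np.float32)
    coords = np.asarray(coords, dtype=np.int64)
    vol[coords[:, 0], coords[:, 1], coords[:, 2]] = values
    nib.save(nib.Nifti1Image(vol, ref.affine, ref.header), str(out_path))
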