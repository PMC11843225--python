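"""Synthetic cohorts with planted gradient, dispersion, and behavior structure.

The generator emulates the statistical skeleton of a multi-subject resting
fMRI study: every subject shares K latent spatial gradient maps, perturbed
by subject-specific per-vertex offsets whose standard deviation varies over
the surface (creating contiguous hotspots of cross-subject dispersion).
Run-structured time series are synthesized from the latent coordinates with
slow (low-pass filtered) orthonormal temporal sources plus white noise, and
a behavioral table couples a fluid-intelligence score to the planted
cluster's first-gradient coordinate with a configurable standardized slope.

Everything downstream (embedding, dispersion mapping, inference, topology)
can therefore be checked against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .mesh import MeshTopology, contiguous_patch

__all__ = [
    "TASKS",
    "SurfaceTimeSeries",
    "CohortConfig",
    "GroundTruth",
    "simulate_cohort",
    "synthetic_atlas",
    "write_cohort",
    "read_cohort",
]

#: The ten cognitive tasks entering the intelligence composites.
TASKS = (
    "picture_vocabulary",
    "oral_reading",
    "card_sorting",
    "flanker",
    "list_sorting",
    "progressive_matrices",
    "picture_sequence",
    "pattern_comparison",
    "line_orientation",
    "word_memory",
)

CRYSTALLIZED_TASKS = ("picture_vocabulary", "oral_reading")
FLUID_TASKS = (
    "card_sorting",
    "flanker",
    "list_sorting",
    "progressive_matrices",
    "picture_sequence",
)

COVARIATES = ("age", "sex", "handedness", "education", "fd")


@dataclass
class SurfaceTimeSeries:
    """One subject's vertex x time matrix with run boundaries.

    ``run_boundaries`` is a list of half-open ``(start, stop)`` index pairs
    that partition the time axis in order; every run has >= 2 timepoints.
    """

    subject_id: str
    data: np.ndarray
    run_boundaries: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be vertex x time")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contain non-finite values")
        t = 0
        for start, stop in self.run_boundaries:
            if start != t:
                raise ValueError("run boundaries must partition the time axis")
            if stop - start < 2:
                raise ValueError("each run needs at least 2 timepoints")
            t = stop
        if t != self.data.shape[1]:
            raise ValueError("run boundaries must cover the full time axis")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def runs(self):
        """Yield each run's vertex x time block."""
        for start, stop in self.run_boundaries:
            yield self.data[:, start:stop]


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults are a desk-scale emulation of a resting-state cohort: four
    ~15 min runs become four 150-timepoint runs, three latent gradients with
    distinct spatial variance (first > second > third), small background
    subject offsets with a single contiguous high-dispersion patch, and a
    fluid score coupled to that patch's first-gradient coordinate with a
    signed standardized slope.
    """

    n_subjects: int = 30
    runs: tuple[int, ...] = (150, 150, 150, 150)
    k_latent: int = 3
    #: spatial SD of each planted gradient map (distinct values make the
    #: latent axes identifiable from data)
    gradient_scales: tuple[float, ...] = (3.0, 2.0, 1.2)
    #: background cross-subject SD of per-vertex gradient coordinates
    offset_sd: float = 0.25
    #: cross-subject SD inside the planted cluster
    cluster_sd: float = 1.0
    #: planted cluster size in vertices (contiguous mesh patch)
    cluster_n_vertices: int = 30
    #: standardized slope of fluid score on the cluster's gradient-1 mean
    behavior_effect: float = -0.4
    covariate_effects: dict = field(
        default_factory=lambda: {
            "age": -0.10,
            "sex": 0.10,
            "handedness": 0.0,
            "education": 0.20,
            "fd": -0.10,
        }
    )
    noise_sd: float = 2.0
    #: temporal smoothing (Gaussian sigma in timepoints) applied to the
    #: latent sources before orthonormalization; emulates the slow dynamics
    #: that dominate resting fMRI
    source_smooth_sigma: float = 3.0
    seed: int = 0
    # explicit overrides; None -> derived defaults on the mesh
    gradient_maps: np.ndarray | None = None
    dispersion_profile: np.ndarray | None = None
    planted_cluster: np.ndarray | None = None

    def validate(self, mesh: MeshTopology) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(t < 2 for t in self.runs):
            raise ValueError("every run needs length >= 2")
        total_t = sum(self.runs)
        if self.k_latent > min(mesh.n_vertices, total_t):
            raise ValueError("k_latent exceeds rank constraints")
        if min(self.runs) < self.k_latent:
            raise ValueError("each run must have at least k_latent timepoints")
        if len(self.gradient_scales) != self.k_latent and self.gradient_maps is None:
            raise ValueError("gradient_scales must have k_latent entries")
        if self.dispersion_profile is not None and np.any(
            np.asarray(self.dispersion_profile) < 0
        ):
            raise ValueError("dispersion_profile must be nonnegative")
        if self.planted_cluster is not None:
            pc = np.asarray(self.planted_cluster)
            if pc.size and (pc.min() < 0 or pc.max() >= mesh.n_vertices):
                raise ValueError("planted_cluster outside the vertex set")
            if pc.size == 0 and self.behavior_effect != 0:
                raise ValueError(
                    "empty planted_cluster is incompatible with a nonzero "
                    "behavior_effect"
                )


@dataclass
class GroundTruth:
    """Planted quantities the downstream stages should recover."""

    coords: np.ndarray  # (n_subjects, n_vertices, k) true gradient coords
    gradient_maps: np.ndarray  # (n_vertices, k) group-level maps
    cluster_mask: np.ndarray  # (n_vertices,) bool
    behavior_effect: float
    dispersion_sd: np.ndarray  # (n_vertices,) per-vertex offset SD
    expected_dispersion: np.ndarray  # (n_vertices,) E[total sum-of-squares]


def default_gradient_maps(mesh: MeshTopology, scales) -> np.ndarray:
    """Smooth orthogonal spatial patterns on the mesh.

    Three low-order polynomial surfaces of the planar coordinates are
    orthogonalized against the constant and each other, then scaled to the
    requested per-map spatial SD.
    """
    x = mesh.coords[:, 0] - mesh.coords[:, 0].mean()
    y = mesh.coords[:, 1] - mesh.coords[:, 1].mean()
    raw = [x, y, x * y, x**2 - y**2, x**2 + y**2, x * y * y]
    k = len(scales)
    if k > len(raw):
        raise ValueError(f"at most {len(raw)} default gradient maps available")
    basis = np.column_stack([np.ones_like(x)] + raw[:k])
    q, _ = np.linalg.qr(basis)
    maps = q[:, 1 : k + 1]  # orthogonal to the constant and to one another
    maps = maps / maps.std(axis=0, ddof=0)
    return maps * np.asarray(scales)


def _latent_sources(rng, n_t: int, k: int, smooth_sigma: float) -> np.ndarray:
    """Zero-mean, mutually orthogonal slow sources with unit per-timepoint
    variance (columns of the returned (n_t, k) matrix)."""
    x = rng.standard_normal((n_t, k))
    if smooth_sigma > 0:
        x = gaussian_filter1d(x, sigma=smooth_sigma, axis=0, mode="wrap")
    x = x - x.mean(axis=0)
    q, r = np.linalg.qr(x)
    q = q * np.sign(np.diag(r))  # deterministic sign
    return q * np.sqrt(n_t)


def simulate_cohort(
    mesh: MeshTopology, config: CohortConfig
) -> tuple[list[SurfaceTimeSeries], pd.DataFrame, GroundTruth]:
    """Simulate time series, a behavioral table, and ground truth.

    The subject-s time series at vertex v is
    ``sum_k coords(s, v, k) * source_k(t) + noise`` with
    ``coords(s, v, k) = gradient_map_k(v) + offset(s, v, k)`` and offsets
    drawn with per-vertex SD from the dispersion profile. Identical
    (mesh, config) including the seed reproduce bit-identical outputs.
    """
    config.validate(mesh)
    n_v = mesh.n_vertices
    k = config.k_latent
    ss = np.random.SeedSequence(config.seed)
    rng_sources, rng_offsets, rng_noise, rng_behavior = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    if config.gradient_maps is not None:
        maps = np.asarray(config.gradient_maps, dtype=float)
        if maps.shape != (n_v, k):
            raise ValueError("gradient_maps must be (n_vertices, k_latent)")
    else:
        maps = default_gradient_maps(mesh, config.gradient_scales)

    if config.planted_cluster is not None:
        cluster = np.asarray(config.planted_cluster, dtype=np.int64)
    else:
        seed_vertex = n_v // 2
        cluster = contiguous_patch(mesh, seed_vertex, config.cluster_n_vertices)
    cluster_mask = np.zeros(n_v, dtype=bool)
    cluster_mask[cluster] = True

    if config.dispersion_profile is not None:
        disp_sd = np.asarray(config.dispersion_profile, dtype=float)
        if disp_sd.shape != (n_v,):
            raise ValueError("dispersion_profile must be per-vertex")
    else:
        disp_sd = np.full(n_v, config.offset_sd)
        disp_sd[cluster_mask] = config.cluster_sd

    # per-subject true coordinates
    offsets = rng_offsets.standard_normal((config.n_subjects, n_v, k))
    offsets *= disp_sd[None, :, None]
    coords = maps[None, :, :] + offsets

    # shared latent sources per run
    sources = [
        _latent_sources(rng_sources, t, k, config.source_smooth_sigma)
        for t in config.runs
    ]
    boundaries = []
    t0 = 0
    for t in config.runs:
        boundaries.append((t0, t0 + t))
        t0 += t

    subjects = []
    for s in range(config.n_subjects):
        blocks = [coords[s] @ src.T for src in sources]
        data = np.concatenate(blocks, axis=1)
        if config.noise_sd > 0:
            data = data + config.noise_sd * rng_noise.standard_normal(data.shape)
        subjects.append(
            SurfaceTimeSeries(
                subject_id=f"sub-{s:04d}",
                data=data,
                run_boundaries=list(boundaries),
            )
        )

    behavior = _simulate_behavior(config, coords, cluster_mask, rng_behavior)
    behavior.insert(0, "subject_id", [ts.subject_id for ts in subjects])

    # E[sum_s sum_k (x - mean)^2] = (n-1) * k * sd^2
    expected = (config.n_subjects - 1) * k * disp_sd**2
    truth = GroundTruth(
        coords=coords,
        gradient_maps=maps,
        cluster_mask=cluster_mask,
        behavior_effect=config.behavior_effect,
        dispersion_sd=disp_sd,
        expected_dispersion=expected,
    )
    return subjects, behavior, truth


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _simulate_behavior(config, coords, cluster_mask, rng) -> pd.DataFrame:
    """Covariates, latent abilities, and raw task scores.

    The fluid latent is ``behavior_effect * z(cluster gradient-1 mean) +
    covariate terms + noise`` with the noise SD chosen so the latent has
    unit variance in expectation (the slope is then the expected Pearson r).
    Task scores load on the latents and are emitted on a mean-100/SD-15
    raw scale.
    """
    n = config.n_subjects
    age = np.clip(rng.normal(28.6, 3.6, n), 22.0, 36.0)
    sex = rng.integers(0, 2, n).astype(float)
    handedness = np.clip(rng.normal(0.6, 0.5, n), -1.0, 1.0)
    education = rng.integers(11, 18, n).astype(float)
    fd = rng.uniform(0.04, 0.24, n)
    cov = {"age": age, "sex": sex, "handedness": handedness, "education": education, "fd": fd}

    if cluster_mask.any():
        cluster_coord = coords[:, cluster_mask, 0].mean(axis=1)
        z_cluster = _zscore(cluster_coord)
    else:
        z_cluster = np.zeros(n)

    effects = config.covariate_effects
    cov_term = sum(effects.get(name, 0.0) * _zscore(cov[name]) for name in COVARIATES)
    explained = config.behavior_effect**2 + sum(
        effects.get(name, 0.0) ** 2 for name in COVARIATES
    )
    eps_sd = np.sqrt(max(1.0 - explained, 0.05))
    fluid = config.behavior_effect * z_cluster + cov_term + eps_sd * rng.standard_normal(n)
    crystallized = 0.3 * _zscore(cov["education"]) + np.sqrt(1 - 0.09) * rng.standard_normal(n)
    g_latent = (fluid + crystallized) / np.sqrt(2.0)

    table = dict(cov)
    loading = 0.7
    resid = np.sqrt(1 - loading**2)
    for task in TASKS:
        if task in FLUID_TASKS:
            latent = fluid
        elif task in CRYSTALLIZED_TASKS:
            latent = crystallized
        else:
            latent = g_latent
        z = loading * latent + resid * rng.standard_normal(n)
        table[task] = 100.0 + 15.0 * z
    frame = pd.DataFrame(table)
    frame["fluid_latent"] = fluid
    frame["cluster_g1_true"] = z_cluster
    return frame


# ---------------------------------------------------------------------------
# synthetic parcellation atlas

ATLAS_NETWORKS = (
    "Vis",
    "SomMot",
    "DorsAttn",
    "SalVentAttn",
    "Limbic",
    "Cont",
    "Default",
)


def synthetic_atlas(mesh: MeshTopology, n_parcels: int = 20) -> pd.DataFrame:
    """Block parcellation of the planar mesh with 7-network communities.

    Returns a DataFrame with columns ``vertex``, ``parcel``, ``network``.
    Parcels are contiguous rectangular blocks; networks are assigned
    cyclically, so every canonical network is represented when
    ``n_parcels >= 7``.
    """
    if n_parcels < 1 or n_parcels > mesh.n_vertices:
        raise ValueError("n_parcels out of range")
    x, y = mesh.coords[:, 0], mesh.coords[:, 1]
    n_bx = max(int(np.round(np.sqrt(n_parcels))), 1)
    n_by = int(np.ceil(n_parcels / n_bx))
    bx = np.minimum((np.argsort(np.argsort(x, kind="stable"), kind="stable") * n_bx) // x.size, n_bx - 1)
    by = np.minimum((np.argsort(np.argsort(y, kind="stable"), kind="stable") * n_by) // y.size, n_by - 1)
    parcel = bx * n_by + by
    # compact labels (drop empty blocks beyond n_parcels)
    uniq, parcel = np.unique(parcel, return_inverse=True)
    frame = pd.DataFrame(
        {
            "vertex": np.arange(mesh.n_vertices),
            "parcel": parcel,
            "network": [ATLAS_NETWORKS[p % len(ATLAS_NETWORKS)] for p in parcel],
        }
    )
    return frame


# ---------------------------------------------------------------------------
# cohort directory I/O

def write_cohort(
    out_dir,
    mesh: MeshTopology,
    subjects: list[SurfaceTimeSeries],
    behavior: pd.DataFrame,
    truth: GroundTruth,
    config: CohortConfig | None = None,
) -> None:
    """Write a cohort directory: per-subject ``.npy`` arrays, ``mesh.json``,
    ``behavior.tsv``, ``truth.npz`` (+ ``truth.json`` with scalar fields)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mesh.to_json(out / "mesh.json")
    run_boundaries = subjects[0].run_boundaries
    for ts in subjects:
        np.save(out / f"{ts.subject_id}.npy", ts.data)
    behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    np.savez(
        out / "truth.npz",
        coords=truth.coords,
        gradient_maps=truth.gradient_maps,
        cluster_mask=truth.cluster_mask,
        dispersion_sd=truth.dispersion_sd,
        expected_dispersion=truth.expected_dispersion,
    )
    meta = {
        "subjects": [ts.subject_id for ts in subjects],
        "run_boundaries": [list(b) for b in run_boundaries],
        "behavior_effect": truth.behavior_effect,
    }
    if config is not None:
        cfg = dataclasses.asdict(config)
        for key in ("gradient_maps", "dispersion_profile", "planted_cluster"):
            val = cfg.pop(key)
            if val is not None:
                cfg[key] = np.asarray(val).tolist()
        cfg["runs"] = list(cfg["runs"])
        cfg["gradient_scales"] = list(cfg["gradient_scales"])
        meta["config"] = cfg
    with open(out / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_cohort(in_dir):
    """Read a cohort directory written by :func:`write_cohort`.

    Returns ``(mesh, subjects, behavior, truth)``.
    """
    src = Path(in_dir)
    mesh = MeshTopology.from_json(src / "mesh.json")
    with open(src / "truth.json") as fh:
        meta = json.load(fh)
    boundaries = [tuple(b) for b in meta["run_boundaries"]]
    subjects = [
        SurfaceTimeSeries(sid, np.load(src / f"{sid}.npy"), list(boundaries))
        for sid in meta["subjects"]
    ]
    behavior = pd.read_csv(src / "behavior.tsv", sep="\t")
    npz = np.load(src / "truth.npz")
    truth = GroundTruth(
        coords=npz["coords"],
        gradient_maps=npz["gradient_maps"],
        cluster_mask=npz["cluster_mask"],
        behavior_effect=float(meta["behavior_effect"]),
        dispersion_sd=npz["dispersion_sd"],
        expected_dispersion=npz["expected_dispersion"],
    )
    return mesh, subjects, behavior, truth
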