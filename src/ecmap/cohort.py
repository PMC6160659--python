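"""Synthetic resting-state cohort generator.

Builds a cohort of 4D BOLD runs, head-motion traces and phenotype records
with the statistical structure the downstream analysis assumes: voxel
communities driven by band-limited latent signals, a planted "hub" community
whose shared-signal loading is reduced in genetic-risk carriers, and
phenotype markers with configurable signed coupling to the planted hub
signal.  Everything is deterministic given the spec's seed.

The generator is first-class, tested code: it is the only data source the
analysis pipeline is exercised on.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecm import BoldRun

__all__ = [
    "CohortSpec",
    "MotionTrace",
    "GroundTruth",
    "generate_cohort",
    "generate_null_cohort",
    "generate_subject_bold",
    "default_community_layout",
]

# Female fraction and marker scales mirror the study cohort's summary table
# (261 subjects, 110 male / 151 female, age 56.6 +/- 6.7, NGMV 0.452 +/- 0.019,
# Framingham 6.46 +/- 6.17, 15OT 13.1 +/- 1.78, MMSE 29.1 +/- 0.8).
_FEMALE_FRACTION = 151.0 / 261.0

_DEFAULT_MARKER_SLOPES: dict[str, float] = {
    "age": -1.7,
    "csf_amyloid": 50.0,
    "ngmv": -0.005,
    "score_15ot": 0.45,
    "tmt_a_s": 3.5,
    "tmt_b_s": 8.0,
}

_DEFAULT_MARKER_NOISE_SD: dict[str, float] = {
    "age": 6.5,
    "csf_amyloid": 195.0,
    "ngmv": 0.018,
    "score_15ot": 1.7,
    "tmt_a_s": 14.0,
    "tmt_b_s": 34.0,
}

_DEFAULT_COVARIATE_DISTRIBUTIONS: dict[str, tuple[float, float, tuple[float, float]]] = {
    "age": (56.6, 6.7, (39.0, 80.0)),
    "csf_amyloid": (1000.0, 200.0, (200.0, 2000.0)),
    "ngmv": (0.452, 0.019, (0.35, 0.55)),
    "score_15ot": (13.1, 1.78, (0.0, 15.0)),
    "tmt_a_s": (40.0, 15.0, (8.0, 300.0)),
    "tmt_b_s": (90.0, 35.0, (15.0, 600.0)),
    "framingham": (6.46, 6.17, (0.0, 40.0)),
}


def default_community_layout(
    grid_shape: tuple[int, int, int], n_communities: int
) -> dict[int, np.ndarray]:
    """Carve ``n_communities`` disjoint cuboid communities out of the grid.

    Blocks are tiled over the x/y plane in the axial mid-section of the
    volume, leaving a background of pure-noise voxels around them, so that a
    community occupies a compact contiguous region (community 0 is placed at
    the largest y coordinates — the "posterior" hub position).

    Returns a map community-id -> flat voxel indices (C order).
    """
    nx, ny, nz = grid_shape
    n_cols = int(np.ceil(np.sqrt(n_communities)))
    n_rows = int(np.ceil(n_communities / n_cols))
    # block extents with a 1-voxel gutter between blocks where space allows
    bx = max(2, nx // n_cols - 1)
    by = max(2, ny // n_rows - 1)
    z0 = nz // 3
    z1 = max(z0 + 2, (2 * nz) // 3)
    layout: dict[int, np.ndarray] = {}
    cid = 0
    # fill from high y (posterior) downwards so community 0 sits posterior
    for row in range(n_rows):
        y_hi = ny - row * (by + 1)
        y_lo = y_hi - by
        if y_lo < 0:
            break
        for col in range(n_cols):
            if cid >= n_communities:
                break
            x_lo = col * (bx + 1)
            x_hi = min(nx, x_lo + bx)
            if x_hi - x_lo < 2:
                continue
            block = np.zeros(grid_shape, dtype=bool)
            block[x_lo:x_hi, y_lo:y_hi, z0:z1] = True
            layout[cid] = np.flatnonzero(block.ravel())
            cid += 1
    if cid < n_communities:
        raise ValueError(
            f"grid {grid_shape} too small to place {n_communities} communities"
        )
    return layout


@dataclass
class CohortSpec:
    """Full parameterization of the synthetic cohort.

    Defaults mirror the study scale: 261 subjects of whom 29% carry the risk
    allele, 325 volumes at TR 1.82 s on a 4 mm isotropic grid.  The grid
    itself is desk-scale (20 x 20 x 12 voxels), not a full brain.
    """

    n_subjects: int = 261
    carrier_fraction: float = 0.29
    grid_shape: tuple[int, int, int] = (20, 20, 12)
    voxel_size_mm: float = 4.0
    n_timepoints: int = 325
    tr_s: float = 1.82
    n_communities: int = 6
    community_layout: dict[int, np.ndarray] | None = None
    hub_community_id: int = 0
    base_global_loading: float = 0.5
    background_global_loading: float = 0.2
    hub_global_loading: float = 1.0
    carrier_hub_deficit: float = 0.3
    noise_sd: float = 1.0
    subject_loading_sd: float = 0.25
    marker_slopes: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MARKER_SLOPES)
    )
    marker_noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MARKER_NOISE_SD)
    )
    covariate_distributions: dict[str, tuple[float, float, tuple[float, float]]] = field(
        default_factory=lambda: dict(_DEFAULT_COVARIATE_DISTRIBUTIONS)
    )
    motion_sd_mm: float = 0.05
    motion_artifact_loading: float = 0.0
    partial_coverage_fraction: float = 0.2
    partial_coverage_slices: int = 2
    band_hz: tuple[float, float] = (0.01, 0.1)
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError(f"carrier_fraction {self.carrier_fraction} not in [0, 1]")
        if not 0.0 <= self.carrier_hub_deficit <= 1.0:
            raise ValueError(
                f"carrier_hub_deficit {self.carrier_hub_deficit} not in [0, 1]"
            )
        if self.hub_global_loading < 0 or self.base_global_loading < 0:
            raise ValueError("global-signal loadings must be >= 0")
        for name, sd in [
            ("noise_sd", self.noise_sd),
            ("subject_loading_sd", self.subject_loading_sd),
            ("motion_sd_mm", self.motion_sd_mm),
        ]:
            if sd < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(sd < 0 for sd in self.marker_noise_sd.values()):
            raise ValueError("marker_noise_sd values must be >= 0")
        if self.n_subjects < 1 or self.n_timepoints < 2:
            raise ValueError("need n_subjects >= 1 and n_timepoints >= 2")
        if self.community_layout is None:
            self.community_layout = default_community_layout(
                self.grid_shape, self.n_communities
            )
        if self.hub_community_id not in self.community_layout:
            raise ValueError(
                f"hub_community_id {self.hub_community_id} not in community_layout"
            )
        flat = np.concatenate([np.asarray(v) for v in self.community_layout.values()])
        if len(np.unique(flat)) != len(flat):
            raise ValueError("community_layout blocks must be disjoint")
        if flat.max() >= int(np.prod(self.grid_shape)):
            raise ValueError("community_layout indexes outside the grid")

    @property
    def n_carriers(self) -> int:
        return int(round(self.carrier_fraction * self.n_subjects))

    def hub_mask(self) -> np.ndarray:
        """Boolean 3D mask of the planted hub community."""
        mask = np.zeros(int(np.prod(self.grid_shape)), dtype=bool)
        mask[self.community_layout[self.hub_community_id]] = True
        return mask.reshape(self.grid_shape)


@dataclass
class MotionTrace:
    """Six rigid-body realignment parameters per volume.

    ``params`` is (T, 6): three translations in mm, three rotations in
    radians.  ``mean_displacement_mm`` is a framewise-displacement style
    summary (mean over frames of the L1 translation step plus 50 mm times the
    L1 rotation step), comparable to the mean relative voxel displacement
    used for subject exclusion.
    """

    params: np.ndarray
    mean_displacement_mm: float

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be (T, 6)")
        if self.mean_displacement_mm < 0:
            raise ValueError("mean displacement must be >= 0")

    def save(self, path) -> None:
        np.savetxt(path, self.params, fmt="%.8f")

    @classmethod
    def load(cls, path) -> "MotionTrace":
        params = np.loadtxt(path, ndmin=2)
        return cls(params=params, mean_displacement_mm=framewise_displacement(params))


def framewise_displacement(params: np.ndarray) -> float:
    """Mean framewise displacement of a (T, 6) realignment trace.

    Rotations are converted to arc length on a 50 mm sphere, the standard
    convention for FD-style motion summaries.
    """
    params = np.asarray(params, dtype=np.float64)
    if params.shape[0] < 2:
        return 0.0
    steps = np.abs(np.diff(params, axis=0))
    fd = steps[:, :3].sum(axis=1) + 50.0 * steps[:, 3:].sum(axis=1)
    return float(fd.mean())


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort, for validation and scoring."""

    hub_mask: np.ndarray
    group: np.ndarray
    hub_loadings: np.ndarray
    loading_z: np.ndarray
    marker_slopes: dict[str, float]
    carrier_hub_deficit: float
    seed: int

    def to_json(self) -> str:
        payload = {
            "hub_voxels": np.flatnonzero(self.hub_mask.ravel()).tolist(),
            "grid_shape": list(self.hub_mask.shape),
            "group": self.group.tolist(),
            "hub_loadings": self.hub_loadings.tolist(),
            "loading_z": self.loading_z.tolist(),
            "marker_slopes": self.marker_slopes,
            "carrier_hub_deficit": self.carrier_hub_deficit,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=1)


def _band_limited_signal(rng: np.random.Generator, n: int, tr_s: float,
                         band_hz: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian series band-limited to ``band_hz`` via FFT."""
    x = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=tr_s)
    spec = np.fft.rfft(x)
    keep = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not keep.any():  # degenerate short series: keep all non-DC bins
        keep = freqs > 0
    spec[~keep] = 0.0
    y = np.fft.irfft(spec, n=n)
    sd = y.std()
    return y / sd if sd > 0 else y


def _subject_seeds(spec: CohortSpec) -> tuple[np.random.SeedSequence, list[np.random.SeedSequence]]:
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_subjects + 1)
    return children[0], children[1:]


def _cohort_level_draws(spec: CohortSpec, rng: np.random.Generator):
    """Group labels, per-subject loadings, motion scales, coverage flags.

    Every community's signal loading and base global loading carries
    independent per-subject lognormal jitter (individual differences in
    network strength are not confined to the hub); the hub's extra global
    loading carries the group deficit on top of its own jitter.
    """
    n = spec.n_subjects
    group = np.zeros(n, dtype=np.int64)
    group[: spec.n_carriers] = 1
    rng.shuffle(group)
    base = spec.hub_global_loading * (1.0 - spec.carrier_hub_deficit * group)
    subject_jitter = np.exp(rng.normal(0.0, spec.subject_loading_sd, size=n))
    hub_loadings = base * subject_jitter
    n_comm = len(spec.community_layout)
    comm_loadings = np.exp(rng.normal(0.0, spec.subject_loading_sd, size=(n, n_comm)))
    base_global = spec.base_global_loading * np.exp(
        rng.normal(0.0, spec.subject_loading_sd, size=(n, n_comm))
    )
    bg_global = spec.background_global_loading * np.exp(
        rng.normal(0.0, spec.subject_loading_sd, size=n)
    )
    motion_scale = np.exp(rng.normal(0.0, 0.4, size=n))
    n_partial = int(round(spec.partial_coverage_fraction * n))
    partial = np.zeros(n, dtype=bool)
    if n_partial > 0:
        partial[rng.choice(n, size=n_partial, replace=False)] = True
    return (group, hub_loadings, comm_loadings, base_global, bg_global,
            motion_scale, partial)


def _generate_motion(spec: CohortSpec, rng: np.random.Generator,
                     scale: float) -> MotionTrace:
    t = spec.n_timepoints
    trans = np.cumsum(rng.normal(0.0, spec.motion_sd_mm * scale, size=(t, 3)), axis=0)
    rots = np.cumsum(rng.normal(0.0, spec.motion_sd_mm * scale / 50.0, size=(t, 3)), axis=0)
    params = np.hstack([trans, rots])
    return MotionTrace(params=params, mean_displacement_mm=framewise_displacement(params))


def generate_subject_bold(
    spec: CohortSpec,
    rng: np.random.Generator,
    hub_loading: float,
    motion: MotionTrace | None = None,
    partial_coverage: bool = False,
    community_loadings: np.ndarray | None = None,
    base_global_loadings: np.ndarray | None = None,
    background_global_loading: float | None = None,
) -> BoldRun:
    """Build one subject's 4D BOLD run.

    Every community voxel loads on a band-limited latent community signal
    plus, with the base loading, on a shared global signal (what makes the
    network a network); hub voxels load the global signal additionally with
    the subject's ``hub_loading``, so a reduced hub loading weakens the
    hub's correlations with the whole network, not just within itself.
    White noise is added everywhere on top of a positive baseline.  With
    ``partial_coverage`` the top axial slices are zeroed, which the
    single-subject temporal-minimum mask later excludes.
    """
    t = spec.n_timepoints
    n_vox = int(np.prod(spec.grid_shape))
    global_sig = _band_limited_signal(rng, t, spec.tr_s, spec.band_hz)
    comm_ids = sorted(spec.community_layout)
    comm_sigs = {
        cid: _band_limited_signal(rng, t, spec.tr_s, spec.band_hz) for cid in comm_ids
    }
    if community_loadings is None:
        community_loadings = np.ones(len(comm_ids))
    if base_global_loadings is None:
        base_global_loadings = np.full(len(comm_ids), spec.base_global_loading)
    if background_global_loading is None:
        background_global_loading = spec.background_global_loading
    data = rng.normal(0.0, spec.noise_sd, size=(n_vox, t))
    # weak global coupling outside the communities: no voxel is pure noise
    in_community = np.zeros(n_vox, dtype=bool)
    for idx in spec.community_layout.values():
        in_community[idx] = True
    data[~in_community] += background_global_loading * global_sig
    for k, cid in enumerate(comm_ids):
        idx = spec.community_layout[cid]
        data[idx] += (community_loadings[k] * comm_sigs[cid]
                      + base_global_loadings[k] * global_sig)
        if cid == spec.hub_community_id:
            data[idx] += hub_loading * global_sig
    if spec.motion_artifact_loading > 0 and motion is not None:
        nuisance = motion.params[:, 0] - motion.params[:, 0].mean()
        sd = nuisance.std()
        if sd > 0:
            data += spec.motion_artifact_loading * (nuisance / sd)
    data += spec.baseline
    vol = data.reshape(*spec.grid_shape, t).astype(np.float32)
    if partial_coverage and spec.partial_coverage_slices > 0:
        vol[:, :, -spec.partial_coverage_slices:, :] = 0.0
    return BoldRun(data=vol, tr_s=spec.tr_s, voxel_size_mm=spec.voxel_size_mm)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float], size: int) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds are generous; fast)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < bounds[0]) | (out > bounds[1])
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < bounds[0]) | (out > bounds[1])
    return out


def _generate_phenotypes(spec: CohortSpec, rng: np.random.Generator,
                         group: np.ndarray, loading_z: np.ndarray) -> pd.DataFrame:
    n = spec.n_subjects
    records: dict[str, np.ndarray] = {
        "subject_id": np.array([f"sub-{i:03d}" for i in range(n)]),
        "group": group,
        "gender": (rng.random(n) < _FEMALE_FRACTION).astype(np.int64),
    }
    for name in ["age", "csf_amyloid", "ngmv", "score_15ot", "tmt_a_s", "tmt_b_s"]:
        mean, _sd, bounds = spec.covariate_distributions[name]
        slope = spec.marker_slopes.get(name, 0.0)
        noise = spec.marker_noise_sd.get(name, 0.0)
        vals = mean + slope * loading_z + rng.normal(0.0, noise, size=n)
        vals = np.clip(vals, bounds[0], bounds[1])
        records[name] = vals
    records["score_15ot"] = np.round(records["score_15ot"]).clip(0, 15).astype(np.int64)
    fr_mean, fr_sd, fr_bounds = spec.covariate_distributions["framingham"]
    records["framingham"] = _truncated_normal(rng, fr_mean, fr_sd, fr_bounds, n)
    records["mmse"] = rng.choice([28, 29, 30], size=n, p=[0.2, 0.45, 0.35])
    records["usable"] = np.ones(n, dtype=bool)
    df = pd.DataFrame(records)
    return df[
        ["subject_id", "group", "gender", "age", "ngmv", "framingham",
         "csf_amyloid", "score_15ot", "tmt_a_s", "tmt_b_s", "mmse", "usable"]
    ]


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[BoldRun], list[MotionTrace], pd.DataFrame, GroundTruth]:
    """Generate the full synthetic cohort.

    Returns per-subject BOLD runs and motion traces, the phenotype table,
    and the ground-truth record of the planted structure.  Identical
    ``spec`` (including seed) reproduces bit-identical outputs.
    """
    cohort_seed, subj_seeds = _subject_seeds(spec)
    cohort_rng = np.random.default_rng(cohort_seed)
    (group, hub_loadings, comm_loadings, base_global, bg_global,
     motion_scale, partial) = _cohort_level_draws(spec, cohort_rng)
    sd = hub_loadings.std()
    loading_z = (hub_loadings - hub_loadings.mean()) / sd if sd > 0 else np.zeros_like(hub_loadings)
    table = _generate_phenotypes(spec, cohort_rng, group, loading_z)

    runs: list[BoldRun] = []
    traces: list[MotionTrace] = []
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(subj_seeds[i])
        trace = _generate_motion(spec, rng, motion_scale[i])
        run = generate_subject_bold(
            spec, rng, hub_loadings[i], motion=trace,
            partial_coverage=bool(partial[i]),
            community_loadings=comm_loadings[i],
            base_global_loadings=base_global[i],
            background_global_loading=float(bg_global[i]),
        )
        runs.append(run)
        traces.append(trace)

    truth = GroundTruth(
        hub_mask=spec.hub_mask(),
        group=group,
        hub_loadings=hub_loadings,
        loading_z=loading_z,
        marker_slopes=dict(spec.marker_slopes),
        carrier_hub_deficit=spec.carrier_hub_deficit,
        seed=spec.seed,
    )
    return runs, traces, table, truth


def generate_null_cohort(
    spec: CohortSpec,
) -> tuple[list[BoldRun], list[MotionTrace], pd.DataFrame, GroundTruth]:
    """Same pipeline with the planted effect and all marker couplings removed.

    Group labels are still assigned (carrier count preserved) but carry no
    signal; the returned ground truth reports a zero deficit and zero slopes.
    """
    null_spec = dataclasses.replace(
        spec,
        carrier_hub_deficit=0.0,
        marker_slopes={k: 0.0 for k in spec.marker_slopes},
        community_layout={k: np.asarray(v) for k, v in spec.community_layout.items()},
    )
    return generate_cohort(null_spec)
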