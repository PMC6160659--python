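"""Eigenvector centrality mapping of masked 4D BOLD data.

Voxelwise connectivity is the shifted Pearson correlation C = R + 1, whose
entries live on the positive scale [0, 2]; by Perron-Frobenius its dominant
eigenvector is strictly positive and serves as the centrality map.  Because
C = M M^T + J for the row-normalized data matrix M (N voxels x T timepoints)
and the all-ones matrix J, the power-iteration matrix-vector product is
evaluated as M (M^T v) + (sum v) 1 at O(N*T) cost per iteration, without
ever materializing the N x N matrix R.

Also houses the temporal-minimum brain masks, the discrete-cosine high-pass
filter and the motion-parameter nuisance regression that precede the
centrality computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "BoldRun",
    "NormalizedMatrix",
    "CentralityMap",
    "single_subject_mask",
    "intersection_mask",
    "variance_mask",
    "highpass_filter",
    "dct_highpass_basis",
    "regress_motion",
    "normalize_timeseries",
    "fast_ecm",
    "ecm_pair",
    "save_volume",
    "load_bold",
]


@dataclass
class BoldRun:
    """One subject's 4D BOLD array (x, y, z, t) on the common grid."""

    data: np.ndarray
    tr_s: float
    voxel_size_mm: float = 4.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("BOLD run needs at least 2 timepoints")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class NormalizedMatrix:
    """Masked voxel time series, each row mean-zero with unit L2 norm.

    The dot product of any two rows is their Pearson correlation, so the
    shifted connectivity entry between voxels i and j is ``rows[i] @ rows[j]
    + 1`` on the scale [0, 2].
    """

    rows: np.ndarray            # (N, T)
    coords: np.ndarray          # (N, 3) voxel coordinates, row order
    grid_shape: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return self.rows.shape[0]

    def connectivity_entry(self, i: int, j: int) -> float:
        """Probe a single entry of C = R + 1 without building C."""
        return float(self.rows[i] @ self.rows[j] + 1.0)


@dataclass
class CentralityMap:
    """Voxelwise eigenvector centrality on the analysis mask.

    ``values`` is unit-L2-norm and strictly positive (Perron-Frobenius);
    ordering matches the ``NormalizedMatrix`` rows / ``mask`` voxels in C
    order.
    """

    values: np.ndarray
    mask: np.ndarray
    iterations_used: int
    converged: bool

    def to_volume(self) -> np.ndarray:
        """Centrality as a 3D volume, zeros off-mask."""
        vol = np.zeros(self.mask.shape, dtype=np.float64)
        vol[self.mask] = self.values
        return vol


# ---------------------------------------------------------------------------
# masks

def single_subject_mask(run: BoldRun) -> np.ndarray:
    """Brain mask from the temporal minimum: true where min over t is > 0."""
    mask = run.data.min(axis=3) > 0
    if not mask.any():
        raise ValueError("single-subject mask is empty; run unusable")
    return mask


def intersection_mask(masks: list[np.ndarray]) -> np.ndarray:
    """Voxelwise AND of single-subject masks (the common analysis mask)."""
    if not masks:
        raise ValueError("no masks given")
    out = masks[0].copy()
    for m in masks[1:]:
        if m.shape != out.shape:
            raise ValueError("masks must share the grid")
        out &= m
    if not out.any():
        raise ValueError("intersection of masks is empty")
    return out


def variance_mask(run: BoldRun, mask: np.ndarray) -> np.ndarray:
    """Shrink ``mask`` to voxels with nonzero temporal variance."""
    sub = run.data[mask]
    keep = sub.std(axis=1) > 0
    out = np.zeros_like(mask)
    out[mask] = keep
    return out


# ---------------------------------------------------------------------------
# temporal preprocessing

def dct_highpass_basis(n_timepoints: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift basis spanning periods longer than ``cutoff_s``.

    The k-th regressor is cos(pi k (t + 1/2) / T); its period is 2 T TR / k
    seconds, so the order is K = floor(2 T TR / cutoff_s).  Returns a (T, K)
    array (K may be 0).
    """
    t_total = n_timepoints * tr_s
    order = int(np.floor(2.0 * t_total / cutoff_s))
    t = np.arange(n_timepoints)
    basis = np.stack(
        [np.cos(np.pi * k * (t + 0.5) / n_timepoints) for k in range(1, order + 1)],
        axis=1,
    ) if order >= 1 else np.empty((n_timepoints, 0))
    return basis


def highpass_filter(run: BoldRun, cutoff_s: float) -> BoldRun:
    """Remove slow drifts with period above ``cutoff_s`` seconds.

    Regresses out an intercept plus the discrete-cosine drift basis from
    every voxel's series; the output is mean-zero per voxel.  If the cutoff
    admits no basis function the data are returned unchanged (a warning is
    issued), still demeaned for consistency.
    """
    if cutoff_s <= 2.0 * run.tr_s:
        raise ValueError(
            f"cutoff {cutoff_s} s must exceed twice the TR ({run.tr_s} s)"
        )
    basis = dct_highpass_basis(run.n_timepoints, run.tr_s, cutoff_s)
    shape = run.data.shape
    flat = run.data.reshape(-1, shape[3]).astype(np.float64)
    flat = flat - flat.mean(axis=1, keepdims=True)
    if basis.shape[1] == 0:
        warnings.warn(
            f"high-pass cutoff {cutoff_s} s admits no drift regressor at "
            f"T={run.n_timepoints}, TR={run.tr_s}; returning demeaned data"
        )
        out = flat
    else:
        q, _ = np.linalg.qr(basis - basis.mean(axis=0, keepdims=True))
        out = flat - (flat @ q) @ q.T
    return BoldRun(
        data=out.reshape(shape), tr_s=run.tr_s, voxel_size_mm=run.voxel_size_mm
    )


def regress_motion(run: BoldRun, motion_params: np.ndarray) -> BoldRun:
    """Subtract the motion-explained signal via per-voxel OLS.

    The design is [intercept, 6 realignment parameters]; residuals are
    returned with the intercept (voxel mean) added back, so the temporal
    mean is preserved and residuals are orthogonal to each centered motion
    regressor.  Collinear motion columns are dropped with a warning.
    """
    params = np.asarray(motion_params, dtype=np.float64)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion parameters must be (T, 6)")
    if params.shape[0] != run.n_timepoints:
        raise ValueError("motion trace length must equal the number of volumes")
    x = params - params.mean(axis=0, keepdims=True)
    # prune zero/collinear columns
    keep = x.std(axis=0) > 0
    x = x[:, keep]
    if x.shape[1] and np.linalg.matrix_rank(x) < x.shape[1]:
        q, r = np.linalg.qr(x)
        indep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
        warnings.warn("collinear motion regressors dropped")
        x = x[:, indep]
    shape = run.data.shape
    flat = run.data.reshape(-1, shape[3]).astype(np.float64)
    mean = flat.mean(axis=1, keepdims=True)
    centered = flat - mean
    if x.shape[1]:
        q, _ = np.linalg.qr(x)
        resid = centered - (centered @ q) @ q.T
    else:
        resid = centered
    out = resid + mean
    return BoldRun(
        data=out.reshape(shape), tr_s=run.tr_s, voxel_size_mm=run.voxel_size_mm
    )


# ---------------------------------------------------------------------------
# centrality

def normalize_timeseries(run: BoldRun, mask: np.ndarray) -> NormalizedMatrix:
    """Center and unit-norm every masked voxel's series (rows of M)."""
    if mask.shape != run.grid_shape:
        raise ValueError("mask grid does not match the run")
    coords = np.argwhere(mask)
    rows = run.data[mask].astype(np.float64)
    rows = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1)
    if np.any(norms == 0):
        bad = coords[np.flatnonzero(norms == 0)[0]]
        raise ValueError(
            f"zero-variance voxel at {tuple(int(c) for c in bad)} inside the mask; "
            "remove it (see variance_mask) before normalization"
        )
    rows /= norms[:, None]
    return NormalizedMatrix(rows=rows, coords=coords, grid_shape=run.grid_shape)


def fast_ecm(
    m: NormalizedMatrix,
    tol: float = 1e-9,
    max_iter: int = 1000,
    mask: np.ndarray | None = None,
) -> CentralityMap:
    """Dominant eigenvector of C = M M^T + J by matrix-free power iteration.

    Each product C v is evaluated as M (M^T v) + (sum v) 1, so the cost is
    O(N*T) per iteration and only O(N + T) extra storage is needed.  The
    start vector is the uniform positive vector 1/sqrt(N); iteration stops
    when successive unit vectors differ by less than ``tol`` in max-norm, or
    at ``max_iter`` (then ``converged`` is False).
    """
    if m.n_voxels < 2:
        raise ValueError("centrality needs at least 2 voxels")
    if tol <= 0:
        raise ValueError("tol must be positive")
    rows = m.rows
    n = m.n_voxels
    v = np.full(n, 1.0 / np.sqrt(n))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = rows @ (rows.T @ v) + v.sum()
        w /= np.linalg.norm(w)
        if np.max(np.abs(w - v)) < tol:
            v = w
            converged = True
            break
        v = w
    if not np.all(v > 0):
        raise RuntimeError("power iteration left the positive cone")
    if mask is None:
        mask = np.zeros(m.grid_shape, dtype=bool)
        mask[tuple(m.coords.T)] = True
    return CentralityMap(values=v, mask=mask, iterations_used=it, converged=converged)


def ecm_pair(
    run: BoldRun,
    motion_params: np.ndarray,
    mask: np.ndarray,
    cutoff_s: float = 182.0,
    tol: float = 1e-9,
    max_iter: int = 1000,
) -> tuple[CentralityMap, CentralityMap]:
    """Centrality with and without motion-parameter regression.

    Both maps are computed from the high-pass-filtered run on the same mask
    (shrunk jointly to voxels with nonzero variance under both variants):
    the first without, the second with the motion nuisance regression.
    """
    filtered = highpass_filter(run, cutoff_s)
    regressed = regress_motion(filtered, motion_params)
    common = variance_mask(filtered, mask) & variance_mask(regressed, mask)
    plain = fast_ecm(normalize_timeseries(filtered, common), tol, max_iter, mask=common)
    mreg = fast_ecm(normalize_timeseries(regressed, common), tol, max_iter, mask=common)
    return plain, mreg


# ---------------------------------------------------------------------------
# NIfTI I/O

def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_volume(data: np.ndarray, voxel_size_mm: float, path) -> None:
    """Write a 3D/4D array as NIfTI with an isotropic diagonal affine.

    ``.gz`` outputs are compressed with a zeroed gzip timestamp so identical
    volumes produce byte-identical files (checksummed manifests).
    """
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size_mm))
    path = str(path)
    if path.endswith(".gz"):
        import gzip

        with open(path, "wb") as fh:
            fh.write(gzip.compress(img.to_bytes(), mtime=0))
    else:
        nib.save(img, path)


def load_bold(path, tr_s: float, voxel_size_mm: float = 4.0) -> BoldRun:
    img = nib.load(str(path))
    return BoldRun(
        data=np.asarray(img.dataobj, dtype=np.float64),
        tr_s=tr_s,
        voxel_size_mm=voxel_size_mm,
    )
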