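"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ecmap import BoldRun, CohortSpec, normalize_timeseries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """Desk-scale cohort spec for fast end-to-end exercises."""
    return CohortSpec(
        n_subjects=10,
        carrier_fraction=0.3,
        grid_shape=(10, 10, 8),
        n_timepoints=60,
        n_communities=4,
        seed=7,
    )


def random_run(rng, shape=(6, 6, 4), t=40, tr_s=2.0):
    data = rng.normal(size=(*shape, t)) + 100.0
    return BoldRun(data=data, tr_s=tr_s)


def random_normalized(rng, n, t, grid=None):
    """NormalizedMatrix from random data (helper for centrality tests)."""
    if grid is None:
        grid = (n, 1, 1)
    data = rng.normal(size=(*grid, t)) + 100.0
    run = BoldRun(data=data, tr_s=2.0)
    mask = np.ones(grid, dtype=bool)
    return normalize_timeseries(run, mask)


def dense_ecm_oracle(rows: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of the explicitly built C = M M^T + 1."""
    c = rows @ rows.T + 1.0
    w, v = np.linalg.eigh(c)
    top = v[:, -1]
    return top * np.sign(top.sum())


def flood_fill_clusters(volume: np.ndarray, threshold: float, connectivity: int):
    """Brute-force connected components of both suprathreshold sets.

    Returns a list of (sign, voxel set frozenset, mass) tuples; independent
    of scipy's labelling.
    """
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    shape = volume.shape
    out = []
    for sign in (1, -1):
        supra = (sign * volume) > threshold
        seen = np.zeros(shape, dtype=bool)
        for start in zip(*np.nonzero(supra)):
            if seen[start]:
                continue
            stack, comp = [start], set()
            seen[start] = True
            while stack:
                cur = stack.pop()
                comp.add(cur)
                for off in offs:
                    nxt = tuple(c + o for c, o in zip(cur, off))
                    if any(c < 0 or c >= s for c, s in zip(nxt, shape)):
                        continue
                    if supra[nxt] and not seen[nxt]:
                        seen[nxt] = True
                        stack.append(nxt)
            mass = float(sum(abs(volume[v]) for v in comp))
            out.append((sign, frozenset(comp), mass))
    return out
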