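"""Reference-grid generation, cube similarity and grouping by matching.

The volume is marched through on a regular grid of reference-cube origins
(step ``Nstep`` per axis, with the final origin clamped so the trailing
border is covered).  Around each reference a cubical search window of
``NS`` candidate origins per axis is placed, clamped (never wrapped) at the
volume borders, and every candidate whose per-voxel mean squared difference
to the reference cube falls below ``tau_match`` is kept.  The kept cubes
are sorted by distance (ties broken by scan order, making results machine
independent), the group is truncated to a power-of-two size so the
group-axis transform runs on dyadic lengths, and the reference is forced to
position 0.

In stage 2 the distances are computed on the stage-1 estimate while cube
values are still extracted from the noisy volume; `match_cubes` therefore
takes the extraction volume and the matching volume separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core_model import (
    CubeCoord,
    Group,
    StageParams,
    Volume,
    largest_power_of_two_at_most,
)


def reference_axis_origins(dim: int, L: int, Nstep: int) -> list[int]:
    """Reference-cube origins along one axis: 0, Nstep, ... plus a clamped
    final origin at ``dim - L`` when the regular grid does not reach it."""
    if dim < L:
        raise ValueError(f"axis dim {dim} smaller than cube side {L}")
    last = dim - L
    origins = list(range(0, last + 1, Nstep))
    if origins[-1] != last:
        origins.append(last)
    return origins


def reference_coordinates(dims: tuple[int, int, int], L: int,
                          Nstep: int) -> list[CubeCoord]:
    """All reference origins, as the per-axis Cartesian product in scan
    order (x slowest, z fastest)."""
    axes = [reference_axis_origins(d, L, Nstep) for d in dims]
    return [CubeCoord(*o) for o in product(*axes)]


def cube_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Per-voxel mean squared difference between two equally shaped cubes."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d = a - b
    return float(np.dot(d.ravel(), d.ravel()) / d.size)


@dataclass
class SearchWindow:
    """Admissible candidate cube origins around a reference."""

    center: CubeCoord
    origins: list[CubeCoord]


def _window_bounds(ref: CubeCoord, dims: tuple[int, int, int], L: int,
                   NS: int) -> tuple[tuple[int, int], ...]:
    """Per-axis inclusive (lo, hi) candidate-origin bounds, clamped."""
    h = (NS - 1) // 2
    return tuple(
        (max(0, r - h), min(d - L, r + h)) for r, d in zip(ref, dims)
    )


def search_candidates(volume: Volume, ref: CubeCoord,
                      params: StageParams) -> SearchWindow:
    """Every admissible candidate origin within the NS-sided window."""
    ref.check(volume.dims, params.L)
    bounds = _window_bounds(ref, volume.dims, params.L, params.NS)
    origins = [
        CubeCoord(x, y, z)
        for x in range(bounds[0][0], bounds[0][1] + 1)
        for y in range(bounds[1][0], bounds[1][1] + 1)
        for z in range(bounds[2][0], bounds[2][1] + 1)
    ]
    return SearchWindow(center=ref, origins=origins)


def extract_cubes(data: np.ndarray, coords: list[CubeCoord],
                  L: int) -> np.ndarray:
    """Stack the L-cubes at the given origins into an (M', L, L, L) array."""
    return np.stack(
        [data[x:x + L, y:y + L, z:z + L] for x, y, z in coords]
    )


def match_cubes(volume: Volume, matching_volume: Volume, ref: CubeCoord,
                params: StageParams,
                _windows: np.ndarray | None = None) -> Group:
    """Grouping by matching around one reference coordinate.

    Distances are evaluated on ``matching_volume``; cube values are
    extracted from ``volume``.  ``_windows`` may carry a precomputed
    ``sliding_window_view`` of the matching volume's data to avoid
    rebuilding the view per call.
    """
    if volume.dims != matching_volume.dims:
        raise ValueError("volume and matching_volume dims differ")
    L = params.L
    ref.check(volume.dims, L)
    if _windows is None:
        _windows = sliding_window_view(matching_volume.data, (L, L, L))
    (x0, x1), (y0, y1), (z0, z1) = _window_bounds(ref, volume.dims, L,
                                                  params.NS)
    win = _windows[x0:x1 + 1, y0:y1 + 1, z0:z1 + 1]
    ref_cube = _windows[ref.ix, ref.iy, ref.iz]
    diff = win - ref_cube
    dist = np.einsum("abcijk,abcijk->abc", diff, diff) / L**3

    keep = dist <= params.tau_match
    xs, ys, zs = np.nonzero(keep)
    d = dist[xs, ys, zs]
    ox, oy, oz = xs + x0, ys + y0, zs + z0
    # ascending distance, ties by scan order of the origin (x, y, z lexicographic)
    order = np.lexsort((oz, oy, ox, d))
    coords = [CubeCoord(int(ox[i]), int(oy[i]), int(oz[i])) for i in order]

    # the reference always matches itself (d = 0); force it to position 0
    ref_pos = coords.index(ref)
    coords.insert(0, coords.pop(ref_pos))
    m = largest_power_of_two_at_most(min(len(coords), params.M))
    coords = coords[:m]
    return Group(cubes=extract_cubes(volume.data, coords, L), coords=coords,
                 reference=ref)
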