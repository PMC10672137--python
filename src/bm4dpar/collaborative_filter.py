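"""The two filtering stages and weighted aggregation.

Stage 1 (hard thresholding): each group is taken to the sparse domain by
the 4D transform, coefficients below ``lambda4d * sigma`` in magnitude are
zeroed (the DC coefficient is exempt, so flat regions are never biased
toward zero), the group is inverse transformed, and its cubes are
aggregated back at their original locations with weight
``1 / (sigma**2 * N_retained)`` — groups that compress into fewer retained
coefficients are less noisy and count more.

Stage 2 (empirical Wiener): grouping runs on the stage-1 estimate, the
noisy and estimate groups are both transformed, and the noisy coefficients
are scaled by the empirical Wiener gains ``W = E**2 / (E**2 + sigma**2)``
built from the estimate coefficients ``E``; the aggregation weight is
``1 / (sigma**2 * ||W||**2)``.

Aggregation is tracked as a numerator (weighted values) and denominator
(weights) pair so partial results from concurrent workers can simply be
summed before the final division.  No windowing taper is applied to the
aggregated cubes: uniform cube weights keep the ``lambda4d = 0`` stage an
exact identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core_model import (
    SIGMA_EPS,
    WIENER_NORM_EPS,
    Accumulators,
    BM4DProfile,
    CubeCoord,
    Group,
    StageParams,
    Volume,
    validate_profile,
)
from .grouping import extract_cubes, match_cubes
from .transforms import Transform4D


@dataclass
class FilteredGroup:
    """A filtered group plus its aggregation weight."""

    cubes: np.ndarray
    coords: list[CubeCoord]
    weight: float

    def __post_init__(self) -> None:
        if not (self.weight > 0 and np.isfinite(self.weight)):
            raise ValueError(f"weight must be positive finite, got {self.weight}")
        if self.cubes.shape[0] != len(self.coords):
            raise ValueError("cubes/coords length mismatch")


def hard_threshold_coeffs(coeffs: np.ndarray, lambda4d: float,
                          sigma: float) -> tuple[np.ndarray, int]:
    """Zero coefficients with magnitude below ``lambda4d * sigma``.

    The DC coefficient (index 0 on every axis) is always retained.
    Returns the shrunk array and the count of retained nonzero coefficients.
    """
    if sigma < 0 or lambda4d < 0:
        raise ValueError("sigma and lambda4d must be >= 0")
    coeffs = np.asarray(coeffs, dtype=np.float64)
    keep = np.abs(coeffs) >= lambda4d * sigma
    keep[(0,) * coeffs.ndim] = True
    out = np.where(keep, coeffs, 0.0)
    return out, int(np.count_nonzero(out))


def _sigma_sq(sigma: float) -> float:
    return sigma * sigma if sigma > 0 else SIGMA_EPS


def filter_group_ht(group: Group, sigma: float, params: StageParams,
                    transforms: Transform4D) -> FilteredGroup:
    """Hard-threshold collaborative filtering of one group."""
    if params.lambda4d is None:
        raise ValueError("hard-threshold stage requires lambda4d")
    coeffs = transforms.forward(group.cubes)
    shrunk, n_retained = hard_threshold_coeffs(coeffs, params.lambda4d, sigma)
    filtered = transforms.inverse(shrunk)
    weight = 1.0 / (_sigma_sq(sigma) * max(n_retained, 1))
    return FilteredGroup(cubes=filtered, coords=list(group.coords),
                         weight=weight)


def wiener_gains(estimate_coeffs: np.ndarray, sigma: float) -> np.ndarray:
    """Empirical Wiener gains W = E^2 / (E^2 + sigma^2), elementwise in [0,1]."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    e2 = np.asarray(estimate_coeffs, dtype=np.float64) ** 2
    if sigma == 0:
        return np.ones_like(e2)
    return e2 / (e2 + sigma * sigma)


def filter_group_wiener(noisy_group: Group, estimate_group: Group,
                        sigma: float,
                        transforms: Transform4D) -> FilteredGroup:
    """Empirical Wiener filtering of a noisy group guided by the pilot group."""
    if noisy_group.cubes.shape != estimate_group.cubes.shape:
        raise ValueError("noisy/estimate group shape mismatch")
    if [tuple(c) for c in noisy_group.coords] != \
            [tuple(c) for c in estimate_group.coords]:
        raise ValueError("noisy/estimate group coordinate mismatch")
    gains = wiener_gains(transforms.forward(estimate_group.cubes), sigma)
    filtered = transforms.inverse(gains * transforms.forward(noisy_group.cubes))
    w_norm_sq = max(float(np.sum(gains * gains)), WIENER_NORM_EPS)
    weight = 1.0 / (_sigma_sq(sigma) * w_norm_sq)
    return FilteredGroup(cubes=filtered, coords=list(noisy_group.coords),
                         weight=weight)


def accumulate_group(acc: Accumulators, fg: FilteredGroup) -> Accumulators:
    """Add one filtered group's weighted cubes into the accumulators.

    Accumulation order within the call is fixed: member order, which is the
    group's selection order.
    """
    L = fg.cubes.shape[1]
    w = fg.weight
    for cube, (x, y, z) in zip(fg.cubes, fg.coords):
        acc.numerator[x:x + L, y:y + L, z:z + L] += w * cube
        acc.denominator[x:x + L, y:y + L, z:z + L] += w
    return acc


def finalize_estimate(acc: Accumulators,
                      fallback: Volume) -> tuple[Volume, int]:
    """Divide numerator by denominator; fall back to the given volume at
    voxels no group ever covered.  Returns (estimate, fallback voxel count)."""
    if acc.numerator.shape != fallback.dims:
        raise ValueError("accumulator/fallback dims mismatch")
    covered = acc.denominator > 0
    out = np.where(covered,
                   acc.numerator / np.where(covered, acc.denominator, 1.0),
                   fallback.data)
    n_fallback = int(out.size - np.count_nonzero(covered))
    return fallback.with_data(out), n_fallback


# -- stage execution ------------------------------------------------------


@dataclass
class StageContext:
    """Everything needed to process one reference coordinate of a stage.

    Holds plain arrays so it can be shipped to worker processes; the
    sliding-window view used for matching is rebuilt lazily on each side.
    """

    volume: Volume
    matching_volume: Volume
    sigma: float
    params: StageParams
    mode: str  # "ht" | "wiener"
    estimate_volume: Volume | None
    transforms: Transform4D

    def __post_init__(self) -> None:
        if self.mode not in ("ht", "wiener"):
            raise ValueError(f"mode must be 'ht' or 'wiener', got {self.mode!r}")
        if self.mode == "wiener" and self.estimate_volume is None:
            raise ValueError("wiener mode requires estimate_volume")
        self._windows = None

    def __getstate__(self):
        state = self.__dict__.copy()
        state["_windows"] = None  # views do not pickle compactly
        return state

    @property
    def windows(self) -> np.ndarray:
        if self._windows is None:
            L = self.params.L
            self._windows = sliding_window_view(self.matching_volume.data,
                                                (L, L, L))
        return self._windows

    def process_reference(self, acc: Accumulators,
                          ref: CubeCoord) -> Accumulators:
        """Match, filter and accumulate one reference coordinate."""
        group = match_cubes(self.volume, self.matching_volume, ref,
                            self.params, _windows=self.windows)
        if self.mode == "ht":
            fg = filter_group_ht(group, self.sigma, self.params,
                                 self.transforms)
        else:
            est = Group(
                cubes=extract_cubes(self.estimate_volume.data, group.coords,
                                    self.params.L),
                coords=list(group.coords), reference=group.reference)
            fg = filter_group_wiener(group, est, self.sigma, self.transforms)
        return accumulate_group(acc, fg)


def _default_schedule_refs(dims, params) -> list[CubeCoord]:
    # class order is the canonical serial order so that a one-worker
    # parallel run is bit-identical to the sequential path
    from .grouping import reference_coordinates
    from .parallel_scheduler import build_nonoverlap_schedule

    refs = reference_coordinates(dims, params.L, params.Nstep)
    return build_nonoverlap_schedule(refs, params, dims).flat()


def run_stage(volume: Volume, matching_volume: Volume, sigma: float,
              params: StageParams, mode: str,
              estimate_volume: Volume | None = None,
              scheduler=None,
              transforms: Transform4D | None = None) -> Volume:
    """Run one full filtering stage over the volume.

    ``scheduler`` maps ``(dims, params)`` to the ordered reference list;
    the default is the non-overlap class schedule in class order.  The
    result is deterministic given a fixed schedule order.
    """
    if transforms is None:
        transforms = Transform4D()
    ctx = StageContext(volume=volume, matching_volume=matching_volume,
                       sigma=sigma, params=params, mode=mode,
                       estimate_volume=estimate_volume, transforms=transforms)
    refs = (scheduler or _default_schedule_refs)(volume.dims, params)
    acc = Accumulators.zeros(volume.dims)
    for ref in refs:
        ctx.process_reference(acc, ref)
    estimate, _ = finalize_estimate(acc, volume)
    return estimate


def run_bm4d(noisy: Volume, sigma: float, profile: BM4DProfile,
             scheduler=None, return_intermediate: bool = False):
    """The full two-stage filter: hard thresholding, then Wiener refinement.

    Returns the final estimate, or ``(final, stage1)`` when
    ``return_intermediate`` is set.
    """
    validate_profile(profile, noisy.dims)
    transforms = Transform4D(profile.spatial_transform,
                             profile.group_transform)
    pilot = run_stage(noisy, noisy, sigma, profile.ht, "ht",
                      scheduler=scheduler, transforms=transforms)
    final = run_stage(noisy, pilot, sigma, profile.wie, "wiener",
                      estimate_volume=pilot, scheduler=scheduler,
                      transforms=transforms)
    if return_intermediate:
        return final, pilot
    return final
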