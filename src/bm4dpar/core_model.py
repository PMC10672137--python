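"""Domain types, the modified-profile defaults, and shared validation.

The filter operates on a 3D scalar volume whose intensities are normalised
to [0, 1]; the noise standard deviation sigma, the similarity threshold
``tau_match`` and the shrinkage multiplier ``lambda4d`` are all interpreted
on that normalised scale.  Axis convention throughout the package: volumes
are indexed ``(x, y, z)`` with ``z`` the axial slice axis, coordinates are
0-based, and cube extents are half-open ``[origin, origin + L)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

#: Epsilon substituted for sigma**2 in aggregation weights when sigma == 0
#: (a sigma = 0 run is an identity pipeline; the weights only need to be
#: finite and equal across groups).
SIGMA_EPS: float = 1e-12

#: Floor for the squared norm of the Wiener gain array in the stage-2
#: aggregation weight (an all-zero pilot group would otherwise divide by 0).
WIENER_NORM_EPS: float = 1e-12


class CubeCoord(NamedTuple):
    """Integer voxel indices of a cube's minimum corner."""

    ix: int
    iy: int
    iz: int

    def check(self, dims: tuple[int, int, int], L: int) -> "CubeCoord":
        for o, d, name in zip(self, dims, "xyz"):
            if o < 0 or o + L > d:
                raise ValueError(
                    f"cube origin {tuple(self)} with side {L} exceeds axis "
                    f"{name} (dim {d})"
                )
        return self


@dataclass
class Volume:
    """A 3D scalar intensity grid with spacing and intensity-map metadata.

    ``intensity_map`` is the affine ``(scale, offset)`` mapping back from the
    normalised scale to the original one: ``original = scale * value + offset``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] | None = None
    intensity_map: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dims must be >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        scale, _ = self.intensity_map
        if scale == 0:
            raise ValueError("intensity_map scale must be nonzero")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def denormalised(self) -> np.ndarray:
        """Data mapped back to the original intensity scale."""
        scale, offset = self.intensity_map
        return self.data * scale + offset

    def with_data(self, data: np.ndarray) -> "Volume":
        """A new volume with the same metadata but different samples."""
        return Volume(data=data, spacing=self.spacing,
                      intensity_map=self.intensity_map)


@dataclass(frozen=True)
class StageParams:
    """Per-stage filtering constants.

    L
        cube side in voxels.
    M
        maximum group size (cubes per group).
    Nstep
        step of the reference-cube grid, in voxels.
    NS
        side of the cubical search window, in candidate cube-origin
        positions; must be odd so the window is centred on the reference.
    tau_match
        similarity threshold on the per-voxel mean squared difference.
    lambda4d
        hard-threshold multiplier (``None`` for the Wiener stage).
    """

    L: int
    M: int
    Nstep: int
    NS: int
    tau_match: float
    lambda4d: float | None = None

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"L must be >= 1, got {self.L}")
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        if self.Nstep < 1:
            raise ValueError(f"Nstep must be >= 1, got {self.Nstep}")
        if self.NS < 1 or self.NS % 2 == 0:
            raise ValueError(f"NS must be odd and >= 1, got {self.NS}")
        if self.tau_match < 0:
            raise ValueError(f"tau_match must be >= 0, got {self.tau_match}")
        if self.lambda4d is not None and self.lambda4d < 0:
            raise ValueError(f"lambda4d must be >= 0, got {self.lambda4d}")


@dataclass(frozen=True)
class BM4DProfile:
    """The full two-stage parameter set plus transform identifiers."""

    ht: StageParams
    wie: StageParams
    spatial_transform: str = "dct"
    group_transform: str = "haar"


def make_modified_profile() -> BM4DProfile:
    """The recommended "modified profile" parameter set.

    Hard-thresholding stage: L=4, M=32, Nstep=3, NS=11, tau_match=24.6,
    lambda4d=2.8.  Wiener stage: L=5, same M/Nstep/NS, tau_match=6.7, no
    shrinkage multiplier.
    """
    return BM4DProfile(
        ht=StageParams(L=4, M=32, Nstep=3, NS=11, tau_match=24.6, lambda4d=2.8),
        wie=StageParams(L=5, M=32, Nstep=3, NS=11, tau_match=6.7, lambda4d=None),
    )


def validate_profile(profile: BM4DProfile,
                     dims: tuple[int, int, int]) -> BM4DProfile:
    """Check that a volume of shape ``dims`` admits the profile's geometry.

    Every axis must accommodate the larger cube side and the search window.
    Raises ``ValueError`` naming the offending axis and parameter; returns
    the profile unchanged otherwise (idempotent).
    """
    if min(dims) < 1:
        raise ValueError(f"dims must be positive, got {dims}")
    for stage_name, stage in (("ht", profile.ht), ("wie", profile.wie)):
        for axis, d in zip("xyz", dims):
            if d < stage.L:
                raise ValueError(
                    f"axis {axis} (dim {d}) smaller than {stage_name}.L="
                    f"{stage.L}"
                )
            if d < stage.NS:
                raise ValueError(
                    f"axis {axis} (dim {d}) smaller than {stage_name}.NS="
                    f"{stage.NS}"
                )
    return profile


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. zero-mean Gaussian noise on the normalised scale."""

    sigma: float
    clip: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass
class Group:
    """A stack of similar cubes collected around a reference.

    ``cubes`` has shape (M', L, L, L) with M' a power of two; ``coords[0]``
    is always the reference coordinate.
    """

    cubes: np.ndarray
    coords: list[CubeCoord]
    reference: CubeCoord

    def __post_init__(self) -> None:
        self.cubes = np.asarray(self.cubes, dtype=np.float64)
        m = self.cubes.shape[0]
        if m < 1 or m & (m - 1):
            raise ValueError(f"group size must be a power of two >= 1, got {m}")
        if len(self.coords) != m:
            raise ValueError("coords length must match cube count")
        if tuple(self.coords[0]) != tuple(self.reference):
            raise ValueError("coords[0] must be the reference coordinate")

    @property
    def size(self) -> int:
        return self.cubes.shape[0]


@dataclass
class Accumulators:
    """Numerator and denominator volumes of the weighted aggregation."""

    numerator: np.ndarray
    denominator: np.ndarray

    @classmethod
    def zeros(cls, dims: tuple[int, int, int]) -> "Accumulators":
        return cls(numerator=np.zeros(dims), denominator=np.zeros(dims))

    def check(self) -> "Accumulators":
        if self.numerator.shape != self.denominator.shape:
            raise ValueError("numerator/denominator shape mismatch")
        if np.any(self.denominator < 0):
            raise ValueError("denominator must be non-negative")
        if np.any((self.denominator == 0) & (self.numerator != 0)):
            raise ValueError("numerator nonzero where denominator is zero")
        return self


@dataclass
class ClassSchedule:
    """Ordered classes of reference coordinates with disjoint write footprints.

    Classes are executed sequentially; references within one class may be
    processed concurrently because their footprints do not overlap.
    """

    classes: list[list[CubeCoord]]
    footprint_side: int
    class_counts: tuple[int, int, int]

    def flat(self) -> list[CubeCoord]:
        """All references in class order (the canonical serial order)."""
        return [r for cls in self.classes for r in cls]

    @property
    def n_references(self) -> int:
        return sum(len(c) for c in self.classes)


# -- profile config round-trip -------------------------------------------

_STAGE_FIELDS = ("L", "M", "Nstep", "NS", "tau_match", "lambda4d")
_INT_FIELDS = {"L", "M", "Nstep", "NS"}


def profile_to_config(profile: BM4DProfile) -> str:
    """Serialise a profile to a flat ``stage.parameter = value`` text config."""
    lines = []
    for stage_name, stage in (("ht", profile.ht), ("wie", profile.wie)):
        for f in _STAGE_FIELDS:
            v = getattr(stage, f)
            if v is None:
                continue
            lines.append(f"{stage_name}.{f} = {v!r}")
    lines.append(f"transform.spatial = {profile.spatial_transform}")
    lines.append(f"transform.group = {profile.group_transform}")
    return "\n".join(lines) + "\n"


def profile_from_config(text: str) -> BM4DProfile:
    """Parse a profile from the flat key-value format of `profile_to_config`."""
    stage_kw: dict[str, dict] = {"ht": {}, "wie": {}}
    transforms = {"spatial": "dct", "group": "haar"}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        prefix, _, fname = key.partition(".")
        if prefix == "transform":
            if fname not in transforms:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            transforms[fname] = value
        elif prefix in stage_kw and fname in _STAGE_FIELDS:
            stage_kw[prefix][fname] = (
                int(value) if fname in _INT_FIELDS else float(value)
            )
        else:
            raise ValueError(f"config line {lineno}: unknown key {key!r}")
    return BM4DProfile(
        ht=StageParams(**stage_kw["ht"]),
        wie=StageParams(**stage_kw["wie"]),
        spatial_transform=transforms["spatial"],
        group_transform=transforms["group"],
    )


def write_profile_config(profile: BM4DProfile, path: str | Path) -> None:
    Path(path).write_text(profile_to_config(profile))


def read_profile_config(path: str | Path) -> BM4DProfile:
    return profile_from_config(Path(path).read_text())


def largest_power_of_two_at_most(n: int) -> int:
    """Largest power of two <= n (n >= 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1 << (n.bit_length() - 1)
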