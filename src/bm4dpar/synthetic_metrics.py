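"""Phantom generation, Gaussian noise injection and slice-averaged metrics.

The phantoms emulate piecewise-constant anatomical structure: nested
ellipsoids with distinct intensity levels (``ellipsoids``) or smooth
Gaussian bumps (``blobs``), both deterministic per seed.  Noise is
additive i.i.d. zero-mean Gaussian on the normalised [0, 1] scale,
optionally clamped to [0, 1]; "25% noise" on that convention means
``sigma = 0.25`` with clamping enabled.

Quality is reported per axial slice and averaged over slices: RMSE, PSNR
with peak 1 (capped at `PSNR_CAP` dB for identical slices), and SSIM with
the standard constants (Gaussian window of side 11, K1 = 0.01, K2 = 0.03).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .core_model import NoiseModel, Volume

#: PSNR reported for a slice with zero RMSE.
PSNR_CAP: float = 100.0

_MIN_PHANTOM_DIM = 16


@dataclass
class Phantom:
    """A synthetic test volume plus the recipe that produced it."""

    volume: Volume
    kind: str
    seed: int
    components: list[dict] = field(default_factory=list)


def _coordinate_grids(dims: tuple[int, int, int]) -> list[np.ndarray]:
    # normalised voxel centres in [0, 1] per axis
    return list(np.meshgrid(*(
        (np.arange(d) + 0.5) / d for d in dims), indexing="ij"))


def make_phantom(dims: tuple[int, int, int], kind: str = "ellipsoids",
                 seed: int = 0) -> Phantom:
    """A deterministic piecewise-constant or smooth phantom in [0, 1]."""
    if min(dims) < _MIN_PHANTOM_DIM:
        raise ValueError(f"dims must be >= {_MIN_PHANTOM_DIM} per axis, got {dims}")
    if kind not in ("ellipsoids", "blobs"):
        raise ValueError(f"kind must be 'ellipsoids' or 'blobs', got {kind!r}")
    rng = np.random.default_rng(seed)
    gx, gy, gz = _coordinate_grids(dims)
    components: list[dict] = []

    if kind == "ellipsoids":
        data = np.full(dims, 0.05)
        # nested head-like shells: each successive ellipsoid is smaller and
        # overwrites the previous level where it lies inside
        n = 4
        center = 0.5 + rng.uniform(-0.05, 0.05, size=3)
        axes = np.array([0.42, 0.38, 0.40]) * (1 + rng.uniform(-0.05, 0.05, 3))
        levels = [0.85, 0.35, 0.60, 0.20]
        for i in range(n):
            shrink = 1.0 - 0.22 * i
            a = axes * shrink
            r2 = (((gx - center[0]) / a[0]) ** 2
                  + ((gy - center[1]) / a[1]) ** 2
                  + ((gz - center[2]) / a[2]) ** 2)
            data[r2 <= 1.0] = levels[i]
            components.append({"center": center.tolist(),
                               "axes": a.tolist(), "intensity": levels[i]})
    else:
        data = np.zeros(dims)
        for _ in range(6):
            center = rng.uniform(0.2, 0.8, size=3)
            width = rng.uniform(0.08, 0.2)
            amp = rng.uniform(0.3, 1.0)
            r2 = ((gx - center[0]) ** 2 + (gy - center[1]) ** 2
                  + (gz - center[2]) ** 2)
            data += amp * np.exp(-r2 / (2 * width ** 2))
            components.append({"center": center.tolist(), "width": width,
                               "amplitude": amp})
        data = 0.05 + 0.9 * data / data.max()

    vol = Volume(data=np.clip(data, 0.0, 1.0), spacing=(1.0, 1.0, 1.0))
    return Phantom(volume=vol, kind=kind, seed=seed, components=components)


def add_gaussian_noise(vol: Volume, noise: NoiseModel, seed: int = 0) -> Volume:
    """Corrupt a volume with additive Gaussian noise, deterministic per seed."""
    rng = np.random.default_rng(seed)
    if noise.sigma == 0:
        return vol.with_data(vol.data.copy())
    out = vol.data + rng.normal(0.0, noise.sigma, size=vol.dims)
    if noise.clip:
        out = np.clip(out, 0.0, 1.0)
    return vol.with_data(out)


@dataclass
class MetricsReport:
    """Slice-averaged PSNR / SSIM / RMSE plus the per-slice series."""

    psnr_db: float
    ssim: float
    rmse: float
    psnr_slices: list[float]
    ssim_slices: list[float]
    rmse_slices: list[float]

    def to_json(self, **extra) -> str:
        payload = {"psnr_db": self.psnr_db, "ssim": self.ssim,
                   "rmse": self.rmse, "per_slice": {
                       "psnr_db": self.psnr_slices,
                       "ssim": self.ssim_slices,
                       "rmse": self.rmse_slices}}
        payload.update(extra)
        return json.dumps(payload, indent=2)


def evaluate(reference: Volume, test: Volume) -> MetricsReport:
    """Per-axial-slice RMSE / PSNR / SSIM, averaged over slices.

    Both volumes must be on the [0, 1] scale; peak = 1 for PSNR and
    data_range = 1 for SSIM.
    """
    if reference.dims != test.dims:
        raise ValueError(f"dims mismatch: {reference.dims} vs {test.dims}")
    psnr_s, ssim_s, rmse_s = [], [], []
    for z in range(reference.dims[2]):
        ref_sl = reference.data[:, :, z]
        test_sl = test.data[:, :, z]
        rmse = float(np.sqrt(np.mean((ref_sl - test_sl) ** 2)))
        psnr = PSNR_CAP if rmse == 0 else min(
            20.0 * np.log10(1.0 / rmse), PSNR_CAP)
        ssim = float(structural_similarity(
            ref_sl, test_sl, data_range=1.0, gaussian_weights=True,
            win_size=11, sigma=1.5, K1=0.01, K2=0.03))
        rmse_s.append(rmse)
        psnr_s.append(float(psnr))
        ssim_s.append(ssim)
    return MetricsReport(
        psnr_db=float(np.mean(psnr_s)), ssim=float(np.mean(ssim_s)),
        rmse=float(np.mean(rmse_s)), psnr_slices=psnr_s, ssim_slices=ssim_s,
        rmse_slices=rmse_s)
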