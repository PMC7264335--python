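"""Synthetic fluorescence-microscopy fields with known ground truth.

The generator emulates the two imaging experiments the pipeline analyses:

* **well mode** (:func:`generate_well_field`) — a 3-channel field of a
  reporter-cell monolayer: disk-shaped nuclei in a nuclear-stain channel,
  per-cell lognormal mCherry expression, and a bimodal sensor channel in which
  negative cells sit at a low baseline and positive cells accumulate signal
  proportional to their own mCherry level.
* **in vivo mode** (:func:`generate_invivo_stack`) — a 2-channel z-stack:
  a green channel holding nuclei plus bright autofluorescent blobs, and a blue
  channel holding the *same* blobs at matched intensity, so that subtracting
  the blue max-projection from the green one recovers the nuclei.

Randomness
----------
Reproducibility is exact: identical :class:`SynthParams` (including ``seed``)
give bit-identical images and tables.  Four independent RNG sub-streams are
spawned from the seed, in this documented order::

    placement, expression, positivity, noise = [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(4)
    ]

* ``placement`` draws, per placed object, the triple (radius, centre row,
  centre col) — plus a z-plane in in vivo mode — redrawing the whole triple on
  every rejected attempt.
* ``expression`` draws per-cell mCherry signal as
  ``rng.lognormal(mcherry_log_mean, mcherry_log_sd, n_cells)`` (and per-object
  brightness factors in in vivo mode).
* ``positivity`` draws the Bernoulli labels as
  ``rng.random(n_cells) < p_positive``.
* ``noise`` is consumed channel by channel in a fixed order, so changing
  ``p_positive`` perturbs only the sensor channel.

This stream discipline lets tests replay any single stream as an independent
oracle.

Nuclei are rendered as hard-edged disks of uniform interior intensity (a pixel
belongs to a nucleus iff its centre lies within the radius); this keeps the
noise-free in-mask mean equal to the ground-truth mean to within integer
rounding, which downstream quantification tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DensityError, ParameterError
from .io import ChannelStack

__all__ = [
    "SynthParams",
    "generate_well_field",
    "generate_invivo_stack",
    "write_ground_truth",
]

#: column order of the ground-truth table / CSV
GT_COLUMNS = [
    "cell_id",
    "row",
    "col",
    "area_px",
    "is_positive",
    "true_mcherry",
    "true_sensor",
]


@dataclass(frozen=True)
class SynthParams:
    """Parameters of one synthetic field / stack.

    Intensities are arbitrary camera units (AU) on the ``bit_depth`` scale.
    Defaults describe a 16-bit field of well-separated reporter cells:
    negative cells carry only the sensor baseline while positive cells gain
    signal proportional to their mCherry expression, so the two populations
    are cleanly bimodal.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    n_cells: int = 150
    nucleus_radius_px: tuple[float, float] = (4.0, 7.0)
    p_positive: float = 0.3
    nuclear_mean_intensity: float = 3000.0
    mcherry_log_mean: float = 7.6  # exp(7.6) ~ 2000 AU median expression
    mcherry_log_sd: float = 0.4
    sensor_baseline_mean: float = 100.0
    sensor_positive_gain: float = 1.0
    background_level: float = 100.0
    read_noise_sd: float = 20.0
    shot_noise: bool = True
    speckle_density: int = 0
    speckle_intensity: float = 4000.0
    speckle_radius_px: tuple[float, float] = (2.0, 5.0)
    min_separation_px: float = 2.0
    n_z: int = 1
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_positive <= 1.0:
            raise ParameterError(f"p_positive must lie in [0, 1], got {self.p_positive}")
        rmin, rmax = self.nucleus_radius_px
        if not (0 < rmin <= rmax):
            raise ParameterError(f"nucleus radii must satisfy 0 < min <= max, got {self.nucleus_radius_px}")
        for name in (
            "nuclear_mean_intensity",
            "mcherry_log_sd",
            "sensor_baseline_mean",
            "sensor_positive_gain",
            "background_level",
            "read_noise_sd",
            "speckle_intensity",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ParameterError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.n_z < 1:
            raise ParameterError("n_z must be >= 1")
        if self.speckle_density < 0:
            raise ParameterError("speckle_density must be >= 0")
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")

    @classmethod
    def invivo(cls, **overrides) -> "SynthParams":
        """Defaults for the in vivo two-photon emulation: a 5-plane stack of
        small nuclei (disk areas within the 20–150 px nucleus size range) plus
        bright autofluorescent blobs shared by both channels."""
        base = dict(
            image_height_px=256,
            image_width_px=256,
            n_cells=40,
            nucleus_radius_px=(2.8, 6.5),
            nuclear_mean_intensity=2000.0,
            speckle_density=15,
            speckle_intensity=4000.0,
            n_z=5,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


def _spawn_streams(seed: int):
    """The documented 4-stream split: placement, expression, positivity, noise."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(4)]


def _place_disks(
    rng: np.random.Generator,
    n: int,
    radius_range: tuple[float, float],
    height: int,
    width: int,
    *,
    occupied: list[tuple[float, float, float]] | None = None,
    n_z: int = 1,
    separation: float = 2.0,
    max_attempts_per_object: int = 500,
) -> list[tuple[float, float, float, int]]:
    """Rejection-sample `n` non-overlapping disks.

    Non-overlap means centre distance >= sum of radii plus a small
    `separation` gap (so rendered masks stay disconnected under
    8-connectivity — the per-cell averaging downstream assumes resolvable
    cells), also against any pre-`occupied` disks (used so autofluorescent
    blobs never sit on nuclei).
    Each attempt redraws (radius, row, col[, z]) in that order from `rng`.
    Raises :class:`DensityError` once the per-object attempt budget, pooled
    over all objects, is exhausted.
    """
    rmin, rmax = radius_range
    placed: list[tuple[float, float, float]] = list(occupied or [])
    out: list[tuple[float, float, float, int]] = []
    budget = max_attempts_per_object * max(n, 1)
    attempts = 0
    for _ in range(n):
        while True:
            attempts += 1
            if attempts > budget:
                raise DensityError(
                    f"could not place {n} disks of radius {radius_range} in a "
                    f"{height}x{width} field after {budget} attempts; "
                    "reduce n_cells or the radii"
                )
            r = rng.uniform(rmin, rmax)
            cy = rng.uniform(r, height - r)
            cx = rng.uniform(r, width - r)
            z = int(rng.integers(n_z)) if n_z > 1 else 0
            ok = all(
                (cy - oy) ** 2 + (cx - ox) ** 2 >= (r + orad + separation) ** 2
                for oy, ox, orad in placed
            )
            if ok:
                placed.append((cy, cx, r))
                out.append((cy, cx, r, z))
                break
    return out


def _disk_coords(cy: float, cx: float, r: float, height: int, width: int):
    """Integer pixel coordinates of a hard-edged disk (centre distance <= r)."""
    y0, y1 = max(int(np.floor(cy - r)), 0), min(int(np.ceil(cy + r)) + 1, height)
    x0, x1 = max(int(np.floor(cx - r)), 0), min(int(np.ceil(cx + r)) + 1, width)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return yy[inside], xx[inside]


def _apply_noise_and_quantize(
    noise_free: np.ndarray, params: SynthParams, noise_rng: np.random.Generator
) -> np.ndarray:
    """Poisson shot noise on the noise-free signal, then Gaussian read noise,
    then rounding and clipping to the bit depth.  Channels are processed in
    storage order so each channel's draws depend only on its own content."""
    out = np.empty_like(noise_free, dtype=np.float64)
    n_z, n_c = noise_free.shape[:2]
    for z in range(n_z):
        for c in range(n_c):
            plane = noise_free[z, c].astype(np.float64)
            if params.shot_noise:
                plane = noise_rng.poisson(plane).astype(np.float64)
            if params.read_noise_sd > 0:
                plane = plane + noise_rng.normal(0.0, params.read_noise_sd, plane.shape)
            out[z, c] = plane
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    return np.clip(np.rint(out), 0, params.max_value).astype(dtype)


def generate_well_field(
    params: SynthParams,
) -> tuple[ChannelStack, np.ndarray, pd.DataFrame]:
    """Generate one 3-channel reporter-cell field.

    Returns
    -------
    stack
        Channels in order (nuclear, expression, sensor); single z-plane.
    labels
        The exact ground-truth mask: int array, 0 = background, cell ids 1..n
        in placement order.
    ground_truth
        One row per placed nucleus with columns :data:`GT_COLUMNS`.
        ``true_mcherry`` / ``true_sensor`` are the expected *raw* in-mask
        means, i.e. cell signal plus the uniform background level.
    """
    placement, expression, positivity, noise = _spawn_streams(params.seed)
    h, w = params.image_height_px, params.image_width_px

    disks = _place_disks(
        placement,
        params.n_cells,
        params.nucleus_radius_px,
        h,
        w,
        separation=params.min_separation_px,
    )
    mcherry_sig = expression.lognormal(
        params.mcherry_log_mean, params.mcherry_log_sd, params.n_cells
    )
    is_positive = positivity.random(params.n_cells) < params.p_positive
    sensor_sig = np.where(
        is_positive,
        params.sensor_baseline_mean + params.sensor_positive_gain * mcherry_sig,
        params.sensor_baseline_mean,
    )

    signal = np.zeros((1, 3, h, w), dtype=np.float64)
    labels = np.zeros((h, w), dtype=np.int32)
    rows = []
    for i, (cy, cx, r, _z) in enumerate(disks):
        yy, xx = _disk_coords(cy, cx, r, h, w)
        labels[yy, xx] = i + 1
        signal[0, 0, yy, xx] = params.nuclear_mean_intensity
        signal[0, 1, yy, xx] = mcherry_sig[i]
        signal[0, 2, yy, xx] = sensor_sig[i]
        rows.append(
            {
                "cell_id": i + 1,
                "row": cy,
                "col": cx,
                "area_px": int(len(yy)),
                "is_positive": bool(is_positive[i]),
                "true_mcherry": mcherry_sig[i] + params.background_level,
                "true_sensor": sensor_sig[i] + params.background_level,
            }
        )

    noise_free = signal + params.background_level
    pixels = _apply_noise_and_quantize(noise_free, params, noise)
    stack = ChannelStack(
        pixels=pixels,
        roles={"nuclear": 0, "expression": 1, "sensor": 2},
        bit_depth=params.bit_depth,
    )
    ground_truth = pd.DataFrame(rows, columns=GT_COLUMNS)
    return stack, labels, ground_truth


def generate_invivo_stack(
    params: SynthParams,
) -> tuple[ChannelStack, pd.DataFrame]:
    """Generate a 2-channel z-stack emulating in vivo two-photon imaging.

    Channel 0 (role ``sensor``, the green emission) holds nuclei plus
    autofluorescent blobs; channel 1 (role ``auxiliary``, the blue emission)
    holds only the same blobs, co-localized and intensity-matched, so a
    pixelwise green-minus-blue subtraction of the max-projections recovers the
    nuclei.  Each object lives on a single z-plane.  The ground truth lists
    nuclei only; ``true_sensor`` is the expected raw green in-mask mean and
    ``true_mcherry`` is NaN (no expression channel exists in this mode).
    """
    placement, expression, _positivity, noise = _spawn_streams(params.seed)
    h, w = params.image_height_px, params.image_width_px

    nuclei = _place_disks(
        placement,
        params.n_cells,
        params.nucleus_radius_px,
        h,
        w,
        n_z=params.n_z,
        separation=params.min_separation_px,
    )
    occupied = [(cy, cx, r) for cy, cx, r, _ in nuclei]
    blobs = _place_disks(
        placement,
        params.speckle_density,
        params.speckle_radius_px,
        h,
        w,
        occupied=occupied,
        n_z=params.n_z,
        separation=params.min_separation_px,
    )
    # per-object brightness spread (uniform 0.8-1.2 of the nominal intensity)
    nuc_int = params.nuclear_mean_intensity * expression.uniform(0.8, 1.2, len(nuclei))
    blob_int = params.speckle_intensity * expression.uniform(0.8, 1.2, len(blobs))

    signal = np.zeros((params.n_z, 2, h, w), dtype=np.float64)
    rows = []
    for i, (cy, cx, r, z) in enumerate(nuclei):
        yy, xx = _disk_coords(cy, cx, r, h, w)
        signal[z, 0, yy, xx] = nuc_int[i]
        rows.append(
            {
                "cell_id": i + 1,
                "row": cy,
                "col": cx,
                "area_px": int(len(yy)),
                "is_positive": True,
                "true_mcherry": np.nan,
                "true_sensor": nuc_int[i] + params.background_level,
            }
        )
    for j, (cy, cx, r, z) in enumerate(blobs):
        yy, xx = _disk_coords(cy, cx, r, h, w)
        signal[z, 0, yy, xx] = blob_int[j]  # green sees the blob ...
        signal[z, 1, yy, xx] = blob_int[j]  # ... and blue sees it identically

    noise_free = signal + params.background_level
    pixels = _apply_noise_and_quantize(noise_free, params, noise)
    stack = ChannelStack(
        pixels=pixels, roles={"sensor": 0, "auxiliary": 1}, bit_depth=params.bit_depth
    )
    ground_truth = pd.DataFrame(rows, columns=GT_COLUMNS)
    return stack, ground_truth


def write_ground_truth(path: str | Path, ground_truth: pd.DataFrame) -> Path:
    """Write the ground-truth table as CSV with the documented header."""
    ground_truth.to_csv(path, index=False, columns=GT_COLUMNS, float_format="%.6g")
    return Path(path)
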