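"""Nucleus/cell segmentation and the in vivo mask workflow.

The operator chain mirrors the Fiji-style analysis of the two-photon data —
maximum-intensity z-projection, blue-channel subtraction, minimum
cross-entropy (Li) thresholding, iterated 3x3 median despeckling, connected
components, and a nucleus-size area filter — and the same audited chain is
reused (with configurable threshold method) for monolayer fields, where the
original analysis is otherwise unspecified.

Conventions
-----------
* Binarization is strict: ``pixel > t`` is foreground; ties at the threshold
  go to background.
* Foreground connectivity defaults to 8-connected; configurable to 4.
* Area bounds are a closed interval (``min <= area <= max``).
* Label images are dense 1..K, assigned in raster-scan order of each object's
  first pixel, so segmentation output is order-stable and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError, ParameterError
from .io import ChannelStack

__all__ = [
    "SegmentationParams",
    "project_max",
    "subtract_channel",
    "li_threshold",
    "despeckle",
    "label_components",
    "size_filter",
    "relabel_raster_order",
    "segment_cells",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the segmentation chain.

    ``despeckle_rounds`` counts 3x3 median passes applied to the binary mask
    (the in vivo workflow uses 4); ``min_area_px``/``max_area_px`` bound the
    accepted object area inclusively (20–150 px is the nucleus size range of
    the in vivo analysis).
    """

    threshold_method: str = "li"  # li | otsu | fixed
    fixed_threshold: float | None = None
    despeckle_rounds: int = 4
    min_area_px: int = 20
    max_area_px: int = 150
    connectivity: int = 8
    border_policy: str = "keep"  # keep | drop

    def __post_init__(self) -> None:
        if self.threshold_method not in ("li", "otsu", "fixed"):
            raise ParameterError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ParameterError("threshold_method 'fixed' requires fixed_threshold")
        if self.despeckle_rounds < 0:
            raise ParameterError("despeckle_rounds must be >= 0")
        if self.min_area_px > self.max_area_px:
            raise ParameterError(
                f"min_area_px ({self.min_area_px}) > max_area_px ({self.max_area_px})"
            )
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")
        if self.border_policy not in ("keep", "drop"):
            raise ParameterError(f"unknown border_policy {self.border_policy!r}")


def project_max(stack: ChannelStack, channel_role: str) -> np.ndarray:
    """Maximum-intensity z-projection of one channel.

    Single-plane input is returned unchanged (a copy is not made).
    """
    planes = stack.channel(channel_role)  # raises ConfigurationError if absent
    if planes.shape[0] == 1:
        return planes[0]
    return planes.max(axis=0)


def subtract_channel(minuend: np.ndarray, subtrahend: np.ndarray) -> np.ndarray:
    """Pixelwise ``minuend - subtrahend`` clipped at 0 (no unsigned wraparound).

    Used to remove co-localized autofluorescence: the blue emission channel
    (autofluorescence only) is subtracted from the green one.
    """
    minuend = np.asarray(minuend)
    subtrahend = np.asarray(subtrahend)
    if minuend.shape != subtrahend.shape:
        raise ParameterError(
            f"shape mismatch: {minuend.shape} vs {subtrahend.shape}"
        )
    diff = minuend.astype(np.int64) - subtrahend.astype(np.int64)
    return np.clip(diff, 0, None).astype(minuend.dtype)


def li_threshold(image: np.ndarray) -> int:
    """Global threshold by exact minimization of the cross-entropy criterion.

    Over every candidate integer threshold ``t`` the criterion

    .. math::

        \\eta(t) = \\sum_{g \\le t} h(g)\\,g\\,\\log(g/\\mu_{low}(t))
                 + \\sum_{g > t}   h(g)\\,g\\,\\log(g/\\mu_{high}(t))

    is evaluated on the intensity histogram ``h`` (class means
    :math:`\\mu_{low},\\mu_{high}` are mean intensities of the two classes)
    and the minimizing ``t`` is returned; ties break toward the smaller
    threshold.  Bins with ``g = 0`` contribute 0 (the ``g log g -> 0`` limit).
    The evaluation is exhaustive over all occupied gray levels — no iterative
    fixed point — so the result is the exact discrete argmin.

    Binarization downstream is strict: ``pixel > t`` is foreground.

    Raises
    ------
    DegenerateInputError
        If the image is constant (fewer than 2 distinct gray levels).
    """
    image = np.asarray(image)
    if not np.issubdtype(image.dtype, np.integer):
        raise ParameterError("li_threshold expects an integer-valued image")
    flat = image.ravel().astype(np.int64)
    counts = np.bincount(flat)
    levels = np.nonzero(counts)[0]
    if levels.size < 2:
        raise DegenerateInputError(
            "constant image: automatic thresholding is undefined"
        )
    g = levels.astype(np.float64)
    h = counts[levels].astype(np.float64)
    wg = h * g  # class intensity mass per bin
    with np.errstate(divide="ignore"):
        wglogg = np.where(g > 0, wg * np.log(np.where(g > 0, g, 1.0)), 0.0)

    # cumulative class sums for thresholds t = levels[0..n-2]
    n_low = np.cumsum(h)[:-1]
    s_low = np.cumsum(wg)[:-1]
    l_low = np.cumsum(wglogg)[:-1]
    n_high = h.sum() - n_low
    s_high = wg.sum() - s_low
    l_high = wglogg.sum() - l_low

    def class_term(s, n, l):
        # sum h g log g  -  (sum h g) log(mu);  all-zero class contributes 0
        out = np.zeros_like(s)
        nz = s > 0
        out[nz] = l[nz] - s[nz] * np.log(s[nz] / n[nz])
        return out

    eta = class_term(s_low, n_low, l_low) + class_term(s_high, n_high, l_high)
    return int(levels[int(np.argmin(eta))])


def despeckle(image: np.ndarray, rounds: int) -> np.ndarray:
    """Apply a 3x3 median filter `rounds` times (Fiji-style despeckling).

    ``rounds = 0`` returns the input unchanged.  Borders are handled by
    nearest-edge replication, matching the replicate-padding convention of the
    ImageJ rank filters.  The output value range is a subset of the input's
    (a median never invents values).
    """
    if rounds < 0:
        raise ParameterError("rounds must be >= 0")
    out = np.asarray(image)
    for _ in range(rounds):
        out = ndimage.median_filter(out, size=3, mode="nearest")
    return out


def label_components(binary: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected components of a boolean mask under 4- or 8-connectivity,
    relabeled into raster-scan order of each object's first pixel."""
    if connectivity not in (4, 8):
        raise ParameterError("connectivity must be 4 or 8")
    skimage_conn = 1 if connectivity == 4 else 2
    labels = measure.label(np.asarray(binary) > 0, connectivity=skimage_conn)
    return relabel_raster_order(labels)


def relabel_raster_order(labels: np.ndarray) -> np.ndarray:
    """Relabel objects densely 1..K in raster-scan order of their first pixel.

    Deterministic tie-free ordering: object A precedes object B iff A's first
    pixel (row-major) precedes B's.
    """
    labels = np.asarray(labels)
    flat = labels.ravel()
    ids, first = np.unique(flat, return_index=True)
    nz = ids > 0
    ids, first = ids[nz], first[nz]
    if ids.size == 0:
        return labels.astype(np.int32)
    lut = np.zeros(int(ids.max()) + 1, dtype=np.int32)
    lut[ids[np.argsort(first, kind="stable")]] = np.arange(1, ids.size + 1)
    return lut[labels]


def size_filter(
    labels: np.ndarray, min_area_px: int, max_area_px: int
) -> np.ndarray:
    """Drop objects whose area lies outside ``[min_area_px, max_area_px]``
    (closed interval) and relabel the survivors densely in raster order."""
    if min_area_px > max_area_px:
        raise ParameterError(
            f"min_area_px ({min_area_px}) > max_area_px ({max_area_px})"
        )
    labels = np.asarray(labels)
    if labels.size == 0 or labels.max() == 0:
        return labels.astype(np.int32)
    areas = np.bincount(labels.ravel())
    keep = (areas >= min_area_px) & (areas <= max_area_px)
    keep[0] = False
    filtered = np.where(keep[labels], labels, 0)
    return relabel_raster_order(filtered)


def _drop_border_objects(labels: np.ndarray) -> np.ndarray:
    border = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    border = border[border > 0]
    if border.size == 0:
        return labels
    mask = np.isin(labels, border)
    out = labels.copy()
    out[mask] = 0
    return relabel_raster_order(out)


def segment_cells(
    stack: ChannelStack, role: str, params: SegmentationParams
) -> np.ndarray:
    """Full segmentation chain on one channel of a stack.

    max-projection (if z > 1) -> global threshold (``li`` by default, or
    ``otsu`` / ``fixed``) -> binary despeckling -> connected components ->
    inclusive size filter -> dense raster-order relabel.  Deterministic for
    fixed input and parameters.
    """
    image = project_max(stack, role)
    if params.threshold_method == "li":
        t = li_threshold(image)
    elif params.threshold_method == "otsu":
        if image.min() == image.max():
            raise DegenerateInputError("constant image: automatic thresholding is undefined")
        t = threshold_otsu(image)
    else:
        t = params.fixed_threshold
    binary = (image > t).astype(np.uint8)
    binary = despeckle(binary, params.despeckle_rounds)
    labels = label_components(binary, params.connectivity)
    labels = size_filter(labels, params.min_area_px, params.max_area_px)
    if params.border_policy == "drop":
        labels = _drop_border_objects(labels)
    return labels
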