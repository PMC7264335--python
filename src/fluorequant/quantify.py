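"""Per-cell intensity quantification and positive-cell classification.

Quantification follows the reporter-assay convention: the average signal
intensity within each segmented cell is corrected for background by
subtracting the mean intensity of the non-cell background region of the same
image (the background ROI is the complement of every object dilated by a
small margin).  The sensor signal may additionally be normalized to the
expression reporter (EGFP-to-mCherry ratio) to factor out induction
differences.

Two positivity rules are supported:

* ``control_null`` — a cell is positive when its background-corrected signal
  exceeds the mean plus ``k_sd`` (default 2) sample standard deviations of the
  same signal measured in negative-control cells.  For a Gaussian null this
  calibrates the false-positive rate to ``1 - Phi(k_sd)`` (~2.28% at k=2).
* ``fixed`` — a cell is positive when the background-corrected signal exceeds
  a fixed cutoff in AU (default 400, the convention of the CSF plate screen).

Both comparisons are strict (``value > threshold``): a cell sitting exactly
at the cutoff is negative.

Cell tables are plain :class:`pandas.DataFrame` objects with one row per
cell; columns are ``cell_id, area_px, centroid_row, centroid_col,
raw_mean_<role>, corr_mean_<role>, ratio, is_positive`` plus whatever
provenance columns the pipeline prepends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.morphology import disk

from .errors import (
    ConfigurationError,
    DegenerateFieldError,
    InsufficientControlError,
    ParameterError,
)
from .io import ChannelStack
from .segmentation import project_max

__all__ = [
    "ClassificationRule",
    "estimate_background",
    "measure_cells",
    "compute_ratio",
    "control_null_threshold",
    "classify_cells",
    "summarize_wells",
]

#: below this background-corrected expression level the sensor/expression
#: ratio is undefined (reported as NaN)
RATIO_EPSILON = 1e-9


@dataclass(frozen=True)
class ClassificationRule:
    """The positivity decision and its parameters.

    ``kind`` is ``"control_null"`` (mean + k_sd * SD of control cells) or
    ``"fixed"`` (absolute cutoff in AU).  ``channel_role`` names the channel
    whose background-corrected mean is compared.
    """

    kind: str = "control_null"
    k_sd: float = 2.0
    fixed_threshold: float = 400.0
    channel_role: str = "sensor"
    strict: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("control_null", "fixed"):
            raise ParameterError(f"unknown rule kind {self.kind!r}")
        if self.kind == "control_null" and self.k_sd <= 0:
            raise ParameterError("k_sd must be > 0 for the control_null rule")
        if self.kind == "fixed" and self.fixed_threshold < 0:
            raise ParameterError("fixed_threshold must be >= 0")


def estimate_background(
    image: np.ndarray, labels: np.ndarray, margin_px: int = 3
) -> float:
    """Mean intensity of the background ROI: all pixels outside every object
    after dilating the object mask by ``margin_px`` (disk-shaped structuring
    element), guarding against halo pixels at cell rims.

    Raises :class:`DegenerateFieldError` when the dilated objects cover the
    entire field.
    """
    image = np.asarray(image)
    labels = np.asarray(labels)
    if image.shape != labels.shape:
        raise ParameterError(
            f"image {image.shape} and labels {labels.shape} are not aligned"
        )
    if margin_px < 0:
        raise ParameterError("margin_px must be >= 0")
    mask = labels > 0
    if margin_px > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, structure=disk(margin_px))
    background = ~mask
    if not background.any():
        raise DegenerateFieldError(
            "no background pixels remain after dilating the object mask"
        )
    return float(image[background].mean())


def measure_cells(
    stack: ChannelStack,
    labels: np.ndarray,
    *,
    margin_px: int = 3,
    roles: list[str] | None = None,
) -> pd.DataFrame:
    """Measure every labeled object in every requested channel.

    For each role, ``raw_mean`` is the arithmetic mean of in-mask pixels of
    that channel's max-projection and ``corr_mean`` is the raw mean minus the
    per-image background estimate for that channel, floored at 0.  An empty
    label image yields an empty table (no error).
    """
    labels = np.asarray(labels)
    roles = list(roles) if roles is not None else sorted(stack.roles)
    props = measure.regionprops(labels)
    base = pd.DataFrame(
        {
            "cell_id": [p.label for p in props],
            "area_px": [int(p.area) for p in props],
            "centroid_row": [p.centroid[0] for p in props],
            "centroid_col": [p.centroid[1] for p in props],
        }
    )
    if base.empty:
        cols = ["cell_id", "area_px", "centroid_row", "centroid_col"]
        cols += [f"raw_mean_{r}" for r in roles] + [f"corr_mean_{r}" for r in roles]
        return pd.DataFrame(columns=cols)
    for role in roles:
        image = project_max(stack, role)
        bg = estimate_background(image, labels, margin_px=margin_px)
        sums = ndimage.sum(
            image.astype(np.float64), labels, base["cell_id"].to_numpy()
        )
        raw = np.asarray(sums) / base["area_px"].to_numpy()
        base[f"raw_mean_{role}"] = raw
        base[f"corr_mean_{role}"] = np.maximum(raw - bg, 0.0)
    return base


def compute_ratio(
    cells: pd.DataFrame,
    *,
    sensor_role: str = "sensor",
    expression_role: str = "expression",
    epsilon: float = RATIO_EPSILON,
) -> pd.DataFrame:
    """Add the sensor-to-expression ratio column.

    ``ratio = corr_mean_sensor / corr_mean_expression`` where the corrected
    expression mean exceeds ``epsilon``; otherwise the ratio is undefined and
    stored as NaN.  The ratio is invariant under a common positive rescaling
    of both channels and the background.
    """
    cells = cells.copy()
    num = cells[f"corr_mean_{sensor_role}"]
    den = cells[f"corr_mean_{expression_role}"]
    cells["ratio"] = np.where(den > epsilon, num / den, np.nan)
    return cells


def control_null_threshold(control_values, k_sd: float = 2.0) -> float:
    """Positivity cutoff from negative-control cells: mean + k_sd * sample SD
    (n-1 denominator).  Requires at least 2 control values."""
    values = np.asarray(control_values, dtype=np.float64)
    if values.size < 2:
        raise InsufficientControlError(
            f"control_null threshold needs >= 2 control values, got {values.size}"
        )
    return float(values.mean() + k_sd * values.std(ddof=1))


def classify_cells(
    cells: pd.DataFrame,
    rule: ClassificationRule,
    control_values=None,
) -> pd.DataFrame:
    """Set ``is_positive`` on a cell table under the given rule.

    The compared value is ``corr_mean_<rule.channel_role>``.  The
    ``control_null`` rule derives its threshold from `control_values`
    (background-corrected means of negative-control cells, pooled across the
    experiment); the ``fixed`` rule uses ``rule.fixed_threshold`` directly.
    The applied threshold is recorded in ``DataFrame.attrs["threshold"]``.
    """
    col = f"corr_mean_{rule.channel_role}"
    if col not in cells.columns:
        raise ConfigurationError(f"cell table has no column {col!r}")
    if rule.kind == "control_null":
        if control_values is None:
            raise ConfigurationError(
                "control_null rule requires control_values"
            )
        threshold = control_null_threshold(control_values, rule.k_sd)
    else:
        threshold = float(rule.fixed_threshold)
    cells = cells.copy()
    values = cells[col].to_numpy(dtype=np.float64)
    cells["is_positive"] = values > threshold if rule.strict else values >= threshold
    cells.attrs["threshold"] = threshold
    return cells


def summarize_wells(
    cells: pd.DataFrame, plate_table: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Aggregate classified cells to image, well, and sample level.

    Expects provenance columns ``sample_id, condition, well_id, field_id``
    and the ``is_positive`` flag (``ratio`` optional).  Returns
    ``(per_image, per_well, per_sample)``:

    * per image — cells of one field;
    * per well — cells pooled across the well's fields;
    * per sample — the *unweighted mean* of its replicate wells' fractions
      (each replicate well is one data point, matching per-patient averaging
      over technical triplicates).

    Wells present in `plate_table` but contributing zero cells are listed in
    ``per_well`` with ``n_cells = 0`` and ``excluded = True`` and do not enter
    the sample mean.
    """
    required = {"sample_id", "condition", "well_id", "field_id", "is_positive"}
    missing = required - set(cells.columns)
    if missing:
        raise ConfigurationError(f"cell table missing column(s): {sorted(missing)}")

    def _agg(group: pd.DataFrame) -> pd.Series:
        n = len(group)
        npos = int(group["is_positive"].sum())
        out = {
            "n_cells": n,
            "n_positive": npos,
            "fraction_positive": npos / n if n else np.nan,
        }
        if "ratio" in group.columns:
            out["mean_ratio"] = float(group["ratio"].mean())  # NaN-aware
        return pd.Series(out)

    img_keys = ["sample_id", "condition", "well_id", "field_id"]
    per_image = (
        cells.groupby(img_keys, sort=True).apply(_agg, include_groups=False).reset_index()
    )
    well_keys = ["sample_id", "condition", "well_id"]
    per_well = (
        cells.groupby(well_keys, sort=True).apply(_agg, include_groups=False).reset_index()
    )
    per_well["excluded"] = per_well["n_cells"] == 0

    if plate_table is not None:
        have = set(per_well["well_id"])
        empty_rows = []
        for _, row in plate_table.iterrows():
            if row["well_id"] not in have:
                empty_rows.append(
                    {
                        "sample_id": row["sample_id"],
                        "condition": row["condition"],
                        "well_id": row["well_id"],
                        "n_cells": 0,
                        "n_positive": 0,
                        "fraction_positive": np.nan,
                        "excluded": True,
                    }
                )
        if empty_rows:
            per_well = pd.concat(
                [per_well, pd.DataFrame(empty_rows)], ignore_index=True
            ).sort_values(well_keys, kind="stable").reset_index(drop=True)

    valid = per_well[~per_well["excluded"]]
    per_sample = (
        valid.groupby(["sample_id", "condition"], sort=True)
        .agg(
            n_wells=("well_id", "count"),
            n_cells=("n_cells", "sum"),
            fraction_positive=("fraction_positive", "mean"),
            **(
                {"mean_ratio": ("mean_ratio", "mean")}
                if "mean_ratio" in per_well.columns
                else {}
            ),
        )
        .reset_index()
    )
    return per_image, per_well, per_sample
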