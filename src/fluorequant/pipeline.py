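"""End-to-end orchestration of the plate and in vivo workflows.

``run_plate`` analyses a well-plate experiment: every field of every well is
segmented (on the expression channel by default, so untransduced cells never
enter the denominator), quantified, and classified; wells are summarized into
per-sample values (the mean over technical replicate wells); and the
condition groups are compared by one-way ANOVA with Tukey's post hoc test.

``run_invivo`` analyses paired two-channel z-stacks: max-projection of both
channels, subtraction of the autofluorescence (blue) channel from the green
one, minimum cross-entropy thresholding, four rounds of despeckling,
connected components, a 20–150 px nucleus-size filter, per-nucleus mean
intensity of the subtracted image, pooling across animals per condition, and
an unpaired two-tailed Student's t-test.

Both runs are fully deterministic for a fixed config: rerunning produces
byte-identical CSVs.  Per-field errors quarantine the field (logged with its
identity) rather than aborting; a run fails only when more than half of its
fields error.  The effective configuration is serialized into the output
directory alongside the tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .errors import ConfigurationError, FluoreQuantError, ValidationError
from .io import PlateMap, load_config, read_plate_map, read_stack
from .quantify import (
    ClassificationRule,
    classify_cells,
    compute_ratio,
    measure_cells,
    summarize_wells,
)
from .segmentation import (
    SegmentationParams,
    despeckle,
    label_components,
    li_threshold,
    project_max,
    segment_cells,
    size_filter,
    subtract_channel,
)
from .stats import StatsResult, t_test_unpaired, tukey_hsd

__all__ = ["RunConfig", "run_plate", "run_invivo", "stats_result_to_frame"]

logger = logging.getLogger("fluorequant")

#: fraction of errored fields above which a run aborts (arbitrary, documented)
MAX_FIELD_ERROR_FRACTION = 0.5

#: fixed float format for every CSV the pipeline writes (determinism contract)
CSV_FLOAT_FORMAT = "%.9g"


@dataclass
class RunConfig:
    """Validated run configuration (one YAML file drives a whole run)."""

    mode: str
    images_dir: Path
    output_dir: Path
    channels: dict[str, int]
    plate_map: Path | None = None
    stack_list: Path | None = None
    n_z: int = 1
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    segment_on: str = "expression"
    rule: ClassificationRule = field(default_factory=ClassificationRule)
    control_condition: str = "control"
    background_margin_px: int = 3
    alpha: float = 0.05
    seed: int = 0
    raw: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        mode = cfg.get("mode")
        if mode not in ("plate", "invivo"):
            raise ConfigurationError(f"mode must be 'plate' or 'invivo', got {mode!r}")
        paths = cfg.get("paths") or {}
        for key in ("images_dir", "output_dir"):
            if key not in paths:
                raise ConfigurationError(f"paths.{key} is required")
        channels = cfg.get("channels")
        if not channels:
            raise ConfigurationError("a 'channels' role map is required")
        seg_cfg = dict(cfg.get("segmentation") or {})
        segment_on = seg_cfg.pop("channel_role", "expression" if mode == "plate" else "sensor")
        seg = SegmentationParams(**seg_cfg) if seg_cfg else SegmentationParams(
            **({} if mode == "invivo" else {"despeckle_rounds": 1, "max_area_px": 200})
        )
        cls_cfg = dict(cfg.get("classification") or {})
        control_condition = cls_cfg.pop("control_condition", "control")
        rule = ClassificationRule(**cls_cfg) if cls_cfg else ClassificationRule()
        stats_cfg = cfg.get("stats") or {}
        return cls(
            mode=mode,
            images_dir=Path(paths["images_dir"]),
            output_dir=Path(paths["output_dir"]),
            plate_map=Path(paths["plate_map"]) if "plate_map" in paths else None,
            stack_list=Path(paths["stack_list"]) if "stack_list" in paths else None,
            channels={str(k): int(v) for k, v in channels.items()},
            n_z=int(cfg.get("n_z", 1)),
            segmentation=seg,
            segment_on=segment_on,
            rule=rule,
            control_condition=control_condition,
            background_margin_px=int((cfg.get("background") or {}).get("margin_px", 3)),
            alpha=float(stats_cfg.get("alpha", 0.05)),
            seed=int(cfg.get("seed", 0)),
            raw=cfg,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(load_config(path))

    def serialize(self) -> None:
        """Copy the effective configuration into the output directory."""
        self.output_dir.mkdir(parents=True, exist_ok=True)
        payload = self.raw or {
            "mode": self.mode,
            "paths": {
                "images_dir": str(self.images_dir),
                "output_dir": str(self.output_dir),
            },
            "channels": self.channels,
        }
        with open(self.output_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def _field_images(config: RunConfig, well_id: str) -> list[Path]:
    """Images of one well: ``<well_id>_*.tif[f]`` in the images dir, sorted."""
    hits = sorted(config.images_dir.glob(f"{well_id}_*.tif")) + sorted(
        config.images_dir.glob(f"{well_id}_*.tiff")
    )
    return hits


def stats_result_to_frame(result: StatsResult) -> pd.DataFrame:
    """Flatten a StatsResult into the stats CSV layout (one omnibus row, one
    row per pairwise comparison)."""
    rows = [
        {
            "test": result.test_name,
            "statistic": result.statistic,
            "df": "/".join(f"{d:g}" for d in result.df),
            "p_value": result.p_value,
            "pair": "",
            "mean_diff": np.nan,
            "adjusted_p": np.nan,
            "note": result.note,
        }
    ]
    for pw in result.pairwise:
        rows.append(
            {
                "test": "tukey_pair",
                "statistic": pw["q"],
                "df": "/".join(f"{d:g}" for d in result.df),
                "p_value": np.nan,
                "pair": f"{pw['pair'][0]} vs {pw['pair'][1]}",
                "mean_diff": pw["mean_diff"],
                "adjusted_p": pw["adjusted_p"],
                "note": "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plate workflow
# ---------------------------------------------------------------------------

def run_plate(
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, StatsResult | None]:
    """Run the well-plate analysis end to end.

    Returns ``(per_cell, per_well, per_sample, stats_result)`` and writes
    ``per_cell.csv``, ``per_image.csv``, ``per_well.csv``, ``per_sample.csv``,
    ``stats.csv`` and ``config.yaml`` into the output directory.
    ``stats_result`` is ``None`` when fewer than two condition groups have the
    two replicates a variance-based test needs.
    """
    if config.plate_map is None:
        raise ConfigurationError("plate mode requires paths.plate_map")
    plate = read_plate_map(config.plate_map)
    if plate.table.empty:
        raise ConfigurationError(f"plate map {config.plate_map} is empty")
    config.serialize()

    all_cells: list[pd.DataFrame] = []
    n_fields = 0
    n_errors = 0
    for _, wrow in plate.table.iterrows():
        well = wrow["well_id"]
        images = _field_images(config, well)
        if not images:
            logger.warning("well %s: no images found in %s", well, config.images_dir)
        for img_path in images:
            n_fields += 1
            try:
                stack = read_stack(img_path, config.channels, n_z=config.n_z)
                labels = segment_cells(stack, config.segment_on, config.segmentation)
                cells = measure_cells(
                    stack, labels, margin_px=config.background_margin_px
                )
                if {"sensor", "expression"} <= set(config.channels):
                    cells = compute_ratio(cells)
                cells.insert(0, "field_id", img_path.stem)
                cells.insert(0, "well_id", well)
                cells.insert(0, "condition", wrow["condition"])
                cells.insert(0, "sample_id", wrow["sample_id"])
                all_cells.append(cells)
            except FluoreQuantError as exc:
                n_errors += 1
                logger.error("field %s (well %s) failed: %s", img_path.name, well, exc)
    if n_fields == 0:
        raise ConfigurationError("no image fields found for any well")
    if n_errors > MAX_FIELD_ERROR_FRACTION * n_fields:
        raise ValidationError(
            f"{n_errors}/{n_fields} fields errored (> {MAX_FIELD_ERROR_FRACTION:.0%})"
        )
    per_cell = pd.concat(all_cells, ignore_index=True) if all_cells else pd.DataFrame()
    if per_cell.empty:
        raise ValidationError("no cells measured in any field")

    control_values = None
    if config.rule.kind == "control_null":
        mask = per_cell["condition"] == config.control_condition
        control_values = per_cell.loc[
            mask, f"corr_mean_{config.rule.channel_role}"
        ].to_numpy()
        if control_values.size < 2:
            raise ConfigurationError(
                f"control_null rule: condition {config.control_condition!r} "
                f"contributed {control_values.size} control cells (need >= 2)"
            )
    per_cell = classify_cells(per_cell, config.rule, control_values)
    threshold = per_cell.attrs["threshold"]
    logger.info("positivity threshold: %.4g AU (%s rule)", threshold, config.rule.kind)

    per_cell = per_cell.sort_values(
        ["sample_id", "condition", "well_id", "field_id", "cell_id"], kind="stable"
    ).reset_index(drop=True)
    per_image, per_well, per_sample = summarize_wells(per_cell, plate.table)

    result: StatsResult | None = None
    by_cond = {
        cond: grp["fraction_positive"].dropna().to_numpy()
        for cond, grp in per_sample.groupby("condition", sort=True)
    }
    by_cond = {c: v for c, v in by_cond.items() if v.size >= 2}
    if len(by_cond) >= 2:
        result = tukey_hsd(by_cond, alpha=config.alpha)
    else:
        logger.warning("fewer than 2 condition groups with n >= 2; skipping stats")

    out = config.output_dir
    _write_csv(per_cell, out / "per_cell.csv")
    _write_csv(per_image, out / "per_image.csv")
    _write_csv(per_well, out / "per_well.csv")
    _write_csv(per_sample, out / "per_sample.csv")
    if result is not None:
        _write_csv(stats_result_to_frame(result), out / "stats.csv")
    return per_cell, per_well, per_sample, result


# ---------------------------------------------------------------------------
# in vivo workflow
# ---------------------------------------------------------------------------

def segment_invivo_field(
    stack, params: SegmentationParams
) -> tuple[np.ndarray, np.ndarray]:
    """The in vivo mask chain on one stack.

    Returns ``(labels, subtracted)`` where `subtracted` is the
    autofluorescence-corrected max-projection the intensities are read from.
    """
    green = project_max(stack, "sensor")
    blue = project_max(stack, "auxiliary")
    subtracted = subtract_channel(green, blue)
    t = li_threshold(subtracted)
    binary = despeckle((subtracted > t).astype(np.uint8), params.despeckle_rounds)
    labels = label_components(binary, params.connectivity)
    labels = size_filter(labels, params.min_area_px, params.max_area_px)
    return labels, subtracted


def run_invivo(config: RunConfig) -> tuple[pd.DataFrame, StatsResult | None]:
    """Run the in vivo nuclei-intensity comparison end to end.

    The stack list CSV (``paths.stack_list``) needs columns
    ``animal_id, condition, path``.  Per-nucleus mean intensities of the
    subtracted image are pooled across animals within each condition and the
    two conditions are compared with an unpaired two-tailed Student's t-test.
    Returns ``(per_nucleus, stats_result)``; writes ``per_nucleus.csv`` and
    ``stats.csv``.
    """
    if config.stack_list is None:
        raise ConfigurationError("invivo mode requires paths.stack_list")
    listing = pd.read_csv(config.stack_list, dtype={"animal_id": str, "condition": str})
    required = {"animal_id", "condition", "path"}
    if not required <= set(listing.columns):
        raise ValidationError(f"stack list needs columns {sorted(required)}")
    if listing.empty:
        raise ConfigurationError(f"stack list {config.stack_list} is empty")
    config.serialize()

    rows: list[pd.DataFrame] = []
    for _, srow in listing.iterrows():
        path = config.images_dir / srow["path"]
        try:
            stack = read_stack(path, config.channels, n_z=config.n_z)
            labels, subtracted = segment_invivo_field(stack, config.segmentation)
        except FluoreQuantError as exc:
            logger.warning("animal %s: skipped (%s)", srow["animal_id"], exc)
            continue
        if labels.max() == 0:
            logger.warning(
                "animal %s: zero nuclei survive the size filter; excluded",
                srow["animal_id"],
            )
            continue
        ids = np.arange(1, labels.max() + 1)
        means = ndimage.mean(subtracted.astype(np.float64), labels, ids)
        areas = np.bincount(labels.ravel())[1:]
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": srow["animal_id"],
                    "condition": srow["condition"],
                    "nucleus_id": ids,
                    "area_px": areas,
                    "mean_intensity": np.asarray(means),
                }
            )
        )
    if not rows:
        raise ValidationError("no animal yielded any nuclei")
    per_nucleus = pd.concat(rows, ignore_index=True)

    result: StatsResult | None = None
    conds = sorted(per_nucleus["condition"].unique())
    if len(conds) == 2:
        a = per_nucleus.loc[per_nucleus["condition"] == conds[0], "mean_intensity"]
        b = per_nucleus.loc[per_nucleus["condition"] == conds[1], "mean_intensity"]
        if a.size >= 2 and b.size >= 2:
            result = t_test_unpaired(a.to_numpy(), b.to_numpy(), two_tailed=True)
    else:
        logger.warning("expected 2 conditions, found %d; skipping t-test", len(conds))

    out = config.output_dir
    _write_csv(per_nucleus, out / "per_nucleus.csv")
    if result is not None:
        _write_csv(stats_result_to_frame(result), out / "stats.csv")
    return per_nucleus, result
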