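"""Reading and writing the formats the pipeline touches.

Conventions
-----------
* Pixel arrays are laid out ``(z, channel, row, col)`` internally; single-plane
  data is stored with ``z = 1``.  Coordinates are 0-based ``(row, col)`` with
  the origin at the top-left.
* Intensities are raw camera counts in arbitrary units (AU); nothing is
  rescaled on load.
* Multi-channel TIFFs store channels as pages in acquisition order (for
  z-stacks: all channels of plane 0, then plane 1, ...).  Channel roles are
  supplied externally (role map argument or the ``channels`` section of a YAML
  config) because plain TIFF carries no role metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigurationError, FormatError, ValidationError

#: Channel roles understood by the pipeline.
ROLES = ("nuclear", "expression", "sensor", "auxiliary")


@dataclass
class ChannelStack:
    """A multi-channel (optionally z-stacked) image with channel roles.

    Parameters
    ----------
    pixels
        Non-negative integer array of shape ``(z, n_channels, rows, cols)``.
        2-D ``(rows, cols)`` or 3-D ``(n_channels, rows, cols)`` input is
        promoted on construction.
    roles
        Map from role name (one of :data:`ROLES`) to channel index.  Every
        declared role must map to exactly one channel index.
    bit_depth
        8 or 16; pixel values must not exceed ``2**bit_depth - 1``.
    """

    pixels: np.ndarray
    roles: dict[str, int]
    bit_depth: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[None, None]
        elif px.ndim == 3:
            px = px[None]
        elif px.ndim != 4:
            raise ValidationError(
                f"pixels must be 2-D, 3-D or 4-D, got {px.ndim}-D"
            )
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValidationError(f"pixels must be integer-typed, got {px.dtype}")
        if px.size and int(px.min()) < 0:
            raise ValidationError("pixel values must be non-negative")
        if px.size and int(px.max()) > 2**self.bit_depth - 1:
            raise ValidationError(
                f"pixel values exceed 2**{self.bit_depth} - 1"
            )
        n_channels = px.shape[1]
        for role, idx in self.roles.items():
            if role not in ROLES:
                raise ConfigurationError(
                    f"unknown channel role {role!r}; expected one of {ROLES}"
                )
            if not 0 <= int(idx) < n_channels:
                raise ConfigurationError(
                    f"role {role!r} maps to channel {idx}, but the stack has "
                    f"{n_channels} channel(s)"
                )
        if len(set(self.roles.values())) != len(self.roles):
            raise ConfigurationError("two roles map to the same channel index")
        self.pixels = px

    # -- convenience accessors -------------------------------------------
    @property
    def n_z(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of one plane."""
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel(self, role: str) -> np.ndarray:
        """All z-planes of the channel holding `role`, shape ``(z, r, c)``."""
        if role not in self.roles:
            raise ConfigurationError(
                f"stack has no channel with role {role!r}; roles: "
                f"{sorted(self.roles)}"
            )
        return self.pixels[:, self.roles[role]]


@dataclass
class PlateMap:
    """Well -> condition -> replicate structure of a plate experiment.

    `table` has columns ``well_id``, ``condition``, ``replicate`` and
    ``sample_id``.  When the source file omits the optional ``sample_id``
    column each well is treated as its own independent sample.
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("well_id", "condition", "replicate")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValidationError(f"plate map missing column(s): {missing}")
        dup = t["well_id"][t["well_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate well_id(s) in plate map: {sorted(set(dup))}"
            )
        if "sample_id" not in t.columns or t["sample_id"].isna().all():
            t = t.copy()
            t["sample_id"] = t["well_id"]
        self.table = t.reset_index(drop=True)

    @property
    def wells(self) -> list[str]:
        return list(self.table["well_id"])

    def replicate_counts(self) -> pd.Series:
        """Number of replicate wells per sample."""
        return self.table.groupby("sample_id", sort=True)["well_id"].count()


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def read_stack(
    path: str | Path,
    role_map: dict[str, int],
    *,
    bit_depth: int | None = None,
    n_z: int = 1,
) -> ChannelStack:
    """Read a single- or multi-page TIFF into a :class:`ChannelStack`.

    Pages are interpreted as channels (z-major when ``n_z > 1``: the file
    holds ``n_z * n_channels`` pages ordered plane-by-plane).  `role_map`
    assigns roles to channel indices and must cover every role the caller
    intends to use downstream.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several unrelated types
        raise FormatError(f"could not read {path} as TIFF: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise FormatError(f"{path}: expected 2-D pages, got shape {pages.shape}")
    n_pages = pages.shape[0]
    if n_pages % n_z:
        raise FormatError(
            f"{path}: {n_pages} pages not divisible by n_z={n_z}"
        )
    n_channels = n_pages // n_z
    px = pages.reshape(n_z, n_channels, *pages.shape[1:])
    if bit_depth is None:
        bit_depth = 8 if px.dtype == np.uint8 else 16
    return ChannelStack(pixels=px, roles=dict(role_map), bit_depth=bit_depth)


def write_stack(path: str | Path, stack: ChannelStack) -> Path:
    """Write a :class:`ChannelStack` as a multi-page TIFF (z-major page order).

    The written file round-trips bit-identically through :func:`read_stack`
    with the same role map and ``n_z``.
    """
    path = Path(path)
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    pages = stack.pixels.reshape(-1, *stack.shape).astype(dtype)
    # channels are pages, not RGB samples
    tifffile.imwrite(path, pages, photometric="minisblack")
    return path


def write_labels(path: str | Path, labels: np.ndarray) -> Path:
    """Write a label image as 16-bit single-channel TIFF."""
    labels = np.asarray(labels)
    if labels.size and labels.max() > np.iinfo(np.uint16).max:
        raise ValidationError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(Path(path), labels.astype(np.uint16))
    return Path(path)


def read_labels(path: str | Path) -> np.ndarray:
    labels = tifffile.imread(Path(path))
    return np.asarray(labels).astype(np.int32)


# ---------------------------------------------------------------------------
# Tables and configuration
# ---------------------------------------------------------------------------

def read_plate_map(path: str | Path) -> PlateMap:
    """Read a CSV plate map with header ``well_id,condition,replicate[,sample_id]``."""
    table = pd.read_csv(path, dtype={"well_id": str, "condition": str})
    return PlateMap(table=table)


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict.

    Parsing is order-independent; section validation happens where each
    section is consumed (see :mod:`fluorequant.pipeline`).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a YAML mapping")
    return cfg
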