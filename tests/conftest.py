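"""Shared fixtures and independent oracle implementations.

The oracles here are deliberately naive (per-pixel loops, exhaustive
searches) and independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import yaml

import fluorequant as fq
from fluorequant import io as fio


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def li_exhaustive(image: np.ndarray) -> int:
    """Exhaustive minimizer of the cross-entropy criterion over every
    candidate integer threshold, computed bin-by-bin in plain Python."""
    flat = np.asarray(image).ravel().astype(np.int64)
    counts = np.bincount(flat)
    levels = [g for g in range(len(counts)) if counts[g] > 0]
    best_eta, best_t = np.inf, None
    for t in levels[:-1]:
        low = [(g, counts[g]) for g in levels if g <= t]
        high = [(g, counts[g]) for g in levels if g > t]
        n_low = sum(h for _, h in low)
        n_high = sum(h for _, h in high)
        mu_low = sum(g * h for g, h in low) / n_low
        mu_high = sum(g * h for g, h in high) / n_high
        eta = 0.0
        for g, h in low:
            if g > 0:
                eta += h * g * np.log(g / mu_low)
        for g, h in high:
            if g > 0:
                eta += h * g * np.log(g / mu_high)
        if eta < best_eta - 1e-12:
            best_eta, best_t = eta, t
    return int(best_t)


def median3x3_naive(image: np.ndarray) -> np.ndarray:
    """One pass of a 3x3 median with nearest-edge (replicate) padding,
    computed with an explicit sliding-window loop."""
    image = np.asarray(image)
    padded = np.pad(image, 1, mode="edge")
    out = np.empty_like(image)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            out[r, c] = np.median(padded[r : r + 3, c : c + 3])
    return out


def flood_fill_components(binary: np.ndarray, connectivity: int) -> int:
    """Count connected components by explicit BFS flood fill."""
    binary = np.asarray(binary) > 0
    visited = np.zeros_like(binary, dtype=bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    count = 0
    h, w = binary.shape
    for r0 in range(h):
        for c0 in range(w):
            if binary[r0, c0] and not visited[r0, c0]:
                count += 1
                queue = [(r0, c0)]
                visited[r0, c0] = True
                while queue:
                    r, c = queue.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and binary[rr, cc] and not visited[rr, cc]:
                            visited[rr, cc] = True
                            queue.append((rr, cc))
    return count


def greedy_centroid_match(
    recovered: np.ndarray, truth: np.ndarray, max_dist: float = 2.0
) -> int:
    """Greedy nearest-centroid matching; returns the number of recovered
    centroids paired with a distinct ground-truth centroid within
    `max_dist` pixels."""
    recovered = np.asarray(recovered, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if len(recovered) == 0 or len(truth) == 0:
        return 0
    dists = np.linalg.norm(recovered[:, None, :] - truth[None, :, :], axis=2)
    pairs = sorted(
        ((dists[i, j], i, j) for i in range(len(recovered)) for j in range(len(truth)))
    )
    used_r, used_t, matched = set(), set(), 0
    for d, i, j in pairs:
        if d > max_dist:
            break
        if i not in used_r and j not in used_t:
            used_r.add(i)
            used_t.add(j)
            matched += 1
    return matched


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def noise_free_params() -> fq.SynthParams:
    return fq.SynthParams(seed=42, read_noise_sd=0.0, shot_noise=False)


@pytest.fixture(scope="session")
def noise_free_field(noise_free_params):
    return fq.generate_well_field(noise_free_params)


@pytest.fixture(scope="session")
def default_field():
    return fq.generate_well_field(fq.SynthParams(seed=42))


@pytest.fixture(scope="session")
def invivo_noise_free():
    params = fq.SynthParams.invivo(seed=42, read_noise_sd=0.0, shot_noise=False)
    return params, fq.generate_invivo_stack(params)


@pytest.fixture(scope="session")
def invivo_default():
    params = fq.SynthParams.invivo(seed=42)
    return params, fq.generate_invivo_stack(params)


@pytest.fixture
def well_seg_params() -> fq.SegmentationParams:
    """Segmentation defaults for monolayer fields (larger nuclei than the
    in vivo 20-150 px range, light despeckling)."""
    return fq.SegmentationParams(despeckle_rounds=1, min_area_px=20, max_area_px=200)


def make_plate(
    root,
    conditions: dict[str, tuple[float, int]],
    *,
    n_fields: int = 2,
    n_cells: int = 60,
    size: int = 256,
    base_seed: int = 0,
    rule: dict | None = None,
):
    """Materialize a synthetic plate experiment on disk.

    `conditions` maps condition label -> (p_positive, n_wells).  Returns the
    RunConfig for the plate.  Seeds derive deterministically from `base_seed`
    and the (well, field) index so reruns are byte-identical.
    """
    images = root / "images"
    out = root / "out"
    images.mkdir(parents=True, exist_ok=True)
    rows = []
    widx = 0
    for cond, (p_pos, n_wells) in conditions.items():
        for rep in range(n_wells):
            well = f"W{widx:02d}"
            widx += 1
            rows.append(
                {
                    "well_id": well,
                    "condition": cond,
                    "replicate": rep + 1,
                    "sample_id": f"{cond}-s{rep + 1}",
                }
            )
            for f in range(n_fields):
                params = fq.SynthParams(
                    seed=base_seed + 1000 * widx + f,
                    n_cells=n_cells,
                    p_positive=p_pos,
                    image_height_px=size,
                    image_width_px=size,
                )
                stack, _, _ = fq.generate_well_field(params)
                fio.write_stack(images / f"{well}_f{f}.tif", stack)
    plate_csv = root / "plate.csv"
    pd.DataFrame(rows).to_csv(plate_csv, index=False)
    cfg = {
        "mode": "plate",
        "paths": {
            "images_dir": str(images),
            "plate_map": str(plate_csv),
            "output_dir": str(out),
        },
        "channels": {"nuclear": 0, "expression": 1, "sensor": 2},
        "segmentation": {
            "channel_role": "expression",
            "threshold_method": "li",
            "despeckle_rounds": 1,
            "min_area_px": 20,
            "max_area_px": 200,
        },
        "classification": rule
        or {
            "kind": "control_null",
            "k_sd": 2.0,
            "channel_role": "sensor",
            "control_condition": "control",
        },
        "seed": base_seed,
    }
    cfg_path = root / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh)
    return fq.RunConfig.from_yaml(cfg_path)
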