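"""Masked grey-level co-occurrence texture analysis of parameter maps.

Each polarimetric parameter map is subdivided into non-overlapping
sub-images (tiles); per tile we compute the mean, the mean absolute
deviation (MAD) and five Haralick-style texture features from a
direction-averaged grey-level co-occurrence matrix (GLCM), plus the
pixel density (count of valid pixels), assembling the 36-column feature
table (5 parameters x 7 statistics + pixel density).

The GLCM here is *masked*: background/invalid pixels are NaN and any
pixel pair touching one is skipped, so texture reflects only the
signal-producing structures.  This is why the matrix is built in-house
rather than with ``skimage.feature.graycomatrix`` (which has no mask
support); the skimage routine serves as an independent cross-check on
fully valid tiles in the test-suite.

Texture definitions (P the normalized direction-averaged GLCM):

* contrast     ``sum (i-j)^2 P(i,j)``
* correlation  ``sum P(i,j)(i-mu)(j-mu)/sigma^2`` with mu, sigma the
  GLCM marginal mean/SD (symmetric GLCM, identical marginals)
* entropy      ``-sum P log2 P`` (0 log 0 := 0), in bits
* ASM          ``sum P^2`` (angular second moment, orderliness)
* IDM          ``sum P / (1 + (i-j)^2)`` (homogeneity)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .polarimetry import ParameterMaps

__all__ = [
    "Glcm",
    "MISSING_LEVEL",
    "tile_image",
    "quantize",
    "masked_glcm",
    "texture_features",
    "subimage_stats",
    "build_feature_table",
    "FEATURE_STATS",
    "feature_columns",
]

#: sentinel grey level marking masked/NaN pixels in quantized images
MISSING_LEVEL = -1

#: per-parameter statistics, in feature-table column order
FEATURE_STATS = ("mean", "mad", "contrast", "correlation", "entropy", "asm", "idm")

#: (dr, dc) unit offsets for the four standard co-occurrence angles
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def feature_columns(params: tuple[str, ...] = ParameterMaps.PARAM_NAMES) -> list[str]:
    """The 36 feature-table columns: pixel_density then {param}_{stat}."""
    return ["pixel_density"] + [f"{p}_{s}" for p in params for s in FEATURE_STATS]


def tile_image(image: np.ndarray, tiles_per_side: int) -> list[tuple[int, int, np.ndarray]]:
    """Split an image into ``tiles_per_side**2`` equal tiles, row-major.

    Returns ``(row, col, view)`` triples.  Dimensions must divide evenly;
    the error names the offending axis.
    """
    image = np.asarray(image)
    h, w = image.shape
    for axis, n in (("rows", h), ("columns", w)):
        if n % tiles_per_side != 0:
            raise ValueError(
                f"image {axis} ({n}) not divisible by tiles_per_side={tiles_per_side}"
            )
    th, tw = h // tiles_per_side, w // tiles_per_side
    return [
        (r, c, image[r * th : (r + 1) * th, c * tw : (c + 1) * tw])
        for r in range(tiles_per_side)
        for c in range(tiles_per_side)
    ]


def quantize(
    image: np.ndarray,
    n_g: int,
    range_spec: tuple[float, float] | None = None,
    robust_percentiles: tuple[float, float] = (1.0, 99.0),
) -> np.ndarray:
    """Linearly bin a float map to integer grey levels {0..n_g-1}.

    NaN (missing) pixels map to :data:`MISSING_LEVEL`.  ``range_spec`` is
    an explicit ``(lo, hi)``; when omitted, the robust per-image range
    (1st-99th percentile of valid pixels by default) is used, which makes
    levels comparable across tiles of one core.  Values outside the range
    are clipped into the end bins.
    """
    if n_g < 2:
        raise ValueError("n_g must be >= 2")
    image = np.asarray(image, dtype=float)
    valid = np.isfinite(image)
    out = np.full(image.shape, MISSING_LEVEL, dtype=np.int32)
    if not valid.any():
        return out
    if range_spec is None:
        lo, hi = np.percentile(image[valid], robust_percentiles)
    else:
        lo, hi = map(float, range_spec)
    if lo > hi:
        raise ValueError(f"invalid quantization range ({lo}, {hi})")
    if lo == hi:  # constant image: single level
        out[valid] = 0
        return out
    scaled = (image[valid] - lo) / (hi - lo) * n_g
    out[valid] = np.clip(np.floor(scaled), 0, n_g - 1).astype(np.int32)
    return out


@dataclass
class Glcm:
    """Normalized direction-averaged grey-level co-occurrence matrix."""

    p: np.ndarray
    n_g: int
    d: int
    angles: tuple[int, ...]
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs > 0 and not math.isclose(
            float(self.p.sum()), 1.0, abs_tol=1e-12
        ):
            raise ValueError("GLCM probabilities must sum to 1")


def masked_glcm(
    quantized: np.ndarray,
    n_g: int,
    d: int = 1,
    angles: tuple[int, ...] = (0, 45, 90, 135),
    symmetric: bool = True,
) -> Glcm:
    """Build the masked, direction-averaged GLCM of a quantized tile.

    Pairs at offset ``d`` along each angle are counted, skipping any pair
    where either pixel is :data:`MISSING_LEVEL`.  In symmetric mode each
    pair is counted in both orders.  Per-angle count matrices are averaged
    and then normalized to a probability matrix.  A tile with no valid
    pairs yields ``n_pairs = 0`` and a zero matrix (downstream features
    become missing).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    bad = set(angles) - set(_ANGLE_OFFSETS)
    if bad:
        raise ValueError(f"unsupported angles {sorted(bad)}; allowed {sorted(_ANGLE_OFFSETS)}")
    q = np.asarray(quantized)
    counts = np.zeros((n_g, n_g), dtype=float)
    n_pairs = 0
    for ang in angles:
        dr, dc = (o * d for o in _ANGLE_OFFSETS[ang])
        h, w = q.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (a != MISSING_LEVEL) & (b != MISSING_LEVEL)
        ai, bi = a[ok].ravel(), b[ok].ravel()
        cmat = np.zeros((n_g, n_g), dtype=float)
        np.add.at(cmat, (ai, bi), 1.0)
        if symmetric:
            cmat = cmat + cmat.T
        counts += cmat
        n_pairs += int(ai.size)
    counts /= len(angles)
    total = counts.sum()
    p = counts / total if total > 0 else counts
    return Glcm(p=p, n_g=n_g, d=d, angles=tuple(angles), n_pairs=n_pairs)


def texture_features(g: Glcm, printed_correlation_sign: bool = False) -> dict[str, float]:
    """Contrast, correlation, entropy, ASM and IDM of a GLCM.

    ``printed_correlation_sign`` negates the correlation, reproducing a
    variant definition in which the sum carries a leading minus sign; the
    default follows the standard Haralick form, whose endpoints (+1 for a
    perfectly positively correlated image) match the usual range
    semantics.  Correlation is NaN when only a single grey level occurs
    (sigma = 0); all features are NaN when the GLCM has no pairs.
    """
    if g.n_pairs == 0:
        return {k: float("nan") for k in ("contrast", "correlation", "entropy", "asm", "idm")}
    p = g.p
    idx = np.arange(g.n_g, dtype=float)
    i = idx[:, None]
    j = idx[None, :]
    contrast = float(((i - j) ** 2 * p).sum())
    marginal = p.sum(axis=1)
    mu = float((idx * marginal).sum())
    var = float(((idx - mu) ** 2 * marginal).sum())
    if var > 0:
        corr = float((p * (i - mu) * (j - mu)).sum() / var)
        if printed_correlation_sign:
            corr = -corr
    else:
        corr = float("nan")
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    asm = float((p**2).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    return {
        "contrast": contrast,
        "correlation": corr,
        "entropy": entropy,
        "asm": asm,
        "idm": idm,
    }


def subimage_stats(tile: np.ndarray) -> tuple[float, float, int]:
    """Mean, mean absolute deviation and valid-pixel count of a tile.

    Statistics are over finite (valid) pixels only; NaN background is
    ignored.  MAD is the mean absolute deviation about the mean.  All
    values are NaN (density 0) for an empty tile.
    """
    tile = np.asarray(tile, dtype=float)
    vals = tile[np.isfinite(tile)]
    if vals.size == 0:
        return float("nan"), float("nan"), 0
    mean = float(vals.mean())
    mad = float(np.abs(vals - mean).mean())
    return mean, mad, int(vals.size)


def build_feature_table(
    params: ParameterMaps,
    core_id: str,
    label: str,
    tiles_per_side: int = 8,
    n_g: int = 64,
    d: int = 1,
    min_density_frac: float = 0.01,
    quant_range: dict[str, tuple[float, float]] | None = None,
    printed_correlation_sign: bool = False,
) -> pd.DataFrame:
    """Assemble the per-sub-image feature table of one core.

    One row per retained tile, with ``core_id``, ``tile_row``, ``tile_col``,
    ``label``, ``pixel_density`` and the 35 ``{param}_{stat}`` columns.
    Quantization uses the per-core robust range (1st-99th percentile of the
    whole core's valid pixels) unless ``quant_range`` provides explicit
    ``(lo, hi)`` per parameter.  Tiles whose valid-pixel fraction falls
    below ``min_density_frac`` (no viable signal) are dropped.
    """
    maps = params.as_dict()
    shapes = {m.shape for m in maps.values()}
    if len(shapes) != 1:
        raise ValueError("parameter maps have mismatched shapes")

    ranges = {}
    for name, m in maps.items():
        if quant_range and name in quant_range:
            ranges[name] = quant_range[name]
        else:
            vals = m[np.isfinite(m)]
            ranges[name] = (
                tuple(np.percentile(vals, (1.0, 99.0))) if vals.size else (0.0, 1.0)
            )

    tiles = {name: tile_image(m, tiles_per_side) for name, m in maps.items()}
    n_tiles = tiles_per_side * tiles_per_side
    tile_px = maps["icp"].size // n_tiles
    min_px = max(int(math.ceil(min_density_frac * tile_px)), 1)

    rows = []
    n_dropped = 0
    for t in range(n_tiles):
        row_idx, col_idx, _ = tiles["icp"][t]
        row: dict[str, object] = {
            "core_id": core_id,
            "tile_row": row_idx,
            "tile_col": col_idx,
            "label": label,
        }
        _, _, density = subimage_stats(tiles["icp"][t][2])
        if density < min_px:
            n_dropped += 1
            continue
        row["pixel_density"] = density
        for name in maps:
            tile = tiles[name][t][2]
            mean, mad, _ = subimage_stats(tile)
            q = quantize(tile, n_g, range_spec=ranges[name])
            feats = texture_features(
                masked_glcm(q, n_g, d=d),
                printed_correlation_sign=printed_correlation_sign,
            )
            row[f"{name}_mean"] = mean
            row[f"{name}_mad"] = mad
            for stat, val in feats.items():
                row[f"{name}_{stat}"] = val
        rows.append(row)

    cols = ["core_id", "tile_row", "tile_col", "label"] + feature_columns(
        tuple(maps.keys())
    )
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["n_dropped_tiles"] = n_dropped
    df.attrs["quant_ranges"] = ranges
    return df
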