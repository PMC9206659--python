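"""TIFF / CSV / JSON input-output for the P-SHG pipeline."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .polarimetry import (
    MeasurementStack,
    ParameterMaps,
    PolState,
    enumerate_measurement_scheme,
)

__all__ = ["read_stack", "write_parameter_maps", "read_parameter_maps"]


def read_stack(path: str | Path, stem: str | None = None) -> MeasurementStack:
    """Load a 16-state measurement stack.

    ``path`` is either a multi-page TIFF whose 16 pages follow the
    canonical (PSG-major) measurement-scheme order, or a directory
    holding 16 single-page files named ``{stem}_{psg}_{psa}.tif`` with
    states in {lcp, hlp, rcp, vlp}.  Missing or duplicate states raise
    an error naming the offending pairs.
    """
    path = Path(path)
    scheme = enumerate_measurement_scheme()
    if path.is_dir():
        images = {}
        missing = []
        for psg, psa in scheme:
            pattern = f"*_{psg.value}_{psa.value}.tif*" if stem is None else f"{stem}_{psg.value}_{psa.value}.tif*"
            matches = sorted(path.glob(pattern))
            if len(matches) == 0:
                missing.append((psg.value, psa.value))
                continue
            if len(matches) > 1:
                raise ValueError(
                    f"duplicate files for state ({psg.value},{psa.value}): "
                    f"{[m.name for m in matches]}"
                )
            images[(psg, psa)] = tifffile.imread(matches[0]).astype(float)
        if missing:
            raise FileNotFoundError(f"missing state files for (psg,psa): {missing}")
        return MeasurementStack(images=images)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 16:
        raise ValueError(
            f"{path.name}: expected a 16-page stack, got shape {pages.shape}"
        )
    images = {key: pages[i].astype(float) for i, key in enumerate(scheme)}
    return MeasurementStack(images=images)


def write_parameter_maps(params: ParameterMaps, out_dir: str | Path, core_id: str) -> Path:
    """Write per-parameter 32-bit float TIFFs (NaN = invalid) plus QC JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, arr in params.as_dict().items():
        tifffile.imwrite(out / f"{core_id}_{name}.tif", arr.astype(np.float32))
    tifffile.imwrite(out / f"{core_id}_valid.tif", params.valid.astype(np.uint8))
    (out / f"{core_id}_qc.json").write_text(json.dumps(params.qc, indent=2, sort_keys=True))
    return out


def read_parameter_maps(out_dir: str | Path, core_id: str) -> ParameterMaps:
    """Load parameter maps previously written by :func:`write_parameter_maps`."""
    out = Path(out_dir)
    maps = {
        name: tifffile.imread(out / f"{core_id}_{name}.tif").astype(float)
        for name in ParameterMaps.PARAM_NAMES
    }
    valid = tifffile.imread(out / f"{core_id}_valid.tif").astype(bool)
    qc_path = out / f"{core_id}_qc.json"
    qc = json.loads(qc_path.read_text()) if qc_path.exists() else {}
    return ParameterMaps(valid=valid, qc=qc, **maps)
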