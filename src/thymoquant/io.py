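"""File round-trips: multi-channel TIFF, spot CSV, mask TIFF, scenario YAML.

TIFFs are written with `tifffile`'s shaped-JSON metadata carrying channel
roles and physical pixel sizes, so the pipeline is self-describing; reading a
third-party TIFF without pixel-size metadata requires an explicit pixel size.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imgen import GroundTruth, SectionImage, TissueScenario

__all__ = [
    "write_section_tiff", "read_section_tiff",
    "write_mask_tiff", "read_mask_tiff",
    "write_spots_csv", "read_spots_csv",
    "write_ground_truth_csv",
    "write_scenario_yaml", "read_scenario_yaml",
]


def write_section_tiff(path, image: SectionImage) -> None:
    names = list(image.channels)
    stack = np.stack([image.channels[n] for n in names]).astype(np.float32)
    axes = "CZYX" if image.is_3d else "CYX"
    meta = {
        "axes": axes,
        "channel_names": names,
        "pixel_size_xy_um": image.pixel_size_xy,
        "pixel_size_z_um": image.pixel_size_z,
        "thickness_um": image.thickness,
    }
    tifffile.imwrite(path, stack, photometric="minisblack", metadata=meta)


def read_section_tiff(path, pixel_size_xy: float | None = None,
                      pixel_size_z: float | None = None) -> SectionImage:
    """Read a multi-channel TIFF.

    For files written by this package, channel names and pixel sizes come from
    the embedded metadata.  For foreign files the leading axis is taken as the
    channel axis (a plain 2D/3D array becomes one ``channel_0``) and
    ``pixel_size_xy`` must be supplied.
    """
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    names = meta.get("channel_names")
    psxy = meta.get("pixel_size_xy_um") or pixel_size_xy
    psz = meta.get("pixel_size_z_um") or pixel_size_z
    if psxy is None:
        raise ValueError(
            f"{path}: no pixel-size metadata found; pass pixel_size_xy "
            "(CLI: --pixel-size)")
    if names is None:
        if arr.ndim == 2:
            arr = arr[None]
        names = [f"channel_{i}" for i in range(arr.shape[0])]
    channels = {n: arr[i] for i, n in enumerate(names)}
    return SectionImage(channels=channels, pixel_size_xy=float(psxy),
                        pixel_size_z=float(psz) if psz else None,
                        thickness=meta.get("thickness_um"))


def write_mask_tiff(path, labels: np.ndarray, pixel_size_xy: float) -> None:
    """Label map as single-channel uint8 TIFF (0 outside, 1 cortex, 2 medulla)."""
    tifffile.imwrite(path, labels.astype(np.uint8),
                     metadata={"pixel_size_xy_um": pixel_size_xy,
                               "encoding": "0=outside,1=cortex,2=medulla"})


def read_mask_tiff(path) -> tuple[np.ndarray, float]:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    return arr.astype(np.uint8), float(meta.get("pixel_size_xy_um", 0.0) or 0.0)


def write_spots_csv(path, spots, params_sidecar: bool = True) -> None:
    spots.to_frame().to_csv(path, index=False)
    if params_sidecar:
        side = Path(str(path)).with_suffix(".params.json")
        side.write_text(json.dumps(spots.detection_params, indent=2,
                                   default=float))


def read_spots_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth_csv(path, truth: GroundTruth) -> None:
    truth.centroid_table().to_csv(path, index=False)


def write_scenario_yaml(path, scenario: TissueScenario) -> None:
    Path(str(path)).write_text(yaml.safe_dump(scenario.to_dict(),
                                              sort_keys=False))


def read_scenario_yaml(path) -> TissueScenario:
    data = yaml.safe_load(Path(str(path)).read_text())
    return TissueScenario.from_dict(data)
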