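"""File-format glue: image reading, trait CSV tables, model/summary JSON.

CSV outputs start with a single ``#``-prefixed provenance line carrying
the configuration that produced them; readers skip comment lines, so the
round trip is lossless.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .calibration import CalibrationModel
from .traits import PanicleMeasurement

__all__ = [
    "RunConfig",
    "read_rgb_image",
    "write_rgb_image",
    "write_mask_png",
    "measurements_to_frame",
    "write_traits_csv",
    "read_traits_csv",
    "write_regions_csv",
    "save_model",
    "load_model",
]

TRAIT_COLUMNS = [
    "panicle_id",
    "variety",
    "n_regions",
    "total_area_px",
    "tlpb2_px",
    "tlpb2_cm",
    "snpp_manual",
]


@dataclass
class RunConfig:
    """Pipeline settings; the defaults reproduce the reference protocol
    (72 dpi scans, radius-1 opening, 100-px cleanup, 5 calibration points)."""

    dpi: float = 72.0
    polarity: str = "dark_foreground"
    opening_radius: int = 1
    min_pixels: int = 100
    trait: str = "area"
    mode: str = "five_point"
    k: int = 5
    seed: int | None = None

    def provenance(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def read_rgb_image(path: str | Path, dpi: float | None = None) -> tuple[np.ndarray, float]:
    """Read a PNG/JPEG/TIFF scan as an H x W x 3 uint8 array.

    The resolution comes from file metadata when present, else from the
    ``dpi`` argument, else defaults to 72.
    """
    with Image.open(path) as im:
        meta_dpi = im.info.get("dpi")
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    if dpi is None:
        dpi = float(meta_dpi[0]) if meta_dpi and meta_dpi[0] else 72.0
    return arr, float(dpi)


def write_rgb_image(path: str | Path, img: np.ndarray, dpi: float = 72.0) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB").save(
        path, dpi=(dpi, dpi)
    )


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary/step mask as an 8-bit PNG (scaled to full range)."""
    a = np.asarray(mask)
    if a.dtype == bool:
        out = (a * 255).astype(np.uint8)
    else:
        m = a.max()
        out = (a.astype(np.float64) * (255.0 / m if m else 1.0)).astype(np.uint8)
    Image.fromarray(out, mode="L").save(path)


def measurements_to_frame(measurements: list[PanicleMeasurement]) -> pd.DataFrame:
    rows = [
        {
            "panicle_id": m.panicle_id,
            "variety": m.variety,
            "n_regions": m.n_regions,
            "total_area_px": m.total_area_px,
            "tlpb2_px": m.tlpb2_px,
            "tlpb2_cm": m.tlpb2_cm,
            "snpp_manual": m.snpp_manual,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=TRAIT_COLUMNS)


def _write_csv_with_provenance(path: Path, df: pd.DataFrame, config: RunConfig | None):
    buf = _io.StringIO()
    if config is not None:
        buf.write(f"# spikescan config: {config.provenance()}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def write_traits_csv(
    path: str | Path,
    measurements: list[PanicleMeasurement],
    config: RunConfig | None = None,
) -> None:
    _write_csv_with_provenance(Path(path), measurements_to_frame(measurements), config)


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_regions_csv(
    path: str | Path, measurement: PanicleMeasurement, config: RunConfig | None = None
) -> None:
    df = pd.DataFrame(
        [
            {
                "label": r.label,
                "area_px": r.area_px,
                "pbl2_px": r.pbl2_px,
                "centroid_row": r.centroid[0],
                "centroid_col": r.centroid[1],
            }
            for r in measurement.regions
        ]
    )
    _write_csv_with_provenance(Path(path), df, config)


def save_model(path: str | Path, model: CalibrationModel) -> None:
    Path(path).write_text(model.to_json() + "\n")


def load_model(path: str | Path) -> CalibrationModel:
    return CalibrationModel.from_json(Path(path).read_text())
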