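"""Reading and writing the pipeline's standard formats.

Images and masks travel as single-slice (or multi-slice) NIfTI volumes
or as PNG pairs for small fixtures; diagrams, Betti curves, feature
tables and manifests as CSV; reports and sidecars as JSON.  Arrays use
row-major (row, col[, slice]) indexing, 0-based; NIfTI affines are
accepted but unused (a non-identity affine only triggers a warning,
since the pipeline is purely intensity-based).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .homology import BettiCurve, PersistenceDiagram, PersistenceInterval

log = logging.getLogger("topoliver")

__all__ = [
    "read_volume",
    "write_nifti",
    "write_png",
    "read_png",
    "diagram_to_frame",
    "frame_to_diagram",
    "write_diagram",
    "read_diagram",
    "write_betti_curve",
    "write_json",
]


def write_nifti(path, array: np.ndarray) -> None:
    array = np.asarray(array, dtype=np.float32)
    if array.ndim == 2:
        array = array[:, :, None]
    nib.save(nib.Nifti1Image(array, np.eye(4)), str(path))


def write_png(path, array: np.ndarray) -> None:
    """16-bit PNG; float arrays are assumed to lie in [0, 1]."""
    import imageio.v3 as iio

    array = np.asarray(array)
    if array.dtype.kind == "f":
        array = np.round(np.clip(array, 0, 1) * 65535).astype(np.uint16)
    iio.imwrite(str(path), array)


def read_png(path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(str(path)))


def _load_one(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read {path}: no such file")
    if path.suffix == ".png":
        return read_png(path).astype(float)
    img = nib.load(str(path))
    if not np.allclose(img.affine[:3, :3], np.eye(3)):
        log.warning("non-identity affine in %s; geometry is ignored", path)
    data = np.asarray(img.dataobj, dtype=float)
    return np.squeeze(data)


def read_volume(image_path, mask_path) -> tuple[np.ndarray, np.ndarray]:
    """Load an image/mask pair; mask is binarized at 0.5."""
    image = _load_one(image_path)
    mask = _load_one(mask_path)
    if image.shape != mask.shape:
        raise ValueError(
            f"image shape {image.shape} != mask shape {mask.shape} "
            f"({image_path} vs {mask_path})"
        )
    return image, (mask > 0.5).astype(np.uint8)


def diagram_to_frame(diagram: PersistenceDiagram) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dim": [iv.dim for iv in diagram.intervals],
            "birth": [iv.birth for iv in diagram.intervals],
            "death": [iv.death for iv in diagram.intervals],
            "essential": [iv.essential for iv in diagram.intervals],
        }
    )


def frame_to_diagram(
    frame: pd.DataFrame, shape=(0, 0), vmin=np.nan, vmax=np.nan
) -> PersistenceDiagram:
    ivs = tuple(
        PersistenceInterval(int(r.dim), float(r.birth), float(r.death), bool(r.essential))
        for r in frame.itertuples()
    )
    return PersistenceDiagram(ivs, tuple(shape), float(vmin), float(vmax))


def write_diagram(path, diagram: PersistenceDiagram) -> None:
    diagram_to_frame(diagram).to_csv(path, index=False)


def read_diagram(path) -> PersistenceDiagram:
    return frame_to_diagram(pd.read_csv(path))


def write_betti_curve(path, curve: BettiCurve) -> None:
    pd.DataFrame({"eps": curve.thresholds, "b0": curve.b0, "b1": curve.b1}).to_csv(
        path, index=False
    )


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
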