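"""Reading and writing frame stacks and ROI sets.

Frame stacks travel as multi-page TIFF (one page per frame, uint8/uint16 or
float) with an optional JSON sidecar ``<stem>.timestamps.json`` holding
either ``{"timestamps_s": [...]}`` or ``{"fps": <float>}`` plus free-form
``meta``.  ROI sets travel as a small JSON document; polygons are stored as
vertex lists and explicit masks as row-major run-length encodings.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile

from .core import FrameStack, Roi, RoiSet

# ITU-R BT.601 luma weights, used to reduce RGB convenience imports to one
# channel; native NIR recordings are single-channel already.
_LUMA = np.array([0.299, 0.587, 0.114])

TimestampsSource = Union[None, float, str, Path, np.ndarray, list]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".timestamps.json")


def save_frame_stack(stack: FrameStack, path: Union[str, Path]) -> Path:
    """Write a stack as multi-page TIFF plus a timestamps/meta JSON sidecar.

    Round-trips bit-exactly through :func:`load_frame_stack` for integer
    dtypes (and float32/float64 frames).
    """
    path = Path(path)
    tifffile.imwrite(path, stack.frames)
    sidecar = {
        "timestamps_s": [float(t) for t in stack.timestamps],
        "meta": stack.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True))
    return path


def load_frame_stack(
    path: Union[str, Path], timestamps: TimestampsSource = None
) -> FrameStack:
    """Load a multi-page TIFF (or imageio-readable video) as a FrameStack.

    Parameters
    ----------
    path
        Multi-page TIFF (preferred) or a container video readable by
        imageio; multi-channel frames are reduced to grayscale by BT.601
        luma.
    timestamps
        One of: ``None`` (use the ``<stem>.timestamps.json`` sidecar if
        present, else error), a float frame rate (``t_k = k / fps``), a path
        to a sidecar JSON, or an explicit array of seconds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    else:  # container video fallback
        import imageio.v3 as iio

        frames = np.asarray(iio.imread(path))
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # T x H x W x C -> luma
        frames = frames[..., :3] @ _LUMA
    if frames.ndim != 3:
        raise ValueError(f"cannot interpret frame array of shape {frames.shape}")
    if frames.shape[0] < 2:
        raise ValueError("insufficient frames: a recording needs at least 2 frames")

    meta: dict = {}
    t: Optional[np.ndarray] = None
    if timestamps is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                "no timestamps given and no sidecar found; pass a frame rate, "
                "a sidecar path or an explicit timestamp array"
            )
        timestamps = sidecar
    if isinstance(timestamps, (int, float)):
        fps = float(timestamps)
        if fps <= 0:
            raise ValueError("frame rate must be positive")
        t = np.arange(frames.shape[0]) / fps
    elif isinstance(timestamps, (str, Path)):
        doc = json.loads(Path(timestamps).read_text())
        meta = doc.get("meta", {})
        if "timestamps_s" in doc:
            t = np.asarray(doc["timestamps_s"], dtype=float)
        elif "fps" in doc:
            t = np.arange(frames.shape[0]) / float(doc["fps"])
        else:
            raise ValueError("sidecar must contain 'timestamps_s' or 'fps'")
    else:
        t = np.asarray(timestamps, dtype=float)
    if len(t) != frames.shape[0]:
        raise ValueError(
            f"timestamp count {len(t)} does not match frame count {frames.shape[0]}"
        )
    return FrameStack(frames=frames, timestamps=t, meta=meta)


# ---------------------------------------------------------------------------
# ROI set JSON


def _rle_encode(mask: np.ndarray) -> dict:
    """Row-major RLE; counts alternate runs starting with a False run."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return {"size": list(mask.shape), "counts": [0]}
    change = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    counts = np.diff(bounds).tolist()
    if flat[0]:  # canonical form starts with a (possibly zero) False run
        counts = [0] + counts
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": counts}


def _rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    counts = rle["counts"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for c in counts:
        if val:
            flat[pos : pos + c] = True
        pos += c
        val = not val
    if pos != h * w:
        raise ValueError("RLE counts do not cover the mask")
    return flat.reshape(h, w)


def write_roi_set(roi_set: RoiSet, path: Union[str, Path]) -> Path:
    """Write an ROI set to JSON (polygons as vertex lists, masks as RLE)."""
    path = Path(path)
    rois = []
    for roi in roi_set.rois:
        entry: dict = {"label": roi.label, "role": roi.role}
        if roi.polygon is not None:
            entry["polygon"] = [[float(r), float(c)] for r, c in roi.polygon]
        else:
            entry["mask_rle"] = _rle_encode(roi.mask)
        rois.append(entry)
    doc = {"frame_shape": list(roi_set.frame_shape), "rois": rois}
    path.write_text(json.dumps(doc, sort_keys=True))
    return path


def read_roi_set(path: Union[str, Path], frame_shape: Optional[tuple[int, int]] = None) -> RoiSet:
    """Read an ROI set from JSON, validating labels and geometry.

    If ``frame_shape`` is given it must match the document's; geometry is
    checked to lie within the frame.
    """
    doc = json.loads(Path(path).read_text())
    shape = tuple(int(x) for x in doc["frame_shape"])
    if frame_shape is not None and tuple(frame_shape) != shape:
        raise ValueError(f"ROI frame_shape {shape} does not match frames {tuple(frame_shape)}")
    h, w = shape
    rois = []
    for entry in doc["rois"]:
        if "polygon" in entry:
            poly = np.asarray(entry["polygon"], dtype=float)
            roi = Roi(label=str(entry["label"]), role=entry["role"], polygon=poly)
            if np.any(poly[:, 0] < 0) or np.any(poly[:, 0] > h) or np.any(
                poly[:, 1] < 0
            ) or np.any(poly[:, 1] > w):
                raise ValueError(f"ROI {roi.label!r}: geometry outside frame")
        elif "mask_rle" in entry:
            mask = _rle_decode(entry["mask_rle"])
            if mask.shape != (h, w):
                raise ValueError(f"ROI {entry['label']!r}: mask shape does not match frame")
            roi = Roi(label=str(entry["label"]), role=entry["role"], mask=mask)
        else:
            raise ValueError(f"ROI {entry.get('label')!r}: needs 'polygon' or 'mask_rle'")
        rois.append(roi)
    return RoiSet(rois=rois, frame_shape=shape)
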