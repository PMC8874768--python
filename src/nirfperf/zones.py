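"""Perfusion zones along the base-to-tip axis and per-zone slope statistics.

The vascular supply of a muscle flap enters at the proximal pedicle, so
perfusion is expected to decay towards the distal tip.  Zones discretize
that axis: each muscle pixel center is projected onto the base->tip line
and the projection range is split into K equal-length intervals (zone 1
proximal).  Explicit per-zone masks may be supplied instead via the zone
spec JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .core import SlopeMap
from .io import _rle_decode, _rle_encode


@dataclass
class Zone:
    """One perfusion zone: index 1..K (1 = proximal) and its pixel mask."""

    index: int
    mask: np.ndarray


@dataclass
class ZoneStats:
    """Population statistics of slope_max within one zone (all in i/s)."""

    zone_index: int
    max_slope: float
    min_slope: float
    mean_slope: float
    sd_slope: float
    range_slope: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("a zone must contain at least one pixel")
        if not (self.min_slope <= self.mean_slope <= self.max_slope):
            raise ValueError("zone statistics violate min <= mean <= max")


def define_zones(
    muscle_mask: np.ndarray,
    base: tuple[float, float],
    tip: tuple[float, float],
    k: int = 4,
) -> list[Zone]:
    """Partition a muscle mask into K equal-length zones along an axis.

    Pixel centers are projected onto the base->tip line; the projection
    range over the mask is divided into K equal intervals.  Raises when the
    axis is degenerate, the mask has fewer than K distinct projections, or
    any zone would be empty.
    """
    muscle_mask = np.asarray(muscle_mask, dtype=bool)
    if not muscle_mask.any():
        raise ValueError("muscle mask is empty")
    br, bc = float(base[0]), float(base[1])
    tr, tc = float(tip[0]), float(tip[1])
    vr, vc = tr - br, tc - bc
    if vr == 0 and vc == 0:
        raise ValueError("degenerate axis: base equals tip")
    rr, cc = np.nonzero(muscle_mask)
    s = (rr + 0.5 - br) * vr + (cc + 0.5 - bc) * vc  # unnormalized projection
    if np.unique(s).size < k:
        raise ValueError(f"fewer than {k} distinct projection values")
    smin, smax = s.min(), s.max()
    edges = np.linspace(smin, smax, k + 1)
    which = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, k - 1)
    zones = []
    for i in range(k):
        m = np.zeros_like(muscle_mask)
        sel = which == i
        if not sel.any():
            raise ValueError(f"zone {i + 1} is empty")
        m[rr[sel], cc[sel]] = True
        zones.append(Zone(index=i + 1, mask=m))
    return zones


def zone_statistics(
    slope_map: SlopeMap,
    zones: list[Zone],
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> list[ZoneStats]:
    """Max/min/mean/SD/range of slope_max per zone (population SD).

    Sub-threshold ("no slope") pixels are included by default — their low
    values carry the impaired-perfusion signal that drives the range
    indicator; set ``config.include_no_slope_in_zones = False`` to drop
    them.
    """
    out = []
    for zone in zones:
        sel = zone.mask & slope_map.analyzed_mask
        if not config.include_no_slope_in_zones:
            sel &= ~slope_map.no_slope_mask
        vals = slope_map.values[sel]
        if vals.size == 0:
            raise ValueError(f"zone {zone.index} has no analyzed pixels")
        out.append(
            ZoneStats(
                zone_index=zone.index,
                max_slope=float(vals.max()),
                min_slope=float(vals.min()),
                mean_slope=float(vals.mean()),
                sd_slope=float(vals.std()),  # population (divisor n)
                range_slope=float(vals.max() - vals.min()),
                n_pixels=int(vals.size),
            )
        )
    return out


def write_zone_spec(path: Union[str, Path], *, base=None, tip=None, k=4, zones=None) -> Path:
    """Write a zone spec JSON: either an axis + K, or explicit zone masks."""
    path = Path(path)
    if zones is not None:
        doc = {"masks_rle": [{"index": z.index, "rle": _rle_encode(z.mask)} for z in zones]}
    else:
        doc = {"axis": {"base": [float(base[0]), float(base[1])],
                        "tip": [float(tip[0]), float(tip[1])]}, "k": int(k)}
    path.write_text(json.dumps(doc, sort_keys=True))
    return path


def read_zone_spec(path: Union[str, Path]):
    """Read a zone spec JSON.

    Returns either ``("axis", (base, tip, k))`` or ``("masks", [Zone, ...])``.
    """
    doc = json.loads(Path(path).read_text())
    if "axis" in doc:
        a = doc["axis"]
        return "axis", (tuple(a["base"]), tuple(a["tip"]), int(doc.get("k", 4)))
    if "masks_rle" in doc:
        zones = [
            Zone(index=int(e["index"]), mask=_rle_decode(e["rle"]))
            for e in sorted(doc["masks_rle"], key=lambda e: e["index"])
        ]
        return "masks", zones
    raise ValueError("zone spec must contain 'axis' or 'masks_rle'")


def zones_for_spec(spec, muscle_mask: np.ndarray) -> list[Zone]:
    """Materialize zones from a parsed spec against a muscle mask."""
    kind, payload = spec
    if kind == "axis":
        base, tip, k = payload
        return define_zones(muscle_mask, base, tip, k)
    return payload
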