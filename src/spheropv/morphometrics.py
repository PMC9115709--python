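"""Spheroid shape metrics from segmented masks or area/perimeter tables.

The central quantity is the circularity 4*pi*Area / perimeter**2, which is
1 for a perfect circle and decreases with elongation or boundary roughness.
The sphericity index (SI) is its square root.  Both are reported side by
side (they coincide at 1 for a circle and order shapes identically), along
with the equivalent circular diameter and a moments-based roundness
4*Area / (pi * major_axis**2).

Mask-derived perimeters use the Crofton-formula estimator (boundary length
from intersection counts over four line directions); naive pixel-edge
counting would inflate a disk's perimeter by roughly 27% — and even
sqrt(2)-weighted chain-code counting by ~5% — destroying the SI ~ 1 circle
property, while the Crofton estimate stays within ~0.5% for disks of
radius >= 20 px.
Digitization can push circularity marginally above 1; such values are
reported as-is with a warning, never clamped.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from .errors import InsufficientDataError, NoObjectError, ValidationError

log = logging.getLogger(__name__)

#: Circularity may exceed 1 by at most this much before a warning is raised.
DIGITIZATION_TOLERANCE = 0.05


@dataclass
class SpheroidShape:
    spheroid_id: str
    area: float                      # um^2 (or px^2 when pixel_size=1)
    perimeter: float                 # um
    equivalent_diameter: float       # um
    circularity: float               # 4*pi*A/P^2, unitless
    sphericity_index: float          # sqrt(circularity)
    roundness: float | None = None   # 4A/(pi*major_axis^2), mask path only
    pixel_size: float | None = None  # um/px when mask-derived
    group: str | None = None


def shape_from_measurements(
    area: float, perimeter: float, spheroid_id: str = "", group: str | None = None
) -> SpheroidShape:
    """Shape metrics from a measured area/perimeter pair."""
    if not area > 0 or not perimeter > 0:
        raise ValidationError(
            f"area and perimeter must be positive, got area={area}, perimeter={perimeter}"
        )
    circ = 4.0 * math.pi * area / perimeter**2
    if circ > 1.0 + DIGITIZATION_TOLERANCE:
        warnings.warn(
            f"{spheroid_id or 'shape'}: circularity {circ:.4f} exceeds 1 beyond "
            f"the digitization tolerance; check the measurements",
            stacklevel=2,
        )
    return SpheroidShape(
        spheroid_id=spheroid_id,
        area=area,
        perimeter=perimeter,
        equivalent_diameter=2.0 * math.sqrt(area / math.pi),
        circularity=circ,
        sphericity_index=math.sqrt(circ),
        group=group,
    )


def shape_from_mask(
    mask: np.ndarray,
    pixel_size: float = 1.0,
    spheroid_id: str = "",
    group: str | None = None,
) -> SpheroidShape:
    """Shape metrics from a single-channel binary mask.

    Multiple foreground components are reduced to the largest (with a logged
    count); an empty mask raises :class:`NoObjectError`.  Area is the
    foreground pixel count scaled by pixel_size**2; the perimeter is the
    Crofton estimate over four directions.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got shape {mask.shape}")
    binary = mask > 0
    if not binary.any():
        raise NoObjectError("mask contains no foreground pixels")
    labels = measure.label(binary)
    props = measure.regionprops(labels)
    if len(props) > 1:
        log.info("mask has %d components; keeping the largest", len(props))
        props.sort(key=lambda p: p.area, reverse=True)
    p = props[0]
    area = float(p.area) * pixel_size**2
    perimeter = float(p.perimeter_crofton) * pixel_size
    shape = shape_from_measurements(area, perimeter, spheroid_id=spheroid_id, group=group)
    shape.pixel_size = pixel_size
    major = float(p.axis_major_length) * pixel_size
    shape.roundness = 4.0 * area / (math.pi * major**2) if major > 0 else None
    return shape


_METRICS = ("area", "perimeter", "equivalent_diameter",
            "circularity", "sphericity_index", "roundness")


def shapes_to_frame(shapes: Iterable[SpheroidShape]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spheroid_id": s.spheroid_id,
                "group": s.group,
                **{m: getattr(s, m) for m in _METRICS},
            }
            for s in shapes
        ]
    )


def summarize_shapes(shapes: Sequence[SpheroidShape]) -> pd.DataFrame:
    """Per-group mean, standard error and n for every shape metric.

    Shapes without a group label are pooled under the group name "all".
    """
    if not shapes:
        raise InsufficientDataError("no shapes to summarize")
    df = shapes_to_frame(shapes)
    df["group"] = df["group"].fillna("all")
    rows = []
    for group, g in df.groupby("group", sort=True):
        for m in _METRICS:
            # sort for permutation-invariant floating-point aggregation
            vals = np.sort(g[m].dropna().to_numpy(float))
            if len(vals) == 0:
                continue
            se = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            rows.append(
                {"group": group, "metric": m, "mean": float(np.mean(vals)),
                 "se": se, "n": int(len(vals))}
            )
    return pd.DataFrame(rows, columns=["group", "metric", "mean", "se", "n"])
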