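"""Derived aneurysm morphometrics.

Implements the two standard dome/vessel ratios used in aneurysm morphometry
and the four-quadrant classification of the frontal base-dome angle (FDA),
the sagittal angle between the aneurysm's maximum-height axis and a baseline
parallel to the frontal skull base.

All measurements enter as scalars (millimetres / degrees); nothing here
touches images.
"""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["size_ratio", "aspect_ratio", "classify_fda", "derive_morphometrics"]


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not isinstance(value, numbers.Real) or not np.isfinite(value) or value <= 0:
            raise DomainError(f"{name} must be a positive finite length, got {value!r}")


def size_ratio(hmax: float, d1: float, d2: float) -> float:
    """Size ratio SR = Hmax / mean(D1, D2).

    Maximum dome height over the average parent-vessel diameter, the vessel
    diameter being measured at the proximal neck (D1) and 1.5 x D1 upstream (D2).
    Dimensionless; invariant to a common rescaling of all three lengths.
    """
    _require_positive(hmax=hmax, d1=d1, d2=d2)
    return hmax / ((d1 + d2) / 2.0)


def aspect_ratio(h: float, d: float) -> float:
    """Aspect ratio AR = H / D: perpendicular dome height over neck diameter."""
    _require_positive(h=h, d=d)
    return h / d


def classify_fda(angle: float) -> int:
    """Bin an FDA angle (degrees) into quadrant categories 1-4.

    0 deg starts ventral to the aneurysm and the angle runs a full 360-degree
    circle. Bins are upper-closed: [0, 90] -> 1, (90, 180] -> 2,
    (180, 270] -> 3, (270, 360] -> 4. 360 is accepted as the top of
    category 4 and is not wrapped to 0.
    """
    if not isinstance(angle, numbers.Real) or not np.isfinite(angle):
        raise DomainError(f"fda angle must be a finite number, got {angle!r}")
    if angle < 0 or angle > 360:
        raise DomainError(f"fda angle must lie in [0, 360], got {angle!r}")
    if angle <= 90:
        return 1
    if angle <= 180:
        return 2
    if angle <= 270:
        return 3
    return 4


def derive_morphometrics(cases: pd.DataFrame) -> pd.DataFrame:
    """Append ``size_ratio``, ``aspect_ratio`` and ``fda_category`` columns.

    Requires the raw measurement columns ``hmax_mm``, ``parent_d1_mm``,
    ``parent_d2_mm``, ``height_mm``, ``neck_mm`` and ``fda_angle_deg``.
    Returns a copy; the input frame is not modified.
    """
    needed = ["hmax_mm", "parent_d1_mm", "parent_d2_mm", "height_mm", "neck_mm", "fda_angle_deg"]
    missing = [c for c in needed if c not in cases.columns]
    if missing:
        raise DomainError(f"cannot derive morphometrics, missing column(s): {', '.join(missing)}")
    out = cases.copy()
    out["size_ratio"] = [
        size_ratio(h, d1, d2)
        for h, d1, d2 in zip(out["hmax_mm"], out["parent_d1_mm"], out["parent_d2_mm"])
    ]
    out["aspect_ratio"] = [aspect_ratio(h, d) for h, d in zip(out["height_mm"], out["neck_mm"])]
    out["fda_category"] = [classify_fda(a) for a in out["fda_angle_deg"]]
    return out
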