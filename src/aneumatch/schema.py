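"""Canonical case-table schema.

One row per patient-aneurysm record. The in-memory container for a cohort is a
:class:`pandas.DataFrame` with the columns registered here; ``case_id`` is a
unique string key and every other column is typed by :class:`ColumnDef`.

Clinical covariates are 0/1 integers, ordinal severity scores are small
integers (Hunt & Hess 1-5, Fisher grade 1-4, mRS 0-6), morphometric lengths
are millimetres, angles are degrees. ``hunt_hess`` and ``fisher_grade`` are
admission scores for subarachnoid hemorrhage and therefore may only be
populated on ruptured cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

ARM_AOI = "AIA"  # interhemispheric arm: the cases being matched
ARM_REFERENCE = "PA"  # pterional arm: the reference pool

#: binary medical-history / aneurysm covariates carried on every case
BINARY_COVARIATES = (
    "hypertension",
    "diabetes_mellitus",
    "hyperlipidemia",
    "peripheral_arterial_disease",
    "heart_disease",
    "ischaemic_stroke",
    "thrombosis",
    "malignant_tumor",
    "autoimmune_disease",
    "obesity",
    "nicotine_abuse",
    "alcohol_abuse",
    "multiple_aneurysms",
)

#: binary surgical / complication outcomes (per-arm probabilities configurable)
BINARY_OUTCOMES = (
    "complete_occlusion",
    "temporary_clipping",
    "intraoperative_rupture",
    "postoperative_stroke",
    "postoperative_hemorrhage",
    "hydrocephalus",
    "vp_shunt",
    "vasospasm",
)


@dataclass(frozen=True)
class ColumnDef:
    kind: str  # binary | ordinal | metric | categorical | id
    required: bool = True
    allowed: tuple | None = None  # categorical levels or (low, high) ordinal range
    lo: float | None = None  # inclusive numeric lower bound
    hi: float | None = None  # numeric upper bound
    hi_open: bool = False  # True -> value must be strictly below hi
    units: str = ""


def _binary(required: bool = True) -> ColumnDef:
    return ColumnDef(kind="binary", required=required, allowed=(0, 1))


@dataclass
class CaseTableSchema:
    """Registry of case-table columns and their validation rules."""

    columns: dict[str, ColumnDef] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "CaseTableSchema":
        cols: dict[str, ColumnDef] = {
            "case_id": ColumnDef(kind="id"),
            "arm": ColumnDef(kind="categorical", allowed=(ARM_AOI, ARM_REFERENCE)),
            "gender": ColumnDef(kind="categorical", allowed=("male", "female")),
            "age": ColumnDef(kind="metric", lo=0, hi=120, units="years"),
            "ruptured": _binary(),
            "hunt_hess": ColumnDef(kind="ordinal", required=False, lo=1, hi=5),
            "fisher_grade": ColumnDef(kind="ordinal", required=False, lo=1, hi=4),
            "shape": ColumnDef(kind="categorical", allowed=("regular", "irregular")),
            "size_mm": ColumnDef(kind="metric", lo=0, units="mm"),
            # raw morphometric measurements
            "width_mm": ColumnDef(kind="metric", required=False, lo=0, units="mm"),
            "height_mm": ColumnDef(kind="metric", required=False, lo=0, units="mm"),
            "neck_mm": ColumnDef(kind="metric", required=False, lo=0, units="mm"),
            "parent_d1_mm": ColumnDef(kind="metric", required=False, lo=0, units="mm"),
            "parent_d2_mm": ColumnDef(kind="metric", required=False, lo=0, units="mm"),
            "hmax_mm": ColumnDef(kind="metric", required=False, lo=0, units="mm"),
            "vessel_angle_deg": ColumnDef(kind="metric", required=False, lo=0, hi=360, units="deg"),
            "inclination_angle_deg": ColumnDef(kind="metric", required=False, lo=0, hi=360, units="deg"),
            "fda_angle_deg": ColumnDef(kind="metric", lo=0, hi=360, hi_open=True, units="deg"),
            "bleb": _binary(required=False),
            # derived morphometrics (populated by the derive stage)
            "size_ratio": ColumnDef(kind="metric", required=False, lo=0),
            "aspect_ratio": ColumnDef(kind="metric", required=False, lo=0),
            "fda_category": ColumnDef(kind="ordinal", required=False, lo=1, hi=4),
            # outcomes
            "mrs_discharge": ColumnDef(kind="ordinal", required=False, lo=0, hi=6),
        }
        for name in BINARY_COVARIATES:
            cols[name] = _binary()
        for name in BINARY_OUTCOMES:
            cols[name] = _binary(required=False)
        return cls(columns=cols)

    @property
    def required_columns(self) -> list[str]:
        return [n for n, c in self.columns.items() if c.required]

    # -- validation ---------------------------------------------------------

    def validate(self, df: pd.DataFrame) -> pd.DataFrame:
        """Validate ``df`` against the registry; returns the (unchanged) frame.

        Raises :class:`SchemaError` naming the first offending row/column/value.
        Row numbers in messages are 1-based positions in the table body.
        """
        missing = [c for c in self.required_columns if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if df["case_id"].duplicated().any():
            dup = df.loc[df["case_id"].duplicated(), "case_id"].iloc[0]
            raise SchemaError(f"duplicate case_id {dup!r}")

        for name, cdef in self.columns.items():
            if name not in df.columns:
                continue
            col = df[name]
            present = col.notna()
            if cdef.required and not present.all():
                row = int(np.flatnonzero(~present.to_numpy())[0]) + 1
                raise SchemaError(f"row {row}: missing value in required column {name!r}")
            if cdef.kind == "id" or not present.any():
                continue
            vals = col[present]
            if cdef.kind == "categorical" or (cdef.kind == "binary" and cdef.allowed):
                bad = ~vals.isin(cdef.allowed)
                if bad.any():
                    idx = vals.index[bad][0]
                    row = int(df.index.get_loc(idx)) + 1
                    raise SchemaError(
                        f"row {row}: column {name!r} has value {vals.loc[idx]!r}, "
                        f"allowed {cdef.allowed}"
                    )
            else:
                numeric = pd.to_numeric(vals, errors="coerce")
                if numeric.isna().any():
                    idx = vals.index[numeric.isna()][0]
                    row = int(df.index.get_loc(idx)) + 1
                    raise SchemaError(f"row {row}: column {name!r} is not numeric: {vals.loc[idx]!r}")
                lo, hi = cdef.lo, cdef.hi
                bad = pd.Series(False, index=numeric.index)
                if lo is not None:
                    bad |= numeric < lo
                if hi is not None:
                    bad |= numeric >= hi if cdef.hi_open else numeric > hi
                if cdef.kind == "ordinal":
                    bad |= numeric != numeric.round()
                if bad.any():
                    idx = numeric.index[bad][0]
                    row = int(df.index.get_loc(idx)) + 1
                    raise SchemaError(
                        f"row {row}: column {name!r} value {vals.loc[idx]!r} outside "
                        f"allowed range [{lo}, {hi}{')' if cdef.hi_open else ']'}"
                    )

        # severity grades only make sense after rupture
        if "hunt_hess" in df.columns:
            bad = df["hunt_hess"].notna() & (df["ruptured"] == 0)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
                raise SchemaError(f"row {row}: hunt_hess populated on an unruptured case")
        if "fisher_grade" in df.columns:
            bad = df["fisher_grade"].notna() & (df["ruptured"] == 0)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
                raise SchemaError(f"row {row}: fisher_grade populated on an unruptured case")
        return df


DEFAULT_SCHEMA = CaseTableSchema.default()
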