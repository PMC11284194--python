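"""Synthetic aneurysm cohort generator.

Emulates the structure of a two-arm microsurgical series of anterior
communicating artery aneurysms: a small interhemispheric (AIA) arm to be
matched against a larger pterional (PA) reference pool, roughly half of the
cases ruptured, binary medical-history covariates, log-normal aneurysm size,
dome angles on the full circle, and arm-specific binary outcome rates.

The defaults mirror the study design this package targets: 14 AIA candidates
versus 36 PA candidates and a 50% rupture rate. Distributional shapes
(truncated-normal age, log-normal size, categorical severity grades) are the
package's own choices and are documented in docs/methods.md.

Planted "twins" (perturbed copies of each AOI inserted into the reference
pool, with a known AOI -> twin map) provide ground truth for matching-recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .morphometry import classify_fda
from .schema import ARM_AOI, ARM_REFERENCE, BINARY_COVARIATES, BINARY_OUTCOMES

__all__ = ["CohortConfig", "PlantedTwinSpec", "generate_cohort", "plant_twins", "simulate_null"]

#: default binary covariate prevalences (order matches Table-style baseline reports)
DEFAULT_COVARIATE_PREVALENCES: dict[str, float] = {
    "hypertension": 0.40,
    "diabetes_mellitus": 0.05,
    "hyperlipidemia": 0.20,
    "peripheral_arterial_disease": 0.05,
    "heart_disease": 0.18,
    "ischaemic_stroke": 0.10,
    "thrombosis": 0.03,
    "malignant_tumor": 0.05,
    "autoimmune_disease": 0.03,
    "obesity": 0.08,
    "nicotine_abuse": 0.35,
    "alcohol_abuse": 0.05,
    "multiple_aneurysms": 0.30,
}

#: default per-arm outcome probabilities (AOI arm, reference arm)
DEFAULT_OUTCOME_EFFECTS: dict[str, tuple[float, float]] = {
    "complete_occlusion": (0.93, 0.80),
    "temporary_clipping": (0.21, 0.64),
    "intraoperative_rupture": (0.14, 0.21),
    "postoperative_stroke": (0.14, 0.29),
    "postoperative_hemorrhage": (0.07, 0.21),
    "hydrocephalus": (0.07, 0.64),
    "vp_shunt": (0.07, 0.57),
    "vasospasm": (0.29, 0.36),
}

# Hunt & Hess mass centred on grades 1-2, Fisher grade on 2-3
DEFAULT_HUNT_HESS_PROBS = (0.35, 0.30, 0.18, 0.12, 0.05)
DEFAULT_FISHER_PROBS = (0.15, 0.35, 0.30, 0.20)

# mRS-at-discharge mass by rupture status (same in both arms by default)
_MRS_UNRUPTURED = (0.55, 0.25, 0.10, 0.05, 0.03, 0.02, 0.00)
_MRS_RUPTURED = (0.20, 0.20, 0.15, 0.15, 0.12, 0.10, 0.08)


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {p!r}")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for one synthetic cohort."""

    n_aoi: int = 14
    n_reference: int = 36
    rupture_rate: float = 0.5
    age_mean: float = 55.0
    age_sd: float = 10.0
    size_log_mean: float = float(np.log(7.0))  # log-mm; median size 7 mm
    size_log_sd: float = 0.5
    female_rate: float = 0.8
    irregular_rate: float = 0.30
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    outcome_effects: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_EFFECTS)
    )
    hunt_hess_probs: tuple[float, ...] = DEFAULT_HUNT_HESS_PROBS
    fisher_probs: tuple[float, ...] = DEFAULT_FISHER_PROBS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_aoi < 1 or self.n_reference < 1:
            raise ConfigError("n_aoi and n_reference must be >= 1")
        if self.age_sd <= 0 or self.size_log_sd <= 0:
            raise ConfigError("age_sd and size_log_sd must be > 0")
        _check_prob("rupture_rate", self.rupture_rate)
        _check_prob("female_rate", self.female_rate)
        _check_prob("irregular_rate", self.irregular_rate)
        for name, p in self.covariate_prevalences.items():
            _check_prob(f"covariate_prevalences[{name!r}]", p)
        for name, (pa, pr) in self.outcome_effects.items():
            _check_prob(f"outcome_effects[{name!r}] AOI arm", pa)
            _check_prob(f"outcome_effects[{name!r}] reference arm", pr)
        for probs, label in ((self.hunt_hess_probs, "hunt_hess_probs"), (self.fisher_probs, "fisher_probs")):
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ConfigError(f"{label} must be a probability vector summing to 1")

    def with_null_outcomes(self) -> "CohortConfig":
        """Copy of the config with identical outcome rates in both arms."""
        null = {k: (p_ref, p_ref) for k, (_, p_ref) in self.outcome_effects.items()}
        return replace(self, outcome_effects=null)


@dataclass(frozen=True)
class PlantedTwinSpec:
    """How to perturb each AOI into its planted reference-pool twin."""

    noise_scale: float = 0.0  # fraction of each continuous feature's sd
    flip_prob: float = 0.0  # probability of flipping each binary feature
    n_decoys: int = 2  # additional unrelated reference cases per AOI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ConfigError("noise_scale must be >= 0")
        _check_prob("flip_prob", self.flip_prob)
        if self.n_decoys < 0:
            raise ConfigError("n_decoys must be >= 0")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int) -> np.ndarray:
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _sample_cases(rng: np.random.Generator, n: int, arm: str, prefix: str, config: CohortConfig) -> pd.DataFrame:
    hmax = np.exp(rng.normal(config.size_log_mean, config.size_log_sd, size=n))
    height = hmax * rng.uniform(0.7, 1.0, size=n)
    d1 = np.exp(rng.normal(np.log(2.4), 0.2, size=n))
    d2 = d1 * rng.uniform(0.8, 1.1, size=n)
    neck = np.exp(rng.normal(np.log(3.0), 0.3, size=n))
    width = hmax * rng.uniform(0.6, 1.2, size=n)
    fda = rng.uniform(0.0, 360.0, size=n)
    ruptured = (rng.random(n) < config.rupture_rate).astype(int)

    df = pd.DataFrame(
        {
            "case_id": [f"{prefix}{i + 1:03d}" for i in range(n)],
            "arm": arm,
            "gender": np.where(rng.random(n) < config.female_rate, "female", "male"),
            "age": np.round(_truncated_normal(rng, config.age_mean, config.age_sd, 18.0, 95.0, n), 1),
            "ruptured": ruptured,
            "hunt_hess": pd.array(
                np.where(ruptured == 1, rng.choice(np.arange(1, 6), size=n, p=config.hunt_hess_probs), -1),
                dtype="Int64",
            ),
            "fisher_grade": pd.array(
                np.where(ruptured == 1, rng.choice(np.arange(1, 5), size=n, p=config.fisher_probs), -1),
                dtype="Int64",
            ),
            "shape": np.where(rng.random(n) < config.irregular_rate, "irregular", "regular"),
            "size_mm": np.round(hmax, 2),
            "width_mm": np.round(width, 2),
            "height_mm": np.round(height, 2),
            "neck_mm": np.round(neck, 2),
            "parent_d1_mm": np.round(d1, 2),
            "parent_d2_mm": np.round(d2, 2),
            "hmax_mm": np.round(hmax, 2),
            "vessel_angle_deg": np.round(rng.uniform(30.0, 150.0, size=n), 1),
            "inclination_angle_deg": np.round(rng.uniform(0.0, 90.0, size=n), 1),
            "fda_angle_deg": np.round(fda, 1),
            "bleb": (rng.random(n) < 0.2).astype(int),
        }
    )
    df.loc[df["ruptured"] == 0, ["hunt_hess", "fisher_grade"]] = pd.NA
    df["fda_category"] = [classify_fda(a) for a in df["fda_angle_deg"]]

    for name in BINARY_COVARIATES:
        p = config.covariate_prevalences.get(name, 0.0)
        df[name] = (rng.random(n) < p).astype(int)

    p_col = 0 if arm == ARM_AOI else 1
    for name in BINARY_OUTCOMES:
        if name in config.outcome_effects:
            p = config.outcome_effects[name][p_col]
            df[name] = (rng.random(n) < p).astype(int)
        else:
            df[name] = pd.NA
    mrs = np.empty(n, dtype=int)
    for i, r in enumerate(ruptured):
        probs = _MRS_RUPTURED if r else _MRS_UNRUPTURED
        mrs[i] = rng.choice(7, p=probs)
    df["mrs_discharge"] = mrs
    return df


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a two-arm case table of ``n_aoi + n_reference`` rows.

    Deterministic: identical config (including seed) reproduces the exact table.
    """
    rng = np.random.default_rng(config.seed)
    aoi = _sample_cases(rng, config.n_aoi, ARM_AOI, "A", config)
    ref = _sample_cases(rng, config.n_reference, ARM_REFERENCE, "P", config)
    return pd.concat([aoi, ref], ignore_index=True)


# continuous / binary matching features a twin is perturbed on
_TWIN_CONTINUOUS = ("age", "size_mm", "hmax_mm", "height_mm")
_TWIN_BINARY = ("gender", "shape")
_TWIN_ORDINAL = ("hunt_hess", "fisher_grade")


def plant_twins(aois: pd.DataFrame, spec: PlantedTwinSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a reference pool containing one perturbed twin per AOI plus decoys.

    Twins keep their AOI's rupture status and FDA category; continuous matching
    features are jittered by ``noise_scale`` times the feature's sd across the
    AOI set, binary features flipped with ``flip_prob``, ordinal grades moved
    one step with ``flip_prob``. Decoys are independent draws constrained to
    the same (rupture status, FDA category) stratum so they compete in
    matching.

    Returns ``(references, twin_map)`` where ``twin_map`` has columns
    ``aoi_id`` and ``twin_id``.
    """
    if len(aois) == 0:
        raise ConfigError("plant_twins requires a nonempty AOI list")
    rng = np.random.default_rng(spec.seed)
    sds = {c: float(aois[c].astype(float).std(ddof=0)) if len(aois) > 1 else 0.0 for c in _TWIN_CONTINUOUS}

    rows: list[pd.DataFrame] = []
    mapping: list[tuple[str, str]] = []
    for _, aoi in aois.iterrows():
        twin = aoi.copy()
        twin_id = f"T-{aoi['case_id']}"
        twin["case_id"] = twin_id
        twin["arm"] = ARM_REFERENCE
        for c in _TWIN_CONTINUOUS:
            jitter = rng.normal(0.0, 1.0) * spec.noise_scale * sds[c]
            twin[c] = max(float(aoi[c]) + jitter, 0.01)
        for c in _TWIN_BINARY:
            if rng.random() < spec.flip_prob:
                if c == "gender":
                    twin[c] = "male" if aoi[c] == "female" else "female"
                else:
                    twin[c] = "regular" if aoi[c] == "irregular" else "irregular"
        if aoi["ruptured"] == 1:
            for c in _TWIN_ORDINAL:
                if rng.random() < spec.flip_prob:
                    lo, hi = (1, 5) if c == "hunt_hess" else (1, 4)
                    step = -1 if (int(aoi[c]) == hi or rng.random() < 0.5) else 1
                    twin[c] = int(np.clip(int(aoi[c]) + step, lo, hi))
        rows.append(twin.to_frame().T)
        mapping.append((aoi["case_id"], twin_id))

        for j in range(spec.n_decoys):
            decoy = aoi.copy()
            decoy["case_id"] = f"D-{aoi['case_id']}-{j + 1}"
            decoy["arm"] = ARM_REFERENCE
            decoy["age"] = round(float(np.clip(rng.normal(55.0, 10.0), 18.0, 95.0)), 1)
            size = float(np.exp(rng.normal(np.log(7.0), 0.5)))
            for c in ("size_mm", "hmax_mm"):
                decoy[c] = round(size, 2)
            decoy["height_mm"] = round(size * rng.uniform(0.7, 1.0), 2)
            decoy["gender"] = "female" if rng.random() < 0.8 else "male"
            decoy["shape"] = "irregular" if rng.random() < 0.3 else "regular"
            if aoi["ruptured"] == 1:
                decoy["hunt_hess"] = int(rng.choice(np.arange(1, 6), p=DEFAULT_HUNT_HESS_PROBS))
                decoy["fisher_grade"] = int(rng.choice(np.arange(1, 5), p=DEFAULT_FISHER_PROBS))
            rows.append(decoy.to_frame().T)

    references = pd.concat(rows, ignore_index=True)
    references = references.astype(aois.dtypes.to_dict())
    twin_map = pd.DataFrame(mapping, columns=["aoi_id", "twin_id"])
    return references, twin_map


def simulate_null(config: CohortConfig, n_reps: int) -> list[pd.DataFrame]:
    """Generate ``n_reps`` independent cohorts with no between-arm outcome effect.

    Requires identical outcome probabilities in both arms (use
    :meth:`CohortConfig.with_null_outcomes`). Child seeds are spawned from the
    config seed so replicates are independent but reproducible.
    """
    for name, (p_aoi, p_ref) in config.outcome_effects.items():
        if p_aoi != p_ref:
            raise ConfigError(
                f"simulate_null requires equal outcome rates in both arms; "
                f"{name!r} has {p_aoi} vs {p_ref}"
            )
    seeds = np.random.SeedSequence(config.seed).generate_state(max(n_reps, 1)) % (2**31)
    return [generate_cohort(replace(config, seed=int(seeds[i]))) for i in range(n_reps)]
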