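"""End-to-end driver: simulate (optional) -> derive -> match -> compare -> report."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .compare import SKIPPED, baseline_table, outcome_analysis
from .io import RunConfig, read_case_table, write_case_table, write_report
from .matching import MatchedCohort, distance_matrix, sequential_match
from .morphometry import derive_morphometrics
from .schema import ARM_AOI, ARM_REFERENCE, DEFAULT_SCHEMA
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger("aneumatch")

__all__ = ["run_pipeline", "matched_case_table"]


def matched_case_table(cases: pd.DataFrame, cohort: MatchedCohort) -> pd.DataFrame:
    """Restrict a case table to the matched pairs (both arms, 1:1)."""
    keep = set(cohort.pairs["aoi_id"]) | set(cohort.pairs["reference_id"])
    return cases[cases["case_id"].isin(keep)].reset_index(drop=True)


def _summary_text(cases: pd.DataFrame, cohort: MatchedCohort, outcomes: pd.DataFrame) -> str:
    lines = [
        f"cases: {len(cases)} "
        f"({(cases['arm'] == ARM_AOI).sum()} {ARM_AOI} / {(cases['arm'] == ARM_REFERENCE).sum()} {ARM_REFERENCE})",
        f"matched pairs: {len(cohort.pairs)}",
        f"stratum merges: {len(cohort.merges)}",
        f"conflicts adjudicated: {len(cohort.conflicts)}",
    ]
    for m in cohort.merges:
        lines.append(f"  merge: {m}")
    for c in cohort.conflicts:
        lines.append(f"  conflict over {c.reference_id}: {c.resolution}")
    for note in cohort.notes:
        lines.append(f"  note: {note}")
    lines.append("outcome comparisons:")
    for _, row in outcomes.iterrows():
        p = row["p_value"]
        p_txt = p if p == SKIPPED else f"p={p:.3f}"
        lines.append(f"  {row['variable']}: {row['test']} {p_txt}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> int:
    """Run the full workflow; returns 0 on success (stage errors propagate)."""
    if config.case_table:
        cases = read_case_table(config.case_table)
        log.info("loaded %d cases from %s", len(cases), config.case_table)
    else:
        cohort_cfg = CohortConfig(
            n_aoi=config.n_aoi,
            n_reference=config.n_reference,
            rupture_rate=config.rupture_rate,
            seed=config.seed,
        )
        cases = generate_cohort(cohort_cfg)
        log.info("simulated %d cases (seed %d)", len(cases), config.seed)

    cases = derive_morphometrics(cases)
    DEFAULT_SCHEMA.validate(cases)

    aois = cases[cases["arm"] == ARM_AOI]
    refs = cases[cases["arm"] == ARM_REFERENCE]
    fallback = None if config.fallback_merge else {}
    cohort = sequential_match(aois, refs, variant=config.variant, k=config.k, fallback=fallback)
    for merge in cohort.merges:
        log.info("stratum merge: %s", merge)
    for conflict in cohort.conflicts:
        log.info("conflict over %s: %s", conflict.reference_id, conflict.resolution)

    matched = matched_case_table(cases, cohort)
    baseline = baseline_table(matched)
    outcomes = outcome_analysis(matched)
    dmat = distance_matrix(aois, refs, k=config.k, fallback=fallback)

    adjudication = pd.DataFrame(
        [
            {
                "reference_id": c.reference_id,
                "claimants": ";".join(f"{a}@{d:.4f}" for a, d in c.claimants),
                "winner": c.winner,
                "resolution": c.resolution,
            }
            for c in cohort.conflicts
        ],
        columns=["reference_id", "claimants", "winner", "resolution"],
    )

    out = Path(config.out_dir)
    write_case_table(cases, out / "case_table.csv")
    write_report(
        {
            "pairs": cohort.pairs,
            "adjudication_log": adjudication,
            "distance_matrix": dmat.reset_index(names="aoi_id"),
            "baseline_table": baseline,
            "outcome_report": outcomes,
        },
        out,
        seed=config.seed,
        config=config,
        summary=_summary_text(cases, cohort, outcomes),
    )
    log.info("wrote results to %s", out)
    return 0
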