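"""Calibration evidence for the matching and comparison engines.

Three studies:

1. Twin recovery — planted-twin cohorts (one perturbed copy of each AOI plus
   two decoys in the reference pool): recovery rate at zero noise and at 5%
   feature noise, over seeded replicates.
2. Exact null size of the routed binary test at n = 14 per arm — computed by
   full enumeration over the two binomial count distributions, not by Monte
   Carlo.  This quantifies the discreteness-driven conservatism of the
   chi-square (no Yates) and Fisher branches.
3. Monte-Carlo type-I error of the full routed engine under the null.

Writes results/calibration.csv and prints the findings.
"""

import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from aneumatch.compare import VariableDef, run_comparison
from aneumatch.io import RunConfig, write_report
from aneumatch.matching import sequential_match
from aneumatch.schema import ARM_AOI
from aneumatch.synthetic import CohortConfig, PlantedTwinSpec, generate_cohort, plant_twins, simulate_null

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1
N_TWIN_REPS = 100
N_NULL_REPS = 1000


def twin_recovery(noise: float, seeds) -> float:
    hits = total = 0
    for s in seeds:
        aois = generate_cohort(CohortConfig(seed=int(s))).query("arm == @ARM_AOI")
        refs, twin_map = plant_twins(aois, PlantedTwinSpec(noise_scale=noise, n_decoys=2, seed=int(s) + 1))
        got = dict(zip(*sequential_match(aois, refs).pairs[["aoi_id", "reference_id"]].T.values))
        expected = dict(zip(twin_map["aoi_id"], twin_map["twin_id"]))
        hits += sum(got[a] == t for a, t in expected.items())
        total += len(expected)
    return hits / total


def exact_routed_binary_size(n: int = 14, p: float = 0.3, alpha: float = 0.05) -> dict:
    """Exact size of the chi/Fisher-routed binary comparison by enumerating
    both arms' binomial counts."""
    pmf = [math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)]
    acc = {"chi-square": [0.0, 0.0], "fisher-exact": [0.0, 0.0]}  # [mass, rejected mass]
    for a in range(n + 1):
        for b in range(n + 1):
            w = pmf[a] * pmf[b]
            tab = np.array([[a, n - a], [b, n - b]])
            if tab.sum(axis=0).min() == 0:
                acc["fisher-exact"][0] += w
                continue
            expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
            if expected.min() < 5:
                pv = stats.fisher_exact(tab)[1]
                key = "fisher-exact"
            else:
                pv = stats.chi2_contingency(tab, correction=False)[1]
                key = "chi-square"
            acc[key][0] += w
            acc[key][1] += w * (pv < alpha)
    return {
        k: {"route_mass": m, "conditional_size": (r / m if m else 0.0)} for k, (m, r) in acc.items()
    }


def monte_carlo_null(seed: int, reps: int) -> dict[str, tuple[int, int]]:
    cfg = CohortConfig(n_aoi=14, n_reference=14, size_log_sd=1.0, seed=seed).with_null_outcomes()
    variables = (
        VariableDef("multiple_aneurysms", "binary"),
        VariableDef("age", "metric"),
        VariableDef("size_mm", "metric"),
    )
    out: dict[str, list[int]] = {}
    for cohort in simulate_null(cfg, reps):
        a = cohort[cohort["arm"] == ARM_AOI]
        b = cohort[cohort["arm"] != ARM_AOI]
        for var in variables:
            row = run_comparison(var, a[var.name].to_numpy(), b[var.name].to_numpy())
            if row.test != "skipped":
                out.setdefault(row.test, []).append(int(row.p_value < 0.05))
    return {k: (sum(v), len(v)) for k, v in out.items()}


def main() -> None:
    seeds = np.random.SeedSequence(SEED).generate_state(N_TWIN_REPS) % (2**31)
    rec0 = twin_recovery(0.0, seeds[:20])
    rec5 = twin_recovery(0.05, seeds)
    print(f"twin recovery: {rec0:.1%} at zero noise (20 reps), {rec5:.1%} at 5% noise ({N_TWIN_REPS} reps)")

    exact = exact_routed_binary_size()
    for test, vals in exact.items():
        print(
            f"exact null size of {test} route (n=14/arm, prevalence 0.3): "
            f"{vals['conditional_size']:.4f} on {vals['route_mass']:.1%} of tables"
        )
    print("  -> both discrete routes are conservative (size < 0.05); this is a property")
    print("     of exact/chi-square tests on 2x2 tables at this sample size, not a defect")

    mc = monte_carlo_null(SEED, N_NULL_REPS)
    rows = []
    for test, (x, m) in sorted(mc.items()):
        print(f"null rejection rate, {test}: {x}/{m} = {x / m:.4f}")
        rows.append({"quantity": f"null_rate_{test}", "value": x / m, "n": m})

    rows += [
        {"quantity": "twin_recovery_zero_noise", "value": rec0, "n": 20 * 14},
        {"quantity": "twin_recovery_noise005", "value": rec5, "n": N_TWIN_REPS * 14},
        {"quantity": "exact_size_chi_square_route", "value": exact["chi-square"]["conditional_size"], "n": 14},
        {"quantity": "exact_size_fisher_route", "value": exact["fisher-exact"]["conditional_size"], "n": 14},
    ]
    write_report({"calibration": pd.DataFrame(rows)}, RESULTS, seed=SEED, config=RunConfig(seed=SEED))
    print(f"wrote {RESULTS / 'calibration.csv'}")


if __name__ == "__main__":
    main()
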