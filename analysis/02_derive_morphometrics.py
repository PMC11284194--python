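"""Derive the morphometric indices used downstream — size ratio (SR),
aspect ratio (AR) and the frontal base-dome-angle (FDA) quadrant category —
from the raw measurement columns of results/cohort.csv.

Writes results/cohort_derived.csv and prints the FDA category distribution.
"""

from pathlib import Path

from aneumatch.io import read_case_table, write_case_table
from aneumatch.morphometry import derive_morphometrics

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cases = read_case_table(RESULTS / "cohort.csv")
    derived = derive_morphometrics(cases)
    write_case_table(derived, RESULTS / "cohort_derived.csv")

    print(f"derived SR/AR/FDA for {len(derived)} cases")
    print("FDA category counts by arm:")
    print(derived.groupby(["arm", "fda_category"]).size().unstack(fill_value=0).to_string())
    print("SR range: %.2f-%.2f, AR range: %.2f-%.2f"
          % (derived.size_ratio.min(), derived.size_ratio.max(),
             derived.aspect_ratio.min(), derived.aspect_ratio.max()))
    print(f"wrote {RESULTS / 'cohort_derived.csv'}")


if __name__ == "__main__":
    main()
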