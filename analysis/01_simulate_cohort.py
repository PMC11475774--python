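"""Generate the default synthetic three-group cohort and check calibration.

Draws 263 NC / 263 MCI / 263 AD subjects (789 total) with per-feature
group means and SDs set to the published reference statistics, ventricle
volumes on moment-matched lognormal margins, independent features.
Writes results/cohort.csv and results/cohort_calibration.tsv and reports
how closely each feature's empirical NC-vs-AD AUC matches the
binormal-formula value implied by its parameters (at this sample size the
differences are dominated by sampling noise).
"""

import argparse
from pathlib import Path

from metaroi.cohort import write_feature_table
from metaroi.simulate import SyntheticConfig, calibration_report, generate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    config = SyntheticConfig(seed=args.seed)
    cohort = generate_cohort(config)
    RESULTS.mkdir(exist_ok=True)
    write_feature_table(cohort, RESULTS / "cohort.csv")

    cal = calibration_report(cohort, config)
    cal.to_csv(RESULTS / "cohort_calibration.tsv", sep="\t", index=False,
               float_format="%.4f")

    print(f"cohort: {len(cohort)} subjects, {len(cohort.features)} features "
          f"-> {RESULTS / 'cohort.csv'}")
    worst = cal.loc[cal.abs_gap.idxmax()]
    print(f"largest empirical-vs-binormal AUC gap: {worst.feature} "
          f"({worst.abs_gap:.3f}; lognormal margins are expected to exceed "
          f"the Gaussian formula)")


if __name__ == "__main__":
    main()
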