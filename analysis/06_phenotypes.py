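"""Classify participants into 3-HPMA vs CEMA phenotypes and check recovery.

Applies the day-majority / median-override rule to the daily excretion
table, counts labels, and compares against the generator's latent truth.
Writes results/phenotypes.csv.
"""

from pathlib import Path

import pandas as pd

from glycacro.phenotype import classify_cohort, cohort_phenotype_counts

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    daily = pd.read_csv(ROOT / "results" / "daily_excretion.csv")
    calls = classify_cohort(daily)
    calls.to_csv(ROOT / "results" / "phenotypes.csv", index=False)
    counts = cohort_phenotype_counts(calls)
    print(f"phenotype counts: {counts}")
    flagged = calls[calls["conflicting"]]
    if len(flagged):
        print(f"{len(flagged)} participants with disagreeing rule clauses:")
        print(flagged[["participant", "label"]].to_string(index=False))

    truth = pd.read_csv(ROOT / "results" / "cohort" / "urine_truth.csv")
    latent = truth[["participant", "phenotype"]].drop_duplicates()
    merged = calls.merge(latent, on="participant")
    agree = (merged["label"] == merged["phenotype"]).mean()
    print(f"latent-label recovery: {100 * agree:.0f}%")


if __name__ == "__main__":
    main()
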