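"""Generate the default synthetic cohort (seed 42) used by every later step.

Writes diet, urine, latent-truth and community tables to results/cohort/.
"""

from pathlib import Path

from glycacro.simulate import CohortConfig, generate_cohort, write_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    tables = generate_cohort(CohortConfig(), seed=42)
    paths = write_cohort(tables, OUT)
    print(f"wrote {len(paths)} tables to {OUT}")
    for name, df in tables.items():
        print(f"  {name}: {df.shape[0]} rows x {df.shape[1]} cols")
    truth = tables["urine_truth"]
    split = truth[["participant", "phenotype"]].drop_duplicates()[
        "phenotype"
    ].value_counts()
    print(f"latent phenotype split: {split.to_dict()}")


if __name__ == "__main__":
    main()
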