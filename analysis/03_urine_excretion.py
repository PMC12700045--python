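"""Daily and overnight mercapturic-acid excretion from the urine intervals.

Writes results/daily_excretion.csv and results/overnight_excretion.csv and
reports the pooled medians and the CEMA/3-HPMA ratio.
"""

from pathlib import Path

import pandas as pd

from glycacro.diet import DEFAULT_EXPOSURE
from glycacro.urine import add_daily_ratios, daily_excretion, overnight_excretion

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    intervals = pd.read_csv(ROOT / "results" / "cohort" / "urine.csv")
    daily = add_daily_ratios(daily_excretion(intervals))
    overnight = overnight_excretion(intervals)
    overnight["dinner_class"] = [
        DEFAULT_EXPOSURE.classify_day(int(d)) for d in overnight["study_day"]
    ]
    daily.to_csv(ROOT / "results" / "daily_excretion.csv", index=False)
    overnight.to_csv(ROOT / "results" / "overnight_excretion.csv", index=False)

    ok = daily[~daily["missing"]]
    print(f"{len(ok)} participant-days")
    for col, label in [("cema_umol", "CEMA"), ("hpma_umol", "3-HPMA"),
                       ("sum_umol", "CEMA+3-HPMA")]:
        print(
            f"daily {label}: median {ok[col].median():.2f} umol "
            f"(range {ok[col].min():.2f}-{ok[col].max():.2f})"
        )
    print(f"pooled median daily CEMA/3-HPMA ratio: {daily['ratio'].median():.2f}")


if __name__ == "__main__":
    main()
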