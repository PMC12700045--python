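"""Interval-to-amount conversion, window aggregation and conservation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycacro.urine import (
    MW_CEMA,
    MW_HPMA,
    UrineValidationError,
    WindowSpec,
    add_daily_ratios,
    daily_excretion,
    daily_ratio,
    interval_amount,
    interval_volume,
    overnight_excretion,
)


def _table(rows):
    df = pd.DataFrame(
        rows,
        columns=[
            "participant", "start", "end", "urine_weight_g",
            "conc_hpma_ng_ml", "conc_cema_ng_ml",
        ],
    )
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df


@pytest.mark.parametrize(
    "weight, density, expected",
    [(500.0, 1.0, 0.5), (0.0, 1.0, 0.0), (1234.0, 1.0, 1.234)],
)
def test_interval_volume(weight, density, expected):
    assert interval_volume(weight, density) == pytest.approx(expected)


@pytest.mark.parametrize(
    "conc, vol, mw, expected",
    [
        (0.0, 0.7, 200.0, 0.0),
        (100.0, 0.5, 221.27, 100 * 500 / 221.27 / 1000),  # = 0.2260 umol
        (50.0, 1.0, 200.0, 0.25),
    ],
)
def test_interval_amount(conc, vol, mw, expected):
    assert interval_amount(conc, vol, mw) == pytest.approx(expected, abs=1e-6)


def test_interval_amount_rejects_bad_mw():
    with pytest.raises(UrineValidationError):
        interval_amount(10.0, 0.5, 0.0)


def test_molar_masses_match_molecular_formulas():
    # 3-HPMA C8H15NO4S, CEMA C8H13NO5S (IUPAC 2021 atomic weights)
    w = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}
    hpma = 8 * w["C"] + 15 * w["H"] + w["N"] + 4 * w["O"] + w["S"]
    cema = 8 * w["C"] + 13 * w["H"] + w["N"] + 5 * w["O"] + w["S"]
    assert MW_HPMA == pytest.approx(hpma, abs=0.005)
    assert MW_CEMA == pytest.approx(cema, abs=0.005)


def test_daily_excretion_sums_within_day(simple_intervals):
    daily = daily_excretion(simple_intervals)
    day1 = daily[daily["study_day"] == 1].iloc[0]
    # both intervals sit entirely inside day 1 (08:00 -> 08:00)
    expect_h = (100 * 600 + 120 * 700) / MW_HPMA / 1e3 / 1e3 * 1e3
    assert day1["hpma_umol"] == pytest.approx(expect_h, rel=1e-9)
    assert day1["sum_umol"] == pytest.approx(
        day1["hpma_umol"] + day1["cema_umol"], abs=1e-9
    )
    assert day1["coverage_h"] == pytest.approx(24.0)


def test_interval_straddling_day_boundary_is_prorated():
    # 12 h interval, 6 h before the 08:00 boundary, 6 h after: split 50/50
    rows = [
        ("P01", "2024-03-04 08:00", "2024-03-05 02:00", 900, 0.0, 0.0),
        ("P01", "2024-03-05 02:00", "2024-03-05 14:00", 600, 110.675, 0.0),
    ]
    daily = daily_excretion(_table(rows))
    amt = 110.675 * 600 / MW_HPMA / 1e6 * 1e3  # total umol of interval 2
    d1 = daily[daily["study_day"] == 1].iloc[0]
    d2 = daily[daily["study_day"] == 2].iloc[0]
    assert d1["hpma_umol"] == pytest.approx(amt / 2, rel=1e-9)
    assert d2["hpma_umol"] == pytest.approx(amt / 2, rel=1e-9)


def test_missing_day_flagged():
    rows = [
        ("P01", "2024-03-04 08:00", "2024-03-05 08:00", 900, 10.0, 10.0),
        ("P01", "2024-03-06 08:00", "2024-03-07 08:00", 900, 10.0, 10.0),
    ]
    daily = daily_excretion(_table(rows))
    day2 = daily[daily["study_day"] == 2].iloc[0]
    assert day2["missing"]
    assert day2["coverage_h"] == 0.0


def test_overlapping_intervals_rejected():
    rows = [
        ("P01", "2024-03-04 08:00", "2024-03-04 20:00", 500, 10, 10),
        ("P01", "2024-03-04 18:00", "2024-03-05 08:00", 500, 10, 10),
    ]
    with pytest.raises(UrineValidationError, match="P01"):
        daily_excretion(_table(rows))


def test_overnight_full_and_partial_overlap():
    rows = [
        # exactly the 20:00-08:00 window
        ("P01", "2024-03-04 20:00", "2024-03-05 08:00", 700, 63.22, 0.0),
        # 18:00-22:00 the next evening: 2 of 4 h inside the window
        ("P01", "2024-03-05 18:00", "2024-03-05 22:00", 200, 221.27, 0.0),
    ]
    on = overnight_excretion(_table(rows))
    night1 = on[on["study_day"] == 1].iloc[0]
    amt1 = 63.22 * 700 / MW_HPMA / 1e3
    assert night1["hpma_umol"] == pytest.approx(amt1, rel=1e-9)
    night2 = on[on["study_day"] == 2].iloc[0]
    amt2 = 221.27 * 200 / MW_HPMA / 1e3  # = 0.2 umol in the interval
    assert night2["hpma_umol"] == pytest.approx(amt2 / 2, rel=1e-9)
    # a night with no overlapping interval is flagged missing
    night3 = on[on["study_day"] == 3]
    if len(night3):
        assert night3.iloc[0]["missing"]


def test_whole_interval_assignment_mode():
    # midpoint at 21:00 -> whole amount lands in the overnight window
    rows = [("P01", "2024-03-04 18:00", "2024-03-05 00:00", 300, 100.0, 0.0)]
    on = overnight_excretion(_table(rows), WindowSpec(prorate=False))
    amt = 100.0 * 300 / MW_HPMA / 1e3
    assert on[on["study_day"] == 1].iloc[0]["hpma_umol"] == pytest.approx(amt)


@settings(derandomize=True, max_examples=30)
@given(
    bounds=st.lists(
        st.floats(0, 72, allow_nan=False), min_size=4, max_size=10, unique=True
    ),
    seed=st.integers(0, 10_000),
)
def test_conservation_under_day_partition(bounds, seed):
    """Summed day-credited amounts equal summed interval amounts."""
    hours = sorted(bounds)
    rng = np.random.default_rng(seed)
    origin = pd.Timestamp("2024-03-04 08:00")
    rows = []
    for s, e in zip(hours[:-1], hours[1:]):
        if e - s < 1e-6:
            return
        rows.append(
            (
                "P01",
                origin + pd.Timedelta(hours=s),
                origin + pd.Timedelta(hours=e),
                float(rng.uniform(50, 800)),
                float(rng.uniform(0, 300)),
                float(rng.uniform(0, 300)),
            )
        )
    table = _table(rows)
    daily = daily_excretion(table)
    ml = table["urine_weight_g"]
    total_h = (table["conc_hpma_ng_ml"] * ml / MW_HPMA / 1e3).sum()
    total_c = (table["conc_cema_ng_ml"] * ml / MW_CEMA / 1e3).sum()
    assert daily["hpma_umol"].sum() == pytest.approx(total_h, abs=1e-9)
    assert daily["cema_umol"].sum() == pytest.approx(total_c, abs=1e-9)


def test_prorating_invariant_to_splitting():
    """Splitting an interval into abutting halves leaves window credits unchanged."""
    whole = _table(
        [("P01", "2024-03-04 18:00", "2024-03-05 06:00", 600, 120.0, 90.0)]
    )
    # same excretion split proportionally over two abutting sub-intervals
    split = _table(
        [
            ("P01", "2024-03-04 18:00", "2024-03-05 00:00", 300, 120.0, 90.0),
            ("P01", "2024-03-05 00:00", "2024-03-05 06:00", 300, 120.0, 90.0),
        ]
    )
    for fn in (daily_excretion, overnight_excretion):
        a = fn(whole).set_index("study_day")
        b = fn(split).set_index("study_day")
        for day in a.index:
            assert a.loc[day, "hpma_umol"] == pytest.approx(
                b.loc[day, "hpma_umol"], abs=1e-9
            )


@pytest.mark.parametrize(
    "cema, hpma, expected", [(0.5, 1.0, 0.5), (1.0, 1.0, 1.0), (0.73, 1.0, 0.73)]
)
def test_daily_ratio(cema, hpma, expected):
    assert daily_ratio(cema, hpma) == pytest.approx(expected)


def test_daily_ratio_undefined_for_zero_hpma():
    with pytest.raises(UrineValidationError):
        daily_ratio(0.5, 0.0)


def test_add_daily_ratios_excludes_zero_hpma():
    daily = pd.DataFrame(
        {
            "participant": ["P01", "P01"],
            "study_day": [1, 2],
            "hpma_umol": [1.0, 0.0],
            "cema_umol": [0.5, 0.5],
            "missing": [False, False],
        }
    )
    out = add_daily_ratios(daily)
    assert out["ratio"].iloc[0] == pytest.approx(0.5)
    assert np.isnan(out["ratio"].iloc[1])


def test_outputs_nonnegative(daily, overnight):
    for df in (daily, overnight):
        assert (df[["hpma_umol", "cema_umol", "sum_umol"]] >= 0).all().all()
        assert df["coverage_h"].between(0, 24).all()
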