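"""Phenotype rule, exposure-group comparison, and day-effect tests.

The Mann-Whitney oracle enumerates every assignment of the pooled values
into two groups and computes the exact two-sided tail probability of the
U statistic, independently of any library routine.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from glycacro.phenotype import (
    ClassifierRule,
    PhenotypeError,
    classify_cohort,
    classify_participant,
    cohort_phenotype_counts,
    compare_exposure_groups,
    day_effect,
)


def _daily(cema, hpma, pid="P01"):
    n = len(cema)
    return pd.DataFrame(
        {
            "participant": [pid] * n,
            "study_day": range(1, n + 1),
            "cema_umol": cema,
            "hpma_umol": hpma,
            "missing": [False] * n,
        }
    )


# ---------------------------------------------------------------- classifier

def test_unanimous_hpma_days_give_hpma_label():
    hpma = np.linspace(0.5, 1.5, 11)
    daily = _daily(hpma * 0.5, hpma)
    assert classify_participant(daily).label == "HPMA"


def test_majority_clause_fires():
    # CEMA > 3-HPMA on 7 of 11 days -> CEMA by the day-majority clause
    cema = [1.0] * 7 + [0.1] * 4
    hpma = [0.5] * 11
    call = classify_participant(_daily(cema, hpma))
    assert call.label == "CEMA"
    assert call.n_days_cema_gt_hpma == 7
    assert call.majority_clause


def test_median_override_clause():
    # only 2/4 CEMA-dominant days (no majority), but the CEMA median is higher
    cema = [1.0, 1.0, 0.3, 0.3]
    hpma = [0.5, 0.5, 0.4, 0.4]
    call = classify_participant(_daily(cema, hpma))
    assert not call.majority_clause
    assert call.median_clause
    assert call.label == "CEMA"
    assert call.conflicting


def test_exact_ties_fall_to_hpma():
    daily = _daily([0.5] * 5, [0.5] * 5)
    assert classify_participant(daily).label == "HPMA"


def test_too_few_days_unclassifiable():
    with pytest.raises(PhenotypeError, match="valid days"):
        classify_participant(_daily([0.5, 0.6], [0.4, 0.5]))


def test_classifier_invariances():
    rng = np.random.default_rng(7)
    cema = rng.uniform(0.1, 1.0, 9)
    hpma = rng.uniform(0.1, 1.0, 9)
    base = classify_participant(_daily(cema, hpma)).label
    perm = rng.permutation(9)
    assert classify_participant(_daily(cema[perm], hpma[perm])).label == base
    for k in (0.2, 5.0):
        assert classify_participant(_daily(cema * k, hpma * k)).label == base


def _brute_force_label(cema, hpma, rule=ClassifierRule()):
    """Literal evaluation of the two rule clauses, no shared code path."""
    days = [(c, h) for c, h in zip(cema, hpma) if c > 0 and h > 0]
    n_gt = sum(1 for c, h in days if c > h)
    clause_majority = n_gt / len(days) > rule.majority_threshold

    def med(xs):
        xs = sorted(xs)
        m = len(xs)
        return xs[m // 2] if m % 2 else (xs[m // 2 - 1] + xs[m // 2]) / 2

    clause_median = rule.use_median_override and (
        med([c for c, _ in days]) > med([h for _, h in days])
    )
    return "CEMA" if (clause_majority or clause_median) else rule.tie_label


def test_classifier_matches_brute_force_on_small_participants():
    rng = np.random.default_rng(11)
    for _ in range(300):
        n = rng.integers(3, 6)
        cema = rng.uniform(0.05, 1.5, n)
        hpma = rng.uniform(0.05, 1.5, n)
        expect = _brute_force_label(cema, hpma)
        got = classify_participant(_daily(cema, hpma)).label
        assert got == expect, (cema, hpma)


def test_cohort_counts():
    daily = pd.concat(
        [
            _daily([0.2] * 4, [0.5] * 4, "A"),
            _daily([0.2] * 4, [0.5] * 4, "B"),
            _daily([0.9] * 4, [0.5] * 4, "C"),
        ]
    )
    calls = classify_cohort(daily)
    assert cohort_phenotype_counts(calls) == {"HPMA": 2, "CEMA": 1}


def test_counts_reject_empty():
    calls = pd.DataFrame({"participant": ["A"], "label": ["unclassifiable"]})
    with pytest.raises(PhenotypeError):
        cohort_phenotype_counts(calls)


# ------------------------------------------------- Mann-Whitney exact oracle

def exact_mwu_two_sided(a, b):
    """Exact two-sided p by enumerating all group assignments of the pool."""
    pooled = list(a) + list(b)
    n, m = len(a), len(b)

    def u_stat(idx_a):
        idx_a = set(idx_a)
        xs = [pooled[i] for i in idx_a]
        ys = [pooled[i] for i in range(n + m) if i not in idx_a]
        return sum(
            (x > y) + 0.5 * (x == y) for x in xs for y in ys
        )

    u_obs = u_stat(range(n))
    center = n * m / 2
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        total += 1
        if abs(u_stat(combo) - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


def test_exact_oracle_reproduces_textbook_case():
    # {1,2,3} vs {10,11,12}: U = 0 for the low group, p = 2/20
    p = exact_mwu_two_sided([1, 2, 3], [10, 11, 12])
    assert p == pytest.approx(0.1)
    assert math.comb(6, 3) == 20


def test_compare_matches_exact_oracle_small_groups():
    rng = np.random.default_rng(3)
    for na, nb in [(3, 3), (4, 5), (6, 4), (8, 8), (5, 8)]:
        a = rng.normal(size=na)  # continuous -> no ties
        b = rng.normal(0.8, size=nb)
        df = pd.DataFrame(
            {
                "dinner_class": ["high"] * na + ["low"] * nb,
                "sum_umol": np.concatenate([a, b]),
            }
        )
        got = compare_exposure_groups(df, analytes=("sum_umol",))
        assert got["p_value"].iloc[0] == pytest.approx(
            exact_mwu_two_sided(a, b), rel=1e-9
        )


def test_identical_groups_give_p_one():
    vals = [0.2, 0.4, 0.4, 0.9]
    df = pd.DataFrame(
        {"dinner_class": ["high"] * 4 + ["low"] * 4, "sum_umol": vals * 2}
    )
    out = compare_exposure_groups(df, analytes=("sum_umol",))
    assert out["p_value"].iloc[0] == pytest.approx(1.0)


def test_empty_group_rejected():
    df = pd.DataFrame({"dinner_class": ["high"] * 3, "sum_umol": [1, 2, 3]})
    with pytest.raises(PhenotypeError, match="attribution"):
        compare_exposure_groups(df, analytes=("sum_umol",))


def test_overnight_effect_detected_in_default_cohort(overnight):
    out = compare_exposure_groups(overnight)
    assert (out["median_high"] > out["median_low"]).all()
    assert (out["p_value"] < 0.05).all()


# ------------------------------------------------------------------ day effect

def test_day_effect_type_one_error_near_alpha():
    """Identical day distributions: Kruskal-Wallis rejects at about alpha."""
    rng = np.random.default_rng(5)
    rejections = 0
    reps = 500
    for _ in range(reps):
        daily = pd.DataFrame(
            {
                "study_day": np.repeat(np.arange(1, 6), 20),
                "sum_umol": rng.lognormal(0, 0.3, 100),
            }
        )
        res = day_effect(daily, pairwise=False)
        rejections += res["p_value"] < 0.05
    assert abs(rejections / reps - 0.05) <= 0.03


def test_day_effect_detects_shifted_day():
    rng = np.random.default_rng(6)
    daily = pd.DataFrame(
        {
            "study_day": np.repeat(np.arange(1, 6), 20),
            "sum_umol": rng.lognormal(0, 0.3, 100),
        }
    )
    daily.loc[daily["study_day"] == 3, "sum_umol"] += 10.0
    res = day_effect(daily)
    assert res["p_value"] < 0.01
    pw = res["pairwise"]
    hits = pw[(pw["day_a"] == 3) | (pw["day_b"] == 3)]
    assert (hits["p_bonferroni"] < 0.05).all()
    assert (pw["p_bonferroni"] >= pw["p_raw"] - 1e-12).all()


def test_day_effect_single_group_rejected():
    daily = pd.DataFrame({"study_day": [1] * 5, "sum_umol": range(5)})
    with pytest.raises(PhenotypeError):
        day_effect(daily)
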