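"""Mercapturic-acid phenotyping and exposure-group comparisons.

Most people excrete more 3-HPMA than CEMA after acrolein exposure, but a
minority shows the reverse, plausibly from polymorphisms in the aldo-keto
reductases and aldehyde dehydrogenases that partition the common OPMA
precursor.  A participant is called CEMA-phenotype when CEMA exceeds 3-HPMA
on a majority of study days and/or the participant's median CEMA exceeds
the median 3-HPMA; otherwise 3-HPMA-phenotype (the population default).

Group contrasts use nonparametric tests throughout: Mann-Whitney U for the
high- vs low-glycerol overnight comparison (participant-nights as units),
Kruskal-Wallis plus Bonferroni-corrected pairwise Mann-Whitney for
between-day effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClassifierRule",
    "PhenotypeCall",
    "GroupComparison",
    "classify_participant",
    "classify_cohort",
    "cohort_phenotype_counts",
    "compare_exposure_groups",
    "day_effect",
    "PhenotypeError",
]


class PhenotypeError(ValueError):
    """Raised for unclassifiable inputs or empty comparison groups."""


@dataclass(frozen=True)
class ClassifierRule:
    """Disjunctive day-majority / median-override phenotype rule.

    A participant is labelled CEMA if the fraction of days with
    CEMA > 3-HPMA exceeds ``majority_threshold``, or (when
    ``use_median_override``) the median daily CEMA exceeds the median daily
    3-HPMA.  Both comparisons are strict, so exact ties fall through to
    ``tie_label`` — 3-HPMA by default, it being the usual dominant
    mercapturic acid.
    """

    majority_threshold: float = 0.5
    use_median_override: bool = True
    tie_label: str = "HPMA"
    min_days: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.majority_threshold <= 1.0:
            raise PhenotypeError(
                f"majority_threshold {self.majority_threshold} outside (0, 1]"
            )


DEFAULT_RULE = ClassifierRule()


@dataclass(frozen=True)
class PhenotypeCall:
    participant: str
    label: str  # "CEMA" or "HPMA"
    n_days: int
    n_days_cema_gt_hpma: int
    median_cema_umol: float
    median_hpma_umol: float
    majority_clause: bool
    median_clause: bool

    @property
    def conflicting(self) -> bool:
        """Clauses disagree (e.g., HPMA-majority days but CEMA median)."""
        return self.majority_clause != self.median_clause


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float


def classify_participant(
    daily: pd.DataFrame, rule: ClassifierRule = DEFAULT_RULE
) -> PhenotypeCall:
    """Phenotype call for one participant's daily excretion table.

    ``daily`` needs ``cema_umol`` and ``hpma_umol`` columns; days flagged
    ``missing`` or with a non-positive amount are dropped before
    evaluation.  At least ``rule.min_days`` valid days are required.
    """
    d = daily
    if "missing" in d.columns:
        d = d.loc[~d["missing"].astype(bool)]
    d = d.loc[(d["cema_umol"] > 0) & (d["hpma_umol"] > 0)]
    n_days = len(d)
    if n_days < rule.min_days:
        pid = str(daily["participant"].iloc[0]) if len(daily) else "<empty>"
        raise PhenotypeError(
            f"participant {pid}: only {n_days} valid days, "
            f"need >= {rule.min_days} to classify"
        )
    cema = d["cema_umol"].to_numpy(float)
    hpma = d["hpma_umol"].to_numpy(float)
    n_gt = int((cema > hpma).sum())
    med_c = float(np.median(cema))
    med_h = float(np.median(hpma))
    majority = (n_gt / n_days) > rule.majority_threshold
    median_ovr = rule.use_median_override and (med_c > med_h)
    label = "CEMA" if (majority or median_ovr) else rule.tie_label
    return PhenotypeCall(
        participant=str(d["participant"].iloc[0]) if "participant" in d else "",
        label=label,
        n_days=n_days,
        n_days_cema_gt_hpma=n_gt,
        median_cema_umol=med_c,
        median_hpma_umol=med_h,
        majority_clause=bool(majority),
        median_clause=bool(med_c > med_h),
    )


def classify_cohort(
    daily: pd.DataFrame, rule: ClassifierRule = DEFAULT_RULE
) -> pd.DataFrame:
    """One phenotype call per participant, as a table.

    Participants with too few valid days are returned with label
    ``"unclassifiable"`` rather than raising.
    """
    rows = []
    for pid, chunk in daily.groupby("participant", sort=True):
        try:
            call = classify_participant(chunk, rule)
        except PhenotypeError:
            rows.append(
                {
                    "participant": str(pid),
                    "label": "unclassifiable",
                    "n_days": 0,
                    "n_days_cema_gt_hpma": 0,
                    "median_cema_umol": np.nan,
                    "median_hpma_umol": np.nan,
                    "conflicting": False,
                }
            )
            continue
        rows.append(
            {
                "participant": call.participant,
                "label": call.label,
                "n_days": call.n_days,
                "n_days_cema_gt_hpma": call.n_days_cema_gt_hpma,
                "median_cema_umol": call.median_cema_umol,
                "median_hpma_umol": call.median_hpma_umol,
                "conflicting": call.conflicting,
            }
        )
    return pd.DataFrame(rows)


def cohort_phenotype_counts(calls: pd.DataFrame) -> dict[str, int]:
    """Label counts over classified participants."""
    classified = calls.loc[calls["label"].isin(["HPMA", "CEMA"])]
    if classified.empty:
        raise PhenotypeError("no classified participants to count")
    counts = classified["label"].value_counts().to_dict()
    return {"HPMA": counts.get("HPMA", 0), "CEMA": counts.get("CEMA", 0)}


def _mwu(a: np.ndarray, b: np.ndarray, la: str, lb: str) -> GroupComparison:
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        group_a=la,
        group_b=lb,
        n_a=len(a),
        n_b=len(b),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def compare_exposure_groups(
    overnight: pd.DataFrame,
    analytes: tuple[str, ...] = ("hpma_umol", "cema_umol", "sum_umol"),
    class_column: str = "dinner_class",
) -> pd.DataFrame:
    """High- vs low-glycerol overnight comparison, per analyte.

    ``overnight`` is a per participant-night table with a ``dinner_class``
    column ('high'/'low'; 'excluded' nights are dropped).  Units are
    participant-nights.  Returns one row per analyte with group medians,
    the Mann-Whitney U statistic (for the high group) and the two-sided p.
    """
    high = overnight.loc[overnight[class_column] == "high"]
    low = overnight.loc[overnight[class_column] == "low"]
    if "missing" in overnight.columns:
        high = high.loc[~high["missing"].astype(bool)]
        low = low.loc[~low["missing"].astype(bool)]
    if high.empty or low.empty:
        raise PhenotypeError(
            "empty exposure group under the current attribution config "
            f"(high n={len(high)}, low n={len(low)})"
        )
    rows = []
    for col in analytes:
        cmp = _mwu(
            high[col].to_numpy(float), low[col].to_numpy(float), "high", "low"
        )
        rows.append(
            {
                "analyte": col,
                "n_high": cmp.n_a,
                "n_low": cmp.n_b,
                "median_high": cmp.median_a,
                "median_low": cmp.median_b,
                "u_statistic": cmp.u_statistic,
                "p_value": cmp.p_value,
            }
        )
    return pd.DataFrame(rows)


def day_effect(
    daily: pd.DataFrame,
    value_column: str = "sum_umol",
    day_column: str = "study_day",
    pairwise: bool = True,
) -> dict:
    """Between-day omnibus test with Bonferroni-corrected pairwise follow-up.

    Kruskal-Wallis across study days (each day a group of participant
    values), then, when ``pairwise``, two-sided Mann-Whitney U for every
    day pair with Bonferroni-adjusted p values.
    """
    d = daily
    if "missing" in d.columns:
        d = d.loc[~d["missing"].astype(bool)]
    groups = {
        day: chunk[value_column].to_numpy(float)
        for day, chunk in d.groupby(day_column)
        if len(chunk) >= 2
    }
    if len(groups) < 2:
        raise PhenotypeError(
            f"day_effect needs >= 2 days with >= 2 values, got {len(groups)}"
        )
    stat, p = stats.kruskal(*groups.values())
    out: dict = {
        "statistic": float(stat),
        "p_value": float(p),
        "n_groups": len(groups),
    }
    if pairwise:
        days = sorted(groups)
        n_pairs = len(days) * (len(days) - 1) // 2
        pw = []
        for i, da in enumerate(days):
            for db in days[i + 1:]:
                res = stats.mannwhitneyu(
                    groups[da], groups[db], alternative="two-sided"
                )
                pw.append(
                    {
                        "day_a": da,
                        "day_b": db,
                        "u_statistic": float(res.statistic),
                        "p_raw": float(res.pvalue),
                        "p_bonferroni": min(1.0, float(res.pvalue) * n_pairs),
                    }
                )
        out["pairwise"] = pd.DataFrame(pw)
    return out
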