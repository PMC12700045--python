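"""Mass-balance back-calculation of intestinal acrolein from diet and urine.

The estimation chain:

1. Dietary triglyceride-bound glycerol is hydrolyzed in the small intestine
   with ~95% efficiency; the unhydrolyzed remainder reaches the colon, where
   microbes carrying glycerol/diol dehydratase (PduCDE) can dehydrate
   glycerol to 3-hydroxypropanal, which spontaneously forms acrolein.
2. In rat studies with orally dosed 14C-acrolein, about 20% of the dose is
   recovered in urine as 3-HPMA.  Assuming the same fraction in humans, the
   intestinal acrolein amount is urinary 3-HPMA divided by 0.20.
3. The fraction of the colonic glycerol pool converted to acrolein is
   expressed in mol%.

Worked example at the defaults: a dinner carrying 0.44 g glycerol delivers
(1 - 0.95) x 0.44 / 92.09 x 1000 = 0.24 mmol glycerol to the colon; a median
overnight 3-HPMA excretion of 0.26 umol implies 0.26 / 0.20 = 1.3 umol of
intestinal acrolein.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "MW_GLYCEROL",
    "MW_ACROLEIN",
    "MassBalanceParams",
    "AcroleinEstimate",
    "glycerol_g_to_mmol",
    "colonic_glycerol",
    "acrolein_from_hpma",
    "molpct_converted",
    "coffee_acrolein",
    "estimate_for_class",
    "MassBalanceConfigError",
]

MW_GLYCEROL = 92.09  # g/mol
MW_ACROLEIN = 56.06  # g/mol


class MassBalanceConfigError(ValueError):
    """Raised for invalid physiological/chemical parameters."""


@dataclass(frozen=True)
class MassBalanceParams:
    """Constants of the diet-to-acrolein mass balance.

    hydrolysis_eff
        Fraction of dietary triglyceride hydrolyzed to glycerol and free
        fatty acids in the small intestine (default 0.95); the remainder
        reaches the colon.
    hpma_excretion_frac
        Fraction of an acrolein dose excreted in urine as 3-HPMA
        (default 0.20, from oral dosing in rats).
    denominator_mode
        Glycerol pool against which mol% conversion is expressed:
        "colonic" (default, the pool actually available to microbes) or
        "intake" (total dietary glycerol).
    """

    mw_glycerol: float = MW_GLYCEROL
    mw_acrolein: float = MW_ACROLEIN
    hydrolysis_eff: float = 0.95
    hpma_excretion_frac: float = 0.20
    denominator_mode: str = "colonic"

    def __post_init__(self) -> None:
        if self.mw_glycerol <= 0 or self.mw_acrolein <= 0:
            raise MassBalanceConfigError("molar masses must be positive")
        if not 0.0 <= self.hydrolysis_eff <= 1.0:
            raise MassBalanceConfigError(
                f"hydrolysis_eff {self.hydrolysis_eff} outside [0, 1]"
            )
        if not 0.0 < self.hpma_excretion_frac <= 1.0:
            raise MassBalanceConfigError(
                f"hpma_excretion_frac {self.hpma_excretion_frac} outside (0, 1]"
            )
        if self.denominator_mode not in ("colonic", "intake"):
            raise MassBalanceConfigError(
                f"denominator_mode {self.denominator_mode!r} not in "
                "{'colonic', 'intake'}"
            )


DEFAULT_PARAMS = MassBalanceParams()


@dataclass(frozen=True)
class AcroleinEstimate:
    """One exposure class's back-calculated intestinal acrolein."""

    dinner_class: str
    dinner_glycerol_g: float
    colonic_glycerol_mmol: float
    median_overnight_hpma_umol: float
    intestinal_acrolein_umol: float
    molpct_converted: float | None


def glycerol_g_to_mmol(glycerol_g: float, mw_glycerol: float = MW_GLYCEROL) -> float:
    """Convert grams of glycerol to mmol."""
    if mw_glycerol <= 0:
        raise MassBalanceConfigError(f"non-positive molar mass {mw_glycerol}")
    if glycerol_g < 0:
        raise MassBalanceConfigError(f"negative glycerol mass {glycerol_g}")
    return glycerol_g / mw_glycerol * 1000.0


def colonic_glycerol(
    glycerol_g: float, params: MassBalanceParams = DEFAULT_PARAMS
) -> float:
    """mmol of dietary glycerol escaping small-intestinal hydrolysis."""
    return (1.0 - params.hydrolysis_eff) * glycerol_g_to_mmol(
        glycerol_g, params.mw_glycerol
    )


def acrolein_from_hpma(
    hpma_umol: float, params: MassBalanceParams = DEFAULT_PARAMS
) -> float:
    """Intestinal acrolein (umol) back-calculated from urinary 3-HPMA."""
    if hpma_umol < 0:
        raise MassBalanceConfigError(f"negative 3-HPMA amount {hpma_umol}")
    return hpma_umol / params.hpma_excretion_frac


def molpct_converted(acrolein_umol: float, glycerol_pool_mmol: float) -> float:
    """mol% of a glycerol pool (mmol) converted to acrolein (umol)."""
    if glycerol_pool_mmol <= 0:
        raise MassBalanceConfigError(
            f"glycerol pool must be positive, got {glycerol_pool_mmol} mmol"
        )
    if acrolein_umol < 0:
        raise MassBalanceConfigError(f"negative acrolein amount {acrolein_umol}")
    return 100.0 * acrolein_umol / (glycerol_pool_mmol * 1000.0)


def coffee_acrolein(
    conc_ug_ml: float, volume_ml: float, mw_acrolein: float = MW_ACROLEIN
) -> float:
    """umol of acrolein ingested with a coffee serving.

    Roasted coffee can contain up to 0.81 ug/mL acrolein; a ~250 mL cup at
    that level carries ~3.6 umol.
    """
    if mw_acrolein <= 0:
        raise MassBalanceConfigError(f"non-positive molar mass {mw_acrolein}")
    if conc_ug_ml < 0 or volume_ml < 0:
        raise MassBalanceConfigError("concentration and volume must be >= 0")
    return conc_ug_ml * volume_ml / mw_acrolein


def estimate_for_class(
    dinner_class: str,
    dinner_glycerol_g: float,
    median_overnight_hpma_umol: float,
    params: MassBalanceParams = DEFAULT_PARAMS,
) -> AcroleinEstimate:
    """Full estimation chain for one dinner-exposure class."""
    pool = colonic_glycerol(dinner_glycerol_g, params)
    if params.denominator_mode == "intake":
        pool_for_pct = glycerol_g_to_mmol(dinner_glycerol_g, params.mw_glycerol)
    else:
        pool_for_pct = pool
    acro = acrolein_from_hpma(median_overnight_hpma_umol, params)
    pct = molpct_converted(acro, pool_for_pct) if pool_for_pct > 0 else None
    return AcroleinEstimate(
        dinner_class=dinner_class,
        dinner_glycerol_g=dinner_glycerol_g,
        colonic_glycerol_mmol=pool,
        median_overnight_hpma_umol=median_overnight_hpma_umol,
        intestinal_acrolein_umol=acro,
        molpct_converted=pct,
    )


def estimates_table(
    day_glycerol: pd.DataFrame,
    overnight: pd.DataFrame,
    params: MassBalanceParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Acrolein estimates for the low and high dinner classes.

    ``day_glycerol`` is the per-day table from :func:`glycacro.diet.
    day_glycerol_table` (needs ``dinner_g`` and ``dinner_class``);
    ``overnight`` the per-night table from :func:`glycacro.urine.
    overnight_excretion` merged with a ``dinner_class`` column.  Median
    dinner glycerol and median overnight 3-HPMA per class feed the chain.
    Reported values are rounded half-even to 2 decimals.
    """
    rows = []
    for cls in ("low", "high"):
        gly = day_glycerol.loc[day_glycerol["dinner_class"] == cls, "dinner_g"]
        hp = overnight.loc[overnight["dinner_class"] == cls, "hpma_umol"]
        if gly.empty or hp.empty:
            continue
        est = estimate_for_class(cls, float(gly.median()), float(hp.median()), params)
        rows.append(
            {
                "dinner_class": est.dinner_class,
                "dinner_glycerol_g": round(est.dinner_glycerol_g, 2),
                "colonic_glycerol_mmol": round(est.colonic_glycerol_mmol, 2),
                "median_overnight_hpma_umol": round(
                    est.median_overnight_hpma_umol, 2
                ),
                "intestinal_acrolein_umol": round(est.intestinal_acrolein_umol, 2),
                "molpct_converted": (
                    round(est.molpct_converted, 3)
                    if est.molpct_converted is not None
                    else None
                ),
            }
        )
    return pd.DataFrame(rows)
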