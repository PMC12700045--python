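"""Seeded synthetic cohorts with the structure the analysis assumes.

The generator emulates an 11-day standardized-diet intervention in 20
adults (10 male, 10 female): four menu schedules cycling over the days,
high-glycerol dinners on days 3, 4, 7 and 8, timed urine collections with
an always-present 20:00-08:00 overnight interval (days 10 and 11 pooled
over 24 h), urinary 3-HPMA/CEMA excretion with persistent per-participant
phenotypes in a 14:6 split, and fecal community tables (pdu gene matrix,
per-donor qPCR-style detection, SCFA profiles, fecal glycerol).

Model of daily excretion: participant-day totals are log-normal with a
participant-level random intercept; the CEMA share follows a
phenotype-specific median ratio with participant- and day-level log-normal
scatter, calibrated so the pooled median daily CEMA/3-HPMA ratio sits at
0.73.  High-glycerol dinners multiply the overnight interval's excretion
by a configurable uplift (default 1.5).

Every draw flows from one ``numpy.random.default_rng(seed)``; identical
config and seed give identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diet import DEFAULT_CORRECTION_FACTOR, SLOTS
from .urine import MW_CEMA, MW_HPMA

__all__ = [
    "CohortConfig",
    "generate_menu",
    "generate_urine",
    "generate_microbiome",
    "generate_cohort",
    "write_cohort",
    "PDU_TAXA",
]

#: pdu-positive species of the human gut (plus one transient dairy culture).
PDU_TAXA = (
    "Anaerobutyricum hallii",
    "Anaerobutyricum soehngenii",
    "Blautia obeum",
    "Blautia ammoniilytica",
    "Blautia sp900066335",
    "Mediterraneibacter gnavus",
    "Mediterraneibacter glycyrrhizinilytica",
    "Flavonifractor plautii",
    "Propionibacterium freudenreichii",
)

# Menu glycerol targets (grams, male menu) per schedule and slot.  Lunch
# dominates on low-dinner days (~50% of the daily total); dinner dominates
# on schedules 3 and 4.  The female menu is scaled by ``female_factor``.
_SCHEDULE_GLYCEROL = {
    1: {"breakfast": 0.90, "lunch": 2.30, "dinner": 0.85, "snack": 0.45},
    2: {"breakfast": 0.80, "lunch": 2.50, "dinner": 1.05, "snack": 0.50},
    3: {"breakfast": 0.80, "lunch": 1.60, "dinner": 2.60, "snack": 0.40},
    4: {"breakfast": 0.85, "lunch": 1.70, "dinner": 3.00, "snack": 0.45},
}

# Food items per schedule and slot with their share of the slot's glycerol.
_MENU_ITEMS = {
    1: {
        "breakfast": [("rye bread with butter", 0.65), ("semi-skimmed milk", 0.35)],
        "lunch": [("pasta with meat sauce", 0.70), ("side salad with dressing", 0.30)],
        "dinner": [("vegetable soup", 0.45), ("cheese sandwich", 0.55)],
        "snack": [("fruit yogurt", 1.00)],
    },
    2: {
        "breakfast": [("oat porridge with milk", 0.55), ("boiled egg", 0.45)],
        "lunch": [("chicken rice bowl", 0.65), ("yogurt dessert", 0.35)],
        "dinner": [("lentil stew", 0.50), ("wheat roll with margarine", 0.50)],
        "snack": [("mixed nuts, small pack", 1.00)],
    },
    3: {
        "breakfast": [("wheat toast with jam", 0.60), ("semi-skimmed milk", 0.40)],
        "lunch": [("vegetable couscous", 0.75), ("fruit compote", 0.25)],
        "dinner": [("salmon with potatoes", 0.60), ("cream sauce", 0.40)],
        "snack": [("plain biscuit", 1.00)],
    },
    4: {
        "breakfast": [("muesli with milk", 0.70), ("banana", 0.30)],
        "lunch": [("tomato soup", 0.40), ("ham sandwich", 0.60)],
        "dinner": [("beef goulash", 0.55), ("buttered noodles", 0.45)],
        "snack": [("cheese cubes", 1.00)],
    },
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the default synthetic cohort.

    Amount units are umol (biomarkers), grams (glycerol, urine weight) and
    umol/g (fecal metabolites); scatter parameters are standard deviations
    on the natural-log scale.
    """

    n_participants: int = 20
    n_male: int = 10
    n_days: int = 11
    start_date: str = "2024-03-04"  # study day 1 starts 08:00 this date

    # Menu
    schedules: dict[int, frozenset[int]] = field(
        default_factory=lambda: {
            1: frozenset({1, 5, 9}),
            2: frozenset({2, 6, 10}),
            3: frozenset({3, 7, 11}),
            4: frozenset({4, 8}),
        }
    )
    high_days: frozenset[int] = frozenset({3, 4, 7, 8})
    low_dinner_range: tuple[float, float] = (0.44, 1.26)  # g glycerol
    high_dinner_range: tuple[float, float] = (2.1, 3.4)  # g glycerol
    female_factor: float = 0.92
    menu_jitter: float = 0.04  # relative, per schedule x slot
    correction_factor: float = DEFAULT_CORRECTION_FACTOR

    # Biomarker excretion model
    hpma_phenotype_fraction: float = 14 / 20
    daily_total_median_umol: float = 1.05
    participant_sd_log: float = 0.25
    day_sd_log: float = 0.20
    ratio_median_hpma_phenotype: float = 0.67
    ratio_median_cema_phenotype: float = 1.45
    ratio_participant_sd_log: float = 0.06
    ratio_day_sd_log: float = 0.13
    overnight_effect: float = 1.5  # multiplicative, after high-glycerol dinners
    noise_cv: float = 0.05  # per interval x analyte measurement scatter
    pooled_days: frozenset[int] = frozenset({10, 11})  # single 24 h interval
    urine_rate_g_per_h: float = 65.0
    urine_rate_sd_log: float = 0.20

    # Fecal tables
    n_fecal_donors: int = 19
    fecal_sample_prob: float = 0.8  # per donor-day
    fecal_glycerol_median: float = 2.0  # umol/g
    fecal_glycerol_sd_log: float = 0.75
    fecal_glycerol_range: tuple[float, float] = (0.2, 19.4)  # umol/g
    total_scfa_median: float = 80.0  # umol/g
    total_scfa_sd_log: float = 0.30
    scfa_alpha: tuple[float, float, float] = (41.0, 5.2, 11.0)  # ace, pro, but

    # pdu community
    n_background_genomes: int = 31
    dominant_taxon: str = "Anaerobutyricum hallii"
    dominant_copies_median: float = 1.0e9  # pduC copies per g feces
    other_copies_median: float = 5.0e6
    copies_sd_log: float = 0.5
    qpcr_lod: float = 1.0e5
    detection_probs: tuple[float, ...] = (
        1.0, 0.95, 0.95, 0.90, 0.90, 0.85, 0.85, 0.80, 0.75
    )
    min_pdu_per_donor: int = 5


DEFAULT_CONFIG = CohortConfig()


def _participants(config: CohortConfig) -> pd.DataFrame:
    pids = [f"P{i:02d}" for i in range(1, config.n_participants + 1)]
    groups = ["male"] * config.n_male + ["female"] * (
        config.n_participants - config.n_male
    )
    return pd.DataFrame({"participant": pids, "group": groups})


def _assign_phenotypes(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic label proportions after a seeded shuffle.

    The first ceil(p * n) participants of a seeded permutation get the
    3-HPMA phenotype, so the 14:6 split is exact in every cohort.
    """
    part = _participants(config)
    n = len(part)
    n_hpma = math.ceil(config.hpma_phenotype_fraction * n)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[order[:n_hpma]] = "HPMA"
    labels[order[n_hpma:]] = "CEMA"
    part["phenotype"] = labels
    return part


def _schedule_of_day(config: CohortConfig, day: int) -> int:
    for sid, days in config.schedules.items():
        if day in days:
            return sid
    raise ValueError(f"study day {day} is in no menu schedule")


def generate_menu(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Long-format diet table for both participant groups.

    Four menus cycle over the 11 days; dinner glycerol lands inside the
    configured low/high ranges on the corresponding days.  A small seeded
    jitter (shared by all days of a schedule, so repeated days have
    identical menus) perturbs the slot targets.
    """
    union = frozenset().union(*config.schedules.values())
    expected = frozenset(range(1, config.n_days + 1))
    if union != expected or sum(len(s) for s in config.schedules.values()) != len(
        expected
    ):
        raise ValueError(
            f"menu schedules must partition days 1..{config.n_days}"
        )
    # one jitter per schedule x slot, drawn in fixed order
    jitter = {
        (sid, slot): 1.0 + config.menu_jitter * (2.0 * rng.random() - 1.0)
        for sid in sorted(_SCHEDULE_GLYCEROL)
        for slot in SLOTS
    }
    rows = []
    for group, factor in (("male", 1.0), ("female", config.female_factor)):
        for day in range(1, config.n_days + 1):
            sid = _schedule_of_day(config, day)
            for slot in SLOTS:
                slot_g = _SCHEDULE_GLYCEROL[sid][slot] * jitter[(sid, slot)] * factor
                for item, share in _MENU_ITEMS[sid][slot]:
                    gly = slot_g * share
                    rows.append(
                        {
                            "group": group,
                            "study_day": day,
                            "slot": slot,
                            "item": item,
                            "fat_g": gly / config.correction_factor,
                            "correction_factor": config.correction_factor,
                        }
                    )
    menu = pd.DataFrame(rows)
    # sanity: dinner glycerol inside the configured exposure ranges
    dinner = (
        menu[menu["slot"] == "dinner"]
        .assign(gly=lambda d: d["fat_g"] * d["correction_factor"])
        .groupby(["group", "study_day"])["gly"]
        .sum()
    )
    high_schedules = {
        sid for sid, days in config.schedules.items() if days & config.high_days
    }
    for (group, day), g in dinner.items():
        lo, hi = (
            config.high_dinner_range
            if _schedule_of_day(config, day) in high_schedules
            else config.low_dinner_range
        )
        if not lo <= g <= hi:
            raise ValueError(
                f"generated dinner glycerol {g:.2f} g on day {day} ({group}) "
                f"outside [{lo}, {hi}]"
            )
    return menu


def _interval_offsets(config: CohortConfig, day: int) -> list[tuple[float, float]]:
    """Interval start/end hours relative to the day's 08:00 boundary."""
    if day in config.pooled_days:
        return [(0.0, 24.0)]
    return [(0.0, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 24.0)]


def generate_urine(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Urine interval table plus the latent truth table.

    Returns ``(urine, truth)``: ``urine`` has the collection-interval
    columns the analysis reads (timestamps, weight, ng/mL concentrations);
    ``truth`` carries each participant-day's latent phenotype and excreted
    amounts (umol, including the overnight uplift, before measurement
    noise) for recovery tests.
    """
    part = _assign_phenotypes(config, rng)
    n, d = config.n_participants, config.n_days
    origin = pd.Timestamp(config.start_date) + pd.Timedelta(hours=8)

    t_part = config.daily_total_median_umol * np.exp(
        rng.normal(0.0, config.participant_sd_log, n)
    )
    t_day = t_part[:, None] * np.exp(rng.normal(0.0, config.day_sd_log, (n, d)))
    r_pheno = np.where(
        part["phenotype"].to_numpy() == "CEMA",
        config.ratio_median_cema_phenotype,
        config.ratio_median_hpma_phenotype,
    )
    rho_part = r_pheno * np.exp(rng.normal(0.0, config.ratio_participant_sd_log, n))
    rho_day = rho_part[:, None] * np.exp(
        rng.normal(0.0, config.ratio_day_sd_log, (n, d))
    )
    cema_day = t_day * rho_day / (1.0 + rho_day)
    hpma_day = t_day / (1.0 + rho_day)

    urine_rows = []
    truth_rows = []
    for i in range(n):
        pid = part["participant"].iloc[i]
        for j in range(d):
            day = j + 1
            offsets = _interval_offsets(config, day)
            durs = np.array([e - s for s, e in offsets])
            shares = durs / 24.0
            uplift = np.ones(len(offsets))
            if day in config.high_days and len(offsets) > 1:
                uplift[-1] = config.overnight_effect  # 20:00-08:00 interval
            amt_h = hpma_day[i, j] * shares * uplift
            amt_c = cema_day[i, j] * shares * uplift
            truth_rows.append(
                {
                    "participant": pid,
                    "group": part["group"].iloc[i],
                    "phenotype": part["phenotype"].iloc[i],
                    "study_day": day,
                    "true_hpma_umol": amt_h.sum(),
                    "true_cema_umol": amt_c.sum(),
                }
            )
            noise_h = np.exp(rng.normal(0.0, config.noise_cv, len(offsets)))
            noise_c = np.exp(rng.normal(0.0, config.noise_cv, len(offsets)))
            weights = (
                durs
                * config.urine_rate_g_per_h
                * np.exp(rng.normal(0.0, config.urine_rate_sd_log, len(offsets)))
            )
            obs_h = amt_h * noise_h
            obs_c = amt_c * noise_c
            for k, (s, e) in enumerate(offsets):
                ml = weights[k]  # density 1 kg/L: grams = mL
                urine_rows.append(
                    {
                        "participant": pid,
                        "start": origin + pd.Timedelta(hours=24.0 * j + s),
                        "end": origin + pd.Timedelta(hours=24.0 * j + e),
                        "urine_weight_g": round(weights[k], 1),
                        "conc_hpma_ng_ml": obs_h[k] * MW_HPMA * 1000.0 / ml,
                        "conc_cema_ng_ml": obs_c[k] * MW_CEMA * 1000.0 / ml,
                    }
                )
    return pd.DataFrame(urine_rows), pd.DataFrame(truth_rows)


def generate_microbiome(
    config: CohortConfig, rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    """pdu gene matrix, per-donor qPCR detection, SCFA and fecal glycerol.

    Nine pdu-positive taxa sit in a background of pdu-negative genomes; one
    dominant taxon receives >90% of simulated pduC copies.  Per-donor
    detected pdu species counts are guaranteed >= ``min_pdu_per_donor``
    (Bernoulli draws, topped up deterministically from the rarest taxa),
    matching the observed cohort minimum.
    """
    taxa = list(PDU_TAXA)
    # presence/absence: seven genomes with the full pduCDE, two partial
    genes = ("pduC", "pduD", "pduE")
    pdu_rows = {}
    for t in taxa[:7]:
        pdu_rows[t] = {g: True for g in genes}
    pdu_rows[taxa[7]] = {"pduC": True, "pduD": True, "pduE": False}
    pdu_rows[taxa[8]] = {"pduC": True, "pduD": False, "pduE": False}
    for b in range(config.n_background_genomes):
        pdu_rows[f"rMAG_{b + 1:03d}"] = {g: False for g in genes}
    pdu_genes = pd.DataFrame.from_dict(pdu_rows, orient="index").rename_axis(
        "genome_id"
    )

    donors = [f"P{i:02d}" for i in range(1, config.n_fecal_donors + 1)]
    probs = np.asarray(config.detection_probs)
    qpcr_rows = []
    for donor in donors:
        detected = rng.random(len(taxa)) < probs
        short = config.min_pdu_per_donor - int(detected.sum())
        if short > 0:  # top up from the rarest taxa, deterministically
            for k in np.argsort(probs):
                if not detected[k]:
                    detected[k] = True
                    short -= 1
                    if short == 0:
                        break
        for k, taxon in enumerate(taxa):
            if detected[k]:
                med = (
                    config.dominant_copies_median
                    if taxon == config.dominant_taxon
                    else config.other_copies_median
                )
                copies = med * np.exp(rng.normal(0.0, config.copies_sd_log))
            else:
                copies = np.nan  # censored below the limit of detection
            qpcr_rows.append(
                {
                    "sample": donor,
                    "taxon": taxon,
                    "copies_per_g": copies,
                    "lod": config.qpcr_lod,
                }
            )
    qpcr = pd.DataFrame(qpcr_rows)

    # fecal samples: shared availability mask for SCFA and glycerol
    scfa_rows = []
    gly_rows = []
    for donor in donors:
        available = rng.random(config.n_days) < config.fecal_sample_prob
        if not available.any():
            available[rng.integers(config.n_days)] = True  # >=1 sample per donor
        for j in np.flatnonzero(available):
            day = int(j) + 1
            sample = f"{donor}_d{day:02d}"
            total = config.total_scfa_median * np.exp(
                rng.normal(0.0, config.total_scfa_sd_log)
            )
            ace, pro, but = rng.dirichlet(config.scfa_alpha)
            scfa_rows.append(
                {
                    "sample": sample,
                    "donor": donor,
                    "study_day": day,
                    "acetate": total * ace,
                    "propionate": total * pro,
                    "butyrate": total * but,
                }
            )
            lo, hi = config.fecal_glycerol_range
            g = float(
                np.clip(
                    config.fecal_glycerol_median
                    * np.exp(rng.normal(0.0, config.fecal_glycerol_sd_log)),
                    lo,
                    hi,
                )
            )
            gly_rows.append(
                {
                    "sample": sample,
                    "donor": donor,
                    "study_day": day,
                    "glycerol_umol_g": g,
                }
            )
    return {
        "pdu_genes": pdu_genes,
        "qpcr": qpcr,
        "scfa": pd.DataFrame(scfa_rows),
        "fecal_glycerol": pd.DataFrame(gly_rows),
    }


def generate_cohort(
    config: CohortConfig = DEFAULT_CONFIG, seed: int = 42
) -> dict[str, pd.DataFrame]:
    """All cohort tables from one seed, in a fixed generation order."""
    rng = np.random.default_rng(seed)
    diet = generate_menu(config, rng)
    urine, truth = generate_urine(config, rng)
    micro = generate_microbiome(config, rng)
    return {
        "diet": diet,
        "urine": urine,
        "urine_truth": truth,
        **micro,
    }


def write_cohort(tables: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write every cohort table as CSV; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=(name == "pdu_genes"))
        paths.append(path)
    return paths
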