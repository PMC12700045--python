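"""End-to-end orchestration: diet -> urine -> mass balance -> phenotypes -> community tables.

``run_all`` reads the input CSVs named in a :class:`RunConfig`, executes
every stage with the configured parameters, writes one CSV per stage plus
a JSON summary and a machine-readable parameter log, and returns the
in-memory results.  A stage failure raises with the stage named; outputs
written before the failure are retained.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import diet as diet_mod
from . import massbalance, microbiome, phenotype, urine

__all__ = ["RunConfig", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths and parameter blocks of one analysis run."""

    diet_csv: str
    urine_csv: str
    outdir: str
    pdu_genes_csv: str | None = None
    qpcr_csv: str | None = None
    scfa_csv: str | None = None
    exposure: diet_mod.ExposureConfig = field(
        default_factory=diet_mod.ExposureConfig
    )
    windows: urine.WindowSpec = field(default_factory=urine.WindowSpec)
    constants: urine.AnalyteConstants = field(
        default_factory=urine.AnalyteConstants
    )
    rule: phenotype.ClassifierRule = field(default_factory=phenotype.ClassifierRule)
    params: massbalance.MassBalanceParams = field(
        default_factory=massbalance.MassBalanceParams
    )
    n_days: int | None = None


def _read(path: str, stage: str, index_col=None) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise PipelineError(f"stage {stage!r}: input file not found: {p}")
    return pd.read_csv(p, index_col=index_col)


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns a dict of stage outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    summary: dict = {}

    def _stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # diet
    def _diet():
        table = diet_mod.day_glycerol_table(
            _read(config.diet_csv, "diet"), config.exposure
        )
        table.to_csv(outdir / "day_glycerol.csv", index=False)
        return table

    day_glycerol = _stage("diet", _diet)
    results["day_glycerol"] = day_glycerol

    # urine
    def _urine():
        intervals = _read(config.urine_csv, "urine")
        daily = urine.daily_excretion(
            intervals, config.windows, config.constants, n_days=config.n_days
        )
        overnight = urine.overnight_excretion(
            intervals, config.windows, config.constants, n_days=config.n_days
        )
        daily = urine.add_daily_ratios(daily)
        overnight["dinner_class"] = [
            config.exposure.classify_day(d) if d in (
                config.exposure.high_days
                | config.exposure.low_days
                | config.exposure.excluded_days
            ) else "excluded"
            for d in overnight["study_day"]
        ]
        daily.to_csv(outdir / "daily_excretion.csv", index=False)
        overnight.to_csv(outdir / "overnight_excretion.csv", index=False)
        return daily, overnight

    daily, overnight = _stage("urine", _urine)
    results["daily"] = daily
    results["overnight"] = overnight
    valid = daily.loc[~daily["missing"]]
    summary["daily_median_umol"] = {
        "hpma": float(valid["hpma_umol"].median()),
        "cema": float(valid["cema_umol"].median()),
        "sum": float(valid["sum_umol"].median()),
    }
    summary["pooled_median_cema_hpma_ratio"] = float(daily["ratio"].median())

    # mass balance
    def _massbalance():
        est = massbalance.estimates_table(day_glycerol, overnight, config.params)
        est.to_csv(outdir / "acrolein_estimates.csv", index=False)
        return est

    estimates = _stage("mass_balance", _massbalance)
    results["acrolein_estimates"] = estimates
    summary["acrolein_estimates"] = estimates.to_dict(orient="records")

    # phenotypes + group comparison
    def _phenotype():
        calls = phenotype.classify_cohort(daily, config.rule)
        calls.to_csv(outdir / "phenotypes.csv", index=False)
        comparison = phenotype.compare_exposure_groups(overnight)
        comparison.to_csv(outdir / "overnight_comparison.csv", index=False)
        return calls, comparison

    calls, comparison = _stage("phenotype_compare", _phenotype)
    results["phenotypes"] = calls
    results["overnight_comparison"] = comparison
    summary["phenotype_counts"] = phenotype.cohort_phenotype_counts(calls)
    summary["overnight_comparison"] = comparison.to_dict(orient="records")

    # community tables (optional inputs)
    if config.pdu_genes_csv:
        def _pdu():
            matrix = _read(config.pdu_genes_csv, "pdu", index_col=0)
            pos = microbiome.pdu_positive(matrix)
            out = {"count": pos["count"], "percentage": pos["percentage"],
                   "n_rows": pos["n_rows"]}
            if config.qpcr_csv:
                qpcr = _read(config.qpcr_csv, "pdu")
                detect = qpcr.assign(
                    donor=qpcr["sample"],
                    detected=qpcr["copies_per_g"].notna()
                    & (qpcr["copies_per_g"] >= qpcr["lod"]),
                )[["donor", "taxon", "detected"]]
                counts = microbiome.per_donor_pdu_species(
                    pos["positive_ids"], detect
                )
                out["per_donor_median"] = counts["median"]
                out["per_donor_minimum"] = counts["minimum"]
                shares = microbiome.taxon_share(qpcr)
                shares.to_csv(outdir / "pduC_shares.csv", index=False)
            return out

        summary["pdu"] = _stage("pdu", _pdu)
    if config.scfa_csv:
        def _scfa():
            profile = microbiome.scfa_proportions(_read(config.scfa_csv, "scfa"))
            profile.to_csv(outdir / "scfa_proportions.csv", index=False)
            return {
                "median_pct_acetate": float(profile["pct_acetate"].median()),
                "median_pct_propionate": float(profile["pct_propionate"].median()),
                "median_pct_butyrate": float(profile["pct_butyrate"].median()),
                "median_butyrate_propionate_ratio": float(
                    profile["butyrate_propionate_ratio"].median()
                ),
            }

        summary["scfa"] = _stage("scfa", _scfa)

    # reproducibility report
    param_log = {
        "exposure": {
            "high_days": sorted(config.exposure.high_days),
            "low_days": sorted(config.exposure.low_days),
            "excluded_days": sorted(config.exposure.excluded_days),
            "threshold_g": config.exposure.threshold_g,
        },
        "windows": {
            "overnight_start": str(config.windows.overnight_start),
            "overnight_end": str(config.windows.overnight_end),
            "day_boundary": str(config.windows.day_boundary),
            "prorate": config.windows.prorate,
        },
        "constants": asdict(config.constants),
        "rule": asdict(config.rule),
        "mass_balance": asdict(config.params),
    }
    (outdir / "params.json").write_text(json.dumps(param_log, indent=2) + "\n")
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=float) + "\n"
    )
    results["summary"] = summary
    return results
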