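"""Summaries of pdu functional potential and fecal fermentation tables.

The pdu-cbi-cob-hem operon encodes the cobalamin-dependent glycerol/diol
dehydratase whose large, medium and small subunits are pduC, pduD and pduE.
Genomes carrying any (or, optionally, all) of these subunit genes are
counted as potential glycerol-to-3-hydroxypropanal (hence acrolein)
transformers.  Downstream summaries cover: per-donor counts of detected
pdu-positive species, per-taxon shares of an absolute signal such as qPCR
pduC copies, taxon prevalence, and short-chain fatty-acid (SCFA)
proportions with the butyrate:propionate ratio.

Quantities below an assay's limit of detection (LOD) are censored, not
zero: they are substituted with LOD/2 when computing shares and treated as
absent when computing occurrence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "PDU_SUBUNIT_GENES",
    "pdu_positive",
    "per_donor_pdu_species",
    "taxon_share",
    "prevalence",
    "scfa_proportions",
    "MicrobiomeError",
]

PDU_SUBUNIT_GENES = ("pduC", "pduD", "pduE")


class MicrobiomeError(ValueError):
    """Raised for malformed community tables."""


def pdu_positive(
    matrix: pd.DataFrame,
    required_genes: tuple[str, ...] = PDU_SUBUNIT_GENES,
    mode: str = "any",
) -> dict:
    """Genomes carrying pdu subunit genes.

    ``matrix`` is genomes x genes with boolean (or 0/1) cells.  A genome is
    positive when it carries at least one (``mode='any'``) or all
    (``mode='all'``) of ``required_genes``.  Returns the positive ids, the
    count, and the percentage of all rows (full precision).
    """
    if matrix.index.duplicated().any():
        raise MicrobiomeError("duplicate genome ids in presence/absence matrix")
    missing = [g for g in required_genes if g not in matrix.columns]
    if missing:
        raise MicrobiomeError(f"matrix missing gene columns {missing}")
    if mode not in ("any", "all"):
        raise MicrobiomeError(f"mode {mode!r} not in {{'any', 'all'}}")
    sub = matrix[list(required_genes)].astype(bool)
    mask = sub.any(axis=1) if mode == "any" else sub.all(axis=1)
    ids = list(matrix.index[mask])
    n = len(matrix)
    return {
        "positive_ids": ids,
        "count": len(ids),
        "percentage": 100.0 * len(ids) / n if n else float("nan"),
        "n_rows": n,
    }


def per_donor_pdu_species(
    positive_ids: list[str], detection: pd.DataFrame
) -> dict:
    """Per-donor counts of detected pdu-positive species.

    ``detection`` is a long table with columns ``donor, taxon, detected``
    (boolean: above the assay LOD in at least one of the donor's samples).
    Donors without rows are excluded.  Returns per-donor counts plus the
    cohort minimum and median.
    """
    if detection.empty:
        raise MicrobiomeError("empty detection table")
    missing = {"donor", "taxon", "detected"} - set(detection.columns)
    if missing:
        raise MicrobiomeError(f"detection table missing columns {sorted(missing)}")
    unknown = set(detection["taxon"]) - set(positive_ids)
    det = detection.loc[detection["taxon"].isin(positive_ids)]
    counts = (
        det.loc[det["detected"].astype(bool)]
        .groupby("donor")["taxon"]
        .nunique()
        .reindex(pd.unique(det["donor"]), fill_value=0)
        .astype(int)
    )
    return {
        "per_donor": counts.to_dict(),
        "minimum": int(counts.min()),
        "median": float(counts.median()),
        "n_donors": int(counts.size),
        "ignored_taxa": sorted(unknown),
    }


def taxon_share(
    abundances: pd.DataFrame,
    value_column: str = "copies_per_g",
    lod_column: str = "lod",
    taxon_column: str = "taxon",
    sample_column: str = "sample",
) -> pd.DataFrame:
    """Per-taxon fraction of the summed absolute signal in each sample.

    Values below the LOD (or NaN) are substituted with LOD/2 before
    normalizing; a sample with every taxon below LOD gets NaN shares and
    an ``undefined`` flag.  Shares within a sample sum to 1.
    """
    d = abundances.copy()
    below = d[value_column].isna() | (d[value_column] < d[lod_column])
    d["_value"] = np.where(below, d[lod_column] / 2.0, d[value_column])
    d["_below_lod"] = below
    out = []
    for sample, chunk in d.groupby(sample_column):
        all_below = chunk["_below_lod"].all()
        total = chunk["_value"].sum()
        for _, r in chunk.iterrows():
            out.append(
                {
                    "sample": sample,
                    "taxon": r[taxon_column],
                    "share": np.nan if all_below else r["_value"] / total,
                    "below_lod": bool(r["_below_lod"]),
                    "undefined": bool(all_below),
                }
            )
    return pd.DataFrame(out)


def prevalence(
    table: pd.DataFrame, threshold: float = 0.0
) -> pd.DataFrame:
    """Per-taxon occurrence percentage and median abundance.

    ``table`` is samples x taxa.  Occurrence counts samples with value
    strictly above ``threshold``; the median is over all samples, zeros
    included.
    """
    if table.empty:
        raise MicrobiomeError("empty abundance table")
    if threshold < 0:
        raise MicrobiomeError(f"negative threshold {threshold}")
    occ = 100.0 * (table > threshold).sum(axis=0) / len(table)
    med = table.median(axis=0)
    return pd.DataFrame(
        {"occurrence_pct": occ, "median_abundance": med}
    ).rename_axis("taxon")


def scfa_proportions(profile: pd.DataFrame) -> pd.DataFrame:
    """SCFA percentages of the acetate+propionate+butyrate sum per sample.

    ``profile`` needs ``sample, acetate, propionate, butyrate`` columns (mM
    or umol/g, any consistent unit).  Adds ``pct_acetate``, ``pct_propionate``,
    ``pct_butyrate`` (NaN for an all-zero sample) and the
    ``butyrate_propionate_ratio`` (NaN when propionate is zero).
    """
    required = {"sample", "acetate", "propionate", "butyrate"}
    missing = required - set(profile.columns)
    if missing:
        raise MicrobiomeError(f"SCFA table missing columns {sorted(missing)}")
    if (profile[["acetate", "propionate", "butyrate"]] < 0).any().any():
        raise MicrobiomeError("negative SCFA value")
    out = profile.copy()
    total = out[["acetate", "propionate", "butyrate"]].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        for a in ("acetate", "propionate", "butyrate"):
            out[f"pct_{a}"] = np.where(total > 0, 100.0 * out[a] / total, np.nan)
        out["butyrate_propionate_ratio"] = np.where(
            out["propionate"] > 0, out["butyrate"] / out["propionate"], np.nan
        )
    out["undefined"] = total == 0
    return out


def log10_abundance(values: pd.Series, lod: float | pd.Series) -> pd.Series:
    """log10 of absolute abundances; below-LOD entries become NaN, never log(0)."""
    v = values.astype(float)
    below = v.isna() | (v < lod)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log10(v.where(~below))
    return out
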