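"""Summarize pdu functional potential and fecal fermentation tables.

pdu-positive genomes, per-donor detected pdu species, dominant-taxon pduC
share, fecal glycerol range and SCFA proportions.  Writes
results/scfa_proportions.csv and results/pduC_shares.csv.
"""

from pathlib import Path

import pandas as pd

from glycacro.microbiome import (
    pdu_positive,
    per_donor_pdu_species,
    scfa_proportions,
    taxon_share,
)

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"


def main() -> None:
    genes = pd.read_csv(COHORT / "pdu_genes.csv", index_col=0)
    pos = pdu_positive(genes)
    print(
        f"{pos['count']} of {pos['n_rows']} genomes carry a pduCDE subunit "
        f"({pos['percentage']:.1f}%)"
    )

    qpcr = pd.read_csv(COHORT / "qpcr.csv")
    detect = qpcr.assign(
        donor=qpcr["sample"],
        detected=qpcr["copies_per_g"].notna()
        & (qpcr["copies_per_g"] >= qpcr["lod"]),
    )[["donor", "taxon", "detected"]]
    counts = per_donor_pdu_species(pos["positive_ids"], detect)
    print(
        f"detected pdu species per donor: min {counts['minimum']}, "
        f"median {counts['median']:.0f} ({counts['n_donors']} donors)"
    )

    shares = taxon_share(qpcr)
    shares.to_csv(ROOT / "results" / "pduC_shares.csv", index=False)
    dominant = (
        shares.groupby("taxon")["share"].median().sort_values(ascending=False)
    )
    top = dominant.index[0]
    print(f"dominant pduC contributor: {top} (median share {dominant.iloc[0]:.0%})")

    gly = pd.read_csv(COHORT / "fecal_glycerol.csv")
    print(
        f"fecal glycerol: {gly['glycerol_umol_g'].min():.1f}-"
        f"{gly['glycerol_umol_g'].max():.1f} umol/g over {len(gly)} samples"
    )

    scfa = scfa_proportions(pd.read_csv(COHORT / "scfa.csv"))
    scfa.to_csv(ROOT / "results" / "scfa_proportions.csv", index=False)
    print(
        f"SCFA medians: acetate {scfa['pct_acetate'].median():.1f}%, "
        f"propionate {scfa['pct_propionate'].median():.1f}%, "
        f"butyrate {scfa['pct_butyrate'].median():.1f}%; "
        f"butyrate:propionate {scfa['butyrate_propionate_ratio'].median():.2f}"
    )


if __name__ == "__main__":
    main()
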