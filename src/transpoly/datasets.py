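"""Packaged reference tables from the archaic/modern shared-polymorphism study.

Three small TSVs ship with the package:

* ``behs_trans_snps`` — the 51 trans-SNPs found in the behaviour-related
  (BEHS) gene set with their population-genetic annotations (average
  heterozygosity, Fst, Tajima's D, phenotype associations, Denisovan
  heterozygosity); the input of the balancing-selection flagging stage.
* ``schizophrenia_trans_snps`` — the 65 trans-SNPs inside loci associated
  with schizophrenia, with ancestral/derived alleles and a marker for the
  six that fall in the immune-system (IMMS) gene set.
* ``null_percentiles`` — the published percentile report of the matched
  permutation null (mean polymorphisms per gene over 10,000 replicates,
  three statistics per gene set); shipped to document the expected report
  shape, not as a numerical oracle.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("transpoly.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False, na_values=["NA"])


def load_behs_trans_snps() -> pd.DataFrame:
    """BEHS trans-SNP table (51 rows) with flagging annotations.

    ``func_class`` is normalised to synonymous/nonsynonymous and
    ``denisova_het`` to a boolean; "NA" heterozygosity/Fst entries become
    NaN and are treated as absent downstream.
    """
    df = _read("behs_trans_snps.tsv")
    df["func_class"] = (
        df["func_class"]
        .str.lower()
        .map({"missense": "nonsynonymous", "synonymous": "synonymous"})
        .fillna("other")
    )
    df["denisova_het"] = df["denisova_het"].str.upper().eq("YES")
    return df


def load_schizophrenia_trans_snps() -> pd.DataFrame:
    """Trans-SNPs within schizophrenia-associated loci (65 rows)."""
    df = _read("schizophrenia_trans_snps.tsv")
    df["in_imms"] = df["in_imms"].str.upper().eq("YES")
    df["chrom"] = df["chrom"].astype(str)
    return df


def load_null_percentiles() -> pd.DataFrame:
    """Published percentile report of the matched permutation null."""
    return _read("null_percentiles.tsv")


def behs_annotations() -> dict:
    """The BEHS table as SNPAnnotation records keyed by rs id."""
    from .io import SNPAnnotation

    out = {}
    for row in load_behs_trans_snps().itertuples(index=False):
        out[row.id] = SNPAnnotation(
            id=row.id,
            avg_het=None if pd.isna(row.avg_het) else float(row.avg_het),
            het_se=None if pd.isna(row.het_se) else float(row.het_se),
            fst=None if pd.isna(row.fst) else float(row.fst),
            tajimas_d=None if pd.isna(row.tajimas_d) else float(row.tajimas_d),
            func_class=row.func_class,
            phenotype_note="" if pd.isna(row.phenotype_note) else str(row.phenotype_note),
            gene=row.gene,
            denisova_het=bool(row.denisova_het),
        )
    return out
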