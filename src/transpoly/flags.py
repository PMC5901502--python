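"""Balancing-selection flagging of individual trans-SNPs.

A SNP is flagged when it combines low population differentiation with an
intermediate allele frequency: clamped Fst <= 0.04 (threshold inclusive)
and average heterozygosity > 0.400 (strict). Negative Fst estimates, an
artifact of the estimator, are interpreted as 0 before thresholding.
Tajima's D is carried through the report as supporting context but plays
no role in the flag. SNPs lacking either statistic are unflaggable and
reported separately — absence of evidence never flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .io import SNPAnnotation

FST_MAX_DEFAULT = 0.04
HET_MIN_DEFAULT = 0.400


@dataclass(frozen=True)
class FlaggedSNP:
    """Per-SNP flag decision with the independent reason codes."""

    id: str
    gene: Optional[str]
    avg_het: Optional[float]
    het_se: Optional[float]
    func_class: str
    fst_raw: Optional[float]
    fst_clamped: Optional[float]
    tajimas_d: Optional[float]
    phenotype_note: str
    denisova_het: Optional[bool]
    flagged: bool
    reasons: tuple  # subset of ("low_fst", "high_het")
    unflaggable: bool


def clamp_fst(fst: Optional[float]) -> Optional[float]:
    """Clamp an Fst estimate into [0, 1]: negative values are read as 0.

    Absent values stay absent.
    """
    if fst is None or (isinstance(fst, float) and math.isnan(fst)):
        return None
    return max(0.0, float(fst))


def _effective_fst(ann: SNPAnnotation) -> Optional[float]:
    """Single Fst per SNP: the maximum when two comparisons are supplied.

    Using the larger of e.g. YRI-CEU and YRI-ASN is conservative for
    claiming low differentiation.
    """
    vals = [v for v in (ann.fst, ann.fst2) if v is not None and not math.isnan(v)]
    if not vals:
        return None
    return max(vals)


def flag_annotation(
    ann: SNPAnnotation,
    fst_max: float = FST_MAX_DEFAULT,
    het_min: float = HET_MIN_DEFAULT,
) -> FlaggedSNP:
    fst_raw = _effective_fst(ann)
    fst_c = clamp_fst(fst_raw)
    het = ann.avg_het
    low_fst = fst_c is not None and fst_c <= fst_max
    high_het = het is not None and het > het_min
    unflaggable = fst_c is None or het is None
    reasons = tuple(
        r for r, hit in (("low_fst", low_fst), ("high_het", high_het)) if hit
    )
    return FlaggedSNP(
        id=ann.id,
        gene=ann.gene,
        avg_het=het,
        het_se=ann.het_se,
        func_class=ann.func_class,
        fst_raw=fst_raw,
        fst_clamped=fst_c,
        tajimas_d=ann.tajimas_d,
        phenotype_note=ann.phenotype_note,
        denisova_het=ann.denisova_het,
        flagged=low_fst and high_het,
        reasons=reasons,
        unflaggable=unflaggable,
    )


def flag_balancing(
    snps: Iterable,
    annotations: Mapping,
    fst_max: float = FST_MAX_DEFAULT,
    het_min: float = HET_MIN_DEFAULT,
) -> list:
    """Flag trans-SNPs using their annotations, joined by rs id.

    ``snps`` may be TransSNP objects or bare rs-id strings; SNPs without an
    annotation record are emitted as unflaggable.
    """
    out = []
    for snp in snps:
        rs = snp if isinstance(snp, str) else snp.site.id
        ann = annotations.get(rs)
        if ann is None:
            gene = None if isinstance(snp, str) else ";".join(snp.genes)
            ann = SNPAnnotation(id=rs, gene=gene)
        elif ann.gene is None and not isinstance(snp, str):
            ann = SNPAnnotation(**{**ann.__dict__, "gene": ";".join(snp.genes)})
        out.append(flag_annotation(ann, fst_max=fst_max, het_min=het_min))
    return out


def flags_table(flags: Iterable[FlaggedSNP]) -> pd.DataFrame:
    """Report table mirroring the flagged-SNP layout of the study tables."""
    rows = []
    for f in flags:
        rows.append(
            {
                "gene": f.gene,
                "id": f.id,
                "avg_het": f.avg_het,
                "het_se": f.het_se,
                "func_class": f.func_class,
                "fst": f.fst_raw,
                "fst_clamped": f.fst_clamped,
                "tajimas_d": f.tajimas_d,
                "phenotype_note": f.phenotype_note,
                "denisova_het": f.denisova_het,
                "flagged": f.flagged,
                "reasons": ";".join(f.reasons),
                "unflaggable": f.unflaggable,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "id", "avg_het", "het_se", "func_class", "fst",
            "fst_clamped", "tajimas_d", "phenotype_note", "denisova_het",
            "flagged", "reasons", "unflaggable",
        ],
    )
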