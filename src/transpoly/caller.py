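"""Trans-SNP calling: archaic heterozygous coding sites shared with a
modern population.

A trans-SNP is operationalised as a site that is (a) heterozygous in at
least one archaic individual, (b) inside the coding-exon union of at least
one gene (which implements the UTR/intergenic exclusion), and (c)
segregating in the modern population sample (0 < alt_count < total_called).
CpG-context sites can optionally be excluded, since deamination of
methylated cytosine makes them hypermutable and inflates identity-by-state
sharing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import ArchaicGenotypes, GeneModel, PopulationCounts, VariantSite, fetch_base

HET_CALL = (0, 1)


@dataclass(frozen=True)
class TransSNP:
    """A shared polymorphism with its context annotations."""

    site: VariantSite
    is_cpg: bool
    func_class: str
    genes: tuple  # gene symbols whose coding exons contain the site
    archaic_het_individuals: int

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"{self.site.key}: trans-SNP must lie in >=1 gene")
        if self.archaic_het_individuals < 1:
            raise ValueError(f"{self.site.key}: needs >=1 archaic heterozygote")


def extract_het_sites(genotypes: ArchaicGenotypes) -> list:
    """Return (site, het_count) for sites heterozygous in >=1 individual.

    Heterozygosity in any one of the archaic individuals suffices: the
    exomes are pooled and individual-level heterozygosity is read as
    evidence of population-level polymorphism. Homozygous-only and
    all-missing sites are excluded.
    """
    out = []
    for site, calls in genotypes.calls.items():
        het = sum(1 for c in calls if c == HET_CALL)
        if het >= 1:
            out.append((site, het))
    out.sort(key=lambda t: (int(t[0].chrom), t[0].pos, t[0].ref, t[0].alt))
    return out


def is_cpg_site(context: str) -> bool:
    """Decide CpG context from a reference trinucleotide (prev, focal, next).

    True iff the focal base is C followed by G, or G preceded by C. A
    non-ACGT focal base is undetermined and treated as non-CpG; absent
    neighbours (sequence ends) are encoded as any non-matching character
    (e.g. 'N').
    """
    if len(context) != 3:
        raise ValueError(f"context must be 3 bases, got {context!r}")
    prev, focal, nxt = context.upper()
    if focal == "C":
        return nxt == "G"
    if focal == "G":
        return prev == "C"
    return False


def cpg_status(sites: Iterable[VariantSite], reference) -> dict:
    """Map each site to its CpG-context flag using the reference sequence."""
    out = {}
    for site in sites:
        pos0 = site.pos - 1
        prev = fetch_base(reference, site.chrom, pos0 - 1) or "N"
        focal = fetch_base(reference, site.chrom, pos0) or "N"
        nxt = fetch_base(reference, site.chrom, pos0 + 1) or "N"
        out[site] = is_cpg_site(prev + focal + nxt)
    return out


def assign_genes(sites: Iterable[VariantSite], models: Iterable[GeneModel]) -> dict:
    """Map each site to every gene whose coding-exon union contains it.

    Positions are converted from 1-based to 0-based before the half-open
    interval test. Sites inside no coding exon are absent from the result,
    which is what excludes UTR and intergenic variants.
    """
    trees: dict = {}
    for model in models:
        tree = trees.setdefault(model.chrom, IntervalTree())
        for s, e in model.coding_exons:
            tree.addi(s, e, model.name)
    out = {}
    for site in sites:
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        hits = sorted({iv.data for iv in tree.at(site.pos - 1)})
        if hits:
            out[site] = hits
    return out


def call_trans_snps(
    het_sites: Iterable,
    pop: PopulationCounts,
    gene_map: Mapping,
    annotations: Optional[Mapping] = None,
    exclude_cpg: bool = False,
    cpg: Optional[Mapping] = None,
) -> list:
    """Call trans-SNPs from archaic het sites against population counts.

    A het site becomes a trans-SNP iff it is present in ``pop`` with
    0 < alt_count < total_called and is assigned to at least one gene.
    With ``exclude_cpg``, CpG-context sites (per ``cpg``) are removed.
    Functional class is joined from ``annotations`` by rs id, defaulting
    to "other".
    """
    annotations = annotations or {}
    cpg = cpg or {}
    out = []
    for site, het_count in het_sites:
        genes = gene_map.get(site)
        if not genes:
            continue
        counts = pop.counts.get(site)
        if counts is None:
            continue
        alt_count, total = counts
        if not 0 < alt_count < total:
            continue
        site_cpg = bool(cpg.get(site, False))
        if exclude_cpg and site_cpg:
            continue
        ann = annotations.get(site.id)
        func = ann.func_class if ann is not None else "other"
        out.append(
            TransSNP(
                site=site,
                is_cpg=site_cpg,
                func_class=func,
                genes=tuple(genes),
                archaic_het_individuals=het_count,
            )
        )
    return out


def per_gene_tallies(het_sites, gene_map, trans_snps) -> pd.DataFrame:
    """Per-gene counts of the three set statistics.

    ``all_polymorphisms`` counts archaic het sites per gene (shared with
    the modern population or not); ``trans_snps`` and ``trans_snps_nonsyn``
    count shared sites. A SNP inside overlapping genes counts once per
    gene here; genome-wide totals must deduplicate by site instead.
    """
    genes = sorted({g for gl in gene_map.values() for g in gl})
    idx = {g: i for i, g in enumerate(genes)}
    tally = np.zeros((len(genes), 3), dtype=int)
    for site, _ in het_sites:
        for g in gene_map.get(site, ()):
            tally[idx[g], 0] += 1
    for snp in trans_snps:
        for g in snp.genes:
            tally[idx[g], 1] += 1
            if snp.func_class == "nonsynonymous":
                tally[idx[g], 2] += 1
    return pd.DataFrame(
        tally,
        index=pd.Index(genes, name="gene"),
        columns=["all_polymorphisms", "trans_snps", "trans_snps_nonsyn"],
    )
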