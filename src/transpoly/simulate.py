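"""Synthetic inputs for the whole pipeline, with plantable enrichment.

The generator emits exactly the formats the readers consume — a reference
FASTA, a refGene-like gene-model table, an archaic multi-sample VCF,
modern-population allele counts, a per-SNP annotation TSV, per-gene
covariates and gene-set lists — plus a truth table of every site's latent
labels, so each stage of the pipeline can be tested end to end without any
external download.

Statistical structure. Polymorphic sites are placed in coding exons at a
per-bp rate, elevated by a configurable multiplier at CpG-context
positions (emulating deamination hypermutability). Each polymorphic site
is heterozygous in the archaic sample with a fixed probability; an
archaic-het site is also segregating in the modern sample with probability
min(1, f*s), where s is the baseline sharing probability and f the
enrichment factor of the gene's designated set (f=1 outside enriched
sets). Modern allele frequencies conditional on segregating are drawn from
a Beta(0.5, 0.5) truncated away from the boundaries, giving the U-shaped
folded spectrum typical of a large population sample; the annotation table
derives average heterozygosity 2p(1-p) from the realised sample frequency
and Fst from two simulated subpopulation samples via Hudson's estimator
(negative draws possible, deliberately exercising the downstream clamp).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigError
from .features import gene_features_table
from .io import (
    ArchaicGenotypes,
    DropCounts,
    GeneModel,
    PopulationCounts,
    SNPAnnotation,
    VariantSite,
)

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class GeneSetSpec:
    """A designated gene set: how many genes and its sharing enrichment f."""

    name: str
    size: int
    factor: float = 1.0

    def __post_init__(self):
        if self.size < 1:
            raise ConfigError(f"gene set {self.name}: size must be >= 1")
        if self.factor < 0:
            raise ConfigError(f"gene set {self.name}: factor must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults define the standard conditions.

    The default scale (2,000 genes, ~1 kb coding sequence each, per-bp
    polymorphism rate 0.01, giving ~20,000 polymorphic sites) runs the
    full pipeline in well under two minutes on one CPU.
    """

    n_genes: int = 2000
    n_archaic: int = 3
    exon_count_mean: float = 1.5  # exons per gene = 1 + Poisson(mean)
    exon_len_mean: float = 400.0
    exon_len_sd: float = 120.0
    exon_len_min: int = 50
    intron_len: int = 60
    spacer_len: int = 100
    gc_mean: float = 0.45
    gc_sd: float = 0.04
    b_alpha: float = 7.5  # Beta shape of the background-selection statistic
    b_beta: float = 2.5
    poly_rate: float = 0.01  # polymorphic sites per coding bp, non-CpG
    cpg_multiplier: float = 2.0
    archaic_het_prob: float = 0.5
    share_prob: float = 0.2  # s: archaic-het site also segregates in moderns
    modern_only_rate: float = 0.3  # archaic-non-het site segregates in moderns
    archaic_homalt_prob: float = 0.3
    frac_nonsyn: float = 0.5
    pop_total_called: int = 216  # 108 diploid individuals
    fst_subpop_n: int = 100  # diploids per simulated subpopulation
    fst_noise: float = 0.03
    tajd_sd: float = 0.7
    rs_prob: float = 0.95
    gene_sets: tuple = (GeneSetSpec("TARGET", 100, 1.0),)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2:
            raise ConfigError("n_genes must be >= 2")
        if self.n_archaic < 1:
            raise ConfigError("n_archaic must be >= 1")
        for name, p in (
            ("poly_rate", self.poly_rate),
            ("archaic_het_prob", self.archaic_het_prob),
            ("share_prob", self.share_prob),
            ("modern_only_rate", self.modern_only_rate),
            ("archaic_homalt_prob", self.archaic_homalt_prob),
            ("frac_nonsyn", self.frac_nonsyn),
            ("rs_prob", self.rs_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {p}")
        if not 0.0 < self.gc_mean < 1.0:
            raise ConfigError(f"gc_mean must be in (0, 1), got {self.gc_mean}")
        if self.cpg_multiplier < 0:
            raise ConfigError("cpg_multiplier must be >= 0")
        if sum(s.size for s in self.gene_sets) > self.n_genes:
            raise ConfigError("gene sets exceed the number of genes")
        names = [s.name for s in self.gene_sets]
        if len(names) != len(set(names)):
            raise ConfigError("gene set names must be unique")


@dataclass
class SimulatedGenome:
    reference: dict  # chrom -> sequence string
    models: list  # GeneModel
    features: pd.DataFrame  # gene -> exonic_length, gc_percent, b_stat


@dataclass
class SimulatedVariants:
    archaic: ArchaicGenotypes
    population: PopulationCounts
    annotations: dict  # rs id -> SNPAnnotation
    truth: pd.DataFrame
    gene_sets: dict  # set name -> list of genes


@dataclass
class SimBundle:
    config: SimConfig
    genome: SimulatedGenome
    variants: SimulatedVariants


def _gene_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def simulate_reference_and_genes(config: SimConfig, rng=None) -> SimulatedGenome:
    """Reference sequence plus non-overlapping gene models and covariates.

    Genes are laid out left to right on one contig, whole exons coding
    (CDS spans the exon range), separated by fixed-length introns and
    intergenic spacers. Per-gene GC is tuned base-by-base to the target
    drawn for that gene, so GC recomputed from the FASTA agrees with the
    features table.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_genes
    n_exons = 1 + rng.poisson(config.exon_count_mean, size=n)
    gc_targets = np.clip(rng.normal(config.gc_mean, config.gc_sd, size=n), 0.2, 0.8)
    b_stats = rng.beta(config.b_alpha, config.b_beta, size=n)

    chunks = []
    models = []
    cursor = 0

    def _emit(arr):
        nonlocal cursor
        chunks.append(arr)
        cursor += len(arr)

    spacer_gc = 0.4
    for i in range(n):
        _emit(_gene_sequence(rng, config.spacer_len, spacer_gc))
        exons = []
        for j in range(n_exons[i]):
            if j > 0:
                _emit(_gene_sequence(rng, config.intron_len, spacer_gc))
            ln = max(
                config.exon_len_min,
                int(round(rng.normal(config.exon_len_mean, config.exon_len_sd))),
            )
            start = cursor
            _emit(_gene_sequence(rng, ln, gc_targets[i]))
            exons.append((start, cursor))
        models.append(
            GeneModel(
                name=f"G{i:05d}",
                chrom="1",
                strand="+" if rng.random() < 0.5 else "-",
                coding_exons=exons,
            )
        )
    _emit(_gene_sequence(rng, config.spacer_len, spacer_gc))

    seq = "".join(_BASES[np.concatenate(chunks)])
    reference = {"1": seq}
    b_table = {m.name: b for m, b in zip(models, b_stats)}
    features = gene_features_table(models, reference, b_table)
    return SimulatedGenome(reference=reference, models=models, features=features)


def _cpg_mask(seq_arr: np.ndarray) -> np.ndarray:
    is_c = seq_arr == "C"
    is_g = seq_arr == "G"
    nxt_g = np.zeros_like(is_c)
    nxt_g[:-1] = is_g[1:]
    prev_c = np.zeros_like(is_c)
    prev_c[1:] = is_c[:-1]
    return (is_c & nxt_g) | (is_g & prev_c)


def _hudson_fst(rng, p: float, n_dip: int, noise: float) -> Optional[float]:
    """Hudson's two-population Fst from simulated subpopulation samples."""
    p1 = float(np.clip(p + rng.normal(0.0, noise), 0.0, 1.0))
    p2 = float(np.clip(p + rng.normal(0.0, noise), 0.0, 1.0))
    n1 = n2 = 2 * n_dip
    p1h = rng.binomial(n1, p1) / n1
    p2h = rng.binomial(n2, p2) / n2
    den = p1h * (1 - p2h) + p2h * (1 - p1h)
    if den <= 0:
        return None
    num = (
        (p1h - p2h) ** 2
        - p1h * (1 - p1h) / (n1 - 1)
        - p2h * (1 - p2h) / (n2 - 1)
    )
    return num / den


def simulate_variants(
    config: SimConfig, genome: SimulatedGenome, rng=None
) -> SimulatedVariants:
    """Place polymorphic sites and generate all per-site observations."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    seq_arr = np.array(list(genome.reference["1"]))
    cpg = _cpg_mask(seq_arr)

    gene_names = [m.name for m in genome.models]
    set_of_gene: dict = {}
    factor_of_set = {s.name: s.factor for s in config.gene_sets}
    gene_sets: dict = {}
    remaining = list(gene_names)
    for spec in config.gene_sets:
        idx = rng.choice(len(remaining), size=spec.size, replace=False)
        chosen = [remaining[i] for i in sorted(idx)]
        gene_sets[spec.name] = chosen
        for g in chosen:
            set_of_gene[g] = spec.name
        remaining = [g for g in remaining if g not in set(chosen)]

    individuals = [f"Archaic{i + 1}" for i in range(config.n_archaic)]
    arch_calls: dict = {}
    pop_counts: dict = {}
    annotations: dict = {}
    truth_rows = []
    rs_counter = 1000
    two_n_pop = config.pop_total_called

    for model in genome.models:
        positions = np.concatenate(
            [np.arange(s, e) for s, e in model.coding_exons]
        )
        site_cpg = cpg[positions]
        rate = np.where(
            site_cpg,
            min(1.0, config.poly_rate * config.cpg_multiplier),
            config.poly_rate,
        )
        hit = rng.random(positions.size) < rate
        sel_pos = positions[hit]
        sel_cpg = site_cpg[hit]
        set_name = set_of_gene.get(model.name, "")
        f = factor_of_set.get(set_name, 1.0)
        share_p = min(1.0, f * config.share_prob)
        for pos0, is_cpg_site in zip(sel_pos, sel_cpg):
            ref = seq_arr[pos0]
            if is_cpg_site and ref == "C":
                alt = "T"
            elif is_cpg_site and ref == "G":
                alt = "A"
            else:
                others = [b for b in "ACGT" if b != ref]
                alt = others[rng.integers(3)]
            if rng.random() < config.rs_prob:
                rs = f"rs{rs_counter}"
                rs_counter += 1
            else:
                rs = "novel"
            site = VariantSite("1", int(pos0) + 1, str(ref), alt, rs)

            archaic_het = bool(rng.random() < config.archaic_het_prob)
            if archaic_het:
                n_het = 1 + int(rng.binomial(config.n_archaic - 1, 0.4))
                het_idx = set(
                    rng.choice(config.n_archaic, size=n_het, replace=False).tolist()
                )
                calls = tuple(
                    (0, 1) if i in het_idx else ((0, 0) if rng.random() < 0.85 else (1, 1))
                    for i in range(config.n_archaic)
                )
                arch_calls[site] = calls
                seg_p = share_p
            else:
                if rng.random() < config.archaic_homalt_prob:
                    arch_calls[site] = tuple((1, 1) for _ in range(config.n_archaic))
                seg_p = config.modern_only_rate

            modern_seg = bool(rng.random() < seg_p)
            if modern_seg:
                p = float(np.clip(rng.beta(0.5, 0.5), 0.02, 0.98))
                alt_count = 0
                while not 0 < alt_count < two_n_pop:
                    alt_count = int(rng.binomial(two_n_pop, p))
                pop_counts[site] = (alt_count, two_n_pop)
                p_hat = alt_count / two_n_pop
                if rs != "novel":
                    fst = _hudson_fst(rng, p_hat, config.fst_subpop_n, config.fst_noise)
                    annotations[rs] = SNPAnnotation(
                        id=rs,
                        avg_het=2.0 * p_hat * (1.0 - p_hat),
                        het_se=0.01,
                        fst=fst,
                        tajimas_d=float(rng.normal(0.0, config.tajd_sd)),
                        func_class=(
                            "nonsynonymous"
                            if rng.random() < config.frac_nonsyn
                            else "synonymous"
                        ),
                        gene=model.name,
                    )
            truth_rows.append(
                {
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "id": rs,
                    "gene": model.name,
                    "is_cpg": bool(is_cpg_site),
                    "archaic_het": archaic_het,
                    "modern_segregating": modern_seg,
                    "set": set_name,
                    "share_prob": share_p if archaic_het else config.modern_only_rate,
                }
            )

    drops = DropCounts(loaded=len(arch_calls))
    archaic = ArchaicGenotypes(individuals, arch_calls, drops)
    population = PopulationCounts(
        pop_counts, DropCounts(loaded=len(pop_counts))
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom", "pos", "id", "gene", "is_cpg", "archaic_het",
            "modern_segregating", "set", "share_prob",
        ],
    )
    return SimulatedVariants(
        archaic=archaic,
        population=population,
        annotations=annotations,
        truth=truth,
        gene_sets=gene_sets,
    )


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Genome plus variants, fully determined by ``config.seed``."""
    genome = simulate_reference_and_genes(config)
    variants = simulate_variants(config, genome)
    return SimBundle(config=config, genome=genome, variants=variants)


# ---------------------------------------------------------------------------
# writers: emit exactly the formats the io module reads


def write_fasta(reference: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gene_models(models, path) -> None:
    rows = []
    for m in models:
        starts = ",".join(str(s) for s, _ in m.coding_exons) + ","
        ends = ",".join(str(e) for _, e in m.coding_exons) + ","
        cds_start = m.coding_exons[0][0] if m.coding_exons else 0
        cds_end = m.coding_exons[-1][1] if m.coding_exons else 0
        rows.append(
            {
                "name": m.name,
                "chrom": m.chrom,
                "strand": m.strand,
                "exonStarts": starts,
                "exonEnds": ends,
                "cdsStart": cds_start,
                "cdsEnd": cds_end,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_archaic_vcf(archaic: ArchaicGenotypes, reference: dict, path) -> None:
    sites = sorted(archaic.calls, key=lambda s: (int(s.chrom), s.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=transpoly-simulate\n")
        for chrom, seq in reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(archaic.individuals)
            + "\n"
        )
        for site in sites:
            gts = []
            for call in archaic.calls[site]:
                gts.append("./." if call is None else f"{call[0]}/{call[1]}")
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.id}\t{site.ref}\t{site.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_population_counts(pop: PopulationCounts, path) -> None:
    rows = [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "id": s.id,
            "ref": s.ref,
            "alt": s.alt,
            "alt_count": ac,
            "total_called": tot,
        }
        for s, (ac, tot) in sorted(
            pop.counts.items(), key=lambda kv: (int(kv[0].chrom), kv[0].pos)
        )
    ]
    pd.DataFrame(
        rows, columns=["chrom", "pos", "id", "ref", "alt", "alt_count", "total_called"]
    ).to_csv(path, sep="\t", index=False)


def write_annotations(annotations: dict, path) -> None:
    rows = []
    for rs in sorted(annotations):
        a = annotations[rs]
        rows.append(
            {
                "id": a.id,
                "gene": a.gene,
                "avg_het": a.avg_het,
                "het_se": a.het_se,
                "fst": a.fst,
                "tajimas_d": a.tajimas_d,
                "func_class": a.func_class,
                "phenotype_note": a.phenotype_note,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "id", "gene", "avg_het", "het_se", "fst", "tajimas_d",
            "func_class", "phenotype_note",
        ],
    ).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_bundle(bundle: SimBundle, out_dir) -> dict:
    """Write the full input bundle; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fa",
        "gene_models": out / "gene_models.tsv",
        "features": out / "features.tsv",
        "archaic_vcf": out / "archaic.vcf",
        "population": out / "population_counts.tsv",
        "annotations": out / "annotations.tsv",
        "truth": out / "truth.tsv",
        "config": out / "sim_config.json",
    }
    write_fasta(bundle.genome.reference, paths["reference"])
    write_gene_models(bundle.genome.models, paths["gene_models"])
    bundle.genome.features.reset_index().to_csv(
        paths["features"], sep="\t", index=False, na_rep="NA"
    )
    write_archaic_vcf(bundle.variants.archaic, bundle.genome.reference, paths["archaic_vcf"])
    write_population_counts(bundle.variants.population, paths["population"])
    write_annotations(bundle.variants.annotations, paths["annotations"])
    bundle.variants.truth.to_csv(paths["truth"], sep="\t", index=False)
    for name, genes in bundle.variants.gene_sets.items():
        p = out / f"geneset_{name}.txt"
        with open(p, "w") as fh:
            fh.write(f"# gene set {name}\n")
            for g in genes:
                fh.write(g + "\n")
        paths[f"geneset_{name}"] = p
    cfg = dataclasses.asdict(bundle.config)
    cfg["gene_sets"] = [dataclasses.asdict(s) for s in bundle.config.gene_sets]
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
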