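"""Readers and writers for every external format the pipeline touches.

Coordinate conventions: VCF positions are 1-based and kept 1-based on the
``VariantSite`` type; all interval work (gene models, exons) is 0-based
half-open. Conversion happens only at I/O boundaries. Chromosome names are
normalised by stripping a leading ``chr`` so that UCSC-style and
Ensembl-style inputs interoperate; only autosomes 1..22 are retained.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import pysam

from .errors import FeatureError, InputError, ParseError, ValidationError

AUTOSOMES = frozenset(str(i) for i in range(1, 23))
SEX_CHROMS = frozenset({"X", "Y"})
MITO_CHROMS = frozenset({"MT", "M"})
NUCLEOTIDES = frozenset("ACGT")

FuncClass = str  # one of "synonymous", "nonsynonymous", "other"


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix and uppercase sex/MT labels."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return c.upper() if c.upper() in SEX_CHROMS | MITO_CHROMS else c


@dataclass(frozen=True, order=True)
class VariantSite:
    """One autosomal biallelic SNV.

    ``pos`` is 1-based (VCF convention). ``id`` is an rs identifier or
    ``"novel"``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "novel"

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValidationError(
                f"alleles must be single nucleotides, got {self.ref}/{self.alt}"
            )
        if self.chrom not in AUTOSOMES:
            raise ValidationError(f"chromosome {self.chrom!r} is not an autosome")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class DropCounts:
    """Why input records were rejected by the site filter.

    Every dropped record increments exactly one counter, so
    ``loaded + total_dropped`` equals the record count of the input.
    """

    multiallelic: int = 0
    indel: int = 0
    sex_chromosome: int = 0
    mitochondrial: int = 0
    other_contig: int = 0
    non_acgt: int = 0
    no_alt: int = 0
    loaded: int = 0

    @property
    def total_dropped(self) -> int:
        return (
            self.multiallelic
            + self.indel
            + self.sex_chromosome
            + self.mitochondrial
            + self.other_contig
            + self.non_acgt
            + self.no_alt
        )

    @property
    def total(self) -> int:
        return self.loaded + self.total_dropped

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# a diploid call is an unordered pair of allele indices (0=ref, 1=alt),
# stored sorted; None means missing ("./.")
Call = Optional[tuple]


@dataclass
class ArchaicGenotypes:
    """Per-individual diploid calls at site-filtered positions."""

    individuals: list
    calls: dict  # VariantSite -> tuple[Call, ...] aligned with individuals
    drops: DropCounts = field(default_factory=DropCounts)

    def __post_init__(self):
        if len(self.individuals) < 1:
            raise InputError("at least one individual is required")


@dataclass
class PopulationCounts:
    """Modern-population alternate-allele counts per site."""

    counts: dict  # VariantSite -> (alt_count, total_called)
    drops: DropCounts = field(default_factory=DropCounts)


@dataclass
class GeneModel:
    """A gene with its coding-exon intervals (0-based half-open)."""

    name: str
    chrom: str
    strand: str
    coding_exons: list  # list[tuple[int, int]], sorted by start
    is_coding: bool = True

    def __post_init__(self):
        for s, e in self.coding_exons:
            if e <= s:
                raise ValidationError(f"gene {self.name}: empty interval ({s},{e})")
        starts = [s for s, _ in self.coding_exons]
        if starts != sorted(starts):
            raise ValidationError(f"gene {self.name}: exons not sorted")


@dataclass
class SNPAnnotation:
    """Per-SNP population-genetic annotation joined by rs identifier.

    Absent values ("NA" in the source) stay ``None`` and are never coerced
    to 0; clamping of negative Fst happens downstream, not here.
    """

    id: str
    avg_het: Optional[float] = None
    het_se: Optional[float] = None
    fst: Optional[float] = None
    fst2: Optional[float] = None
    tajimas_d: Optional[float] = None
    func_class: FuncClass = "other"
    phenotype_note: str = ""
    gene: Optional[str] = None
    denisova_het: Optional[bool] = None

    def __post_init__(self):
        if self.avg_het is not None and not 0.0 <= self.avg_het <= 0.5:
            raise ValidationError(
                f"{self.id}: avg_het {self.avg_het} outside [0, 0.5]"
            )
        if self.func_class not in ("synonymous", "nonsynonymous", "other"):
            raise ValidationError(f"{self.id}: bad func_class {self.func_class!r}")


def _classify_chrom(raw: str, drops: DropCounts) -> Optional[str]:
    c = normalize_chrom(raw)
    if c in AUTOSOMES:
        return c
    if c in SEX_CHROMS:
        drops.sex_chromosome += 1
    elif c in MITO_CHROMS:
        drops.mitochondrial += 1
    else:
        drops.other_contig += 1
    return None


def read_archaic_vcf(path) -> ArchaicGenotypes:
    """Load archaic genotypes from a VCF, applying the site filter.

    Only autosomal biallelic SNVs are kept; indels, multiallelic records
    and sex-chromosome/MT records are counted in the returned ``drops``.
    Missing genotypes are preserved as ``None``, never imputed.
    """
    drops = DropCounts()
    calls: dict = {}
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise InputError(f"cannot open VCF {path}: {exc}") from exc
    with vcf:
        individuals = list(vcf.header.samples)
        if not individuals:
            raise InputError(f"{path}: VCF has no sample columns")
        record_no = 0
        records = iter(vcf)
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except (ValueError, OSError) as exc:
                raise ParseError(
                    f"{path}: malformed VCF record #{record_no + 1}: {exc}"
                ) from exc
            record_no += 1
            alts = rec.alts
            if alts is None or len(alts) == 0:
                drops.no_alt += 1
                continue
            if len(alts) > 1:
                drops.multiallelic += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1:
                drops.indel += 1
                continue
            if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                drops.non_acgt += 1
                continue
            chrom = _classify_chrom(rec.chrom, drops)
            if chrom is None:
                continue
            site = VariantSite(chrom, rec.pos, ref, alt, rec.id or "novel")
            per_ind = []
            for name in individuals:
                gt = rec.samples[name].get("GT")
                if gt is None or any(a is None for a in gt):
                    per_ind.append(None)
                else:
                    if any(a not in (0, 1) for a in gt):
                        raise ValidationError(
                            f"{path}: call at {site.key} references allele index "
                            f"outside the site's two alleles"
                        )
                    per_ind.append(tuple(sorted(gt)))
            calls[site] = tuple(per_ind)
            drops.loaded += 1
    return ArchaicGenotypes(individuals, calls, drops)


def read_population_counts(path) -> PopulationCounts:
    """Load modern-population allele counts from VCF (AC/AN) or TSV.

    TSV columns: chrom, pos, ref, alt, alt_count, total_called. The reader
    is non-judgmental about monomorphic rows (alt_count 0 or == total):
    filtering to segregating sites is the caller's job.
    """
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".bcf") or path.name.endswith(".vcf.gz"):
        return _read_population_vcf(path)
    return _read_population_tsv(path)


def _read_population_vcf(path) -> PopulationCounts:
    drops = DropCounts()
    counts: dict = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts
            if alts is None or len(alts) == 0:
                drops.no_alt += 1
                continue
            if len(alts) > 1:
                drops.multiallelic += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1:
                drops.indel += 1
                continue
            if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                drops.non_acgt += 1
                continue
            chrom = _classify_chrom(rec.chrom, drops)
            if chrom is None:
                continue
            ac = rec.info.get("AC")
            an = rec.info.get("AN")
            if ac is None or an is None:
                raise InputError(f"{path}: record at {rec.chrom}:{rec.pos} lacks AC/AN")
            alt_count = int(ac[0] if isinstance(ac, (tuple, list)) else ac)
            total = int(an)
            site = VariantSite(chrom, rec.pos, ref, alt, rec.id or "novel")
            if alt_count > total:
                raise ValidationError(f"{path}: alt_count > total_called at {site.key}")
            counts[site] = (alt_count, total)
            drops.loaded += 1
    return PopulationCounts(counts, drops)


def _read_population_tsv(path) -> PopulationCounts:
    drops = DropCounts()
    counts: dict = {}
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "alt_count", "total_called"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    has_id = "id" in df.columns
    for row in df.itertuples(index=False):
        ref, alt = str(row.ref), str(row.alt)
        if len(ref) != 1 or len(alt) != 1:
            drops.indel += 1
            continue
        if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
            drops.non_acgt += 1
            continue
        chrom = _classify_chrom(str(row.chrom), drops)
        if chrom is None:
            continue
        rid = str(row.id) if has_id else "novel"
        site = VariantSite(chrom, int(row.pos), ref, alt, rid)
        alt_count, total = int(row.alt_count), int(row.total_called)
        if total <= 0:
            raise ValidationError(f"{path}: total_called <= 0 at {site.key}")
        if not 0 <= alt_count <= total:
            raise ValidationError(
                f"{path}: alt_count {alt_count} outside [0, {total}] at {site.key}"
            )
        counts[site] = (alt_count, total)
        drops.loaded += 1
    return PopulationCounts(counts, drops)


def _parse_ucsc_list(text: str) -> list:
    return [int(x) for x in str(text).rstrip(",").split(",") if x != ""]


def read_gene_models(path, fmt: Optional[str] = None) -> list:
    """Read gene models from a refGene-like TSV or BED12 file.

    Coding exons are the intersection of each exon with the CDS interval,
    0-based half-open. Genes with a degenerate CDS (start == end) come back
    with zero exons and ``is_coding=False``.
    """
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "refgene" if "exonStarts" in first else "bed12"
    if fmt == "refgene":
        return _read_refgene(path)
    if fmt == "bed12":
        return _read_bed12(path)
    raise InputError(f"unknown gene-model format {fmt!r}")


def _coding_exons(exon_starts, exon_ends, cds_start, cds_end) -> list:
    out = []
    for s, e in zip(exon_starts, exon_ends):
        cs, ce = max(s, cds_start), min(e, cds_end)
        if ce > cs:
            out.append((cs, ce))
    return out


def _read_refgene(path) -> list:
    df = pd.read_csv(path, sep="\t")
    required = {"name", "chrom", "strand", "exonStarts", "exonEnds", "cdsStart", "cdsEnd"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    models = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        starts = _parse_ucsc_list(row.exonStarts)
        ends = _parse_ucsc_list(row.exonEnds)
        if len(starts) != len(ends):
            raise ParseError(
                f"{path}:{i}: exonStarts/exonEnds length mismatch for {row.name}"
            )
        cds_start, cds_end = int(row.cdsStart), int(row.cdsEnd)
        coding = _coding_exons(starts, ends, cds_start, cds_end)
        models.append(
            GeneModel(
                name=str(row.name),
                chrom=normalize_chrom(str(row.chrom)),
                strand=str(row.strand),
                coding_exons=coding,
                is_coding=bool(coding),
            )
        )
    return models


def _read_bed12(path) -> list:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(fields)}")
            chrom_start = int(fields[1])
            name, strand = fields[3], fields[5]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = _parse_ucsc_list(fields[10])
            offsets = _parse_ucsc_list(fields[11])
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(f"{path}:{lineno}: block count mismatch for {name}")
            starts = [chrom_start + o for o in offsets]
            ends = [s + sz for s, sz in zip(starts, sizes)]
            coding = _coding_exons(starts, ends, thick_start, thick_end)
            models.append(
                GeneModel(
                    name=name,
                    chrom=normalize_chrom(fields[0]),
                    strand=strand,
                    coding_exons=coding,
                    is_coding=bool(coding),
                )
            )
    return models


_ANNOTATION_FLOATS = ("avg_het", "het_se", "fst", "fst2", "tajimas_d")


def _norm_func_class(raw) -> FuncClass:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return "other"
    s = str(raw).strip().lower()
    if s in ("synonymous", "syn"):
        return "synonymous"
    if s in ("nonsynonymous", "non-synonymous", "missense", "nonsyn"):
        return "nonsynonymous"
    return "other"


def read_annotations(path) -> dict:
    """Read a per-SNP annotation TSV keyed by rs identifier.

    "NA" stays absent (``None``). Duplicate ids with identical values
    collapse to one record; conflicting duplicates raise, listing the ids.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=["NA", ""]
    )
    if "id" not in df.columns:
        raise InputError(f"{path}: annotation TSV needs an 'id' column")
    out: dict = {}
    conflicts = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        kwargs = {"id": str(d["id"])}
        for col in _ANNOTATION_FLOATS:
            val = d.get(col)
            kwargs[col] = None if val is None or pd.isna(val) else float(val)
        kwargs["func_class"] = _norm_func_class(d.get("func_class"))
        note = d.get("phenotype_note")
        kwargs["phenotype_note"] = "" if note is None or pd.isna(note) else str(note)
        gene = d.get("gene")
        kwargs["gene"] = None if gene is None or pd.isna(gene) else str(gene)
        den = d.get("denisova_het")
        if den is None or pd.isna(den):
            kwargs["denisova_het"] = None
        else:
            kwargs["denisova_het"] = str(den).strip().upper() in ("YES", "TRUE", "1")
        ann = SNPAnnotation(**kwargs)
        prev = out.get(ann.id)
        if prev is not None and prev != ann:
            conflicts.append(ann.id)
        out[ann.id] = ann
    if conflicts:
        raise ValidationError(
            f"{path}: duplicate ids with conflicting values: {sorted(set(conflicts))}"
        )
    return out


def read_b_table(path) -> dict:
    """Read the per-gene background-selection table (columns: gene, b_stat)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["NA", ""])
    cols = set(df.columns)
    bcol = "b_stat" if "b_stat" in cols else ("B" if "B" in cols else None)
    if "gene" not in cols or bcol is None:
        raise InputError(f"{path}: B table needs columns gene and b_stat (or B)")
    out = {}
    for row in df.itertuples(index=False):
        val = getattr(row, bcol)
        out[str(row.gene)] = None if pd.isna(val) else float(val)
    return out


def read_gene_set(path) -> list:
    """Read a gene-set list: one symbol per line, '#' comments allowed."""
    genes = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            name = line.split("#", 1)[0].strip()
            if name and name not in seen:
                genes.append(name)
                seen.add(name)
    return genes


def write_table(df: pd.DataFrame, path) -> None:
    """Write a TSV with header; the single output-table convention."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["NA", ""])


def write_sidecar(path, payload: Mapping) -> None:
    """Write the JSON run-metadata sidecar (seed, thresholds, counts)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def verify_reference(sites: Iterable[VariantSite], reference) -> list:
    """Check each site's ref allele against the reference sequence.

    ``reference`` is a pyfaidx.Fasta or a mapping chrom -> sequence string.
    Returns the list of mismatching sites; callers report, never auto-fix.
    """
    mismatches = []
    for site in sites:
        base = fetch_base(reference, site.chrom, site.pos - 1)
        if base is not None and base.upper() != site.ref:
            mismatches.append(site)
    return mismatches


def _contig_lookup(reference, chrom: str):
    if chrom in reference:
        return reference[chrom]
    pref = f"chr{chrom}"
    if pref in reference:
        return reference[pref]
    return None


def fetch_base(reference, chrom: str, pos0: int) -> Optional[str]:
    """Fetch one base at a 0-based position; None if out of range."""
    contig = _contig_lookup(reference, chrom)
    if contig is None or pos0 < 0 or pos0 >= len(contig):
        return None
    return str(contig[pos0]).upper()


def fetch_sequence(reference, chrom: str, start: int, end: int) -> str:
    """Fetch [start, end) 0-based from a pyfaidx.Fasta or a dict of strings."""
    contig = _contig_lookup(reference, chrom)
    if contig is None:
        raise FeatureError(f"contig {chrom!r} not found in reference")
    if end > len(contig):
        raise IndexError(f"interval [{start},{end}) past end of {chrom} ({len(contig)})")
    return str(contig[start:end]).upper()
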