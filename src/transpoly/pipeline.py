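"""End-to-end orchestration: calling, matching, permutation, flagging.

``run_pipeline`` wires the stages together over file inputs and writes one
TSV per stage, a percentile report per gene set, and a JSON manifest
(seed, thresholds, drop-reason counts partitioning the input records,
results). Any stage failure aborts with a stage-named error and leaves a
FAILED marker next to whatever partial outputs were already written.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import pyfaidx

from . import __version__
from .caller import (
    assign_genes,
    call_trans_snps,
    cpg_status,
    extract_het_sites,
    per_gene_tallies,
)
from .errors import StageError
from .features import (
    MatchThresholds,
    gene_features_table,
    match_controls,
    pool_table,
    read_features_table,
)
from .flags import FST_MAX_DEFAULT, HET_MIN_DEFAULT, flag_balancing, flags_table
from .io import (
    read_annotations,
    read_archaic_vcf,
    read_b_table,
    read_gene_models,
    read_gene_set,
    read_population_counts,
    verify_reference,
    write_sidecar,
    write_table,
)
from .permutation import (
    KINDS,
    count_set_statistic,
    percentile_table,
    permutation_test,
    result_payload,
)


@dataclass
class RunConfig:
    """Inputs, thresholds and knobs for one pipeline run."""

    archaic_vcf: str
    population: str
    gene_models: str
    reference: Optional[str] = None
    b_table: Optional[str] = None
    features: Optional[str] = None  # precomputed covariates, else derived
    annotations: Optional[str] = None
    gene_sets: dict = field(default_factory=dict)  # set name -> path
    out_dir: str = "results"
    thresholds: MatchThresholds = field(default_factory=MatchThresholds)
    fst_max: float = FST_MAX_DEFAULT
    het_min: float = HET_MIN_DEFAULT
    n_perm: int = 10_000
    exclude_cpg: bool = True
    kinds: tuple = KINDS
    seed: int = 0


def _trans_snp_table(trans_snps) -> pd.DataFrame:
    rows = [
        {
            "chrom": t.site.chrom,
            "pos": t.site.pos,
            "id": t.site.id,
            "ref": t.site.ref,
            "alt": t.site.alt,
            "is_cpg": t.is_cpg,
            "func_class": t.func_class,
            "genes": ";".join(t.genes),
            "het_count": t.archaic_het_individuals,
        }
        for t in trans_snps
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "id", "ref", "alt", "is_cpg",
            "func_class", "genes", "het_count",
        ],
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "exclude_cpg": config.exclude_cpg,
        "thresholds": {
            "match_b": config.thresholds.b,
            "match_length_bp": config.thresholds.length_bp,
            "match_gc_points": config.thresholds.gc_points,
            "fst_max": config.fst_max,
            "het_min": config.het_min,
        },
    }
    stage = "read_inputs"
    try:
        archaic = read_archaic_vcf(config.archaic_vcf)
        pop = read_population_counts(config.population)
        models = read_gene_models(config.gene_models)
        annotations = (
            read_annotations(config.annotations) if config.annotations else {}
        )
        reference = pyfaidx.Fasta(config.reference) if config.reference else None
        manifest["drop_counts"] = {
            "archaic": archaic.drops.as_dict(),
            "population": pop.drops.as_dict(),
        }

        stage = "call_trans_snps"
        het_sites = extract_het_sites(archaic)
        if reference is not None:
            mism = verify_reference([s for s, _ in het_sites], reference)
            manifest["reference_mismatches"] = [s.key for s in mism]
        gene_map = assign_genes([s for s, _ in het_sites], models)
        cpg = cpg_status([s for s, _ in het_sites], reference) if reference else {}
        trans = call_trans_snps(
            het_sites, pop, gene_map, annotations,
            exclude_cpg=config.exclude_cpg, cpg=cpg,
        )
        tallies = per_gene_tallies(het_sites, gene_map, trans)
        write_table(_trans_snp_table(trans), out / "trans_snps.tsv")
        write_table(tallies.reset_index(), out / "gene_tallies.tsv")
        manifest["counts"] = {
            "archaic_het_sites": len(het_sites),
            "genic_het_sites": len(gene_map),
            "trans_snps": len(trans),
            "trans_snp_genes": len({g for t in trans for g in t.genes}),
        }

        stage = "gene_features"
        if config.features:
            features = read_features_table(config.features)
        else:
            if reference is None:
                raise StageError(stage, "need either a features table or a reference FASTA")
            b_table = read_b_table(config.b_table) if config.b_table else {}
            features = gene_features_table(models, reference, b_table)
            write_table(features.reset_index(), out / "features.tsv")

        stage = "enrichment"
        manifest["gene_sets"] = {}
        for set_name, path in config.gene_sets.items():
            targets = read_gene_set(path)
            pool = match_controls(
                targets, features, config.thresholds, set_name=set_name
            )
            write_table(pool_table(pool), out / f"pool_{set_name}.tsv")
            set_entry = {
                "n_defined": len(targets),
                "n_retained": len(pool.candidates),
                "excluded_targets": pool.excluded_targets,
                "missing_covariates_in_universe": len(pool.missing_covariates),
                "tests": {},
            }
            nulls = {}
            for kind in config.kinds:
                observed = count_set_statistic(pool.targets, tallies, kind)
                result = permutation_test(
                    tallies, pool, kind,
                    n_perm=config.n_perm, seed=config.seed, observed=observed,
                )
                set_entry["tests"][kind] = result_payload(result)
                nulls[kind] = result.null
            write_table(percentile_table(nulls), out / f"percentiles_{set_name}.tsv")
            manifest["gene_sets"][set_name] = set_entry

        stage = "flagging"
        flagged = flag_balancing(
            trans, annotations, fst_max=config.fst_max, het_min=config.het_min
        )
        ftab = flags_table(flagged)
        write_table(ftab, out / "flagged_snps.tsv")
        manifest["counts"]["flagged_snps"] = int(ftab["flagged"].sum())
        manifest["counts"]["unflaggable_snps"] = int(ftab["unflaggable"].sum())
    except StageError:
        (out / "FAILED").write_text(stage + "\n")
        raise
    except Exception as exc:
        (out / "FAILED").write_text(stage + "\n")
        raise StageError(stage, str(exc)) from exc

    write_sidecar(out / "manifest.json", manifest)
    # wall-clock provenance lives apart from the deterministic manifest
    import datetime

    (out / "run_info.json").write_text(
        json.dumps({"completed_utc": datetime.datetime.utcnow().isoformat()}) + "\n"
    )
    return manifest


def config_from_mapping(data: dict) -> RunConfig:
    """Build a RunConfig from a parsed YAML/JSON mapping."""
    data = dict(data)
    thr = data.pop("thresholds", {})
    thresholds = MatchThresholds(
        b=thr.get("match_b", 0.1),
        length_bp=thr.get("match_length_bp", 400.0),
        gc_points=thr.get("match_gc_points", 5.0),
    )
    fst_max = thr.get("fst_max", FST_MAX_DEFAULT)
    het_min = thr.get("het_min", HET_MIN_DEFAULT)
    kinds = tuple(data.pop("kinds", KINDS))
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise StageError("config", f"unknown keys: {sorted(unknown)}")
    return RunConfig(
        thresholds=thresholds, fst_max=fst_max, het_min=het_min, kinds=kinds, **data
    )
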