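"""Per-gene matching covariates and the matched-control pool.

Control genes are matched to each target gene on three covariates known to
drive per-gene polymorphism counts: background selection (McVicker's B, the
expected remaining fraction of neutral diversity, in [0,1]), total coding
exonic length (a proxy for mutational target size), and GC percentage (a
proxy for local mutation rate). A control is eligible for a target only if
all three differences are simultaneously within threshold, thresholds
inclusive:

    |B_c - B_t| <= 0.1,  |len_c - len_t| <= 400 bp,  |GC_c - GC_t| <= 5 points

"within 5%" is read as 5 absolute percentage points of GC. Targets with no
eligible control are excluded from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import FeatureError, InputError
from .io import GeneModel, fetch_sequence


@dataclass(frozen=True)
class MatchThresholds:
    """Covariate windows for control eligibility (all inclusive)."""

    b: float = 0.1
    length_bp: float = 400.0
    gc_points: float = 5.0

    def __post_init__(self):
        if min(self.b, self.length_bp, self.gc_points) <= 0:
            raise InputError("matching thresholds must be positive")


@dataclass
class MatchedPool:
    """Eligible control genes per target, after exclusions.

    ``candidates`` maps each retained target gene to its non-empty list of
    eligible controls; targets with an empty candidate list are in
    ``excluded_targets`` and never appear as keys. No candidate is a member
    of the (full, pre-exclusion) target set.
    """

    set_name: str
    candidates: dict  # target gene -> list of control genes
    excluded_targets: list = field(default_factory=list)
    missing_covariates: list = field(default_factory=list)
    control_universe: list = field(default_factory=list)

    @property
    def targets(self) -> list:
        return list(self.candidates.keys())


def merge_intervals(intervals: Iterable) -> list:
    """Union of half-open intervals, merged and sorted."""
    ivs = sorted(intervals)
    out: list = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def exonic_length(model: GeneModel) -> int:
    """Length of the union of coding-exon intervals (overlaps merged)."""
    return sum(e - s for s, e in merge_intervals(model.coding_exons))


def gc_content(model: GeneModel, reference) -> float:
    """GC percentage over the concatenated coding-exon sequence.

    Non-ACGT bases are excluded from both numerator and denominator.
    Returns NaN for a gene whose coding sequence has no ACGT bases.
    """
    gc = 0
    acgt = 0
    for s, e in model.coding_exons:
        try:
            seq = fetch_sequence(reference, model.chrom, s, e)
        except IndexError as exc:
            raise FeatureError(f"gene {model.name}: {exc}") from exc
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return 100.0 * gc / acgt


def gene_features_table(
    models: Iterable[GeneModel],
    reference,
    b_table: Optional[Mapping] = None,
) -> pd.DataFrame:
    """Per-gene covariate table: exonic_length, gc_percent, b_stat.

    Genes absent from ``b_table`` (or with a null B) get NaN and are later
    dropped from both target and control universes by ``match_controls``.
    """
    b_table = b_table or {}
    rows = []
    for model in models:
        b = b_table.get(model.name)
        rows.append(
            {
                "gene": model.name,
                "exonic_length": exonic_length(model),
                "gc_percent": gc_content(model, reference),
                "b_stat": np.nan if b is None else float(b),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def read_features_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["NA", ""])
    required = {"gene", "exonic_length", "gc_percent", "b_stat"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return df.set_index("gene")


def match_controls(
    targets: Iterable[str],
    features: pd.DataFrame,
    thresholds: MatchThresholds = MatchThresholds(),
    set_name: str = "target",
) -> MatchedPool:
    """Build the matched-control pool for one target gene set.

    Genes lacking any covariate are removed from both sides and reported in
    ``missing_covariates``. Targets with zero eligible controls go to
    ``excluded_targets`` and are dropped from downstream statistics.
    """
    targets = list(dict.fromkeys(targets))
    if not targets:
        raise InputError("target gene list is empty")
    target_set = set(targets)
    complete = features.dropna(subset=["exonic_length", "gc_percent", "b_stat"])
    missing = sorted(set(features.index) - set(complete.index))

    universe = [g for g in complete.index if g not in target_set]
    usable_targets = [g for g in targets if g in complete.index]
    dropped_missing_targets = [g for g in targets if g not in complete.index]

    if not universe:
        return MatchedPool(
            set_name,
            {},
            excluded_targets=usable_targets + dropped_missing_targets,
            missing_covariates=missing,
            control_universe=[],
        )

    uni = complete.loc[universe]
    b_u = uni["b_stat"].to_numpy(float)
    len_u = uni["exonic_length"].to_numpy(float)
    gc_u = uni["gc_percent"].to_numpy(float)
    universe_arr = np.asarray(universe, dtype=object)

    candidates: dict = {}
    excluded = list(dropped_missing_targets)
    for g in usable_targets:
        row = complete.loc[g]
        ok = (
            (np.abs(b_u - float(row["b_stat"])) <= thresholds.b)
            & (np.abs(len_u - float(row["exonic_length"])) <= thresholds.length_bp)
            & (np.abs(gc_u - float(row["gc_percent"])) <= thresholds.gc_points)
        )
        hits = universe_arr[ok]
        if hits.size:
            candidates[g] = [str(x) for x in hits]
        else:
            excluded.append(g)
    return MatchedPool(
        set_name,
        candidates,
        excluded_targets=excluded,
        missing_covariates=missing,
        control_universe=universe,
    )


def pool_table(pool: MatchedPool) -> pd.DataFrame:
    """Serialisable view of a matched pool (one row per retained target)."""
    rows = [
        {
            "target": t,
            "n_candidates": len(cands),
            "candidates": ";".join(cands),
        }
        for t, cands in pool.candidates.items()
    ]
    return pd.DataFrame(rows, columns=["target", "n_candidates", "candidates"])
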