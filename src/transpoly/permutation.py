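"""Matched-control permutation null and empirical enrichment p-values.

Each replicate draws one control gene per target, uniformly from that
target's matched candidates; within a replicate an already-drawn gene is
skipped when the target has other candidates and reused (with a logged
counter) only on pool exhaustion, so a replicate set has exactly the target
set's size. The one-sided empirical p-value for an excess of the statistic
is (r + 1) / (n_perm + 1), where r is the number of replicates whose count
is >= the observed count; the add-one rule avoids p = 0 and differs from
the raw proportion by at most 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import InputError
from .features import MatchedPool

KINDS = ("all_polymorphisms", "trans_snps", "trans_snps_nonsyn")
PERCENTILE_STEPS = tuple(range(5, 101, 5))


@dataclass(frozen=True)
class SetStatistic:
    """A gene-set polymorphism count and its per-gene mean."""

    kind: str
    count: int
    n_genes: int

    def __post_init__(self):
        if self.count < 0 or self.n_genes < 1:
            raise InputError("count must be >= 0 over a non-empty gene set")

    @property
    def mean_per_gene(self) -> float:
        return self.count / self.n_genes


@dataclass
class NullDistribution:
    """Per-replicate gene-set counts from matched permutations."""

    kind: str
    counts: np.ndarray  # one count per replicate
    n_genes: int
    n_perm: int
    seed: int
    reuse_total: int = 0

    @property
    def mean_per_gene(self) -> np.ndarray:
        return self.counts / self.n_genes


@dataclass
class EnrichmentResult:
    """Observed statistic, empirical p, and the percentile report."""

    observed: SetStatistic
    p_value: float
    null: NullDistribution
    percentiles: dict  # 5, 10, ..., 100 -> null mean_per_gene quantile


def count_set_statistic(genes: Iterable[str], tallies: pd.DataFrame, kind: str) -> SetStatistic:
    """Sum per-gene tallies over a gene set.

    Genes absent from the tally table count zero. SNPs inside overlapping
    genes contribute once per gene, matching the per-gene construction of
    the null.
    """
    genes = list(genes)
    if not genes:
        raise InputError("gene set is empty")
    if kind not in tallies.columns:
        raise InputError(f"unknown statistic kind {kind!r}")
    col = tallies[kind].reindex(genes, fill_value=0)
    return SetStatistic(kind=kind, count=int(col.sum()), n_genes=len(genes))


class _PoolSampler:
    """Pre-indexed uniform sampler over a matched pool."""

    def __init__(self, pool: MatchedPool, tallies: pd.DataFrame, kind: str):
        if not pool.candidates:
            raise InputError(f"pool for {pool.set_name!r} has no retained targets")
        genes = sorted({g for cands in pool.candidates.values() for g in cands})
        self.gene_index = {g: i for i, g in enumerate(genes)}
        self.genes = genes
        counts = tallies[kind].reindex(genes, fill_value=0).to_numpy()
        self.counts = counts.astype(np.int64)
        self.cand_idx = [
            np.array([self.gene_index[g] for g in cands], dtype=np.int64)
            for cands in pool.candidates.values()
        ]
        self.n_genes = len(genes)

    def draw(self, rng: np.random.Generator):
        """One replicate: (total count, member indices, n_reused)."""
        used = np.zeros(self.n_genes, dtype=bool)
        total = 0
        reused = 0
        members = np.empty(len(self.cand_idx), dtype=np.int64)
        for i, cands in enumerate(self.cand_idx):
            avail = cands[~used[cands]]
            if avail.size:
                pick = avail[rng.integers(avail.size)]
            else:
                pick = cands[rng.integers(cands.size)]
                reused += 1
            used[pick] = True
            members[i] = pick
            total += self.counts[pick]
        return total, members, reused


def sample_null_set(pool: MatchedPool, rng: np.random.Generator) -> tuple:
    """Draw one control set of the target set's size.

    Returns (genes, n_reused): one uniform draw per target from its
    candidate list, skipping already-drawn genes while alternatives remain.
    """
    genes = []
    used = set()
    reused = 0
    for cands in pool.candidates.values():
        avail = [c for c in cands if c not in used]
        if avail:
            pick = avail[rng.integers(len(avail))]
        else:
            pick = cands[rng.integers(len(cands))]
            reused += 1
        used.add(pick)
        genes.append(pick)
    return genes, reused


def build_null(
    pool: MatchedPool,
    tallies: pd.DataFrame,
    kind: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> NullDistribution:
    """Monte-Carlo null of set counts from ``n_perm`` matched replicates."""
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    sampler = _PoolSampler(pool, tallies, kind)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_perm, dtype=np.int64)
    reuse_total = 0
    for r in range(n_perm):
        total, _, reused = sampler.draw(rng)
        counts[r] = total
        reuse_total += reused
    return NullDistribution(
        kind=kind,
        counts=counts,
        n_genes=len(pool.candidates),
        n_perm=n_perm,
        seed=seed,
        reuse_total=reuse_total,
    )


def null_percentiles(null: NullDistribution) -> dict:
    """Type-7 (linear-interpolation) percentiles of the null per-gene mean."""
    vals = np.percentile(null.mean_per_gene, PERCENTILE_STEPS, method="linear")
    return {p: float(v) for p, v in zip(PERCENTILE_STEPS, vals)}


def permutation_test(
    tallies: pd.DataFrame,
    pool: MatchedPool,
    kind: str,
    n_perm: int = 10_000,
    seed: int = 0,
    observed: Optional[SetStatistic] = None,
) -> EnrichmentResult:
    """One-sided matched-permutation test for an excess of a set statistic.

    The observed statistic is computed over the pool's retained targets
    (post-exclusion) unless supplied. p = (r + 1)/(n_perm + 1) with r the
    number of replicates whose count >= the observed count.
    """
    if observed is None:
        observed = count_set_statistic(pool.targets, tallies, kind)
    null = build_null(pool, tallies, kind, n_perm=n_perm, seed=seed)
    r = int(np.sum(null.counts >= observed.count))
    p = (r + 1) / (n_perm + 1)
    return EnrichmentResult(
        observed=observed,
        p_value=p,
        null=null,
        percentiles=null_percentiles(null),
    )


def percentile_table(nulls: dict) -> pd.DataFrame:
    """Percentile report over one or more null distributions.

    ``nulls`` maps a statistic kind to its NullDistribution; rows are the
    5%-step percentiles (row 100 = maximum) of the per-gene mean, one
    column per kind — the conventional three-column layout reports SNPs,
    non-synonymous trans-SNPs and trans-SNPs side by side.
    """
    data = {"percentile": list(PERCENTILE_STEPS)}
    for kind, null in nulls.items():
        pct = null_percentiles(null)
        data[kind] = [pct[p] for p in PERCENTILE_STEPS]
    return pd.DataFrame(data)


def result_payload(result: EnrichmentResult) -> dict:
    """JSON-ready summary of one enrichment test."""
    return {
        "kind": result.observed.kind,
        "observed_count": result.observed.count,
        "observed_mean_per_gene": result.observed.mean_per_gene,
        "n_genes": result.observed.n_genes,
        "p_value": result.p_value,
        "n_perm": result.null.n_perm,
        "seed": result.null.seed,
        "reuse_total": result.null.reuse_total,
        "quantile_rule": "type-7 linear interpolation",
    }
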