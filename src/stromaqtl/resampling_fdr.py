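"""Resampling-based false discovery rate estimation for consensus calls.

Two schemes are provided.  The nested permutation scheme shuffles whole
per-sample genotype vectors within the smallest stratum, then shuffles only
the increment samples of each successively larger stratum, so every sample
carries one coherent permuted genotype vector across all four analyses while
expression stays untouched.  The random-panel scheme re-draws the SNP panel
from a large pool of candidate-independent SNPs.  In both, each replicate
runs the full stratified consensus pipeline and its consensus size is a
false-association count; FDR% = 100 * mean(false counts) / observed count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .consensus import (
    DEFAULT_STRATA,
    derive_seed,
    run_consensus_pipeline,
    stratify_samples,
)
from .containers import DataFormatError, GenotypeMatrix

__all__ = [
    "PermutationSummary",
    "nested_permutation",
    "permutation_fdr",
    "random_snp_fdr",
    "estimate_fdr",
]


@dataclass
class PermutationSummary:
    """Per-replicate null consensus sizes and the derived FDR percentage.

    ``fdr_pct`` is exact arithmetic (100 * mean_false / n_observed) and is
    ``None`` when no observed consensus exists; ``fdr_pct_display`` rounds
    half-up to one decimal for reporting.
    """

    n_reps: int
    false_counts: list
    n_observed: int
    scheme: str
    seed: int

    def __post_init__(self) -> None:
        if len(self.false_counts) != self.n_reps:
            raise ValueError("false_counts length must equal n_reps")

    @property
    def mean_false(self) -> float:
        return float(np.mean(self.false_counts)) if self.false_counts else 0.0

    @property
    def max_false(self) -> int:
        return int(max(self.false_counts)) if self.false_counts else 0

    @property
    def fdr_pct(self) -> float | None:
        if not self.n_observed:
            return None
        return 100.0 * self.mean_false / self.n_observed

    @property
    def fdr_pct_display(self) -> float | None:
        if self.fdr_pct is None:
            return None
        return _round_half_up(self.fdr_pct)


def _round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def nested_permutation(geno: GenotypeMatrix, stratum_samples: dict,
                       rng: np.random.Generator) -> GenotypeMatrix:
    """Permute genotype rows coherently across nested strata.

    Rows (whole per-sample genotype vectors) are shuffled within the smallest
    stratum; for each successively larger stratum only the increment samples
    — those not in any smaller stratum — are shuffled among themselves.  A
    sample therefore carries the same permuted vector in every stratum that
    contains it, and each stratum's genotype multiset is preserved.
    """
    ordered = sorted(stratum_samples.items(), key=lambda kv: len(kv[1]))
    prev: set = set()
    blocks = []
    for label, samples in ordered:
        current = set(samples)
        if not prev <= current:
            raise DataFormatError(
                f"strata are not nested: stratum {label!r} does not contain "
                "all smaller strata"
            )
        blocks.append([s for s in samples if s not in prev])
        prev = current
    dosages = geno.dosages.copy()
    for block in blocks:
        if len(block) < 2:
            continue  # a singleton block is a fixed point
        perm = rng.permutation(len(block))
        dosages.loc[block] = geno.dosages.loc[[block[i] for i in perm]].to_numpy()
    return GenotypeMatrix(dosages=dosages, risk_allele=dict(geno.risk_allele),
                          imputed=geno.imputed)


def permutation_fdr(expr, geno, annotations, strata=DEFAULT_STRATA,
                    config=None, n_reps: int = 1000,
                    n_observed: int | None = None) -> PermutationSummary:
    """Estimate FDR by the nested genotype-permutation scheme.

    Each replicate permutes the genotype rows (coherently across strata),
    reruns the full stratified consensus pipeline, and records the null
    consensus size.  Replicates use independent deterministic sub-streams of
    the master seed, so results are reproducible and order-invariant.
    """
    from .eqtl_engine import SemConfig

    config = config or SemConfig()
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_observed is None:
        n_observed = len(run_consensus_pipeline(expr, geno, annotations, strata, config))
    stratum_samples = stratify_samples(annotations, strata)
    counts = []
    for rep in range(n_reps):
        rep_seed = derive_seed(config.seed, f"perm-rep-{rep}")
        rng = np.random.default_rng(rep_seed)
        permuted = nested_permutation(geno, stratum_samples, rng)
        rep_config = replace(config, seed=rep_seed)
        null_consensus = run_consensus_pipeline(
            expr, permuted, annotations, strata, rep_config
        )
        counts.append(len(null_consensus))
    return PermutationSummary(
        n_reps=n_reps, false_counts=counts, n_observed=int(n_observed),
        scheme="nested_permutation", seed=config.seed,
    )


def random_snp_fdr(expr, snp_pool: GenotypeMatrix, annotations,
                   strata=DEFAULT_STRATA, config=None, n_select: int = 35,
                   n_reps: int = 1000,
                   n_observed: int | None = None) -> PermutationSummary:
    """Estimate FDR by re-drawing the SNP panel from a null pool.

    Each replicate draws ``n_select`` SNPs uniformly without replacement from
    ``snp_pool`` (a pool independent of the candidate panel), runs the full
    stratified consensus pipeline, and records the consensus size.
    """
    from .eqtl_engine import SemConfig

    config = config or SemConfig()
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if snp_pool.n_snps < n_select:
        raise DataFormatError(
            f"SNP pool has {snp_pool.n_snps} SNPs; cannot draw {n_select}"
        )
    counts = []
    for rep in range(n_reps):
        rep_seed = derive_seed(config.seed, f"panel-rep-{rep}")
        rng = np.random.default_rng(rep_seed)
        cols = rng.choice(snp_pool.n_snps, size=n_select, replace=False)
        panel = GenotypeMatrix(
            dosages=snp_pool.dosages.iloc[:, sorted(cols)],
            imputed=snp_pool.imputed,
        )
        rep_config = replace(config, seed=rep_seed)
        null_consensus = run_consensus_pipeline(
            expr, panel, annotations, strata, rep_config
        )
        counts.append(len(null_consensus))
    return PermutationSummary(
        n_reps=n_reps, false_counts=counts,
        n_observed=int(n_observed) if n_observed else 0,
        scheme="random_snp_panel", seed=config.seed,
    )


def estimate_fdr(mean_false: float, n_observed: int) -> float:
    """FDR percentage 100 * mean_false / n_observed, rounded half-up to one decimal."""
    if n_observed <= 0:
        raise ValueError("FDR is undefined when the observed consensus is empty")
    if mean_false < 0:
        raise ValueError("mean_false must be nonnegative")
    return _round_half_up(100.0 * mean_false / n_observed)
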