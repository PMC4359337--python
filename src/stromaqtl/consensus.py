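"""Stroma-stratified consensus calling.

The cohort is analysed four times, on nested sample subsets of increasing
stroma content (>50%, >60%, >70%, >80% stroma), and an association is
accepted only when it is called in every analysis.  Because a false call
must recur independently in all four fits, the intersection itself acts as a
false-discovery suppression device.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

from .containers import (
    DataFormatError,
    ExpressionMatrix,
    GenotypeMatrix,
    SampleAnnotation,
)
from .eqtl_engine import (
    AssociationCall,
    SemConfig,
    call_associations,
    fit_sem,
    standardize_and_prepare,
)

__all__ = [
    "StratumSpec",
    "DEFAULT_STRATA",
    "ConsensusSet",
    "stratify_samples",
    "run_stratified",
    "intersect_calls",
    "run_consensus_pipeline",
    "derive_seed",
]


@dataclass(frozen=True)
class StratumSpec:
    """A stratum keeps samples with stroma percentage strictly above the cut."""

    label: str
    min_stroma_pct: float


DEFAULT_STRATA = (
    StratumSpec(">50%", 50.0),
    StratumSpec(">60%", 60.0),
    StratumSpec(">70%", 70.0),
    StratumSpec(">80%", 80.0),
)


def _check_strata(strata) -> list[StratumSpec]:
    strata = list(strata)
    if not strata:
        raise DataFormatError("at least one stratum is required")
    cuts = [s.min_stroma_pct for s in strata]
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise DataFormatError("stratum thresholds must be strictly increasing")
    return strata


@dataclass
class ConsensusSet:
    """Associations surviving every stratified analysis.

    ``calls`` is the sorted list of (snp_id, transcript_id) pairs present in
    all strata; ``per_stratum_support`` maps (snp_id, transcript_id, label)
    to that stratum's support fraction.
    """

    calls: list
    per_stratum_support: dict
    stratum_sizes: dict = field(default_factory=dict)

    @property
    def stratum_labels(self) -> list:
        return list(self.stratum_sizes) if self.stratum_sizes else sorted(
            {lab for (_, _, lab) in self.per_stratum_support}
        )

    def __len__(self) -> int:
        return len(self.calls)


def derive_seed(master_seed: int, tag: str) -> int:
    """Deterministic, platform-independent sub-seed for a labelled sub-run."""
    digest = hashlib.sha256(f"{master_seed}:{tag}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def stratify_samples(annotations: SampleAnnotation, strata=DEFAULT_STRATA) -> dict:
    """Map stratum label -> sample ids with stroma strictly above the cut.

    Thresholds increase, so subsets are nested by construction.
    """
    strata = _check_strata(strata)
    table = annotations.table
    stroma = table["stroma_pct"]
    if stroma.isna().any():
        bad = table.index[stroma.isna()][0]
        raise DataFormatError(f"sample {bad!r} lacks a stroma_pct annotation")
    return {
        s.label: list(table.index[stroma > s.min_stroma_pct]) for s in strata
    }


def run_stratified(expr: ExpressionMatrix, geno: GenotypeMatrix,
                   annotations: SampleAnnotation, strata=DEFAULT_STRATA,
                   config: SemConfig | None = None) -> dict:
    """Fit the SEM independently in each stratum and return its calls.

    Genotypes are re-prepared per subset (re-imputation, re-exclusion of
    monomorphic SNPs), so a SNP degenerate in one stratum drops out of that
    stratum only.  Per-stratum fit seeds are derived deterministically from
    the master seed and the stratum label.
    """
    config = config or SemConfig()
    strata = _check_strata(strata)
    by_stratum = stratify_samples(annotations, strata)
    results: dict[str, list[AssociationCall]] = {}
    for stratum in strata:
        samples = by_stratum[stratum.label]
        if len(samples) < 3:
            raise DataFormatError(
                f"stratum {stratum.label!r} has only {len(samples)} samples (minimum 3)"
            )
        sub_expr, sub_geno, excluded = standardize_and_prepare(
            expr, geno, samples, config
        )
        stratum_config = replace(config, seed=derive_seed(config.seed, stratum.label))
        fit = fit_sem(sub_expr, sub_geno, stratum_config, excluded_snps=excluded)
        results[stratum.label] = call_associations(fit, stratum_label=stratum.label)
    return results


def intersect_calls(per_stratum_calls: dict, stratum_sizes: dict | None = None) -> ConsensusSet:
    """Keep only the (SNP, transcript) pairs called in every stratum."""
    if not per_stratum_calls:
        raise DataFormatError("at least one stratum of calls is required")
    pair_sets = [
        {c.pair for c in calls} for calls in per_stratum_calls.values()
    ]
    common = set.intersection(*pair_sets)
    support = {
        (c.snp_id, c.transcript_id, label): c.support
        for label, calls in per_stratum_calls.items()
        for c in calls
        if c.pair in common
    }
    ordered = sorted(common)
    sizes = dict(stratum_sizes) if stratum_sizes else {
        label: None for label in per_stratum_calls
    }
    return ConsensusSet(calls=ordered, per_stratum_support=support,
                        stratum_sizes=sizes)


def run_consensus_pipeline(expr: ExpressionMatrix, geno: GenotypeMatrix,
                           annotations: SampleAnnotation, strata=DEFAULT_STRATA,
                           config: SemConfig | None = None) -> ConsensusSet:
    """Full stratified analysis: stratify, fit per stratum, intersect."""
    config = config or SemConfig()
    strata = _check_strata(strata)
    by_stratum = stratify_samples(annotations, strata)
    calls = run_stratified(expr, geno, annotations, strata, config)
    sizes = {label: len(samples) for label, samples in by_stratum.items()}
    return intersect_calls(calls, stratum_sizes=sizes)
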