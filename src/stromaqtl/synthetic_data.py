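"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the design of the motivating study: ~49 prostatectomy
patients with stroma-enriched expression profiles, a candidate panel of 35
GWAS risk SNPs, thousands of transcripts, sparse planted trans-effects
following the additive model y_ij = beta_j + sum_k Z_ik gamma_jk + eps_ij,
stroma percentages spanning the >50/60/70/80% strata, and binary relapse
outcomes with follow-up times.  Ground-truth planted pairs are recorded so
every downstream stage can be scored against them.

Planted effect sizes are standardized: ``effect_size`` is the expression
shift, in units of the residual SD, per standard deviation of genotype
dosage (gamma_jk = effect_size * resid_sd / sd(Z_k)).  This makes planted
detectability independent of each SNP's allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    DataFormatError,
    ExpressionMatrix,
    GenotypeMatrix,
    SampleAnnotation,
)

__all__ = [
    "SyntheticConfig",
    "PlantedEffect",
    "SyntheticStudy",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_annotations",
    "make_study",
    "simulate_survival_cohort",
    "write_study",
]

#: Cohort stroma profile: share of samples per stroma bin, chosen so that at
#: n = 49 the four nested strata (>50/60/70/80%) contain 49/41/33/25 samples.
_COHORT_BIN_COUNTS = (8, 8, 8, 25)
_COHORT_BIN_EDGES = ((50.5, 60.0), (60.5, 70.0), (70.5, 80.0), (80.5, 99.5))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for a full synthetic cohort.

    Defaults mirror the motivating study: 49 patients, 35 candidate SNPs,
    4030 transcripts, a hub SNP carrying several planted transcripts (the
    analogue of the one risk variant associated with 32 transcripts), a
    relapse rate of 20/47 with 2/49 of outcomes unknown.
    """

    n_samples: int = 49
    n_snps: int = 35
    n_transcripts: int = 4030
    maf_range: tuple = (0.1, 0.5)
    n_planted: int = 10
    effect_size: float = 1.0
    resid_sd: float = 1.0
    stroma_range: tuple = (51.0, 100.0)
    stroma_profile: str = "cohort"  # "cohort" (Table-style nested bins) or "uniform"
    relapse_rate: float = 20.0 / 47.0
    unknown_relapse_fraction: float = 2.0 / 49.0
    hub_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_snps < 1 or self.n_transcripts < 1:
            raise ValueError("n_samples >= 2, n_snps >= 1, n_transcripts >= 1 required")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_planted > self.n_snps * self.n_transcripts:
            raise ValueError("n_planted exceeds n_snps * n_transcripts")
        if not (0.0 <= self.relapse_rate <= 1.0):
            raise ValueError("relapse_rate must be in [0, 1]")
        if self.hub_size > self.n_planted:
            raise ValueError("hub_size cannot exceed n_planted")
        if self.stroma_profile not in ("cohort", "uniform"):
            raise ValueError("stroma_profile must be 'cohort' or 'uniform'")


@dataclass(frozen=True)
class PlantedEffect:
    """One ground-truth trans-association: gamma is the per-dosage effect."""

    snp_id: str
    transcript_id: str
    gamma: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.snp_id, self.transcript_id)


@dataclass
class SyntheticStudy:
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    annotations: SampleAnnotation
    truth: list = field(default_factory=list)

    def __post_init__(self) -> None:
        g = set(self.genotypes.sample_ids)
        if g != set(self.expression.sample_ids) or g != set(self.annotations.sample_ids):
            raise DataFormatError("sample id sets of study components differ")
        snps = set(self.genotypes.snp_ids)
        transcripts = set(self.expression.transcript_ids)
        for eff in self.truth:
            if eff.snp_id not in snps or eff.transcript_id not in transcripts:
                raise DataFormatError(
                    f"truth pair ({eff.snp_id}, {eff.transcript_id}) references unknown ids"
                )

    @property
    def truth_pairs(self) -> set:
        return {eff.pair for eff in self.truth}


def _sample_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def _snp_ids(n: int, prefix: str = "snp") -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _transcript_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"T{i:0{width}d}_at" for i in range(1, n + 1)]


def simulate_genotypes(n_samples: int, n_snps: int, maf_range=(0.1, 0.5),
                       seed: int = 0, snp_prefix: str = "snp") -> GenotypeMatrix:
    """Independent Hardy-Weinberg SNPs: dosage ~ Binomial(2, MAF) per sample.

    Each SNP's MAF is drawn uniformly from ``maf_range``; the risk allele is
    the minor allele, so dosages count minor alleles.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    lo, hi = maf_range
    if lo <= 0.0:
        raise ValueError(f"maf_range lower bound {lo} violates the bound maf > 0")
    if hi > 0.5:
        raise ValueError(f"maf_range upper bound {hi} violates the bound maf <= 0.5")
    if lo > hi:
        raise ValueError("maf_range lower bound exceeds upper bound")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)
    dosages = rng.binomial(2, mafs, size=(n_samples, n_snps)).astype(float)
    df = pd.DataFrame(dosages, index=_sample_ids(n_samples), columns=_snp_ids(n_snps, snp_prefix))
    return GenotypeMatrix(dosages=df)


def simulate_expression(genotypes: GenotypeMatrix, truth, resid_sd: float = 1.0,
                        seed: int = 0, n_transcripts: int | None = None,
                        transcript_ids=None) -> ExpressionMatrix:
    """Expression from the additive model with planted effects and Gaussian noise.

    y_ij = beta_j + sum_k Z_ik gamma_jk + eps_ij with eps ~ N(0, resid_sd^2)
    and per-transcript baselines beta_j ~ N(7, 1) (log2 microarray scale).
    Transcripts not named in ``truth`` have all gamma_jk = 0.
    """
    if transcript_ids is None:
        if n_transcripts is None:
            n_transcripts = len({eff.transcript_id for eff in truth})
            transcript_ids = sorted({eff.transcript_id for eff in truth})
        else:
            transcript_ids = _transcript_ids(n_transcripts)
    transcript_ids = list(transcript_ids)
    if not transcript_ids:
        raise ValueError("no transcripts to simulate")
    snp_index = {s: i for i, s in enumerate(genotypes.snp_ids)}
    t_index = {t: i for i, t in enumerate(transcript_ids)}
    for eff in truth:
        if eff.snp_id not in snp_index:
            raise DataFormatError(f"truth references unknown SNP {eff.snp_id!r}")
        if eff.transcript_id not in t_index:
            raise DataFormatError(
                f"truth references unknown transcript {eff.transcript_id!r}"
            )
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    J = len(transcript_ids)
    Z = genotypes.dosages.to_numpy(dtype=float)
    if np.isnan(Z).any():
        raise DataFormatError("genotypes contain missing dosages; impute first")
    beta = rng.normal(7.0, 1.0, size=J)
    Y = np.tile(beta, (n, 1))
    for eff in truth:
        Y[:, t_index[eff.transcript_id]] += eff.gamma * Z[:, snp_index[eff.snp_id]]
    if resid_sd > 0:
        Y = Y + rng.normal(0.0, resid_sd, size=(n, J))
    df = pd.DataFrame(Y, index=genotypes.sample_ids, columns=transcript_ids)
    return ExpressionMatrix(values=df)


def _stroma_values(n: int, profile: str, stroma_range, rng) -> np.ndarray:
    if profile == "uniform":
        lo, hi = stroma_range
        if lo > hi:
            raise ValueError("stroma_range is empty (lower bound exceeds upper)")
        return rng.uniform(lo, hi, size=n)
    # cohort profile: largest-remainder allocation of n samples to the four
    # nested bins, proportional to the 8/8/8/25 design
    total = sum(_COHORT_BIN_COUNTS)
    quota = [n * c / total for c in _COHORT_BIN_COUNTS]
    counts = [int(q) for q in quota]
    remainders = np.argsort([q - int(q) for q in quota])[::-1]
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    values = np.concatenate([
        rng.uniform(lo, hi, size=c) for c, (lo, hi) in zip(counts, _COHORT_BIN_EDGES)
    ])
    rng.shuffle(values)
    return values


def simulate_annotations(n_samples: int, stroma_range=(51.0, 100.0),
                         relapse_rate: float = 20.0 / 47.0, seed: int = 0,
                         unknown_fraction: float = 2.0 / 49.0,
                         stroma_profile: str = "uniform",
                         sample_ids=None) -> SampleAnnotation:
    """Per-sample annotations: tissue composition, outcome, clinical covariates.

    Follow-up times are exponential with outcome-dependent scales (relapse
    events occur earlier than censoring of non-relapse patients) so the
    survival stage has signal to find.  A seeded fraction of relapse flags is
    set to "unknown", mirroring incomplete clinical records.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    lo, hi = stroma_range
    if lo > hi:
        raise ValueError("stroma_range is empty (lower bound exceeds upper)")
    rng = np.random.default_rng(seed)
    ids = list(sample_ids) if sample_ids is not None else _sample_ids(n_samples)
    stroma = _stroma_values(n_samples, stroma_profile, stroma_range, rng)
    tumor = (100.0 - stroma) * rng.uniform(0.3, 0.9, size=n_samples)
    relapse = np.where(rng.random(n_samples) < relapse_rate, "yes", "no").astype(object)
    n_unknown = int(round(unknown_fraction * n_samples))
    if n_unknown:
        unknown_idx = rng.choice(n_samples, size=n_unknown, replace=False)
        relapse[unknown_idx] = "unknown"
    # relapse events observed early; others followed until censoring
    followup = np.where(
        relapse == "yes",
        rng.exponential(3.0, size=n_samples),
        rng.exponential(6.0, size=n_samples),
    ) + 0.25
    table = pd.DataFrame(
        {
            "stroma_pct": stroma,
            "tumor_pct": tumor,
            "relapse": relapse,
            "followup_time": followup,
            "gleason_sum": rng.choice([6, 7, 8, 9], size=n_samples,
                                      p=[0.3, 0.45, 0.15, 0.1]).astype(float),
            "pre_psa": np.round(rng.lognormal(2.0, 0.6, size=n_samples), 2),
            "stage": rng.choice(["T2", "T3"], size=n_samples, p=[0.7, 0.3]),
            "age": np.round(rng.normal(63.0, 7.0, size=n_samples), 1),
            "margin_status": rng.choice(["negative", "positive"], size=n_samples,
                                        p=[0.7, 0.3]),
        },
        index=ids,
    )
    return SampleAnnotation(table=table)


def _plant_truth(genotypes: GenotypeMatrix, transcript_ids, config: SyntheticConfig,
                 rng) -> list[PlantedEffect]:
    Z = genotypes.dosages.to_numpy(dtype=float)
    sds = Z.std(axis=0)
    usable = np.nonzero(sds > 0)[0]
    if config.n_planted == 0:
        return []
    hub = config.hub_size
    n_distinct_snps = config.n_planted - hub + (1 if hub else 0)
    if len(usable) < max(n_distinct_snps, 1):
        raise DataFormatError(
            "not enough polymorphic SNPs to place planted effects on distinct SNPs"
        )
    snp_order = rng.permutation(usable)
    transcripts = rng.choice(len(transcript_ids), size=config.n_planted, replace=False)
    scale = config.resid_sd if config.resid_sd > 0 else 1.0
    truth: list[PlantedEffect] = []
    snp_iter = iter(snp_order)
    chosen: list[int] = []
    if hub:
        hub_snp = next(snp_iter)
        chosen.extend([hub_snp] * hub)
    for _ in range(config.n_planted - hub):
        chosen.append(next(snp_iter))
    signs = rng.choice([-1.0, 1.0], size=config.n_planted)
    for t_idx, s_idx, sign in zip(transcripts, chosen, signs):
        gamma = sign * config.effect_size * scale / sds[s_idx]
        truth.append(PlantedEffect(
            snp_id=genotypes.snp_ids[s_idx],
            transcript_id=transcript_ids[t_idx],
            gamma=float(gamma),
        ))
    return truth


def make_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a complete seeded study: genotypes, expression, annotations, truth.

    One master seed drives four deterministic child seeds, so identical
    configs yield bit-identical studies.
    """
    child = np.random.SeedSequence(config.seed).generate_state(4)
    genotypes = simulate_genotypes(
        config.n_samples, config.n_snps, config.maf_range, seed=int(child[0])
    )
    transcript_ids = _transcript_ids(config.n_transcripts)
    rng_truth = np.random.default_rng(int(child[1]))
    truth = _plant_truth(genotypes, transcript_ids, config, rng_truth)
    expression = simulate_expression(
        genotypes, truth, resid_sd=config.resid_sd, seed=int(child[2]),
        transcript_ids=transcript_ids,
    )
    annotations = simulate_annotations(
        config.n_samples, stroma_range=config.stroma_range,
        relapse_rate=config.relapse_rate, seed=int(child[3]),
        unknown_fraction=config.unknown_relapse_fraction,
        stroma_profile=config.stroma_profile, sample_ids=genotypes.sample_ids,
    )
    return SyntheticStudy(
        genotypes=genotypes, expression=expression, annotations=annotations,
        truth=truth,
    )


def simulate_survival_cohort(n: int = 49, hazard_ratio: float = 2.2,
                             seed: int = 0, baseline_rate: float = 0.07,
                             followup_range=(1.0, 10.0),
                             group_probs=(1 / 3, 1 / 3, 1 / 3)) -> pd.DataFrame:
    """Three-group survival cohort with exponential event times.

    The low-risk group has hazard ``baseline_rate`` (events per year), the
    high-risk group ``baseline_rate * hazard_ratio``, and the intermediate
    group the geometric mean of the two.  Censoring times are uniform over
    ``followup_range`` (staggered follow-up); at the defaults roughly 40% of
    patients experience the event, matching a 20-of-47 event fraction.
    """
    rng = np.random.default_rng(seed)
    rates = {
        "low": baseline_rate,
        "intermediate": baseline_rate * np.sqrt(hazard_ratio),
        "high": baseline_rate * hazard_ratio,
    }
    groups = rng.choice(["low", "intermediate", "high"], size=n, p=list(group_probs))
    event_time = rng.exponential(1.0 / np.array([rates[g] for g in groups]))
    censor_time = rng.uniform(*followup_range, size=n)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    return pd.DataFrame(
        {"group": groups, "time": time, "event": event}, index=_sample_ids(n)
    )


def write_study(study: SyntheticStudy, directory) -> dict:
    """Write a study as the TSV dialect ``data_io`` reads, plus a truth table."""
    from . import data_io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": directory / "genotypes.tsv",
        "expression": directory / "expression.tsv",
        "annotations": directory / "annotations.tsv",
        "truth": directory / "truth.tsv",
    }
    data_io.write_genotypes(study.genotypes, paths["genotypes"])
    data_io.write_expression(study.expression, paths["expression"])
    data_io.write_annotations(study.annotations, paths["annotations"])
    truth_df = pd.DataFrame(
        [(e.snp_id, e.transcript_id, e.gamma) for e in study.truth],
        columns=["snp_id", "transcript_id", "gamma"],
    )
    truth_df.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return paths
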