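"""Joint trans-eQTL model fitted by Stochastic EM.

The model regresses every transcript on every SNP simultaneously,

    y_ij = beta_j + sum_k Z_ik gamma_jk + eps_ij,    eps_ij ~ N(0, sigma2_j),

with a two-group (spike-and-slab) structure on each effect: for every SNP k
a transcript either belongs to the SNP-associated cluster (gamma_jk drawn
from a slab N(0, v_k)) or to the non-associated cluster (gamma_jk exactly
zero).  Cluster membership is the binary indicator eta_jk with per-SNP
mixing proportion pi_k.

Fitting alternates a stochastic E-step — each eta_jk is drawn from its
conditional posterior, which compares the slab marginal likelihood of the
transcript's conditional least-squares effect against the spike at zero with
prior odds pi_k/(1-pi_k) — with a deterministic M-step that re-estimates
intercepts, active effects (least squares on the active design columns),
mixing proportions, slab variances and residual variances.  The share of
post-burn-in iterations in which eta_jk = 1 is the pair's *support*; a pair
is called associated when its support strictly exceeds the threshold
(default 0.80).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DataFormatError, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "SemConfig",
    "ModelState",
    "ModelFit",
    "AssociationCall",
    "standardize",
    "prepare_genotypes",
    "sem_step",
    "fit_sem",
    "call_associations",
    "inclusion_log_odds",
]

_RESID_VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class SemConfig:
    """Tuning parameters of the Stochastic EM fit.

    ``pi_bounds`` of ``None`` means the default [1/(2J), 0.5], resolved once
    the number of transcripts J is known; the lower bound keeps the sampler
    out of the absorbing state pi -> 0 and the upper bound keeps cluster
    semantics (the associated cluster is the minority one).
    """

    n_iterations: int = 3000
    burn_in: int = 1000
    support_threshold: float = 0.80
    init_pi: float = 0.01
    pi_bounds: tuple[float, float] | None = None
    slab_var_floor: float = 1e-4
    maf_min: float = 0.0
    var_estimator: str = "ml"  # "ml": SSR/n; "dof": SSR/(n - 1 - k_active)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if not (0.0 < self.support_threshold < 1.0):
            raise ValueError("support_threshold must be in (0, 1)")
        if self.pi_bounds is not None:
            lo, hi = self.pi_bounds
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError("pi_bounds must lie within (0, 1)")
        if self.slab_var_floor <= 0:
            raise ValueError("slab_var_floor must be positive")
        if self.var_estimator not in ("ml", "dof"):
            raise ValueError("var_estimator must be 'ml' or 'dof'")

    def resolved_pi_bounds(self, n_transcripts: int) -> tuple[float, float]:
        if self.pi_bounds is not None:
            return self.pi_bounds
        return (1.0 / (2.0 * n_transcripts), 0.5)


@dataclass
class ModelState:
    """Complete SEM parameter state for one iteration.

    Arrays are indexed transcript-major: ``gamma`` and ``eta`` are J x K.
    The spike is exact: ``gamma[j, k] == 0`` wherever ``eta[j, k]`` is False.
    """

    beta: np.ndarray          # (J,) intercepts
    gamma: np.ndarray         # (J, K) effects
    eta: np.ndarray           # (J, K) bool cluster indicators
    pi: np.ndarray            # (K,) mixing proportions
    slab_var: np.ndarray      # (K,) slab variances
    resid_var: np.ndarray     # (J,) residual variances
    n_collinear_drops: int = 0

    def copy(self) -> "ModelState":
        return ModelState(
            beta=self.beta.copy(), gamma=self.gamma.copy(), eta=self.eta.copy(),
            pi=self.pi.copy(), slab_var=self.slab_var.copy(),
            resid_var=self.resid_var.copy(), n_collinear_drops=self.n_collinear_drops,
        )


@dataclass
class ModelFit:
    """Result of a full SEM run: per-pair support fractions plus diagnostics."""

    support: pd.DataFrame      # transcripts x SNPs, fractions in [0, 1]
    config: SemConfig
    n_post_burnin: int
    excluded_snps: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class AssociationCall:
    snp_id: str
    transcript_id: str
    support: float
    stratum_label: str = ""

    @property
    def pair(self) -> tuple[str, str]:
        return (self.snp_id, self.transcript_id)


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center each transcript to mean 0 and scale to unit sample variance.

    Zero-variance transcripts cannot be scaled; they are dropped with a
    warning naming them.  Idempotent on already-standardized data.
    """
    if expr.n_samples < 3:
        raise DataFormatError("standardize requires at least 3 samples")
    vals = expr.values
    sd = vals.std(axis=0, ddof=1)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        warnings.warn(
            f"dropping {len(degenerate)} zero-variance transcript(s): "
            f"{degenerate[:5]}", stacklevel=2,
        )
        vals = vals.drop(columns=degenerate)
        sd = sd.drop(degenerate)
    out = (vals - vals.mean(axis=0)) / sd
    return ExpressionMatrix(values=out)


def prepare_genotypes(geno: GenotypeMatrix, samples,
                      maf_min: float = 0.0) -> tuple[GenotypeMatrix, list]:
    """Restrict genotypes to a sample subset and make them model-ready.

    Missing dosages are imputed to the per-SNP mean over non-missing samples
    in the subset.  SNPs that are monomorphic in the subset, or whose
    subset minor-allele frequency falls below ``maf_min``, are excluded and
    reported as ``(snp_id, reason)`` pairs.
    """
    samples = list(samples)
    if not samples:
        raise DataFormatError("empty sample subset")
    missing = [s for s in samples if s not in geno.dosages.index]
    if missing:
        raise DataFormatError(f"samples absent from genotype matrix: {missing[:5]}")
    sub = geno.dosages.loc[samples].astype(float)
    excluded: list[tuple[str, str]] = []
    keep = []
    for snp in sub.columns:
        col = sub[snp]
        obs = col.dropna()
        if obs.empty:
            excluded.append((snp, "all genotypes missing"))
            continue
        freq = obs.mean() / 2.0
        maf = min(freq, 1.0 - freq)
        if obs.nunique() == 1:
            excluded.append((snp, "monomorphic"))
            continue
        if maf < maf_min:
            excluded.append((snp, f"maf {maf:.4g} below threshold {maf_min:g}"))
            continue
        if col.isna().any():
            col = col.fillna(obs.mean())
            sub[snp] = col
        keep.append(snp)
    out = GenotypeMatrix(
        dosages=sub[keep],
        risk_allele={k: v for k, v in geno.risk_allele.items() if k in keep},
        imputed=True,
    )
    return out, excluded


def inclusion_log_odds(b: np.ndarray, se2: np.ndarray,
                       slab_var: float, pi: float) -> np.ndarray:
    """Posterior log-odds that an effect estimate came from the slab.

    ``b`` is the conditional least-squares effect with sampling variance
    ``se2``; the slab marginal of ``b`` is N(0, se2 + slab_var) and the spike
    marginal is N(0, se2); prior odds are pi/(1-pi).
    """
    b = np.asarray(b, dtype=float)
    se2 = np.asarray(se2, dtype=float)
    tot = se2 + slab_var
    return (
        np.log(pi) - np.log1p(-pi)
        + 0.5 * (np.log(se2) - np.log(tot))
        + 0.5 * b * b * (1.0 / se2 - 1.0 / tot)
    )


def _as_arrays(expr, geno) -> tuple[np.ndarray, np.ndarray]:
    Y = expr.values.to_numpy(dtype=float) if isinstance(expr, ExpressionMatrix) else np.asarray(expr, float)
    Z = geno.dosages.to_numpy(dtype=float) if isinstance(geno, GenotypeMatrix) else np.asarray(geno, float)
    return Y, Z


def sem_step(state: ModelState, expr, geno, config: SemConfig,
             rng: np.random.Generator) -> ModelState:
    """One full SEM sweep (stochastic E-step then M-step); returns a new state.

    The E-step scans SNPs in fixed column order, updating residuals after
    each SNP so later SNPs condition on earlier draws within the sweep.
    """
    Y, Z = _as_arrays(expr, geno)
    n, J = Y.shape
    K = Z.shape[1]
    if state.gamma.shape != (J, K):
        raise DataFormatError(
            f"state dimensions {state.gamma.shape} do not match data ({J}, {K})"
        )
    new = state.copy()
    mu_y = Y.mean(axis=0)
    z_mean = Z.mean(axis=0)
    Yc = Y - mu_y
    Zc = Z - z_mean
    s = np.einsum("ik,ik->k", Zc, Zc)
    if np.any(s <= 0):
        bad = int(np.argmin(s))
        raise DataFormatError(
            f"SNP column {bad} is constant; run prepare_genotypes first"
        )
    pi_lo, pi_hi = config.resolved_pi_bounds(J)

    R = Yc - Zc @ new.gamma.T  # (n, J) residuals under current effects

    # --- stochastic E-step: coordinate scan over SNPs --------------------
    for k in range(K):
        zk = Zc[:, k]
        b = (zk @ R) / s[k] + new.gamma[:, k]      # conditional OLS excluding k
        se2 = np.maximum(new.resid_var, _RESID_VAR_FLOOR) / s[k]
        lo = inclusion_log_odds(b, se2, float(new.slab_var[k]), float(new.pi[k]))
        p = 1.0 / (1.0 + np.exp(-np.clip(lo, -700, 700)))
        eta_k = rng.random(J) < p
        gamma_k = np.where(eta_k, b, 0.0)
        delta = gamma_k - new.gamma[:, k]
        nz = np.nonzero(delta)[0]
        if nz.size:
            R[:, nz] -= zk[:, None] * delta[nz]
        new.eta[:, k] = eta_k
        new.gamma[:, k] = gamma_k

    # --- M-step -----------------------------------------------------------
    # joint least-squares refit for transcripts with >= 2 active SNPs
    multi = np.nonzero(new.eta.sum(axis=1) >= 2)[0]
    if multi.size:
        G = Zc.T @ Zc
        B = Zc.T @ Yc  # (K, J) cross-products
        for j in multi:
            active = np.nonzero(new.eta[j])[0]
            while True:
                try:
                    coef = np.linalg.solve(G[np.ix_(active, active)], B[active, j])
                except np.linalg.LinAlgError:
                    coef = None
                if coef is not None and np.all(np.isfinite(coef)):
                    break
                # collinear active design: drop the later-indexed SNP's effect
                dropped = active[-1]
                new.eta[j, dropped] = False
                new.gamma[j, dropped] = 0.0
                new.n_collinear_drops += 1
                active = active[:-1]
                if active.size == 0:
                    coef = np.empty(0)
                    break
            new.gamma[j, active] = coef
            R[:, j] = Yc[:, j] - Zc[:, active] @ coef

    new.beta = mu_y - new.gamma @ z_mean
    # "ml" divides SSR by n (maximum likelihood); "dof" corrects for the
    # intercept plus the transcript's active effects, which removes the
    # mild self-reinforcement of inclusion at small n but costs power
    if config.var_estimator == "dof":
        denom = np.maximum(n - 1 - new.eta.sum(axis=1), 1)
    else:
        denom = n
    new.resid_var = np.maximum(
        np.einsum("ij,ij->j", R, R) / denom, _RESID_VAR_FLOOR
    )
    new.pi = np.clip(new.eta.mean(axis=0), pi_lo, pi_hi)
    for k in range(K):
        active = new.eta[:, k]
        if active.any():
            new.slab_var[k] = max(
                float(np.mean(new.gamma[active, k] ** 2)), config.slab_var_floor
            )
        # no active effects: slab variance carried over from the previous sweep
    return new


def _init_state(J: int, K: int, Y: np.ndarray, config: SemConfig,
                rng: np.random.Generator) -> ModelState:
    pi_lo, pi_hi = config.resolved_pi_bounds(J)
    pi0 = float(np.clip(config.init_pi, pi_lo, pi_hi))
    eta = rng.random((J, K)) < config.init_pi
    return ModelState(
        beta=Y.mean(axis=0).copy(),
        gamma=np.zeros((J, K)),
        eta=eta,
        pi=np.full(K, pi0),
        slab_var=np.ones(K),
        resid_var=np.maximum(Y.var(axis=0), _RESID_VAR_FLOOR),
    )


def fit_sem(expr: ExpressionMatrix, geno: GenotypeMatrix, config: SemConfig,
            excluded_snps: list | None = None) -> ModelFit:
    """Run the full Stochastic EM chain and record per-pair support.

    Inputs are expected to be prepared (``standardize`` for expression,
    ``prepare_genotypes`` for dosages); sample ids must match.  The run is
    deterministic given (data, config, config.seed).
    """
    if expr.sample_ids != geno.sample_ids:
        if set(expr.sample_ids) != set(geno.sample_ids):
            raise DataFormatError("expression and genotype sample sets differ")
        geno = GenotypeMatrix(dosages=geno.dosages.loc[expr.sample_ids],
                              risk_allele=geno.risk_allele)
    if expr.n_samples < 3:
        raise DataFormatError("fit_sem requires at least 3 samples")
    Y, Z = _as_arrays(expr, geno)
    n, J = Y.shape
    K = Z.shape[1]
    rng = np.random.default_rng(config.seed)
    # gamma starts at zero even for initially active indicators; the first
    # sweep's E-step assigns their values
    state = _init_state(J, K, Y, config, rng)

    eta_sum = np.zeros((J, K))
    pi_sum = np.zeros(K)
    slab_sum = np.zeros(K)
    resid_sum = np.zeros(J)
    n_post = 0
    for it in range(config.n_iterations):
        state = sem_step(state, Y, Z, config, rng)
        if it >= config.burn_in:
            eta_sum += state.eta
            pi_sum += state.pi
            slab_sum += state.slab_var
            resid_sum += state.resid_var
            n_post += 1
    support = pd.DataFrame(
        eta_sum / n_post, index=expr.transcript_ids, columns=geno.snp_ids
    )
    diagnostics = {
        "mean_pi": pd.Series(pi_sum / n_post, index=geno.snp_ids),
        "mean_slab_var": pd.Series(slab_sum / n_post, index=geno.snp_ids),
        "mean_resid_var": pd.Series(resid_sum / n_post, index=expr.transcript_ids),
        "n_collinear_drops": state.n_collinear_drops,
    }
    return ModelFit(
        support=support, config=config, n_post_burnin=n_post,
        excluded_snps=list(excluded_snps or []), diagnostics=diagnostics,
    )


def call_associations(fit: ModelFit, stratum_label: str = "") -> list[AssociationCall]:
    """Emit pairs whose support strictly exceeds the threshold.

    The threshold is strict ("more than 80%"): support exactly equal to the
    threshold is not called.  Output is sorted by SNP id, then descending
    support, then transcript id for a deterministic order.
    """
    thr = fit.config.support_threshold
    sup = fit.support
    calls: list[AssociationCall] = []
    rows, cols = np.nonzero(sup.to_numpy() > thr)
    for r, c in zip(rows, cols):
        calls.append(AssociationCall(
            snp_id=str(sup.columns[c]), transcript_id=str(sup.index[r]),
            support=float(sup.iat[r, c]), stratum_label=stratum_label,
        ))
    calls.sort(key=lambda c: (c.snp_id, -c.support, c.transcript_id))
    return calls


def standardize_and_prepare(expr: ExpressionMatrix, geno: GenotypeMatrix,
                            samples, config: SemConfig):
    """Convenience: subset both matrices to ``samples`` and prepare them."""
    samples = list(samples)
    sub_expr = ExpressionMatrix(values=expr.values.loc[samples])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sub_expr = standardize(sub_expr)
    sub_geno, excluded = prepare_genotypes(geno, samples, config.maf_min)
    return sub_expr, sub_geno, excluded
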