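"""Clinical follow-up of consensus associations.

For each called SNP-transcript association, patients are partitioned into
high / intermediate / low risk groups by a declared, fully parameterised
rule (risk-allele carriage combined with which side of an expression
quantile the patient falls on, oriented by the sign of the fitted effect).
Risk groups are screened against clinical outcomes with proportional-odds
ordinal logistic regression (univariate and covariate-adjusted), and the
high vs low groups are compared by Kaplan-Meier / logrank survival analysis
with an O/E-ratio hazard ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DataFormatError, ExpressionMatrix, GenotypeMatrix

__all__ = [
    "RiskRule",
    "RiskGroupAssignment",
    "OrdinalRegressionResult",
    "SurvivalResult",
    "ZeroEventsError",
    "assign_risk_groups",
    "ordinal_logistic",
    "km_logrank",
    "km_curves",
]

GROUP_ORDER = ("low", "intermediate", "high")


class ZeroEventsError(DataFormatError):
    """Raised when a survival group has no events, leaving the HR undefined."""


@dataclass(frozen=True)
class RiskRule:
    """Parameterised risk-group rule.

    ``direction`` is the sign of the fitted SNP effect on the transcript:
    +1 means the risk allele raises expression, so expression above the
    cohort quantile is the risk-direction side.  ``allele_threshold`` is the
    minimum dosage counted as carrying the risk allele.
    """

    allele_threshold: int = 1
    expr_quantile: float = 0.5
    direction: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.expr_quantile < 1.0):
            raise ValueError("expr_quantile must be in (0, 1)")
        if self.allele_threshold not in (1, 2):
            raise ValueError("allele_threshold must be 1 or 2")
        if self.direction == 0:
            raise ValueError("direction must be nonzero (sign of the fitted effect)")


@dataclass
class RiskGroupAssignment:
    association: tuple
    groups: pd.Series            # patient -> low / intermediate / high
    rule: RiskRule
    expr_cut: float
    omitted: list = field(default_factory=list)

    def sizes(self) -> dict:
        return {g: int((self.groups == g).sum()) for g in GROUP_ORDER}


def assign_risk_groups(association: tuple, genotypes: GenotypeMatrix,
                       expression: ExpressionMatrix,
                       rule: RiskRule = RiskRule()) -> RiskGroupAssignment:
    """Partition patients into three risk groups for one association.

    High: carries at least ``allele_threshold`` risk alleles AND expression
    on the risk-direction side of the cohort quantile.  Low: zero risk
    alleles AND expression strictly on the opposite side.  Intermediate: all
    others (including expression exactly at the cut).  Patients with missing
    genotype are omitted with a warning.
    """
    snp_id, transcript_id = association
    if snp_id not in genotypes.dosages.columns:
        raise DataFormatError(f"SNP {snp_id!r} absent from genotype matrix")
    if transcript_id not in expression.values.columns:
        raise DataFormatError(f"transcript {transcript_id!r} absent from expression matrix")
    common = [s for s in genotypes.sample_ids if s in set(expression.sample_ids)]
    if not common:
        raise DataFormatError("no samples shared between genotypes and expression")
    dosage = genotypes.dosages.loc[common, snp_id]
    expr = expression.values.loc[common, transcript_id]
    omitted = list(dosage.index[dosage.isna()])
    if omitted:
        warnings.warn(
            f"omitting {len(omitted)} patient(s) with missing genotype for "
            f"{snp_id}: {omitted[:5]}", stacklevel=2,
        )
        dosage = dosage.dropna()
        expr = expr.loc[dosage.index]
    cut = float(expr.quantile(rule.expr_quantile))
    side = np.sign(rule.direction) * (expr - cut)
    carrier = dosage >= rule.allele_threshold
    noncarrier = dosage == 0
    groups = pd.Series("intermediate", index=dosage.index, dtype=object)
    groups[carrier & (side > 0)] = "high"
    groups[noncarrier & (side < 0)] = "low"
    return RiskGroupAssignment(
        association=(snp_id, transcript_id), groups=groups, rule=rule,
        expr_cut=cut, omitted=omitted,
    )


@dataclass
class OrdinalRegressionResult:
    coefficient: float
    p_univariate: float
    p_multivariate: float | None
    covariates: list
    coefficients_multivariate: dict = field(default_factory=dict)
    separation_flagged: bool = False
    n: int = 0


def _group_scores(groups: pd.Series) -> pd.Series:
    scores = groups.map({g: i for i, g in enumerate(GROUP_ORDER)})
    if scores.isna().any():
        bad = groups[scores.isna()].unique().tolist()
        raise DataFormatError(f"unrecognised risk-group labels: {bad}")
    return scores.astype(float)


def _fit_ordered(endog: pd.Series, exog: pd.DataFrame):
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    model = OrderedModel(endog, exog, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(method="bfgs", disp=False, maxiter=200)
    return model, fit


def _lr_pvalue(endog: pd.Series, exog: pd.DataFrame, drop: str, llf_full: float) -> float:
    reduced = exog.drop(columns=[drop])
    if reduced.shape[1] == 0:
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        model = OrderedModel(endog, None, distr="logit")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit0 = model.fit(method="bfgs", disp=False, maxiter=200)
    else:
        _, fit0 = _fit_ordered(endog, reduced)
    lr = max(0.0, 2.0 * (llf_full - fit0.llf))
    return float(stats.chi2.sf(lr, df=1))


def ordinal_logistic(groups: pd.Series, clinical_outcome: pd.Series,
                     covariates: pd.DataFrame | None = None) -> OrdinalRegressionResult:
    """Proportional-odds regression of a clinical outcome on risk group.

    Risk groups enter as an ordinal score (low=0, intermediate=1, high=2).
    Reports the univariate (group-only) Wald p-value and, when covariates
    are supplied, the covariate-adjusted one.  Under (near-)complete
    separation the Wald statistic degenerates; such fits are flagged and the
    p-value falls back to the likelihood-ratio test.
    """
    common = groups.index.intersection(clinical_outcome.index)
    groups = groups.loc[common]
    outcome = clinical_outcome.loc[common]
    keep = outcome.notna() & groups.notna()
    groups, outcome = groups[keep], outcome[keep]
    if groups.nunique() < 2:
        raise DataFormatError("need at least two non-empty risk groups")
    levels = np.sort(outcome.unique())
    if len(levels) < 2:
        raise DataFormatError("clinical outcome is constant")
    endog = pd.Categorical(outcome, categories=levels, ordered=True)
    endog = pd.Series(endog, index=outcome.index)
    score = _group_scores(groups).rename("risk_group")
    exog_uni = score.to_frame()

    def run(exog: pd.DataFrame):
        _, fit = _fit_ordered(endog, exog)
        coef = float(fit.params["risk_group"])
        se = float(fit.bse["risk_group"]) if np.isfinite(fit.bse["risk_group"]) else np.nan
        separated = (not fit.mle_retvals.get("converged", True)) or not np.isfinite(se) \
            or abs(coef) > 15
        if separated:
            p = _lr_pvalue(endog, exog, "risk_group", fit.llf)
        else:
            p = float(fit.pvalues["risk_group"])
        return fit, coef, p, separated

    fit_u, coef_u, p_uni, sep_u = run(exog_uni)

    p_multi = None
    coefs_multi: dict = {}
    cov_names: list = []
    sep_m = False
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.loc[groups.index]
        cov = pd.get_dummies(cov, drop_first=True, dtype=float)
        cov = cov.loc[:, cov.std() > 0]
        cov_names = list(cov.columns)
        exog_multi = pd.concat([exog_uni, cov], axis=1)
        fit_m, _, p_multi, sep_m = run(exog_multi)
        coefs_multi = {k: float(v) for k, v in fit_m.params.items()
                       if k in exog_multi.columns}
    return OrdinalRegressionResult(
        coefficient=coef_u, p_univariate=p_uni, p_multivariate=p_multi,
        covariates=cov_names, coefficients_multivariate=coefs_multi,
        separation_flagged=sep_u or sep_m, n=len(groups),
    )


@dataclass
class SurvivalResult:
    hazard_ratio: float
    logrank_stat: float
    p_value: float
    group_sizes: dict
    events_per_group: dict


def _logrank_oe(time: np.ndarray, event: np.ndarray,
                in_high: np.ndarray) -> tuple[float, float, float, float, float]:
    """Observed/expected events and hypergeometric variance over risk sets."""
    o_high = float(event[in_high].sum())
    o_low = float(event[~in_high].sum())
    e_high = 0.0
    var = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n_tot = float(at_risk.sum())
        n_high = float((at_risk & in_high).sum())
        d = float((event & (time == t)).sum())
        e_high += d * n_high / n_tot
        if n_tot > 1:
            var += d * (n_high / n_tot) * (1 - n_high / n_tot) * (n_tot - d) / (n_tot - 1)
    e_low = (o_high + o_low) - e_high
    return o_high, o_low, e_high, e_low, var


def km_logrank(groups: pd.Series, followup_time: pd.Series,
               event_flag: pd.Series) -> SurvivalResult:
    """Two-group logrank test and O/E hazard ratio, high vs low risk only.

    The intermediate group is excluded.  The statistic is the classical
    (O - E)^2 / V over event-time risk sets (chi-square, 1 df); the hazard
    ratio is (O_high/E_high) / (O_low/E_low).  A group with zero events
    leaves the HR undefined and is signalled as ``ZeroEventsError``.
    """
    common = groups.index.intersection(followup_time.index).intersection(event_flag.index)
    sel = groups.loc[common].isin(("high", "low"))
    idx = common[sel]
    if len(idx) == 0:
        raise DataFormatError("no patients in the high or low risk groups")
    time = followup_time.loc[idx].to_numpy(dtype=float)
    event = event_flag.loc[idx].astype(bool).to_numpy()
    in_high = (groups.loc[idx] == "high").to_numpy()
    if np.any(time < 0) or np.isnan(time).any():
        raise DataFormatError("follow-up times must be nonnegative and present")
    o_h, o_l, e_h, e_l, var = _logrank_oe(time, event, in_high)
    sizes = {"high": int(in_high.sum()), "low": int((~in_high).sum())}
    events = {"high": int(o_h), "low": int(o_l)}
    if o_h == 0 or o_l == 0:
        raise ZeroEventsError(
            f"zero events in a group (high={int(o_h)}, low={int(o_l)}); "
            "hazard ratio undefined"
        )
    stat = 0.0 if var == 0 else (o_h - e_h) ** 2 / var
    p = float(stats.chi2.sf(stat, df=1))
    hr = (o_h / e_h) / (o_l / e_l)
    return SurvivalResult(
        hazard_ratio=float(hr), logrank_stat=float(stat), p_value=p,
        group_sizes=sizes, events_per_group=events,
    )


def km_curves(groups: pd.Series, followup_time: pd.Series,
              event_flag: pd.Series) -> pd.DataFrame:
    """Kaplan-Meier survival curves per risk group (tidy coordinates).

    Returns columns ``group``, ``time``, ``survival`` suitable for plotting
    or TSV export.
    """
    from lifelines import KaplanMeierFitter

    frames = []
    for g in GROUP_ORDER:
        idx = groups.index[groups == g]
        idx = idx.intersection(followup_time.index).intersection(event_flag.index)
        if len(idx) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(followup_time.loc[idx], event_observed=event_flag.loc[idx].astype(bool))
        sf = kmf.survival_function_
        frames.append(pd.DataFrame({
            "group": g,
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        }))
    if not frames:
        raise DataFormatError("no patients with survival data in any group")
    return pd.concat(frames, ignore_index=True)
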