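"""Group statistics: mixed-effects tissue contrast, FDR, EOR, OLS, KM/log-rank.

These are the clinical/statistical summaries that sit downstream of the
signal pipelines: a random-intercept linear mixed model contrasting
electrode high-gamma power between tumour-infiltrated and
normal-appearing cortex (participants as random effects),
Benjamini-Hochberg false-discovery-rate adjustment, volumetric extent
of resection, simple two-sided linear regression, and Kaplan-Meier
survival with a two-tailed log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "LmeResult",
    "RegressionResult",
    "KmResult",
    "fit_lme_tissue",
    "fdr_adjust",
    "extent_of_resection",
    "linear_regression",
    "km_logrank",
]


@dataclass
class LmeResult:
    fixed_effect_estimate: float
    standard_error: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    participant_random_intercept_sd: float


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


@dataclass
class KmResult:
    survival: dict  # group -> DataFrame(time, survival)
    median: dict  # group -> float (inf when not reached)
    logrank_chi2: float
    logrank_p: float
    median_followup: float | None = None

    def median_label(self, group) -> str:
        m = self.median[group]
        return "not reached" if np.isinf(m) else f"{m:g}"


def fit_lme_tissue(
    table: pd.DataFrame,
    value_col: str = "hgp",
    group_col: str = "participant",
    tissue_col: str = "tissue",
) -> LmeResult:
    """Random-intercept mixed model of channel HGp on tissue label.

    Tissue (tumour vs non_tumour) enters as a fixed effect with
    ``non_tumour`` as the reference level; participants are random
    intercepts; the model is fit by REML.  The tissue effect is reported
    as a Wald F (1 numerator df) with between-within denominator df
    n_obs - n_participants - 1.
    """
    import statsmodels.formula.api as smf

    participants = table[group_col].unique()
    tissues = table[tissue_col].unique()
    if len(participants) < 2:
        raise ValueError("need >= 2 participants for a mixed model")
    if len(tissues) < 2:
        raise ValueError("need both tissue labels present")
    df = table.rename(
        columns={value_col: "_y", group_col: "_grp", tissue_col: "_tissue"}
    ).copy()
    df["_tissue"] = pd.Categorical(
        df["_tissue"], categories=["non_tumour", "tumour"], ordered=True
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("_y ~ _tissue", df, groups=df["_grp"])
        fit = None
        last_err: Exception | None = None
        # small samples with near-zero random-effect variance can make a
        # single optimizer's Hessian singular; fall back through methods
        for method in ("bfgs", "lbfgs", "powell", "nm"):
            try:
                fit = model.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_err = exc
        if fit is None:
            raise RuntimeError(f"mixed model did not converge: {last_err}")
    name = [n for n in fit.params.index if "tumour" in n and "Group" not in n][0]
    est = float(fit.params[name])
    se = float(fit.bse[name])
    n_obs = len(df)
    df_den = n_obs - len(participants) - 1
    f_stat = (est / se) ** 2
    p = float(sstats.f.sf(f_stat, 1, df_den))
    re_var = float(np.asarray(fit.cov_re)[0, 0])
    return LmeResult(
        fixed_effect_estimate=est,
        standard_error=se,
        f_stat=float(f_stat),
        df_num=1,
        df_den=int(df_den),
        p_value=p,
        participant_random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, <= 1)."""
    from statsmodels.stats.multitest import fdrcorrection

    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    _, adj = fdrcorrection(p, alpha=0.05, method="indep")
    return adj


def extent_of_resection(pre_volume_cm3: float, post_volume_cm3: float) -> float:
    """Volumetric extent of resection: (pre - post) / pre x 100%."""
    if pre_volume_cm3 <= 0:
        raise ValueError("pre-operative volume must be positive")
    if post_volume_cm3 < 0 or post_volume_cm3 > pre_volume_cm3:
        raise ValueError("post-operative volume must lie in [0, pre-operative volume]")
    return (pre_volume_cm3 - post_volume_cm3) / pre_volume_cm3 * 100.0


def linear_regression(x, y) -> RegressionResult:
    """OLS of y on x with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 points")
    if np.all(x == x[0]):
        raise ValueError("predictor is constant")
    res = sstats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
    )


def km_logrank(
    cohort: pd.DataFrame,
    time_col: str = "time_weeks",
    event_col: str = "event",
    group_col: str = "group",
    reverse_km_followup: bool = False,
) -> KmResult:
    """Kaplan-Meier curves per group with a two-tailed log-rank test.

    The per-group median is the earliest time at which the product-limit
    survival estimate drops to <= 0.5 (infinity when never reached).
    ``reverse_km_followup`` additionally reports the median follow-up by
    the reverse Kaplan-Meier method (censoring flags inverted).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    t = cohort[time_col].to_numpy(float)
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    e = cohort[event_col].to_numpy(bool)
    g = cohort[group_col].to_numpy()
    groups = pd.unique(g)
    if any((g == grp).sum() == 0 for grp in groups) or len(groups) == 0:
        raise ValueError("empty group")
    survival, median = {}, {}
    for grp in groups:
        m = g == grp
        kmf = KaplanMeierFitter().fit(t[m], e[m])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        survival[grp] = sf
        median[grp] = float(kmf.median_survival_time_)
    if e.sum() == 0:
        chi2, p = 0.0, 1.0
    else:
        res = multivariate_logrank_test(t, g, e)
        chi2, p = float(res.test_statistic), float(res.p_value)
    followup = None
    if reverse_km_followup:
        kmf = KaplanMeierFitter().fit(t, ~e)
        followup = float(kmf.median_survival_time_)
    return KmResult(
        survival=survival,
        median=median,
        logrank_chi2=chi2,
        logrank_p=p,
        median_followup=followup,
    )
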