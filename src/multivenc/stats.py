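"""Coupling regression, Bland-Altman/RPC, ICC, Pearson matrices, LME.

The central physiological statistic is the regression of spinal-canal CSF
pulsatile volume change on net transcranial blood volume change
(deltaV_SC ~ deltaV(tCBF - tJBF)); agreement and repeatability across scan
types use Bland-Altman bias/limits with the repeatability coefficient
RPC = 1.96 * sd(d/m) * 100 (differences as proportions of pair means), and
the intra-class correlation ICC = var_between / (var_between + var_error)
computed from REML mixed-model variance components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CouplingFit",
    "AgreementStats",
    "coupling_regression",
    "bland_altman",
    "icc",
    "pearson_matrix",
    "lme_variance_components",
]


@dataclass(frozen=True)
class CouplingFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class AgreementStats:
    bias: float
    loa_low: float
    loa_high: float
    rpc_percent: float
    rpc_percent_population: float  # same with ddof=0, reported alongside
    n_pairs: int


def coupling_regression(x, y) -> CouplingFit:
    """OLS regression of CSF deltaV on net blood deltaV.

    Returns slope, intercept, R^2, and the two-sided slope p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = sps.linregress(x, y)
    return CouplingFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), p_value=float(res.pvalue), n=int(x.size),
    )


def bland_altman(y1, y2) -> AgreementStats:
    """Bland-Altman agreement with the repeatability coefficient.

    ``bias = mean(d)``, limits of agreement ``bias +/- 1.96 sd(d)`` with the
    sample (n-1) standard deviation, and
    ``RPC = 1.96 * sd(d/m) * 100`` where ``d = y1 - y2`` and
    ``m = (y1 + y2)/2``.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if y1.size != y2.size or y1.size < 2:
        raise ValueError("need >= 2 pairs of equal length")
    m = (y1 + y2) / 2.0
    if np.any(m == 0):
        raise ValueError("pair mean of zero; RPC undefined")
    d = y1 - y2
    sd = d.std(ddof=1)
    prop = d / m
    return AgreementStats(
        bias=float(d.mean()),
        loa_low=float(d.mean() - 1.96 * sd),
        loa_high=float(d.mean() + 1.96 * sd),
        rpc_percent=float(1.96 * prop.std(ddof=1) * 100.0),
        rpc_percent_population=float(1.96 * prop.std(ddof=0) * 100.0),
        n_pairs=int(y1.size),
    )


def icc(var_between: float, var_error: float) -> float:
    """Intra-class correlation: var_between / (var_between + var_error)."""
    if var_between < 0 or var_error < 0:
        raise ValueError("variances must be nonnegative")
    if var_between == 0 and var_error == 0:
        raise ValueError("both variance components are zero")
    return var_between / (var_between + var_error)


def pearson_matrix(table: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pearson correlation matrix across columns (scan types / repeats)."""
    table = pd.DataFrame(table)
    n = table.notna().astype(int).T @ table.notna().astype(int)
    if (np.asarray(n) < min_pairs).any():
        raise ValueError(f"need >= {min_pairs} paired observations per cell")
    return table.corr(method="pearson")


def lme_variance_components(
    table: pd.DataFrame,
    value_col: str = "value",
    participant_col: str = "participant",
    scan_type_col: str = "scan_type",
    hr_col: str = "heart_rate",
    reference_scan_type: str | None = None,
) -> dict:
    """REML linear mixed model: fixed scan-type + heart-rate effects,
    random intercepts per participant.

    Fitting is delegated to statsmodels MixedLM; the returned dict carries
    the participant-intercept variance, residual variance, fixed-effect
    coefficients with 95% CIs, and the ICC computed from the components.
    A singular fit produces a warning, not an error.
    """
    import warnings

    import statsmodels.formula.api as smf

    df = table.rename(
        columns={value_col: "value", participant_col: "participant",
                 scan_type_col: "scan_type", hr_col: "heart_rate"}
    ).copy()
    if df["participant"].nunique() < 2:
        raise ValueError("need >= 2 participants with repeats")
    if reference_scan_type is not None:
        levels = [reference_scan_type] + sorted(
            set(df["scan_type"]) - {reference_scan_type}
        )
        df["scan_type"] = pd.Categorical(df["scan_type"], categories=levels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ C(scan_type) + heart_rate", df,
                            groups=df["participant"])
        fit = model.fit(reml=True)
    var_between = float(np.asarray(fit.cov_re)[0, 0])
    var_error = float(fit.scale)
    ci = fit.conf_int()
    fixed = {
        name: {
            "estimate": float(fit.params[name]),
            "se": float(fit.bse[name]),
            "ci_low": float(ci.loc[name, 0]),
            "ci_high": float(ci.loc[name, 1]),
            "p_value": float(fit.pvalues[name]),
        }
        for name in fit.fe_params.index
    }
    return {
        "var_participant": var_between,
        "var_residual": var_error,
        "icc": icc(var_between, var_error),
        "fixed_effects": fixed,
        "converged": bool(fit.converged),
    }
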