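"""Lesion- and patient-level statistics for the chronic-lesion cohort.

Covers the 2x2 SEL-by-rim cross-tabulation (chi-square with Yates
continuity correction), patient stratification, confirmed disability
progression, Spearman and partial Spearman correlations, mixed-effects
disability models with metric-by-time interactions, Poisson/linear models
for lesion counts and log-volumes, and logistic models of progression risk.

Percentages in summary tables are rounded half-up to integers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps


class Stratum(str, Enum):
    SEL_PRL_BOTH = "SEL_PRL_BOTH"  # >= 1 SEL and >= 1 PRL
    SEL_ONLY = "SEL_ONLY"  # >= 1 SEL, 0 PRLs
    SEL_NEG = "SEL_NEG"  # 0 SELs (PRL status pooled)


class ModelKind(str, Enum):
    MIXED = "MIXED"
    POISSON = "POISSON"
    LINEAR = "LINEAR"
    LOGISTIC = "LOGISTIC"
    CHI2 = "CHI2"
    SPEARMAN = "SPEARMAN"


@dataclass
class ModelResult:
    """Uniform container for fitted terms: beta, 95% CI, p-value."""

    kind: ModelKind
    terms: pd.DataFrame  # columns: term, beta, ci_low, ci_high, p
    flags: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.terms
        ok = (t["ci_low"] <= t["beta"] + 1e-12) & (t["beta"] <= t["ci_high"] + 1e-12)
        bad = t.loc[~ok & t[["ci_low", "ci_high"]].notna().all(axis=1)]
        if len(bad):
            raise ValueError(f"CI does not bracket beta for terms: {list(bad['term'])}")

    def term(self, name: str) -> pd.Series:
        row = self.terms.loc[self.terms["term"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def _terms_frame(rows: List[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["term", "beta", "ci_low", "ci_high", "p"])


def round_half_up_percent(fraction: float) -> int:
    """Integer percent with exact half-up rounding (91.8 -> 92, 50.8 -> 51)."""
    return int(math.floor(fraction * 100.0 + 0.5))


# ---------------------------------------------------------------------------
# lesion-level cross-tabulation
# ---------------------------------------------------------------------------

def crosstab_sel_prl(
    lesions: pd.DataFrame,
) -> Tuple[pd.DataFrame, ModelResult]:
    """2x2 table of SEL status against rim status, with Yates chi-square.

    ``lesions`` needs boolean columns ``is_sel`` and ``is_prl``. Row
    proportions give the share of each lesion type carrying a rim. With an
    empty margin the chi-square is skipped (flagged) but the table is still
    returned.
    """
    is_sel = lesions["is_sel"].astype(bool)
    is_prl = lesions["is_prl"].astype(bool)
    counts = np.array(
        [
            [int((is_sel & is_prl).sum()), int((is_sel & ~is_prl).sum())],
            [int((~is_sel & is_prl).sum()), int((~is_sel & ~is_prl).sum())],
        ]
    )
    table = pd.DataFrame(
        counts, index=["SEL", "non-SEL"], columns=["PRL", "no PRL"]
    )
    row_tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        table["prop_PRL"] = np.where(row_tot > 0, counts[:, 0] / row_tot, np.nan)

    flags: Dict[str, object] = {}
    if np.any(counts.sum(axis=0) == 0) or np.any(row_tot == 0):
        flags["chi2_skipped"] = "empty margin"
        beta = ci_low = ci_high = p = math.nan
    else:
        chi2, p, _, _ = sps.chi2_contingency(counts, correction=True)
        beta, ci_low, ci_high = chi2, math.nan, math.nan
        flags["continuity_correction"] = True
    result = ModelResult(
        kind=ModelKind.CHI2,
        terms=_terms_frame(
            [{"term": "chi2", "beta": beta, "ci_low": ci_low, "ci_high": ci_high,
              "p": p}]
        ),
        flags=flags,
    )
    return table, result


# ---------------------------------------------------------------------------
# patient stratification and progression
# ---------------------------------------------------------------------------

def assign_stratum(has_sel: bool, has_prl: bool) -> Stratum:
    if has_sel and has_prl:
        return Stratum.SEL_PRL_BOTH
    if has_sel:
        return Stratum.SEL_ONLY
    return Stratum.SEL_NEG  # PRL subsets pooled among SEL-negative patients


def stratify_patients(patients: pd.DataFrame) -> Tuple[pd.DataFrame, pd.Series]:
    """Set the stratum per patient from ``has_sel`` / ``has_prl`` flags.

    Returns the patients frame with a ``stratum`` column plus the stratum
    counts (every patient in exactly one stratum).
    """
    out = patients.copy()
    out["stratum"] = [
        assign_stratum(bool(s), bool(p)).value
        for s, p in zip(out["has_sel"], out["has_prl"])
    ]
    counts = out["stratum"].value_counts().reindex(
        [s.value for s in Stratum], fill_value=0
    )
    return out, counts


def cdp_flag(
    visits: Sequence[Tuple[float, float]],
    confirmation_window: float = 0.5,
) -> Optional[bool]:
    """Confirmed disability progression from a time-ordered EDSS series.

    The qualifying change from baseline is >= 1.5 when baseline EDSS is 0,
    else >= 1.0. It must be reached at the final-scan visit (the last visit
    that still has a confirmation assessment >= ``confirmation_window``
    years later) and sustained at that confirmation visit. Returns ``None``
    (undetermined) when no confirmation assessment exists.
    """
    if len(visits) < 2:
        return None
    times = [t for t, _ in visits]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("visits must be time-ordered")
    base_t, base_e = visits[0]
    threshold = 1.5 if base_e == 0 else 1.0

    final_idx = None
    for i in range(len(visits) - 1, 0, -1):
        t_i = visits[i][0]
        if any(t_j >= t_i + confirmation_window for t_j, _ in visits[i + 1:]):
            final_idx = i
            break
    if final_idx is None:
        return None
    t_f, e_f = visits[final_idx]
    conf = next(v for v in visits[final_idx + 1:] if v[0] >= t_f + confirmation_window)
    reached = (e_f - base_e) >= threshold
    sustained = (conf[1] - base_e) >= threshold
    return bool(reached and sustained)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _rho_ci(rho: float, n: int, n_controls: int = 0) -> Tuple[float, float]:
    # Fisher z interval; degrees of freedom reduced by controlled variables
    if abs(rho) >= 1 or n - n_controls < 4:
        return (math.nan, math.nan)
    z = math.atanh(rho)
    se = 1.0 / math.sqrt(n - n_controls - 3)
    return (math.tanh(z - 1.959963984540054 * se), math.tanh(z + 1.959963984540054 * se))


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> ModelResult:
    """Spearman rank correlation with a Fisher-z 95% interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    flags: Dict[str, object] = {}
    if np.all(x == x[0]) or np.all(y == y[0]):
        flags["undefined"] = "constant vector"
        rho = p = math.nan
        ci = (math.nan, math.nan)
    else:
        rho, p = sps.spearmanr(x, y)
        ci = _rho_ci(rho, len(x))
    return ModelResult(
        kind=ModelKind.SPEARMAN,
        terms=_terms_frame(
            [{"term": "rho", "beta": rho, "ci_low": ci[0], "ci_high": ci[1], "p": p}]
        ),
        flags=flags,
    )


def partial_spearman(
    x: Sequence[float], y: Sequence[float], control: Sequence[float]
) -> ModelResult:
    """Partial Spearman correlation by the rank-residual method.

    Ranks of x and y are each regressed on the ranks of the control
    variable; the Pearson correlation of the residuals is reported with a
    t-test on n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(control, dtype=float)
    n = len(x)
    if not (len(y) == n and len(c) == n) or n < 5:
        raise ValueError("need equal-length vectors with n >= 5")
    flags: Dict[str, object] = {}
    if np.all(x == x[0]) or np.all(y == y[0]) or np.all(c == c[0]):
        flags["undefined"] = "constant vector"
        return ModelResult(
            kind=ModelKind.SPEARMAN,
            terms=_terms_frame(
                [{"term": "rho_partial", "beta": math.nan, "ci_low": math.nan,
                  "ci_high": math.nan, "p": math.nan}]
            ),
            flags=flags,
        )
    rx, ry, rc = (sps.rankdata(v) for v in (x, y, c))
    design = np.column_stack([np.ones(n), rc])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    rho = float(np.corrcoef(res_x, res_y)[0, 1])
    df = n - 3
    t = rho * math.sqrt(df / max(1e-12, 1 - rho**2))
    p = float(2 * sps.t.sf(abs(t), df))
    ci = _rho_ci(rho, n, n_controls=1)
    return ModelResult(
        kind=ModelKind.SPEARMAN,
        terms=_terms_frame(
            [{"term": "rho_partial", "beta": rho, "ci_low": ci[0], "ci_high": ci[1],
              "p": p}]
        ),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# regression models
# ---------------------------------------------------------------------------

DEFAULT_COVARIATES = ("age_baseline", "sex", "relapse_rate", "log_tlv", "treated_end")


def _result_from_params(
    kind: ModelKind,
    params: pd.Series,
    conf: pd.DataFrame,
    pvals: pd.Series,
    flags: Dict[str, object],
) -> ModelResult:
    rows = [
        {
            "term": name,
            "beta": float(params[name]),
            "ci_low": float(conf.loc[name, 0]),
            "ci_high": float(conf.loc[name, 1]),
            "p": float(pvals[name]),
        }
        for name in params.index
    ]
    return ModelResult(kind=kind, terms=_terms_frame(rows), flags=flags)


def fit_edss_mixed(
    visits_long: pd.DataFrame,
    metric: str,
    covariates: Sequence[str] = (),
) -> ModelResult:
    """Linear mixed model of per-visit EDSS with a metric-by-time interaction.

    ``visits_long`` is one row per visit: ``patient_id``, ``time`` (years
    from baseline), ``edss``, the metric column and any covariates. A random
    intercept is fitted per patient (REML).

    For ``metric == "stratum"`` the slopes use cell-means coding
    (``C(stratum) + C(stratum):time``) so each stratum's time coefficient is
    that stratum's EDSS slope in points/year — directly comparable with a
    generating slope. Numeric metrics use ``metric + time + metric:time``.
    """
    df = visits_long.copy()
    cov = " + ".join(covariates)
    cov = f" + {cov}" if cov else ""
    if metric == "stratum":
        formula = f"edss ~ C(stratum) + C(stratum):time{cov} - 1"
    else:
        formula = f"edss ~ {metric} + time + {metric}:time{cov}"
    flags: Dict[str, object] = {"formula": formula}
    model = smf.mixedlm(formula, df, groups=df["patient_id"])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=True, method="lbfgs")
        except (np.linalg.LinAlgError, ValueError) as exc:
            flags["singular"] = str(exc)
            return ModelResult(kind=ModelKind.MIXED, terms=_terms_frame([]), flags=flags)
    if not fit.converged:
        flags["not_converged"] = True
    params = fit.params.drop(labels=["Group Var"], errors="ignore")
    conf = fit.conf_int().loc[params.index]
    pvals = fit.pvalues.loc[params.index]
    return _result_from_params(ModelKind.MIXED, params, conf, pvals, flags)


def slope_term_name(stratum: Stratum) -> str:
    """Name of the cell-means slope coefficient for one stratum."""
    return f"C(stratum)[{stratum.value}]:time"


def fit_count_model(
    patients: pd.DataFrame,
    count_col: str,
    predictors: Sequence[str] = (),
) -> ModelResult:
    """Poisson log-link regression for per-patient lesion counts."""
    y = patients[count_col].to_numpy()
    flags: Dict[str, object] = {}
    if np.all(y == 0):
        flags["degenerate"] = "all counts zero"
        return ModelResult(kind=ModelKind.POISSON, terms=_terms_frame([]), flags=flags)
    rhs = " + ".join(predictors) if predictors else "1"
    fit = smf.glm(
        f"{count_col} ~ {rhs}", patients, family=sm.families.Poisson()
    ).fit()
    return _result_from_params(
        ModelKind.POISSON, fit.params, fit.conf_int(), fit.pvalues, flags
    )


def fit_volume_model(
    patients: pd.DataFrame,
    volume_col: str,
    predictors: Sequence[str] = (),
) -> ModelResult:
    """OLS on log-transformed volumes; zero volumes excluded and counted.

    Residual normality (Shapiro-Wilk) is reported in the flags.
    """
    df = patients.copy()
    nonzero = df[volume_col] > 0
    flags: Dict[str, object] = {"n_zero_excluded": int((~nonzero).sum())}
    df = df.loc[nonzero].copy()
    if len(df) < 3:
        flags["degenerate"] = "too few positive volumes"
        return ModelResult(kind=ModelKind.LINEAR, terms=_terms_frame([]), flags=flags)
    df["_logvol"] = np.log(df[volume_col])
    rhs = " + ".join(predictors) if predictors else "1"
    fit = smf.ols(f"_logvol ~ {rhs}", df).fit()
    flags["r_squared"] = float(fit.rsquared) if fit.df_model > 0 else math.nan
    resid = np.asarray(fit.resid)
    if len(resid) >= 3 and np.ptp(resid) > 0:
        w, p_norm = sps.shapiro(resid)
        flags["shapiro_w"], flags["shapiro_p"] = float(w), float(p_norm)
    return _result_from_params(
        ModelKind.LINEAR, fit.params, fit.conf_int(), fit.pvalues, flags
    )


def fit_count_and_volume_models(
    patients: pd.DataFrame,
    count_col: str = "sel_count",
    volume_col: str = "sel_volume_ml",
    predictors: Sequence[str] = (),
) -> List[ModelResult]:
    """Poisson model for counts plus log-volume OLS, as a pair."""
    return [
        fit_count_model(patients, count_col, predictors),
        fit_volume_model(patients, volume_col, predictors),
    ]


def fit_cdp_logistic(
    patients: pd.DataFrame,
    predictor: str,
    covariates: Sequence[str] = (),
) -> ModelResult:
    """Logistic model of confirmed progression; odds ratios with 95% CI."""
    df = patients.loc[patients["cdp"].notna()].copy()
    y = df["cdp"].astype(int)
    flags: Dict[str, object] = {"n": int(len(df))}
    if y.nunique() < 2:
        flags["degenerate"] = "needs >= 1 event and >= 1 non-event"
        return ModelResult(kind=ModelKind.LOGISTIC, terms=_terms_frame([]), flags=flags)
    rhs = " + ".join([predictor, *covariates])
    df["cdp"] = y
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.logit(f"cdp ~ {rhs}", df).fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparationError and kin
            flags["separation"] = str(exc)
            return ModelResult(
                kind=ModelKind.LOGISTIC, terms=_terms_frame([]), flags=flags
            )
    if not fit.mle_retvals.get("converged", True) or np.any(
        np.abs(fit.params) > 15
    ):
        flags["separation"] = "non-converged or extreme coefficients"
    with np.errstate(over="ignore"):
        params = np.exp(fit.params)  # odds ratios
        conf = np.exp(fit.conf_int())
    return _result_from_params(
        ModelKind.LOGISTIC, params, conf, fit.pvalues, flags
    )


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------

def cohort_summary(
    patients: pd.DataFrame, lesions: pd.DataFrame
) -> Dict[str, object]:
    """Headline cohort numbers: counts, ratios and half-up integer percents.

    Patient flags come from ``has_sel`` / ``has_prl``; lesion flags from
    ``is_sel`` / ``is_prl``. An empty cohort yields an empty report.
    """
    report: Dict[str, object] = {}
    if len(lesions):
        n = len(lesions)
        n_sel = int(lesions["is_sel"].sum())
        n_prl = int(lesions["is_prl"].sum())
        n_both = int((lesions["is_sel"] & lesions["is_prl"]).sum())
        report.update(
            n_lesions=n,
            n_sel=n_sel,
            n_prl=n_prl,
            n_sel_and_prl=n_both,
            sel_over_total=n_sel / n,
            prl_over_total=n_prl / n,
            pct_lesions_sel=round_half_up_percent(n_sel / n),
            pct_lesions_prl=round_half_up_percent(n_prl / n),
        )
        if n_prl:
            report["pct_prl_that_are_sel"] = round_half_up_percent(n_both / n_prl)
        if n_sel:
            report["pct_sel_that_are_prl"] = round_half_up_percent(n_both / n_sel)
        if n - n_sel:
            report["pct_nonsel_that_are_prl"] = round_half_up_percent(
                (n_prl - n_both) / (n - n_sel)
            )
    if len(patients):
        m = len(patients)
        has_sel = patients["has_sel"].astype(bool)
        has_prl = patients["has_prl"].astype(bool)
        report.update(
            n_patients=m,
            n_patients_sel=int(has_sel.sum()),
            n_patients_prl=int(has_prl.sum()),
            n_patients_both=int((has_sel & has_prl).sum()),
            pct_patients_sel=round_half_up_percent(has_sel.mean()),
            pct_patients_prl=round_half_up_percent(has_prl.mean()),
            pct_patients_both=round_half_up_percent((has_sel & has_prl).mean()),
        )
    return report
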