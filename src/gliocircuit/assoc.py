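"""Regression layer linking electrophysiology, connectivity and outcomes.

Three model families:

* the 2-contrast x 7-network grid of linear mixed-effects models relating
  each electrode's percentage signal change (response) to its median network
  connectivity (fixed effect) with a participant random intercept; the fixed
  effect is tested with a Type II Wald chi-square on 1 df, computed as
  (estimate / SE)^2 against chi2(1);
* the tumour-location model: mean tumour-network connectivity regressed on
  location, hemisphere, network overlap, age, gender and antiseizure
  medication;
* the outcome models: latest follow-up attention score regressed on the
  pre-operative score, pre-operative tumour-network connectivity, location,
  hemisphere, age, gender and assessment timepoint, with an optional
  sensitivity filter dropping patients whose latest assessment was
  immediately post-operative.

Estimates in the cohort models are standardized by scaling the response and
continuous predictors to unit sample SD; dummy-coded categorical terms stay
0/1 (reference levels: frontal location, left hemisphere, no antiseizure
medication, female, month-12 timepoint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sst
import statsmodels.api as sm

from .errors import DegenerateInputError

NETWORK_NAMES = ("VN", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")


@dataclass
class ModelReport:
    """Fitted-model summary: per-term estimates and headline statistics."""

    response: str
    model_type: str  # 'ols' | 'mixed'
    terms: pd.DataFrame  # term, estimate, se, statistic, p
    n_used: int
    extra: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        hit = self.terms[self.terms["term"] == name]
        if not len(hit):
            raise KeyError(f"no term {name!r} in report for {self.response!r}")
        return hit.iloc[0]


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateInputError(f"cannot standardise constant column {x.name!r}")
    return (x - x.mean()) / sd


def _dummies(values: pd.Series, name: str, reference: str) -> pd.DataFrame:
    """0/1 columns named ``name[level]`` for every non-reference level present."""
    levels = [l for l in pd.unique(values) if l != reference]
    return pd.DataFrame(
        {f"{name}[{level}]": (values == level).astype(float) for level in sorted(map(str, levels))},
        index=values.index,
    )


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify aliased columns by pivoting through QR
        q, r = np.linalg.qr(arr)
        aliased = [X.columns[j] for j in range(arr.shape[1]) if abs(r[j, j]) < 1e-8]
        raise DegenerateInputError(f"design matrix is rank deficient; aliased terms: {aliased}")


def _ols_report(y: pd.Series, X: pd.DataFrame, response: str, extra=None) -> ModelReport:
    _check_rank(X)
    fit = sm.OLS(y.to_numpy(dtype=float), X.to_numpy(dtype=float)).fit()
    terms = pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate": fit.params,
            "se": fit.bse,
            "statistic": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return ModelReport(response=response, model_type="ols", terms=terms,
                       n_used=int(fit.nobs), extra=dict(extra or {}))


# ---------------------------------------------------------------------------
# mixed-effects PSC ~ FC grid


def fit_psc_fc(rows: pd.DataFrame, force_zero_group_variance: bool = False) -> ModelReport:
    """One linear mixed model psc ~ fc with a participant random intercept.

    ``force_zero_group_variance`` pins the random-intercept variance at zero
    (a diagnostic mode in which the fixed-effect estimate must collapse to
    the ordinary pooled regression slope).
    """
    rows = rows.dropna(subset=["psc", "fc", "participant"])
    participants = rows["participant"].unique()
    if len(participants) < 2:
        raise DegenerateInputError("mixed model needs >= 2 participants")
    if (rows.groupby("participant").size() < 2).any():
        raise DegenerateInputError("every participant needs >= 2 electrodes")
    endog = rows["psc"].to_numpy(dtype=float)
    exog = sm.add_constant(rows["fc"].to_numpy(dtype=float))
    flags = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if force_zero_group_variance:
            # at tau^2 = 0 the mixed likelihood factorises into the pooled
            # ordinary least-squares problem; profile it exactly
            ols = sm.OLS(endog, exog).fit()
            est, se = ols.params[1], ols.bse[1]
            chi2 = (est / se) ** 2
            terms = pd.DataFrame(
                {
                    "term": ["const", "fc"],
                    "estimate": ols.params,
                    "se": ols.bse,
                    "statistic": ols.params / ols.bse,
                    "p": [np.nan, float(sst.chi2.sf(chi2, df=1))],
                }
            )
            return ModelReport(
                response="psc",
                model_type="mixed",
                terms=terms,
                n_used=len(rows),
                extra={"wald_chi2": float(chi2), "chi2_df": 1,
                       "chi2_p": float(sst.chi2.sf(chi2, df=1)),
                       "random_intercept_var": 0.0},
                flags=["random-intercept variance fixed at 0"],
            )
        model = sm.MixedLM(endog, exog, groups=rows["participant"].to_numpy())
        try:
            fit = model.fit(reml=True)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=True, method="powell")
            flags.append("refit: powell after singular gradient step")
        for w in caught:
            if "converge" in str(w.message).lower() or "singular" in str(w.message).lower():
                flags.append(f"fit-warning: {w.category.__name__}")
    est, se = fit.fe_params[1], fit.bse_fe[1]
    chi2 = (est / se) ** 2
    terms = pd.DataFrame(
        {
            "term": ["const", "fc"],
            "estimate": fit.fe_params,
            "se": fit.bse_fe,
            "statistic": fit.fe_params / fit.bse_fe,
            "p": [np.nan, float(sst.chi2.sf(chi2, df=1))],
        }
    )
    return ModelReport(
        response="psc",
        model_type="mixed",
        terms=terms,
        n_used=len(rows),
        extra={
            "wald_chi2": float(chi2),
            "chi2_df": 1,
            "chi2_p": float(sst.chi2.sf(chi2, df=1)),
            "random_intercept_var": float(np.asarray(fit.cov_re).ravel()[0]),
        },
        flags=sorted(set(flags)),
    )


def fit_psc_fc_grid(
    rows: pd.DataFrame,
    networks=None,
    contrasts=None,
) -> dict:
    """The full contrasts x networks grid of mixed models.

    ``rows`` is long format with columns participant, electrode, contrast,
    network, psc, fc.  Returns {(contrast, network): ModelReport} with exactly
    len(contrasts) * len(networks) entries; singular or non-converged fits are
    flagged, never dropped.
    """
    networks = list(networks) if networks is not None else sorted(rows["network"].unique())
    contrasts = list(contrasts) if contrasts is not None else sorted(rows["contrast"].unique())
    reports = {}
    for contrast in contrasts:
        for network in networks:
            cell = rows[(rows["contrast"] == contrast) & (rows["network"] == network)]
            reports[(contrast, network)] = fit_psc_fc(cell)
    assert len(reports) == len(contrasts) * len(networks)
    return reports


def grid_table(reports: dict) -> pd.DataFrame:
    """Flatten a model grid into one row per (contrast, network)."""
    rows = []
    for (contrast, network), rep in reports.items():
        fc = rep.term("fc")
        rows.append(
            {
                "contrast": contrast,
                "network": network,
                "estimate": fc["estimate"],
                "se": fc["se"],
                "wald_chi2": rep.extra["wald_chi2"],
                "p": rep.extra["chi2_p"],
                "n": rep.n_used,
                "flags": ";".join(rep.flags),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort models


def fit_location_model(cohort: pd.DataFrame) -> ModelReport:
    """Tumour-network connectivity regressed on location and covariates."""
    df = cohort.dropna(
        subset=["tumour_network_connectivity", "location", "hemisphere",
                "overlap_with_network", "antiseizure", "age", "gender"]
    ).copy()
    if df["location"].nunique() < 2:
        raise DegenerateInputError("need >= 2 tumour location levels to model location")
    y = _zscore(df["tumour_network_connectivity"])
    X = pd.concat(
        [
            _dummies(df["location"], "location", reference="frontal"),
            _dummies(df["hemisphere"], "hemisphere", reference="left"),
            _zscore(df["overlap_with_network"].astype(float)).rename("overlap_with_network"),
            _dummies(df["antiseizure"], "antiseizure", reference="no"),
            _zscore(df["age"].astype(float)).rename("age"),
            _dummies(df["gender"], "gender", reference="female"),
        ],
        axis=1,
    )
    X.insert(0, "intercept", 1.0)
    return _ols_report(y, X, response="tumour_network_connectivity")


def fit_outcome_model(
    cohort: pd.DataFrame,
    outcome_col: str = "followup_score",
    sensitivity: bool = False,
) -> ModelReport:
    """Latest follow-up score regressed on pre-op score, connectivity and
    covariates; ``sensitivity`` drops patients whose latest assessment was
    immediately post-operative (< 3 months)."""
    needed = [outcome_col, "preop_score", "tumour_network_connectivity", "location",
              "hemisphere", "age", "gender", "latest_timepoint"]
    df = cohort.dropna(subset=needed).copy()
    if sensitivity:
        df = df[df["latest_timepoint"] != "post-op"]
    if len(df) < 8:
        raise DegenerateInputError(
            f"only {len(df)} complete rows after filtering; need >= 8"
        )
    y = _zscore(df[outcome_col])
    X = pd.concat(
        [
            _zscore(df["preop_score"].astype(float)).rename("preop_score"),
            _zscore(df["tumour_network_connectivity"].astype(float)).rename(
                "tumour_network_connectivity"
            ),
            _dummies(df["location"], "location", reference="frontal"),
            _dummies(df["hemisphere"], "hemisphere", reference="left"),
            _dummies(df["latest_timepoint"], "timepoint", reference="month 12"),
            _zscore(df["age"].astype(float)).rename("age"),
            _dummies(df["gender"], "gender", reference="female"),
        ],
        axis=1,
    )
    X.insert(0, "intercept", 1.0)
    return _ols_report(
        y, X, response=outcome_col, extra={"sensitivity": sensitivity}
    )
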