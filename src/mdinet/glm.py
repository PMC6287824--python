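"""Per-metabolite covariate-adjusted group comparison (ANCOVA).

Case and control cohorts in observational metabolomics are rarely matched
for age and sex, and both covariates shift metabolite levels.  Each
feature is therefore fitted with an ordinary least-squares linear model
``intensity ~ group + age + sex``; the group contrast is evaluated on
least-squares means — model predictions at the mean age with the two sexes
weighted equally — so that the comparison is freed from the cohorts'
covariate imbalance.  An interaction screen (group x age, group x sex)
runs first to flag features whose group effect is covariate-dependent.

With exactly two groups the Dunnett many-to-one adjustment is the
identity (a single comparison), so the reported contrast p-value is the
unadjusted LS-mean difference test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = ["GlmResult", "fit_ancova", "fit_ancova_many", "interaction_screen"]


@dataclass
class GlmResult:
    feature_id: str
    lsmean_control: float
    lsmean_case: float
    contrast: float                 # case - control LS-mean difference
    p_value: float                  # group contrast
    p_gxage: float
    p_gxsex: float
    coefficients: pd.Series
    dropped_terms: tuple[str, ...] = ()

    @property
    def direction(self) -> str:
        return "up" if self.contrast >= 0 else "down"


def _design(group, age, sex):
    """Main-effects design matrix: intercept, case indicator, age, female
    indicator.  Constant columns are dropped (singular otherwise)."""
    is_case = (np.asarray(group) == "case").astype(float)
    is_f = (np.asarray(sex) == "f").astype(float)
    age = np.asarray(age, dtype=float)
    cols = {"const": np.ones(len(is_case)), "case": is_case,
            "age": age, "female": is_f}
    dropped = tuple(k for k in ("age", "female") if np.ptp(cols[k]) == 0)
    for k in dropped:
        del cols[k]
    return pd.DataFrame(cols), dropped


def fit_ancova(y, group, age, sex, feature_id: str = "") -> GlmResult:
    """OLS ANCOVA of one feature with LS-means and interaction screen.

    The interaction model (adding group:age and group:sex) is fitted first
    purely to extract interaction p-values; the group contrast itself comes
    from the main-effects model, as LS-means at mean age and a 50/50 sex
    mix.  For the main-effects parametrisation that contrast equals the
    ``case`` coefficient, and its t-test is the contrast test.
    """
    y = np.asarray(y, dtype=float)
    Xm, dropped = _design(group, age, sex)
    n_params = Xm.shape[1] + 2
    if len(y) < n_params + 2:
        raise ValueError(f"need at least {n_params + 2} samples, got {len(y)}")
    if len(np.unique(group)) < 2:
        raise ValueError("both groups must be present")

    Xi = Xm.copy()
    if "age" in Xi:
        Xi["case_x_age"] = Xi["case"] * Xi["age"]
    if "female" in Xi:
        Xi["case_x_female"] = Xi["case"] * Xi["female"]
    fit_i = sm.OLS(y, Xi).fit()
    p_gxage = float(fit_i.pvalues.get("case_x_age", np.nan))
    p_gxsex = float(fit_i.pvalues.get("case_x_female", np.nan))

    fit_m = sm.OLS(y, Xm).fit()
    mean_age = float(np.mean(np.asarray(age, dtype=float)))
    ref = {"const": 1.0, "age": mean_age, "female": 0.5}
    x_ctrl = np.array([ref.get(c, 0.0) if c != "case" else 0.0 for c in Xm.columns])
    x_case = np.array([ref.get(c, 0.0) if c != "case" else 1.0 for c in Xm.columns])
    ls_ctrl = float(x_ctrl @ fit_m.params.to_numpy())
    ls_case = float(x_case @ fit_m.params.to_numpy())
    tt = fit_m.t_test(x_case - x_ctrl)
    # Dunnett adjustment over a single comparison is the identity
    p = float(np.atleast_1d(tt.pvalue)[0])
    return GlmResult(feature_id, ls_ctrl, ls_case, ls_case - ls_ctrl, p,
                     p_gxage, p_gxsex, fit_m.params, dropped)


def fit_ancova_many(X: np.ndarray, feature_ids, group, age, sex) -> pd.DataFrame:
    """Row-wise ANCOVA over a samples x features matrix; tidy result table."""
    rows = []
    for j, fid in enumerate(feature_ids):
        r = fit_ancova(X[:, j], group, age, sex, feature_id=str(fid))
        rows.append({"feature_id": r.feature_id,
                     "lsmean_control": r.lsmean_control,
                     "lsmean_case": r.lsmean_case,
                     "direction": r.direction,
                     "p_value": r.p_value,
                     "p_gxage": r.p_gxage,
                     "p_gxsex": r.p_gxsex})
    return pd.DataFrame(rows).set_index("feature_id")


def interaction_screen(results: pd.DataFrame, alpha: float = 0.05,
                       bh_correct: bool = False) -> pd.DataFrame:
    """Flag features with significant group x age / group x sex interaction.

    No multiplicity correction is applied by default; ``bh_correct``
    switches both screens to Benjamini-Hochberg-adjusted decisions.
    """
    out = results.copy()
    for col, flag in (("p_gxage", "interaction_age"), ("p_gxsex", "interaction_sex")):
        p = out[col].to_numpy()
        ok = np.isfinite(p)
        rej = np.zeros(len(p), dtype=bool)
        if alpha > 0 and ok.any():
            if bh_correct:
                rej[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
            else:
                rej[ok] = p[ok] < alpha
        out[flag] = rej
    return out
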