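"""Per-domain linear mixed models relating reorientation time to postictal
EEG restoration.

One model per cognitive domain (person, place, time). Outcome: domain time
to reorientation (minutes). Fixed effects: the EEG features (T_max,
amplitude A, time constant tau), electrical charge (mC), seizure duration
(s), midazolam administration, electrode placement (bilateral vs right
unilateral), session number, sex and age. Random effects: by-subject
intercept and by-subject slope on T_max, downgraded to intercept-only when
the full specification is singular. Estimation is REML; confidence intervals
and p-values use a Wald t approximation with df = n_obs - n_fixed.

Continuous predictors are z-scored before fitting, so reported coefficients
are minutes per standardized unit (binary predictors: minutes per level,
reference levels right-unilateral placement, no midazolam, female sex).
A raw-units mode is available via ``standardize=False``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import ConvergenceWarning
from sklearn.base import BaseEstimator

from .simulate import COVARIATES, CONTINUOUS_COVARIATES

logger = logging.getLogger(__name__)

__all__ = [
    "LMMResult",
    "DomainLMM",
    "build_session_table",
    "fit_domain_lmm",
    "vif_screen",
    "midazolam_sensitivity",
]


@dataclass
class LMMResult:
    """Fitted mixed-model summary for one domain."""

    domain: str
    coef: pd.DataFrame  # index: effect; columns: beta, se, ci_low, ci_high, p
    random_sds: dict[str, float]
    method: str  # "REML" | "OLS-degenerate"
    n_obs: int
    n_subjects: int
    vif: pd.Series
    converged: bool
    singular: bool
    fallback: str  # "", "intercept-only", "ols"
    diagnostics: dict = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return not self.converged


def build_session_table(
    features: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    rots: pd.DataFrame | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Join EEG features, covariates and ROT outcomes into one row per session.

    Inner join on ``session_id``; rows missing a domain outcome are kept here
    and dropped per-model (never globally). Continuous predictors are
    z-scored; binary predictors stay 0/1 (reference: right-unilateral
    placement, no midazolam, female).

    Raises
    ------
    ValueError
        On duplicate session_id in any input (data-integrity error).
    """
    table = features.copy()
    for other, name in ((covariates, "covariates"), (rots, "rots")):
        if other is None:
            continue
        dup_cols = [c for c in other.columns
                    if c in table.columns and c != "session_id"]
        table = table.merge(other.drop(columns=dup_cols), on="session_id",
                            how="inner")
    if table["session_id"].duplicated().any():
        dups = table.loc[table["session_id"].duplicated(), "session_id"]
        raise ValueError(f"duplicate session_id: {sorted(set(dups))}")
    bad = table[CONTINUOUS_COVARIATES].apply(
        lambda c: ~np.isfinite(c)).any(axis=None)
    if bad:
        raise ValueError("non-finite continuous covariate in session table")
    if standardize:
        for c in CONTINUOUS_COVARIATES:
            sd = table[c].std(ddof=1)
            table[c] = (table[c] - table[c].mean()) / (sd if sd > 0 else 1.0)
    return table


class DomainLMM(BaseEstimator):
    """Linear mixed model for one reorientation domain (sklearn-style).

    Parameters
    ----------
    domain : str
        "person", "place" or "time"; outcome column is ``rot_<domain>``.
    fixed_effects : list of str, optional
        Fixed-effect columns (default: the full study design).
    re_slope : str or None
        Column carrying the by-subject random slope (default "t_max");
        None fits a random intercept only.
    reml : bool
        REML estimation (default True).

    Attributes
    ----------
    coef_ : DataFrame with beta, se, ci_low, ci_high, p per effect.
    random_sds_ : dict of random-effect SDs (minutes).
    converged_, singular_, fallback_ : fit status.
    n_obs_, n_subjects_ : sample sizes used.
    result_ : the underlying statsmodels results object (None for the
        degenerate OLS path).
    """

    def __init__(self, domain: str = "person", fixed_effects=None,
                 re_slope: str | None = "t_max", reml: bool = True,
                 random_effects: bool = True):
        self.domain = domain
        self.fixed_effects = fixed_effects
        self.re_slope = re_slope
        self.reml = reml
        self.random_effects = random_effects

    def _effects(self):
        return list(self.fixed_effects) if self.fixed_effects is not None \
            else list(COVARIATES)

    def fit(self, X: pd.DataFrame, y=None):
        """Fit to a session table (see :func:`build_session_table`)."""
        effects = self._effects()
        outcome = f"rot_{self.domain}"
        cols = ["subject_id", outcome] + effects
        data = X[cols].dropna().reset_index(drop=True)
        self.n_obs_ = len(data)
        self.n_subjects_ = data["subject_id"].nunique()
        if self.n_subjects_ < 10 or self.n_obs_ < 30:
            warnings.warn(
                f"{self.domain}: small sample ({self.n_subjects_} subjects, "
                f"{self.n_obs_} sessions)", stacklevel=2)

        design = sm.add_constant(data[effects])
        yv = data[outcome].to_numpy()
        ols = sm.OLS(yv, design).fit()
        n_fixed = design.shape[1]
        self.df_resid_ = self.n_obs_ - n_fixed

        # random effects forced to zero: the mixed model degenerates to
        # ordinary least squares on the fixed-effects design
        if not self.random_effects:
            self._from_params(ols.params.to_numpy(), ols.bse.to_numpy(),
                              design.columns)
            self.random_sds_ = {"residual": float(np.sqrt(ols.scale))}
            self.method_ = "OLS"
            self.converged_, self.singular_ = True, False
            self.fallback_ = ""
            self.result_ = ols
            self._diagnostics(ols.resid, None)
            return self

        # degenerate data (zero residual variance): REML undefined, GLS = OLS
        if ols.ssr / max(self.n_obs_, 1) < 1e-9:
            self._from_params(ols.params.to_numpy(),
                              np.zeros(n_fixed), design.columns)
            self.random_sds_ = {"subject_intercept": 0.0, "t_max_slope": 0.0,
                                "residual": 0.0}
            self.method_ = "OLS-degenerate"
            self.converged_, self.singular_ = True, True
            self.fallback_ = "ols"
            self.result_ = None
            self._diagnostics(np.zeros(self.n_obs_), None)
            return self

        formula = f"{outcome} ~ " + " + ".join(effects)
        self.method_ = "REML" if self.reml else "ML"
        res, singular, fallback = self._fit_mixed(formula, data)
        if res is None:  # all mixed fits failed -> flagged OLS fallback
            logger.warning("%s: mixed model failed, reporting OLS", self.domain)
            self._from_params(ols.params.to_numpy(), ols.bse.to_numpy(),
                              design.columns)
            self.random_sds_ = {"residual": float(np.sqrt(ols.scale))}
            self.method_ = "OLS-fallback"
            self.converged_, self.singular_ = False, True
            self.fallback_ = "ols"
            self.result_ = None
            self._diagnostics(ols.resid, None)
            return self

        self.result_ = res
        self.converged_ = bool(res.converged)
        self.singular_ = singular
        self.fallback_ = fallback
        names = list(res.fe_params.index)
        self._from_params(res.fe_params.to_numpy(), res.bse_fe.to_numpy(),
                          names)
        re_sds = {"residual": float(np.sqrt(res.scale))}
        cov_re = np.asarray(res.cov_re)
        re_names = list(res.cov_re.index)
        for i, nm in enumerate(re_names):
            key = ("subject_intercept" if nm in ("Group", "Intercept", "const")
                   else f"{nm}_slope")
            re_sds[key] = float(np.sqrt(max(cov_re[i, i], 0.0)))
        self.random_sds_ = re_sds
        ranef = pd.DataFrame(res.random_effects).T
        self._diagnostics(np.asarray(res.resid), ranef)
        return self

    def _fit_mixed(self, formula, data):
        """Fallback ladder: intercept + slope -> intercept-only."""
        ladder = []
        if self.re_slope is not None:
            ladder.append((f"~{self.re_slope}", ""))
        ladder.append(("~1", "intercept-only" if self.re_slope else ""))
        for re_formula, tag in ladder:
            for method in ("lbfgs", "bfgs", "powell"):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    try:
                        md = smf.mixedlm(formula, data,
                                         groups=data["subject_id"],
                                         re_formula=re_formula)
                        res = md.fit(reml=self.reml, method=[method])
                    except (np.linalg.LinAlgError, ValueError):
                        continue
                if (not res.converged
                        or not np.all(np.isfinite(res.fe_params))
                        or not np.all(np.isfinite(res.bse_fe))):
                    continue
                cov_re = np.asarray(res.cov_re)
                eig = (np.linalg.eigvalsh(cov_re) if cov_re.size
                       else np.array([0.0]))
                # statsmodels rarely lands exactly on the variance boundary;
                # treat a component < 2% of residual variance as singular
                singular = bool(eig.min() < 0.02 * res.scale)
                if singular and re_formula != "~1":
                    logger.info(
                        "%s: singular random-effects covariance, dropping "
                        "the %s slope", self.domain, self.re_slope)
                    break  # next rung of the ladder
                return res, singular, tag
        return None, True, "ols"

    def _from_params(self, beta, se, names):
        tcrit = stats.t.ppf(0.975, max(self.df_resid_, 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = 2 * stats.t.sf(np.abs(tstat), max(self.df_resid_, 1))
        p = np.where(se > 0, p, 0.0)
        names = ["Intercept" if n in ("const", "Intercept") else n
                 for n in names]
        self.coef_ = pd.DataFrame(
            {"beta": beta, "se": se, "ci_low": beta - tcrit * se,
             "ci_high": beta + tcrit * se, "p": p}, index=names)

    def _diagnostics(self, resid, ranef: pd.DataFrame | None):
        """Normality checks on residuals and random effects (advisory only)."""
        diag = {}
        r = np.asarray(resid, dtype=float)
        if len(r) >= 3 and np.ptp(r) > 0:
            diag["resid_shapiro_p"] = float(stats.shapiro(r[:5000]).pvalue)
        if ranef is not None and len(ranef) >= 3:
            for col in ranef.columns:
                v = ranef[col].to_numpy(dtype=float)
                if np.ptp(v) > 0:
                    diag[f"ranef_{col}_shapiro_p"] = float(
                        stats.shapiro(v).pvalue)
        self.diagnostics_ = diag

    def to_result(self, vif: pd.Series | None = None) -> LMMResult:
        return LMMResult(
            domain=self.domain, coef=self.coef_.copy(),
            random_sds=dict(self.random_sds_), method=self.method_,
            n_obs=self.n_obs_, n_subjects=self.n_subjects_,
            vif=vif if vif is not None else pd.Series(dtype=float),
            converged=self.converged_, singular=self.singular_,
            fallback=self.fallback_, diagnostics=dict(self.diagnostics_),
        )


def fit_domain_lmm(table: pd.DataFrame, domain: str, **kwargs) -> LMMResult:
    """Fit the domain model and attach the collinearity screen."""
    model = DomainLMM(domain=domain, **kwargs).fit(table)
    effects = model._effects()
    outcome = f"rot_{domain}"
    data = table[["subject_id", outcome] + effects].dropna()
    vif = vif_screen(data, effects)
    flagged = vif[vif >= 5].index.tolist()
    if flagged:
        logger.warning("%s: predictors with VIF >= 5: %s", domain, flagged)
    return model.to_result(vif=vif)


def vif_screen(table: pd.DataFrame, fixed_effects) -> pd.Series:
    """Variance inflation factor per fixed effect (auxiliary regressions on
    the fixed-effects design, intercept included). VIF >= 5 is flagged by the
    caller; perfectly collinear columns yield ``inf``."""
    fixed_effects = list(fixed_effects)
    if len(fixed_effects) < 2:
        raise ValueError("VIF needs at least two fixed effects")
    design = sm.add_constant(table[fixed_effects].astype(float)).to_numpy()
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, name in enumerate(fixed_effects):
            try:
                v = variance_inflation_factor(design, j + 1)
            except (np.linalg.LinAlgError, ZeroDivisionError):
                v = np.inf
            if not np.isfinite(v) or v > 1e12:
                v = np.inf
            out[name] = float(v)
    return pd.Series(out, name="vif")


def midazolam_sensitivity(
    table: pd.DataFrame, min_sessions: int = 10, **kwargs
) -> dict[str, LMMResult]:
    """Refit all three domain models on midazolam-free sessions, dropping the
    midazolam term. Returns an empty dict (with a warning) when the subset is
    too small."""
    subset = table[table["midazolam"] == 0]
    if len(subset) < min_sessions:
        warnings.warn(
            f"midazolam-free subset has {len(subset)} sessions "
            f"(< {min_sessions}); sensitivity analysis skipped", stacklevel=2)
        return {}
    effects = [c for c in COVARIATES if c != "midazolam"]
    return {
        d: fit_domain_lmm(subset, d, fixed_effects=effects, **kwargs)
        for d in ("person", "place", "time")
    }
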