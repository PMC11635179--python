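"""Driver analysis: which predictors explain temporal β-diversity?

The inference chain mirrors standard multimodel practice in community
ecology: each meadow contributes one observation — its β-diversity
components as responses and the temporal variability (coefficient of
variation over sampling times) of habitat-structure metrics plus mean
climate values as candidate predictors.  Predictors are screened for rank
correlation (Spearman ρ² above a threshold drops the lower-priority
member), collinearity is summarized by variance inflation factors, and
Gaussian identity-link models are fitted for every predictor subset up to
a size cap.  Models are ranked by the small-sample Akaike information
criterion::

    AICc = AIC + 2k(k+1)/(n − k − 1),   k = slopes + intercept + dispersion

with Akaike weights w_m = exp(−Δ_m/2)/Σ exp(−Δ/2), and the relative
importance of a predictor is the sum of weights of the models containing
it.  A greedy backward-stepwise search is run as well and cross-validated
against the exhaustive ranking.  Heteroskedasticity is checked by the
studentized Breusch–Pagan test (n·R² of the auxiliary regression of
squared residuals on the model's predictors, against χ² with as many
degrees of freedom as predictors).

Responses bounded in [0, 1] are nonetheless fitted by ordinary least
squares by default (the field's convention for these summary statistics);
a logit-link quasi-binomial alternative is available via ``family``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, LookupError_, ValidationError

__all__ = [
    "DEFAULT_PRIORITY",
    "ModelFit",
    "ModelRanking",
    "DriverResult",
    "coefficient_of_variation",
    "predictor_summary",
    "spearman_screen",
    "vif",
    "fit_glm",
    "aicc_from_loglik",
    "akaike_weights",
    "backward_stepwise",
    "exhaustive_ranking",
    "breusch_pagan",
    "driver_analysis",
]

#: default biological-significance order used to resolve correlated pairs
#: (most important first): habitat structure before climate.
DEFAULT_PRIORITY = (
    "cv_leaf_biomass",
    "cv_cover",
    "cv_shoot_density",
    "cv_epiphytic_load",
    "mean_sst",
    "mean_par",
)

RESPONSES = ("beta_sor", "beta_sim", "beta_sne", "bc_total")


def coefficient_of_variation(values) -> float:
    """CV in percent: sample SD (n−1) / mean × 100.

    Undefined (raises) for non-positive means or fewer than 2 values.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InsufficientDataError(f"CV needs ≥ 2 finite values, got {x.size}")
    mean = x.mean()
    if mean <= 0:
        raise ValidationError(f"CV undefined for mean {mean} ≤ 0")
    return float(x.std(ddof=1) / mean * 100.0)


def predictor_summary(predictors: pd.DataFrame, *,
                      cv_columns=("leaf_biomass", "cover", "shoot_density",
                                  "epiphytic_load"),
                      mean_columns=("sst", "par")) -> pd.DataFrame:
    """Per-meadow design rows from a long per-meadow-per-time predictor table.

    Habitat-structure columns are summarized as temporal CVs (percent);
    climate columns as temporal means.  Returns one row per meadow indexed
    by meadow, columns ``cv_<name>`` and ``mean_<name>``.
    """
    required = {"meadow", *cv_columns, *mean_columns}
    missing = required - set(predictors.columns)
    if missing:
        raise LookupError_(f"predictor table missing column(s): {sorted(missing)}")
    rows = {}
    for meadow, grp in predictors.groupby("meadow", sort=False):
        row = {f"cv_{c}": coefficient_of_variation(grp[c]) for c in cv_columns}
        row.update({f"mean_{c}": float(grp[c].mean()) for c in mean_columns})
        rows[meadow] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "meadow"
    return out


# ------------------------------------------------------------- screening

def spearman_screen(design: pd.DataFrame, r2_threshold: float = 0.6,
                    priority=DEFAULT_PRIORITY):
    """Drop rank-correlated predictors, keeping the higher-priority member.

    Computes Spearman ρ for every pair; while any retained pair has
    ρ² > ``r2_threshold``, the pair member appearing later in ``priority``
    is removed.  Constant columns (undefined ρ) are dropped with a warning.

    Returns ``(retained_columns, rho_matrix)``.
    """
    if len(design) < 3:
        raise InsufficientDataError("screening needs ≥ 3 rows")
    cols = list(design.columns)
    rank = {name: i for i, name in enumerate(priority)}
    order = sorted(cols, key=lambda c: (rank.get(c, len(priority)), cols.index(c)))

    retained = []
    for c in order:
        if design[c].nunique() <= 1:
            warnings.warn(f"predictor {c!r} is constant; dropped from screening",
                          stacklevel=2)
            continue
        retained.append(c)

    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for c1, c2 in itertools.combinations(cols, 2):
        if design[c1].nunique() <= 1 or design[c2].nunique() <= 1:
            r = np.nan
        else:
            r = stats.spearmanr(design[c1], design[c2]).statistic
        rho.loc[c1, c2] = rho.loc[c2, c1] = r

    changed = True
    while changed:
        changed = False
        for c1, c2 in itertools.combinations(list(retained), 2):
            r = rho.loc[c1, c2]
            if np.isfinite(r) and r ** 2 > r2_threshold:
                retained.remove(c2)      # c2 is lower priority by construction
                changed = True
                break
    # restore the original column order for the caller
    retained = [c for c in cols if c in retained]
    return retained, rho


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1 − R²_j) per predictor, R²_j from
    regressing predictor j on the others (with intercept)."""
    cols = list(design.columns)
    n, p = design.shape
    if n <= p + 1:
        raise InsufficientDataError(f"VIF needs n > p + 1 (n={n}, p={p})")
    out = {}
    for j, c in enumerate(cols):
        others = [k for k in cols if k != c]
        X = sm.add_constant(design[others].to_numpy(dtype=float)) if others \
            else np.ones((n, 1))
        r2 = sm.OLS(design[c].to_numpy(dtype=float), X).fit().rsquared
        if r2 >= 1 - 1e-12:
            warnings.warn(f"predictor {c!r} perfectly collinear; VIF infinite",
                          stacklevel=2)
            out[c] = np.inf
        else:
            out[c] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ------------------------------------------------------------------ fits

@dataclass(frozen=True)
class ModelFit:
    """One fitted model with its information-theoretic bookkeeping."""

    response: str
    predictors: tuple
    coefficients: pd.DataFrame      # term × (estimate, se, stat, p)
    n: int
    k: int                          # slopes + intercept + dispersion
    loglik: float
    aic: float
    aicc: float
    adj_r2: float
    f_stat: float
    f_p: float
    resid: np.ndarray = field(repr=False, default=None)
    design: pd.DataFrame = field(repr=False, default=None)
    family: str = "gaussian"


def aicc_from_loglik(loglik: float, n: int, k: int) -> float:
    """AICc = −2ℓ + 2k + 2k(k+1)/(n − k − 1); +inf when n ≤ k + 1."""
    aic = -2.0 * loglik + 2.0 * k
    if n - k - 1 <= 0:
        return math.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_glm(response: pd.Series, design: pd.DataFrame,
            family: str = "gaussian", response_name: str | None = None) -> ModelFit:
    """Fit one model of a β-diversity response on a predictor subset.

    ``family="gaussian"`` is ordinary least squares (identity link);
    ``family="quasibinomial"`` fits a logit-link binomial GLM for
    responses in (0, 1).  k counts intercept + slopes + dispersion.
    """
    y = np.asarray(response, dtype=float)
    n = y.size
    preds = tuple(design.columns)
    p = len(preds)
    if n <= p + 1:
        raise InsufficientDataError(f"n={n} too small for {p} predictors")
    if n - p - 1 < 3:
        warnings.warn(f"only {n - p - 1} residual degrees of freedom; "
                      f"estimates are fragile", stacklevel=2)
    X = np.column_stack([np.ones(n)] + [design[c].to_numpy(dtype=float) for c in preds])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValidationError(
            f"singular design: aliased column among {('const',) + preds}"
        )
    if family == "gaussian":
        res = sm.OLS(y, X).fit()
        loglik = res.llf
        stat_name = res.tvalues, res.pvalues
        adj_r2, f_stat, f_p = res.rsquared_adj, res.fvalue, res.f_pvalue
    elif family == "quasibinomial":
        if ((y <= 0) | (y >= 1)).any():
            raise ValidationError("quasibinomial family needs responses in (0, 1)")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(scale="X2")
        loglik = res.llf
        stat_name = res.tvalues, res.pvalues
        adj_r2, f_stat, f_p = np.nan, np.nan, np.nan
    else:
        raise ValidationError(f"unknown family {family!r}")
    k = p + 2                        # slopes + intercept + dispersion
    terms = ["intercept", *preds]
    coefs = pd.DataFrame(
        {"estimate": res.params, "se": res.bse,
         "stat": stat_name[0], "p": stat_name[1]},
        index=terms,
    )
    if p == 0 and family == "gaussian":      # statsmodels leaves F undefined
        adj_r2, f_stat, f_p = 0.0, np.nan, np.nan
    return ModelFit(
        response=response_name or getattr(response, "name", "y") or "y",
        predictors=preds, coefficients=coefs, n=n, k=k,
        loglik=float(loglik), aic=-2.0 * float(loglik) + 2 * k,
        aicc=aicc_from_loglik(float(loglik), n, k),
        adj_r2=float(adj_r2), f_stat=float(f_stat), f_p=float(f_p),
        resid=y - res.fittedvalues, design=design.copy(), family=family,
    )


def akaike_weights(aicc_values) -> np.ndarray:
    """exp(−Δ/2) normalized to sum 1; invariant to a constant shift."""
    a = np.asarray(aicc_values, dtype=float)
    rel = np.exp(-(a - a.min()) / 2.0)
    return rel / rel.sum()


def backward_stepwise(response: pd.Series, design: pd.DataFrame,
                      family: str = "gaussian",
                      response_name: str | None = None) -> ModelFit:
    """Greedy backward selection on AICc.

    From the full model, repeatedly drop the single predictor whose
    removal lowers AICc the most; stop when no removal improves.  Ties
    (within 1e−10) prefer the smaller model, then the lexicographically
    earlier predictor set.
    """
    current = list(design.columns)
    best = fit_glm(response, design[current], family, response_name)
    while current:
        candidates = []
        for drop in current:
            sub = [c for c in current if c != drop]
            fit = fit_glm(response, design[sub], family, response_name)
            candidates.append((fit.aicc, len(sub), tuple(sub), fit))
        candidates.sort(key=lambda t: (round(t[0] / 1e-10), t[1], t[2]))
        # a removal wins if it lowers AICc; an exact tie also wins
        # (parsimony tie-break: prefer the smaller model)
        if candidates[0][0] <= best.aicc + 1e-10:
            best = candidates[0][3]
            current = list(best.predictors)
        else:
            break
    return best


@dataclass(frozen=True)
class ModelRanking:
    """Exhaustive candidate-set ranking with Akaike weights."""

    response: str
    table: pd.DataFrame             # per model: predictors, k, loglik, aicc, delta_aicc, weight, adj_r2, f_stat, f_p
    importance: pd.Series           # per predictor: Σ weights of models containing it
    fits: dict = field(repr=False, default=None)

    @property
    def best(self) -> ModelFit:
        return self.fits[self.table.iloc[0]["predictors"]]


def exhaustive_ranking(response: pd.Series, design: pd.DataFrame,
                       max_size: int = 5, family: str = "gaussian",
                       response_name: str | None = None) -> ModelRanking:
    """Fit every predictor subset up to ``max_size`` (plus intercept-only),
    rank by AICc and compute Akaike weights and per-predictor importance."""
    cols = list(design.columns)
    if len(cols) > 20:
        raise ValidationError(f"{len(cols)} predictors: combinatorial guard tripped")
    subsets = [()]
    for size in range(1, min(max_size, len(cols)) + 1):
        subsets.extend(itertools.combinations(cols, size))
    fits = {}
    rows = []
    for sub in subsets:
        fit = fit_glm(response, design[list(sub)], family, response_name)
        fits[sub] = fit
        rows.append({"predictors": sub, "k": fit.k, "loglik": fit.loglik,
                     "aicc": fit.aicc, "adj_r2": fit.adj_r2,
                     "f_stat": fit.f_stat, "f_p": fit.f_p})
    table = pd.DataFrame(rows)
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    table["weight"] = akaike_weights(table["aicc"])
    table = table.sort_values(
        by=["aicc", "k", "predictors"],
        key=lambda s: s.map(lambda v: round(v / 1e-10)) if s.name == "aicc" else s,
    ).reset_index(drop=True)
    importance = pd.Series(
        {c: table.loc[table["predictors"].map(lambda s: c in s), "weight"].sum()
         for c in cols},
        name="importance",
    )
    return ModelRanking(response=response_name or "y", table=table,
                        importance=importance, fits=fits)


def breusch_pagan(fit: ModelFit) -> tuple[float, int, float]:
    """Studentized Breusch–Pagan heteroskedasticity test.

    Squared residuals are regressed on the fitted model's predictors;
    the statistic is n·R² of that auxiliary regression, compared with a
    χ² distribution on (number of predictors) degrees of freedom.
    """
    if not fit.predictors:
        raise InsufficientDataError("Breusch–Pagan needs ≥ 1 predictor")
    e2 = np.asarray(fit.resid, dtype=float) ** 2
    df = len(fit.predictors)
    if np.allclose(e2, e2[0]):
        return 0.0, df, 1.0
    X = sm.add_constant(fit.design[list(fit.predictors)].to_numpy(dtype=float))
    r2 = sm.OLS(e2, X).fit().rsquared
    statistic = fit.n * r2
    return float(statistic), df, float(stats.chi2.sf(statistic, df))


# ------------------------------------------------------------- full chain

@dataclass(frozen=True)
class DriverResult:
    """The full inference chain for one response."""

    response: str
    retained: list
    rho: pd.DataFrame
    vifs: pd.Series
    stepwise: ModelFit
    ranking: ModelRanking
    bp_stat: float
    bp_df: int
    bp_p: float


def driver_analysis(partitions, predictors: pd.DataFrame, *,
                    responses=RESPONSES, r2_threshold: float = 0.6,
                    priority=DEFAULT_PRIORITY, max_size: int = 5,
                    family: str = "gaussian") -> dict[str, DriverResult]:
    """Run screening → VIF → stepwise → exhaustive ranking → diagnostics
    for each β-diversity response.

    ``partitions`` is a list of :class:`~tempbeta.partition.BetaPartition`
    or an equivalent frame with a ``meadow`` column; ``predictors`` is the
    per-meadow design (index or column ``meadow``).  No multiplicity
    correction is applied across responses.
    """
    from .partition import partition_frame  # local to avoid cycle

    part = partitions if isinstance(partitions, pd.DataFrame) else partition_frame(partitions)
    part = part.set_index("meadow")
    design_all = predictors.set_index("meadow") if "meadow" in predictors.columns else predictors
    unmatched = set(part.index).symmetric_difference(design_all.index)
    if unmatched:
        raise LookupError_(f"meadows not matched between partitions and "
                           f"predictors: {sorted(map(str, unmatched))}")
    design_all = design_all.loc[part.index]

    retained, rho = spearman_screen(design_all, r2_threshold, priority)
    design = design_all[retained]
    vifs = vif(design)

    results = {}
    for resp in responses:
        y = part[resp]
        step = backward_stepwise(y, design, family, resp)
        ranking = exhaustive_ranking(y, design, max_size, family, resp)
        # greedy search can never beat the exhaustive optimum
        assert step.aicc >= ranking.table["aicc"].min() - 1e-9
        diag_fit = step if step.predictors else ranking.best
        if diag_fit.predictors:
            bp_stat, bp_df, bp_p = breusch_pagan(diag_fit)
        else:
            bp_stat, bp_df, bp_p = (np.nan, 0, np.nan)
        results[resp] = DriverResult(
            response=resp, retained=retained, rho=rho, vifs=vifs,
            stepwise=step, ranking=ranking,
            bp_stat=bp_stat, bp_df=bp_df, bp_p=bp_p,
        )
    return results
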