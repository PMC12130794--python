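"""Gaussian mixed models of potential inter- and intraspecific competition.

The model table has one row per (network day, bee species present that
day).  Two Gaussian linear mixed models are fit by restricted maximum
likelihood (REML; switchable to plain ML) with a random intercept for bee
species identity.  REML is the default because the species-level variance
component is estimated from few groups, where ML shrinks it toward zero
and deflates the standard errors of species-level covariates such as
proboscis length.  Models:

* interspecific: response = the species' mean column PAC index (its average
  effect on the other species that day);
* intraspecific: response = the diagonal PAC index d_ii.

Fixed effects in both: estimated abundance of the acting/focal species
(log- then z-transformed), floral density (log-z), proboscis length (z),
year (categorical, reference 2018-analogue = first year), flowering period
(categorical, reference early), and the abundance x density interaction.
Collinearity is screened with VIFs on the main-effects design (the
interaction is excluded from screening, since it inflates the VIF of its
own components spuriously); term-level inference uses Wald chi-square
tests; effect displays use partial (component-plus-residual) values with
predicted curves at the 10th/50th/90th floral-density quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .data_model import classify_flowering_period

__all__ = [
    "ModelResult",
    "assemble_model_table",
    "log_z",
    "add_transforms",
    "fit_interspecific_model",
    "fit_intraspecific_model",
    "vif",
    "wald_tests",
    "partial_residuals",
]

PERIOD_LEVELS = ["early", "middle", "late"]


def assemble_model_table(
    indices: pd.DataFrame,
    abundances: pd.DataFrame,
    densities: pd.Series,
    traits: pd.DataFrame,
) -> pd.DataFrame:
    """Inner-join indices, abundances, per-day floral density and traits.

    One row per (day, species present that day).  Every retained species
    must have a trait entry; a missing trait is an error naming the
    species.  Adds ``flowering_period`` and ``year`` derived from the date.
    """
    table = indices.merge(abundances, on=["date", "species"], how="inner")
    dens = densities.rename("floral_density").rename_axis("date").reset_index()
    table = table.merge(dens, on="date", how="inner")
    missing = set(table["species"]) - set(traits["bee_species"])
    if missing:
        raise KeyError(f"no proboscis trait for species: {sorted(missing)}")
    table = table.merge(
        traits.rename(columns={"bee_species": "species"}), on="species", how="left"
    )
    if "year" not in table.columns:
        table["year"] = table["date"].map(lambda d: d.year)
    table["flowering_period"] = table["date"].map(classify_flowering_period)
    return table.reset_index(drop=True)


def log_z(values, ddof: int = 0) -> np.ndarray:
    """z-score of the natural log: (log x - mean) / sd.

    All values must be positive and not all equal.  ``ddof=0`` (population
    standard deviation) by default.
    """
    x = np.asarray(values, dtype=float)
    if (x <= 0).any():
        raise ValueError("log_z requires strictly positive values")
    logs = np.log(x)
    sd = logs.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("log_z undefined for a constant vector")
    return (logs - logs.mean()) / sd


def _z(values, ddof: int = 0) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("z-score undefined for a constant vector")
    return (x - x.mean()) / sd


def add_transforms(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``abundance_lz``, ``floral_density_lz``, ``proboscis_z`` columns.

    Transforms are computed over the rows of this table (the rows entering
    the model), not per year.
    """
    out = table.copy()
    out["abundance_lz"] = log_z(out["abundance_est"])
    out["floral_density_lz"] = log_z(out["floral_density"])
    out["proboscis_z"] = _z(out["proboscis_mm"])
    return out


@dataclass
class ModelResult:
    """Fitted mixed-model summary in the layout of a coefficient table."""

    response: str
    fixed_effects: pd.DataFrame  # term, estimate, std_error, z_value, p_value
    random_effect: dict  # {"variance": ..., "sd": ...} for species intercept
    wald: pd.DataFrame  # term, chi2, df, p
    vif: dict
    converged: bool
    n_obs: int
    formula: str
    _fit: object = field(repr=False, default=None)
    _table: pd.DataFrame = field(repr=False, default=None)


_FIXED_RHS = (
    "abundance_lz + floral_density_lz + abundance_lz:floral_density_lz"
    " + proboscis_z + C(year) + C(flowering_period)"
)


def _order_periods(data: pd.DataFrame) -> pd.DataFrame:
    # early < middle < late ordering, keeping only levels present so an
    # absent stage does not create an all-zero (singular) dummy column
    data = data.copy()
    present = set(data["flowering_period"])
    data["flowering_period"] = pd.Categorical(
        data["flowering_period"],
        categories=[lv for lv in PERIOD_LEVELS if lv in present],
    )
    return data


def _fit_gaussian_mixed(
    table: pd.DataFrame, response: str, years=None, reml: bool = True
) -> ModelResult:
    data = table.dropna(subset=[response]).copy()
    if years is not None:
        data = data[data["year"].isin(list(years))]
    data = _order_periods(data.reset_index(drop=True))
    if data["species"].nunique() < 2:
        raise ValueError("need >= 2 species for a species random intercept")
    formula = f"{response} ~ {_FIXED_RHS}"
    model = smf.mixedlm(formula, data, groups=data["species"])
    # the species variance can sit on the boundary (-> singular Hessian for
    # some optimizers); fall through a chain of increasingly robust methods
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                fit = model.fit(reml=reml, method=method, maxiter=500)
                break
            except np.linalg.LinAlgError:
                continue
    if fit is None:
        raise RuntimeError(f"mixed model for {response!r} failed to fit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se = np.asarray(fit.bse_fe)
    est = np.asarray(fit.fe_params)
    zval = est / se
    fixed = pd.DataFrame(
        {
            "term": list(fit.fe_params.index),
            "estimate": est,
            "std_error": se,
            "z_value": zval,
            "p_value": 2 * stats.norm.sf(np.abs(zval)),
        }
    )
    re_var = float(np.asarray(fit.cov_re).ravel()[0])
    result = ModelResult(
        response=response,
        fixed_effects=fixed,
        random_effect={"variance": re_var, "sd": float(np.sqrt(re_var))},
        wald=pd.DataFrame(),
        vif={},
        converged=bool(getattr(fit, "converged", True)) and bool(np.isfinite(se).all()),
        n_obs=len(data),
        formula=formula,
        _fit=fit,
        _table=data,
    )
    result.wald = wald_tests(result)
    result.vif = vif(data)
    return result


def fit_interspecific_model(table: pd.DataFrame, years=None, reml: bool = True) -> ModelResult:
    """Mixed model of the mean interspecific PAC index of the acting species."""
    return _fit_gaussian_mixed(table, "inter_acting", years=years, reml=reml)


def fit_intraspecific_model(table: pd.DataFrame, years=None, reml: bool = True) -> ModelResult:
    """Mixed model of the intraspecific (diagonal) PAC index of the focal species."""
    return _fit_gaussian_mixed(table, "intra", years=years, reml=reml)


def vif(table: pd.DataFrame, predictors: list[str] | None = None) -> dict[str, float]:
    """Variance inflation factors of the main-effects design.

    Each continuous predictor (and each categorical dummy) is regressed on
    the remaining columns; VIF = 1 / (1 - R^2).  The abundance x density
    interaction is excluded from screening.  A singular design raises.
    """
    import patsy

    if predictors is None:
        rhs = (
            "abundance_lz + floral_density_lz + proboscis_z + C(year)"
            " + C(flowering_period)"
        )
        X = patsy.dmatrix(rhs, _order_periods(table))
        names = X.design_info.column_names
        X = np.asarray(X)
    else:
        names = ["Intercept"] + list(predictors)
        X = np.column_stack(
            [np.ones(len(table))] + [np.asarray(table[p], dtype=float) for p in predictors]
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular fixed-effects design")
    out = {}
    for j, name in enumerate(names):
        if name == "Intercept":
            continue
        others = np.delete(X, j, axis=1)
        y = X[:, j]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = ((y - y.mean()) ** 2).sum()
        r2 = 1 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
        out[name] = float(np.inf if r2 >= 1 else 1 / (1 - r2))
    return out


def wald_tests(model: ModelResult) -> pd.DataFrame:
    """Per-term Wald chi-square tests of the fixed effects.

    For each model term (dummy blocks tested jointly, intercept excluded):
    chi2 = b' V^{-1} b with V the fixed-effect covariance block; df = the
    number of coefficients in the term.  A single-df term's chi-square is
    the square of its z value.
    """
    fit = model._fit
    design_info = fit.model.data.design_info
    cov = np.asarray(fit.cov_params())[: len(fit.fe_params), : len(fit.fe_params)]
    est = np.asarray(fit.fe_params)
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(sl.start, sl.stop)
        b = est[idx]
        V = cov[np.ix_(idx, idx)]
        chi2 = float(b @ np.linalg.solve(V, b))
        df = len(idx)
        rows.append(
            {"term": term, "chi2": chi2, "df": df, "p_value": float(stats.chi2.sf(chi2, df))}
        )
    return pd.DataFrame(rows)


def partial_residuals(
    model: ModelResult,
    term: str,
    density_quantiles: tuple[float, ...] = (0.1, 0.5, 0.9),
) -> dict[str, pd.DataFrame]:
    """Component-plus-residual values for ``term`` and predicted curves.

    ``points``: one row per observation with the term's value and its
    partial residual (residual + that term's fitted component).
    ``lines``: predicted response over the term's observed range at each
    floral-density quantile (10th/50th/90th by default), with the other
    covariates at their reference levels / zero (the covariates are
    centered, so zero is the mean).
    """
    import patsy

    fit = model._fit
    data = model._table
    design_info = fit.model.data.design_info
    X = np.asarray(fit.model.exog)
    est = np.asarray(fit.fe_params)
    sl = design_info.term_name_slices[term]
    resid = np.asarray(fit.resid)
    component = X[:, sl] @ est[sl]
    term_values = data[term].to_numpy() if term in data.columns else component
    points = pd.DataFrame(
        {
            "term_value": term_values,
            "partial_residual": resid + component,
            "floral_density_lz": data["floral_density_lz"].to_numpy(),
        }
    )

    grid = np.linspace(data[term].min(), data[term].max(), 25) if term in data.columns else np.array([])
    qs = np.quantile(data["floral_density_lz"], density_quantiles)
    line_rows = []
    ref_year = sorted(data["year"].unique())[0]
    for q, dq in zip(density_quantiles, qs):
        new = pd.DataFrame(
            {
                "abundance_lz": grid if term == "abundance_lz" else np.zeros_like(grid),
                "floral_density_lz": np.full_like(grid, dq),
                "proboscis_z": grid if term == "proboscis_z" else np.zeros_like(grid),
                "year": ref_year,
                "flowering_period": "early",
            }
        )
        if term in new.columns and term not in ("abundance_lz", "proboscis_z"):
            new[term] = grid
        (Xnew,) = patsy.build_design_matrices([design_info], new)
        pred = np.asarray(Xnew) @ est
        for g, p in zip(grid, pred):
            line_rows.append(
                {"term_value": g, "density_quantile": q, "predicted": p}
            )
    return {"points": points, "lines": pd.DataFrame(line_rows)}
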