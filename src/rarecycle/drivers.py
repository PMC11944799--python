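"""Causal and importance layer: recursive path analysis and forest importance.

The path model is a recursive system of linear equations among observed,
internally standardized variables (classic path analysis): each endogenous
variable is regressed on its parents by OLS, which for a recursive model
with observed variables coincides with the ML point estimates. Global fit
is judged from the model-implied covariance via the ML discrepancy:

    chi^2 = (n - 1) * [ln|Sigma| - ln|S| + tr(S Sigma^-1) - k]
    RMSEA = sqrt(max(chi^2 - df, 0) / (df * (n - 1)))

Predictor importance for rare-taxa diversity uses a regression forest with
out-of-bag permutation importance (the %IncMSE convention): the percent
increase in a tree's out-of-bag MSE when one predictor's values are
permuted, averaged over trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
from sklearn.tree import DecisionTreeRegressor

from .diversity import alpha_diversity
from .mnc import MNCResult, compute_mnc
from .tables import MNC_VARIABLES, NutrientTable, OTUTable
from .taxa import classify_taxa, subset_by_class

__all__ = [
    "PathModelSpec",
    "PathModelFit",
    "ImportanceReport",
    "default_path_spec",
    "fit_path_model",
    "rf_importance",
    "assemble_driver_table",
]

DIVERSITY_COLUMNS = [
    "rare_bact_shannon",
    "abundant_bact_shannon",
    "rare_fung_shannon",
    "abundant_fung_shannon",
]


# ---------------------------------------------------------------------------
# Path model
# ---------------------------------------------------------------------------

@dataclass
class PathModelSpec:
    """Directed acyclic path diagram over observed variables."""

    variables: list[str]
    edges: list[tuple[str, str]]  # (parent, child)

    def __post_init__(self) -> None:
        for parent, child in self.edges:
            if parent not in self.variables or child not in self.variables:
                raise ValueError(f"edge ({parent}, {child}) uses unknown variable")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        self.topological_order()  # raises on cycles
        if not self.exogenous():
            raise ValueError("model needs at least one exogenous variable")

    def parents(self, var: str) -> list[str]:
        return [p for p, c in self.edges if c == var]

    def endogenous(self) -> list[str]:
        return [v for v in self.variables if self.parents(v)]

    def exogenous(self) -> list[str]:
        return [v for v in self.variables if not self.parents(v)]

    def topological_order(self) -> list[str]:
        remaining = {v: set(self.parents(v)) for v in self.variables}
        order = []
        while remaining:
            free = [v for v, deps in remaining.items() if not deps]
            if not free:
                raise ValueError("path diagram contains a cycle")
            for v in free:
                order.append(v)
                del remaining[v]
            for deps in remaining.values():
                deps.difference_update(free)
        return order


def default_path_spec(direct_salt_to_mnc: bool = True) -> PathModelSpec:
    """Salinity -> four Shannon sub-community diversities -> MNC.

    The direct salinity -> MNC path is included by default (saturating the
    ambiguous path avoids unwarranted degrees-of-freedom claims); drop it
    with ``direct_salt_to_mnc=False``.
    """
    variables = ["salt"] + DIVERSITY_COLUMNS + ["MNC"]
    edges = [("salt", d) for d in DIVERSITY_COLUMNS]
    edges += [(d, "MNC") for d in DIVERSITY_COLUMNS]
    if direct_salt_to_mnc:
        edges.append(("salt", "MNC"))
    return PathModelSpec(variables=variables, edges=edges)


@dataclass
class PathModelFit:
    """Standardized path coefficients, per-edge p, and global fit indices."""

    coefficients: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    r_squared: dict[str, float]
    chi_square: float
    df: int
    chi_df_ratio: float
    rmsea: float
    n: int

    def as_dict(self) -> dict:
        return {
            "edges": [
                {
                    "from": parent,
                    "to": child,
                    "coefficient": float(b),
                    "p_value": float(self.p_values[(parent, child)]),
                }
                for (parent, child), b in self.coefficients.items()
            ],
            "r_squared": {k: float(v) for k, v in self.r_squared.items()},
            "chi_square": float(self.chi_square),
            "df": int(self.df),
            "chi_df_ratio": None if self.df == 0 else float(self.chi_df_ratio),
            "rmsea": float(self.rmsea),
            "n": int(self.n),
        }


def fit_path_model(data: pd.DataFrame, spec: PathModelSpec) -> PathModelFit:
    """Fit a recursive path model on standardized complete cases.

    Per-equation OLS on z-scored variables gives standardized coefficients
    with t-based two-sided p-values; the implied covariance assembled from
    the coefficients and residual variances yields chi^2, df and RMSEA.
    """
    frame = data[spec.variables].dropna()
    n = len(frame)
    k = len(spec.variables)
    n_params = (
        len(spec.edges)
        + len(spec.endogenous())
        + len(spec.exogenous()) * (len(spec.exogenous()) + 1) // 2
    )
    if n <= n_params:
        raise ValueError(f"n={n} too small for {n_params} free parameters")
    df_model = k * (k + 1) // 2 - n_params
    if df_model < 0:
        raise ValueError("model has more free parameters than moments")

    z = (frame - frame.mean()) / frame.std(ddof=1)
    if z.isna().any().any():
        bad = z.columns[z.isna().any()].tolist()
        raise ValueError(f"constant variable(s): {bad}")
    S = np.asarray(z.cov())  # correlation matrix of the observed variables
    var_idx = {v: i for i, v in enumerate(spec.variables)}

    B = np.zeros((k, k))
    psi = np.ones(k)  # residual variances; exogenous entries replaced below
    coefficients: dict[tuple[str, str], float] = {}
    p_values: dict[tuple[str, str], float] = {}
    r_squared: dict[str, float] = {}

    for child in spec.endogenous():
        parents = spec.parents(child)
        X = z[parents].to_numpy()
        y = z[child].to_numpy()
        XtX = X.T @ X
        try:
            beta = np.linalg.solve(XtX, X.T @ y)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"singular design for {child!r}") from exc
        resid = y - X @ beta
        dof = n - len(parents) - 1  # centering consumed one df
        sigma2 = resid @ resid / dof
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
        with np.errstate(divide="ignore"):
            t_stats = beta / se
        p_vals = 2 * sps.t.sf(np.abs(t_stats), df=dof)
        for parent, b, p in zip(parents, beta, p_vals):
            B[var_idx[child], var_idx[parent]] = b
            coefficients[(parent, child)] = float(b)
            p_values[(parent, child)] = float(p)
        # ML-consistent residual variance from the correlation matrix, so a
        # saturated model reproduces S exactly
        s_xy = np.array([S[var_idx[child], var_idx[p]] for p in parents])
        psi[var_idx[child]] = S[var_idx[child], var_idx[child]] - beta @ s_xy
        r_squared[child] = float(1.0 - psi[var_idx[child]])

    Psi = np.diag(psi)
    exog = spec.exogenous()
    for a in exog:
        for b in exog:
            Psi[var_idx[a], var_idx[b]] = S[var_idx[a], var_idx[b]]

    if df_model == 0:
        chi_square = 0.0  # saturated model reproduces S exactly
    else:
        inv = np.linalg.inv(np.eye(k) - B)
        sigma = inv @ Psi @ inv.T
        sign_s, logdet_s = np.linalg.slogdet(S)
        sign_m, logdet_m = np.linalg.slogdet(sigma)
        if sign_s <= 0 or sign_m <= 0:
            raise ValueError("covariance matrix not positive definite")
        f_ml = logdet_m - logdet_s + float(np.trace(S @ np.linalg.inv(sigma))) - k
        chi_square = max(0.0, (n - 1) * f_ml)
    rmsea = (
        0.0
        if df_model == 0
        else float(np.sqrt(max(chi_square - df_model, 0.0) / (df_model * (n - 1))))
    )
    return PathModelFit(
        coefficients=coefficients,
        p_values=p_values,
        r_squared=r_squared,
        chi_square=chi_square,
        df=df_model,
        chi_df_ratio=chi_square / df_model if df_model > 0 else 0.0,
        rmsea=rmsea,
        n=n,
    )


# ---------------------------------------------------------------------------
# Random-forest permutation importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceReport:
    """Per-predictor %IncMSE importance with ranking and OOB model fit."""

    importance: pd.Series  # percent increase in OOB MSE, sorted descending
    r_squared: float
    n_trees: int
    seed: int

    @property
    def ranking(self) -> list[str]:
        return list(self.importance.index)


def rf_importance(
    predictors: pd.DataFrame,
    response: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
    max_features: int | None = None,
) -> ImportanceReport:
    """Out-of-bag permutation importance of a regression forest (%IncMSE).

    Each tree is fit on a bootstrap resample; importance of a predictor is
    the mean over trees of the percent increase in that tree's out-of-bag
    MSE after permuting the predictor among the out-of-bag rows. Features
    per split default to ceil(p / 3) (the regression-forest convention).
    """
    X = predictors.to_numpy(dtype=float)
    y = response.reindex(predictors.index).to_numpy(dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least ten samples")
    if p < 2:
        raise ValueError("need at least two predictors")
    if np.ptp(y) == 0:
        warnings.warn("constant response; importances are all zero")
        imp = pd.Series(0.0, index=predictors.columns).sort_values(ascending=False)
        return ImportanceReport(importance=imp, r_squared=0.0, n_trees=n_trees, seed=seed)
    mtry = max_features if max_features is not None else int(np.ceil(p / 3))
    rng = np.random.default_rng(seed)

    increases = np.zeros((n_trees, p))
    used = np.zeros(p)
    oob_pred_sum = np.zeros(n)
    oob_pred_count = np.zeros(n)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if len(oob) < 2:
            continue
        tree = DecisionTreeRegressor(
            max_features=mtry, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        pred = tree.predict(X[oob])
        oob_pred_sum[oob] += pred
        oob_pred_count[oob] += 1
        mse = float(np.mean((pred - y[oob]) ** 2))
        for j in range(p):
            X_perm = X[oob].copy()
            X_perm[:, j] = X_perm[rng.permutation(len(oob)), j]
            mse_perm = float(np.mean((tree.predict(X_perm) - y[oob]) ** 2))
            if mse > 0:
                increases[t, j] += 100.0 * (mse_perm - mse) / mse
            else:
                increases[t, j] += 100.0 * mse_perm
        used[:] += 1

    importance = pd.Series(
        increases.sum(axis=0) / np.maximum(used, 1), index=predictors.columns
    ).sort_values(ascending=False)
    seen = oob_pred_count > 0
    oob_mean = oob_pred_sum[seen] / oob_pred_count[seen]
    r2 = float(1.0 - np.mean((oob_mean - y[seen]) ** 2) / np.var(y[seen]))
    return ImportanceReport(importance=importance, r_squared=r2, n_trees=n_trees, seed=seed)


# ---------------------------------------------------------------------------
# Modeling table assembly
# ---------------------------------------------------------------------------

def assemble_driver_table(
    bacteria: OTUTable,
    fungi: OTUTable,
    nutrients: NutrientTable,
    mnc: MNCResult | None = None,
    rare_max: float = 1e-5,
    abundant_min: float = 5e-4,
) -> pd.DataFrame:
    """One modeling row per sample: salt, four sub-community Shannon indices,
    MNC and the seven MNC nutrients (13 columns).

    Sample ids must overlap across the three tables; rows with missing
    values are dropped (complete-case) and at least three must remain.
    """
    common = (
        pd.Index(bacteria.sample_ids)
        .intersection(fungi.sample_ids)
        .intersection(nutrients.sample_ids)
    )
    if len(common) == 0:
        raise ValueError("no shared sample ids across tables")
    bacteria = bacteria.subset_samples(common)
    fungi = fungi.subset_samples(common)
    nutrients = nutrients.subset_samples(common)
    if mnc is None:
        mnc = compute_mnc(nutrients)

    columns = {"salt": nutrients.data["salt"]}
    for kingdom, table in (("bact", bacteria), ("fung", fungi)):
        classes = classify_taxa(table, rare_max=rare_max, abundant_min=abundant_min)
        for which in ("rare", "abundant"):
            sub = subset_by_class(table, classes, which)
            profile = alpha_diversity(sub, allow_empty=True)
            columns[f"{which}_{kingdom}_shannon"] = profile.shannon
    columns["MNC"] = mnc.mnc
    for var in MNC_VARIABLES:
        columns[var] = nutrients.data[var]

    table = pd.DataFrame(columns).loc[common]
    complete = table.dropna()
    if len(complete) < len(table):
        warnings.warn(f"dropped {len(table) - len(complete)} incomplete case(s)")
    if len(complete) < 3:
        raise ValueError("fewer than three complete cases")
    return complete
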