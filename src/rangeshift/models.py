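"""The three-component niche-model ensemble: GLM, random forest, MaxEnt-like.

Components are fit on the weighted presence/pseudo-absence table, each
predicting suitability in [0, 1]; the ensemble is their plain (unweighted)
average. The GLM uses linear + quadratic terms of standardized predictors
plus the sampling-bias covariate, optionally reduced by backward-forward
stepwise AIC with the bias term never dropped. The MaxEnt-like component is
an L1-penalized logistic regression on linear + quadratic + pairwise-product
features with the penalty chosen by 5-fold cross-validated deviance.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .grid import EnvGrid
from .occurrences import TrainingTable
from .range_metrics import SuitabilityMap

log = logging.getLogger(__name__)


# -- standardized term design ----------------------------------------------

@dataclass
class Standardizer:
    """Per-column mean/sd captured on the training table."""

    means: dict[str, float]
    sds: dict[str, float]

    @classmethod
    def fit(cls, df: pd.DataFrame, cols: list[str]) -> "Standardizer":
        means, sds = {}, {}
        for c in cols:
            v = df[c].to_numpy(float)
            means[c] = float(v.mean())
            sd = float(v.std())
            sds[c] = sd if sd > 0 else 1.0
        return cls(means, sds)

    def z(self, df: pd.DataFrame, col: str) -> np.ndarray:
        return (df[col].to_numpy(float) - self.means[col]) / self.sds[col]


def glm_terms(predictors: list[str]) -> list[str]:
    """Droppable GLM terms: a linear and a quadratic term per predictor."""
    out = []
    for p in predictors:
        out += [p, f"{p}^2"]
    return out


def build_design(df: pd.DataFrame, terms: list[str], std: Standardizer,
                 include_bias: bool = True) -> np.ndarray:
    """Design matrix: intercept column, then terms, then the bias covariate."""
    cols = [np.ones(len(df))]
    for t in terms:
        if t.endswith("^2"):
            cols.append(std.z(df, t[:-2]) ** 2)
        else:
            cols.append(std.z(df, t))
    if include_bias:
        cols.append(std.z(df, "bias"))
    return np.column_stack(cols)


# -- components -------------------------------------------------------------

@dataclass
class GlmComponent:
    """Weighted binomial logistic regression on linear+quadratic terms."""

    name: str
    predictors: list[str]
    terms: list[str]
    std: Standardizer
    params: np.ndarray
    deviance: float
    aic: float
    include_bias: bool = True

    def predict_df(self, df: pd.DataFrame) -> np.ndarray:
        X = build_design(df, self.terms, self.std, self.include_bias)
        return expit(X @ self.params)


#: Ridge applied to the normal equations (standardized design). Keeps IRLS
#: bounded under quasi-complete separation; far below coefficient scale.
_IRLS_RIDGE = 1e-6


def _fit_glm_design(y: np.ndarray, X: np.ndarray, w: np.ndarray,
                    start_params: np.ndarray | None = None,
                    maxiter: int = 100, tol: float = 1e-9):
    """Weighted-binomial IRLS with a tiny ridge; returns (params, dev, aic).

    For 0/1 responses the weighted log-likelihood is -deviance/2, so
    AIC = deviance + 2k.
    """
    n, k = X.shape
    beta = np.zeros(k) if start_params is None else np.asarray(start_params, float)
    ridge = _IRLS_RIDGE * np.eye(k)
    dev = _binomial_deviance(y, expit(X @ beta), w)
    for _ in range(maxiter):
        mu = np.clip(expit(X @ beta), 1e-10, 1 - 1e-10)
        wls_w = w * mu * (1 - mu)
        z = X @ beta + (y - mu) / (mu * (1 - mu))
        Xw = X * wls_w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ Xw + ridge, Xw.T @ z)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                f"GLM failed to converge (n={n}, k={k}): singular system: {exc}"
            ) from exc
        dev_new = _binomial_deviance(y, expit(X @ beta_new), w)
        if dev_new > dev + 1e-8:  # step overshoot: halve toward previous iterate
            for _ in range(20):
                beta_new = 0.5 * (beta_new + beta)
                dev_new = _binomial_deviance(y, expit(X @ beta_new), w)
                if dev_new <= dev + 1e-8:
                    break
        converged = abs(dev - dev_new) < tol * (abs(dev_new) + 0.1)
        beta, dev = beta_new, dev_new
        if converged:
            break
    if not np.all(np.isfinite(beta)):
        raise RuntimeError(f"GLM failed to converge (n={n}, k={k}): non-finite fit")
    return beta, float(dev), float(dev + 2 * k)


def _binomial_deviance(y, mu, w):
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    ll = y * np.log(mu) + (1 - y) * np.log(1 - mu)
    return float(-2 * np.sum(w * ll))


def fit_glm(table: TrainingTable, seed: int = 0,
            predictors: list[str] | None = None,
            include_bias: bool = True) -> GlmComponent:
    """Fit the full linear+quadratic weighted logistic GLM.

    ``predictors=[]`` with ``include_bias=True`` gives the bias-only null
    model used as the reference in deviance partitioning.
    """
    df = table.data
    y = df["response"].to_numpy(float)
    w = df["weight"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("degenerate response: single class, no contrast to fit")
    predictors = table.predictors if predictors is None else predictors
    terms = glm_terms(predictors)
    std = Standardizer.fit(df, predictors + ["bias"])
    X = build_design(df, terms, std, include_bias)
    params, dev, aic = _fit_glm_design(y, X, w)
    return GlmComponent("glm", predictors, terms, std, params, dev, aic, include_bias)


def stepwise_aic(component: GlmComponent, table: TrainingTable) -> GlmComponent:
    """Backward-forward stepwise term selection by AIC.

    Each linear and quadratic term is independently droppable; the
    intercept and the sampling-bias covariate always stay. Returns the
    AIC-minimal model found (never worse than the input model).
    """
    df = table.data
    y = df["response"].to_numpy(float)
    w = df["weight"].to_numpy(float)
    all_terms = list(component.terms)
    std = component.std
    X_full = build_design(df, all_terms, std, component.include_bias)
    n_terms = len(all_terms)
    bias_col = [n_terms + 1] if component.include_bias else []

    full_params, _, _ = _fit_glm_design(y, X_full, w)
    col_param = dict(zip([0] + [1 + i for i in range(n_terms)] + bias_col, full_params))

    def fit_subset(active: tuple[int, ...]):
        cols = [0] + [1 + i for i in active] + bias_col
        start = np.array([col_param[c] for c in cols])
        params, dev, aic = _fit_glm_design(y, X_full[:, cols], w, start_params=start)
        return params, dev, aic

    cache: dict[tuple[int, ...], tuple] = {}

    def cached(active_set: frozenset[int]):
        key = tuple(sorted(active_set))
        if key not in cache:
            cache[key] = fit_subset(key)
        return cache[key]

    current = frozenset(range(n_terms))
    _, _, best_aic = cached(current)
    improved = True
    while improved:
        improved = False
        candidates = [current - {i} for i in current] + \
                     [current | {i} for i in range(n_terms) if i not in current]
        for cand in candidates:
            _, _, aic = cached(cand)
            if aic < best_aic - 1e-9:
                best_aic, current, improved = aic, cand, True
    params, dev, aic = cached(current)
    kept = [all_terms[i] for i in sorted(current)]
    return GlmComponent(component.name, component.predictors, kept, std,
                        params, dev, aic, component.include_bias)


@dataclass
class RfComponent:
    """Probability-voting random forest honoring case weights."""

    name: str
    predictors: list[str]
    model: RandomForestClassifier
    feature_names: list[str] = field(default_factory=list)

    def predict_df(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.feature_names].to_numpy(float)
        return self.model.predict_proba(X)[:, 1]


def fit_rf(table: TrainingTable, seed: int = 0, n_trees: int = 500,
           min_samples_leaf: int = 25) -> RfComponent:
    """Random forest on raw predictors + bias (trees need no quadratics).

    Leaves are kept large (default 25 rows) so tree votes estimate the
    local presence probability instead of memorizing individual presence
    labels — the component outputs a suitability, not a classification.
    """
    feats = table.predictors + ["bias"]
    df = table.data
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                   min_samples_leaf=min_samples_leaf, n_jobs=1)
    model.fit(df[feats].to_numpy(float), df["response"].to_numpy(int),
              sample_weight=df["weight"].to_numpy(float))
    return RfComponent("rf", table.predictors, model, feats)


@dataclass
class MaxentComponent:
    """L1-penalized logistic regression on an expanded feature basis."""

    name: str
    predictors: list[str]
    std: Standardizer
    model: LogisticRegression | None
    feature_terms: list[tuple[str, ...]] = field(default_factory=list)
    C_chosen: float = float("nan")

    def features(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for term in self.feature_terms:
            if len(term) == 1:
                cols.append(self.std.z(df, term[0]))
            else:  # quadratic or product
                a, b = term
                cols.append(self.std.z(df, a) * self.std.z(df, b))
        return np.column_stack(cols)

    def predict_df(self, df: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(self.features(df))[:, 1]


def fit_maxentlike(table: TrainingTable, seed: int = 0,
                   Cs: np.ndarray | None = None, n_folds: int = 5) -> MaxentComponent:
    """Penalized-logistic analogue of MaxEnt on quadratic+product features.

    The L1 penalty is chosen by k-fold cross-validated weighted deviance
    with the one-standard-error rule: the strongest penalty whose CV
    deviance is within one SE of the minimum. That keeps features with no
    real signal at exactly zero.
    """
    df = table.data
    vars_all = table.predictors + ["bias"]
    std = Standardizer.fit(df, vars_all)
    terms: list[tuple[str, ...]] = [(v,) for v in vars_all]
    terms += [(v, v) for v in table.predictors]
    terms += [(a, b) for a, b in itertools.combinations(table.predictors, 2)]
    comp = MaxentComponent("maxent-like", table.predictors, std, None, terms)
    X = comp.features(df)
    y = df["response"].to_numpy(int)
    w = df["weight"].to_numpy(float)
    if Cs is None:
        Cs = np.logspace(-2, 0.7, 6)  # larger C invites separation blow-ups
    Cs = np.sort(np.asarray(Cs, float))

    def l1_fit(C, Xt, yt, wt):
        m = LogisticRegression(C=C, penalty="l1", solver="liblinear",
                               max_iter=500, random_state=0)
        with warnings.catch_warnings():
            # sklearn 1.8+ renames penalty= to l1_ratio=; liblinear still
            # needs the old spelling
            warnings.simplefilter("ignore", FutureWarning)
            warnings.simplefilter("ignore", UserWarning)
            m.fit(Xt, yt, sample_weight=wt)
        return m

    kf = KFold(n_folds, shuffle=True, random_state=seed)
    dev = np.zeros((Cs.size, n_folds))
    for j, (tr, va) in enumerate(kf.split(X)):
        for i, C in enumerate(Cs):
            m = l1_fit(C, X[tr], y[tr], w[tr])
            p = np.clip(m.predict_proba(X[va])[:, 1], 1e-12, 1 - 1e-12)
            dev[i, j] = -2 * np.sum(
                w[va] * (y[va] * np.log(p) + (1 - y[va]) * np.log(1 - p))
            ) / w[va].sum()
    mean = dev.mean(axis=1)
    best = int(np.argmin(mean))
    se_best = dev[best].std(ddof=1) / np.sqrt(n_folds)
    eligible = np.nonzero(mean <= mean[best] + se_best)[0]
    chosen = float(Cs[eligible[0]])  # smallest C = strongest penalty
    comp.model = l1_fit(chosen, X, y, w)
    comp.C_chosen = chosen
    return comp


# -- ensemble ---------------------------------------------------------------

@dataclass
class FittedEnsemble:
    """Component models plus training metadata needed to project them."""

    components: list
    species_id: str
    predictors: list[str]
    bias_max: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("ensemble needs at least one fitted component")


def fit_ensemble(table: TrainingTable, seed: int = 0, stepwise: bool = True,
                 n_trees: int = 500) -> FittedEnsemble:
    """Fit GLM (stepwise-reduced), random forest and MaxEnt-like components."""
    glm = fit_glm(table, seed)
    if stepwise:
        glm = stepwise_aic(glm, table)
    rf = fit_rf(table, seed, n_trees=n_trees)
    mx = fit_maxentlike(table, seed)
    return FittedEnsemble([glm, rf, mx], table.species_id, table.predictors,
                          float(table.data["bias"].max()), seed)


def predict_table(ens: FittedEnsemble, df: pd.DataFrame) -> np.ndarray:
    """Unweighted mean of component predictions on table rows.

    Components are averaged in name order so the result is bit-identical
    under any permutation of the component list.
    """
    ordered = sorted(ens.components, key=lambda c: c.name)
    preds = np.stack([c.predict_df(df) for c in ordered])
    return preds.mean(axis=0)


def predict_ensemble(ens: FittedEnsemble, env: EnvGrid,
                     bias_value: str | float = "max",
                     scenario: str = "current", mode: str = "current") -> SuitabilityMap:
    """Project the ensemble over a grid.

    The sampling-bias covariate is fixed at its training maximum when
    ``bias_value="max"`` (the projection convention), or at the given real.
    Masked cells stay masked.
    """
    missing = [n for n in ens.predictors if n not in env.layers]
    if missing:
        raise KeyError(f"environment lacks predictor layers: {missing}")
    ok = ~env.mask
    df = pd.DataFrame({n: env.layers[n][ok] for n in ens.predictors})
    df["bias"] = ens.bias_max if bias_value == "max" else float(bias_value)
    vals = np.zeros(env.shape)
    vals[ok] = np.clip(predict_table(ens, df), 0.0, 1.0)
    return SuitabilityMap(env.origin_lon, env.origin_lat, env.res_arcmin,
                          vals, env.mask.copy(), ens.species_id, scenario, mode)
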