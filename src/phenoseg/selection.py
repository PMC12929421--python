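"""Multi-method feature selection against canopy coverage.

Four routes: a Pearson correlation screen (|r| > 0.8 by default), LASSO
with 5-fold cross-validation and the one-standard-error rule, least-angle
regression (first k entries of the forward path), and competitive adaptive
reweighted sampling (CARS) over PLS regression coefficients with an
exponentially decreasing retention budget. A consensus report counts
per-feature selection frequency across methods; the core set is the
intersection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Lasso, lars_path, lasso_path
from sklearn.model_selection import KFold

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "pearson_screen",
    "lasso_select",
    "lars_select",
    "cars_select",
    "cars_retention_schedule",
    "consensus",
]


@dataclass
class SelectionConfig:
    pearson_threshold: float = 0.8
    lasso_cv_folds: int = 5
    lasso_n_lambdas: int = 100
    lars_max_steps: int | None = None    # default: size of the Pearson screen
    cars_runs: int = 50
    cars_row_ratio: float = 0.8
    cars_max_components: int = 5
    cars_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pearson_threshold < 1:
            raise ValueError("pearson_threshold must be in (0, 1)")
        if self.cars_runs < 2:
            raise ValueError("cars_runs must be >= 2")
        if not 0 < self.cars_row_ratio < 1:
            raise ValueError("cars_row_ratio must be in (0, 1)")


@dataclass
class SelectionResult:
    method: str
    selected: list[str]                    # ordered by method-specific importance
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected feature names must be unique")


def _validate_xy(X: pd.DataFrame, y: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    if len(X) != len(y):
        raise ValueError(f"X has {len(X)} rows but y has {len(y)}")
    if len(X) < 3:
        raise ValueError("need >= 3 rows")
    return X, y


def _standardize(X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    keep = sd > 0
    dropped = [c for c, k in zip(X.columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}")
    arr = arr[:, keep]
    arr = (arr - arr.mean(axis=0)) / arr.std(axis=0)
    return arr, [c for c, k in zip(X.columns, keep) if k]


def pearson_screen(X: pd.DataFrame, y: np.ndarray,
                   threshold: float = 0.8) -> SelectionResult:
    """All features with |r| > threshold, sorted by |r| descending."""
    X, y = _validate_xy(X, y)
    if y.std() == 0:
        raise ValueError("y has zero variance")
    rs: dict[str, float] = {}
    excluded: list[str] = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if x.std() == 0:
            excluded.append(col)
            continue
        rs[col] = float(np.corrcoef(x, y)[0, 1])
    if excluded:
        warnings.warn(f"zero-variance columns excluded from the screen: {excluded}")
    hits = sorted((c for c, r in rs.items() if abs(r) > threshold),
                  key=lambda c: -abs(rs[c]))
    return SelectionResult(method="pearson", selected=hits,
                           diagnostics={"r": rs, "threshold": threshold,
                                        "excluded": excluded})


def lasso_select(X: pd.DataFrame, y: np.ndarray,
                 config: SelectionConfig | None = None) -> SelectionResult:
    """L1 path over a lambda grid; lambda chosen by CV MSE with the 1-SE rule.

    Selected features are the nonzero coefficients at the chosen lambda,
    ordered by |coefficient| descending.
    """
    config = config or SelectionConfig()
    X, y = _validate_xy(X, y)
    if y.std() == 0:
        raise ValueError("y has zero variance (degenerate response)")
    Xs, names = _standardize(X)
    yc = y - y.mean()
    n = len(yc)

    alpha_max = np.max(np.abs(Xs.T @ yc)) / n
    alphas = np.geomspace(alpha_max, alpha_max * 1e-4, config.lasso_n_lambdas)

    kf = KFold(n_splits=config.lasso_cv_folds, shuffle=True,
               random_state=config.seed)
    mse = np.zeros((config.lasso_cv_folds, len(alphas)))
    for fi, (tr, te) in enumerate(kf.split(Xs)):
        _, coefs, _ = lasso_path(Xs[tr], yc[tr], alphas=alphas, max_iter=10_000)
        pred = Xs[te] @ coefs + yc[tr].mean()
        mse[fi] = ((pred - yc[te][:, None]) ** 2).mean(axis=0)
    mean_mse = mse.mean(axis=0)
    se = mse.std(axis=0, ddof=1) / np.sqrt(config.lasso_cv_folds)
    i_min = int(mean_mse.argmin())
    # 1-SE rule: the sparsest (largest) lambda within one SE of the minimum
    within = np.nonzero(mean_mse <= mean_mse[i_min] + se[i_min])[0]
    i_sel = int(within.min())

    model = Lasso(alpha=alphas[i_sel], fit_intercept=True, max_iter=50_000)
    model.fit(Xs, yc)
    coef = model.coef_
    order = np.argsort(-np.abs(coef))
    selected = [names[j] for j in order if abs(coef[j]) > 1e-10]
    return SelectionResult(
        method="lasso", selected=selected,
        diagnostics={"alpha": float(alphas[i_sel]),
                     "alpha_min_mse": float(alphas[i_min]),
                     "alphas": alphas.tolist(),
                     "cv_mse": mean_mse.tolist(),
                     "cv_se": se.tolist(),
                     "coefficients": dict(zip(names, coef.tolist())),
                     "seed": config.seed})


def lars_select(X: pd.DataFrame, y: np.ndarray,
                k: int | None = None) -> SelectionResult:
    """First ``k`` features to enter the least-angle-regression path,
    in entry order. Exactly collinear ties resolve first-by-column-name."""
    X, y = _validate_xy(X, y)
    Xs, names = _standardize(X)
    if k is None:
        k = len(names)
    if k > len(names):
        raise ValueError(f"k={k} exceeds the number of usable features {len(names)}")
    yc = y - y.mean()
    alphas, active, coefs = lars_path(Xs, yc, method="lar")
    entry_order = [names[j] for j in active][:k]
    return SelectionResult(
        method="lars", selected=entry_order,
        diagnostics={"k": k,
                     "full_entry_order": [names[j] for j in active],
                     "alphas": alphas.tolist(),
                     "coef_path": coefs.tolist()})


def cars_retention_schedule(p: int, n_runs: int) -> np.ndarray:
    """Exponentially decreasing retention fractions r_i = a*exp(-k*i) with
    r_1 = 1 and r_N = 2/p (closed form a = (p/2)^(1/(N-1)) = e^k)."""
    if p < 2:
        raise ValueError("need p >= 2 features")
    n = n_runs
    kk = np.log(p / 2.0) / (n - 1)
    a = np.exp(kk)
    i = np.arange(1, n + 1)
    return a * np.exp(-kk * i)


def _pls_rmsecv(X: np.ndarray, y: np.ndarray, max_comp: int, folds: int,
                seed: int) -> tuple[float, int]:
    """RMSE of K-fold CV PLS predictions; component count chosen by inner CV."""
    n, p = X.shape
    best = (np.inf, 1)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for ncomp in range(1, min(max_comp, p, n - 2) + 1):
        sq = 0.0
        for tr, te in kf.split(X):
            pls = PLSRegression(n_components=ncomp, scale=False)
            pls.fit(X[tr], y[tr])
            pred = pls.predict(X[te]).ravel()
            sq += ((pred - y[te]) ** 2).sum()
        rmse = np.sqrt(sq / n)
        if rmse < best[0]:
            best = (rmse, ncomp)
    return best


def cars_select(X: pd.DataFrame, y: np.ndarray,
                config: SelectionConfig | None = None) -> SelectionResult:
    """Competitive adaptive reweighted sampling over PLS coefficients.

    Each run fits PLS on a Monte-Carlo row sample, weights features by
    normalised |coefficient|, enforces the exponentially decreasing
    retention budget (top features by weight), then resamples within the
    budget with probability proportional to the weights. The run whose
    retained set minimises cross-validated RMSE wins.
    """
    config = config or SelectionConfig()
    X, y = _validate_xy(X, y)
    if len(X) < config.cars_cv_folds:
        raise ValueError("need n >= CV folds")
    Xs, names = _standardize(X)
    p = len(names)
    if p < 2:
        raise ValueError("need >= 2 usable features")
    yc = y - y.mean()
    n = len(yc)
    rng = np.random.default_rng(config.seed)

    ratios = cars_retention_schedule(p, config.cars_runs)
    retained = np.arange(p)
    history = []
    best = (np.inf, retained.copy(), 0)
    n_sub = max(config.cars_cv_folds, int(np.ceil(config.cars_row_ratio * n)))

    for run, ratio in enumerate(ratios, start=1):
        if len(retained) < 2:
            warnings.warn(f"retained set collapsed at run {run}; stopping early")
            break
        rows = rng.choice(n, size=n_sub, replace=False)
        Xr = Xs[np.ix_(rows, retained)]
        yr = yc[rows]
        ncomp = min(config.cars_max_components, len(retained), len(rows) - 2)
        pls = PLSRegression(n_components=max(1, ncomp), scale=False)
        pls.fit(Xr, yr)
        w = np.abs(np.asarray(pls.coef_).ravel())
        if w.sum() == 0:
            w = np.ones_like(w)
        w = w / w.sum()

        budget = max(2, int(round(ratio * p)))
        budget = min(budget, len(retained))
        # enforced top-by-weight cut, then adaptive reweighted sampling
        top = np.argsort(-w)[:budget]
        w_top = w[top] / w[top].sum()
        draws = rng.choice(len(top), size=budget, replace=True, p=w_top)
        keep_local = np.unique(top[draws])
        if len(keep_local) < 2:   # budget floor: never collapse below 2
            keep_local = top[:2]
        retained = retained[keep_local]

        rmsecv, ncomp_used = _pls_rmsecv(Xs[:, retained], yc,
                                         config.cars_max_components,
                                         config.cars_cv_folds, config.seed)
        history.append({"run": run, "ratio": float(ratio),
                        "n_retained": int(len(retained)),
                        "rmsecv": float(rmsecv),
                        "n_components": ncomp_used,
                        "retained": [names[j] for j in retained]})
        if rmsecv < best[0]:
            best = (rmsecv, retained.copy(), run)

    final_idx = best[1]
    # order by final PLS |coefficient| on the winning subset
    pls = PLSRegression(n_components=max(1, min(config.cars_max_components,
                                                len(final_idx), n - 2)),
                        scale=False)
    pls.fit(Xs[:, final_idx], yc)
    w = np.abs(np.asarray(pls.coef_).ravel())
    order = np.argsort(-w)
    selected = [names[final_idx[j]] for j in order]
    return SelectionResult(
        method="cars", selected=selected,
        diagnostics={"best_run": best[2], "best_rmsecv": float(best[0]),
                     "schedule": ratios.tolist(), "history": history,
                     "seed": config.seed})


def consensus(results: list[SelectionResult]) -> dict:
    """Cross-method agreement: per-feature frequency, core set (selected by
    every method) and the pairwise overlap matrix."""
    if len(results) < 2:
        raise ValueError("need >= 2 selection results")
    sets = {r.method: set(r.selected) for r in results}
    all_feats = sorted(set().union(*sets.values()))
    freq = {f: sum(f in s for s in sets.values()) for f in all_feats}
    core = sorted(set.intersection(*sets.values())) if sets else []
    methods = list(sets)
    overlap = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in methods] for a in methods],
        index=methods, columns=methods)
    table = pd.DataFrame(
        {"feature": all_feats,
         "n_methods_selected": [freq[f] for f in all_feats],
         "methods": [",".join(m for m in methods if f in sets[m])
                     for f in all_feats]})
    return {"frequency": freq, "core_set": core, "overlap": overlap,
            "table": table.sort_values(["n_methods_selected", "feature"],
                                       ascending=[False, True])
                          .reset_index(drop=True)}
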