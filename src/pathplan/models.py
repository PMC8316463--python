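"""Logistic choice models, surrogate bootstrap, effect partition, LOOCV, and
the judgment-test psychometric threshold.

Choices are coded right = 1, left = 0.  The multivariate model standardizes
its features over the design before fitting, selects a sparse feature set
with an L1 penalty, and reports effects from an unpenalized refit on the
selected set (avoiding shrinkage bias).

Uncertainty comes from two seeded resampling routes, both at 2000
replicates by default: label-shuffled surrogates give null p-values
(fraction of surrogate effects at least as large in magnitude as the
observed one) and case resampling gives percentile 95% CIs.  Both routes
run through a batched, frequency-weighted IRLS solver so thousands of
refits stay cheap.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy.special import expit
from scipy.stats import pearsonr, spearmanr
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "UnivariateFit",
    "ChoiceModelFit",
    "JudgmentCurve",
    "fit_univariate",
    "fit_multivariate",
    "bootstrap_effects",
    "effect_partition",
    "loocv_accuracy",
    "judgment_threshold",
    "fit_amgr_models",
    "choice_probability_table",
    "batched_logit_fit",
]

MAIN_EFFECTS = ("delta_theta", "delta_d", "amr")
INTERACTIONS = ("delta_theta:delta_d", "delta_theta:amr")


@contextmanager
def _quiet():
    """Silence per-iteration optimizer warnings; flags carry the signal."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@dataclass(frozen=True)
class UnivariateFit:
    feature: str
    coef: float
    intercept: float
    p_value: float
    se: float
    separated: bool = False


@dataclass
class ChoiceModelFit:
    """Multivariate fit: standardized effects, selection, and diagnostics."""

    coefficients: dict[str, float]
    intercept: float
    selected: tuple[str, ...]
    scaler_mean: dict[str, float]
    scaler_sd: dict[str, float]
    penalty_C: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    partition_shares: dict[str, float] = field(default_factory=dict)
    loocv_mean: float | None = None
    loocv_sd: float | None = None


def _check_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both classes (0 and 1) must be present")


def _is_separated(x: np.ndarray, y: np.ndarray) -> bool:
    x0, x1 = x[y == 0], x[y == 1]
    return bool(x0.max() < x1.min() or x1.max() < x0.min())


def fit_univariate(x: Sequence[float], y: Sequence[int], feature: str = "x") -> UnivariateFit:
    """Maximum-likelihood logistic slope for one feature, with Wald p.

    Perfectly separated data are flagged and reported with an unbounded
    slope instead of a spurious finite estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    _check_classes(y)
    if np.ptp(x) == 0:
        raise ValueError("feature is constant; slope undefined")
    if _is_separated(x, y):
        sign = 1.0 if x[y == 1].mean() > x[y == 0].mean() else -1.0
        return UnivariateFit(feature, sign * np.inf, np.nan, np.nan, np.inf, True)
    model = sm.Logit(y, sm.add_constant(x))
    with _quiet():
        res = model.fit(disp=0, maxiter=200)
    return UnivariateFit(
        feature=feature,
        coef=float(res.params[1]),
        intercept=float(res.params[0]),
        p_value=float(res.pvalues[1]),
        se=float(res.bse[1]),
        separated=False,
    )


def _standardize(X: pd.DataFrame) -> tuple[np.ndarray, dict, dict]:
    mean = X.mean()
    sd = X.std(ddof=0).replace(0.0, 1.0)
    Z = (X - mean) / sd
    return Z.to_numpy(), mean.to_dict(), sd.to_dict()


def _design_with_interactions(Z: np.ndarray, names: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols = [Z[:, i] for i in range(Z.shape[1])]
    out_names = list(names)
    idx = {n: i for i, n in enumerate(names)}
    for pair in INTERACTIONS:
        a, b = pair.split(":")
        if a in idx and b in idx:
            cols.append(Z[:, idx[a]] * Z[:, idx[b]])
            out_names.append(pair)
    return np.column_stack(cols), out_names


def fit_multivariate(
    features: pd.DataFrame,
    y: Sequence[int],
    include_interactions: bool = True,
    penalty_C: float | str = "cv",
    rng: np.random.Generator | None = None,
) -> ChoiceModelFit:
    """L1-selected, refit-unpenalized logistic model on standardized features.

    ``features`` must contain the main-effect columns (``delta_theta``,
    ``delta_d``, ``amr``); interactions with ``delta_theta`` are appended on
    the standardized scale.  ``penalty_C="cv"`` picks the L1 strength by
    internal cross-validation.
    """
    y = np.asarray(y, dtype=int)
    _check_classes(y)
    missing = [c for c in MAIN_EFFECTS if c not in features.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    X = features[list(MAIN_EFFECTS)].astype(float)
    Z, mean, sd = _standardize(X)
    if include_interactions:
        D, names = _design_with_interactions(Z, MAIN_EFFECTS)
    else:
        D, names = Z, list(MAIN_EFFECTS)

    seed = int(rng.integers(2**31 - 1)) if rng is not None else 0
    with _quiet():
        if penalty_C == "cv":
            lasso = LogisticRegressionCV(
                Cs=10, cv=5, penalty="l1", solver="liblinear", random_state=seed
            ).fit(D, y)
            C = float(lasso.C_[0])
        else:
            C = float(penalty_C)
            lasso = LogisticRegression(
                C=C, penalty="l1", solver="liblinear", random_state=seed
            ).fit(D, y)
    lasso_coefs = lasso.coef_.ravel()
    selected = [n for n, c in zip(names, lasso_coefs) if abs(c) > 1e-8]
    if not selected:  # degenerate penalty: keep main effects
        selected = list(MAIN_EFFECTS)

    # perfectly collinear survivors would make the unpenalized refit
    # singular; keep the first of each duplicated column and zero the rest
    pruned: list[str] = []
    for name in selected:
        col = D[:, names.index(name)]
        if any(
            np.allclose(col, D[:, names.index(prev)])
            or np.allclose(col, -D[:, names.index(prev)])
            for prev in pruned
        ):
            warnings.warn(
                f"feature {name!r} is collinear with a selected feature; dropped",
                stacklevel=2,
            )
            continue
        pruned.append(name)
    selected = pruned

    keep_idx = [names.index(n) for n in selected]
    with _quiet():
        refit = sm.Logit(y, sm.add_constant(D[:, keep_idx])).fit(disp=0, maxiter=200)
    coefficients = {n: 0.0 for n in names}
    p_values = {}
    for i, n in enumerate(selected):
        coefficients[n] = float(refit.params[i + 1])
        p_values[n] = float(refit.pvalues[i + 1])
    fit = ChoiceModelFit(
        coefficients=coefficients,
        intercept=float(refit.params[0]),
        selected=tuple(selected),
        scaler_mean=mean,
        scaler_sd=sd,
        penalty_C=C,
        p_values=p_values,
    )
    fit.partition_shares = effect_partition(
        {n: coefficients[n] for n in MAIN_EFFECTS}
    )
    return fit


# ---------------------------------------------------------------------------
# Batched weighted IRLS (the resampling engine)

def batched_logit_fit(
    X: np.ndarray,
    Y: np.ndarray,
    weights: np.ndarray | None = None,
    n_iter: int = 30,
    ridge: float = 1e-8,
    chunk: int = 200,
) -> np.ndarray:
    """Fit B logistic regressions sharing the design matrix ``X`` (n, d).

    ``Y`` is (B, n) labels; ``weights`` (B, n) optional frequency weights
    (case resampling is expressed as multinomial count weights so the
    design never has to be materialized per replicate).  Returns (B, d)
    coefficient rows.  A small ridge keeps shuffled/near-separated
    replicates finite.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    B, n = Y.shape
    d = X.shape[1]
    out = np.empty((B, d))
    for start in range(0, B, chunk):
        yb = Y[start : start + chunk]
        wb = None if weights is None else weights[start : start + chunk]
        out[start : start + chunk] = _irls_chunk(X, yb, wb, n_iter, ridge)
    return out


def _irls_chunk(X, Y, W, n_iter, ridge):
    B, n = Y.shape
    d = X.shape[1]
    beta = np.zeros((B, d))
    eye = ridge * np.eye(d)
    for _ in range(n_iter):
        eta = np.clip(beta @ X.T, -35, 35)
        p = expit(eta)
        w = p * (1 - p) + 1e-10
        resid = Y - p
        if W is not None:
            w = w * W
            resid = resid * W
        grad = resid @ X
        # Hessian per replicate: X^T diag(w_b) X
        WX = w[:, :, None] * X[None, :, :]
        H = np.einsum("bnd,ne->bde", WX, X) + eye
        step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        np.clip(step, -10, 10, out=step)
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    return beta


def bootstrap_effects(
    features: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    n_surrogates: int = 2000,
    rng: np.random.Generator | None = None,
    standardize: bool = False,
) -> dict[str, dict]:
    """Surrogate-null p-values and percentile bootstrap CIs for each slope.

    Two resampling routes: (a) label shuffling -> null distribution of each
    effect, p = fraction of surrogates with ``|effect| >= |observed|``;
    (b) case resampling -> percentile 95% CI.  Seeded via ``rng``.
    """
    if n_surrogates < 100:
        raise ValueError("n_surrogates must be >= 100")
    rng = rng or np.random.default_rng(0)
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        F = features.to_numpy(dtype=float)
    else:
        F = np.atleast_2d(np.asarray(features, dtype=float))
        if F.shape[0] != len(y):
            F = F.T
        names = [f"x{i}" for i in range(F.shape[1])]
    y = np.asarray(y, dtype=float)
    _check_classes(y.astype(int))
    if standardize:
        F = (F - F.mean(axis=0)) / np.where(F.std(axis=0) == 0, 1, F.std(axis=0))
    n = len(y)
    X = np.column_stack([np.ones(n), F])

    observed = batched_logit_fit(X, y[None, :])[0]

    # (a) label-shuffle surrogates
    shuffled = np.empty((n_surrogates, n))
    for b in range(n_surrogates):
        shuffled[b] = y[rng.permutation(n)]
    null_betas = batched_logit_fit(X, shuffled)

    # (b) case resampling as multinomial frequency weights
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_surrogates).astype(float)
    boot_betas = batched_logit_fit(X, np.broadcast_to(y, (n_surrogates, n)), counts)

    out = {}
    for j, name in enumerate(names):
        obs = float(observed[j + 1])
        null = null_betas[:, j + 1]
        boot = boot_betas[:, j + 1]
        out[name] = {
            "observed": obs,
            "p_value": float(np.mean(np.abs(null) >= abs(obs))),
            "ci": (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5))),
            "se": float(boot.std(ddof=1)),
        }
    return out


def effect_partition(effects: Mapping[str, float]) -> dict[str, float]:
    """Percent share of each main effect: |effect| / sum |effects| * 100.

    Interactions are excluded by passing only main effects.  Raises when
    every effect is zero.
    """
    keys = list(effects)
    mags = np.array([abs(effects[k]) for k in keys], dtype=float)
    total = mags.sum()
    if total == 0:
        raise ValueError("all effects are zero; partition undefined")
    return {k: float(m / total * 100.0) for k, m in zip(keys, mags)}


def loocv_accuracy(
    features: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    unit_ids: Sequence | None = None,
) -> tuple[float, float]:
    """Leave-one-unit-out accuracy (%), mean and SD.

    The default unit is the trial (row).  With ``unit_ids`` all rows
    sharing an id are held out together and per-fold accuracy is the
    fraction correct among them; SD is across folds either way.  A
    predicted probability of exactly 0.5 counts as incorrect.
    """
    if isinstance(features, pd.DataFrame):
        F = features.to_numpy(dtype=float)
    else:
        F = np.atleast_2d(np.asarray(features, dtype=float))
        if F.shape[0] != len(y):
            F = F.T
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 units")
    X = np.column_stack([np.ones(n), F])
    if unit_ids is None:
        folds = [np.array([i]) for i in range(n)]
    else:
        unit_ids = np.asarray(unit_ids)
        folds = [np.flatnonzero(unit_ids == u) for u in pd.unique(unit_ids)]
    if len(folds) < 2:
        raise ValueError("need at least 2 folds")
    weights = np.ones((len(folds), n))
    for k, idx in enumerate(folds):
        weights[k, idx] = 0.0
        held_y = y[idx]
        if len(np.unique(np.delete(y, idx))) < 2:
            raise ValueError("degenerate fold: one class absent from training data")
        del held_y
    betas = batched_logit_fit(X, np.broadcast_to(y, (len(folds), n)), weights)
    fold_acc = []
    for k, idx in enumerate(folds):
        p = expit(X[idx] @ betas[k])
        # a tie at exactly 0.5 counts as incorrect either way
        correct = ((p > 0.5) & (y[idx] == 1)) | ((p < 0.5) & (y[idx] == 0))
        fold_acc.append(float(np.mean(correct)))
    acc = np.asarray(fold_acc)
    return float(acc.mean() * 100.0), float(acc.std(ddof=1) * 100.0)


@dataclass(frozen=True)
class JudgmentCurve:
    """Fitted psychometric curve of the path-selection judgment test."""

    offsets: tuple[float, ...]
    p_right: tuple[float, ...]
    threshold: float  # 50% crossing, cm (+ = right of shelf center)
    slope: float  # logit per cm
    extrapolated: bool
    monotone_rho: float


def judgment_threshold(ratings: pd.DataFrame) -> JudgmentCurve:
    """Least-squares logistic psychometric fit to 0-10 ratings.

    ``ratings`` has columns ``offset_cm`` and ``rating``; mean rating / 10
    per offset is treated as P(right).  The threshold is the fitted 50%
    crossing; fits without a crossing inside the offset range are flagged
    as extrapolated.
    """
    grouped = ratings.groupby("offset_cm")["rating"].mean() / 10.0
    offsets = grouped.index.to_numpy(dtype=float)
    p = grouped.to_numpy(dtype=float)
    if len(offsets) < 4:
        raise ValueError("need ratings at >= 4 distinct offsets")

    def curve(x, slope, thr):
        return expit(slope * (x - thr))

    p0 = (0.1, float(offsets[np.argmin(np.abs(p - 0.5))]))
    popt, _ = curve_fit(curve, offsets, p, p0=p0, maxfev=10000)
    slope, thr = float(popt[0]), float(popt[1])
    extrapolated = not (offsets.min() <= thr <= offsets.max()) or (
        p.min() > 0.5 or p.max() < 0.5
    )
    rho = float(spearmanr(offsets, p).statistic)
    return JudgmentCurve(
        offsets=tuple(offsets),
        p_right=tuple(curve(offsets, *popt)),
        threshold=thr,
        slope=slope,
        extrapolated=extrapolated,
        monotone_rho=rho,
    )


def fit_amgr_models(
    amgr_values: Sequence[float],
    amr_values: Sequence[float],
    y: Sequence[int],
) -> dict[str, UnivariateFit | dict]:
    """Univariate (AMGR) and bivariate (AMGR + AMR) logistic fits.

    Rows with undefined AMGR (NaN) are refused; callers filter first.
    """
    amgr_arr = np.asarray(amgr_values, dtype=float)
    if np.isnan(amgr_arr).any():
        raise ValueError("undefined AMGR rows present; filter before fitting")
    uni = fit_univariate(amgr_arr, y, feature="amgr")
    amr_arr = np.asarray(amr_values, dtype=float)
    y_arr = np.asarray(y, dtype=int)
    X = sm.add_constant(np.column_stack([amgr_arr, amr_arr]))
    try:
        with _quiet():
            res = sm.Logit(y_arr, X).fit(disp=0, maxiter=200)
        bi = {
            "amgr": {"coef": float(res.params[1]), "p_value": float(res.pvalues[1])},
            "amr": {"coef": float(res.params[2]), "p_value": float(res.pvalues[2])},
            "intercept": float(res.params[0]),
            "separated": False,
        }
    except np.linalg.LinAlgError:
        # (near-)separated data: report a ridge-stabilized estimate, flagged
        beta = batched_logit_fit(X, y_arr[None, :].astype(float), ridge=1e-3)[0]
        bi = {
            "amgr": {"coef": float(beta[1]), "p_value": float("nan")},
            "amr": {"coef": float(beta[2]), "p_value": float("nan")},
            "intercept": float(beta[0]),
            "separated": True,
        }
    return {"univariate": uni, "bivariate": bi}


def choice_probability_table(
    df: pd.DataFrame,
    feature: str,
    bins: int | Sequence[float] = 8,
    by: str = "target_offset_cm",
) -> pd.DataFrame:
    """Empirical P(right) vs binned feature per target position, with
    binomial 95% CIs; empty bins are dropped."""
    if df.empty:
        raise ValueError("no trials")
    work = df.copy()
    work["_bin"] = pd.cut(work[feature], bins)
    rows = []
    for (grp, interval), sub in work.groupby([by, "_bin"], observed=True):
        n = len(sub)
        if n == 0:
            continue
        k = int((sub["choice"] == 1).sum())
        lo, hi = proportion_confint(k, n, method="wilson")
        rows.append(
            {
                by: grp,
                "bin_mid": float(interval.mid),
                "n": n,
                "p_right": k / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def start_foot_choice_correlation(
    start_foot: Sequence[str], chosen_side: Sequence[str]
) -> tuple[float, float]:
    """Pearson correlation between start-foot and chosen-side indicators.

    Returns (nan, nan) when either indicator is constant.
    """
    f = np.asarray([1.0 if s == "right" else 0.0 for s in start_foot])
    c = np.asarray([1.0 if s == "right" else 0.0 for s in chosen_side])
    if np.ptp(f) == 0 or np.ptp(c) == 0:
        return float("nan"), float("nan")
    r = pearsonr(f, c)
    return float(r.statistic), float(r.pvalue)
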