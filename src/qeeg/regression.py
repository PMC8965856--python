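"""Forward-stepwise multivariate linear regression.

SPSS-style stepwise selection over ordinary least squares: at each step the
candidate whose partial F/t test has the smallest p-value enters if that
p-value is <= ``p_enter`` (default 0.05); after each entry, included
predictors whose p-value exceeds ``p_remove`` (default 0.10) are removed,
worst first. With ``p_enter = p_remove = 1`` the procedure reduces exactly
to the full-entry OLS fit.

The estimator reports both the selected model and the full-entry model's
coefficient table: published stepwise tables often print coefficients for
every candidate, and the full-entry coefficients are the unbiased ones for
effect-size recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class RegressionTable:
    """Stepwise-regression report for one outcome."""

    outcome: str
    selected: pd.DataFrame      # per-candidate: name, B, t, p, selected (final model)
    full_model: pd.DataFrame    # per-candidate: name, B, t, p, selected (all-entered fit)
    trace: list                 # [("enter"|"remove", name), ...]
    r_squared: float            # R^2 of the selected model
    r_squared_full: float


def _ols(X: np.ndarray, y: np.ndarray):
    """OLS with intercept; returns (beta, t, p, r2). beta[0] is the intercept."""
    n = X.shape[0]
    A = np.column_stack([np.ones(n), X])
    k = A.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < k:
        raise np.linalg.LinAlgError("rank deficient design")
    resid = y - A @ beta
    dof = n - k
    if dof <= 0:
        raise ValueError("not enough observations for the candidate set")
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * sstats.t.sf(np.abs(t), df=dof)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return beta, t, p, r2


class StepwiseLinearRegression(RegressorMixin, BaseEstimator):
    """Forward-stepwise OLS with backward removal, sklearn-compatible.

    Parameters
    ----------
    p_enter : float
        Largest partial p-value at which a candidate may enter (default 0.05).
    p_remove : float
        Smallest p-value at which an included predictor is removed
        (default 0.10). Must satisfy ``p_remove >= p_enter`` to avoid cycling.

    Attributes
    ----------
    feature_names_in_ : ndarray of str
    selected_features_ : list of str — predictors in the final model.
    coef_, intercept_ : selected-model coefficients (coef_ is zero for
        unselected candidates, matching ``feature_names_in_`` order).
    table_ : :class:`RegressionTable` with selected and full-entry reports.
    """

    def __init__(self, p_enter: float = 0.05, p_remove: float = 0.10):
        self.p_enter = p_enter
        self.p_remove = p_remove

    def fit(self, X, y, outcome_name: str = "outcome"):
        if self.p_remove < self.p_enter:
            raise ValueError("p_remove must be >= p_enter")
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            names = [f"x{i}" for i in range(Xa.shape[1])]
        y = np.asarray(y, dtype=float).ravel()
        n, m = Xa.shape
        if y.shape[0] != n:
            raise ValueError("X and y length mismatch")
        if not (np.all(np.isfinite(Xa)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in design or outcome")
        if n <= m + 1:
            raise ValueError("need n > number of candidates + 1")
        self._check_collinearity(Xa, names)

        included: list[str] = []
        trace: list[tuple[str, str]] = []
        idx = {nm: j for j, nm in enumerate(names)}
        tss = float(((y - y.mean()) ** 2).sum())
        while True:
            changed = False
            # stop once the included model fits to machine precision:
            # partial tests on a numerically zero residual are meaningless
            if included:
                cols = [idx[c] for c in included]
                _, _, _, r2_cur = _ols(Xa[:, cols], y)
                if tss == 0 or 1.0 - r2_cur < 1e-12:
                    break
            # forward entry: candidate with smallest partial p
            best_name, best_p = None, np.inf
            for nm in names:
                if nm in included:
                    continue
                cols = [idx[c] for c in included + [nm]]
                try:
                    _, t, p, _ = _ols(Xa[:, cols], y)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if p[-1] < best_p:
                    best_name, best_p = nm, p[-1]
            if best_name is not None and best_p <= self.p_enter:
                included.append(best_name)
                trace.append(("enter", best_name))
                changed = True
            # backward removal: worst included predictor with p > p_remove
            while len(included) > 0:
                cols = [idx[c] for c in included]
                _, t, p, _ = _ols(Xa[:, cols], y)
                pv = p[1:]  # skip intercept
                worst = int(np.argmax(pv))
                if pv[worst] > self.p_remove:
                    trace.append(("remove", included[worst]))
                    del included[worst]
                    changed = True
                else:
                    break
            if not changed:
                break

        # selected-model report
        if included:
            cols = [idx[c] for c in included]
            beta_s, t_s, p_s, r2_s = _ols(Xa[:, cols], y)
        else:
            beta_s, t_s, p_s, r2_s = np.array([y.mean()]), np.array([np.nan]), np.array([np.nan]), 0.0
        sel_rows = []
        for nm in names:
            if nm in included:
                j = included.index(nm) + 1
                sel_rows.append((nm, beta_s[j], t_s[j], p_s[j], True))
            else:
                sel_rows.append((nm, np.nan, np.nan, np.nan, False))
        selected_df = pd.DataFrame(sel_rows, columns=["name", "B", "t", "p", "selected"])

        # full-entry report
        beta_f, t_f, p_f, r2_f = _ols(Xa, y)
        full_df = pd.DataFrame({
            "name": names,
            "B": beta_f[1:], "t": t_f[1:], "p": p_f[1:],
            "selected": [nm in included for nm in names],
        })

        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = m
        self.selected_features_ = list(included)
        self.intercept_ = float(beta_s[0])
        coef = np.zeros(m)
        for j, nm in enumerate(included):
            coef[idx[nm]] = beta_s[j + 1]
        self.coef_ = coef
        self.full_coef_ = beta_f[1:].copy()
        self.full_intercept_ = float(beta_f[0])
        self.table_ = RegressionTable(
            outcome=outcome_name,
            selected=selected_df,
            full_model=full_df,
            trace=trace,
            r_squared=r2_s,
            r_squared_full=r2_f,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names_in_)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    @staticmethod
    def _check_collinearity(X: np.ndarray, names: list[str]) -> None:
        centered = X - X.mean(axis=0)
        norms = np.linalg.norm(centered, axis=0)
        if np.any(norms == 0):
            bad = [nm for nm, s in zip(names, norms) if s == 0]
            raise ValueError(f"constant candidate column(s): {bad}")
        corr = (centered / norms).T @ (centered / norms)
        dup = [
            (names[i], names[j])
            for i in range(len(names)) for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        if dup:
            raise ValueError(f"collinear duplicate candidate columns: {dup}")


def stepwise_regression(
    outcome,
    candidates: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    outcome_name: str = "outcome",
) -> RegressionTable:
    """Functional wrapper over :class:`StepwiseLinearRegression`."""
    est = StepwiseLinearRegression(p_enter=p_enter, p_remove=p_remove)
    est.fit(candidates, np.asarray(outcome, dtype=float), outcome_name=outcome_name)
    return est.table_
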