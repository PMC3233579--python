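"""Per-trial analysis: adjusted treatment-effect estimation.

Each completed trial is analysed by ordinary least squares of the
response on an intercept, the treatment indicator, and one dummy per
non-reference level of every prognostic factor — the regression
adjustment for the force-balanced covariates.  The quantities recorded
per trial are the treatment coefficient, its model-based variance
estimate ``sigma_hat^2 * [(X'X)^-1]_tt`` with ``sigma_hat^2 = RSS/(n-p)``,
and the two-sided t-test p-value on ``n - p`` degrees of freedom.

The solver is a direct normal-equations Cholesky solve, which keeps the
Monte-Carlo loops fast; the design matrices here are tiny (at most a
dozen columns) and well-conditioned once constant columns are removed.
Levels unobserved in a cohort yield zero-variance dummies; these are
dropped and the fit is flagged degenerate rather than failing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .simulate import TrialRecord
from .state import FactorSpec


class FitError(RuntimeError):
    """The treatment effect is not estimable for this trial (all subjects
    in one arm, or no residual degrees of freedom)."""


@dataclass(frozen=True)
class FitResult:
    estimate: float
    variance_estimate: float
    p_value: float
    residual_df: int
    degenerate: bool
    dropped_columns: tuple[str, ...] = ()

    @property
    def std_error(self) -> float:
        return float(np.sqrt(self.variance_estimate))


def build_design_matrix(
    record_or_profiles: TrialRecord | np.ndarray,
    spec: FactorSpec | None = None,
    treatment: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str], tuple[str, ...]]:
    """Design matrix for the adjusted treatment-effect regression.

    Accepts either a :class:`TrialRecord` or an explicit ``(n, K)``
    profile matrix plus a treatment indicator.  Returns ``(X, labels,
    dropped)`` where columns are ``intercept``, ``treatment`` (1 for the
    treatment arm) and ``f{k}_l{l}`` dummies for every non-reference
    level; dummy columns constant in the sample are dropped and listed
    in ``dropped``.  The treatment column is never dropped — its
    degeneracy is the fitter's concern.
    """
    if isinstance(record_or_profiles, TrialRecord):
        record = record_or_profiles
        profiles = record.profiles
        spec = record.spec
        treatment = record.treatment_indicator
    else:
        profiles = np.asarray(record_or_profiles)
        if spec is None or treatment is None:
            raise ValueError("explicit profiles need a FactorSpec and a treatment indicator")
    n = len(profiles)
    columns = [np.ones(n), np.asarray(treatment, dtype=np.float64)]
    labels = ["intercept", "treatment"]
    dropped: list[str] = []
    for k, L in enumerate(spec.levels):
        for l in range(1, L):
            dummy = (profiles[:, k] == l).astype(np.float64)
            label = f"f{k}_l{l}"
            if dummy.min() == dummy.max():  # level unobserved (or universal)
                dropped.append(label)
            else:
                columns.append(dummy)
                labels.append(label)
    return np.column_stack(columns), labels, tuple(dropped)


def fit_treatment_effect(
    y: np.ndarray, X: np.ndarray, treatment_column: int = 1,
    dropped: tuple[str, ...] = (),
) -> FitResult:
    """OLS fit returning the treatment coefficient, variance and p-value.

    Raises :class:`FitError` when the treatment column is constant or no
    residual degrees of freedom remain.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("response length does not match the design matrix")
    t_col = X[:, treatment_column]
    if t_col.min() == t_col.max():
        raise FitError("treatment indicator is constant: all subjects in one arm")
    if n - p < 1:
        raise FitError(f"no residual degrees of freedom (n={n}, p={p})")

    xtx = X.T @ X
    xty = X.T @ y
    degenerate = bool(dropped)
    try:
        cho = linalg.cho_factor(xtx, check_finite=False)
        beta = linalg.cho_solve(cho, xty, check_finite=False)
        unit = np.zeros(p)
        unit[treatment_column] = 1.0
        inv_tt = linalg.cho_solve(cho, unit, check_finite=False)[treatment_column]
        df = n - p
    except linalg.LinAlgError:
        # residual collinearity after the zero-variance drops: pseudoinverse
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if n - rank < 1:
            raise FitError("singular design with no residual degrees of freedom")
        inv_tt = float(np.linalg.pinv(xtx)[treatment_column, treatment_column])
        df = n - rank
        degenerate = True

    resid = y - X @ beta
    rss = float(resid @ resid)
    if rss <= np.finfo(float).eps * max(1.0, float(y @ y)):
        rss = 0.0  # numerically perfect fit (e.g. constant response)
    sigma2 = rss / df
    estimate = float(beta[treatment_column])
    variance = float(sigma2 * inv_tt)
    if variance > 0:
        t_stat = estimate / np.sqrt(variance)
        p_value = float(2.0 * stats.t.sf(abs(t_stat), df))
    else:  # perfect fit (e.g. constant response): nothing to test
        p_value = 1.0 if abs(estimate) < 1e-12 else 0.0
    return FitResult(
        estimate=estimate,
        variance_estimate=variance,
        p_value=p_value,
        residual_df=int(df),
        degenerate=degenerate,
        dropped_columns=tuple(dropped),
    )


def analyze_trial(record: TrialRecord, adjust: bool = True) -> FitResult:
    """Build the design matrix and fit one trial.

    ``adjust=False`` regresses on the intercept and treatment indicator
    only, i.e. the pooled two-sample t-test — the conventional analysis
    for schemes that make no attempt to balance the prognostic factors.
    """
    if adjust:
        X, _, dropped = build_design_matrix(record)
        return fit_treatment_effect(record.responses, X, dropped=dropped)
    n = record.n
    X = np.column_stack([np.ones(n), record.treatment_indicator])
    return fit_treatment_effect(record.responses, X)
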