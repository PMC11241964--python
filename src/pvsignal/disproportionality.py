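"""Reporting odds ratios, the signal rule, and collinearity diagnostics.

The case/non-case method compares the odds of exposure among reports of the
event of interest (cases) with the odds among all other reports (non-cases)
within the same database.  The crude reporting odds ratio (r-OR) of the
2x2 table

    ==============  =========  ============
    .               cases      non-cases
    exposed         a          c
    unexposed       b          d
    ==============  =========  ============

is ``ad / bc`` with Woolf standard error of the log r-OR
``sqrt(1/a + 1/b + 1/c + 1/d)``.  Adjusted r-ORs are Wald estimates
``exp(beta)`` from a multivariable logistic regression of case status on
exposure and confounders, fit by iteratively reweighted least squares.
A *signal* is an r-OR whose 95% CI lower bound exceeds 1; r-ORs below 1
are never interpreted as protective — the method cannot support that
reading — and are classified as no_signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import ConvergenceError, EstimateError, PvSignalError, SeparationError

logger = logging.getLogger(__name__)

#: normal 97.5% quantile used for every 95% interval in the package, so the
#: Wald CI of a saturated 2x2 logistic fit reproduces the Woolf CI exactly
Z_95 = 1.96

SIGNAL = "signal"
NO_SIGNAL = "no_signal"

#: below this many exposed cases an estimate is flagged as low-count
LOW_COUNT_THRESHOLD = 10

#: |beta| beyond which continued growth across IRLS iterations is read as separation
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class ContingencyTable:
    """Case-by-exposure counts: a=exposed cases, b=unexposed cases,
    c=exposed non-cases, d=unexposed non-cases."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise PvSignalError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_exposed(self) -> int:
        return self.a + self.c

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def tabulate(case_vector: pd.Series, exposure_vector: pd.Series) -> ContingencyTable:
    """Cross-tabulate binary case and exposure vectors sharing a report index."""
    if not case_vector.index.equals(exposure_vector.index):
        raise PvSignalError("case and exposure vectors have mismatched report indexes")
    y = case_vector.to_numpy().astype(bool)
    x = exposure_vector.to_numpy().astype(bool)
    return ContingencyTable(
        a=int(np.sum(y & x)),
        b=int(np.sum(y & ~x)),
        c=int(np.sum(~y & x)),
        d=int(np.sum(~y & ~x)),
    )


@dataclass(frozen=True)
class RorEstimate:
    """A reporting odds ratio with its 95% CI and signal classification."""

    point: float
    ci_low: float
    ci_high: float
    se_log: float
    method: str  # "crude" or "adjusted"
    n_exposed_cases: int
    low_count_flag: bool = False
    signal: str = field(default=NO_SIGNAL)

    def __post_init__(self):
        if not (0 < self.ci_low <= self.point <= self.ci_high):
            raise PvSignalError(
                f"inconsistent estimate: point={self.point}, "
                f"CI=[{self.ci_low}, {self.ci_high}]"
            )
        object.__setattr__(self, "signal", SIGNAL if self.ci_low > 1.0 else NO_SIGNAL)


def classify_signal(estimate: RorEstimate) -> str:
    """Signal iff the lower 95% bound exceeds 1.

    Estimates with point < 1 are never labelled protective; the case/non-case
    method cannot detect the absence of a signal, so they are no_signal.
    """
    return SIGNAL if estimate.ci_low > 1.0 else NO_SIGNAL


def crude_ror(
    table: ContingencyTable, zero_cell_correction: str = "haldane_anscombe"
) -> RorEstimate:
    """Crude r-OR ``ad/bc`` with the Woolf 95% CI.

    With the Haldane-Anscombe correction (default), a table containing any
    zero cell has 0.5 added to all four cells before estimation and the
    estimate is flagged; with ``zero_cell_correction="none"`` a zero cell
    raises.  ``n_exposed_cases`` is always the uncorrected ``a``; estimates
    with fewer than 10 exposed cases carry the low-count flag.
    """
    if zero_cell_correction not in ("haldane_anscombe", "none"):
        raise PvSignalError(f"unknown zero_cell_correction {zero_cell_correction!r}")
    a, b, c, d = (float(v) for v in table.cells())
    corrected = False
    if min(a, b, c, d) == 0:
        if zero_cell_correction == "none":
            raise EstimateError("2x2 table contains a zero cell; r-OR undefined")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    point = (a * d) / (b * c)
    se_log = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    log_point = float(np.log(point))
    return RorEstimate(
        point=point,
        ci_low=float(np.exp(log_point - Z_95 * se_log)),
        ci_high=float(np.exp(log_point + Z_95 * se_log)),
        se_log=se_log,
        method="crude",
        n_exposed_cases=table.a,
        low_count_flag=corrected or table.a < LOW_COUNT_THRESHOLD,
    )


@dataclass(frozen=True)
class ModelOptions:
    """IRLS fitting options.

    Convergence requires both a relative deviance change below ``tolerance``
    and a maximum coefficient step below ``param_tolerance`` — the latter
    forces one more Newton step, which (quadratic convergence) pushes the
    coefficient error well below the 1e-6 agreement the closed-form 2x2
    checks rely on.
    """

    tolerance: float = 1e-8
    param_tolerance: float = 1e-6
    max_iter: int = 100
    zero_cell_correction: str = "haldane_anscombe"


@dataclass
class LogisticFit:
    """A converged maximum-likelihood logistic fit.

    ``params`` is indexed by column name (including "(Intercept)");
    ``cov`` is the inverse observed information at the optimum.
    """

    params: pd.Series
    cov: pd.DataFrame
    converged: bool
    n_iterations: int
    deviance: float

    def se(self, term: str) -> float:
        if term not in self.params.index:
            raise PvSignalError(f"term {term!r} not in fitted model: {list(self.params.index)}")
        return float(np.sqrt(self.cov.loc[term, term]))


def fit_logistic(
    design_matrix, case_vector: pd.Series, options: ModelOptions | None = None
) -> LogisticFit:
    """Fit the logistic model by iteratively reweighted least squares.

    *design_matrix* may be a :class:`~pvsignal.cohort_builder.DesignMatrix`
    or a plain DataFrame of covariates (no intercept column; one is added).
    Convergence is a relative deviance change below ``options.tolerance``.
    Separation is diagnosed when a coefficient passes ``|beta| > 15`` and
    keeps growing; the error names the offending column.
    """
    X_df = getattr(design_matrix, "X", design_matrix)
    if not X_df.index.equals(case_vector.index):
        raise PvSignalError("design matrix and case vector have mismatched indexes")
    for c in X_df.columns:
        if X_df[c].nunique() <= 1:
            raise PvSignalError(f"covariate column {c!r} is constant")
    opts = options or ModelOptions()

    y = case_vector.to_numpy().astype(float)
    names = ["(Intercept)", *X_df.columns]
    X = np.column_stack([np.ones(len(y)), X_df.to_numpy(dtype=float)])
    n, p = X.shape
    beta = np.zeros(p)
    dev_old = np.inf
    converged = False
    n_iter = 0
    prev_max = 0.0
    for n_iter in range(1, opts.max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        XtW = X.T * w
        beta_old = beta
        try:
            beta = linalg.solve(XtW @ X, XtW @ z, assume_a="pos")
        except linalg.LinAlgError as exc:
            j = int(np.argmax(np.abs(beta[1:]))) if p > 1 else 0
            raise SeparationError(
                names[j + 1] if p > 1 else names[0],
                f"information matrix singular at iteration {n_iter}",
            ) from exc
        with np.errstate(divide="ignore", invalid="ignore"):
            eta = np.clip(X @ beta, -30, 30)
        dev = float(2.0 * np.sum(np.log1p(np.exp(eta)) - y * eta))
        slope_abs = np.abs(beta[1:]) if p > 1 else np.abs(beta)
        cur_max = float(slope_abs.max()) if slope_abs.size else 0.0
        if cur_max > SEPARATION_BOUND and cur_max > prev_max:
            j = int(np.argmax(slope_abs))
            raise SeparationError(names[j + 1] if p > 1 else names[0])
        prev_max = cur_max
        if (
            abs(dev - dev_old) / (abs(dev) + 0.1) < opts.tolerance
            and float(np.max(np.abs(beta - beta_old))) < opts.param_tolerance
        ):
            converged = True
            break
        dev_old = dev
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {opts.max_iter} iterations "
            f"(last deviance {dev:.6g})"
        )
    mu = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30)))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    info = (X.T * w) @ X
    cov = linalg.inv(info)
    return LogisticFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        converged=True,
        n_iterations=n_iter,
        deviance=dev,
    )


def adjusted_ror(
    fit: LogisticFit, term_name: str, n_exposed_cases: int = 0
) -> RorEstimate:
    """Wald r-OR ``exp(beta_term)`` with 95% CI from a converged fit."""
    if not fit.converged:
        raise PvSignalError("fit did not converge; adjusted r-OR unavailable")
    if term_name not in fit.params.index:
        raise PvSignalError(
            f"term {term_name!r} not in fitted model: {list(fit.params.index)}"
        )
    b = float(fit.params[term_name])
    se = fit.se(term_name)
    return RorEstimate(
        point=float(np.exp(b)),
        ci_low=float(np.exp(b - Z_95 * se)),
        ci_high=float(np.exp(b + Z_95 * se)),
        se_log=se,
        method="adjusted",
        n_exposed_cases=n_exposed_cases,
        low_count_flag=n_exposed_cases < LOW_COUNT_THRESHOLD,
    )


#: variance-inflation factor above which a covariate is flagged as collinear
VIF_FLAG_THRESHOLD = 5.0


def compute_vif(design_matrix) -> pd.DataFrame:
    """Classical variance-inflation factors on the dummy-coded matrix.

    For each covariate column j, ``VIF_j = 1 / (1 - R²_j)`` where R²_j is
    the (centred) coefficient of determination of the OLS regression of
    column j on all other columns plus an intercept.  Exactly collinear
    columns are reported with infinite VIF.  Returns a DataFrame indexed by
    column with ``vif`` and ``flagged`` (VIF > 5).
    """
    X_df = getattr(design_matrix, "X", design_matrix)
    cols = list(X_df.columns)
    if len(cols) < 2:
        raise PvSignalError("VIF requires at least two covariate columns")
    X = X_df.to_numpy(dtype=float)
    vifs = {}
    for j, name in enumerate(cols):
        yj = X[:, j]
        others = np.column_stack(
            [np.ones(len(yj)), np.delete(X, j, axis=1)]
        )
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        if ss_tot == 0:
            raise PvSignalError(f"column {name!r} is constant; VIF undefined")
        r2 = max(0.0, 1.0 - ss_res / ss_tot)  # guards VIF >= 1 numerically
        if r2 >= 1.0 - 1e-12:
            vifs[name] = np.inf
        else:
            vifs[name] = 1.0 / (1.0 - r2)
    out = pd.DataFrame({"vif": pd.Series(vifs)})
    out["flagged"] = out["vif"] > VIF_FLAG_THRESHOLD
    inf_cols = out.index[~np.isfinite(out["vif"])].tolist()
    if inf_cols:
        logger.warning("exactly collinear column(s): %s", inf_cols)
    return out
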