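"""Age- and disease-duration-adjusted quartile segmentation of HRQoL scores.

The reference distribution for a person with MS is not the general
population but persons with comparable age and disease duration.  This
module fits linear conditional quantile surfaces (25th, 50th, 75th
percentile) of an HRQoL score on age and years since diagnosis, then
classifies each participant relative to their *own* fitted quartiles:

* ``low``    — observed score strictly below the fitted 25th percentile,
* ``normal`` — between the 25th and 75th percentile (ties inclusive),
* ``high``   — strictly above the fitted 75th percentile.

A four-level quartile bin (1-4) refines the three groups and feeds the
discordance rule comparing the EQ-5D index with the visual analogue
scale (VAS): bins separated by at least two quantiles in either
direction mark a discordant pair of self-assessments.

Each quantile is fitted independently by minimising the pinball (check)
loss, solved exactly as a linear program.  Quantile crossing (fitted
q25 > q50 or q50 > q75 at some covariate values) is detected, reported,
and repaired pointwise by sorting the three fitted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

__all__ = [
    "QuantileFit",
    "SegmentationResult",
    "pinball_loss",
    "fit_quantile",
    "fit_conditional_quantiles",
    "classify",
    "assign_quartile_bin",
    "label_discordance",
    "segment_cohort",
]

DEFAULT_TAUS = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class QuantileFit:
    """A fitted linear conditional-quantile surface."""

    tau: float
    coef: np.ndarray  # (intercept, slope_age, slope_duration, ...)
    loss: float  # achieved pinball loss (sum over observations)
    n: int
    columns: tuple[str, ...] = ()

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coef)):
            raise ValueError("quantile fit produced non-finite coefficients")
        if self.loss < -1e-9:
            raise ValueError("pinball loss cannot be negative")


@dataclass
class SegmentationResult:
    """Per-participant quartile positions and group labels.

    ``table`` has one row per participant and instrument with the fitted
    q25/q50/q75 at that participant's covariates, the quartile bin, the
    low/normal/high label, and (when both instruments were segmented)
    the EQ-5D-vs-VAS discordance label.
    """

    table: pd.DataFrame
    fits: dict[str, list[QuantileFit]]
    crossing: pd.DataFrame = field(default_factory=pd.DataFrame)

    def group_counts(self, instrument: str) -> dict[str, int]:
        sub = self.table[self.table["instrument"] == instrument]
        return sub["label"].value_counts().to_dict()


def pinball_loss(y, yhat, tau: float) -> float:
    """Sum of the check-function loss ``u*(tau - 1{u<0})`` with ``u = y - yhat``."""
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    u = y - yhat
    return float(np.sum(u * (tau - (u < 0))))


def _check_design(X: np.ndarray, columns) -> None:
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-dimensional")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        names = list(columns) if columns is not None else list(range(p))
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {p} columns): "
            f"columns {names} are collinear"
        )


def fit_quantile(
    y,
    X,
    tau: float,
    *,
    columns=None,
    refine: bool = True,
    solver: str = "highs",
) -> QuantileFit:
    """Minimise the pinball loss at level ``tau`` over linear coefficients.

    The problem is posed as the standard LP

        min  tau * 1'u+ + (1 - tau) * 1'u-
        s.t. X b + u+ - u- = y,   u+, u- >= 0,   b free

    and solved with the HiGHS simplex.  Two deterministic refinements
    follow: (i) the solution is polished by exact interpolation of the
    ``p`` observations with the smallest absolute residuals (a basic
    optimal solution interpolates ``p`` points when the design is in
    general position), and (ii) among loss-ties the minimal-L1-norm
    slope vector is selected by a second LP, which makes the fit
    reproducible across platforms and resolves degenerate cases such as
    a constant outcome.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X must have the same number of rows")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValueError("missing values in y or X")
    _check_design(X, columns)

    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1.0 - tau)])
    eye = sparse.eye(n, format="csr")
    A_eq = sparse.hstack([sparse.csr_matrix(X), eye, -eye], format="csr")
    bounds = [(None, None)] * p + [(0.0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method=solver)
    if not res.success:  # pragma: no cover - HiGHS failure is exceptional
        raise RuntimeError(f"quantile LP failed at tau={tau}: {res.message}")
    beta = res.x[:p]
    loss = pinball_loss(y, X @ beta, tau)

    if refine:
        beta, loss = _polish_by_interpolation(y, X, tau, beta, loss)
        beta, loss = _min_norm_tiebreak(y, X, tau, beta, loss)

    cols = tuple(columns) if columns is not None else tuple(f"x{j}" for j in range(p))
    return QuantileFit(tau=tau, coef=beta, loss=loss, n=n, columns=cols)


def _polish_by_interpolation(y, X, tau, beta, loss):
    """Snap the LP solution onto the exact-interpolation vertex it approximates."""
    n, p = X.shape
    resid = np.abs(y - X @ beta)
    idx = np.argsort(resid, kind="stable")[:p]
    sub = X[idx]
    if np.linalg.matrix_rank(sub) == p:
        cand = np.linalg.solve(sub, y[idx])
        cand_loss = pinball_loss(y, X @ cand, tau)
        if cand_loss <= loss + 1e-12:
            return cand, cand_loss
    return beta, loss


def _min_norm_tiebreak(y, X, tau, beta, loss, tol: float = 1e-8):
    """Among coefficient vectors with (near-)optimal loss, minimise the L1
    norm of the non-intercept coefficients (then of the intercept)."""
    n, p = X.shape
    if p < 2:
        return beta, loss
    # variables: b (p), u+ (n), u- (n), t (p) with t >= |b|
    c = np.concatenate([np.zeros(p), np.zeros(2 * n), np.ones(p)])
    c[2 * n + p] = 1e-6  # intercept norm only as a final, weak tie-break
    c[2 * n + p + 1 :] = 1.0
    eye = sparse.eye(n, format="csr")
    A_eq = sparse.hstack(
        [sparse.csr_matrix(X), eye, -eye, sparse.csr_matrix((n, p))], format="csr"
    )
    # loss constraint: tau 1'u+ + (1-tau) 1'u- <= loss + tol
    loss_row = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1 - tau), np.zeros(p)])
    # |b_j| <= t_j  ->  b_j - t_j <= 0 and -b_j - t_j <= 0
    eye_p = sparse.eye(p, format="csr")
    zero_mid = sparse.csr_matrix((p, 2 * n))
    abs_rows_pos = sparse.hstack([eye_p, zero_mid, -eye_p], format="csr")
    abs_rows_neg = sparse.hstack([-eye_p, zero_mid, -eye_p], format="csr")
    A_ub = sparse.vstack([sparse.csr_matrix(loss_row), abs_rows_pos, abs_rows_neg], format="csr")
    b_ub = np.concatenate([[loss + tol], np.zeros(2 * p)])
    bounds = [(None, None)] * p + [(0.0, None)] * (2 * n) + [(0.0, None)] * p
    res = linprog(c, A_eq=A_eq, b_eq=y, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if res.success:
        cand = res.x[:p]
        cand_loss = pinball_loss(y, X @ cand, tau)
        if cand_loss <= loss + tol:
            return cand, min(cand_loss, loss)
    return beta, loss


def fit_conditional_quantiles(
    y,
    X,
    taus=DEFAULT_TAUS,
    *,
    columns=("intercept", "age", "duration"),
    refine: bool = True,
) -> list[QuantileFit]:
    """Fit one :class:`QuantileFit` per tau on a shared design matrix.

    ``X`` must already contain the intercept column.  Quantiles are
    fitted independently; see :func:`segment_cohort` for crossing
    detection and repair.
    """
    return [fit_quantile(y, X, tau, columns=columns, refine=refine) for tau in taus]


TIE_TOL = 1e-9  # numeric ties with a fitted quartile count as boundary ties


def classify(y, q25, q75):
    """Label scores relative to fitted quartiles: strict tails, ties to normal."""
    y = np.asarray(y, dtype=float)
    q25 = np.asarray(q25, dtype=float)
    q75 = np.asarray(q75, dtype=float)
    out = np.where(y < q25 - TIE_TOL, "low", np.where(y > q75 + TIE_TOL, "high", "normal"))
    return out if out.ndim else str(out)


def assign_quartile_bin(y, q25, q50, q75):
    """Quartile bin 1-4 partitioning the outcome axis.

    bin 1: y < q25; bin 2: q25 <= y < q50; bin 3: q50 <= y <= q75;
    bin 4: y > q75.  Consistent with :func:`classify` (bin 1 == low,
    bin 4 == high, bins 2-3 == normal).
    """
    y = np.asarray(y, dtype=float)
    q25 = np.asarray(q25, dtype=float)
    q50 = np.asarray(q50, dtype=float)
    q75 = np.asarray(q75, dtype=float)
    out = np.where(
        y < q25 - TIE_TOL,
        1,
        np.where(y < q50 - TIE_TOL, 2, np.where(y <= q75 + TIE_TOL, 3, 4)),
    )
    return out if out.ndim else int(out)


_LOWER_VAS = {(4, 1), (4, 2), (3, 1)}
_HIGHER_VAS = {(1, 3), (1, 4), (2, 4)}


def label_discordance(eq_bin, vas_bin):
    """Two-quantile-separation rule comparing EQ-5D and VAS quartile bins.

    ``lower_vas`` (high EQ-5D, low VAS): EQ-5D in the highest quartile
    with VAS in the lowest two, or EQ-5D in the highest two with VAS in
    the lowest.  ``higher_vas`` is the mirror image.  Everything else is
    ``within_expectation``.
    """
    eq = np.atleast_1d(np.asarray(eq_bin, dtype=int))
    va = np.atleast_1d(np.asarray(vas_bin, dtype=int))
    if eq.shape != va.shape:
        raise ValueError("bin arrays must have equal shape")
    if ((eq < 1) | (eq > 4) | (va < 1) | (va > 4)).any():
        raise ValueError("quartile bins must be in {1, 2, 3, 4}")
    out = np.full(eq.shape, "within_expectation", dtype=object)
    for e, v in _LOWER_VAS:
        out[(eq == e) & (va == v)] = "lower_vas"
    for e, v in _HIGHER_VAS:
        out[(eq == e) & (va == v)] = "higher_vas"
    if np.isscalar(eq_bin) or np.ndim(eq_bin) == 0:
        return str(out[0])
    return out


def _design_from_table(table: pd.DataFrame) -> np.ndarray:
    X = np.column_stack(
        [
            np.ones(len(table)),
            table["age_years"].to_numpy(dtype=float),
            table["years_since_diagnosis"].to_numpy(dtype=float),
        ]
    )
    return X


def segment_cohort(
    table: pd.DataFrame,
    instruments=("eq5d_index", "vas"),
    taus=DEFAULT_TAUS,
) -> SegmentationResult:
    """Full segmentation of a prepared cohort table.

    For each instrument column, fits the three conditional quartile
    surfaces on age and years since diagnosis, evaluates them at every
    participant's covariates, repairs any pointwise quantile crossing by
    sorting, and assigns labels and bins.  When both instruments are
    segmented the EQ-5D-vs-VAS discordance label is attached.
    """
    taus = tuple(sorted(taus))
    if taus != (0.25, 0.5, 0.75):
        raise ValueError("segmentation requires taus (0.25, 0.5, 0.75)")
    for col in ("age_years", "years_since_diagnosis"):
        if col not in table.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
    missing = [c for c in instruments if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks instrument column(s) {missing}")

    X = _design_from_table(table)
    fits: dict[str, list[QuantileFit]] = {}
    frames = []
    crossing_rows = []
    bins_by_instrument: dict[str, np.ndarray] = {}

    for inst in instruments:
        y = table[inst].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"instrument column {inst!r} contains missing values")
        inst_fits = fit_conditional_quantiles(y, X, taus)
        fits[inst] = inst_fits
        Q = np.column_stack([f.predict(X) for f in inst_fits])  # q25, q50, q75
        crossed = (np.diff(Q, axis=1) < -1e-9).any(axis=1)
        if crossed.any():
            for i in np.flatnonzero(crossed):
                crossing_rows.append(
                    {
                        "participant_id": table.iloc[i].get("participant_id", i),
                        "instrument": inst,
                        "q25": Q[i, 0],
                        "q50": Q[i, 1],
                        "q75": Q[i, 2],
                    }
                )
            Q = np.sort(Q, axis=1)
        q25, q50, q75 = Q.T
        labels = classify(y, q25, q75)
        bins = assign_quartile_bin(y, q25, q50, q75)
        bins_by_instrument[inst] = bins
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": table["participant_id"].to_numpy()
                    if "participant_id" in table.columns
                    else np.arange(len(table)),
                    "instrument": inst,
                    "value": y,
                    "q25": q25,
                    "q50": q50,
                    "q75": q75,
                    "bin": bins,
                    "label": labels,
                }
            )
        )

    out = pd.concat(frames, ignore_index=True)
    if {"eq5d_index", "vas"} <= set(instruments):
        disc = label_discordance(bins_by_instrument["eq5d_index"], bins_by_instrument["vas"])
        disc_map = pd.Series(
            disc,
            index=frames[0]["participant_id"].to_numpy(),
        )
        out["discordance"] = out["participant_id"].map(disc_map)
    else:
        out["discordance"] = pd.NA

    crossing = pd.DataFrame(crossing_rows)
    if len(crossing_rows):
        warnings.warn(
            f"quantile crossing detected and repaired for {len(crossing_rows)} "
            "participant/instrument pairs",
            stacklevel=2,
        )
    return SegmentationResult(table=out, fits=fits, crossing=crossing)


def enumeration_quantile_oracle(y, X, tau: float):
    """Brute-force conditional-quantile fit for tiny problems.

    Enumerates every subset of up to ``p`` observations, solves the
    exact-interpolation coefficients for each nonsingular subset, and
    returns the coefficient vector with minimal pinball loss.  Intended
    as an independent correctness oracle for n <= ~12; cost grows
    combinatorially.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    best_loss = np.inf
    best_beta = None
    for k in range(1, p + 1):
        for idx in combinations(range(n), k):
            sub = X[list(idx)]
            if np.linalg.matrix_rank(sub) < k:
                continue
            beta, *_ = np.linalg.lstsq(sub, y[list(idx)], rcond=None)
            loss = pinball_loss(y, X @ beta, tau)
            if loss < best_loss - 1e-15:
                best_loss = loss
                best_beta = beta
    return best_beta, best_loss
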