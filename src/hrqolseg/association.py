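"""Descriptive and multinomial-regression comparison of HRQoL groups.

The three HRQoL groups produced by the quartile segmentation (low /
normal / high, the normal range as reference) are compared
descriptively (median [IQR] for continuous variables, n (%) for
categorical ones) and with multivariable multinomial logistic
regression reported as relative risk ratios (RRR, the exponentiated
multinomial-logit coefficient versus the reference group) with Wald
95% confidence intervals.

Model building follows a pre-specified forward-retention rule: sex,
clinical phenotype and the SRDSS gait-impairment class are always in
the model; further candidates are added one at a time in a declared
order and retained iff they reduce the AIC by two or more points.  The
MS Severity Score is never a candidate; the selected model is re-fitted
with MSSS as a linear term on the subsample where MSSS is observed.
The same machinery serves the discordance outcome (lower_vas /
within_expectation / higher_vas).

Maximum-likelihood fitting is delegated to statsmodels' MNLogit and
then polished with explicit Newton steps until the score vector is
below 1e-8 in the maximum norm, so the convergence contract does not
depend on the library's default stopping rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MultinomialFit",
    "SelectionTrace",
    "build_design",
    "descriptive_table",
    "fit_multinomial",
    "aic_retained",
    "forward_select_aic",
    "collinearity_check",
    "refit_with_msss",
]

# reference levels for dummy expansion of the cohort categoricals
REFERENCE_LEVELS = {
    "sex": "female",
    "phenotype": "RRMS",
    "srdss_class": "0-3.5",
    "disability_benefit": "none",
    "smoking": "never",
    "dmt_class": "oral",
    "symptom_count_class": "0-2",
    "education": "mandatory",
    "living_situation": "family",
    "marital_status": "divorced",
}

SEPARATION_BOUND = 15.0  # |log RRR| beyond this flags (quasi-)separation


class SeparationWarning(UserWarning):
    pass


def build_design(table: pd.DataFrame, terms) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand model terms into a numeric design matrix with intercept.

    Categorical columns become treatment-coded dummies against the
    reference level in :data:`REFERENCE_LEVELS` (first observed level
    otherwise); numeric columns enter linearly.  Returns the design and
    a map from term to its design columns (used by the selection trace
    and the collinearity diagnostics).
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(table))}
    term_map: dict[str, list[str]] = {}
    for term in terms:
        if term not in table.columns:
            raise ValueError(f"term {term!r} is not a column of the cohort table")
        s = table[term]
        if s.isna().any():
            raise ValueError(f"term {term!r} contains missing values; encode or impute first")
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            levels = list(pd.unique(s.astype(object)))
            ref = REFERENCE_LEVELS.get(term, levels[0])
            if ref in levels:
                levels.remove(ref)
            names = []
            for lev in sorted(map(str, levels)):
                name = f"{term}[{lev}]"
                cols[name] = (s.astype(str) == lev).to_numpy(dtype=float)
                names.append(name)
            term_map[term] = names
        else:
            cols[term] = s.to_numpy(dtype=float)
            term_map[term] = [term]
    X = pd.DataFrame(cols, index=table.index)
    return X, term_map


@dataclass
class MultinomialFit:
    """A fitted 3-category (or K-category) multinomial logit model."""

    categories: list[str]  # reference first
    params: pd.DataFrame  # rows: design columns; columns: non-reference categories
    cov: np.ndarray  # covariance of vec(params), column-major per category
    loglik: float
    aic: float
    n: int
    rrr: pd.DataFrame  # long table: category, covariate, RRR, ci_low, ci_high, p

    @property
    def reference(self) -> str:
        return self.categories[0]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        Xv = X[self.params.index].to_numpy(dtype=float)
        eta = Xv @ self.params.to_numpy()
        eta = np.column_stack([np.zeros(len(Xv)), eta])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)


def _newton_polish(model, params, tol=1e-8, maxiter=50):
    """Drive the score to < tol in max norm with safeguarded Newton steps.

    Under (quasi-)separation the MLE is at infinity and the gradient
    cannot vanish; the loop then stops at the last finite improvement.
    """
    p = np.asarray(params, dtype=float).ravel(order="F")
    ll = model.loglike(p)
    for _ in range(maxiter):
        g = model.score(p)
        if np.max(np.abs(g)) < tol:
            break
        H = model.hessian(p)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        improved = False
        for _half in range(12):
            new = p - step
            if np.all(np.isfinite(new)):
                ll_new = model.loglike(new)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    p, ll, improved = new, ll_new, True
                    break
            step = step / 2.0
        if not improved:
            break
    return p


def fit_multinomial(labels, design: pd.DataFrame, reference: str) -> MultinomialFit:
    """Maximum-likelihood multinomial logit with the declared reference.

    Coefficients are reported per non-reference category; RRR = exp(coef)
    with Wald 95% CIs (z = 1.96) from the observed information.  A
    coefficient beyond +-15 on the log scale triggers a separation
    warning naming the covariate.
    """
    labels = pd.Series(np.asarray(labels, dtype=object)).reset_index(drop=True)
    design = design.reset_index(drop=True)
    observed = list(pd.unique(labels))
    if reference not in observed:
        raise ValueError(f"reference category {reference!r} not present in the outcome")
    cats = [reference] + sorted(c for c in observed if c != reference)
    counts = labels.value_counts()
    if (counts < 1).any() or len(cats) < 2:
        raise ValueError("every outcome category needs at least one observation")
    Xv = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank deficient")

    codes = pd.Categorical(labels, categories=cats).codes
    model = sm.MNLogit(codes, Xv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=200, disp=False)
            start = np.asarray(res.params, dtype=float)
        except np.linalg.LinAlgError:  # singular Hessian mid-iteration
            start = None
        if (
            start is None
            or not np.all(np.isfinite(start))
            or not np.isfinite(model.loglike(start.ravel(order="F")))
        ):
            res = model.fit(method="lbfgs", maxiter=2000, disp=False)
            start = np.asarray(res.params, dtype=float)
    p = _newton_polish(model, start)
    if not np.all(np.isfinite(p)):
        raise RuntimeError("multinomial fit failed to produce finite coefficients")
    K = len(cats)
    params = pd.DataFrame(
        p.reshape(Xv.shape[1], K - 1, order="F"), index=design.columns, columns=cats[1:]
    )
    H = model.hessian(p)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:  # separation: information matrix singular
        cov = np.linalg.pinv(-H)
    llf = float(model.loglike(p))
    aic = 2.0 * p.size - 2.0 * llf

    se = np.sqrt(np.diag(cov)).reshape(Xv.shape[1], K - 1, order="F")
    from scipy.stats import norm

    rows = []
    for j, cat in enumerate(cats[1:]):
        for i, cov_name in enumerate(design.columns):
            b, s = params.iloc[i, j], se[i, j]
            if abs(b) > SEPARATION_BOUND:
                warnings.warn(
                    f"possible separation: |coef| of {cov_name!r} for category "
                    f"{cat!r} exceeds {SEPARATION_BOUND}",
                    SeparationWarning,
                    stacklevel=2,
                )
            zval = b / s if s > 0 else np.inf
            with np.errstate(over="ignore"):  # separated cells: CI endpoint inf
                rows.append(
                    {
                        "category": cat,
                        "covariate": cov_name,
                        "coef": b,
                        "se": s,
                        "RRR": np.exp(b),
                        "ci_low": np.exp(b - 1.96 * s),
                        "ci_high": np.exp(b + 1.96 * s),
                        "p": 2 * norm.sf(abs(zval)),
                    }
                )
    rrr = pd.DataFrame(rows)
    fit = MultinomialFit(
        categories=cats, params=params, cov=cov, loglik=llf, aic=aic, n=len(labels), rrr=rrr
    )
    probs = fit.predict_proba(design)
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
        raise AssertionError("fitted category probabilities must sum to 1")
    return fit


def aic_retained(delta_aic: float, threshold: float = 2.0) -> bool:
    """Forward-retention rule: keep a candidate iff the AIC dropped by the
    threshold (two points) *or more* — a drop of exactly 2.0 retains."""
    return delta_aic <= -threshold


@dataclass
class SelectionTrace:
    """Audit trail of the AIC forward-retention procedure."""

    base_terms: list[str]
    steps: list[dict] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def forward_select_aic(
    table: pd.DataFrame,
    labels,
    base_terms,
    candidates,
    reference: str,
    threshold: float = 2.0,
) -> tuple[SelectionTrace, MultinomialFit]:
    """Pre-specified forward retention: candidates are tried one at a
    time in the given order and kept iff the AIC drops by ``threshold``
    (two points) or more.  MSSS is never eligible; a candidate whose
    dummies make the design rank deficient is skipped with a logged
    reason.  The running AIC is non-increasing across retained steps.
    """
    candidates = [c for c in candidates]
    trace = SelectionTrace(base_terms=list(base_terms))
    for banned in ("msss", "edss"):
        if banned in candidates:
            candidates.remove(banned)
            trace.steps.append(
                {"candidate": banned, "decision": "excluded", "reason": "severity score is not a model-building candidate"}
            )
    current_terms = list(base_terms)
    X, _ = build_design(table, current_terms)
    current = fit_multinomial(labels, X, reference)
    for cand in candidates:
        trial_terms = current_terms + [cand]
        try:
            X_trial, _ = build_design(table, trial_terms)
            trial = fit_multinomial(labels, X_trial, reference)
        except ValueError as err:
            trace.steps.append(
                {"candidate": cand, "aic_before": current.aic, "decision": "skipped", "reason": str(err)}
            )
            continue
        delta = trial.aic - current.aic
        retained = aic_retained(delta, threshold)
        trace.steps.append(
            {
                "candidate": cand,
                "aic_before": current.aic,
                "aic_after": trial.aic,
                "delta_aic": delta,
                "decision": "retained" if retained else "rejected",
            }
        )
        if retained:
            current_terms = trial_terms
            current = trial
            trace.retained.append(cand)
    return trace, current


def descriptive_table(table: pd.DataFrame, groups, variables=None) -> pd.DataFrame:
    """Per-group summaries: median [IQR] for numeric variables, n (%) for
    categorical ones, in the layout of a cohort description table."""
    groups = pd.Series(np.asarray(groups, dtype=object), index=table.index)
    if groups.isna().any():
        raise ValueError("group labels must cover all rows")
    if variables is None:
        variables = [c for c in table.columns if c != "participant_id"]
    rows = []
    group_levels = list(pd.unique(groups))
    sizes = groups.value_counts()
    for var in variables:
        s = table[var]
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > 2:
            entry = {"variable": var, "kind": "continuous"}
            for g in group_levels:
                v = s[groups == g].dropna()
                entry[str(g)] = (
                    f"{v.median():.1f} [{v.quantile(0.25):.1f}; {v.quantile(0.75):.1f}]"
                    if len(v)
                    else "-"
                )
            rows.append(entry)
        else:
            for level in sorted(map(str, pd.unique(s.dropna().astype(object)))):
                entry = {"variable": f"{var}={level}", "kind": "categorical"}
                for g in group_levels:
                    sub = s[groups == g]
                    k = int((sub.astype(str) == level).sum())
                    entry[str(g)] = f"{k} ({100.0 * k / sizes[g]:.1f})"
                rows.append(entry)
    return pd.DataFrame(rows)


def collinearity_check(design: pd.DataFrame, term_map=None) -> pd.DataFrame:
    """Generalised variance-inflation factors per model term.

    Computed from correlation-matrix determinants (Fox & Monette):
    GVIF = det(R_term) det(R_other) / det(R).  Terms with
    GVIF^(1/(2 df)) > sqrt(5) are flagged.  Raises if the design is rank
    deficient (e.g. duplicated columns).
    """
    X = design.drop(columns=[c for c in ("intercept",) if c in design.columns])
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), Xv])) < Xv.shape[1] + 1:
        raise ValueError("design matrix is rank deficient; remove aliased columns")
    R = np.corrcoef(Xv, rowvar=False)
    if Xv.shape[1] == 1:
        R = np.array([[1.0]])
    det_R = np.linalg.det(R)
    if term_map is None:
        term_map = {c: [c] for c in X.columns}
    cond = float(np.linalg.cond(Xv - Xv.mean(axis=0)))
    rows = []
    col_index = {c: i for i, c in enumerate(X.columns)}
    for term, cols in term_map.items():
        idx = [col_index[c] for c in cols if c in col_index]
        if not idx:
            continue
        other = [i for i in range(Xv.shape[1]) if i not in idx]
        det_sub = np.linalg.det(R[np.ix_(idx, idx)])
        det_oth = np.linalg.det(R[np.ix_(other, other)]) if other else 1.0
        gvif = det_sub * det_oth / det_R
        df = len(idx)
        adj = gvif ** (1.0 / (2.0 * df))
        rows.append(
            {
                "term": term,
                "df": df,
                "gvif": gvif,
                "gvif_adj": adj,
                "flagged": bool(adj > np.sqrt(5.0)),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["condition_number"] = cond
    return out


def refit_with_msss(
    table: pd.DataFrame,
    labels,
    final_terms,
    reference: str,
    msss_column: str = "msss",
) -> MultinomialFit:
    """Re-fit the selected model on the MSSS-observed subsample with MSSS
    added as a linear term (per-unit RRR)."""
    labels = pd.Series(np.asarray(labels, dtype=object), index=table.index)
    observed = table[msss_column].notna()
    sub = table[observed]
    if len(sub) == 0:
        raise ValueError("no rows with an observed MSSS")
    if sub[msss_column].nunique() < 2:
        raise ValueError("MSSS is constant on the subsample; its effect is inestimable")
    X, _ = build_design(sub, list(final_terms))
    X[msss_column] = sub[msss_column].to_numpy(dtype=float)
    return fit_multinomial(labels[observed], X, reference)
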