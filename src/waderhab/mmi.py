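"""AICc multimodel inference for the breeding-response models.

A candidate set is a list of a-priori fixed-effect term combinations drawn
from the season covariate table (means, SEs, monthly means and Δs of
abundance, FI and the flocking ratio). Each candidate is a Gaussian model
of the (possibly fourth-root transformed) response, optionally with a
random intercept for the hydrologic-regime Decade, fitted by maximum
likelihood so that AICc is comparable across fixed-effect sets. Candidates
are ranked by AICc; Akaike weights give model probabilities, natural model
averaging gives coefficients with unconditional SEs, and summed weights
give per-term variable importance.

K counts the intercept, the fixed slopes, the residual variance, and the
random-intercept variance when retained. When the random-effect variance
estimate collapses to zero the model is refitted without it and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

PLAUSIBLE_DELTA = 2.0     # ΔAICc < 2: equally plausible
UNSUPPORTED_DELTA = 4.0   # ΔAICc > 4: little to no support


@dataclass
class CandidateSpec:
    """One a-priori model: response, fixed terms, transform, random term."""

    response: str
    terms: tuple
    transform: str = "identity"            # "identity" | "fourth-root"
    random_intercept: str | None = None    # column name (e.g. "decade") or None
    name: str = ""

    def __post_init__(self) -> None:
        self.terms = tuple(self.terms)
        if self.transform not in ("identity", "fourth-root"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if not self.name:
            self.name = " + ".join(self.terms) if self.terms else "intercept-only"


@dataclass
class FittedCandidate:
    spec: CandidateSpec
    loglik: float
    k: int
    n: int
    coefs: dict                      # term -> (estimate, se), incl. "const"
    aicc_value: float = np.nan
    random_removed: bool = False
    delta: float = np.nan
    weight: float = np.nan
    support: str = ""

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Fixed-effect prediction on the fitting scale."""
        pred = np.full(len(table), self.coefs["const"][0])
        for term in self.spec.terms:
            pred = pred + self.coefs[term][0] * table[term].to_numpy(dtype=float)
        return pred


def transform_response(y: np.ndarray, transform: str) -> np.ndarray:
    if transform == "fourth-root":
        y = np.asarray(y, dtype=float)
        if (y < 0).any():
            raise ValueError("fourth-root transform requires nonnegative response")
        return y ** 0.25
    return np.asarray(y, dtype=float)


def back_transform(y: np.ndarray, transform: str) -> np.ndarray:
    return np.asarray(y, dtype=float) ** 4 if transform == "fourth-root" else np.asarray(y, dtype=float)


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = −2·logLik + 2K + 2K(K+1)/(n − K − 1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_candidate(table: pd.DataFrame, spec: CandidateSpec) -> FittedCandidate:
    """ML fit of one candidate on the season covariate table."""
    cols = [spec.response, *spec.terms]
    if spec.random_intercept:
        cols.append(spec.random_intercept)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns {missing}")
    data = table.dropna(subset=cols)
    y = transform_response(data[spec.response].to_numpy(), spec.transform)
    X = np.column_stack([np.ones(len(data))] + [
        data[t].to_numpy(dtype=float) for t in spec.terms])
    names = ["const", *spec.terms]
    n, p = X.shape
    if n < p + 1 + (1 if spec.random_intercept else 0) + 3:
        raise ValueError(f"too few rows (n={n}) for {p} fixed parameters")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"singular design for terms {spec.terms}")

    random_removed = False
    if spec.random_intercept:
        groups = data[spec.random_intercept].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.MixedLM(y, X, groups=groups).fit(reml=False)
                re_var = float(np.asarray(res.cov_re)[0, 0])
                fe_bse = np.asarray(res.bse_fe)
                ok = (np.isfinite(res.llf) and np.all(np.isfinite(fe_bse))
                      and re_var > 1e-6 * max(res.scale, 1e-12))
            except Exception:
                ok = False
        if ok:
            coefs = {nm: (float(b), float(se))
                     for nm, b, se in zip(names, res.fe_params, fe_bse)}
            k = p + 2  # + residual variance + random-intercept variance
            fc = FittedCandidate(spec=spec, loglik=float(res.llf), k=k, n=n,
                                 coefs=coefs)
            fc.aicc_value = aicc(fc.loglik, fc.k, fc.n)
            return fc
        random_removed = True  # zero-variance collapse: drop the random term

    ols = sm.OLS(y, X).fit()
    if not np.isfinite(ols.llf):
        raise ValueError("non-finite likelihood")
    coefs = {nm: (float(b), float(se))
             for nm, b, se in zip(names, ols.params, ols.bse)}
    k = p + 1  # + residual variance
    fc = FittedCandidate(spec=spec, loglik=float(ols.llf), k=k, n=n,
                         coefs=coefs, random_removed=random_removed)
    fc.aicc_value = aicc(fc.loglik, fc.k, fc.n)
    return fc


def rank_and_weight(fits: list[FittedCandidate]) -> list[FittedCandidate]:
    """ΔAICc and Akaike weights; returns the fits sorted by AICc."""
    if len(fits) < 2:
        raise ValueError("need at least two candidate models")
    responses = {f.spec.response for f in fits}
    if len(responses) > 1:
        raise ValueError(f"mixed responses in one candidate set: {responses}")
    if len({f.n for f in fits}) > 1:
        raise ValueError("candidates fitted on differing row counts")
    values = np.array([f.aicc_value for f in fits])
    deltas = values - values.min()
    w = np.exp(-deltas / 2.0)
    w /= w.sum()
    for f, d, wi in zip(fits, deltas, w):
        f.delta = float(d)
        f.weight = float(wi)
        f.support = ("plausible" if d < PLAUSIBLE_DELTA
                     else "unsupported" if d > UNSUPPORTED_DELTA
                     else "intermediate")
    return sorted(fits, key=lambda f: f.aicc_value)


def ranking_table(fits: list[FittedCandidate]) -> pd.DataFrame:
    return pd.DataFrame([
        {"model": f.spec.name, "K": f.k, "AICc": f.aicc_value,
         "delta_AICc": f.delta, "weight": f.weight, "support": f.support,
         "random_removed": f.random_removed}
        for f in sorted(fits, key=lambda f: f.aicc_value)])


def model_average(fits: list[FittedCandidate]) -> pd.DataFrame:
    """Natural model averaging with unconditional standard errors.

    For each term, weights are renormalized over the models containing it;
    the averaged coefficient is Σ ω̃ β and the unconditional SE is
    Σ ω̃ √(SE² + (β − β̄)²).
    """
    terms: list[str] = []
    for f in fits:
        for t in f.coefs:
            if t not in terms:
                terms.append(t)
    rows = []
    for term in terms:
        containing = [f for f in fits if term in f.coefs]
        wsum = sum(f.weight for f in containing)
        if wsum <= 0:
            raise ValueError(f"term {term!r} carried by zero-weight models only")
        wt = np.array([f.weight / wsum for f in containing])
        beta = np.array([f.coefs[term][0] for f in containing])
        se = np.array([f.coefs[term][1] for f in containing])
        avg = float(wt @ beta)
        unc = float(wt @ np.sqrt(se ** 2 + (beta - avg) ** 2))
        rows.append({"term": term, "n_models": len(containing),
                     "estimate": avg, "unconditional_se": unc,
                     "importance": float(sum(f.weight for f in containing))})
    return pd.DataFrame(rows)


def variable_importance(fits: list[FittedCandidate]) -> dict[str, float]:
    """Σ of Akaike weights over the models containing each term."""
    out: dict[str, float] = {}
    for f in fits:
        for t in f.spec.terms:
            out[t] = out.get(t, 0.0) + f.weight
    return out


def model_averaged_predictions(fits: list[FittedCandidate],
                               table: pd.DataFrame) -> np.ndarray:
    """ω-weighted predictions over all models, back-transformed."""
    transform = fits[0].spec.transform
    pred = np.zeros(len(table))
    for f in fits:
        pred += f.weight * f.predict(table)
    return back_transform(pred, transform)


def fit_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation of observed vs predicted responses."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    keep = np.isfinite(observed) & np.isfinite(predicted)
    observed, predicted = observed[keep], predicted[keep]
    if observed.std() == 0 or predicted.std() == 0:
        raise ValueError("zero variance in observed or predicted values")
    r = np.corrcoef(observed, predicted)[0, 1]
    return float(r ** 2)


def effort_success_correlation(effort, success) -> tuple[float, float, int]:
    """Spearman rank correlation (rs, two-sided p, N) of paired annual values."""
    effort = np.asarray(effort, dtype=float)
    success = np.asarray(success, dtype=float)
    keep = np.isfinite(effort) & np.isfinite(success)
    effort, success = effort[keep], success[keep]
    n = len(effort)
    if n < 4:
        raise ValueError("need at least 4 paired years")
    if np.std(effort) == 0 or np.std(success) == 0:
        raise ValueError("constant vector")
    rs, p = stats.spearmanr(effort, success)
    return float(rs), float(p), n


@dataclass
class MMIResult:
    """Ranked models plus averaging/importance/fit summaries."""

    response: str
    fits: list = field(default_factory=list)
    ranking: pd.DataFrame = None
    averaged: pd.DataFrame = None
    importance: dict = field(default_factory=dict)
    r2: float = np.nan


def run_mmi(table: pd.DataFrame, specs: list[CandidateSpec]) -> MMIResult:
    """Fit a candidate set end to end: rank, average, importance, R²."""
    fits = [fit_candidate(table, s) for s in specs]
    fits = rank_and_weight(fits)
    result = MMIResult(response=specs[0].response, fits=fits)
    result.ranking = ranking_table(fits)
    result.averaged = model_average(fits)
    result.importance = variable_importance(fits)
    data = table.dropna(subset=[specs[0].response])
    obs = data[specs[0].response].to_numpy(dtype=float)
    pred = model_averaged_predictions(fits, data)
    result.r2 = fit_r2(obs, pred)
    return result
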