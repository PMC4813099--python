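"""Overdispersed count-regression helper shared by the TFC and SFC models.

Fits a negative-binomial regression (log link) by maximum likelihood and
falls back to a Poisson GLM when the NB optimizer fails to converge or the
dispersion estimate degenerates; the fallback is recorded in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm


@dataclass
class CountFit:
    params: np.ndarray
    bse: np.ndarray
    alpha: float          # NB2 dispersion; 0.0 means Poisson fallback
    family: str           # "negbin" or "poisson"
    converged: bool
    columns: list

    def predict_mean(self, X: np.ndarray, offset=None) -> np.ndarray:
        eta = np.asarray(X) @ self.params
        if offset is not None:
            eta = eta + np.log(np.asarray(offset, dtype=float))
        # guard against overflow when extrapolating far outside the fit range
        return np.exp(np.clip(eta, -700.0, 50.0))


def fit_count_glm(y, X, offset=None, columns=None) -> CountFit:
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not np.any(y > 0):
        raise ValueError("all-zero response: count model is unidentifiable")
    columns = list(columns) if columns is not None else [
        f"x{i}" for i in range(X.shape[1])]
    exposure = None if offset is None else np.asarray(offset, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.NegativeBinomial(y, X, exposure=exposure)
            res = model.fit(disp=0, maxiter=500)
            ok = (res.mle_retvals.get("converged", False)
                  and np.all(np.isfinite(res.params))
                  and np.all(np.isfinite(res.bse[:-1])))
        except Exception:
            ok = False
        if ok:
            # last parameter is ln(alpha) in statsmodels' NB2 parametrization
            return CountFit(params=res.params[:-1], bse=res.bse[:-1],
                            alpha=float(np.exp(res.params[-1])),
                            family="negbin", converged=True, columns=columns)
        res = sm.GLM(y, X, family=sm.families.Poisson(),
                     exposure=exposure).fit()
    return CountFit(params=np.asarray(res.params), bse=np.asarray(res.bse),
                    alpha=0.0, family="poisson", converged=True,
                    columns=columns)
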