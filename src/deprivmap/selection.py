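"""Model selection: hold-out cross-validation with MSE, and WAIC."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import model as M
from . import predict as P

__all__ = ["CVReport", "WAICResult", "PAPER_FRACTIONS", "holdout_cv", "mse", "waic"]

#: The seven hold-out fractions used in the study's cross-validation.
PAPER_FRACTIONS = (0.025, 0.037, 0.050, 0.062, 0.075, 0.087, 0.100)


@dataclass
class CVReport:
    fraction: float
    held_out_ids: list
    predicted: np.ndarray  # posterior-mean probability per held-out EA
    observed: np.ndarray  # binary labels of held-out EAs
    mse: float
    seed: int
    fitted_reference: Optional[np.ndarray] = None  # full-data fitted probs
    mse_vs_fitted: Optional[float] = None


def mse(pred: Sequence[float], ref: Sequence[float]) -> float:
    """Mean of squared differences (the Brier score when ref is binary)."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.size == 0:
        raise ValueError("mse of empty input is undefined")
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have equal length")
    return float(np.mean((pred - ref) ** 2))


class WAICResult(NamedTuple):
    waic: float
    lppd: float
    p_waic: float


def waic(pointwise_loglik: np.ndarray) -> WAICResult:
    """Watanabe-Akaike information criterion from a [draws x obs] matrix.

    lppd = sum_i log mean_s exp(ll_si) (via log-sum-exp); p_waic = sum_i of
    the sample variance of ll over draws; waic = -2 (lppd - p_waic).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("pointwise log-likelihood must be [draws x obs]")
    if not np.isfinite(ll).all():
        raise ValueError("pointwise log-likelihood contains non-finite entries")
    s = ll.shape[0]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(s)))
    if s < 2:
        warnings.warn("WAIC with a single draw: p_waic set to 0")
        p_waic = 0.0
    else:
        p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return WAICResult(waic=-2.0 * (lppd - p_waic), lppd=lppd, p_waic=p_waic)


def holdout_cv(
    spec: M.ModelSpec,
    X,
    y,
    fractions: Sequence[float] = PAPER_FRACTIONS,
    seed: int = 0,
    neighbourhood_ids: Optional[Sequence] = None,
    reference: str = "labels",
    repeats: int = 1,
    new_neighbourhoods_policy: str = "marginal",
) -> list[CVReport]:
    """Hold-out cross-validation at each fraction.

    For each fraction a random sample of EAs (without replacement) is removed,
    the model refit on the remainder, and posterior-predictive probabilities
    computed for the excluded EAs. The default MSE compares predictions with
    the observed binary labels (Brier score); ``reference='fitted'`` also
    compares against full-data fitted probabilities. ``repeats > 1`` averages
    the MSE over independent partitions (reported per-partition reports are
    concatenated). Partitions are deterministic in (seed, fraction index,
    repeat).
    """
    from .synthetic_data import _as_matrix, _is_predictor_matrix

    if _is_predictor_matrix(X):
        Xdf = X.data
    elif isinstance(X, pd.DataFrame):
        Xdf = X
    else:
        m = _as_matrix(X)
        Xdf = pd.DataFrame(m, columns=[f"x{j}" for j in range(m.shape[1])])
    y = np.asarray(y)
    n = len(Xdf)
    nb = np.asarray(neighbourhood_ids) if neighbourhood_ids is not None else None

    fitted_ref = None
    if reference == "fitted":
        full = M.fit(spec, Xdf, y, neighbourhood_ids=nb)
        fitted_ref = P.fitted_probabilities(full, Xdf, nb)
    elif reference != "labels":
        raise ValueError("reference must be 'labels' or 'fitted'")

    reports: list[CVReport] = []
    for fi, frac in enumerate(fractions):
        if not 0 < frac < 0.5:
            raise ValueError(f"fraction {frac} outside (0, 0.5)")
        n_held = int(round(frac * n))
        if n_held < 1:
            raise ValueError(f"fraction {frac} holds out zero EAs at n={n}")
        for rep in range(repeats):
            rng = np.random.default_rng(np.random.SeedSequence([int(seed), fi, rep]))
            held = np.sort(rng.choice(n, size=n_held, replace=False))
            keep = np.setdiff1d(np.arange(n), held)
            sub_spec = replace(spec, seed=int(spec.seed) + 1000 * fi + rep)
            draws = M.fit(
                sub_spec,
                Xdf.iloc[keep],
                y[keep],
                neighbourhood_ids=nb[keep] if nb is not None else None,
            )
            p_held = P.posterior_predict_probs(
                draws,
                Xdf.iloc[held],
                neighbourhood_ids=nb[held] if nb is not None else None,
                policy=new_neighbourhoods_policy,
                seed=int(seed) + 7 * fi + rep,
            ).mean(axis=0)
            rep_obj = CVReport(
                fraction=float(frac),
                held_out_ids=list(Xdf.index[held]),
                predicted=p_held,
                observed=y[held],
                mse=mse(p_held, y[held]),
                seed=int(seed),
            )
            if fitted_ref is not None:
                rep_obj.fitted_reference = fitted_ref[held]
                rep_obj.mse_vs_fitted = mse(p_held, fitted_ref[held])
            reports.append(rep_obj)
    return reports


def cv_summary(reports: list[CVReport]) -> pd.DataFrame:
    rows = [
        {
            "fraction": r.fraction,
            "n_held_out": len(r.held_out_ids),
            "mse": r.mse,
            "mse_vs_fitted": r.mse_vs_fitted,
        }
        for r in reports
    ]
    return pd.DataFrame(rows)
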