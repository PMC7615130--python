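"""Posterior-predictive probabilities, quintile summaries and cluster detection."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from .frames import EAFrame
from .model import PosteriorDraws

__all__ = [
    "QUINTILE_LABELS",
    "posterior_predict",
    "posterior_predict_probs",
    "fitted_probabilities",
    "classify",
    "quintile_table",
    "find_clusters",
]

QUINTILE_EDGES = (0.0, 0.20, 0.40, 0.60, 0.80)
QUINTILE_LABELS = ("<0.20", "0.20-0.40", "0.40-0.60", "0.60-0.80", ">=0.80")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _beta_matrix(d: PosteriorDraws, X: pd.DataFrame) -> np.ndarray:
    names = d.beta_names()
    missing = [c for c in names if c not in X.columns]
    extra = [c for c in X.columns if c not in names]
    if missing or extra:
        raise ValueError(
            f"predictor columns do not match training: missing={missing}, unexpected={extra}"
        )
    return X[names].to_numpy(dtype=float)


def posterior_predict_probs(
    d: PosteriorDraws,
    X_new: pd.DataFrame,
    neighbourhood_ids: Optional[Sequence] = None,
    policy: str = "marginal",
    seed: int = 0,
) -> np.ndarray:
    """Per-draw probabilities, shape [n_draws, n_new].

    For the random-effects model, EAs in neighbourhoods seen during training
    reuse that neighbourhood's sampled V draws; unseen neighbourhoods either
    get a fresh V ~ Normal(0, sigma_v) per draw (``policy='marginal'``) or
    V = 0 (``policy='zero'``).
    """
    from .synthetic_data import _is_predictor_matrix

    if _is_predictor_matrix(X_new):
        X_new = X_new.data
    xm = _beta_matrix(d, X_new)
    alpha = d.param("alpha")
    eta = alpha[:, None] + d.beta_draws() @ xm.T
    if d.spec.random_effects:
        if neighbourhood_ids is None:
            raise ValueError("neighbourhood_ids required for the random-effects model")
        v = d.v_draws()
        levels = {l: i for i, l in enumerate(d.neighbourhood_levels)}
        sigma = d.param("sigma_v")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
        for col, nb in enumerate(np.asarray(neighbourhood_ids)):
            if nb in levels:
                eta[:, col] += v[:, levels[nb]]
            elif policy == "marginal":
                eta[:, col] += rng.standard_normal(eta.shape[0]) * sigma
            elif policy != "zero":
                raise ValueError("policy must be 'marginal' or 'zero'")
    return _expit(eta)


def fitted_probabilities(
    d: PosteriorDraws, X: pd.DataFrame, neighbourhood_ids: Optional[Sequence] = None
) -> np.ndarray:
    """Posterior-mean fitted probability for the training EAs."""
    return posterior_predict_probs(d, X, neighbourhood_ids, policy="zero").mean(axis=0)


def quintile_bin(p: np.ndarray) -> np.ndarray:
    """Lower-closed probability bins; the last bin is [0.80, 1]."""
    p = np.asarray(p, dtype=float)
    idx = np.searchsorted(QUINTILE_EDGES[1:], p, side="right")
    return np.asarray(QUINTILE_LABELS, dtype=object)[idx]


def classify(p_mean: np.ndarray, threshold: float = 0.80) -> np.ndarray:
    """Deprived iff p_mean >= threshold (inclusive)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return np.asarray(p_mean, dtype=float) >= threshold


def posterior_predict(
    d: PosteriorDraws,
    X_new,
    frame: Optional[EAFrame] = None,
    neighbourhood_ids: Optional[Sequence] = None,
    policy: str = "marginal",
    threshold: float = 0.80,
    urban_only: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-EA posterior predictive summary.

    Returns a frame with ea_id, p_mean, p_low/p_high (2.5/97.5 posterior
    percentiles), quintile_bin and the deprived flag. When ``frame`` is given
    and ``urban_only`` is set, prediction is restricted to EAs flagged urban.
    """
    from .synthetic_data import _is_predictor_matrix

    Xdf = X_new.data if _is_predictor_matrix(X_new) else X_new
    nb = np.asarray(neighbourhood_ids) if neighbourhood_ids is not None else None
    if frame is not None and urban_only:
        urban = frame.df.set_index("ea_id")["urban"].reindex(Xdf.index).fillna(False)
        keep = urban.to_numpy(dtype=bool)
        Xdf = Xdf.loc[keep]
        if nb is not None:
            nb = nb[keep]
    probs = posterior_predict_probs(d, Xdf, nb, policy=policy, seed=seed)
    p_mean = probs.mean(axis=0)
    p_low = np.percentile(probs, 2.5, axis=0)
    p_high = np.percentile(probs, 97.5, axis=0)
    return pd.DataFrame(
        {
            "ea_id": Xdf.index,
            "p_mean": p_mean,
            "p_low": p_low,
            "p_high": p_high,
            "quintile_bin": quintile_bin(p_mean),
            "deprived": classify(p_mean, threshold),
        }
    ).reset_index(drop=True)


def quintile_table(pred: pd.DataFrame, frame: EAFrame) -> pd.DataFrame:
    """EA and population counts/shares per probability quintile, plus a total row."""
    pop = frame.df.set_index("ea_id")["population"]
    merged = pred.set_index("ea_id").join(pop, how="left")
    missing = merged.index[merged["population"].isna()].tolist()
    if missing:
        import warnings

        warnings.warn(f"EAs without population excluded from quintile table: {missing}")
        merged = merged.dropna(subset=["population"])
    rows = []
    total_eas = len(merged)
    total_pop = merged["population"].sum()
    for lab in QUINTILE_LABELS:
        sub = merged[merged["quintile_bin"] == lab]
        rows.append(
            {
                "quintile": lab,
                "n_eas": len(sub),
                "pct_eas": round(100.0 * len(sub) / total_eas, 1) if total_eas else 0.0,
                "population": int(sub["population"].sum()),
                "pct_population": round(100.0 * sub["population"].sum() / total_pop, 1)
                if total_pop
                else 0.0,
            }
        )
    rows.append(
        {
            "quintile": "Total",
            "n_eas": total_eas,
            "pct_eas": 100.0,
            "population": int(total_pop),
            "pct_population": 100.0,
        }
    )
    return pd.DataFrame(rows)


@dataclass
class Cluster:
    members: list
    size: int
    centroid: tuple[float, float]


def find_clusters(frame: EAFrame, deprived_flags: Sequence[bool], min_size: int = 3) -> list[Cluster]:
    """Connected components (queen adjacency) of deprived EAs with >= min_size members."""
    from .lisa import queen_weights

    flags = np.asarray(deprived_flags, dtype=bool)
    if flags.shape[0] != len(frame):
        raise ValueError("deprived_flags must align with the frame")
    w = queen_weights(frame)

    parent = np.arange(len(frame))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in np.flatnonzero(flags):
        for j in w.neighbours[i]:
            if flags[j]:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[rj] = ri

    comps: dict[int, list[int]] = {}
    for i in np.flatnonzero(flags):
        comps.setdefault(find(i), []).append(i)

    clusters = []
    ids = frame.df["ea_id"].to_numpy()
    for members in comps.values():
        if len(members) >= min_size:
            union = shapely.unary_union([frame.geometry[m] for m in members])
            c = shapely.centroid(union)
            clusters.append(
                Cluster(
                    members=[ids[m] for m in sorted(members)],
                    size=len(members),
                    centroid=(float(c.x), float(c.y)),
                )
            )
    clusters.sort(key=lambda cl: (-cl.size, cl.members[0]))
    return clusters
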