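"""Upper-quartile normalization and per-time-point negative-binomial
differential expression.

Counts are modeled per entity as NB(mu, phi) with ``Var = mu + phi*mu^2``
and a log link.  The full model has one mean parameter per treatment x time
cell (10 cells) plus, optionally, a centered RIN covariate; each time point
is tested by a likelihood-ratio test against the model with treated and
control merged at that time point.  The fitter is written directly in numpy
so that thousands of entities can be fit in a vectorized sweep; statsmodels
is used in the test suite as an independent oracle on small fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from mirlag.io_model import TIMEPOINTS, CountMatrix, Sample

_LOG2 = np.log(2.0)
_ETA_MIN, _ETA_MAX = -30.0, 30.0
_MAX_ITER = 100
_TOL = 1e-8
# below this, the NB likelihood is numerically indistinguishable from Poisson
_POISSON_EPS = 1e-8


@dataclass
class NormalizedMatrix:
    """Counts with per-sample upper-quartile scale factors (geomean 1)."""

    base: CountMatrix
    scale_factors: np.ndarray
    normalized: np.ndarray

    @property
    def samples(self) -> list[Sample]:
        return self.base.samples


def upper_quartile_normalize(counts: CountMatrix) -> NormalizedMatrix:
    """Scale each sample by its 75th-percentile count over expressed entities.

    The percentile is taken (with linear interpolation) over entities whose
    row total across all samples is nonzero; factors are rescaled to have
    geometric mean 1 so the normalized values stay on the count scale.
    """
    raw = counts.counts.astype(np.float64)
    expressed = raw.sum(axis=1) > 0
    if not expressed.any():
        raise ValueError("no entity with nonzero total count")
    uq = np.percentile(raw[expressed], 75, axis=0)
    if (uq == 0).any():
        bad = counts.sample_ids[int(np.argmin(uq))]
        raise ValueError(f"upper quartile is 0 for sample {bad!r}")
    factors = uq / np.exp(np.mean(np.log(uq)))
    return NormalizedMatrix(counts, factors, raw / factors)


def benjamini_hochberg(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (with monotonicity)."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersions(
    norm: NormalizedMatrix,
    groups: Sequence[str] | None = None,
    trend_weight: float = 0.7,
) -> np.ndarray:
    """Method-of-moments NB dispersions shrunk toward a mean-dispersion trend.

    Per entity the raw estimate is ``max(0, (s2 - mu) / mu^2)`` where ``s2``
    is the within-group variance pooled over the design cells and ``mu`` the
    grand mean of normalized counts.  Raw values are then shrunk toward a
    least-squares fit of the trend ``phi(mu) = a/mu + b`` with fixed weight
    0.3 on the raw value.
    """
    if groups is None:
        groups = [f"{s.treatment}:{s.time_h}" for s in norm.samples]
    groups = np.asarray(groups)
    y = norm.normalized
    labels = np.unique(groups)
    n_ent = y.shape[0]
    ss = np.zeros(n_ent)
    df = 0
    means = np.zeros((n_ent, len(labels)))
    for k, g in enumerate(labels):
        cols = groups == g
        n_g = int(cols.sum())
        if n_g < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
        sub = y[:, cols]
        means[:, k] = sub.mean(axis=1)
        ss += ((sub - means[:, [k]]) ** 2).sum(axis=1)
        df += n_g - 1
    s2 = ss / df
    mu = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)
    raw = np.maximum(raw, 0.0)

    usable = mu > 0
    if usable.sum() >= 2:
        X = np.column_stack([1.0 / mu[usable], np.ones(usable.sum())])
        coef, *_ = np.linalg.lstsq(X, raw[usable], rcond=None)
        a, b = coef
    else:
        a, b = 0.0, float(raw[usable].mean()) if usable.any() else 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a / np.maximum(mu, 1e-12) + b, b)
    trend = np.maximum(trend, 0.0)
    phi = (1.0 - trend_weight) * raw + trend_weight * trend
    return np.maximum(phi, 0.0)


# ---------------------------------------------------------------------------
# NB log-likelihood and GLM fitting
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB2 log-likelihood (Poisson in the phi -> 0 limit).

    ``y`` and ``mu`` are (entities x samples); ``phi`` is per-entity.
    """
    y = np.atleast_2d(y)
    mu = np.maximum(np.atleast_2d(mu), 1e-12)
    phi = np.atleast_1d(np.asarray(phi, dtype=np.float64))
    out = np.empty(y.shape[0])
    pois = phi < _POISSON_EPS
    if pois.any():
        yp, mp = y[pois], mu[pois]
        out[pois] = (yp * np.log(mp) - mp - gammaln(yp + 1)).sum(axis=1)
    nb = ~pois
    if nb.any():
        yn, mn = y[nb], mu[nb]
        r = 1.0 / phi[nb, None]
        out[nb] = (
            gammaln(yn + r) - gammaln(r) - gammaln(yn + 1)
            + r * np.log(r / (r + mn)) + yn * np.log(mn / (r + mn))
        ).sum(axis=1)
    return out


def _fit_cellmeans(
    y: np.ndarray, cell_idx: np.ndarray, n_cells: int,
    offset: np.ndarray, phi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit per-cell NB means for all entities at once.

    With a purely categorical design the cells decouple, so each (entity,
    cell) coefficient solves an independent 1-D score equation by Newton
    steps.  Returns (betas (entities x cells), mu (entities x samples)).
    """
    n_ent, n_samp = y.shape
    eo = np.exp(offset)
    cell_mask = np.equal.outer(np.arange(n_cells), cell_idx)  # cells x samples
    sum_eo = cell_mask @ eo
    sum_y = y @ cell_mask.T
    # Poisson MLE is closed-form and is the exact solution when phi == 0
    beta = np.log(np.maximum(sum_y, 1e-8) / sum_eo)
    beta = np.clip(beta, _ETA_MIN, _ETA_MAX)
    phi_col = phi[:, None]
    need_newton = phi >= _POISSON_EPS
    if need_newton.any():
        active = np.where(need_newton)[0]
        b = beta[active]
        ya = y[active]
        pa = phi_col[active]
        for _ in range(_MAX_ITER):
            eta = b[:, cell_idx] + offset[None, :]
            mu = np.exp(np.clip(eta, _ETA_MIN, _ETA_MAX))
            denom = 1.0 + pa * mu
            score = ((ya - mu) / denom) @ cell_mask.T
            info = (mu / denom) @ cell_mask.T
            step = score / np.maximum(info, 1e-12)
            step = np.clip(step, -5.0, 5.0)
            b = np.clip(b + step, _ETA_MIN, _ETA_MAX)
            if np.max(np.abs(step)) < _TOL:
                break
        beta[active] = b
    mu = np.exp(np.clip(beta[:, cell_idx] + offset[None, :], _ETA_MIN, _ETA_MAX))
    return beta, mu


def _fit_irls(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for an arbitrary design matrix shared across entities.

    Returns (betas (entities x p), mu, converged flags).
    """
    n_ent, n_samp = y.shape
    p = X.shape[1]
    beta = np.zeros((n_ent, p))
    # initialize intercept-free cell columns from column-wise means
    z0 = np.log(np.maximum(y, 0.5)) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T
    converged = np.zeros(n_ent, dtype=bool)
    dev_old = np.full(n_ent, np.inf)
    phi_col = phi[:, None]
    for _ in range(_MAX_ITER):
        eta = np.clip(beta @ X.T + offset[None, :], _ETA_MIN, _ETA_MAX)
        mu = np.exp(eta)
        W = mu / (1.0 + phi_col * mu)  # expected information weights
        z = eta - offset[None, :] + (y - mu) / mu
        XtWX = np.einsum("si,es,sj->eij", X, W, X)
        XtWz = np.einsum("si,es,es->ei", X, W, z)
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        beta_new = np.clip(beta_new, -50.0, 50.0)
        dev = -2.0 * nb_loglik(y, np.exp(np.clip(beta_new @ X.T + offset[None, :],
                                                 _ETA_MIN, _ETA_MAX)), phi)
        delta = np.abs(dev - dev_old) / (np.abs(dev) + 0.1)
        newly = delta < _TOL
        converged |= newly
        beta = beta_new
        dev_old = dev
        if converged.all():
            break
    mu = np.exp(np.clip(beta @ X.T + offset[None, :], _ETA_MIN, _ETA_MAX))
    return beta, mu, converged


def _design_cells(samples: Sequence[Sample]) -> tuple[np.ndarray, list[tuple[str, int]]]:
    cells = [(trt, t) for t in TIMEPOINTS for trt in ("control", "treated")]
    lookup = {c: i for i, c in enumerate(cells)}
    idx = np.array([lookup[(s.treatment, s.time_h)] for s in samples])
    return idx, cells


def _merged_index(cell_idx: np.ndarray, cells: list[tuple[str, int]],
                  time_h: int) -> tuple[np.ndarray, int]:
    """Cell index remapped so treated and control at ``time_h`` share a cell."""
    i_ctl = cells.index(("control", time_h))
    i_trt = cells.index(("treated", time_h))
    remap = {}
    nxt = 0
    for i in range(len(cells)):
        if i == i_trt:
            continue
        remap[i] = nxt
        nxt += 1
    remap[i_trt] = remap[i_ctl]
    merged = np.array([remap[i] for i in cell_idx])
    return merged, nxt


def _onehot(idx: np.ndarray, n: int) -> np.ndarray:
    X = np.zeros((idx.size, n))
    X[np.arange(idx.size), idx] = 1.0
    return X


def fit_group_models(
    norm: NormalizedMatrix,
    phi: np.ndarray,
    use_rin: bool = False,
) -> dict:
    """Fit the full treatment x time model (optionally with centered RIN).

    Returns a dict with cell betas, fitted means, the cell layout and
    convergence flags; used by the LRT driver and by the RIN diagnostics.
    """
    samples = norm.samples
    y = norm.base.counts.astype(np.float64)
    offset = np.log(norm.scale_factors)
    cell_idx, cells = _design_cells(samples)
    if not use_rin:
        beta, mu = _fit_cellmeans(y, cell_idx, len(cells), offset, phi)
        return {
            "cells": cells, "cell_idx": cell_idx, "beta": beta, "mu": mu,
            "converged": np.ones(y.shape[0], dtype=bool), "offset": offset,
            "loglik": nb_loglik(y, mu, phi), "use_rin": False,
        }
    rin = np.array([s.rin for s in samples])
    rin_c = rin - rin.mean()
    X = np.column_stack([_onehot(cell_idx, len(cells)), rin_c])
    beta, mu, conv = _fit_irls(y, X, offset, phi)
    return {
        "cells": cells, "cell_idx": cell_idx, "beta": beta[:, :-1],
        "rin_coef": beta[:, -1], "mu": mu, "converged": conv,
        "offset": offset, "loglik": nb_loglik(y, mu, phi),
        "use_rin": True, "rin_centered": rin_c,
    }


def test_differential_expression(
    norm: NormalizedMatrix,
    use_rin: bool = False,
    dispersions: np.ndarray | None = None,
    significance: str = "fdr",
    threshold: float = 0.05,
    global_bh: bool = False,
) -> pd.DataFrame:
    """Per-entity, per-time-point NB likelihood-ratio tests.

    For every time point the full model is compared against the model with
    the treated and control means constrained equal at that time point
    (chi-square, df=1).  ``significance`` selects whether the per-entity
    flag uses adjusted ("fdr") or raw ("p") values at ``threshold``; BH
    adjustment is applied within each time point (or globally over all
    5 x entities tests when ``global_bh``).
    """
    if significance not in ("fdr", "p"):
        raise ValueError("significance must be 'fdr' or 'p'")
    y = norm.base.counts.astype(np.float64)
    n_ent = y.shape[0]
    if dispersions is None:
        dispersions = estimate_dispersions(norm)
    phi = np.asarray(dispersions, dtype=np.float64)
    full = fit_group_models(norm, phi, use_rin=use_rin)
    cells, cell_idx, offset = full["cells"], full["cell_idx"], full["offset"]
    ll_full = full["loglik"]
    converged = full["converged"].copy()

    result: dict[str, np.ndarray] = {"entity_id": np.array(norm.base.entity_ids)}
    pmat = np.empty((n_ent, len(TIMEPOINTS)))
    fcmat = np.empty((n_ent, len(TIMEPOINTS)))
    rin_cols = None
    if use_rin:
        rin_cols = full["rin_centered"]
    for j, t in enumerate(TIMEPOINTS):
        merged_idx, n_merged = _merged_index(cell_idx, cells, t)
        if not use_rin:
            _, mu0 = _fit_cellmeans(y, merged_idx, n_merged, offset, phi)
            conv0 = np.ones(n_ent, dtype=bool)
        else:
            X0 = np.column_stack([_onehot(merged_idx, n_merged), rin_cols])
            _, mu0, conv0 = _fit_irls(y, X0, offset, phi)
        ll0 = nb_loglik(y, mu0, phi)
        lr = np.maximum(2.0 * (ll_full - ll0), 0.0)
        p = chi2.sf(lr, df=1)
        i_trt = cells.index(("treated", t))
        i_ctl = cells.index(("control", t))
        fc = (full["beta"][:, i_trt] - full["beta"][:, i_ctl]) / _LOG2
        # a cell with no counts on either arm carries no contrast information
        both_zero = np.zeros(n_ent, dtype=bool)
        trt_cols = cell_idx == cells.index(("treated", t))
        ctl_cols = cell_idx == cells.index(("control", t))
        both_zero = (y[:, trt_cols].sum(axis=1) == 0) & (y[:, ctl_cols].sum(axis=1) == 0)
        fc[both_zero] = np.nan
        p[both_zero] = 1.0
        bad = ~(converged & conv0)
        p[bad] = 1.0
        pmat[:, j] = p
        fcmat[:, j] = fc

    if global_bh:
        fdr = benjamini_hochberg(pmat.ravel()).reshape(pmat.shape)
    else:
        fdr = np.column_stack(
            [benjamini_hochberg(pmat[:, j]) for j in range(pmat.shape[1])]
        )
    for j, t in enumerate(TIMEPOINTS):
        result[f"log2fc_{t}"] = fcmat[:, j]
    for j, t in enumerate(TIMEPOINTS):
        result[f"p_{t}"] = pmat[:, j]
    for j, t in enumerate(TIMEPOINTS):
        result[f"fdr_{t}"] = fdr[:, j]
    result["dispersion"] = phi
    basis = fdr if significance == "fdr" else pmat
    result["significant"] = basis.min(axis=1) <= threshold
    result["converged"] = converged
    return pd.DataFrame(result)


def deviance_residuals(
    norm: NormalizedMatrix,
    phi: np.ndarray,
    use_rin: bool = True,
) -> np.ndarray:
    """Signed square-root unit-deviance residuals of the fitted group model."""
    y = norm.base.counts.astype(np.float64)
    fit = fit_group_models(norm, np.asarray(phi, dtype=np.float64), use_rin=use_rin)
    mu = np.maximum(fit["mu"], 1e-12)
    phi_col = np.asarray(phi, dtype=np.float64)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        pois = phi_col < _POISSON_EPS
        r = 1.0 / np.maximum(phi_col, 1e-300)
        nb_term2 = (y + r) * np.log((y + r) / (mu + r))
        pois_term2 = y - mu
        term2 = np.where(pois, pois_term2, nb_term2)
    d = 2.0 * (term1 - term2)
    return np.sign(y - mu) * np.sqrt(np.maximum(d, 0.0))


def write_de_results(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
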