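"""Fold-change time profiles, the differencing transform, and soft
clustering of profiles into temporal templates.

Profiles are 5-point log2 fold changes (treated vs time-matched control)
ordered by the study time points 1, 3, 6, 24, 48 h.  Clustering is fuzzy
c-means on per-profile standardized values; time points are treated as
equally spaced ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from mirlag.de import NormalizedMatrix
from mirlag.io_model import TIMEPOINTS

PSEUDOCOUNT = 0.5

FCM_MAX_ITER = 200
FCM_TOL = 1e-8


@dataclass
class FoldChangeSeries:
    """Ordered 5-point log2 fold-change profile for one entity."""

    entity_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (5,):
            raise ValueError(
                f"fold-change series must have exactly 5 points, "
                f"got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite fold change for {self.entity_id!r}")


@dataclass
class DifferencedSeries:
    """Consecutive differences of a 5-point profile (4 points)."""

    entity_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (4,):
            raise ValueError("differenced series must have exactly 4 points")


@dataclass
class ClusterModel:
    """Fuzzy c-means fit in standardized profile space."""

    c: int
    centers: np.ndarray            # c x 5
    memberships: np.ndarray        # entities x c, rows sum to 1
    fuzzifier: float
    entity_ids: list[str]
    objective: float
    excluded: list[str]            # zero-variance profiles left out
    objective_history: list[float] | None = None

    def hard_labels(self) -> np.ndarray:
        return self.memberships.argmax(axis=1)


def compute_log2fc_series(
    norm: NormalizedMatrix,
    entity_ids: Sequence[str] | None = None,
) -> list[FoldChangeSeries]:
    """Group-mean log2 fold changes with a 0.5 pseudocount on both means."""
    samples = norm.samples
    ids = list(norm.base.entity_ids)
    index = {e: i for i, e in enumerate(ids)}
    if entity_ids is None:
        entity_ids = ids
    rows = []
    for e in entity_ids:
        if e not in index:
            raise KeyError(f"unknown entity {e!r}")
        rows.append(index[e])
    values = np.empty((len(rows), 5))
    for j, t in enumerate(TIMEPOINTS):
        trt = [i for i, s in enumerate(samples)
               if s.time_h == t and s.treatment == "treated"]
        ctl = [i for i, s in enumerate(samples)
               if s.time_h == t and s.treatment == "control"]
        if not trt or not ctl:
            raise ValueError(f"missing treated or control samples at {t} h")
        m_trt = norm.normalized[np.ix_(rows, trt)].mean(axis=1)
        m_ctl = norm.normalized[np.ix_(rows, ctl)].mean(axis=1)
        values[:, j] = np.log2((m_trt + PSEUDOCOUNT) / (m_ctl + PSEUDOCOUNT))
    return [FoldChangeSeries(e, values[i]) for i, e in enumerate(entity_ids)]


def difference_series(fc: FoldChangeSeries) -> DifferencedSeries:
    return DifferencedSeries(fc.entity_id, np.diff(fc.values))


def standardize_profiles(
    series: Sequence[FoldChangeSeries],
) -> tuple[np.ndarray, list[str], list[str]]:
    """Per-profile standardization (mean 0, sd 1 across the 5 points).

    Returns (matrix, kept ids, excluded zero-sd ids).
    """
    kept, excluded, rows = [], [], []
    for s in series:
        sd = s.values.std()
        if sd == 0:
            excluded.append(s.entity_id)
            continue
        rows.append((s.values - s.values.mean()) / sd)
        kept.append(s.entity_id)
    mat = np.array(rows) if rows else np.empty((0, 5))
    return mat, kept, excluded


def mfuzz_fuzzifier(n: int, d: int = 5) -> float:
    """Data-size heuristic for the fuzzy c-means fuzzifier m."""
    return (
        1.0
        + (1418.0 / n + 22.05) * d ** -2
        + (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134)
    )


def _fcm(
    data: np.ndarray, c: int, m: float, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    n = data.shape[0]
    centers = data[rng.choice(n, size=c, replace=False)].copy()
    u = np.full((n, c), 1.0 / c)
    history: list[float] = []
    for _ in range(FCM_MAX_ITER):
        d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        u = inv / inv.sum(axis=1, keepdims=True)
        um = u ** m
        centers = (um.T @ data) / um.sum(axis=0)[:, None]
        d2 = np.maximum(
            ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), 1e-12)
        obj = float(((u ** m) * d2).sum())
        if history and abs(history[-1] - obj) < FCM_TOL * max(1.0, abs(obj)):
            history.append(obj)
            break
        history.append(obj)
    return centers, u, history[-1], history


def cluster_profiles(
    series: Sequence[FoldChangeSeries],
    c: int,
    m: float | None = None,
    seed: int = 0,
    n_init: int = 5,
) -> ClusterModel:
    """Fuzzy c-means clustering of standardized 5-point profiles.

    ``m=None`` selects the fuzzifier by the data-size heuristic.  The best
    of ``n_init`` seeded random initializations (lowest objective) is kept,
    so results are deterministic given ``seed``.
    """
    if c < 1:
        raise ValueError("cluster count must be >= 1")
    data, kept, excluded = standardize_profiles(series)
    if c > len(kept):
        raise ValueError(
            f"cannot form {c} clusters from {len(kept)} usable profiles"
        )
    if m is None:
        m = mfuzz_fuzzifier(len(kept))
    if m <= 1:
        raise ValueError("fuzzifier must be > 1")
    if c == 1:
        center = data.mean(axis=0, keepdims=True)
        u = np.ones((len(kept), 1))
        d2 = ((data - center) ** 2).sum(axis=1)
        return ClusterModel(1, center, u, m, kept, float(d2.sum()), excluded)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers, u, obj, history = _fcm(data, c, m, rng)
        if best is None or obj < best[2]:
            best = (centers, u, obj, history)
    centers, u, obj, history = best
    return ClusterModel(c, centers, u, m, kept, obj, excluded, history)


def memberships_frame(model: ClusterModel) -> pd.DataFrame:
    df = pd.DataFrame(
        model.memberships,
        index=model.entity_ids,
        columns=[f"cluster_{k + 1}" for k in range(model.c)],
    )
    df.index.name = "entity_id"
    df["cluster"] = model.hard_labels() + 1
    return df


def series_frame(series: Sequence[FoldChangeSeries]) -> pd.DataFrame:
    df = pd.DataFrame(
        np.array([s.values for s in series]),
        index=[s.entity_id for s in series],
        columns=[f"log2fc_{t}" for t in TIMEPOINTS],
    )
    df.index.name = "entity_id"
    return df
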