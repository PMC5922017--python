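"""RNA-quality bias diagnostics.

Covers three checks: a two-way fixed-effects ANOVA of RIN on treatment and
time (interaction included), per-time-point two-sample t-tests of RIN, and
the distribution of per-entity count-RIN correlations before and after the
RIN-covariate model correction (correlations of deviance residuals).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mirlag.de import NormalizedMatrix, deviance_residuals, estimate_dispersions
from mirlag.io_model import TIMEPOINTS, Sample


@dataclass
class AnovaTable:
    """Sequential (type-I) sums of squares for RIN ~ treatment * time."""

    frame: pd.DataFrame  # rows: treatment, time, interaction, residual

    @property
    def interaction_p(self) -> float:
        return float(self.frame.loc["treatment:time", "p"])


@dataclass
class RinDiagnostics:
    anova: AnovaTable
    t_tests: pd.DataFrame            # per time point: t, p, zero_variance
    count_rin_correlations: np.ndarray | None = None
    corrected_correlations: np.ndarray | None = None


def _two_way_anova(rin: np.ndarray, treatment: np.ndarray, time_h: np.ndarray) -> AnovaTable:
    """Sequential two-way ANOVA via nested OLS projections."""
    n = rin.size
    trt_levels = np.unique(treatment)
    time_levels = np.unique(time_h)

    def dummies(labels: np.ndarray, levels: np.ndarray) -> np.ndarray:
        # full-rank treatment coding, first level as reference
        return np.column_stack([(labels == l).astype(float) for l in levels[1:]])

    X_trt = dummies(treatment, trt_levels)
    X_time = dummies(time_h, time_levels)
    inter_cols = []
    for j in range(X_trt.shape[1]):
        for k in range(X_time.shape[1]):
            inter_cols.append(X_trt[:, j] * X_time[:, k])
    X_int = np.column_stack(inter_cols) if inter_cols else np.empty((n, 0))

    def rss(X: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(X, rin, rcond=None)
        resid = rin - X @ coef
        return float(resid @ resid)

    ones = np.ones((n, 1))
    rss0 = rss(ones)
    rss1 = rss(np.hstack([ones, X_trt]))
    rss2 = rss(np.hstack([ones, X_trt, X_time]))
    rss3 = rss(np.hstack([ones, X_trt, X_time, X_int]))

    df_trt = X_trt.shape[1]
    df_time = X_time.shape[1]
    df_int = X_int.shape[1]
    df_res = n - 1 - df_trt - df_time - df_int
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom for ANOVA")
    ms_res = rss3 / df_res

    rows = []
    for name, ss, df in (
        ("treatment", rss0 - rss1, df_trt),
        ("time", rss1 - rss2, df_time),
        ("treatment:time", rss2 - rss3, df_int),
    ):
        ms = ss / df
        if ms_res == 0:
            f = np.inf if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            f = ms / ms_res
            p = float(stats.f.sf(f, df, df_res))
        rows.append({"source": name, "ss": ss, "df": df, "F": f, "p": p})
    rows.append({"source": "residual", "ss": rss3, "df": df_res,
                 "F": np.nan, "p": np.nan})
    frame = pd.DataFrame(rows).set_index("source")
    frame.attrs["total_ss"] = rss0
    return AnovaTable(frame)


def rin_group_tests(samples: Sequence[Sample], welch: bool = False) -> RinDiagnostics:
    """ANOVA and per-time-point t-tests of RIN between treatment arms."""
    rin = np.array([s.rin for s in samples])
    treatment = np.array([s.treatment for s in samples])
    time_h = np.array([s.time_h for s in samples])
    for t in TIMEPOINTS:
        for arm in ("treated", "control"):
            if ((time_h == t) & (treatment == arm)).sum() < 2:
                raise ValueError(f"fewer than 2 {arm} samples at {t} h")
    anova = _two_way_anova(rin, treatment, time_h)
    rows = []
    for t in TIMEPOINTS:
        a = rin[(time_h == t) & (treatment == "treated")]
        b = rin[(time_h == t) & (treatment == "control")]
        if a.std() == 0 and b.std() == 0:
            # degenerate: no variance anywhere, report p = 1 with a flag
            rows.append({"time_h": t, "t": 0.0, "p": 1.0, "zero_variance": True})
            continue
        t_stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append({"time_h": t, "t": float(t_stat), "p": float(p),
                     "zero_variance": False})
    return RinDiagnostics(anova, pd.DataFrame(rows))


def _row_pearson(matrix: np.ndarray, vector: np.ndarray) -> np.ndarray:
    xc = matrix - matrix.mean(axis=1, keepdims=True)
    yc = vector - vector.mean()
    num = xc @ yc
    den = np.sqrt((xc ** 2).sum(axis=1) * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    return np.clip(r, -1.0, 1.0)


def count_rin_correlations(
    norm: NormalizedMatrix,
    corrected: bool = False,
    dispersions: np.ndarray | None = None,
) -> np.ndarray:
    """Per-entity Pearson correlation with sample RIN.

    Uncorrected mode correlates normalized counts with RIN; corrected mode
    correlates the deviance residuals of the RIN-covariate group model,
    i.e. what remains after the model has absorbed the RIN effect.
    """
    rin = np.array([s.rin for s in norm.samples], dtype=np.float64)
    if not corrected:
        return _row_pearson(norm.normalized, rin)
    if dispersions is None:
        dispersions = estimate_dispersions(norm)
    resid = deviance_residuals(norm, dispersions, use_rin=True)
    return _row_pearson(resid, rin)


def correlation_summary(r: np.ndarray, cutoff: float = 0.5) -> dict:
    r = r[~np.isnan(r)]
    return {
        "n": int(r.size),
        "n_above_cutoff": int((r > cutoff).sum()),
        "median_abs": float(np.median(np.abs(r))) if r.size else float("nan"),
        "max": float(r.max()) if r.size else float("nan"),
    }
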