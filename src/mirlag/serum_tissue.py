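"""Per-miRNA Pearson correlation between serum (qPCR relative quantity)
and tissue (normalized sequencing count) levels across animals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from mirlag.anticorr import pearson_r
from mirlag.io_model import SerumTissueTable


@dataclass(frozen=True)
class CorrelationResult:
    mirna_id: str
    r: float
    p: float
    n: int


def correlate_serum_tissue(
    table: SerumTissueTable,
    mirna_id: str,
    log_transform: bool = False,
) -> CorrelationResult:
    """Correlate an animal's serum and tissue levels for one miRNA.

    Animals missing either member of the pair are dropped listwise; the
    two-sided p-value uses the t distribution with n-2 degrees of freedom.
    """
    sub = table.frame[table.frame["mirna_id"] == mirna_id]
    sub = sub.dropna(subset=["serum_level", "tissue_level"])
    n = len(sub)
    if n < 3:
        raise ValueError(
            f"need >= 3 complete animal pairs for {mirna_id!r}, got {n}"
        )
    serum = sub["serum_level"].to_numpy(dtype=np.float64)
    tissue = sub["tissue_level"].to_numpy(dtype=np.float64)
    if log_transform:
        serum = np.log2(serum)
        tissue = np.log2(tissue + 1.0)
    r = pearson_r(serum, tissue)
    if np.isnan(r):
        raise ValueError(f"zero variance in serum or tissue levels for {mirna_id!r}")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t_stat = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * t_dist.sf(abs(t_stat), df=n - 2)
    return CorrelationResult(mirna_id, r, float(p), n)


def correlate_all(table: SerumTissueTable, log_transform: bool = False) -> pd.DataFrame:
    rows = [
        correlate_serum_tissue(table, m, log_transform)
        for m in sorted(table.frame["mirna_id"].unique())
    ]
    return pd.DataFrame(
        {
            "mirna_id": [x.mirna_id for x in rows],
            "r": [x.r for x in rows],
            "p": [x.p for x in rows],
            "n": [x.n for x in rows],
        }
    )
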