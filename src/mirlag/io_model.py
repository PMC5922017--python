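"""Domain types and tabular/sequence I/O shared across the pipeline.

All tables are tab-separated UTF-8 with a header row; lines starting with
``#`` are comments.  miRNA and mRNA identifiers live in separate matrices,
so no cross-namespace collision checking is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TIMEPOINTS = (1, 3, 6, 24, 48)
TREATMENTS = ("treated", "control")
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_FLOAT_FMT = "%.6f"


class TableFormatError(ValueError):
    """Raised when an input table violates a format or type invariant."""


@dataclass(frozen=True)
class Sample:
    """One sequenced sample: animal, treatment arm, time point and RIN."""

    sample_id: str
    animal_id: str
    treatment: str
    time_h: int
    rin: float

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise TableFormatError(
                f"unknown treatment {self.treatment!r} for sample {self.sample_id!r}"
            )
        if self.time_h not in TIMEPOINTS:
            raise TableFormatError(
                f"time point {self.time_h!r} not in {TIMEPOINTS} "
                f"(sample {self.sample_id!r})"
            )
        if not 1.0 <= self.rin <= 10.0:
            raise TableFormatError(
                f"RIN {self.rin!r} outside [1, 10] (sample {self.sample_id!r})"
            )


@dataclass
class CountMatrix:
    """Non-negative integer counts, entities x samples."""

    entity_ids: list[str]
    samples: list[Sample]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.entity_ids)) != len(self.entity_ids):
            dup = _first_duplicate(self.entity_ids)
            raise TableFormatError(f"duplicate entity id {dup!r}")
        if self.counts.shape != (len(self.entity_ids), len(self.samples)):
            raise TableFormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise TableFormatError("non-integer count value")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise TableFormatError("negative count value")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.entity_ids, columns=self.sample_ids
        )


@dataclass
class PairTable:
    """(miRNA, gene) pairs from a prediction or validation source.

    ``site_type`` is present exactly when ``source == "predicted"``.
    """

    frame: pd.DataFrame  # columns: mirna_id, gene_id, source, site_type, evidence

    def __post_init__(self) -> None:
        required = {"mirna_id", "gene_id", "source"}
        missing = required - set(self.frame.columns)
        if missing:
            raise TableFormatError(f"pair table missing columns {sorted(missing)}")
        for col in ("site_type", "evidence"):
            if col not in self.frame.columns:
                self.frame[col] = None
        bad = ~self.frame["source"].isin(["predicted", "validated"])
        if bad.any():
            raise TableFormatError(
                f"unknown source {self.frame.loc[bad, 'source'].iloc[0]!r}"
            )
        sites = self.frame["site_type"].dropna()
        unknown = sites[~sites.isin(SITE_TYPES)]
        if len(unknown):
            raise TableFormatError(f"unknown site type {unknown.iloc[0]!r}")
        self.frame = self.frame.drop_duplicates(
            subset=["mirna_id", "gene_id", "source"]
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.frame["mirna_id"], self.frame["gene_id"]))


@dataclass
class SerumTissueTable:
    """Per-animal paired serum (qPCR) and tissue (sequencing) miRNA levels."""

    frame: pd.DataFrame  # columns: animal_id, mirna_id, serum_level, tissue_level

    def __post_init__(self) -> None:
        required = {"animal_id", "mirna_id", "serum_level", "tissue_level"}
        missing = required - set(self.frame.columns)
        if missing:
            raise TableFormatError(
                f"serum/tissue table missing columns {sorted(missing)}"
            )
        if self.frame.duplicated(subset=["animal_id", "mirna_id"]).any():
            raise TableFormatError("duplicate (animal_id, mirna_id) row")
        if (self.frame["serum_level"] <= 0).any():
            raise TableFormatError("serum_level must be > 0")
        if (self.frame["tissue_level"] < 0).any():
            raise TableFormatError("tissue_level must be >= 0")


def _first_duplicate(items: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise ValueError("no duplicate found")


def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.empty and len(df.columns) == 0:
        raise TableFormatError(f"empty table: {path}")
    return df


def read_sample_meta(path: str | Path) -> list[Sample]:
    """Read sample metadata (sample_id, animal_id, treatment, time_h, rin).

    Accepts tab- or comma-separated files; animal ids must be unique.
    """
    text = Path(path).read_text(encoding="utf-8")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    required = {"sample_id", "animal_id", "treatment", "time_h", "rin"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"metadata missing columns {sorted(missing)}")
    samples = [
        Sample(
            sample_id=row.sample_id,
            animal_id=row.animal_id,
            treatment=row.treatment,
            time_h=int(row.time_h),
            rin=float(row.rin),
        )
        for row in df.itertuples()
    ]
    animals = [s.animal_id for s in samples]
    if len(set(animals)) != len(animals):
        raise TableFormatError(f"duplicate animal id {_first_duplicate(animals)!r}")
    return samples


def write_sample_meta(samples: Sequence[Sample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "animal_id": [s.animal_id for s in samples],
            "treatment": [s.treatment for s in samples],
            "time_h": [s.time_h for s in samples],
            "rin": [s.rin for s in samples],
        }
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_counts(path: str | Path, meta: Sequence[Sample]) -> CountMatrix:
    """Read an entities x samples count TSV and validate it against ``meta``.

    The first column holds entity ids; remaining column names must cover all
    sample ids in ``meta``.  Columns are reordered to match ``meta`` order.
    """
    df = _read_table(path)
    entity_col = df.columns[0]
    entity_ids = df[entity_col].tolist()
    if len(set(entity_ids)) != len(entity_ids):
        raise TableFormatError(f"duplicate entity id {_first_duplicate(entity_ids)!r}")
    wanted = [s.sample_id for s in meta]
    missing = set(wanted) - set(df.columns[1:])
    if missing:
        raise TableFormatError(
            f"count columns missing for samples {sorted(missing)} "
            "(metadata mismatch)"
        )
    raw = df[wanted]
    try:
        values = raw.astype(np.float64).to_numpy()
    except ValueError as exc:
        raise TableFormatError(f"malformed numeric cell: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise TableFormatError("malformed numeric cell: non-finite value")
    if np.any(np.mod(values, 1) != 0):
        raise TableFormatError("non-integer count value")
    if (values < 0).any():
        raise TableFormatError("negative count value")
    return CountMatrix(entity_ids, list(meta), values.astype(np.int64))


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "entity_id"
    df.to_csv(path, sep="\t")


def read_pair_table(path: str | Path, source: str) -> PairTable:
    """Read a miRNA/gene pair TSV, dedupe it and tag it with ``source``."""
    if source not in ("predicted", "validated"):
        raise ValueError(f"source must be 'predicted' or 'validated', got {source!r}")
    df = _read_table(path)
    rename = {}
    for col in df.columns:
        low = col.strip().lower()
        if low in ("mirna", "mirna_id", "mir"):
            rename[col] = "mirna_id"
        elif low in ("gene", "gene_id", "target", "mrna", "mrna_id"):
            rename[col] = "gene_id"
        elif low == "site_type":
            rename[col] = "site_type"
        elif low == "evidence":
            rename[col] = "evidence"
    df = df.rename(columns=rename)
    missing = {"mirna_id", "gene_id"} - set(df.columns)
    if missing:
        raise TableFormatError(f"pair table missing columns {sorted(missing)}")
    if df.empty:
        raise TableFormatError(f"empty pair table: {path}")
    df["source"] = source
    if source == "validated":
        df["site_type"] = None
    keep = [c for c in ("mirna_id", "gene_id", "source", "site_type", "evidence")
            if c in df.columns]
    return PairTable(df[keep].copy())


def write_pair_table(table: PairTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_serum_tissue(path: str | Path) -> SerumTissueTable:
    df = _read_table(path)
    rename = {}
    for col in df.columns:
        low = col.strip().lower()
        if low in ("animal", "animal_id"):
            rename[col] = "animal_id"
        elif low in ("mirna", "mirna_id", "mir"):
            rename[col] = "mirna_id"
        elif low in ("serum", "serum_level"):
            rename[col] = "serum_level"
        elif low in ("tissue", "tissue_level"):
            rename[col] = "tissue_level"
    df = df.rename(columns=rename)
    for col in ("serum_level", "tissue_level"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    return SerumTissueTable(df)


def write_serum_tissue(table: SerumTissueTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


NETWORK_COLUMNS = [
    "mirna_id",
    "gene_id",
    "r_tm",
    "r_ts",
    "score",
    "pass",
    "site_type",
    "validated",
]


def write_network(rows: pd.DataFrame, path: str | Path) -> None:
    """Serialize a scored pair network (one row per miRNA-mRNA pair).

    Floats are written with 6 decimals; ``read_network`` round-trips the
    result up to that precision.
    """
    out = rows.copy()
    for col in NETWORK_COLUMNS:
        if col not in out.columns:
            out[col] = None
    out = out[NETWORK_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_network(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(NETWORK_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"network table missing columns {sorted(missing)}")
    if len(df):
        df["pass"] = df["pass"].astype(bool)
        df["validated"] = df["validated"].astype(bool)
    return df


def read_fasta(path: str | Path) -> dict[str, str]:
    """Minimal FASTA reader returning an ordered {id: sequence} mapping."""
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                if name in records:
                    raise TableFormatError(f"duplicate FASTA id {name!r}")
                chunks = []
            else:
                if name is None:
                    raise TableFormatError("FASTA sequence before first header")
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    if not records:
        raise TableFormatError(f"empty FASTA: {path}")
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
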