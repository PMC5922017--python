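"""Seeded synthetic dataset generator.

Produces miRNA and mRNA count matrices (2 treatments x 5 time points x
``n_per_group`` animals), sample metadata with a treatment/time-dependent
RIN shift, mature miRNA and 3'UTR FASTA sequences with planted seed sites,
a validated pair table (true pairs plus decoys), a serum/tissue table, and
the full ground truth - everything needed to run and test the pipeline
offline.

Counts follow NB(mean, phi) with ``Var = mu + phi*mu^2``; differential
entities carry smooth 5-point log2 fold-change templates; each true
regulatory pair's mRNA profile is the negatively scaled, optionally lag-1
shifted copy of its miRNA's realized profile plus pointwise noise, so the
delayed anti-correlation score has a planted signal to recover.  All
randomness flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mirlag.io_model import (
    TIMEPOINTS,
    CountMatrix,
    PairTable,
    Sample,
    SerumTissueTable,
)

_RNA = "ACGU"
_DNA = "ACGT"

# miRNA templates are monotone with strong curvature: their differenced
# series vary smoothly (positive lag-1 autocorrelation), which a lag-1
# negatively coupled partner needs in order to also anti-correlate at lag 0
MIRNA_TEMPLATES = {
    "up_accel": np.array([0.0, 0.05, 0.2, 0.5, 1.0]),
    "up_decel": np.array([0.0, 0.5, 0.8, 0.95, 1.0]),
    "down_accel": np.array([0.0, -0.05, -0.2, -0.5, -1.0]),
    "down_decel": np.array([0.0, -0.5, -0.8, -0.95, -1.0]),
}

# uncoupled mRNA templates: transient shapes whose differenced series are
# near-orthogonal to every miRNA template axis (|corr| <= 0.33), so chance
# anti-correlation with an uncoupled miRNA stays rare
MRNA_TEMPLATES = {
    "transient_up": np.array([0.0, 1.0, 0.05, -0.85, 0.0]),
    "transient_down": np.array([0.0, -1.0, -0.05, 0.85, 0.0]),
    "dip_rebound": np.array([0.2, -0.8, -0.1, 0.7, 0.1]),
    "rise_fade": np.array([-0.2, 0.8, 0.1, -0.7, -0.1]),
    "spike_settle": np.array([0.0, 0.9, -0.4, 0.3, -0.1]),
    "drop_settle": np.array([0.0, -0.9, 0.4, -0.3, 0.1]),
}


@dataclass
class SimConfig:
    n_mirna: int = 300
    n_mrna: int = 3000
    n_per_group: int = 6
    frac_de: float = 0.25
    n_true_pairs: int = 20
    n_decoy_pairs: int = 200
    coupling_strength: float = 3.0
    lag1_fraction: float = 1.0        # remainder of true pairs couple at lag 0
    coupling_noise_sd: float = 0.2    # pointwise noise on coupled mRNA profiles
    profile_noise_sd: float = 0.15    # pointwise noise on miRNA DE profiles
    uncoupled_noise_sd: float = 1.0   # pointwise noise on uncoupled mRNA profiles
    amplitude_range: tuple[float, float] = (2.5, 4.0)
    dispersion: float = 0.03
    base_mean_log_mu: float = 5.0     # log of per-entity baseline mean
    base_mean_log_sd: float = 1.0
    library_log_sd: float = 0.15
    rin_base: float = 8.0
    rin_sd: float = 0.4
    rin_treated_late_shift: float = 1.0
    degradation_gamma: tuple[float, float] = (0.5, 2.0)
    frac_rin_biased: float = 0.0
    serum_tissue_rho: float = 0.0
    serum_tissue_mirnas: tuple[str, ...] = ("miR-sim-A", "miR-sim-B")
    utr_length: int = 200
    mirna_length: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if not 0.0 <= self.lag1_fraction <= 1.0:
            raise ValueError("lag1_fraction must lie in [0, 1]")
        if self.coupling_strength <= 0:
            raise ValueError("coupling_strength must be > 0")
        n_de_mirna = int(round(self.frac_de * self.n_mirna))
        n_de_mrna = int(round(self.frac_de * self.n_mrna))
        if self.n_true_pairs > min(n_de_mirna, n_de_mrna):
            raise ValueError(
                f"n_true_pairs={self.n_true_pairs} exceeds available DE "
                f"entities ({n_de_mirna} miRNA, {n_de_mrna} mRNA)"
            )


@dataclass
class GroundTruth:
    de_mirna: list[str]
    de_mrna: list[str]
    mirna_profiles: pd.DataFrame      # entity x 5 true log2fc (DE only)
    mrna_profiles: pd.DataFrame
    template_assignment: pd.DataFrame  # entity_id, species, template
    true_pairs: pd.DataFrame          # mirna_id, gene_id, lag, k
    decoy_pairs: pd.DataFrame         # mirna_id, gene_id
    planted_sites: pd.DataFrame       # mirna_id, gene_id, start, end (1-based)
    rin_biased_entities: pd.DataFrame  # entity_id, species, gamma


@dataclass
class SyntheticDataset:
    config: SimConfig
    mirna_counts: CountMatrix
    mrna_counts: CountMatrix
    samples: list[Sample]
    mirna_fasta: dict[str, str]
    utr_fasta: dict[str, str]
    validated: PairTable
    serum_tissue: SerumTissueTable
    truth: GroundTruth


def _make_samples(cfg: SimConfig, rng: np.random.Generator) -> list[Sample]:
    samples = []
    animal = 0
    for t in TIMEPOINTS:
        for trt in ("control", "treated"):
            for _ in range(cfg.n_per_group):
                animal += 1
                rin = cfg.rin_base + cfg.rin_sd * rng.standard_normal()
                if trt == "treated" and t in (24, 48):
                    rin += cfg.rin_treated_late_shift
                rin = float(np.clip(rin, 1.0, 10.0))
                samples.append(
                    Sample(
                        sample_id=f"S{animal:03d}",
                        animal_id=f"R{animal:03d}",
                        treatment=trt,
                        time_h=t,
                        rin=rin,
                    )
                )
    return samples


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, phi) with Var = mu + phi*mu^2 (Poisson when phi == 0)."""
    mean = np.maximum(mean, 1e-8)
    if phi <= 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    lam = rng.gamma(shape, mean * phi)
    return rng.poisson(lam)


def _random_seq(rng: np.random.Generator, n: int, alphabet: str) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, 4, size=n))


def _plant_site(
    rng: np.random.Generator,
    utr: str,
    mirna_seq: str,
    occupied: list[tuple[int, int]],
) -> tuple[str, int, int]:
    """Insert an 8mer site (rc of seed 2-8 + A) at a random free position.

    Avoids overwriting previously planted sites in the same UTR so planted
    sites are always recoverable.
    """
    comp = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}
    seed7 = mirna_seq[1:8].upper()
    site = "".join(comp[b] for b in reversed(seed7)) + "A"
    for _ in range(200):
        pos = int(rng.integers(0, len(utr) - len(site) + 1))
        span = (pos, pos + len(site) - 1)
        if all(span[1] < a or span[0] > b for a, b in occupied):
            break
    else:
        raise ValueError("could not place seed site without overlap")
    occupied.append(span)
    new = utr[:pos] + site + utr[pos + len(site):]
    return new, pos + 1, pos + len(site)


def _simulate_counts(
    rng: np.random.Generator,
    ids: list[str],
    samples: Sequence[Sample],
    profiles: dict[str, np.ndarray],
    gammas: dict[str, float],
    cfg: SimConfig,
) -> CountMatrix:
    n_ent, n_samp = len(ids), len(samples)
    base = np.exp(rng.normal(cfg.base_mean_log_mu, cfg.base_mean_log_sd, size=n_ent))
    lib = np.exp(rng.normal(0.0, cfg.library_log_sd, size=n_samp))
    t_index = {t: j for j, t in enumerate(TIMEPOINTS)}
    counts = np.zeros((n_ent, n_samp), dtype=np.int64)
    fc = np.zeros((n_ent, 5))
    for i, e in enumerate(ids):
        if e in profiles:
            fc[i] = profiles[e]
    gamma_vec = np.array([gammas.get(e, 0.0) for e in ids])
    rins = np.array([s.rin for s in samples])
    deg = (rins[None, :] / 10.0) ** gamma_vec[:, None]
    for j, s in enumerate(samples):
        mu = base * lib[j]
        if s.treatment == "treated":
            mu = mu * 2.0 ** fc[:, t_index[s.time_h]]
        mu = mu * deg[:, j]
        counts[:, j] = _nb_draw(rng, mu, cfg.dispersion)
    return CountMatrix(list(ids), list(samples), counts)


def generate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate the full synthetic study; reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    samples = _make_samples(cfg, rng)

    mirna_ids = [f"miR-sim-{i:04d}" for i in range(1, cfg.n_mirna + 1)]
    gene_ids = [f"Gene{i:05d}" for i in range(1, cfg.n_mrna + 1)]

    n_de_mi = int(round(cfg.frac_de * cfg.n_mirna))
    n_de_mr = int(round(cfg.frac_de * cfg.n_mrna))
    de_mi = list(rng.choice(mirna_ids, size=n_de_mi, replace=False))
    de_mr = list(rng.choice(gene_ids, size=n_de_mr, replace=False))

    # true regulatory pairs: distinct DE miRNAs paired with distinct DE mRNAs
    pair_mi = list(rng.choice(de_mi, size=cfg.n_true_pairs, replace=False))
    pair_mr = list(rng.choice(de_mr, size=cfg.n_true_pairs, replace=False))

    mi_names = list(MIRNA_TEMPLATES)
    mr_names = list(MRNA_TEMPLATES)
    profiles_mi: dict[str, np.ndarray] = {}
    profiles_mr: dict[str, np.ndarray] = {}
    assignment = []

    for e in de_mi:
        name = mi_names[int(rng.integers(len(mi_names)))]
        amp = rng.uniform(*cfg.amplitude_range)
        noise = rng.normal(0.0, cfg.profile_noise_sd, size=5)
        profiles_mi[e] = amp * MIRNA_TEMPLATES[name] + noise
        assignment.append({"entity_id": e, "species": "miRNA", "template": name})

    coupled = dict(zip(pair_mr, pair_mi))
    lags = {}
    true_rows = []
    for g, m in coupled.items():
        lag = 1 if rng.random() < cfg.lag1_fraction else 0
        lags[g] = lag
        src = profiles_mi[m]
        if lag == 1:
            # postpone by one step, extrapolating the initial trend backward
            # so the differenced series becomes [d0, d0, d1, d2]
            shifted = np.concatenate([[2.0 * src[0] - src[1]], src[:-1]])
        else:
            shifted = src
        profiles_mr[g] = (
            -cfg.coupling_strength * shifted
            + rng.normal(0.0, cfg.coupling_noise_sd, size=5)
        )
        assignment.append({"entity_id": g, "species": "mRNA", "template": "coupled"})
        true_rows.append({"mirna_id": m, "gene_id": g, "lag": lag,
                          "k": cfg.coupling_strength})

    for g in de_mr:
        if g in coupled:
            continue
        name = mr_names[int(rng.integers(len(mr_names)))]
        amp = rng.uniform(*cfg.amplitude_range)
        noise = rng.normal(0.0, cfg.uncoupled_noise_sd, size=5)
        profiles_mr[g] = amp * MRNA_TEMPLATES[name] + noise
        assignment.append({"entity_id": g, "species": "mRNA", "template": name})

    # count-RIN degradation bias planted on non-differential entities
    gammas_mi: dict[str, float] = {}
    gammas_mr: dict[str, float] = {}
    bias_rows = []
    if cfg.frac_rin_biased > 0:
        non_de_mi = [e for e in mirna_ids if e not in profiles_mi]
        n_bias = int(round(cfg.frac_rin_biased * cfg.n_mirna))
        n_bias = min(n_bias, len(non_de_mi))
        for e in rng.choice(non_de_mi, size=n_bias, replace=False):
            g = float(rng.uniform(*cfg.degradation_gamma))
            gammas_mi[e] = g
            bias_rows.append({"entity_id": e, "species": "miRNA", "gamma": g})
        non_de_mr = [e for e in gene_ids if e not in profiles_mr]
        n_bias = min(int(round(cfg.frac_rin_biased * cfg.n_mrna)), len(non_de_mr))
        for e in rng.choice(non_de_mr, size=n_bias, replace=False):
            g = float(rng.uniform(*cfg.degradation_gamma))
            gammas_mr[e] = g
            bias_rows.append({"entity_id": e, "species": "mRNA", "gamma": g})

    mirna_counts = _simulate_counts(rng, mirna_ids, samples, profiles_mi,
                                    gammas_mi, cfg)
    mrna_counts = _simulate_counts(rng, gene_ids, samples, profiles_mr,
                                   gammas_mr, cfg)

    # sequences: every miRNA gets a mature sequence, every gene a UTR; true
    # and decoy pairs get a planted canonical 8mer site
    mirna_fasta = {m: _random_seq(rng, cfg.mirna_length, _RNA) for m in mirna_ids}
    utr_fasta = {g: _random_seq(rng, cfg.utr_length, _DNA) for g in gene_ids}

    decoy_candidates = [
        (m, g)
        for m in de_mi
        for g in de_mr
        if g not in coupled  # coupled mRNAs are reserved for their true pair
    ]
    idx = rng.choice(len(decoy_candidates),
                     size=min(cfg.n_decoy_pairs, len(decoy_candidates)),
                     replace=False)
    decoy_pairs = [decoy_candidates[i] for i in idx]

    site_rows = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for m, g in true_rows_pairs(true_rows) + decoy_pairs:
        utr_fasta[g], start, end = _plant_site(
            rng, utr_fasta[g], mirna_fasta[m], occupied.setdefault(g, []))
        site_rows.append({"mirna_id": m, "gene_id": g, "start": start, "end": end})

    validated_rows = [
        {"mirna_id": m, "gene_id": g, "source": "validated",
         "site_type": None, "evidence": "planted"}
        for m, g in true_rows_pairs(true_rows) + decoy_pairs
    ]
    validated = PairTable(pd.DataFrame(
        validated_rows,
        columns=["mirna_id", "gene_id", "source", "site_type", "evidence"],
    ))

    serum_tissue = _make_serum_tissue(cfg, rng, samples)

    truth = GroundTruth(
        de_mirna=de_mi,
        de_mrna=de_mr,
        mirna_profiles=_profiles_frame(profiles_mi),
        mrna_profiles=_profiles_frame(profiles_mr),
        template_assignment=pd.DataFrame(
            assignment, columns=["entity_id", "species", "template"]),
        true_pairs=pd.DataFrame(
            true_rows, columns=["mirna_id", "gene_id", "lag", "k"]),
        decoy_pairs=pd.DataFrame(
            decoy_pairs, columns=["mirna_id", "gene_id"]),
        planted_sites=pd.DataFrame(
            site_rows, columns=["mirna_id", "gene_id", "start", "end"]),
        rin_biased_entities=pd.DataFrame(
            bias_rows, columns=["entity_id", "species", "gamma"]),
    )
    return SyntheticDataset(
        cfg, mirna_counts, mrna_counts, samples, mirna_fasta, utr_fasta,
        validated, serum_tissue, truth,
    )


def true_rows_pairs(true_rows: list[dict]) -> list[tuple[str, str]]:
    return [(r["mirna_id"], r["gene_id"]) for r in true_rows]


def _profiles_frame(profiles: dict[str, np.ndarray]) -> pd.DataFrame:
    df = pd.DataFrame(
        {e: v for e, v in profiles.items()},
        index=[f"log2fc_{t}" for t in TIMEPOINTS],
    ).T
    df.index.name = "entity_id"
    return df


def _make_serum_tissue(
    cfg: SimConfig, rng: np.random.Generator, samples: Sequence[Sample],
) -> SerumTissueTable:
    """Per-animal serum/tissue levels with configurable true correlation."""
    rho = cfg.serum_tissue_rho
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    rows = []
    for mirna in cfg.serum_tissue_mirnas:
        z = rng.standard_normal(size=(len(samples), 2)) @ chol.T
        for (s, (zs, zt)) in zip(samples, z):
            rows.append(
                {
                    "animal_id": s.animal_id,
                    "mirna_id": mirna,
                    "serum_level": float(np.exp(1.0 + 0.8 * zs)),
                    "tissue_level": float(np.exp(5.0 + 0.6 * zt)),
                }
            )
    return SerumTissueTable(pd.DataFrame(rows))


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write every artifact in the formats the readers consume.

    Returns a manifest mapping artifact names to paths; also writes the
    manifest itself (with seed and config) as ``manifest.tsv``.
    """
    from mirlag import io_model

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_counts": outdir / "mirna_counts.tsv",
        "mrna_counts": outdir / "mrna_counts.tsv",
        "sample_meta": outdir / "samples.tsv",
        "mirna_fasta": outdir / "mirna.fa",
        "utr_fasta": outdir / "utr.fa",
        "validated_pairs": outdir / "validated_pairs.tsv",
        "serum_tissue": outdir / "serum_tissue.tsv",
        "truth_pairs": outdir / "truth_pairs.tsv",
        "truth_de_mirna": outdir / "truth_de_mirna.tsv",
        "truth_de_mrna": outdir / "truth_de_mrna.tsv",
    }
    io_model.write_counts(ds.mirna_counts, paths["mirna_counts"])
    io_model.write_counts(ds.mrna_counts, paths["mrna_counts"])
    io_model.write_sample_meta(ds.samples, paths["sample_meta"])
    io_model.write_fasta(ds.mirna_fasta, paths["mirna_fasta"])
    io_model.write_fasta(ds.utr_fasta, paths["utr_fasta"])
    io_model.write_pair_table(ds.validated, paths["validated_pairs"])
    io_model.write_serum_tissue(ds.serum_tissue, paths["serum_tissue"])
    ds.truth.true_pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
    pd.Series(ds.truth.de_mirna).to_csv(
        paths["truth_de_mirna"], sep="\t", index=False, header=["entity_id"])
    pd.Series(ds.truth.de_mrna).to_csv(
        paths["truth_de_mrna"], sep="\t", index=False, header=["entity_id"])
    manifest = pd.DataFrame(
        [{"artifact": k, "path": str(v)} for k, v in paths.items()]
        + [{"artifact": "seed", "path": str(ds.config.seed)}]
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
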