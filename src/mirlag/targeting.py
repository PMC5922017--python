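"""Canonical seed-match target prediction and validated-pair filtering.

A miRNA's seed is positions 2-8 of the mature 5'->3' sequence.  A site on
the 3'UTR sense strand is classified (highest priority first) as:

* ``8mer``    — reverse complement of positions 2-8, followed by an A
* ``7mer-m8`` — reverse complement of positions 2-8
* ``7mer-A1`` — reverse complement of positions 2-7, followed by an A
* ``6mer``    — reverse complement of positions 2-7

Each occurrence (anchored at its 6mer core) is reported once at its
highest-priority type.  Context scoring and conservation tiers are out of
scope; any validated-table evidence string is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SITE_PRIORITY = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_PRIORITY_RANK = {t: i for i, t in enumerate(SITE_PRIORITY)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}
_IUPAC = set("ACGTUacgtuNn")


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class SeedSite:
    """One predicted seed-match site, 1-based inclusive UTR coordinates."""

    mirna_id: str
    gene_id: str
    site_type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        length = self.end - self.start + 1
        expected = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[self.site_type]
        if length != expected:
            raise ValueError(
                f"{self.site_type} site must span {expected} nt, got {length}"
            )


def _clean(seq: str, what: str) -> str:
    bad = set(seq) - _IUPAC
    if bad:
        raise SequenceError(f"non-IUPAC character {sorted(bad)[0]!r} in {what}")
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def seed_match_patterns(mirna_seq: str) -> dict[str, str]:
    """UTR-sense match strings for the four canonical site types."""
    seq = _clean(mirna_seq, "miRNA sequence")
    if len(seq) < 8:
        raise SequenceError("miRNA sequence shorter than 8 nt")
    seed7 = seq[1:8]   # positions 2-8
    seed6 = seq[1:7]   # positions 2-7
    rc7 = reverse_complement(seed7)
    rc6 = reverse_complement(seed6)
    return {
        "8mer": rc7 + "A",
        "7mer-m8": rc7,
        "7mer-A1": rc6 + "A",
        "6mer": rc6,
    }


def scan_utr(mirna_id: str, mirna_seq: str, gene_id: str, utr_seq: str) -> list[SeedSite]:
    """All seed sites of one miRNA in one UTR, one record per occurrence.

    Occurrences are anchored at the 6mer core (reverse complement of seed
    positions 2-7); flanking matches upgrade the type, and the reported
    start/end expand to the full site.
    """
    patterns = seed_match_patterns(mirna_seq)
    utr = _clean(utr_seq, f"UTR {gene_id}")
    core = patterns["6mer"]
    m8_base = patterns["7mer-m8"][0]  # nt pairing miRNA position 8
    sites: list[SeedSite] = []
    pos = utr.find(core)
    while pos != -1:
        has_m8 = pos > 0 and utr[pos - 1] == m8_base
        has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if has_m8 and has_a1:
            site_type, start, end = "8mer", pos - 1, pos + 6
        elif has_m8:
            site_type, start, end = "7mer-m8", pos - 1, pos + 5
        elif has_a1:
            site_type, start, end = "7mer-A1", pos, pos + 6
        else:
            site_type, start, end = "6mer", pos, pos + 5
        sites.append(SeedSite(mirna_id, gene_id, site_type, start + 1, end + 1))
        pos = utr.find(core, pos + 1)
    return sites


def predict_seed_sites(
    mirna_seqs: dict[str, str],
    utr_seqs: dict[str, str],
) -> tuple[pd.DataFrame, list[SeedSite]]:
    """Scan every miRNA against every UTR.

    Returns (pair table frame with best site per pair, full site list).
    The pair table keeps the highest-priority site type found for the pair.
    """
    if not mirna_seqs:
        raise SequenceError("empty miRNA FASTA")
    if not utr_seqs:
        raise SequenceError("empty UTR FASTA")
    all_sites: list[SeedSite] = []
    best: dict[tuple[str, str], str] = {}
    for mirna_id, mseq in mirna_seqs.items():
        for gene_id, useq in utr_seqs.items():
            sites = scan_utr(mirna_id, mseq, gene_id, useq)
            all_sites.extend(sites)
            for s in sites:
                key = (mirna_id, gene_id)
                if key not in best or _PRIORITY_RANK[s.site_type] < _PRIORITY_RANK[best[key]]:
                    best[key] = s.site_type
    frame = pd.DataFrame(
        [
            {"mirna_id": m, "gene_id": g, "source": "predicted",
             "site_type": t, "evidence": None}
            for (m, g), t in sorted(best.items())
        ],
        columns=["mirna_id", "gene_id", "source", "site_type", "evidence"],
    )
    return frame, all_sites


def sites_frame(sites: list[SeedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"mirna_id": s.mirna_id, "gene_id": s.gene_id,
             "site_type": s.site_type, "start": s.start, "end": s.end}
            for s in sites
        ],
        columns=["mirna_id", "gene_id", "site_type", "start", "end"],
    )


def filter_validated(predicted: pd.DataFrame, validated: pd.DataFrame) -> pd.DataFrame:
    """Keep predicted pairs with database support; attach validated evidence."""
    val = validated[["mirna_id", "gene_id"]].copy()
    if "evidence" in validated.columns:
        val["validated_evidence"] = validated["evidence"]
    merged = predicted.merge(val.drop_duplicates(subset=["mirna_id", "gene_id"]),
                             on=["mirna_id", "gene_id"], how="inner")
    return merged.reset_index(drop=True)
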