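"""Amino-acid composition profiles and disordered-vs-ordered contrasts.

The mole fraction of amino acid j over a set of sequences is the
length-weighted mean of per-sequence frequencies,

    P_j = sum_i(n_i * P_ji) / sum_i(n_i),

which is identical to the pooled count of j divided by the total residue
count.  The fractional difference between a disordered set *a* and an
ordered set *b* is (P_j(a) - P_j(b)) / P_j(b): negative values mark residues
depleted in disorder (order promoters), positive values residues enriched in
disorder (disorder promoters).

Residues outside the 20-letter alphabet (X, B, Z, U, ...) occupy positions
during segmentation but are excluded from both numerator and denominator
here, so the 20 fractions always sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io import AMINO_ACIDS
from .regions import run_lengths

__all__ = [
    "DISORDER_PROMOTERS",
    "ORDER_PROMOTERS",
    "CompositionProfile",
    "FractionalDifference",
    "residue_counts",
    "mole_fractions",
    "fractional_difference",
    "rank_amino_acids",
    "region_sequences",
]

#: Residues empirically enriched in disordered regions.
DISORDER_PROMOTERS: frozenset[str] = frozenset("AEKPQRS")
#: Residues empirically depleted in disordered regions.
ORDER_PROMOTERS: frozenset[str] = frozenset("CFHILVWY")

_AA_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _aa in enumerate(AMINO_ACIDS):
    _AA_INDEX[ord(_aa)] = _i


@dataclass(frozen=True)
class CompositionProfile:
    """Mole fractions of the 20 standard residues over a sequence set."""

    fractions: dict[str, float]
    total_residues: int

    def __getitem__(self, residue: str) -> float:
        return self.fractions[residue]

    def as_array(self) -> np.ndarray:
        return np.array([self.fractions[a] for a in AMINO_ACIDS])


@dataclass(frozen=True)
class FractionalDifference:
    """(P_a - P_b) / P_b per residue; NaN where P_b is zero."""

    values: dict[str, float]
    set_a_id: str = "disordered"
    set_b_id: str = "ordered"

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def mean_over(self, residues: Iterable[str]) -> float:
        vals = [self.values[r] for r in residues if not np.isnan(self.values[r])]
        return float(np.mean(vals)) if vals else float("nan")


def residue_counts(sequences: Iterable[str]) -> np.ndarray:
    """Pooled counts of the 20 standard residues (non-standard excluded)."""
    counts = np.zeros(20, dtype=np.int64)
    for seq in sequences:
        if not seq:
            continue
        codes = _AA_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        codes = codes[codes >= 0]
        counts += np.bincount(codes, minlength=20)
    return counts


def mole_fractions(sequences: Iterable[str]) -> CompositionProfile:
    """Length-weighted mean amino-acid frequencies over a sequence set."""
    counts = residue_counts(sequences)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no standard residues in the sequence set")
    frac = counts / total
    return CompositionProfile(
        fractions={aa: float(f) for aa, f in zip(AMINO_ACIDS, frac)},
        total_residues=total,
    )


def fractional_difference(
    profile_a: CompositionProfile,
    profile_b: CompositionProfile,
    set_a_id: str = "disordered",
    set_b_id: str = "ordered",
) -> FractionalDifference:
    """Relative enrichment of each residue in set a versus set b.

    Residues absent from set b (P_b = 0) are undefined and reported as NaN
    rather than infinity, so downstream rankings stay total.
    """
    if profile_b.total_residues == 0:
        raise ValueError("reference profile is empty")
    values: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        pb = profile_b.fractions[aa]
        pa = profile_a.fractions[aa]
        values[aa] = (pa - pb) / pb if pb > 0 else float("nan")
    return FractionalDifference(values=values, set_a_id=set_a_id, set_b_id=set_b_id)


def rank_amino_acids(fd: FractionalDifference) -> list[str]:
    """Residues in ascending order of fractional difference.

    Undefined (NaN) values sort last; ties break alphabetically so the
    ordering is deterministic.
    """
    defined = sum(1 for v in fd.values.values() if not np.isnan(v))
    if defined < 2:
        raise ValueError("need at least two defined values to rank")
    return sorted(
        fd.values,
        key=lambda aa: (np.isnan(fd.values[aa]), fd.values[aa] if not np.isnan(fd.values[aa]) else 0.0, aa),
    )


def region_sequences(
    sequence: str, labels: np.ndarray, kind: str = "disordered", min_length: int = 1
) -> list[str]:
    """Subsequences of the maximal regions of ``kind`` with length >= min_length."""
    starts, lengths, values = run_lengths(labels)
    want = 1 if kind == "disordered" else 0
    return [
        sequence[s : s + ln]
        for s, ln, v in zip(starts, lengths, values)
        if v == want and ln >= min_length
    ]
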