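"""Disordered/ordered region segmentation and region-level statistics.

A *region* is a maximal run of residues with the same binary disorder state.
The regions of a protein tile it exactly: sorted, contiguous, alternating in
kind.  Region statistics are reported for length classes L >= 1, 11, 21, 31,
41 AA (all thresholds inclusive), the classes used throughout the analysis.

Collection-level per-100-AA statistics are *pooled* by default (sum of region
counts over sum of residue counts); a per-protein-mean variant is available
because the pooled/averaged distinction matters when protein lengths vary.
Undefined ratios (zero denominator) are reported as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .io import ProteinRecord

__all__ = [
    "LENGTH_CLASSES",
    "Region",
    "RegionStats",
    "segment",
    "run_lengths",
    "disordered_run_lengths",
    "count_regions",
    "regions_per_100aa",
    "pct_disordered_aa",
    "pct_ordered_aa",
    "pct_proteins_with_region",
    "avg_regions_per_protein",
    "classify_purity",
    "bin_by_length",
    "region_stats",
]

#: Minimum region lengths (inclusive) reported throughout.
LENGTH_CLASSES: tuple[int, ...] = (1, 11, 21, 31, 41)

Kind = Literal["disordered", "ordered"]


@dataclass(frozen=True)
class Region:
    """A maximal run of constant disorder state, 0-based half-open."""

    protein_id: str
    start: int
    end: int
    kind: Kind

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionStats:
    """Collection-level disorder statistics for one length class."""

    collection_id: str
    min_length: int
    n_proteins: int
    n_regions_disordered: int
    n_regions_ordered: int
    regions_per_100aa_protein_basis: float
    regions_per_100aa_region_basis: float
    pct_length_disordered: float
    avg_regions_per_protein: float
    pct_proteins_with_region: float
    avg_protein_length: float


def _labels_of(item: ProteinRecord | np.ndarray | Sequence[int]) -> np.ndarray:
    if isinstance(item, ProteinRecord):
        if item.labels is None:
            raise ValueError(f"protein {item.protein_id!r} has no disorder labels")
        return item.labels
    return np.asarray(item, dtype=np.uint8)


def run_lengths(labels: np.ndarray | Sequence[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose a label vector into runs: (starts, lengths, values)."""
    lab = np.asarray(labels, dtype=np.uint8)
    if lab.size == 0:
        raise ValueError("empty label vector")
    change = np.flatnonzero(np.diff(lab)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [lab.size]))
    return starts, ends - starts, lab[starts]


def segment(
    labels: np.ndarray | Sequence[int], protein_id: str = ""
) -> list[Region]:
    """Segment a binary label vector into maximal regions.

    Disordered regions are maximal runs of 1, ordered regions maximal runs
    of 0; together they tile the protein.
    """
    starts, lengths, values = run_lengths(labels)
    return [
        Region(
            protein_id=protein_id,
            start=int(s),
            end=int(s + ln),
            kind="disordered" if v else "ordered",
        )
        for s, ln, v in zip(starts, lengths, values)
    ]


def disordered_run_lengths(labels: np.ndarray | Sequence[int]) -> np.ndarray:
    """Lengths of maximal disordered runs, in order of occurrence."""
    starts, lengths, values = run_lengths(labels)
    return lengths[values == 1]


def _run_lengths_by_kind(labels: np.ndarray, kind: Kind) -> np.ndarray:
    starts, lengths, values = run_lengths(labels)
    return lengths[values == (1 if kind == "disordered" else 0)]


def count_regions(regions: Iterable[Region], kind: Kind, min_length: int = 1) -> int:
    """Number of regions of ``kind`` with length >= ``min_length``."""
    return sum(1 for r in regions if r.kind == kind and r.length >= min_length)


def regions_per_100aa(
    proteins: Iterable[ProteinRecord | np.ndarray],
    kind: Kind = "disordered",
    min_length: int = 1,
    basis: Literal["protein", "region"] = "protein",
    per_protein_mean: bool = False,
) -> float:
    """Qualifying regions per 100 AA over a collection.

    ``basis='protein'`` normalizes by the total residues of the proteins;
    ``basis='region'`` by the residues inside the qualifying regions
    themselves.  ``per_protein_mean`` averages the per-protein ratios instead
    of pooling.  Returns NaN when the denominator is zero.
    """
    ratios: list[float] = []
    total_count = 0
    total_denom = 0
    for item in proteins:
        lab = _labels_of(item)
        runs = _run_lengths_by_kind(lab, kind)
        qual = runs[runs >= min_length]
        denom = lab.size if basis == "protein" else int(qual.sum())
        total_count += qual.size
        total_denom += denom
        if per_protein_mean:
            ratios.append(100.0 * qual.size / denom if denom else np.nan)
    if per_protein_mean:
        arr = np.asarray(ratios, dtype=float)
        return float(np.nanmean(arr)) if np.any(~np.isnan(arr)) else float("nan")
    return 100.0 * total_count / total_denom if total_denom else float("nan")


def pct_disordered_aa(
    proteins: Iterable[ProteinRecord | np.ndarray] | ProteinRecord | np.ndarray,
    min_length: int = 1,
) -> float:
    """Percent of residues inside disordered regions of length >= min_length."""
    items = _as_collection(proteins)
    inside = 0
    total = 0
    for item in items:
        lab = _labels_of(item)
        runs = _run_lengths_by_kind(lab, "disordered")
        inside += int(runs[runs >= min_length].sum())
        total += lab.size
    return 100.0 * inside / total if total else float("nan")


def pct_ordered_aa(
    proteins: Iterable[ProteinRecord | np.ndarray] | ProteinRecord | np.ndarray,
    min_length: int = 1,
) -> float:
    """Percent of residues inside ordered regions of length >= min_length."""
    items = _as_collection(proteins)
    inside = 0
    total = 0
    for item in items:
        lab = _labels_of(item)
        runs = _run_lengths_by_kind(lab, "ordered")
        inside += int(runs[runs >= min_length].sum())
        total += lab.size
    return 100.0 * inside / total if total else float("nan")


def _as_collection(
    proteins: Iterable[ProteinRecord | np.ndarray] | ProteinRecord | np.ndarray,
) -> list[ProteinRecord | np.ndarray]:
    if isinstance(proteins, (ProteinRecord, np.ndarray)):
        return [proteins]
    return list(proteins)


def pct_proteins_with_region(
    proteins: Iterable[ProteinRecord | np.ndarray],
    min_length: int = 1,
    kind: Kind = "disordered",
) -> float:
    """Percent of proteins with at least one qualifying region."""
    items = _as_collection(proteins)
    if not items:
        raise ValueError("empty collection")
    hits = 0
    for item in items:
        runs = _run_lengths_by_kind(_labels_of(item), kind)
        if np.any(runs >= min_length):
            hits += 1
    return 100.0 * hits / len(items)


def avg_regions_per_protein(
    proteins: Iterable[ProteinRecord | np.ndarray],
    min_length: int = 1,
    kind: Kind = "disordered",
) -> float:
    """Mean number of qualifying regions per protein."""
    items = _as_collection(proteins)
    if not items:
        raise ValueError("empty collection")
    counts = [
        int(np.sum(_run_lengths_by_kind(_labels_of(item), kind) >= min_length))
        for item in items
    ]
    return float(np.mean(counts))


@dataclass(frozen=True)
class Purity:
    category: Literal["fully_disordered", "fully_ordered", "mixed"]
    gt90_disordered: bool
    fully_disordered: bool


def classify_purity(protein: ProteinRecord | np.ndarray) -> Purity:
    """Classify a protein as fully disordered / fully ordered / mixed.

    The >90% flag uses the strict inequality: a protein with exactly 90% of
    residues disordered is not flagged.
    """
    lab = _labels_of(protein)
    frac = float(lab.mean())
    if frac == 1.0:
        cat = "fully_disordered"
    elif frac == 0.0:
        cat = "fully_ordered"
    else:
        cat = "mixed"
    return Purity(category=cat, gt90_disordered=frac > 0.9, fully_disordered=frac == 1.0)


def bin_by_length(
    proteins: Iterable[ProteinRecord], bin_width: int = 100
) -> dict[tuple[int, int], list[ProteinRecord]]:
    """Group proteins into half-open length bins [0,w), [w,2w), ..."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    out: dict[tuple[int, int], list[ProteinRecord]] = {}
    for prot in proteins:
        lo = (prot.length // bin_width) * bin_width
        out.setdefault((lo, lo + bin_width), []).append(prot)
    return dict(sorted(out.items()))


def region_stats(
    proteins: Sequence[ProteinRecord],
    min_length: int = 41,
    collection_id: str = "",
) -> RegionStats:
    """All collection-level statistics for one length class, pooled."""
    if not proteins:
        raise ValueError("empty collection")
    n_dis = 0
    n_ord = 0
    dis_aa = 0
    total_aa = 0
    with_region = 0
    for prot in proteins:
        lab = _labels_of(prot)
        starts, lengths, values = run_lengths(lab)
        dis_runs = lengths[values == 1]
        ord_runs = lengths[values == 0]
        q_dis = dis_runs[dis_runs >= min_length]
        n_dis += q_dis.size
        n_ord += int(np.sum(ord_runs >= min_length))
        dis_aa += int(q_dis.sum())
        total_aa += lab.size
        if q_dis.size:
            with_region += 1
    n = len(proteins)
    region_aa = dis_aa
    return RegionStats(
        collection_id=collection_id,
        min_length=min_length,
        n_proteins=n,
        n_regions_disordered=int(n_dis),
        n_regions_ordered=int(n_ord),
        regions_per_100aa_protein_basis=100.0 * n_dis / total_aa,
        regions_per_100aa_region_basis=(
            100.0 * n_dis / region_aa if region_aa else float("nan")
        ),
        pct_length_disordered=100.0 * dis_aa / total_aa,
        avg_regions_per_protein=n_dis / n,
        pct_proteins_with_region=100.0 * with_region / n,
        avg_protein_length=total_aa / n,
    )
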