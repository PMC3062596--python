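"""COG functional groups, organism-characteristic discretization and
characteristic-pair cross-tables.

The 25 single-letter COG categories partition into four functional groups:

* Isp (information storage and processing): A, B, J, K, L
* Cp  (cellular processes):                 D, M, N, O, T, U, V, W, Y, Z
* Me  (metabolism):                         C, E, F, G, H, I, P, Q
* Pc  (poorly characterized):               R, S

plus the pseudo-group NC for proteins without a COG assignment ("N.C.").

Continuous organism characteristics are discretized into modalities:
genome size is short/long at 4 Mb (bacteria) or 2.5 Mb (archaea), with
"short" defined by strict <; GC content is low/medium/high with borders at
the collection mean +/- one sample standard deviation, borders inclusive to
medium.  Organism disorder level uses the same mean+/-SD scheme by default,
with a tertile alternative.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Dataset, OrganismRecord, ProteinRecord, NOT_CLASSIFIED
from .regions import pct_disordered_aa, pct_ordered_aa

__all__ = [
    "FUNCTIONAL_GROUPS",
    "GROUP_OF_COG",
    "cog_to_group",
    "proteins_in_group",
    "group_memberships",
    "discretize_gc",
    "discretize_genome_size",
    "discretize_disorder",
    "order_cogs",
    "cross_table",
]

FUNCTIONAL_GROUPS: dict[str, frozenset[str]] = {
    "Isp": frozenset("ABJKL"),
    "Cp": frozenset("DMNOTUVWYZ"),
    "Me": frozenset("CEFGHIPQ"),
    "Pc": frozenset("RS"),
}

GROUP_OF_COG: dict[str, str] = {
    cog: grp for grp, cogs in FUNCTIONAL_GROUPS.items() for cog in cogs
}

#: Group order used in report tables.
GROUP_ORDER = ("Isp", "Cp", "Me", "Pc", "NC")


def cog_to_group(letter: str) -> str:
    """Functional group of a COG letter; ``N.C.`` maps to ``NC``."""
    if letter == NOT_CLASSIFIED:
        return "NC"
    try:
        return GROUP_OF_COG[letter]
    except KeyError:
        raise ValueError(f"unknown COG category {letter!r}") from None


def group_memberships(protein: ProteinRecord) -> frozenset[str]:
    """Functional groups a protein belongs to (each at most once)."""
    if not protein.cogs:
        return frozenset({"NC"})
    return frozenset(GROUP_OF_COG[c] for c in protein.cogs)


def proteins_in_group(
    proteins: Iterable[ProteinRecord], group: str
) -> list[ProteinRecord]:
    """Distinct proteins with at least one COG in ``group``.

    A protein with several COGs inside the same group is returned once, so
    group aggregates count each protein once per collection.
    """
    return [p for p in proteins if group in group_memberships(p)]


def _mean_sd_discretize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """low/medium/high at mean +/- 1 sample SD; borders inclusive to medium."""
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.all(values == values[0]):
        return np.full(values.size, "medium", dtype=object), float("nan"), float("nan")
    mu = float(values.mean())
    sd = float(values.std(ddof=1))
    lo, hi = mu - sd, mu + sd
    out = np.full(values.size, "medium", dtype=object)
    out[values < lo] = "low"
    out[values > hi] = "high"
    return out, lo, hi


def discretize_gc(organisms: Sequence[OrganismRecord]) -> dict[str, str]:
    """GC modality (low/medium/high) per organism, borders at mean +/- 1 SD.

    The mean and SD are computed over exactly the organism set passed in, so
    stratify by superkingdom before calling if per-superkingdom borders are
    wanted.
    """
    values = np.array([o.gc_percent for o in organisms], dtype=float)
    labels, _, _ = _mean_sd_discretize(values)
    return {o.organism_id: lab for o, lab in zip(organisms, labels)}


def discretize_genome_size(size_mb: float, superkingdom: str) -> str:
    """short/long genome at 4 Mb (Bacteria) or 2.5 Mb (Archaea).

    "short" is strict <, so a genome exactly at the cut is long.
    """
    if size_mb <= 0:
        raise ValueError("genome size must be > 0")
    cut = 2.5 if superkingdom == "Archaea" else 4.0
    return "short" if size_mb < cut else "long"


def discretize_disorder(
    measures: Mapping[str, float], scheme: str = "mean_sd"
) -> dict[str, str]:
    """Disorder-level modality (low/medium/high) per organism.

    ``scheme='mean_sd'`` mirrors the GC discretization; ``'tertile'`` splits
    the organisms into three equal-count groups (ties broken by organism id).
    """
    ids = list(measures)
    values = np.array([measures[i] for i in ids], dtype=float)
    if scheme == "mean_sd":
        labels, _, _ = _mean_sd_discretize(values)
        return dict(zip(ids, labels))
    if scheme == "tertile":
        order = sorted(range(len(ids)), key=lambda k: (values[k], ids[k]))
        n = len(ids)
        out: dict[str, str] = {}
        for rank, k in enumerate(order):
            if rank < n / 3:
                out[ids[k]] = "low"
            elif rank < 2 * n / 3:
                out[ids[k]] = "medium"
            else:
                out[ids[k]] = "high"
        return out
    raise ValueError(f"unknown scheme {scheme!r}")


def order_cogs(values: Mapping[str, float]) -> list[str]:
    """COG letters in ascending order of a disorder criterion.

    ``values`` maps COG letter (or ``N.C.``) to the criterion value (e.g.,
    average regions per protein, regions per 100 AA, percent of proteins
    with a qualifying region, percent disordered residues).  Ties break
    alphabetically; NaN values sort last.
    """
    if len(values) < 2:
        raise ValueError("need at least two COGs to order")
    return sorted(
        values,
        key=lambda c: (np.isnan(values[c]), values[c] if not np.isnan(values[c]) else 0.0, c),
    )


def cross_table(
    dataset: Dataset,
    char1: Mapping[str, str],
    char2: Mapping[str, str],
    min_length: int = 41,
    groups: Sequence[str] = GROUP_ORDER,
    char1_name: str = "char1",
    char2_name: str = "char2",
) -> pd.DataFrame:
    """Disorder content by pairs of organism-characteristic modalities.

    ``char1``/``char2`` map organism_id to a modality (organisms missing from
    either map are left out).  For each (modality1, modality2) cell and each
    functional group the table reports the pooled percent of residues inside
    disordered and inside ordered regions of length >= ``min_length``,
    computed over all proteins of the cell's organisms.  The two percentages
    plus the residues in sub-threshold regions sum to 100.  Empty cells are
    reported with NaN.
    """
    cells: dict[tuple[str, str], list[str]] = {}
    for oid in dataset.organisms:
        if oid in char1 and oid in char2:
            cells.setdefault((char1[oid], char2[oid]), []).append(oid)
    rows = []
    for (m1, m2), oids in sorted(cells.items()):
        cell_proteins = dataset.proteins_of(oids)
        for group in groups:
            members = proteins_in_group(cell_proteins, group)
            if members:
                pct_dis = pct_disordered_aa(members, min_length)
                pct_ord = pct_ordered_aa(members, min_length)
            else:
                pct_dis = pct_ord = float("nan")
            rows.append(
                {
                    char1_name: m1,
                    char2_name: m2,
                    "group": group,
                    "n_organisms": len(oids),
                    "n_proteins": len(members),
                    "pct_disordered": pct_dis,
                    "pct_ordered": pct_ord,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            char1_name,
            char2_name,
            "group",
            "n_organisms",
            "n_proteins",
            "pct_disordered",
            "pct_ordered",
        ],
    )
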