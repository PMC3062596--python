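"""Reading, writing and joining the pipeline's external tables.

The pipeline consumes four plain-text inputs:

* protein sequences (FASTA),
* a per-residue disorder annotation table (TSV: ``protein_id``, ``position``
  1-based, ``score`` in [0, 1] and/or binary ``label``) in the layout produced
  by per-residue disorder predictors such as VSL2B,
* a protein-to-COG assignment table (TSV: ``protein_id``, ``cog``; one row per
  assignment, so a protein may carry several COG letters),
* an organism metadata table (TSV: superkingdom, phylum, genome size in Mb,
  GC %, habitat, oxygen requirement, temperature range).

All coordinates are 1-based inclusive in files and 0-based half-open in
memory.  Scores are binarized with ``score >= threshold`` meaning disordered;
the threshold defaults to 0.5 and is configurable because disorder predictors
differ in their decision boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "HABITATS",
    "OXYGEN_CLASSES",
    "TEMPERATURE_CLASSES",
    "NOT_CLASSIFIED",
    "ProteinRecord",
    "OrganismRecord",
    "Dataset",
    "read_fasta",
    "write_fasta",
    "read_disorder_annotation",
    "write_disorder_annotation",
    "read_cog_table",
    "write_cog_table",
    "read_organism_table",
    "write_organism_table",
    "assemble_dataset",
    "load_dataset",
]

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Residue letters tolerated in sequences but excluded from composition
#: vectors (they still occupy positions during region segmentation).
NONSTANDARD_RESIDUES: frozenset[str] = frozenset("BJOUXZ*")

HABITATS = ("aquatic", "multiple", "specialized", "host-associated", "terrestrial")
OXYGEN_CLASSES = ("aerobic", "facultative", "anaerobic", "microaerophilic")
TEMPERATURE_CLASSES = ("mesophile", "thermophile", "hyperthermophile", "cryophile")
SUPERKINGDOMS = ("Archaea", "Bacteria")

#: COG code for proteins with no COG assignment.
NOT_CLASSIFIED = "N.C."

# "psychrophile" and "cryophile" are synonyms in genome metadata; normalize.
_TEMPERATURE_SYNONYMS = {"psychrophile": "cryophile"}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class ProteinRecord:
    """One protein: sequence, organism, COG letters and disorder annotation.

    ``cogs`` is empty for proteins without a COG assignment; such proteins
    belong to the pseudo-category ``N.C.``.  ``labels`` is a uint8 vector with
    1 = disordered, aligned with ``sequence``; ``scores`` is optional.
    """

    protein_id: str
    organism_id: str
    sequence: str
    cogs: frozenset[str] = frozenset()
    labels: np.ndarray | None = None
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")
        for arr_name in ("labels", "scores"):
            arr = getattr(self, arr_name)
            if arr is not None and len(arr) != len(self.sequence):
                raise ValueError(
                    f"protein {self.protein_id!r}: {arr_name} length "
                    f"{len(arr)} != sequence length {len(self.sequence)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class OrganismRecord:
    """One genome's metadata.

    Categorical fields may be ``None`` (missing); missing values are flagged
    with a warning at load time and the organism is simply omitted from
    transactions/cross-tables that need the missing characteristic.
    """

    organism_id: str
    superkingdom: str
    phylum: str
    genome_size_mb: float
    gc_percent: float
    habitat: str | None = None
    oxygen: str | None = None
    temperature: str | None = None

    def __post_init__(self) -> None:
        if self.superkingdom not in SUPERKINGDOMS:
            raise ValueError(
                f"organism {self.organism_id!r}: superkingdom must be one of "
                f"{SUPERKINGDOMS}, got {self.superkingdom!r}"
            )
        if not self.genome_size_mb > 0:
            raise ValueError(f"organism {self.organism_id!r}: genome size must be > 0")
        if not 0.0 <= self.gc_percent <= 100.0:
            raise ValueError(f"organism {self.organism_id!r}: GC % outside [0, 100]")
        if self.temperature in _TEMPERATURE_SYNONYMS:
            self.temperature = _TEMPERATURE_SYNONYMS[self.temperature]
        for name, allowed in (
            ("habitat", HABITATS),
            ("oxygen", OXYGEN_CLASSES),
            ("temperature", TEMPERATURE_CLASSES),
        ):
            value = getattr(self, name)
            if value is not None and value not in allowed:
                raise ValueError(
                    f"organism {self.organism_id!r}: {name}={value!r} not in {allowed}"
                )


@dataclass
class Dataset:
    """Joined proteome: proteins plus the organisms they belong to."""

    proteins: list[ProteinRecord]
    organisms: dict[str, OrganismRecord]
    _by_organism: dict[str, list[ProteinRecord]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_organism = {}
        for prot in self.proteins:
            self._by_organism.setdefault(prot.organism_id, []).append(prot)

    def proteins_of(self, organism_ids: Iterable[str]) -> list[ProteinRecord]:
        out: list[ProteinRecord] = []
        for oid in organism_ids:
            out.extend(self._by_organism.get(oid, []))
        return out

    def organisms_in(self, superkingdom: str) -> list[OrganismRecord]:
        return [o for o in self.organisms.values() if o.superkingdom == superkingdom]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(protein_id, sequence), ...]``.

    The identifier is the header token before the first whitespace.
    Duplicate identifiers are an error; an empty file yields an empty list.
    """
    path = Path(path)
    text_head = path.read_text()[:1].strip()
    if text_head and text_head != ">":
        raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    dupes: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            dupes.append(rec.id)
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if dupes:
        raise FormatError(f"{path}: duplicate protein ids: {sorted(set(dupes))}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Disorder annotation


def read_disorder_annotation(
    path: str | Path, threshold: float = 0.5
) -> dict[str, tuple[np.ndarray | None, np.ndarray]]:
    """Read the per-residue disorder table into ``{pid: (scores, labels)}``.

    The table needs a ``score`` column or a ``label`` column (or both).
    Labels derive from scores as ``score >= threshold``; a residue exactly at
    the threshold is called disordered.  Positions must be contiguous from 1
    for every protein.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    has_score = "score" in df.columns
    has_label = "label" in df.columns
    if not has_score and not has_label:
        raise FormatError(f"{path}: need a 'score' or 'label' column")
    if has_score:
        scores_all = df["score"].to_numpy(dtype=float)
        if np.any((scores_all < 0.0) | (scores_all > 1.0)):
            bad = df.loc[(scores_all < 0) | (scores_all > 1), "protein_id"].iloc[0]
            raise FormatError(f"{path}: score outside [0, 1] for protein {bad!r}")
    out: dict[str, tuple[np.ndarray | None, np.ndarray]] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        pos = grp["position"].to_numpy(dtype=np.int64)
        n = len(pos)
        if not np.array_equal(np.sort(pos), np.arange(1, n + 1)):
            raise FormatError(
                f"{path}: protein {pid!r}: position gap or duplicate "
                f"(expected contiguous 1..{n})"
            )
        order = np.argsort(pos, kind="stable")
        scores = grp["score"].to_numpy(dtype=float)[order] if has_score else None
        if has_score:
            labels = (scores >= threshold).astype(np.uint8)
        else:
            labels = grp["label"].to_numpy(dtype=np.uint8)[order]
            if not np.isin(labels, (0, 1)).all():
                raise FormatError(f"{path}: protein {pid!r}: label must be 0/1")
        out[str(pid)] = (scores, labels)
    return out


def write_disorder_annotation(
    annotations: Mapping[str, tuple[np.ndarray | None, np.ndarray]], path: str | Path
) -> None:
    """Write the annotation table; positions are 1-based inclusive."""
    frames = []
    for pid, (scores, labels) in annotations.items():
        n = len(labels)
        cols: dict[str, object] = {
            "protein_id": np.repeat(pid, n),
            "position": np.arange(1, n + 1),
        }
        if scores is not None:
            cols["score"] = np.round(scores, 4)
        cols["label"] = labels.astype(np.uint8)
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["protein_id", "position", "label"]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# COG and organism tables


def read_cog_table(path: str | Path) -> dict[str, frozenset[str]]:
    """Read protein→COG assignments; one row per (protein, COG letter)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if missing := {"protein_id", "cog"} - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, set[str]] = {}
    for pid, cog in zip(df["protein_id"], df["cog"]):
        out.setdefault(pid, set()).add(cog)
    return {pid: frozenset(cogs) for pid, cogs in out.items()}


def write_cog_table(assignments: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [
        {"protein_id": pid, "cog": cog}
        for pid, cogs in assignments.items()
        for cog in sorted(cogs)
    ]
    pd.DataFrame(rows, columns=["protein_id", "cog"]).to_csv(path, sep="\t", index=False)


_ORGANISM_COLUMNS = [
    "organism_id",
    "superkingdom",
    "phylum",
    "genome_size_mb",
    "gc_percent",
    "habitat",
    "oxygen",
    "temperature",
]


def read_organism_table(path: str | Path) -> dict[str, OrganismRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if missing := set(_ORGANISM_COLUMNS) - set(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    organisms: dict[str, OrganismRecord] = {}
    n_missing = 0
    for row in df.itertuples(index=False):
        def _opt(value: object) -> str | None:
            return None if pd.isna(value) or value == "" else str(value)

        rec = OrganismRecord(
            organism_id=str(row.organism_id),
            superkingdom=str(row.superkingdom),
            phylum=str(row.phylum),
            genome_size_mb=float(row.genome_size_mb),
            gc_percent=float(row.gc_percent),
            habitat=_opt(row.habitat),
            oxygen=_opt(row.oxygen),
            temperature=_opt(row.temperature),
        )
        n_missing += sum(
            v is None for v in (rec.habitat, rec.oxygen, rec.temperature)
        )
        if rec.organism_id in organisms:
            raise FormatError(f"{path}: duplicate organism_id {rec.organism_id!r}")
        organisms[rec.organism_id] = rec
    if n_missing:
        warnings.warn(
            f"{path}: {n_missing} missing categorical value(s) in organism table",
            stacklevel=2,
        )
    return organisms


def write_organism_table(organisms: Mapping[str, OrganismRecord], path: str | Path) -> None:
    rows = [
        {
            "organism_id": o.organism_id,
            "superkingdom": o.superkingdom,
            "phylum": o.phylum,
            "genome_size_mb": o.genome_size_mb,
            "gc_percent": round(o.gc_percent, 3),
            "habitat": o.habitat or "",
            "oxygen": o.oxygen or "",
            "temperature": o.temperature or "",
        }
        for o in organisms.values()
    ]
    pd.DataFrame(rows, columns=_ORGANISM_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Assembly


def assemble_dataset(
    fasta_records: Iterable[tuple[str, str]],
    annotations: Mapping[str, tuple[np.ndarray | None, np.ndarray]],
    cog_table: Mapping[str, frozenset[str]],
    organism_table: Mapping[str, OrganismRecord],
    protein_organism: Mapping[str, str],
) -> Dataset:
    """Join the four inputs into a :class:`Dataset`.

    Every protein must resolve to a known organism and carry an annotation of
    matching length.  Proteins absent from the COG table get an empty ``cogs``
    set (category ``N.C.``).  A protein assigned to several COGs appears once
    in the dataset; collection-level aggregates count it once per collection.
    """
    proteins: list[ProteinRecord] = []
    for pid, seq in fasta_records:
        if pid not in protein_organism:
            raise FormatError(f"protein {pid!r}: no organism mapping")
        oid = protein_organism[pid]
        if oid not in organism_table:
            raise FormatError(f"protein {pid!r}: unknown organism_id {oid!r}")
        if pid not in annotations:
            raise FormatError(f"protein {pid!r}: no disorder annotation")
        scores, labels = annotations[pid]
        if len(labels) != len(seq):
            raise FormatError(
                f"protein {pid!r}: annotation length {len(labels)} != "
                f"sequence length {len(seq)}"
            )
        proteins.append(
            ProteinRecord(
                protein_id=pid,
                organism_id=oid,
                sequence=seq,
                cogs=cog_table.get(pid, frozenset()),
                labels=np.asarray(labels, dtype=np.uint8),
                scores=None if scores is None else np.asarray(scores, dtype=float),
            )
        )
    return Dataset(proteins=proteins, organisms=dict(organism_table))


def load_dataset(
    fasta_path: str | Path,
    annotation_path: str | Path,
    cog_path: str | Path,
    organism_path: str | Path,
    protein_organism_path: str | Path,
    threshold: float = 0.5,
) -> Dataset:
    """Load and join the standard five files (see module docstring).

    ``protein_organism_path`` is a two-column TSV (protein_id, organism_id).
    """
    mapping_df = pd.read_csv(protein_organism_path, sep="\t", dtype=str)
    if missing := {"protein_id", "organism_id"} - set(mapping_df.columns):
        raise FormatError(f"{protein_organism_path}: missing columns {sorted(missing)}")
    protein_organism = dict(zip(mapping_df["protein_id"], mapping_df["organism_id"]))
    return assemble_dataset(
        read_fasta(fasta_path),
        read_disorder_annotation(annotation_path, threshold=threshold),
        read_cog_table(cog_path),
        read_organism_table(organism_path),
        protein_organism,
    )
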