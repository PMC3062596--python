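"""Synthetic prokaryotic proteomes with planted, parameterized structure.

The generator emulates the four pipeline inputs (sequences, per-residue
disorder annotation, COG assignments, organism metadata) with controllable
planted effects, so every analysis stage can be verified against known
ground truth:

* **Functional-group effect** — proteins of the Isp and Cp groups are
  generated with a higher disordered fraction than Me proteins (default
  fractions 0.30/0.33 vs 0.13, a ratio >= 2).
* **GC -> disorder coupling** — each organism's disordered fraction is
  shifted on the logit scale proportionally to its GC z-score, producing the
  positive GC-disorder association the analysis is meant to recover.
* **Composition bias** — inside disordered regions the probability mass of
  the disorder-promoting residues (A, E, K, P, Q, R, S) is multiplied by an
  enrichment factor (default 1.5) and renormalized.

Organism GC is drawn from a three-component mixture spanning roughly 25-75%
(the range observed across bacterial genomes), so the low/medium/high GC
modalities are well-populated clusters rather than tails of one Gaussian.
Disordered and ordered run lengths are geometric, giving the monotone decay
of region-length frequencies seen in real disorder annotations and
populating every length class (>= 1, 11, 21, 31, 41 AA) at the defaults.
Protein lengths are lognormal with mean about 290 AA, matching typical
prokaryotic proteome averages (about 280 AA in archaea, 300 AA in bacteria).

Everything is driven by one :class:`numpy.random.Generator` seeded from the
mandatory ``seed``; identical seed + config yields byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as dio
from .io import AMINO_ACIDS, Dataset, OrganismRecord, ProteinRecord
from .grouping import FUNCTIONAL_GROUPS

__all__ = ["GeneratorConfig", "GroundTruth", "generate", "write_fixture", "small_fixture"]

_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)

#: Background amino-acid frequencies (order of AMINO_ACIDS, i.e. alphabetical
#: one-letter codes), Swiss-Prot-like values normalized to 1.
_BACKGROUND = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0593, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0687, "W": 0.0110, "Y": 0.0292,
}

_PROMOTER_MASK = np.array([aa in "AEKPQRS" for aa in AMINO_ACIDS])
_GC_RICH_MASK = np.array([aa in "GARP" for aa in AMINO_ACIDS])


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic proteome; defaults are the study conditions."""

    seed: int
    n_bacteria: int = 40
    n_archaea: int = 20
    proteins_per_organism: int = 200
    # protein length: lognormal, mean ~290 AA, floored
    protein_length_mu: float = 5.52
    protein_length_sigma: float = 0.55
    min_protein_length: int = 60
    # phyla (labels, weights)
    bacterial_phyla: tuple[str, ...] = (
        "Proteobacteria", "Firmicutes", "Actinobacteria", "Bacteroidetes",
    )
    bacterial_phylum_weights: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    archaeal_phyla: tuple[str, ...] = ("Euryarchaeota", "Crenarchaeota", "Thaumarchaeota")
    archaeal_phylum_weights: tuple[float, ...] = (0.6, 0.3, 0.1)
    # GC % mixture: (mean, sd, weight) per component, shared across kingdoms
    gc_components: tuple[tuple[float, float, float], ...] = (
        (34.0, 3.0, 0.15), (49.0, 5.0, 0.60), (70.0, 3.0, 0.25),
    )
    # genome size, lognormal Mb
    genome_size_mu: float = 1.15
    genome_size_sigma: float = 0.45
    habitat_probs: tuple[float, ...] = (0.30, 0.25, 0.15, 0.20, 0.10)
    oxygen_probs: tuple[float, ...] = (0.40, 0.25, 0.25, 0.10)
    temperature_probs: tuple[float, ...] = (0.70, 0.15, 0.10, 0.05)
    # COG assignment: probability a protein's primary category is in each group
    group_probs: dict[str, float] = field(
        default_factory=lambda: {"Isp": 0.20, "Cp": 0.20, "Me": 0.30, "Pc": 0.15, "NC": 0.15}
    )
    second_cog_prob: float = 0.08
    # disorder model: per-group expected disordered fraction at GC z = 0
    group_disorder_fraction: dict[str, float] = field(
        default_factory=lambda: {"Isp": 0.30, "Cp": 0.33, "Me": 0.13, "Pc": 0.17, "NC": 0.15}
    )
    mean_disordered_run: float = 18.0
    gc_coupling: float = 1.2
    organism_noise_sd: float = 0.25
    # composition model
    promoter_enrichment: float = 1.5
    gc_composition_coupling: float = 0.10
    binarization_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("bacterial_phylum_weights", "archaeal_phylum_weights",
                     "habitat_probs", "oxygen_probs", "temperature_probs"):
            w = np.asarray(getattr(self, name), dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError(f"{name}: weights must be non-negative and sum to 1")
        for name in ("group_probs",):
            p = np.array(list(getattr(self, name).values()))
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{name}: probabilities must be non-negative and sum to 1")
        for g, f in self.group_disorder_fraction.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"group_disorder_fraction[{g}]: must be in (0, 1)")
        if self.promoter_enrichment <= 0:
            raise ValueError("promoter_enrichment: must be > 0")
        if self.mean_disordered_run < 1:
            raise ValueError("mean_disordered_run: must be >= 1")

    def gc_population_moments(self) -> tuple[float, float]:
        """Analytic mean and SD of the GC mixture (fixed, not cohort-estimated)."""
        means = np.array([c[0] for c in self.gc_components])
        sds = np.array([c[1] for c in self.gc_components])
        ws = np.array([c[2] for c in self.gc_components])
        ws = ws / ws.sum()
        mu = float(ws @ means)
        var = float(ws @ (sds**2) + ws @ (means - mu) ** 2)
        return mu, math.sqrt(var)


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    organism_gc_z: dict[str, float]
    organism_disorder_shift: dict[str, float]
    protein_group: dict[str, str]
    protein_run_lengths: dict[str, list[int]]
    protein_first_run_disordered: dict[str, bool]
    effect_sizes: dict[str, float]

    def to_json(self, path: str | Path, include_regions: bool = True) -> None:
        payload = {
            "organism_gc_z": self.organism_gc_z,
            "organism_disorder_shift": self.organism_disorder_shift,
            "protein_group": self.protein_group,
            "effect_sizes": self.effect_sizes,
        }
        if include_regions:
            payload["protein_run_lengths"] = self.protein_run_lengths
            payload["protein_first_run_disordered"] = self.protein_first_run_disordered
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _alternating_runs(
    rng: np.random.Generator, length: int, p_dis: float, p_ord: float, first_dis: bool
) -> tuple[np.ndarray, bool]:
    """Geometric run lengths alternating in kind, trimmed to ``length``.

    Returns (run_lengths, first_run_is_disordered); the final run is cut at
    the protein boundary.
    """
    expect_pair = 1.0 / p_dis + 1.0 / p_ord
    m = max(4, int(2.0 * length / expect_pair) + 4)
    while True:
        dis = rng.geometric(p_dis, size=m)
        ordr = rng.geometric(p_ord, size=m)
        runs = np.empty(2 * m, dtype=np.int64)
        if first_dis:
            runs[0::2], runs[1::2] = dis, ordr
        else:
            runs[0::2], runs[1::2] = ordr, dis
        csum = np.cumsum(runs)
        if csum[-1] >= length:
            k = int(np.searchsorted(csum, length))
            out = runs[: k + 1].copy()
            out[k] = length - (csum[k - 1] if k else 0)
            return out, first_dis
        m *= 2  # rare: resample with more runs


def _labels_from_runs(runs: np.ndarray, first_dis: bool) -> np.ndarray:
    kinds = np.zeros(len(runs), dtype=np.uint8)
    kinds[0::2] = 1 if first_dis else 0
    kinds[1::2] = 0 if first_dis else 1
    return np.repeat(kinds, runs)


def _composition_probs(config: GeneratorConfig, gc_z: float) -> tuple[np.ndarray, np.ndarray]:
    """(ordered, disordered) residue sampling probabilities for one organism."""
    base = np.array([_BACKGROUND[a] for a in AMINO_ACIDS])
    # GC-rich codon families (Gly, Ala, Arg, Pro) drift up with genomic GC
    base = base * np.exp(config.gc_composition_coupling * gc_z * _GC_RICH_MASK)
    p_ord = base / base.sum()
    boosted = p_ord * np.where(_PROMOTER_MASK, config.promoter_enrichment, 1.0)
    p_dis = boosted / boosted.sum()
    return p_ord, p_dis


def generate(config: GeneratorConfig, with_scores: bool = False) -> tuple[Dataset, GroundTruth]:
    """Sample a synthetic dataset with the configured planted structure.

    ``with_scores`` additionally draws per-residue scores from two beta
    distributions conditioned on the labels (disordered scores in
    [threshold, 1], ordered below), so the score input path round-trips
    through binarization.
    """
    rng = np.random.default_rng(config.seed)
    gc_mu, gc_sd = config.gc_population_moments()
    group_letters = {
        g: sorted(members) for g, members in FUNCTIONAL_GROUPS.items()
    }
    all_letters = sorted(set().union(*FUNCTIONAL_GROUPS.values()))
    group_names = list(config.group_probs)
    group_p = np.array([config.group_probs[g] for g in group_names])
    comp_weights = np.array([c[2] for c in config.gc_components], dtype=float)
    comp_weights /= comp_weights.sum()

    organisms: dict[str, OrganismRecord] = {}
    proteins: list[ProteinRecord] = []
    truth = GroundTruth({}, {}, {}, {}, {}, {})

    plans = [("Bacteria", config.n_bacteria), ("Archaea", config.n_archaea)]
    idx = 0
    for kingdom, n_org in plans:
        phyla = config.bacterial_phyla if kingdom == "Bacteria" else config.archaeal_phyla
        phylum_w = (
            config.bacterial_phylum_weights
            if kingdom == "Bacteria"
            else config.archaeal_phylum_weights
        )
        for _ in range(n_org):
            idx += 1
            oid = f"org{idx:03d}"
            comp = rng.choice(len(config.gc_components), p=comp_weights)
            mean, sd, _ = config.gc_components[comp]
            gc = float(np.clip(rng.normal(mean, sd), 1.0, 99.0))
            gc_z = (gc - gc_mu) / gc_sd
            shift = config.gc_coupling * gc_z + rng.normal(0.0, config.organism_noise_sd)
            organisms[oid] = OrganismRecord(
                organism_id=oid,
                superkingdom=kingdom,
                phylum=str(rng.choice(phyla, p=phylum_w)),
                genome_size_mb=float(rng.lognormal(config.genome_size_mu, config.genome_size_sigma)),
                gc_percent=gc,
                habitat=str(rng.choice(dio.HABITATS, p=config.habitat_probs)),
                oxygen=str(rng.choice(dio.OXYGEN_CLASSES, p=config.oxygen_probs)),
                temperature=str(rng.choice(dio.TEMPERATURE_CLASSES, p=config.temperature_probs)),
            )
            truth.organism_gc_z[oid] = gc_z
            truth.organism_disorder_shift[oid] = float(shift)

            n_prot = config.proteins_per_organism
            lengths = np.maximum(
                config.min_protein_length,
                np.rint(rng.lognormal(config.protein_length_mu, config.protein_length_sigma, n_prot)).astype(int),
            )
            prot_groups = rng.choice(group_names, size=n_prot, p=group_p)
            p_ord_comp, p_dis_comp = _composition_probs(config, gc_z)

            all_labels: list[np.ndarray] = []
            records_meta: list[tuple[str, frozenset[str]]] = []
            for j in range(n_prot):
                pid = f"{oid}_p{j + 1:04d}"
                grp = str(prot_groups[j])
                f_base = config.group_disorder_fraction[grp]
                f = float(np.clip(_sigmoid(_logit(f_base) + shift), 1e-4, 1 - 1e-4))
                ld = config.mean_disordered_run
                lo = max(1.0, ld * (1.0 - f) / f)
                first_dis = bool(rng.random() < f)
                runs, first = _alternating_runs(
                    rng, int(lengths[j]), 1.0 / ld, 1.0 / lo, first_dis
                )
                labels = _labels_from_runs(runs, first)
                all_labels.append(labels)
                if grp == "NC":
                    cogs: frozenset[str] = frozenset()
                else:
                    letters = {str(rng.choice(group_letters[grp]))}
                    if rng.random() < config.second_cog_prob:
                        letters.add(str(rng.choice(all_letters)))
                    cogs = frozenset(letters)
                records_meta.append((pid, cogs))
                truth.protein_group[pid] = grp
                truth.protein_run_lengths[pid] = [int(r) for r in runs]
                truth.protein_first_run_disordered[pid] = bool(first)

            # pooled residue sampling: same composition for every protein of
            # the organism, split by region kind
            cat = np.concatenate(all_labels)
            codes = np.empty(cat.size, dtype=np.int64)
            n_dis = int(cat.sum())
            codes[cat == 1] = rng.choice(20, size=n_dis, p=p_dis_comp)
            codes[cat == 0] = rng.choice(20, size=cat.size - n_dis, p=p_ord_comp)
            seq_bytes = _AA_BYTES[codes]
            if with_scores:
                scores = np.empty(cat.size, dtype=float)
                thr = config.binarization_threshold
                scores[cat == 1] = thr + (1 - thr) * rng.beta(2.0, 2.0, size=n_dis)
                scores[cat == 0] = thr * rng.beta(2.0, 2.0, size=cat.size - n_dis) * 0.999
            offsets = np.concatenate(([0], np.cumsum([len(l) for l in all_labels])))
            for j, (pid, cogs) in enumerate(records_meta):
                lo_i, hi_i = offsets[j], offsets[j + 1]
                proteins.append(
                    ProteinRecord(
                        protein_id=pid,
                        organism_id=oid,
                        sequence=seq_bytes[lo_i:hi_i].tobytes().decode("ascii"),
                        cogs=cogs,
                        labels=all_labels[j],
                        scores=scores[lo_i:hi_i].copy() if with_scores else None,
                    )
                )

    fractions = config.group_disorder_fraction
    truth.effect_sizes = {
        "gc_coupling": config.gc_coupling,
        "promoter_enrichment": config.promoter_enrichment,
        "isp_me_ratio": fractions["Isp"] / fractions["Me"],
        "cp_me_ratio": fractions["Cp"] / fractions["Me"],
    }
    return Dataset(proteins=proteins, organisms=organisms), truth


def write_fixture(
    dataset: Dataset,
    out_dir: str | Path,
    truth: GroundTruth | None = None,
    with_scores: bool = False,
) -> dict[str, Path]:
    """Write a dataset in the pipeline's input formats; returns file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "proteins.fasta",
        "disorder": out / "disorder.tsv",
        "cogs": out / "cogs.tsv",
        "organisms": out / "organisms.tsv",
        "protein_organism": out / "protein_organism.tsv",
    }
    dio.write_fasta([(p.protein_id, p.sequence) for p in dataset.proteins], paths["fasta"])
    dio.write_disorder_annotation(
        {
            p.protein_id: (p.scores if with_scores else None, p.labels)
            for p in dataset.proteins
        },
        paths["disorder"],
    )
    dio.write_cog_table(
        {p.protein_id: p.cogs for p in dataset.proteins if p.cogs}, paths["cogs"]
    )
    dio.write_organism_table(dataset.organisms, paths["organisms"])
    import pandas as pd

    pd.DataFrame(
        {
            "protein_id": [p.protein_id for p in dataset.proteins],
            "organism_id": [p.organism_id for p in dataset.proteins],
        }
    ).to_csv(paths["protein_organism"], sep="\t", index=False)
    if truth is not None:
        paths["ground_truth"] = out / "ground_truth.json"
        truth.to_json(paths["ground_truth"], include_regions=len(dataset.proteins) <= 1000)
    return paths


# ---------------------------------------------------------------------------
# Hand-checkable fixture


def _fixture_protein(pid, oid, pattern, cogs):
    """pattern: list of (run_length, is_disordered); sequence cycles 'ACDEFGHIK...'."""
    labels = np.concatenate(
        [np.full(n, 1 if d else 0, dtype=np.uint8) for n, d in pattern]
    )
    seq = (AMINO_ACIDS * (len(labels) // 20 + 1))[: len(labels)]
    return ProteinRecord(
        protein_id=pid, organism_id=oid, sequence=seq, cogs=frozenset(cogs), labels=labels
    )


def small_fixture() -> tuple[Dataset, dict]:
    """A tiny, fully hand-checkable dataset (5 organisms, 20 proteins).

    Every protein is 100 AA with explicitly constructed runs, so all region
    statistics can be verified by hand.  GC values (30, 50, 50, 50, 70) give
    mean 50 and sample SD ~14.14, so org A is low-GC and org E high-GC under
    the mean +/- 1 SD borders.  Per-organism percent of residues in
    disordered regions >= 41 AA is 0, 20, 20, 20, 60 (mean 24, SD ~21.9), so
    the disorder modalities are low, medium, medium, medium, high.  The rule
    gc=high => disorder=high then holds with support 0.2, confidence 1.0 and
    lift 5 at permissive thresholds.
    """
    orgs = {
        "orgA": OrganismRecord("orgA", "Bacteria", "Proteobacteria", 3.0, 30.0,
                               "aquatic", "aerobic", "mesophile"),
        "orgB": OrganismRecord("orgB", "Bacteria", "Firmicutes", 5.0, 50.0,
                               "terrestrial", "anaerobic", "mesophile"),
        "orgC": OrganismRecord("orgC", "Bacteria", "Proteobacteria", 4.0, 50.0,
                               "multiple", "facultative", "mesophile"),
        "orgD": OrganismRecord("orgD", "Archaea", "Euryarchaeota", 2.0, 50.0,
                               "specialized", "anaerobic", "thermophile"),
        "orgE": OrganismRecord("orgE", "Archaea", "Crenarchaeota", 2.5, 70.0,
                               "aquatic", "anaerobic", "hyperthermophile"),
    }
    full_dis = [(100, True)]
    full_ord = [(100, False)]
    mixed_80 = [(80, True), (20, False)]     # one qualifying (>=41) run of 80
    mixed_short = [(10, True), (30, False), (20, True), (40, False)]  # none >=41
    proteins = [
        # orgA: no residues in runs >= 41 -> 0%
        _fixture_protein("pA1", "orgA", full_ord, {"J"}),
        _fixture_protein("pA2", "orgA", mixed_short, {"C"}),
        _fixture_protein("pA3", "orgA", [(40, True), (60, False)], {"R"}),
        _fixture_protein("pA4", "orgA", full_ord, set()),
        # orgB/C/D: one 80-run in 400 AA -> 20%
        _fixture_protein("pB1", "orgB", mixed_80, {"J", "L"}),
        _fixture_protein("pB2", "orgB", full_ord, {"E"}),
        _fixture_protein("pB3", "orgB", mixed_short, {"T"}),
        _fixture_protein("pB4", "orgB", full_ord, set()),
        _fixture_protein("pC1", "orgC", mixed_80, {"K"}),
        _fixture_protein("pC2", "orgC", full_ord, {"G"}),
        _fixture_protein("pC3", "orgC", mixed_short, {"S"}),
        _fixture_protein("pC4", "orgC", full_ord, {"D"}),
        _fixture_protein("pD1", "orgD", mixed_80, {"L"}),
        _fixture_protein("pD2", "orgD", full_ord, {"P"}),
        _fixture_protein("pD3", "orgD", mixed_short, {"O"}),
        _fixture_protein("pD4", "orgD", full_ord, set()),
        # orgE: 100 + 100 + 41 residues in qualifying runs -> 60.25%... use
        # 100 + 100 + 40(sub-threshold) -> exactly 240/400 with a 41-run:
        _fixture_protein("pE1", "orgE", full_dis, {"J"}),
        _fixture_protein("pE2", "orgE", full_dis, {"N"}),
        _fixture_protein("pE3", "orgE", [(41, True), (59, False)], {"K"}),
        _fixture_protein("pE4", "orgE", [(1, True), (99, False)], {"C"}),
    ]
    # orgE residues in disordered runs >=41: 100+100+41 = 241 -> 60.25%
    meta = {
        "expected_gc_modality": {"orgA": "low", "orgB": "medium", "orgC": "medium",
                                 "orgD": "medium", "orgE": "high"},
        "expected_disorder_pct41": {"orgA": 0.0, "orgB": 20.0, "orgC": 20.0,
                                    "orgD": 20.0, "orgE": 60.25},
        "expected_disorder_modality": {"orgA": "low", "orgB": "medium", "orgC": "medium",
                                       "orgD": "medium", "orgE": "high"},
        "guaranteed_rule": {"body": ["gc=high"], "head": ["disorder=high"],
                            "support": 0.2, "confidence": 1.0, "lift": 5.0},
    }
    return Dataset(proteins=proteins, organisms=orgs), meta
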