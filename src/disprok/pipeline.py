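"""End-to-end orchestration: from an assembled dataset to report tables.

``analyze`` runs the full analysis — region statistics by superkingdom,
functional group and COG across all length classes, purity tables,
composition and fractional-difference tables, organism-characteristic
discretization, characteristic-pair cross-tables, the GC comparison t-tests,
COG orderings, and filtered association rules — and ``write_report`` writes
every table to a directory together with a run log and a config hash, so two
runs with the same config hash are identical.

``recover_planted_effects`` is the lean single-replicate evaluation used to
check that the pipeline recovers what the synthetic generator planted.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import composition as comp
from . import grouping, regions, rules as rulemod, stats as dstats
from .composition import DISORDER_PROMOTERS, ORDER_PROMOTERS
from .io import AMINO_ACIDS, Dataset, ProteinRecord
from .synthetic import GeneratorConfig, generate

__all__ = ["RunConfig", "AnalysisResult", "analyze", "write_report", "recover_planted_effects"]

_AA_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _aa in enumerate(AMINO_ACIDS):
    _AA_INDEX[ord(_aa)] = _i


@dataclass
class RunConfig:
    """Settings of one analysis run; serialized into the output directory."""

    binarization_threshold: float = 0.5
    length_classes: tuple[int, ...] = regions.LENGTH_CLASSES
    focus_length: int = 41
    gc_per_superkingdom: bool = True
    disorder_scheme: str = "mean_sd"
    min_support: dict = field(default_factory=lambda: {"Bacteria": 0.13, "Archaea": 0.16})
    min_confidence: dict = field(default_factory=lambda: {"Bacteria": 0.66, "Archaea": 0.90})
    excluded_items: tuple[str, ...] = ()
    max_body_items: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.length_classes) != sorted(set(self.length_classes)):
            raise ValueError("length_classes must be strictly increasing")
        if self.focus_length not in self.length_classes:
            raise ValueError("focus_length must be one of length_classes")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisResult:
    config: RunConfig
    region_stats: pd.DataFrame
    purity: pd.DataFrame
    composition: pd.DataFrame
    fractional_difference: pd.DataFrame
    organism_modalities: pd.DataFrame
    cross_tables: dict[tuple[str, str], pd.DataFrame]
    gc_tests: pd.DataFrame
    cog_orderings: pd.DataFrame
    rules: dict[str, list[rulemod.AssociationRule]]


# ---------------------------------------------------------------------------
# Fast per-protein summaries (computed once, reused by every aggregate)


@dataclass
class _Summary:
    length: np.ndarray          # protein length
    qual_regions: np.ndarray    # number of disordered regions >= L
    qual_aa: np.ndarray         # residues inside those regions
    dis_aa: np.ndarray          # residues labeled disordered (L >= 1)

    def pooled_pct_disordered(self, idx: np.ndarray) -> float:
        tot = self.length[idx].sum()
        return 100.0 * self.qual_aa[idx].sum() / tot if tot else float("nan")


def _summarize(proteins: Sequence[ProteinRecord], min_length: int) -> _Summary:
    n = len(proteins)
    out = _Summary(
        np.empty(n, dtype=np.int64), np.empty(n, dtype=np.int64),
        np.empty(n, dtype=np.int64), np.empty(n, dtype=np.int64),
    )
    for i, prot in enumerate(proteins):
        runs = regions.disordered_run_lengths(prot.labels)
        qual = runs[runs >= min_length]
        out.length[i] = prot.length
        out.qual_regions[i] = qual.size
        out.qual_aa[i] = qual.sum()
        out.dis_aa[i] = prot.labels.sum()
    return out


def _group_masks(proteins: Sequence[ProteinRecord]) -> dict[str, np.ndarray]:
    masks = {g: np.zeros(len(proteins), dtype=bool) for g in grouping.GROUP_ORDER}
    for i, prot in enumerate(proteins):
        for g in grouping.group_memberships(prot):
            masks[g][i] = True
    return masks


def _residue_counts_by_state(proteins: Sequence[ProteinRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Pooled 20-residue counts inside disordered and ordered positions."""
    dis = np.zeros(20, dtype=np.int64)
    ordr = np.zeros(20, dtype=np.int64)
    for prot in proteins:
        codes = _AA_INDEX[np.frombuffer(prot.sequence.encode("ascii"), dtype=np.uint8)]
        ok = codes >= 0
        lab = prot.labels.astype(bool)
        dis += np.bincount(codes[ok & lab], minlength=20)
        ordr += np.bincount(codes[ok & ~lab], minlength=20)
    return dis, ordr


def organism_disorder_measure(dataset: Dataset, min_length: int = 41) -> dict[str, float]:
    """Per-organism pooled percent of residues in disordered regions >= L
    (the PROC_DIS-style attribute used for discretization and mining)."""
    out: dict[str, float] = {}
    for oid in dataset.organisms:
        prots = dataset.proteins_of([oid])
        if not prots:
            out[oid] = float("nan")
            continue
        out[oid] = regions.pct_disordered_aa(prots, min_length)
    return out


# ---------------------------------------------------------------------------
# Full analysis


def _collection_rows(proteins, collection_id, length_classes):
    rows = []
    for lc in length_classes:
        st = regions.region_stats(proteins, min_length=lc, collection_id=collection_id)
        rows.append(asdict(st))
    return rows


def analyze(dataset: Dataset, config: RunConfig | None = None) -> AnalysisResult:
    config = config or RunConfig()
    lcs = config.length_classes
    focus = config.focus_length

    # --- region statistics: superkingdom, functional group, COG collections
    region_rows: list[dict] = []
    purity_rows: list[dict] = []
    comp_rows: list[dict] = []
    fd_rows: list[dict] = []
    orderings: list[dict] = []
    for kingdom in ("Archaea", "Bacteria"):
        oids = [o.organism_id for o in dataset.organisms_in(kingdom)]
        prots = dataset.proteins_of(oids)
        if not prots:
            continue
        region_rows += _collection_rows(prots, f"{kingdom}", lcs)
        for group in grouping.GROUP_ORDER:
            members = grouping.proteins_in_group(prots, group)
            if members:
                region_rows += _collection_rows(members, f"{kingdom}/{group}", lcs)
        cogs_present = sorted({c for p in prots for c in p.cogs})
        by_cog = {
            c: [p for p in prots if c in p.cogs] for c in cogs_present
        }
        by_cog["N.C."] = [p for p in prots if not p.cogs]
        crit_values: dict[str, dict[str, float]] = {
            "avg_regions_per_protein": {}, "regions_per_100aa": {},
            "pct_proteins_with_region": {}, "pct_disordered_aa": {},
        }
        for cog, members in by_cog.items():
            if not members:
                continue
            region_rows += _collection_rows(members, f"{kingdom}/COG:{cog}", lcs)
            crit_values["avg_regions_per_protein"][cog] = regions.avg_regions_per_protein(members, focus)
            crit_values["regions_per_100aa"][cog] = regions.regions_per_100aa(members, min_length=focus)
            crit_values["pct_proteins_with_region"][cog] = regions.pct_proteins_with_region(members, focus)
            crit_values["pct_disordered_aa"][cog] = regions.pct_disordered_aa(members, focus)
        for crit, values in crit_values.items():
            if len(values) >= 2:
                orderings.append(
                    {"superkingdom": kingdom, "criterion": crit,
                     "ascending_order": ",".join(grouping.order_cogs(values))}
                )

        # --- purity
        purities = [regions.classify_purity(p) for p in prots]
        n = len(purities)
        purity_rows.append(
            {
                "superkingdom": kingdom,
                "n_proteins": n,
                "pct_fully_disordered": 100.0 * sum(p.category == "fully_disordered" for p in purities) / n,
                "pct_fully_ordered": 100.0 * sum(p.category == "fully_ordered" for p in purities) / n,
                "pct_gt90_disordered": 100.0 * sum(p.gt90_disordered for p in purities) / n,
            }
        )

        # --- composition (focus length class)
        summaries = _summarize(prots, focus)
        with_region = [p for p, q in zip(prots, summaries.qual_regions) if q > 0]
        all_counts = comp.residue_counts(p.sequence for p in prots)
        wr_counts = comp.residue_counts(p.sequence for p in with_region)
        dis_seqs = [
            s for p in with_region
            for s in comp.region_sequences(p.sequence, p.labels, "disordered", focus)
        ]
        dis_counts = comp.residue_counts(dis_seqs)
        total_all = all_counts.sum()
        for i, aa in enumerate(AMINO_ACIDS):
            comp_rows.append(
                {
                    "superkingdom": kingdom,
                    "residue": aa,
                    "pct_all_proteins": 100.0 * all_counts[i] / total_all if total_all else float("nan"),
                    # both candidate normalizations of the middle column:
                    "pct_in_proteins_with_regions_of_all": 100.0 * wr_counts[i] / total_all if total_all else float("nan"),
                    "pct_in_proteins_with_regions_of_subset": 100.0 * wr_counts[i] / wr_counts.sum() if wr_counts.sum() else float("nan"),
                    "pct_in_disordered_regions": 100.0 * dis_counts[i] / dis_counts.sum() if dis_counts.sum() else float("nan"),
                }
            )

        # --- fractional difference per functional group (all region lengths)
        for group in grouping.GROUP_ORDER:
            members = grouping.proteins_in_group(prots, group)
            if not members:
                continue
            dcnt, ocnt = _residue_counts_by_state(members)
            if dcnt.sum() == 0 or ocnt.sum() == 0:
                continue
            pa = dcnt / dcnt.sum()
            pb = ocnt / ocnt.sum()
            for i, aa in enumerate(AMINO_ACIDS):
                fd = (pa[i] - pb[i]) / pb[i] if pb[i] > 0 else float("nan")
                fd_rows.append(
                    {"superkingdom": kingdom, "group": group, "residue": aa,
                     "fractional_difference": fd}
                )

    # --- organism modalities
    measures = organism_disorder_measure(dataset, focus)
    gc_mod: dict[str, str] = {}
    if config.gc_per_superkingdom:
        for kingdom in ("Archaea", "Bacteria"):
            orgs = dataset.organisms_in(kingdom)
            if orgs:
                gc_mod.update(grouping.discretize_gc(orgs))
    else:
        gc_mod = grouping.discretize_gc(list(dataset.organisms.values()))
    dis_mod = grouping.discretize_disorder(
        {k: v for k, v in measures.items() if not np.isnan(v)}, config.disorder_scheme
    )
    modality_rows = []
    for oid, org in dataset.organisms.items():
        modality_rows.append(
            {
                "organism_id": oid,
                "superkingdom": org.superkingdom,
                "gc_modality": gc_mod.get(oid),
                "genome_size_modality": grouping.discretize_genome_size(
                    org.genome_size_mb, org.superkingdom
                ),
                "habitat": org.habitat,
                "oxygen": org.oxygen,
                "temperature": org.temperature,
                "pct_disordered_aa_focus": measures[oid],
                "disorder_modality": dis_mod.get(oid),
            }
        )
    modalities = pd.DataFrame(modality_rows)

    # --- cross tables over all characteristic pairs
    char_maps: dict[str, dict[str, str]] = {
        "gc": gc_mod,
        "genome_size": {
            oid: grouping.discretize_genome_size(o.genome_size_mb, o.superkingdom)
            for oid, o in dataset.organisms.items()
        },
        "habitat": {oid: o.habitat for oid, o in dataset.organisms.items() if o.habitat},
        "oxygen": {oid: o.oxygen for oid, o in dataset.organisms.items() if o.oxygen},
        "temperature": {oid: o.temperature for oid, o in dataset.organisms.items() if o.temperature},
    }
    names = list(char_maps)
    cross: dict[tuple[str, str], pd.DataFrame] = {}
    for i, c1 in enumerate(names):
        for c2 in names[i + 1 :]:
            cross[(c1, c2)] = grouping.cross_table(
                dataset, char_maps[c1], char_maps[c2], min_length=focus,
                char1_name=c1, char2_name=c2,
            )

    # --- GC comparison t-tests (high vs low GC per group per superkingdom)
    test_rows = []
    for kingdom in ("Archaea", "Bacteria"):
        oids = [o.organism_id for o in dataset.organisms_in(kingdom)]
        high = [o for o in oids if gc_mod.get(o) == "high"]
        low = [o for o in oids if gc_mod.get(o) == "low"]
        if not high or not low:
            continue
        for group in grouping.GROUP_ORDER:
            try:
                res = dstats.compare_categories(
                    dataset, high, low, group=group, min_length=focus
                )
            except ValueError:
                continue
            test_rows.append(
                {"superkingdom": kingdom, "group": group, "comparison": "gc_high_vs_low",
                 "statistic": res.statistic, "p_value": res.p_value,
                 "n_a": res.n_a, "n_b": res.n_b}
            )

    # --- association rules per superkingdom
    mined: dict[str, list[rulemod.AssociationRule]] = {}
    policy = rulemod.RuleFilterPolicy(
        max_body_items=config.max_body_items,
        excluded_items=frozenset(config.excluded_items),
    )
    for kingdom in ("Archaea", "Bacteria"):
        orgs = dataset.organisms_in(kingdom)
        if len(orgs) < 2:
            mined[kingdom] = []
            continue
        transactions = rulemod.build_transactions(orgs, gc_mod, dis_mod)
        itemsets = rulemod.frequent_itemsets(
            transactions, config.min_support.get(kingdom, 0.13)
        )
        derived = rulemod.derive_rules(itemsets, config.min_confidence.get(kingdom, 0.66))
        mined[kingdom] = rulemod.filter_rules(derived, policy)

    return AnalysisResult(
        config=config,
        region_stats=pd.DataFrame(region_rows),
        purity=pd.DataFrame(purity_rows),
        composition=pd.DataFrame(comp_rows),
        fractional_difference=pd.DataFrame(fd_rows),
        organism_modalities=modalities,
        cross_tables=cross,
        gc_tests=pd.DataFrame(test_rows),
        cog_orderings=pd.DataFrame(orderings),
        rules=mined,
    )


def write_report(result: AnalysisResult, out_dir: str | Path) -> dict[str, Path]:
    """Write every table as TSV (plus DOT rule graphs and a run log)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = result.config.config_hash()

    def _write(df: pd.DataFrame, name: str) -> Path:
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            fh.write("# coordinates 1-based inclusive; length thresholds inclusive (>=); "
                     "percentages pooled unless noted\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        return path

    paths = {
        "region_stats": _write(result.region_stats, "region_stats.tsv"),
        "purity": _write(result.purity, "purity.tsv"),
        "composition": _write(result.composition, "composition.tsv"),
        "fractional_difference": _write(result.fractional_difference, "fractional_difference.tsv"),
        "organism_modalities": _write(result.organism_modalities, "organism_modalities.tsv"),
        "gc_tests": _write(result.gc_tests, "gc_tests.tsv"),
        "cog_orderings": _write(result.cog_orderings, "cog_orderings.tsv"),
    }
    for (c1, c2), df in result.cross_tables.items():
        paths[f"cross_{c1}_{c2}"] = _write(df, f"cross_{c1}_{c2}.tsv")
    for kingdom, ruleset in result.rules.items():
        rows = [
            {"body": ";".join(sorted(r.body)), "head": ";".join(sorted(r.head)),
             "support_pct": 100.0 * r.support, "confidence_pct": 100.0 * r.confidence,
             "lift": r.lift}
            for r in ruleset
        ]
        df = pd.DataFrame(rows, columns=["body", "head", "support_pct", "confidence_pct", "lift"])
        paths[f"rules_{kingdom}"] = _write(df, f"rules_{kingdom}.tsv")
        dot_path = out / f"rules_{kingdom}.dot"
        dot_path.write_text(rulemod.rules_to_dot(ruleset, title=kingdom))
        paths[f"rules_{kingdom}_dot"] = dot_path
    log = {
        "config": asdict(result.config),
        "config_hash": chash,
        "settings": {
            "binarization": "score >= threshold is disordered",
            "length_thresholds": "inclusive (>=)",
            "per_100aa": "pooled (sum of counts / sum of lengths)",
            "gc_borders": "mean +/- 1 sample SD, borders inclusive to medium",
            "genome_size_borders": "short iff < 4 Mb (Bacteria) / < 2.5 Mb (Archaea)",
            "disorder_discretization": result.config.disorder_scheme,
            "rule_reliability": "lexicographic (confidence, support, lift)",
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True, default=str))
    paths["run_log"] = out / "run_log.json"
    return paths


# ---------------------------------------------------------------------------
# Planted-effect recovery (one replicate)


def recover_planted_effects(
    gen_config: GeneratorConfig,
    min_support: float = 0.13,
    min_confidence: float = 0.66,
) -> dict:
    """Generate one synthetic replicate and check what the pipeline recovers.

    Returns a dict with the four recovery outcomes: functional-group ordering
    (Cp and Isp above Me on all four ordering criteria at L >= 41), sign of
    the mean fractional difference over the disorder-promoter and
    order-promoter residue sets, the Welch p-value for high-vs-low GC
    disorder after top-25% reduction, and the mined ``gc=high =>
    disorder=high`` rule (if it survives filtering).
    """
    dataset, truth = generate(gen_config)
    focus = 41
    prots = dataset.proteins
    summary = _summarize(prots, focus)
    masks = _group_masks(prots)

    group_values: dict[str, dict[str, float]] = {}
    for crit in ("avg_regions_per_protein", "regions_per_100aa",
                 "pct_proteins_with_region", "pct_disordered_aa"):
        group_values[crit] = {}
    for g in ("Isp", "Cp", "Me", "Pc", "NC"):
        idx = np.flatnonzero(masks[g])
        if idx.size == 0:
            continue
        group_values["avg_regions_per_protein"][g] = float(summary.qual_regions[idx].mean())
        group_values["regions_per_100aa"][g] = float(
            100.0 * summary.qual_regions[idx].sum() / summary.length[idx].sum()
        )
        group_values["pct_proteins_with_region"][g] = float(
            100.0 * (summary.qual_regions[idx] > 0).mean()
        )
        group_values["pct_disordered_aa"][g] = summary.pooled_pct_disordered(idx)
    ordering_ok = all(
        vals["Cp"] > vals["Me"] and vals["Isp"] > vals["Me"]
        for vals in group_values.values()
    )

    dcnt, ocnt = _residue_counts_by_state(prots)
    pa, pb = dcnt / dcnt.sum(), ocnt / ocnt.sum()
    fd = {aa: (pa[i] - pb[i]) / pb[i] for i, aa in enumerate(AMINO_ACIDS)}
    fd_promoters = float(np.mean([fd[a] for a in sorted(DISORDER_PROMOTERS)]))
    fd_order = float(np.mean([fd[a] for a in sorted(ORDER_PROMOTERS)]))

    all_orgs = list(dataset.organisms.values())
    gc_mod = grouping.discretize_gc(all_orgs)
    high = [o.organism_id for o in all_orgs if gc_mod[o.organism_id] == "high"]
    low = [o.organism_id for o in all_orgs if gc_mod[o.organism_id] == "low"]
    ttest_p = float("nan")
    if high and low:
        res = dstats.compare_categories(dataset, high, low, group="Cp", min_length=focus)
        ttest_p = res.p_value

    measures = organism_disorder_measure(dataset, focus)
    dis_mod = grouping.discretize_disorder(measures, "mean_sd")
    transactions = rulemod.build_transactions(all_orgs, gc_mod, dis_mod)
    itemsets = rulemod.frequent_itemsets(transactions, min_support)
    derived = rulemod.derive_rules(itemsets, min_confidence)
    surviving = rulemod.filter_rules(derived)
    target = next(
        (r for r in surviving
         if r.body == frozenset({"gc=high"}) and r.head == frozenset({"disorder=high"})),
        None,
    )
    return {
        "group_values": group_values,
        "ordering_ok": ordering_ok,
        "fd_promoters": fd_promoters,
        "fd_order_promoters": fd_order,
        "ttest_p": ttest_p,
        "gc_rule": target,
        "n_rules": len(surviving),
    }
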