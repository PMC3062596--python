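import json
from pathlib import Path

import numpy as np
import pytest

from disprok import io as dio
from disprok import regions
from disprok.pipeline import organism_disorder_measure
from disprok.synthetic import GeneratorConfig, GroundTruth, generate, small_fixture, write_fixture

from conftest import DATA_DIR


def _tiny_cfg(seed=1, **kw):
    defaults = dict(n_bacteria=4, n_archaea=2, proteins_per_organism=20)
    defaults.update(kw)
    return GeneratorConfig(seed=seed, **defaults)


class TestDeterminism:
    def test_same_seed_identical_fixture_files(self, tmp_path):
        for sub in ("a", "b"):
            dataset, truth = generate(_tiny_cfg(), with_scores=True)
            write_fixture(dataset, tmp_path / sub, truth=truth, with_scores=True)
        for name in ("proteins.fasta", "disorder.tsv", "cogs.tsv",
                     "organisms.tsv", "protein_organism.tsv", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seed_differs(self):
        d1, _ = generate(_tiny_cfg(seed=1))
        d2, _ = generate(_tiny_cfg(seed=2))
        assert d1.proteins[0].sequence != d2.proteins[0].sequence


class TestConfigValidation:
    def test_bad_weights_named(self):
        with pytest.raises(ValueError, match="habitat_probs"):
            GeneratorConfig(seed=1, habitat_probs=(0.5, 0.5, 0.5, 0.0, 0.0))

    def test_bad_fraction_named(self):
        with pytest.raises(ValueError, match="group_disorder_fraction"):
            GeneratorConfig(seed=1, group_disorder_fraction={
                "Isp": 1.5, "Cp": 0.3, "Me": 0.1, "Pc": 0.2, "NC": 0.2})


class TestSelfConsistency:
    def test_segmentation_recovers_true_runs(self):
        dataset, truth = generate(_tiny_cfg(seed=3))
        for prot in dataset.proteins:
            starts, lengths, values = regions.run_lengths(prot.labels)
            true_runs = truth.protein_run_lengths[prot.protein_id]
            first_dis = truth.protein_first_run_disordered[prot.protein_id]
            # adjacent true runs can merge only across the kind boundary; the
            # generator alternates kinds, so recovery must be exact
            assert lengths.tolist() == true_runs
            assert bool(values[0]) == first_dis

    def test_scores_binarize_back_to_labels(self):
        dataset, _ = generate(_tiny_cfg(seed=4), with_scores=True)
        for prot in dataset.proteins:
            assert np.array_equal((prot.scores >= 0.5).astype(np.uint8), prot.labels)

    def test_label_round_trip_through_files(self, tmp_path):
        dataset, _ = generate(_tiny_cfg(seed=5))
        write_fixture(dataset, tmp_path)
        loaded = dio.load_dataset(
            tmp_path / "proteins.fasta", tmp_path / "disorder.tsv",
            tmp_path / "cogs.tsv", tmp_path / "organisms.tsv",
            tmp_path / "protein_organism.tsv",
        )
        orig = {p.protein_id: p for p in dataset.proteins}
        assert len(loaded.proteins) == len(orig)
        for p in loaded.proteins:
            assert p.sequence == orig[p.protein_id].sequence
            assert np.array_equal(p.labels, orig[p.protein_id].labels)
            assert p.cogs == orig[p.protein_id].cogs


class TestPlantedEffects:
    def test_zero_coupling_null_correlation(self):
        cfg = GeneratorConfig(seed=6, n_bacteria=20, n_archaea=10,
                              proteins_per_organism=60, gc_coupling=0.0)
        dataset, _ = generate(cfg)
        m = organism_disorder_measure(dataset, 41)
        gc = np.array([o.gc_percent for o in dataset.organisms.values()])
        dis = np.array([m[oid] for oid in dataset.organisms])
        assert abs(np.corrcoef(gc, dis)[0, 1]) < 0.35

    def test_no_enrichment_flat_composition(self):
        from disprok import composition as comp

        cfg = GeneratorConfig(seed=7, n_bacteria=10, n_archaea=5,
                              proteins_per_organism=60, promoter_enrichment=1.0,
                              gc_composition_coupling=0.0)
        dataset, _ = generate(cfg)
        dis, ordr = [], []
        for p in dataset.proteins:
            dis += comp.region_sequences(p.sequence, p.labels, "disordered", 1)
            ordr += comp.region_sequences(p.sequence, p.labels, "ordered", 1)
        fd = comp.fractional_difference(
            comp.mole_fractions(dis), comp.mole_fractions(ordr)
        )
        vals = [v for v in fd.values.values() if not np.isnan(v)]
        assert max(abs(v) for v in vals) < 0.1

    def test_group_disorder_ratio_realized(self):
        # measured at zero organism-level shift: the logistic GC coupling
        # compresses marginal ratios, so the configured ratio is exact only
        # conditional on shift = 0
        dataset, truth = generate(GeneratorConfig(
            seed=8, n_bacteria=10, n_archaea=5, proteins_per_organism=100,
            gc_coupling=0.0, organism_noise_sd=0.0))
        by_group = {"Isp": [], "Me": []}
        for p in dataset.proteins:
            g = truth.protein_group[p.protein_id]
            if g in by_group:
                by_group[g].append(p)
        isp = regions.pct_disordered_aa(by_group["Isp"], 1)
        me = regions.pct_disordered_aa(by_group["Me"], 1)
        assert isp / me == pytest.approx(truth.effect_sizes["isp_me_ratio"], rel=0.25)

    def test_every_length_class_populated(self):
        dataset, _ = generate(_tiny_cfg(seed=9, proteins_per_organism=100))
        for lc in regions.LENGTH_CLASSES:
            assert regions.pct_proteins_with_region(dataset.proteins, lc) > 0


class TestSmallFixture:
    def test_shape(self, small_dataset):
        dataset, meta = small_dataset
        assert len(dataset.organisms) == 5 and len(dataset.proteins) == 20
        assert all(p.length == 100 for p in dataset.proteins)

    def test_hand_checked_region_statistics(self, small_dataset):
        dataset, meta = small_dataset
        m = organism_disorder_measure(dataset, 41)
        for oid, expected in meta["expected_disorder_pct41"].items():
            assert m[oid] == pytest.approx(expected)
        pE3 = next(p for p in dataset.proteins if p.protein_id == "pE3")
        # one disordered run of exactly 41: counted at every class threshold
        for lc in (1, 11, 21, 31, 41):
            assert regions.pct_proteins_with_region([pE3], lc) == 100.0
        assert regions.pct_proteins_with_region([pE3], 42) == 0.0

    def test_gc_and_disorder_modalities(self, small_dataset):
        from disprok.grouping import discretize_disorder, discretize_gc

        dataset, meta = small_dataset
        gc_mod = discretize_gc(list(dataset.organisms.values()))
        assert gc_mod == meta["expected_gc_modality"]
        dis_mod = discretize_disorder(organism_disorder_measure(dataset, 41))
        assert dis_mod == meta["expected_disorder_modality"]

    def test_guaranteed_rule_survives(self, small_dataset):
        from disprok import rules as rl
        from disprok.grouping import discretize_disorder, discretize_gc

        dataset, meta = small_dataset
        gc_mod = discretize_gc(list(dataset.organisms.values()))
        dis_mod = discretize_disorder(organism_disorder_measure(dataset, 41))
        ts = rl.build_transactions(dataset.organisms.values(), gc_mod, dis_mod)
        surviving = rl.filter_rules(
            rl.derive_rules(rl.frequent_itemsets(ts, 0.2), 0.6)
        )
        want = meta["guaranteed_rule"]
        rule = next(
            r for r in surviving
            if r.body == frozenset(want["body"]) and r.head == frozenset(want["head"])
        )
        assert rule.support == pytest.approx(want["support"])
        assert rule.confidence == pytest.approx(want["confidence"])
        assert rule.lift == pytest.approx(want["lift"])

    def test_committed_files_match_regeneration(self, small_dataset, tmp_path):
        dataset, _ = small_dataset
        write_fixture(dataset, tmp_path)
        for name in ("proteins.fasta", "disorder.tsv", "cogs.tsv",
                     "organisms.tsv", "protein_organism.tsv"):
            assert (tmp_path / name).read_bytes() == (DATA_DIR / name).read_bytes()
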