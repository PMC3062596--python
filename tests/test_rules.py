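from itertools import combinations

import numpy as np
import pytest

from disprok import rules as rl
from disprok.io import OrganismRecord


def brute_force_itemsets(transactions, min_support):
    """Exhaustive enumeration oracle over all 2^k candidate itemsets."""
    items = sorted(set().union(*transactions))
    index = {it: i for i, it in enumerate(items)}
    tmasks = [sum(1 << index[i] for i in t) for t in transactions]
    n = len(tmasks)
    out = {}
    for mask in range(1, 1 << len(items)):
        cnt = sum((tm & mask) == mask for tm in tmasks)
        if cnt / n >= min_support:
            itemset = frozenset(items[i] for i in range(len(items)) if (mask >> i) & 1)
            out[itemset] = cnt / n
    return out


def brute_force_rules(transactions, min_support, min_confidence):
    """All body/head bipartitions of frequent itemsets, by direct counting."""
    n = len(transactions)

    def support(s):
        return sum(1 for t in transactions if s <= t) / n

    rules = set()
    for itemset, supp in brute_force_itemsets(transactions, min_support).items():
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for body in combinations(sorted(itemset), r):
                body_set = frozenset(body)
                head_set = itemset - body_set
                conf = supp / support(body_set)
                if conf >= min_confidence:
                    rules.add((body_set, head_set, supp, conf, conf / support(head_set)))
    return rules


def random_instance(rng, max_items=12, max_transactions=50):
    n_items = rng.integers(5, max_items + 1)
    items = [f"a{i}=v" for i in range(n_items)]
    n_t = rng.integers(5, max_transactions + 1)
    transactions = []
    for _ in range(n_t):
        mask = rng.random(n_items) < rng.uniform(0.2, 0.7)
        t = frozenset(it for it, m in zip(items, mask) if m)
        if t:
            transactions.append(t)
    return transactions or [frozenset(items[:1])]


class TestTransactions:
    @staticmethod
    def _orgs():
        return [
            OrganismRecord("o1", "Bacteria", "Firmicutes", 5.0, 62.0,
                           habitat="aquatic", oxygen="aerobic", temperature="mesophile"),
            OrganismRecord("o2", "Archaea", "Euryarchaeota", 2.0, 40.0,
                           oxygen="anaerobic", temperature="thermophile"),
        ]

    def test_items_and_missing_attributes(self):
        t1, t2 = rl.build_transactions(
            self._orgs(), {"o1": "high", "o2": "low"}, {"o1": "high"}
        )
        assert "gc=high" in t1.items and "disorder=high" in t1.items
        assert "genome_size=long" in t1.items  # 5.0 Mb bacterium
        assert "genome_size=short" in t2.items  # 2.0 Mb archaeon
        assert not any(i.startswith("habitat=") for i in t2.items)  # missing habitat
        assert not any(i.startswith("disorder=") for i in t2.items)

    def test_one_transaction_per_organism(self):
        assert len(rl.build_transactions(self._orgs(), {}, {})) == 2

    def test_duplicate_attribute_rejected(self):
        with pytest.raises(ValueError, match="duplicate attribute"):
            rl.Transaction("x", frozenset({"gc=high", "gc=low"}))


class TestApriori:
    def test_single_item_support(self):
        ts = [frozenset({"A"})] * 4 + [frozenset({"B"})]
        out = rl.frequent_itemsets(ts, 0.5)
        assert out[frozenset({"A"})] == pytest.approx(0.8)

    def test_min_support_one(self):
        ts = [frozenset({"A", "B"}), frozenset({"A"}), frozenset({"A", "C"})]
        out = rl.frequent_itemsets(ts, 1.0)
        assert set(out) == {frozenset({"A"})}

    def test_downward_closure(self):
        rng = np.random.default_rng(0)
        ts = random_instance(rng)
        out = rl.frequent_itemsets(ts, 0.2)
        for itemset, supp in out.items():
            for r in range(1, len(itemset)):
                for sub in combinations(sorted(itemset), r):
                    assert out[frozenset(sub)] >= supp - 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        ts = random_instance(rng, max_items=10, max_transactions=30)
        min_s = float(rng.uniform(0.1, 0.5))
        assert rl.frequent_itemsets(ts, min_s) == brute_force_itemsets(ts, min_s)


class TestDeriveRules:
    def test_direct_arithmetic(self):
        ts = (
            [frozenset({"A", "B"})] * 3 + [frozenset({"A"})] + [frozenset({"C"})]
        )
        itemsets = rl.frequent_itemsets(ts, 0.1)
        rules = rl.derive_rules(itemsets, 0.5)
        rule = next(r for r in rules if r.body == frozenset({"A"}))
        assert rule.support == pytest.approx(0.6)
        assert rule.confidence == pytest.approx(0.75)
        assert rule.lift == pytest.approx(0.75 / 0.6)

    def test_universal_head_lift_one(self):
        ts = [frozenset({"A", "B"}), frozenset({"B"}), frozenset({"A", "B"})]
        itemsets = rl.frequent_itemsets(ts, 0.1)
        rules = rl.derive_rules(itemsets, 0.1)
        rule = next(r for r in rules if r.head == frozenset({"B"}))
        assert rule.lift == pytest.approx(1.0)

    def test_lift_symmetric_in_direction(self):
        rng = np.random.default_rng(4)
        ts = random_instance(rng)
        itemsets = rl.frequent_itemsets(ts, 0.15)
        rules = rl.derive_rules(itemsets, 0.01, max_head=None)
        by_pair = {(tuple(sorted(r.body)), tuple(sorted(r.head))): r for r in rules}
        for (b, h), r in by_pair.items():
            rev = by_pair.get((h, b))
            if rev is not None:
                assert r.lift == pytest.approx(rev.lift, abs=1e-12)

    def test_independent_items_lift_near_one(self):
        rng = np.random.default_rng(99)
        ts = []
        for _ in range(2000):
            t = set()
            if rng.random() < 0.5:
                t.add("A=1")
            if rng.random() < 0.5:
                t.add("B=1")
            # empty transactions stay in N: dropping them would induce
            # negative dependence between the two items
            ts.append(frozenset(t))
        itemsets = rl.frequent_itemsets(ts, 0.05)
        rules = rl.derive_rules(itemsets, 0.01)
        rule = next(
            r for r in rules
            if r.body == frozenset({"A=1"}) and r.head == frozenset({"B=1"})
        )
        assert 0.9 <= rule.lift <= 1.1


def _rule(body, head, conf, supp, lift):
    return rl.AssociationRule(frozenset(body), frozenset(head), supp, conf, lift)


class TestFilterPolicy:
    D1, D2 = "disorder=high", "disorder=low"
    G, G2 = "gc=high", "gc=low"
    H, S, O = "habitat=aquatic", "genome_size=short", "oxygen=aerobic"
    T, P = "temperature=mesophile", "phylum=Euryarchaeota"

    def rules(self):
        return [
            _rule({self.G}, {self.D1}, 0.90, 0.30, 2.0),            # 1 keep
            _rule({self.G, self.H}, {self.D1}, 0.85, 0.20, 1.8),    # 2 superset body
            _rule({self.G, self.H, self.S}, {self.D1}, 0.99, 0.10, 2.5),  # 3 body too big
            _rule({self.H}, {self.O}, 0.95, 0.40, 1.1),             # 4 no disorder item
            _rule({self.T}, {self.D1}, 0.97, 0.50, 1.2),            # 5 excluded item
            _rule({self.P}, {self.D1}, 0.80, 0.30, 1.5),            # 6 excluded item
            _rule({self.G2}, {self.D2}, 0.70, 0.25, 1.4),           # 7 keep
            _rule({self.G}, {self.D2}, 0.60, 0.20, 1.1),            # 8 same head+attr as 7
            _rule({self.S, self.O}, {self.D1}, 0.95, 0.15, 2.2),    # 9 keep (more reliable than 10)
            _rule({self.O}, {self.D1}, 0.50, 0.30, 0.9),            # 10 keep
            _rule({self.D1}, {self.H}, 0.88, 0.22, 1.3),            # 11 keep (disorder in body)
            _rule({self.G, self.H}, {self.D2}, 0.90, 0.18, 1.7),    # 12 keep (more reliable than 8)
        ]

    def policy(self):
        return rl.RuleFilterPolicy(excluded_items=frozenset({self.T, self.P}))

    def test_expected_survivors(self):
        surviving = rl.filter_rules(self.rules(), self.policy())
        got = {(tuple(sorted(r.body)), tuple(sorted(r.head))) for r in surviving}
        expected = {
            (tuple(sorted({self.G})), (self.D1,)),
            (tuple(sorted({self.G2})), (self.D2,)),
            (tuple(sorted({self.S, self.O})), (self.D1,)),
            (tuple(sorted({self.O})), (self.D1,)),
            ((self.D1,), (self.H,)),
            (tuple(sorted({self.G, self.H})), (self.D2,)),
        }
        assert got == expected

    def test_body_size_criterion_alone(self):
        surviving = rl.filter_rules(self.rules(), rl.RuleFilterPolicy(
            max_body_items=1, excluded_items=frozenset({self.T, self.P})))
        assert all(len(r.body) <= 1 for r in surviving)

    def test_minimal_body_superset_removed(self):
        rules = [
            _rule({self.G}, {self.D1}, 0.90, 0.30, 2.0),
            _rule({self.G, self.H}, {self.D1}, 0.85, 0.20, 1.8),
        ]
        surviving = rl.filter_rules(rules, rl.RuleFilterPolicy())
        assert [r.body for r in surviving] == [frozenset({self.G})]

    def test_reliability_ranking_is_confidence_first(self):
        a = _rule({self.G}, {self.D1}, 0.9, 0.1, 1.0)
        b = _rule({self.G2}, {self.D1}, 0.8, 0.9, 9.0)
        assert a.reliability > b.reliability


class TestDotExport:
    def test_dot_contains_edges(self):
        rules = [_rule({"gc=high"}, {"disorder=high"}, 0.9, 0.3, 2.0)]
        dot = rl.rules_to_dot(rules)
        assert dot.startswith("digraph") and "gc=high" in dot and "lift=2.00" in dot
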