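"""Association-rule mining over organism characteristics (apriori, in-repo).

Each organism contributes one transaction of ``attribute=modality`` items
(superkingdom, phylum, GC level, genome size, habitat, oxygen requirement,
temperature range, disorder level).  Rules A => B are scored by

* support    s(A=>B) = sigma(A u B) / N     (N = number of transactions),
* confidence c(A=>B) = sigma(A u B) / sigma(A),
* lift       Lift(A=>B) = c(A=>B) / s(B);   Lift = 1 under independence.

Frequent itemsets come from a level-wise apriori with candidate pruning
(every subset of a candidate must itself be frequent).  The rule filter
implements the selection criteria used to keep mined rule sets readable:
bounded body size, a disorder item somewhere in the rule, configurable
exclusion of dominant items (e.g., an overwhelming phylum or temperature
modality), minimal bodies, and one rule per (head, body-attribute) pattern —
keeping the most reliable, ranked lexicographically by (confidence, support,
lift).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .io import OrganismRecord

__all__ = [
    "Transaction",
    "AssociationRule",
    "RuleFilterPolicy",
    "build_transactions",
    "frequent_itemsets",
    "derive_rules",
    "filter_rules",
    "rules_to_dot",
]

Itemset = frozenset[str]


@dataclass(frozen=True)
class Transaction:
    organism_id: str
    items: Itemset

    def __post_init__(self) -> None:
        attrs = [item.split("=", 1)[0] for item in self.items]
        if len(attrs) != len(set(attrs)):
            dupes = sorted({a for a in attrs if attrs.count(a) > 1})
            raise ValueError(
                f"transaction {self.organism_id!r}: duplicate attribute(s) {dupes}"
            )


@dataclass(frozen=True)
class AssociationRule:
    body: Itemset
    head: Itemset
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if self.body & self.head:
            raise ValueError("body and head must be disjoint")

    @property
    def reliability(self) -> tuple[float, float, float]:
        """Ranking key: confidence first, then support, then lift."""
        return (self.confidence, self.support, self.lift)

    def __str__(self) -> str:
        return (
            f"{{{', '.join(sorted(self.body))}}} => {{{', '.join(sorted(self.head))}}}"
            f" (s={self.support:.3f}, c={self.confidence:.3f}, lift={self.lift:.3f})"
        )


def build_transactions(
    organisms: Iterable[OrganismRecord],
    gc_modality: Mapping[str, str],
    disorder_modality: Mapping[str, str],
) -> list[Transaction]:
    """One transaction per organism; attributes with missing values omitted."""
    out = []
    for org in organisms:
        items = {
            f"superkingdom={org.superkingdom}",
            f"phylum={org.phylum}",
        }
        size_mod = "short" if org.genome_size_mb < (
            2.5 if org.superkingdom == "Archaea" else 4.0
        ) else "long"
        items.add(f"genome_size={size_mod}")
        if org.organism_id in gc_modality:
            items.add(f"gc={gc_modality[org.organism_id]}")
        if org.habitat is not None:
            items.add(f"habitat={org.habitat}")
        if org.oxygen is not None:
            items.add(f"oxygen={org.oxygen}")
        if org.temperature is not None:
            items.add(f"temperature={org.temperature}")
        if org.organism_id in disorder_modality:
            items.add(f"disorder={disorder_modality[org.organism_id]}")
        out.append(Transaction(org.organism_id, frozenset(items)))
    return out


def _support_counts(
    candidates: Iterable[Itemset], transactions: Sequence[Itemset]
) -> dict[Itemset, int]:
    counts: dict[Itemset, int] = {}
    for cand in candidates:
        counts[cand] = sum(1 for t in transactions if cand <= t)
    return counts


def frequent_itemsets(
    transactions: Sequence[Transaction] | Sequence[Itemset],
    min_support: float,
) -> dict[Itemset, float]:
    """All itemsets with support >= min_support (level-wise apriori)."""
    if not 0.0 < min_support <= 1.0:
        raise ValueError("min_support must be in (0, 1]")
    tsets: list[Itemset] = [
        t.items if isinstance(t, Transaction) else frozenset(t) for t in transactions
    ]
    n = len(tsets)
    if n == 0:
        return {}
    result: dict[Itemset, float] = {}
    # level 1
    singles = sorted({item for t in tsets for item in t})
    counts = _support_counts([frozenset({i}) for i in singles], tsets)
    frequent = {c for c, cnt in counts.items() if cnt / n >= min_support}
    result.update({c: counts[c] / n for c in frequent})
    k = 2
    while frequent:
        # join step: union pairs at level k-1 that produce size-k candidates
        prev = sorted(frequent, key=sorted)
        candidates = set()
        for i, a in enumerate(prev):
            for b in prev[i + 1 :]:
                u = a | b
                if len(u) == k:
                    candidates.add(u)
        # prune step: every (k-1)-subset must be frequent
        candidates = {
            c
            for c in candidates
            if all(frozenset(sub) in frequent for sub in combinations(c, k - 1))
        }
        if not candidates:
            break
        counts = _support_counts(candidates, tsets)
        frequent = {c for c, cnt in counts.items() if cnt / n >= min_support}
        result.update({c: counts[c] / n for c in frequent})
        k += 1
    return result


def derive_rules(
    itemsets: Mapping[Itemset, float],
    min_confidence: float,
    max_head: int | None = 1,
) -> list[AssociationRule]:
    """Rules from every body/head bipartition of each frequent itemset.

    ``max_head`` bounds the head size (default 1, the form used in mined-rule
    reports; pass None for all bipartitions).  Support, confidence and lift
    come exactly from the itemset supports — every proper subset of a
    frequent itemset is frequent, so all needed supports are present.
    """
    if not 0.0 < min_confidence <= 1.0:
        raise ValueError("min_confidence must be in (0, 1]")
    rules: list[AssociationRule] = []
    for itemset, supp in itemsets.items():
        if len(itemset) < 2:
            continue
        items = sorted(itemset)
        for head_size in range(1, len(items)):
            if max_head is not None and head_size > max_head:
                continue
            for head in combinations(items, head_size):
                head_set = frozenset(head)
                body_set = itemset - head_set
                conf = supp / itemsets[body_set]
                if conf >= min_confidence:
                    rules.append(
                        AssociationRule(
                            body=body_set,
                            head=head_set,
                            support=supp,
                            confidence=conf,
                            lift=conf / itemsets[head_set],
                        )
                    )
    rules.sort(key=lambda r: (-r.confidence, -r.support, -r.lift, sorted(r.body), sorted(r.head)))
    return rules


@dataclass(frozen=True)
class RuleFilterPolicy:
    """Selection criteria applied to mined rules.

    ``excluded_items`` holds dominant items to suppress everywhere in a rule
    (the analogue of dropping an overwhelming phylum or the near-universal
    mesophile modality); it is data-driven configuration, not a hard-coded
    taxon list.
    """

    max_body_items: int = 2
    required_attribute: str = "disorder"
    excluded_items: frozenset[str] = frozenset()
    enforce_minimal_body: bool = True
    dedupe_same_attributes: bool = True


def _attrs(items: Itemset) -> frozenset[str]:
    return frozenset(item.split("=", 1)[0] for item in items)


def filter_rules(
    rules: Sequence[AssociationRule], policy: RuleFilterPolicy = RuleFilterPolicy()
) -> list[AssociationRule]:
    """Apply the rule-selection criteria; see :class:`RuleFilterPolicy`.

    Minimal-body enforcement drops a rule when another rule with the same
    head has a body that is a strict subset and is at least as reliable; a
    strictly more reliable superset-body rule survives.  Among rules with the
    same head and the same body attributes (different modalities), only the
    most reliable is kept.
    """
    kept = [
        r
        for r in rules
        if not (r.body | r.head) & policy.excluded_items
        and len(r.body) <= policy.max_body_items
        and (
            policy.required_attribute is None
            or policy.required_attribute in _attrs(r.body | r.head)
        )
    ]
    if policy.enforce_minimal_body:
        kept = [
            r
            for r in kept
            if not any(
                q.head == r.head
                and q.body < r.body
                and q.reliability >= r.reliability
                for q in kept
            )
        ]
    if policy.dedupe_same_attributes:
        best: dict[tuple[Itemset, frozenset[str]], AssociationRule] = {}
        for r in kept:
            key = (r.head, _attrs(r.body))
            if key not in best or r.reliability > best[key].reliability:
                best[key] = r
        kept = [r for r in kept if best[(r.head, _attrs(r.body))] is r]
    kept.sort(key=lambda r: (-r.confidence, -r.support, -r.lift, sorted(r.body), sorted(r.head)))
    return kept


def rules_to_dot(rules: Sequence[AssociationRule], title: str = "rules") -> str:
    """Graphviz DOT export: edge weight tracks lift, color tracks support."""
    lines = [f'digraph "{title}" {{', "  rankdir=LR;", "  node [shape=box];"]
    if rules:
        smin = min(r.support for r in rules)
        smax = max(r.support for r in rules)
    for r in rules:
        body = "\\n".join(sorted(r.body))
        head = "\\n".join(sorted(r.head))
        rel = 0.0 if smax == smin else (r.support - smin) / (smax - smin)
        # blue (low support) to yellow (high support)
        color = f"{0.66 * (1 - rel):.3f} 0.8 0.9"
        lines.append(
            f'  "{body}" -> "{head}" [penwidth={max(0.5, r.lift):.2f}, '
            f'color="{color}", label="s={100 * r.support:.0f}% lift={r.lift:.2f}"];'
        )
    lines.append("}")
    return "\n".join(lines)
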