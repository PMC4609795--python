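"""Apriori mining of features co-deregulated across cohorts.

Transactions are cohorts; items are feature identifiers that passed the
three-stage eligibility screen (multiplicity-corrected significance,
selection stability across cross-validation repeats, agreement of several
algorithms).  Frequent sets are mined level-wise with the downward-closure
prune and turned into association rules carrying support, confidence and
lift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

__all__ = ["TransactionSet", "AssociationRule", "eligible_items", "apriori",
           "rules"]


@dataclass
class TransactionSet:
    """Per-cohort item sets over a common universe."""

    transactions: list[frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        self.transactions = [frozenset(t) for t in self.transactions]
        self.universe = frozenset(self.universe)
        if not self.transactions:
            raise ValueError("need at least one transaction")
        for t in self.transactions:
            if not t <= self.universe:
                raise ValueError(f"items {set(t - self.universe)} outside the universe")

    @classmethod
    def from_lists(cls, transactions) -> "TransactionSet":
        ts = [frozenset(t) for t in transactions]
        return cls(ts, frozenset().union(*ts) if ts else frozenset())

    def support(self, items: frozenset) -> float:
        items = frozenset(items)
        return sum(items <= t for t in self.transactions) / len(self.transactions)


@dataclass
class AssociationRule:
    antecedent: frozenset
    consequent: frozenset
    support: float
    confidence: float
    lift: float

    def __post_init__(self) -> None:
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")


def eligible_items(
    per_dataset_results: dict,
    n_cv: int = 100,
    bonferroni_alpha: float = 0.05,
    min_frequency: int = 80,
    min_algorithms: int = 3,
) -> dict:
    """Three-stage deregulated-feature screen, per cohort.

    ``per_dataset_results`` maps cohort -> method -> a dict with
    ``selection_frequency`` (per-item counts over the ``n_cv`` CV repeats)
    and optionally ``p_values`` and ``n_tests``.  An item is eligible when
    (a) some method's p-value passes Bonferroni (methods without p-values
    don't constrain this stage), (b) it was selected at least
    ``min_frequency`` times by at least one method, and (c) at least
    ``min_algorithms`` methods selected it at all.
    """
    out = {}
    for cohort, methods in per_dataset_results.items():
        if len(methods) < min_algorithms:
            warnings.warn(
                f"{cohort}: only {len(methods)} methods available; "
                f"criterion (c) evaluated over those", stacklevel=2)
        items = set()
        for res in methods.values():
            items |= set(res.get("selection_frequency", {}))
        eligible = set()
        for item in items:
            freqs = [m.get("selection_frequency", {}).get(item, 0)
                     for m in methods.values()]
            stage_b = max(freqs, default=0) >= min_frequency
            stage_c = sum(f > 0 for f in freqs) >= min(min_algorithms, len(methods))
            has_p = [m for m in methods.values() if "p_values" in m]
            stage_a = (not has_p) or any(
                m["p_values"].get(item, 1.0)
                < bonferroni_alpha / m.get("n_tests", len(m["p_values"]))
                for m in has_p)
            if stage_a and stage_b and stage_c:
                eligible.add(item)
        out[cohort] = frozenset(eligible)
    return out


def apriori(transactions: TransactionSet | list, min_support: float = 0.5) -> dict:
    """All item sets with support >= ``min_support``, mined level-wise.

    Candidate (k+1)-sets are joined from frequent k-sets and pruned by
    downward closure before counting.  Returns {frozenset: support}.
    """
    if not 0 < min_support <= 1:
        raise ValueError("min_support must be in (0, 1]")
    if not isinstance(transactions, TransactionSet):
        transactions = TransactionSet.from_lists(transactions)
    frequent: dict[frozenset, float] = {}
    level = []
    for item in sorted(transactions.universe):
        s = transactions.support(frozenset([item]))
        if s >= min_support:
            candidate = frozenset([item])
            frequent[candidate] = s
            level.append(candidate)
    k = 1
    while level:
        candidates = set()
        for a, b in combinations(level, 2):
            joined = a | b
            if len(joined) == k + 1 and all(
                    frozenset(sub) in frequent for sub in combinations(joined, k)):
                candidates.add(joined)
        level = []
        for cand in candidates:
            s = transactions.support(cand)
            if s >= min_support:
                frequent[cand] = s
                level.append(cand)
        k += 1
    return frequent


def rules(
    frequent_sets: dict,
    transactions: TransactionSet | list,
    min_confidence: float = 0.5,
) -> list[AssociationRule]:
    """All rules A -> B from frequent A | B with confidence >= threshold.

    ``confidence = support(A|B) / support(A)``; ``lift = confidence /
    support(B)``.
    """
    if not isinstance(transactions, TransactionSet):
        transactions = TransactionSet.from_lists(transactions)
    out = []
    for itemset, s_union in frequent_sets.items():
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for ante in combinations(sorted(itemset), r):
                antecedent = frozenset(ante)
                consequent = itemset - antecedent
                s_a = transactions.support(antecedent)
                if s_a == 0:
                    continue
                conf = s_union / s_a
                if conf >= min_confidence:
                    s_b = transactions.support(consequent)
                    out.append(AssociationRule(
                        antecedent, consequent, s_union, conf,
                        conf / s_b if s_b > 0 else float("inf")))
    out.sort(key=lambda r: (-r.confidence, -r.support,
                            tuple(sorted(r.antecedent)), tuple(sorted(r.consequent))))
    return out
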