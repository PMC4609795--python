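"""Mine features co-deregulated across cohorts with Apriori.

Transactions are cohorts, items are features that passed the three-stage
eligibility screen (multiplicity-corrected significance, selected >= 80
of 100 CV repeats by some algorithm, flagged by >= 3 algorithms).  Here the
screen and the miner run on a small synthetic six-cohort configuration in
which two features always travel together in three cohorts.
"""

from nbselect import itemsets as it

# per-cohort, per-method selection frequencies and p-values
def strong(item):
    return {"selection_frequency": {item: 95}, "p_values": {item: 1e-8},
            "n_tests": 500}

results = {}
for cohort in ("BRCA", "HNSC", "KICH"):
    results[cohort] = {
        "edger": {
            "selection_frequency": {"mir-96": 95, "mir-133a-1": 90},
            "p_values": {"mir-96": 1e-8, "mir-133a-1": 1e-7},
            "n_tests": 500},
        "deseq": {"selection_frequency": {"mir-96": 85, "mir-133a-1": 82}},
        "ranksum": {"selection_frequency": {"mir-96": 9, "mir-133a-1": 12}},
    }
for cohort in ("LUAD", "STAD", "THCA"):
    results[cohort] = {
        "edger": strong("mir-937"),
        "deseq": {"selection_frequency": {"mir-937": 88}},
        "ranksum": {"selection_frequency": {"mir-937": 30}},
    }

eligible = it.eligible_items(results)
for cohort, items in eligible.items():
    print(f"{cohort}: {sorted(items)}")

transactions = it.TransactionSet.from_lists(eligible.values())
frequent = it.apriori(transactions, min_support=0.5)
print("\nfrequent sets (support >= 0.5):")
for s, sup in sorted(frequent.items(), key=lambda kv: -kv[1]):
    print(f"  {{{', '.join(sorted(s))}}}  support={sup:.2f}")

print("\nrules (confidence >= 0.5):")
for r in it.rules(frequent, transactions, min_confidence=0.5):
    print(f"  {set(r.antecedent)} -> {set(r.consequent)}  "
          f"support={r.support:.2f} confidence={r.confidence:.2f} lift={r.lift:.2f}")
# A lift of 2 with confidence 1 says: whenever the antecedent is
# deregulated in a cohort the consequent is too, and the consequent
# appears in only half the cohorts overall.
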