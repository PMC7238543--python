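# fcmkit

Analysis of stakeholder **fuzzy cognitive maps** (FCMs): signed, weighted
digraphs that encode how a group of knowledge-holders believes factors
influence an outcome.  The package was built around participatory maps of
risk and protective factors for maternal health drawn by two groups of
indigenous traditional midwives (18 Me'phaa and 11 Nancue ñomndaa
participants), but every stage is generic: it reads maps, propagates
influence, condenses factors into themes, combines groups, and quantifies
where two groups agree.

## What it computes

* **Signed max–min transitive closure.**  A walk's strength is the minimum
  edge magnitude along it; its character is its parity (even/odd count of
  inhibitory edges).  The influence of node *i* on node *j* is
  `P(i,j) − N(i,j)`, where `P`/`N` are the strongest even-/odd-parity walk
  strengths — a single signed value in [−1, 1], with an ambiguity flag where
  both parities are reachable.
* **Cumulative net influence (CNI).**  Factor-level closure summed into
  thematic categories (`cumulative(C1,C2) = Σ_{a∈C1,b∈C2} closure(a,b)`),
  normalized so the strongest category scores 1.
* **Group combination** by participant-weighted averaging of cumulative
  weights.
* **Cross-group comparison**: validated / non-validated / conflicting
  connections and the *average difference* (mean absolute CNI difference;
  closer to 1 = less agreement).
* **Sensitivity scans** over a contested edge's weight (0–5), re-running the
  whole pipeline per value.

Formats: adjacency-matrix CSV, edge-list CSV, GraphML (directed).  See
`docs/methods.md` for the model, design choices and limitations.

## Worked example

```python
import fcmkit as fk

# the published per-category tables ship as fixtures
tables = fk.load_fixture("table2_cni")
risk = tables["risk"]
print(round(fk.average_difference(risk["difference"]), 2), len(risk))

a, b = fk.table2_profiles("protective")          # the two municipalities
table = fk.compare_category_maps(a, b, polarity="protective")
hospital = table.row("P09")
print(hospital.cni_a, hospital.cni_b, hospital.validation)
print(table.counts)
```

prints

```
0.14 17
-0.13 0.36 conflicting
{'validated': 5, 'non-validated': 6, 'conflicting': 1}
```

— over the 17 risk categories the two municipalities differ by 0.14 CNI on
average (high agreement), and on the protective side the
hospital-availability category is the single *conflicting* connection: a
negative influence on safe maternity in one group's map (−0.13) against a
positive one in the other's (+0.36).

Factor-level analysis of your own maps:

```python
m = fk.read_adjacency_csv("my_map.csv", participant_count=18)
closure = fk.transitive_closure(fk.scale_weights(m))      # raw 1-5 -> (0,1]
catmap = fk.aggregate_to_categories(
    closure, fk.CategoryMapping.from_csv("mapping.csv", "categories.csv"),
    map_name=m.name,
)
print(catmap.outcome_table())
```

The same chain is available from the shell:

```bash
fcmkit simulate --out-dir demo --seed 7          # synthetic 44-node map
fcmkit closure demo/synthetic_map.csv --out-dir demo
fcmkit pipeline config.yaml                      # full multi-group run
fcmkit sensitivity map.csv --source F01 --target F02 \
    --mapping mapping.csv --categories categories.csv --values 0,1,2,3,4,5
```

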