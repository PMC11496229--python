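# siakit — statistical implication analysis for binary outcomes

Most association measures for binary variables — correlations, chi-square,
odds ratios, psychometric network edges — are *symmetric*: they cannot say
whether "achieving outcome A implies achieving outcome B" holds more
strongly than the converse. Statistical implication analysis (SIA) asks the
directed question instead: is B almost always present when A is present,
with counterexamples (A = 1, B = 0) rarer than chance would predict? That
framing matters for clinical and developmental outcomes, where one
achievement may be a near-prerequisite of another (working independently vs.
symptomatic remission at the end of an early-intervention program, say)
without the reverse holding.

`siakit` provides, for a subjects × outcomes table of 0/1 variables:

- a **full-information implication index** ι on the log-odds scale. With
  Jeffreys-smoothed cell probabilities π of the 2×2 table of (A, B),

  ι(A⇒B) = ½ [ ln( π₁₁ π₊₀ / (π₁₀ π₊₁) ) + ln( π₀₀ π₁₊ / (π₁₀ π₀₊) ) ],

  the average of a *direct* term (odds of B given A against the marginal
  odds of B) and a *contrapositive* term (odds of ¬A given ¬B against the
  marginal odds of ¬A), both penalized by the counterexample cell π₁₀.
  It ranges over (−∞, +∞); positive favours the implication, 0 is the
  independence point, and ι(A⇒B) = ι(¬B⇒¬A) exactly. The classical
  counterexample-rarity intensity (Poisson tail of the counterexample
  count) is provided alongside as `gras_intensity`.
- **bootstrap inference**: case-resampling percentile confidence intervals;
  a directed implication is significant at the 0.05 level when its 95% CI
  excludes zero. Each ordered pair gets a deterministic random substream,
  so runs are bit-reproducible and order-independent.
- **all-ordered-pairs and stratified analyses**, pair classification
  (reciprocal / forward-only / backward-only / none) and a directed
  **implication graph** exportable as DOT or JSON.
- a **synthetic cohort generator** with planted implicative links
  (`P(B=1|A=1) = 1−ε`, `P(B=1|A=0) = q`, noisy-OR for multiple sources,
  optional per-stratum structure) for validation and power studies.

## Worked example

```python
import siakit as sk

# a 219-subject synthetic cohort: "working" implies the three other
# outcomes; symptomatic and functional recovery are tightly coupled
cohort = sk.generate_cohort(sk.study_like_spec(n=219), seed=42)

model = sk.ImplicationAnalysis(cohort.to_frame(), strata="baseline_work")
res = model.fit(n_replicates=2000, seed=42)
print(res.summary())
```

```
Statistical Implication Analysis (bootstrap percentile CIs)
==============================================================================
subjects: 219   dropped (incomplete): 0   outcomes: 4
replicates: 2000   smoothing alpha: 0.5   CI level: 95%   seed: 42
------------------------------------------------------------------------------
source        target            iota   ci_low  ci_high  sig     phi    b
------------------------------------------------------------------------------
working       living           1.847    1.304    2.754    *   1.000    8
working       symptomatic      1.547    1.031    2.353    *   1.000    9
working       functional       3.938    3.599    4.211    *   1.000    0
living        working          0.838    0.640    1.059    *   1.000   51
...
------------------------------------------------------------------------------
* CI excludes 0. phi: counterexample-rarity intensity. b: counterexamples.
```

Each row is one *directed* pair. `working -> functional` has ι = 3.94 with
zero observed counterexamples (`b = 0`): among 219 subjects nobody works
without functional recovery, far beyond what the margins predict. The
reverse direction, `functional -> working` (ι = 0.56, 84 counterexamples),
is much weaker — the asymmetry is the point of the method — though its CI
also excludes zero here: with n ≈ 219 this index detects even the weak
reverse dependence that any true implication induces, so planted one-way
links typically classify as reciprocal with unequal strengths (see
`docs/methods.md` for why). Graph views:

```python
res.graph()                  # networkx.DiGraph of significant positive edges
print(res.export_graph("dot"))
res.classifications()        # reciprocal / forward_only / ... per pair
res.to_csv("results.csv")    # canonical results table with provenance header
```

The same pipeline runs from the shell:

```sh
sia analyze --input cohort.csv --id-col id \
    --outcomes working,living,symptomatic,functional \
    --strata-col baseline_work --replicates 2000 --seed 42 \
    --out results.csv --graph-dot graph.dot --graph-json graph.json
sia simulate --spec cohort_spec.json --out cohort.csv
```

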