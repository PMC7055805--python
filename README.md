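# gdistinct

Re-identification risk analysis of demographic quasi-identifiers — date of
birth, gender, and hierarchically encoded residence — using the
**g-distinct** population-uniqueness statistic.

## The problem

Clinical datasets stripped of names and ID numbers still carry
*quasi-identifiers*: attribute combinations that single patients out when
linked with outside data. This package quantifies that risk for the
(DOB, gender, geography) triple, the classic worst offender, under two
HIPAA-style release policies:

- **limited dataset** — full date of birth, gender, and a full 9-digit
  *surrogate ZIP code* built from administrative geography (2-digit
  provincial-level division + 3-digit city + 4-digit district codes);
- **safe harbor** — birth year only, gender, and the first 6 ZIP digits.

Patients sharing an identical key form an *equivalence class*; a patient
is **g-distinct** when their class has at most g members (1-distinct =
unique). With |bin(i)| the number of classes of exact size i,

```
h(g) = Σ_{i=1..g} i · |bin(i)|
```

counts patients in classes of size ≤ g, and h(g)/N is the population
fraction at risk at threshold g. h is non-decreasing and reaches N at the
largest class, giving a cumulative risk curve; h(1)/N is the uniquely
identifiable share, and the smallest g with h(g)/N ≥ p answers "how
indistinguishable are the safest p of the population?".

Because real hospital records are private, the package ships a seeded
synthetic-population generator with the structure the analysis assumes:
a three-level gazetteer (province → city → district), Zipf-skewed regional
populations, decades of birth dates, and the data-quality defects the
preprocessing removes (missing addresses, sentinel `1900-01-01` birth
dates). Every pipeline stage — filtering, gazetteer encoding, partition by
provincial division (PAD), policy views, risk curves, per-region
stratification — is therefore testable end to end with no external data.

## Worked example

```python
import gdistinct as gd

cfg = gd.PopulationConfig(n_patients=20_000, seed=7)
bundle = gd.generate_population(cfg)
result = gd.run_pipeline(bundle.records, bundle.gazetteer)

print(result.filter_report.to_text())
print(f"nonempty PADs: {result.partition.n_pads}")
for name, pol in result.policies.items():
    print(
        f"{name}: N={pol.n_total}  1-distinct={pol.analyzer.h(1)} "
        f"({100 * pol.unique_fraction:.2f}%)  trend rho={pol.trend_rho:.3f}"
    )
lim = result.policies["limited"].analyzer
sh = result.policies["safe_harbor"].analyzer
print(f"limited 10-distinct share: {100 * lim.fraction_at(10):.2f}%")
print(f"safe harbor: 95% of patients are {sh.g_for_fraction(0.95)}-indistinguishable or rarer")
```

prints

```
n_input: 20000
n_missing_address: 364
n_sentinel_dob: 187
n_retained: 19449
nonempty PADs: 33
limited: N=19449  1-distinct=19445 (99.98%)  trend rho=-0.297
safe_harbor: N=19449  1-distinct=5527 (28.42%)  trend rho=-0.977
limited 10-distinct share: 100.00%
safe harbor: 95% of patients are 10-indistinguishable or rarer
```

Reading this: 551 of 20,000 generated records are excluded (missing
address, then sentinel DOB — each exclusion attributed to exactly one
rule). Under the limited view essentially everyone is unique; generalizing
to birth year + 6 ZIP digits collapses uniqueness to 28% at this modest
sample size, and the Spearman rank correlation between a region's
population and its 1-distinct percentage is negative under both policies:
bigger regions give every attribute combination more chances to recur.

The same pipeline is available from the shell:

```sh
gdistinct simulate --preset tiny --seed 7 --out pop/
gdistinct analyze --records pop/records.csv --gazetteer pop/gazetteer.csv --out report/
```

which writes the filter report, class-size histograms, (optionally
log-thinned) risk curves and per-PAD tables as delimited text plus a JSON
summary.

Estimator-style classes compose with scikit-learn:
`GazetteerEncoder(gazetteer).transform(records)` attaches surrogate ZIPs,
`PolicyTransformer(policy="safe_harbor")` produces key frames, and
`GDistinctAnalyzer(policy=...).fit(encoded)` exposes `histogram_`,
`curve_`, `unique_fraction_` and threshold queries.

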