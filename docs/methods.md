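# Methods

## Statistic

Patients are binned by exact equality of the quasi-identifier tuple
(dob_key, gender, zip_key) produced by a generalization policy. With
|bin(i)| classes of exact size i and N patients,

    h(g) = Σ_{i=1..g} i·|bin(i)|

is the number of patients lying in classes of size ≤ g ("g-distinct or
rarer"). Conservation (Σ i·|bin(i)| = N) and monotonicity of h are
enforced as invariants of the histogram type. All counts are exact
integers; ratios such as h(g)/N or the 1-distinct share h(1)/N are formed
only at reporting time, and threshold queries (smallest g with
h(g)/N ≥ p) compare integer counts against ⌈p·N⌉ with a one-ulp guard,
so no cumulative floating-point error can shift a threshold.

Keys are canonical strings compared exactly (pandas groupby on the three
key columns); equality, not hashing, is the contract. Curves materialize
every g from 1 to the largest class size; exports can thin the grid
log-spaced for plotting, since the largest class can hold thousands.

## Pipeline

1. **Filter.** Records with any missing address component are excluded,
   then records whose DOB is a configured sentinel (default exactly
   `1900-01-01`). Attribution order is fixed (address first) so a record
   failing both rules is counted once and reports are deterministic.
   Missing gender or missing non-sentinel DOB does *not* exclude a record
   here; such records drop out at key construction, where the drop is
   counted separately (`n_dropped_missing`). This keeps the filter
   faithful to the two stated exclusion rules while leaving the statistic
   well defined; the separate count makes the choice auditable.
2. **Encode.** Address triples are looked up in a gazetteer mapping
   (province, city, district) to 2-, 3- and 4-digit codes, concatenated
   into a 9-digit surrogate ZIP. Matching is exact after whitespace
   trimming and Unicode NFC normalization — no fuzzy matching, so the
   step is fully auditable. Codes are opaque digit strings; parsing them
   as integers would destroy leading zeros. Unmapped triples are counted
   and excluded downstream, never guessed.
3. **Partition.** Encoded records are grouped by the first two ZIP digits
   (the provincial-level division, PAD) — a disjoint, exhaustive cover.
4. **Policy views.** `limited` keeps day-level DOB and all 9 ZIP digits;
   `safe_harbor` keeps birth year and 6 digits. A custom policy sweeps
   DOB granularity (day/month/year/decade; decade floors the birth year)
   and ZIP prefix length 0–9 (0 drops geography entirely). HIPAA-style
   age top-coding ("ages over 89") is implemented but off by default,
   since the two named policies generalize only DOB and ZIP; it needs a
   reference date to compute ages. `coarsens(A, B)` formalizes when B's
   view is a deterministic function of A's (coarser-or-equal DOB,
   shorter-or-equal prefix, derivable top-coding); coarsening can only
   merge classes, which yields the tested monotonicity h_B(g) ≤ h_A(g).
5. **Stratified analysis.** Per-PAD 1-distinct percentages are computed
   from bins formed *within* each PAD. Because PADs are prefix-disjoint
   in the ZIP, this equals nationwide binning restricted to the PAD
   whenever the policy keeps ≥ 2 ZIP digits (both named policies do); the
   equality is asserted in the test suite rather than assumed. Rows sort
   by ascending population with pad_code tie-breaks for deterministic
   exports. The population-vs-uniqueness trend is summarized by Spearman
   rank correlation (scipy); fewer than 3 regions or constant ranks are
   reported as undefined (NaN) rather than silently zero.

## Synthetic populations

The generator emulates the *structure* the analysis assumes, not any real
census: n_pads provincial divisions (default 33) whose population shares
follow a Zipf law (share of rank r ∝ r^(−s), default s = 1), uniform city
and district choice within the parent, DOBs uniform over calendar days in
1930–2010 (~80 years; a year-weighted hook exists for age-pyramid
emulation and ships with uniform weights), gender Bernoulli(0.5), entire
address triples blanked with probability 0.02 and DOBs replaced by the
sentinel with probability 0.01. A single seeded stream is consumed in a
fixed order (gazetteer structure, then per-record PAD → city → district →
DOB → gender → defects), with each stage's draw count depending only on
the config, so generation is reproducible and extensible without
reshuffling. The bundle carries a truth table (assigned PAD and ZIP per
record) used as an end-to-end oracle for the encoding stage.

Scenario presets: `tiny` (1,000 patients, unit tests), `paper_like`
(100,000, the default analysis scale), `stress` (1,000,000).

### Why 4 cities × 20 districts per PAD

The default geography (33 × 4 × 20 = 2,640 districts) is deliberately
stylized. The contrast the method exists to expose — near-total
uniqueness under the limited view versus a collapsed safe-harbor view —
arises when safe-harbor cells (city × birth-year × gender within a PAD)
are *saturated*: expected occupancy well above 1. A full-scale cohort of
~0.8M patients saturates realistic geography; at the package's default
analysis scale of 10⁵ patients the same regime requires proportionally
fewer safe-harbor cells. A Poisson occupancy calculation at design time
(expected uniques ≈ Σ_PAD n_PAD·exp(−n_PAD/cells)) puts safe-harbor
uniqueness near 4% with 4 cities of 20 districts — an order-of-magnitude
gap below the ~99.7% limited-view uniqueness — whereas a
10-cities × 8-districts split would leave safe harbor near 15%. District
codes are numbered sequentially (0001…0020), so the 6-digit prefix's
single district digit carries no information and safe harbor effectively
keys on PAD + city, consistent with the prefix spanning only the first
district digit; the prefix length remains configurable for sweeps.

What passing tests on these populations do **not** show: calibration to
any real demographic structure (age pyramids, urban/rural mix, per-region
attribute heterogeneity, correlated missingness), free-text address noise
(the gazetteer lookup here is exact by construction), or the exact
percentages of any real cohort. Results at this scale are qualitative —
orderings, gaps, trends — not point estimates for real data.

## Numerical and degenerate-input choices

- Dates: strict ISO-8601; other dialects become missing with a logged
  warning (never reinterpreted). A configurable reference date invalidates
  future DOBs.
- Empty inputs: filtering an empty table yields zero counts; an empty
  view yields an empty histogram (N = 0); risk curves and fractions on
  N = 0 raise with guidance, since "fraction of nobody" is undefined.
- Ties: equal PAD populations order by pad_code; Spearman uses
  average-rank ties (cross-checked against a hand-rolled rank
  correlation in the tests).
- Determinism: writing the same records twice is byte-identical;
  generation is byte-identical per (config, seed).

## Problem sizes

Unit tests run on the `tiny` preset and key sets of ≤ 500 records, where
everything is cross-checked against O(n²) pairwise-comparison oracles.
End-to-end checks use `paper_like` (10⁵ patients), chosen as the scale
where the qualitative study findings (order-of-magnitude policy gap,
negative population–uniqueness trend across 33 regions) are stable across
seeds while a full run stays under a couple of seconds.

## Known limitations

- Free-text address parsing is out of scope; the gazetteer lookup
  replaces it with exact matching, so real-world address noise appears
  only as "unmapped" counts.
- Only the DOB/gender/ZIP quasi-identifiers are modeled; the other HIPAA
  safe-harbor identifier removals concern fields this pipeline never
  sees.
- No k-anonymization search, l-diversity, t-closeness or differential
  privacy — the package measures risk; it does not transform data to meet
  a target.
- Within-PAD binning and nationwide binning diverge for ZIP prefixes
  shorter than 2 digits; per-PAD tables for such sweeps should be read as
  within-region statistics only.
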