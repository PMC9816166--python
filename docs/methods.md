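# Methods

## The read model

All inference rests on a two-population accounting of sequenced DNA. At a
locus with tumor total copy number `CN_tot` in a sample of purity ρ, a
mutation present on `m` tumor copies (and on `m_normal` copies in normal
cells — 0 for somatic variants, 1 for a heterozygous germline variant) has
expected variant allele fraction

```
E[VAF] = (m·ρ + m_normal·(1−ρ)) / (ρ·CN_tot + 2·(1−ρ))
```

capped at 1−ε with ε = 0.01, so that fully mutant loci (e.g. m = 2 on a 2+0
segment in a pure tumor) keep nonzero likelihood in the presence of rare
reference-supporting error reads. Observed alt counts are modelled
Binomial(depth, E[VAF]); the continuous mutation copy number inverts the
map: `m_cont = VAF·(ρ·CN_tot + 2(1−ρ))/ρ`.

Per-mutation multiplicity is assigned by comparing binomial likelihoods over
m ∈ {1..major} plus one subclonal branch (m = 1 with CCF averaged over a
0.1–0.7 grid), flat prior. CCF is `m_cont/m` clipped to [0, 1.2]; a mutation
is called clonal when its CCF reaches 0.8 **or** its 95% Clopper–Pearson
CCF interval covers 1. The second clause matters for unbiased timing: with
the hard threshold alone, at depth 60 and ρ = 0.7 about 13% of true clonal
m = 1 mutations fall below 0.8 by sampling noise and would be dropped,
inflating π; the interval clause makes the exclusion rates of the m = 1 and
m = 2 classes symmetric (~2% each).

Clonality here is a read-model stand-in for phylogenetic clustering (which
needs multi-sample data and is out of scope); reports carry a note to that
effect.

## LOH classification

The locus state is the (major, minor) pair of the clonal allele-specific
segment containing the locus midpoint:

| state | (major, minor) | meaning |
|---|---|---|
| NO_LOH | (1,1) | diploid heterozygous |
| LOH_LOSS | (1,0), (0,0) | loss without gain |
| CN_LOH | (2,0) | wildtype lost, mutant duplicated |
| CG_LOH | (≥3,0) | multiple mutant copies, wildtype lost |
| GAIN_NO_LOH | (≥2,≥1) | gain with wildtype retained |

`LOH_LOSS` exists for totality even though the LFS cohorts essentially never
show loss without gain; (0,0) (homozygous deletion) is folded into it as
"wildtype copies = 0, no gain". Extent is `WHOLE_CHROMOSOME` when the run of
abutting segments sharing the locus state spans ≥ 95% of the chromosome
(configurable; the literature does not quantify "whole chromosome"), else
`SEGMENTAL`. Subclonal-only coverage (clonal fraction < 0.8) flags the call
low-confidence rather than failing.

Which physical allele was gained is decided by binomial likelihood of the
germline variant's tumor alt count under "mutant on major" vs "mutant on
minor" (normal cells contribute one mutant copy); balanced states return an
explicit tie. The tumor-vs-germline VAF shift itself is a two-sided Fisher
exact test on the 2×2 allele-count table.

## Gain timing

A clonal mutation predating a duplication is carried by every product copy
(multiplicity ≥ 2); later mutations sit on one copy. With a constant
per-copy mutation rate and a single synchronous gain at molecular time π:

* **2+0** (CN-LOH): pre-gain rate 1 (the surviving allele), post-gain 2 →
  `π = 2n₂/(2n₂+n₁)`
* **2+1**: the untouched minor copy accumulates m = 1 mutations throughout →
  `π = 3n₂/(2n₂+n₁)`
* **2+2** (synchronous double gain): `π = 2n₂/(2n₂+n₁)`

Values above 1 (possible by noise) are capped with an overflow flag; states
with major ≥ 3 are refused by the closed forms and flagged — timing there
requires a multi-event maximum-likelihood model that is intentionally not
implemented (the cohort analysis this package supports focuses on
whole-chromosome CN-LOH).

**Soft counts.** The pipeline does not count hard per-mutation argmax
assignments. At depth ~60 the m = 1 and m = 2 binomial components overlap,
and because n₁ ≫ n₂ at small π, even a ~1% m₁→m₂ misassignment rate doubles
n₂ and biases π upward by several points (worst measured: +0.065 for 2+2 at
π = 0.05). Instead the segment's multiplicity **mixture weights** are fitted
by EM (components fixed by the read model, only the proportions free) and
the closed form is evaluated on posterior-weighted expected counts — the
maximum-likelihood estimate of the category fractions, which is consistent;
measured bias is < 0.006 over all states × π ∈ {0.05..0.95}. The
per-mutation flat-prior assignment remains available and is what the
reported per-mutation calls use.

Uncertainty is a percentile bootstrap (default B = 200; B = 10 reproduces
the coarser published default) resampling mutations with replacement —
realised as multinomial weights over the responsibility rows, which is
distributionally identical and fast. Subclonal mutations are excluded from
n₁ by default.

**Clock conversion.** Clock mutations are CpG C>T calls plus any SNV whose
fitted posterior P(SBS1)+P(SBS5) exceeds 0.5 (strict; a tie at exactly 0.5
is not clock). Because these accumulate roughly linearly with age, the
clock-only molecular time converts to an age bound,
`age_gain ≈ π_clock × age_at_diagnosis`. This is reported as a model-based
bound under the stated linearity assumption, never as a measurement.

Cohort comparisons use the two-sided Wilcoxon rank-sum test (exact for
small tie-free groups, normal approximation with tie correction otherwise)
and Pearson correlation against age at diagnosis.

## Signature refitting

Exposures are multinomial mixture weights over a fixed 96-channel catalog,
fitted by EM (`e_s ← Σ_c n_c·P(s|c)/N`), tolerance 1e-8 on the
log-likelihood, at most 10,000 iterations; the log-likelihood is
non-decreasing by construction and asserted so in tests. De-novo discovery
(NMF) is out of scope: the catalog is an input (COSMIC v3.2 TSV at run
time; a built-in 3-signature fixture — CpG-concentrated SBS1-like, flat
SBS5-like, TCW-focused APOBEC-like — for download-free testing). Duplicate
catalog columns are flagged non-identifiable. Per-mutation posteriors are
Bayes' rule over the fitted exposures.

## Telomere content

A read is telomeric when it contains ≥ 12 non-overlapping TTAGGG copies on
one strand (or CCCTAA on the other; strands are not summed). Length per
chromosome end is telomeric sequence mass over GC-matched coverage:
`(k_tel·L/c_gc)/46` with `c_gc = n_gc·L/g_gc`, where the GC bin is reads at
48–52% GC (telomeric repeats are 50% GC) and `g_gc`, the genome span that
bin represents, is supplied in config. Reads passing the telomeric
threshold are excluded from the GC bin so the estimator stays linear in
telomere content. The published verbal description of the normalisation is
ambiguous about operation order; the dimensional-analysis-consistent form
above is used and tested. T/N is the ratio of tumor to matched-normal kb.

## The synthetic generator

`simulate_tumor` emulates exactly the structure the analysis assumes: a
planted gain time fixes lineage weights for multiplicity (for 2+0 at time t:
P(m=2) ∝ t, P(m=1) ∝ 2(1−t); analogues for 2+1, 2+2), contexts are drawn
from exposures × catalog, coverage is Poisson (zero-depth draws are redrawn
so every site is sequenced), alt counts binomial with success rate set by
multiplicity, purity, local copy number and CCF. Subclonal mutations sit at
a single CCF (default 0.4) on m = 1. A heterozygous germline *TP53* variant
is planted on the major allele of the segment covering the locus. Outputs
round-trip the package's own readers (plain VCF 4.2 with `INFO/TNC`,
1-based segment TSV, truth JSON) and are byte-identical under a fixed seed.

Study-condition defaults: purity 0.7, depth 60X, 2000 SNVs on a
whole-chr17 2+0 segment with π = 0.25 — a typical high-purity pediatric-WGS
configuration for the scenario the package times.

What the generator does **not** emulate: mapping artefacts, multi-clone
subclonal structure, copy-number miscalls, purity estimation error, strand
bias, or real trinucleotide genome composition (channels are drawn from the
signature mixture directly). Passing recovery tests therefore demonstrate
correctness of the inference chain under its own model, not robustness to
real-data artefacts — the QC filter stage exists precisely because real
inputs violate the clean model.

## Numerical choices and degenerate inputs

- Expected-VAF cap ε = 0.01; CCF clip at 1.2; clonal threshold 0.8.
- EM (both uses): flat initialisation; multiplicity mixture tol 1e-10,
  ≤ 500 iterations; zero-likelihood rows guarded at 1e-300.
- Bootstrap with < 2 informative mutations returns an undefined-CI flag
  (the point estimate is reported with a degenerate interval); < 20
  informative mutations flags low confidence.
- `molecular_time(0, 0, …) = 0` with low-confidence flagging upstream.
- Mutant-allele assignment refuses germline VAFs outside [0.25, 0.75]
  (non-heterozygous input) and returns an explicit tie for major = minor.
- Timing of a locus with no overlapping gained segment returns a null
  result with a `not_timeable` flag rather than an error.

## Benchmarks and problem sizes

`lohtime.benchmarks` (used by the acceptance tests and
`scripts/acceptance.py`) runs: 3 states × 5 gain times × 50 tumors × 2000
SNVs for timing recovery; 10⁵ exact lineage draws per cell for the closed
forms; 5000 mutations × 3 purities at 80X for multiplicity accuracy; 5000
context draws for exposure recovery; 200 tumors × 200 bootstrap replicates
for CI calibration; 4000 background reads per sample for the telomere
ratio. These sizes give Monte-Carlo error comfortably inside each asserted
bound while keeping the whole suite in well under a minute per benchmark.

## Known limitations

- Single synchronous gain per segment; no sequential-gain or WGD timing.
- Closed forms limited to (2,0), (2,1), (2,2).
- Clonality is read-model based, not phylogenetic.
- Signature refitting assumes the catalog is complete for the sample.
- The linear-clock age conversion ignores developmental mutation-rate
  differences, so "age at gain" is an assumption-labelled bound.
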