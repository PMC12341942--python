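# Methods

## Scope and design

`phasebench` is a simulation benchmark, not an LAI method. It generates
two-way admixed genomes with known per-haplotype ancestry, emulates the damage
that statistical-phasing switch errors do to phase-based local ancestry calls,
and measures two downstream quantities: diploid call accuracy (Pearson R of
ancestry dosage) and tract-based admixture-time estimates. External tools
(HAPMIX, LAMP-LD, RFMix, FLARE, SHAPEIT4) are deliberately out of scope; their
output files can be *imported* and scored (`.msp.tsv`, ancestry FORMAT-field
VCFs), but the in-package caller is an oracle/stub driven by the ground truth.

## Tract models

**Founder-pool Markov model** (`simulate_markov_tracts`). Each chromosome is a
Markov path over a conceptual pool of founder haplotypes: switch points are
Poisson with rate T per Morgan, and the ancestry at the chromosome start and
after each switch is 0 with probability p (the pool's ancestry-0 fraction).
Merging same-ancestry neighbours gives canonical tracts whose ancestry-a
lengths are exponential with rate λₐ = T·p₍₁₋ₐ₎ per Morgan — the generative
model the time estimator inverts.

A subtlety verified by the test suite: the exponential law holds exactly on an
unbounded line, but *interior* tracts on a finite chromosome are a
length-biased sample (a long tract is more likely to touch a chromosome end
and be excluded). On 1.6-Morgan chromosomes this selection effect is easily
detectable at n = 5000 (KS D ≈ 0.075); the distributional test therefore runs
on a 100-Morgan chromosome where it is negligible. Estimation on realistic
chromosomes is unaffected because the censoring correction (below) handles
chromosome ends explicitly.

**Pedigree model** (`simulate_pedigree_tracts`). The admixed individual sits
in generation 0; its ancestors extend to unadmixed founders in generation T.
Each transmitted haplotype is the outcome of T successive meioses, each laying
crossovers as a Poisson process of rate 1 per Morgan and alternating between
the two parental haplotypes (no crossover interference — the Markov
approximation and the rate estimator both assume Poisson-like switch
processes, and interference is orthogonal to the phase-error mechanism under
study). Ancestry is assigned i.i.d. Bernoulli(p) per founder *haplotype* —
the 2^T leaves of one gamete's lineage tree — so one admixed individual
consumes 2^T founder individuals when founders are not reused
(`founders_required`). The two gametes are simulated over disjoint ancestor
trees (no shared ancestors, no inbreeding).

The implementation is top-down: inherited intervals flow through each meiosis
and only non-empty parts recurse, so cost scales with the number of realized
segments (≈ T × genome length in Morgans) rather than with 2^T founders.
Expected *visible* ancestry-switch density is 2p(1−p)·T per Morgan under both
models (junction density T, thinned by the probability that the two flanking
founder haplotypes differ in ancestry), which is what the convergence test
checks at T = 15.

## Haplotype panels and genotype synthesis

Panels stand in for diverged continental reference panels. Per marker, an
ancestral frequency q ~ Uniform(0.05, 0.95) is drawn; each population's
frequency follows the Balding–Nichols Beta(q(1−FST)/FST, (1−q)(1−FST)/FST),
giving Var(q_a|q) = FST·q(1−q). Default FST = 0.15, typical of African–
European differentiation. Markers are unlinked within panels: background LD is
*not* modelled, because none of the measured quantities (tract statistics,
estimator recovery, SER, dosage R) depends on it, and LD-aware panels would
require external haplotype data. This is the main respect in which passing
tests here do not certify behaviour on real data — real LAI methods exploit
LD, and their error processes are richer than the oracle's.

Genotypes are synthesized by segment copying: for every ground-truth tract one
panel haplotype of the matching ancestry is drawn uniformly (redrawn at every
tract boundary, including same-ancestry boundaries before merging would have
occurred — this avoids long-range donor identity) and its alleles are copied
over the tract's markers. No genotyping-error model is applied (array data
post-QC is the emulated regime); a config hook is left for future noise.

## Switch errors and SER

Switch errors are injected i.i.d. per heterozygous interval — the standard SER
generative model — flipping the haplotype assignment from the right-hand het
site until the next flip. Genotype content is untouched. The SER metric counts
consecutive heterozygous pairs whose relative phase orientation disagrees
between two phasings of the same genotypes, pooled across chromosomes and
individuals with pair weights (per-individual values are also reported). The
inject→measure round trip is exactly Binomial(n_intervals, rate), hence
unbiased. Real phasing error is clustered and covaries with allele frequency
and ancestry; the parametric injector reproduces only marginal rates (target
rates in the 3–5% range of statistically phased data at moderate sample
sizes).

The pipeline converts genotype-level switch records into phase-based oracle
calls by exchanging the two truth ancestry tracks downstream of each flip
point: this is what a hypothetical error-free phase-based caller would report
on mis-phased input, isolating the phase-error mechanism from LAI model error.
Separate oracle corruption knobs (tract-boundary jitter in cM, whole-tract
miscall probability, per-marker-interval track switches) emulate LAI model
error when a degraded caller is wanted.

## Admixture-time estimation

Marker-level calls are segmented into maximal constant-ancestry runs; each
tract boundary is placed at the genetic midpoint between flanking markers
(unbiased when the true boundary is uniform within the interval; the
convention is otherwise arbitrary). Per individual, both haplotypes' tracts
are pooled into one set of statistics (so the total length is 2L and the
per-ancestry terminal counts satisfy m₀ + m₁ = 2 × n_chromosomes; per-haplotype
statistics, where mₐ ≤ n_chromosomes, are available for diagnostics).

λ̂ₐ = (Nₐ − mₐ)/Σxᵢ,ₐ is the maximum-likelihood rate of a censored exponential:
only tract *ends* cut off by a chromosome's right edge are censored, so mₐ
counts, per chromosome per haplotype, the single rightmost tract. Dropping the
correction strictly inflates λ̂ (and hence T̂) whenever mₐ > 0. p̂ₐ is the
genome fraction of ancestry a; T̂ averages the two solutions of λₐ = p₍₁₋ₐ₎T.
Individuals with a single-ancestry genome (possible at extreme p) yield a
flagged missing estimate, excluded from cohort means with a count — never a
silently propagated infinity.

Numerical notes: coordinates are cM internally, converted to Morgans only in
the estimator; tract tiling is validated to 1e-6 cM; rasterization at marker
spacing s loses tracts shorter than ~s, which biases T̂ down by roughly the
lost-switch fraction (≈1% at 1-cM spacing for T = 5), well inside the
Monte-Carlo tolerances used.

## Phase correction

Following the ancestry-based rephasing idea, the corrector scans left to right
and, wherever the two call tracks change ancestry in opposite directions
within `window` markers (default 1 = simultaneous, since the injected error
flips both tracks at one site; "nearby" has no canonical width), exchanges the
haplotype assignment of calls and genotypes from the detected point onward.
The operation never alters diploid dosage and is idempotent. Its intrinsic
blind spot is switches inside ancestry-homozygous regions, which leave no
ancestry signal; with oracle calls every ancestry-visible switch is a clean
double switch, so correction restores the clean-phase time estimate exactly —
against real, noisy LAI output the repair is partial.

## Experimental grid

`run_grid` reproduces the benchmarking design at configurable scale: cells are
the product of T values, p values, switch rates and replicates (defaults: 3
replicates × 30 individuals per cell, matching the study design), each cell
seeded deterministically from (master seed, cell index) so cells are
independent and individually reproducible byte-for-byte. Per-cell outputs:
realized SER, pooled dosage R, mean T̂ and mean deviation from the true T.
Because the oracle caller commits no dosage errors, R stays 1 under pure
switch corruption — by design, as the metric is phase-free; enabling the
miscall/jitter knobs produces R < 1.

Problem sizes in the shipped tests and acceptance script (100 diploid
individuals on a 22 × 163.2 cM map for estimator recovery; 30-individual
cohorts on marker grids of 0.2–1 cM for end-to-end runs) were chosen so the
whole suite completes in well under a minute while keeping Monte-Carlo error
far below the asserted tolerances.

## Known limitations

- No background LD in panels; no genotyping error; no missing data.
- The phasing-error injector is marginal-rate-only (no clustering, no
  dependence on p or panel strategy).
- The oracle caller cannot reproduce LAI-model-specific error structure;
  imported real tool output is required for that.
- Crossover interference is not modelled in the pedigree simulator.
- Two-way admixture only; autosomes only; no sex-specific maps.
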