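# phasebench

Benchmarking machinery for **local ancestry inference (LAI) under phasing
error**. The package simulates two-way admixed genomes (African/European-style
admixture) with known ancestry tracts, converts them to phased genotypes by
copying alleles from diverged reference panels, injects haplotype **switch
errors** at controlled rates, scores diploid LAI accuracy, applies
ancestry-based phase correction, and estimates **time since admixture** from
tract lengths — making it possible to study, at desk scale, how phase quality
propagates into downstream demographic inference.

It is aimed at population geneticists who want a controlled sandbox for the
question: *how much do switch errors in statistically phased data distort
phase-based LAI calls and the analyses built on them?*

## The model

**Tract simulation.** Two generators produce ground-truth haploid ancestry
tract sets:

* a *founder-pool Markov model*: along each chromosome, switch points form a
  Poisson process of rate `T` per Morgan (T = generations since admixture),
  and the ancestry after each switch is 0 ("African") with probability `p`;
  after merging, ancestry-`a` tracts end at rate `T·p₍₁₋ₐ₎` per Morgan;
* an explicit *depth-T pedigree*: each meiosis lays Poisson(1/Morgan)
  crossovers and alternates parental haplotypes; founder haplotypes in
  generation T carry i.i.d. Bernoulli(p) ancestry. Without founder reuse such
  a pedigree needs 2^T founders per admixed individual (128 at T = 7).

**Admixture-time estimator.** Per diploid individual, pooling both haplotypes'
tracts of ancestry a ∈ {0,1} with Morgan lengths x₍ᵢ,ₐ₎:

    λ̂ₐ = (Nₐ − mₐ) / Σᵢ x₍ᵢ,ₐ₎            p̂ₐ = Σᵢ x₍ᵢ,ₐ₎ / 2L
    T̂  = ½ (λ̂₀/p̂₁ + λ̂₁/p̂₀)

where Nₐ counts tracts, mₐ counts tracts cut off by a chromosome's right end
(their terminating crossover is censored), and L is the haploid genome length
in Morgans. Under the founder-pool model λₐ = p₍₁₋ₐ₎·T, so each ancestry gives
an estimate of T and the two are averaged.

**Accuracy metric.** Diploid ancestry dosage (count of ancestry-1 haplotypes
per marker, 0/1/2) is concatenated across all markers and individuals, and
inferred vs true dosage is scored with Pearson's R; probabilistic callers are
scored through the expected dosage E[a] = Σ P(a)·a. Because dosage is
phase-free, switch errors alone never change R — yet they fragment haplotype
tracts and inflate T̂, which is precisely the effect under study.

**Phase correction.** A switch error inside a region where the two haplotypes
carry different ancestries makes *both* call tracks flip in opposite
directions at the same position; detecting such double switches and exchanging
the haplotype assignment downstream (as TRACTOR does) repairs them. Switches
in ancestry-homozygous stretches are invisible to this signal.

## Worked example

```python
import numpy as np
from phasebench import *

gmap = make_uniform_map(22, 163.2, 0.2)        # ~35.9 Morgans, 0.2-cM marker grid
rng = np.random.default_rng(7)
panels = simulate_panels(gmap, n_hap_per_pop=70, fst=0.15, seed=rng)

# one admixed individual, T = 10 generations, p = 0.5
h0 = simulate_markov_tracts(gmap, T=10, p=0.5, seed=rng)
h1 = simulate_markov_tracts(gmap, T=10, p=0.5, seed=rng)
gt = synthesize(h0, h1, panels, gmap, seed=rng)

est = estimate_time(tract_stats([h0, h1], gmap))
print(f"T_hat from true tracts = {est.t_hat:.2f}")

# corrupt the phase at a realistic statistical-phasing error rate
gt_bad, records = inject_switch_errors(gt, rate=0.035, seed=rng)
print(f"SER = {ser(gt, gt_bad).ser:.4f}")

# what a perfect phase-based caller would report on the mis-phased input
truth = oracle_lai([(h0, h1)], gmap, panels[0].markers, mode="perfect")
tracks = apply_switches_to_tracks(truth.tracks[0], records[0], panels[0].markers)
observed = PhasedAncestryCalls(panels[0].markers, ["sim_0_0"], tracks[None])
(pair,) = extract_tracts(observed, gmap)
print(f"T_hat from mis-phased calls = {estimate_time(tract_stats(pair, gmap)).t_hat:.2f}")

fixed, _, _ = correct_phase(observed, None)
(pair_fixed,) = extract_tracts(fixed, gmap)
print(f"T_hat after phase correction = {estimate_time(tract_stats(pair_fixed, gmap)).t_hat:.2f}")
```

Output:

```
T_hat from true tracts = 10.46
SER = 0.0343
T_hat from mis-phased calls = 16.76
T_hat after phase correction = 10.35
```

A 3.4% switch-error rate — typical of statistical phasing at moderate sample
sizes — inflates the admixture-time estimate from ~10.5 to ~16.8 generations;
the diploid dosage (and hence Pearson R) is untouched, and the ancestry-based
phase correction removes nearly all of the bias. The full experimental grid
(T × p × switch rate × replicates) is driven by a YAML config:

```
phasebench grid --config grid.yaml --out results/
```

with subcommands `simulate`, `corrupt`, `ser`, `call`, `fix`, `score` and
`time` for the individual stages (see `phasebench --help`). External LAI
output can be scored through the RFMix v2 `.msp.tsv` reader, a per-haplotype
ancestry-FORMAT-field VCF reader, or the internal TSV dialect.

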