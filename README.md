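# domainloss

Inference of protein-domain **total loss rates** on a dated species tree,
with joint false-positive flagging, trait statistics and a
differential-retention simulation.

## The problem

Protein domains (e.g. Pfam families) are born rarely and can be lost from a
lineage entirely — every copy gone. Across a dated phylogeny, the
presence/absence pattern of a domain carries information about its per-My
rate of total loss, and trends in domain traits (intrinsic structural
disorder, hydrophobic residue clustering) across age cohorts can arise
purely from *differential retention*: domains with some trait values
survive total loss preferentially. Testing that hypothesis needs (i)
reliable loss rates from noisy presence calls, (ii) per-domain trait
statistics, and (iii) regressions and simulations connecting them. This
package implements that full stack and a synthetic-data generator that
produces trees, presence patterns with planted errors, and sequences, so
every stage is testable offline against known truth.

## The model

A domain arises exactly once (Dollo parsimony), on the branch basal to the
smallest clade containing every species that has it, and is subsequently
only lost. Loss is a Poisson process with rate λ (losses/My), so the
probability of total loss on a branch of length *t* is 1 − exp(−tλ). With
retention branches indexed *k* and loss branches *j* (the basal branches of
the maximal absent subtrees), the likelihood is

    L(λ) = ∏ₖ exp(−tₖ λ) · ∏ⱼ (1 − exp(−tⱼ λ))

maximized by safeguarded Newton iteration on log λ, initialized at the
parsimony rate (#losses / Σtₖ), with runaway fits (λ̂ > 1/My) reset to the
initialization.

Presence calls can be spurious. With priors f_c (a coding-evidence presence
is false) and f_i (an intergenic-scan-only presence is false), flip sets
F_C ⊆ P_C and F_i ⊆ P_i have joint likelihood

    L = L_loss(λ̂ | P − F) · f_c^|F_C| (1−f_c)^|P_C−F_C| · f_i^|F_i| (1−f_i)^|P_i−F_i|

searched greedily over maximal monophyletic presence clades; an outer
empirical-Bayes loop re-estimates (f_c, f_i) from pooled flips until
convergence. A separate screen z-scores each observed Dollo loss count
against random placement of the same number of presences.

Trait statistics: per-domain ISD is the mean disorder over residues then
instances; hydrophobic clustering is a null-normalized index of dispersion
of {L,I,V,F,M,W} in blocks of six residues, averaged over reading frames
(1 = random placement, >1 clustered, <1 interspersed). Loss rates are
Box–Cox transformed and regressed on traits with a continuous
one-breakpoint model (Davies-corrected test against the linear null); the
fitted rate map drives an exponential-survival simulation of a resampled
young cohort.

## Worked example

Generate a contaminated synthetic data set (64 species, 800 My, 200
domains, intergenic false-positive fraction 0.2), fit loss rates before and
after quality control, and recover the planted error rates:

```python
import numpy as np
from domainloss import SimConfig, eb_loop, dollo_reconstruct, mle_loss_rate
from domainloss.synthetic_data import (make_tree, sample_traits,
                                       make_presence, realized_fp_fractions)

config = SimConfig(n_tips=64, n_pfams=200, f_i=0.2, f_c=1e-3, seed=11)
rng = config.rng()
tree = make_tree(config, rng)
traits = sample_traits(config, rng)
patterns, truth = make_presence(tree, traits, config, rng)

fits0 = [mle_loss_rate(dollo_reconstruct(tree, p.present, p.pfam_id))
         for p in patterns]
print(f"mean loss rate before QC: {np.mean([f.lambda_hat for f in fits0]):.5f} /My")

model, flips, fits = eb_loop(patterns, tree)
print(f"EB converged in {model.iteration} iterations: "
      f"f_c = {model.f_c:.2e}, f_i = {model.f_i:.3f}")
fc, fi = realized_fp_fractions(truth)
print(f"planted (realized) rates:  f_c = {fc:.2e}, f_i = {fi:.3f}")
print(f"mean loss rate after QC:  {np.mean([f.lambda_hat for f in fits]):.5f} /My")
```

prints

```
mean loss rate before QC: 0.00052 /My
EB converged in 2 iterations: f_c = 1.00e-09, f_i = 0.195
planted (realized) rates:  f_c = 0.00e+00, f_i = 0.187
mean loss rate after QC:  0.00029 /My
```

The loop recovers the planted intergenic error fraction (0.195 vs the
realized 0.187), collapses the coding prior to its floor (no coding errors
were planted at this seed), and removing the spurious scattered presences
lowers the mean fitted loss rate — contamination inflates apparent loss.

A command-line interface mirrors the library:
`domainloss simulate`, `fit-loss`, `fit-fp`, `screen`, `traits`,
`trends fit`, `trends simulate` (see `domainloss --help`).

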