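# Methods

## Data model and coordinates

A sample's methylome is a table of CpG units: chromosome, 1-based position
of the + strand C, methylated read count mC and total count. Internally all
interval arithmetic is 0-based half-open; conversion happens only at the
I/O boundary. Counts on the two strands of a symmetric CpG are pooled onto
the + strand C *before* the coverage filter — analysis operates on
reference CpG dinucleotides, and collapsing first maximises usable
coverage (a flag restores strand-separate filtering). Sites below the
coverage floor (default 5×) are absent records, never imputed zeros, so a
"level of 0" always means observed unmethylated reads.

Region levels come in two flavours: the pooled level Σ mC / Σ total (used
as the default region statistic, since it weights sites by information)
and the unweighted mean of site levels (reported alongside).

## DMR calling

The site model is beta-binomial: replicate j of group g contributes
mC ~ BetaBin(n_j, μ_g, φ_g), φ ∈ [0, 1), φ = 0 being binomial.

1. **Smoothing.** Group levels are smoothed with a coverage-weighted
   moving window of 500 bp total span centred on each site. An isolated
   site keeps its raw level.
2. **Dispersion.** The per-site, per-group method-of-moments estimator
   averages ((p_j − μ)² · m/(m−1) · n_j/(μ(1−μ)) − 1)/(n_j − 1) over
   covered replicates (the m/(m−1) factor corrects for estimating μ from
   the same data; the estimator is unbiased under the beta-binomial moment
   structure). With two residual degrees of freedom per site at 3
   replicates, the raw values are noisy, so they are shrunk toward the
   genome-wide mean with an empirical-Bayes weight (prior weight 20 vs the
   site's m − 1); boundary sites (μ(1−μ) ≈ 0) and single-replicate sites
   take the prior. Results are clipped to [0, 0.99).
3. **Wald test.** The variance of a smoothed group mean is
   μ(1−μ) · Σ_w A_i / (Σ_w N_i)² over the window, with per-site
   information A_i = Σ_j n_ij (1 + (n_ij − 1) φ_i) — i.e. the exact
   beta-binomial variance of the coverage-weighted window mean under local
   constancy of μ. SE² is floored at the binomial variance of one pooled
   pseudo-observation, p̃(1−p̃)/(N+1) with p̃ = (ΣmC + 0.5)/(N + 1), so
   boundary groups never produce infinite statistics; exact zero
   differences get p = 1. Two-sided p-values come from the normal
   reference; BH adjustment runs across all tested sites. Tested sites
   need at least one covered replicate per group.
4. **DMC/DMR assembly.** DMCs are sites with |Δβ| > 0.1 and FDR < 0.01.
   Consecutive same-sign DMCs within 100 bp chain together unless an
   intervening non-significant CpG reverses the sign with |Δβ| above the
   DMC threshold. Chains need ≥ 4 DMCs and ≥ 50 bp span. Region group
   levels average the smoothed levels of *all* tested CpGs in the span —
   interleaved non-DMCs therefore dilute the region Δβ, which is exactly
   what the post-filter (keep if |Δβ| ≥ 0.1 or relative change > 0.2,
   relative change = |Δβ|/max(β_control, 0.01)) exists to catch. A
   candidate whose diluted Δβ flips sign against its chain is dropped.
   Orientation is fixed as stress − control; "hypo" means the stress group
   is de-methylated.

The merging gap, the treatment of intervening CpGs and the relative-change
formula are not uniquely determined by the verbal description they
implement; all three are explicit parameters with the defaults above.

## Heritability

Region levels per replicate are pooled-count levels over sites with ≥ 5×
coverage. Two routes:

* **Per-generation route** (primary): Welch t-test on the 3 v 3 replicate
  levels within each generation (pooled-variance assumptions are
  untestable at n = 3, so the unequal-variance form is the safer default),
  BH-adjusted across the F0-DMR universe within that generation.
  Significance additionally requires |Δβ| ≥ 0.1 or relative change > 0.2.
  Label truth table: significant in F0+F1+F2 → transgenerational; F0+F1
  only → intergenerational; F0 only → F0-only; anything else (including
  any uncallable generation) → irregular. Direction consistency across
  generations is reported but not required (a strict mode exists).
* **Cross-generation route**: a paired one-tailed exact Wilcoxon
  signed-rank over the generation-mean (control, stress) pairs, the tail
  set by the F0 direction, n = 3 for the transgenerational scope and
  n = 2 for the intergenerational scope. The exact one-sided p at n = 3
  can never fall below 1/8 (1/4 at n = 2), so a 0.01 alpha would be
  vacuous; the operative alpha defaults to that attainable floor, making
  the test a direction-consistency screen, combined with the effect rule
  applied in every generation in scope. The alpha is a parameter; the
  stricter setting remains expressible.

The headline "inherited" percentage is inclusive (intergenerational +
transgenerational), matching the "x % inherited, of which y %
transgenerational" reporting convention. Attenuation of |Δβ| down the
generations is tested with one-sided paired t-tests on the heritable set
(skipped below two regions).

## Reprogramming and escape

Stage levels are single-profile pooled counts (one scWGBS-style profile
per stage/group — no replicate testing at the embryo level). Categories
against paternal sperm use Δ = embryo − sperm with delta_min = 0.1:
Δ ≤ −0.1 is the hypo branch (free-hypo if the embryo level ≤ 0.1, i.e.
fully erased), Δ ≥ +0.1 the hyper branch (full-hyper if ≥ 0.9), else
unchanged. The 0.1/0.9 cutoffs quantify the verbal notions "completely
erased"/"completely methylated" at the same 0.1 granularity the rest of
the pipeline uses; all three are parameters. total-hypo/total-hyper are
derived sums, never counted independently, and the five base categories
partition the covered DMRs.

The heritable vs un-heritable contrast draws an equal-sized, seeded,
|Δβ|-decile-matched sample of non-inherited F0 DMRs (matching toggleable),
computes stress-group categories per stage and tests each category's 2×2
table with a two-sided Fisher exact test; a stage counts as significant
when any Holm-adjusted category p falls below 0.01. Trajectories threshold
stress − control at ±0.1 per stage into hypo/hyper/unchanged; 3 states ×
3 stages gives 27 patterns, all enumerated in the frequency table. (A
"36 combinations" figure sometimes quoted for this scheme does not follow
from 3³; the package enumerates the 27.)

Escape profiling considers regions highly methylated in sperm (> 0.8):
maintained = |embryo − sperm| < 0.1, erased = embryo ≤ 0.1, remainder
intermediate — with the > 0.8 restriction the three fractions partition.
VM-IAP regions with sperm-sample SD > 0.1 are removed before site-level
analysis; per CpG, de-methylated means sperm − ICM ≥ 0.1, completely
erased additionally ICM ≤ 0.1, reestablished (among de-methylated sites)
PS − ICM ≥ 0.1, and reestablished-below-sperm additionally
PS < sperm − 0.1. At ~10× embryo coverage the hard 0.1 cutoff on observed
levels biases the "completely erased" fraction a few points below the
generating probability (a site at true level 0.05 shows ≥ 2 methylated
reads in 10 reasonably often); recovered erase/reestablish proportions
should be compared with that counting noise in mind.

## sncRNA

RPM = 1e6 · count / library size; when the table is library-complete the
per-sample RPM sums are exactly 1e6. Entities (subclasses by summed
counts, or unique sequences) are tested only when Σ counts > 15 and
Σ RPM > 1 over the six samples; the test is a pooled-variance Student t
on RPM at raw p < 0.05 — deliberately uncorrected, as is common for
low-replicate sperm sncRNA screens (a BH option exists). The pooled form
is the default because at n = 3 on overdispersed counts the
unequal-variance form is measurably conservative (~3.5 % at nominal 5 %),
while the pooled test sits at the nominal rate; a Welch flag is provided.

Seed matching slides every 7-mer of the sequence (direct) and of its
reverse complement (antisense) over the DMR sequence, extends each hit
maximally without gaps, and records the longest extension per (sequence,
DMR, mode); windows containing N never match. The longest reported match
equals the true longest common substring (with the reverse complement in
antisense mode) whenever that length is ≥ 7. Matching steps by 1 nt and
reports longest-only per pair and mode. The alignment burden of a DMR is
the number of distinct differential sequences with any match; arms are
compared with a one-sided Mann-Whitney U. tsRNA target pairing reports
(tsRNA, mRNA) pairs sharing any perfect antisense 7-mer.

## Synthetic data generator

The generator is first-class code and defines the conditions every
validation runs under:

* **Genome**: 2 chromosomes assembled from planted regions separated by
  ~2 kb of background CpGs (geometric spacing, mean 100 bp) plus a
  background tail. Background levels are block-constant bimodal domains
  (mean 10 sites/block; 75 % mass near high methylation, matching a sperm
  methylome), so the caller's local-constancy smoothing assumption is well
  specified. Coverage is Poisson (sperm 20×, embryo 10×); counts are
  beta-binomial with dispersion 0.02 — low biological variability, as
  expected for inbred littermate sperm pools.
* **Planted DMR classes**: 100 transgenerational / 400 intergenerational /
  1,500 F0-only regions, |Δβ| = 0.3 in F0 attenuated 0.8×/generation for
  the heritable classes, direction away from the nearer boundary (hence
  mostly de-methylated). Ordinary DMRs are 300 bp with island-like 10 bp
  CpG spacing (~30 CpGs) — the scale the caller is validated on.
  Heritable candidate regions default to CpG-island-scale 3 kb blocks
  (~300 CpGs): the replicate-level region estimate carries a counting-noise
  floor of about sqrt(μ(1−μ)(1+(c−1)φ)/(cK)) ≈ 0.02 · sqrt(30/K) at
  c = 20×, and resolving the attenuated F2 effect (0.192) with a 3 v 3
  t-test under BH across 2,000 regions requires the larger K; the choice
  was fixed by this power analysis, not by the caller's behaviour.
* **Embryo dynamics**: ICM low (0.05) except escape regions (3 % of TE and
  VM-IAP regions copy sperm); PS bimodal with half the background sites
  reestablished to the paternal level; PGC lowest (0.03). Heritable
  planted DMRs reestablish at PS with a stress-group deficit of 0.3 —
  erased at ICM and PGC in both groups, so the heritable-vs-unheritable
  contrast is PS-specific by construction. VM-IAP CpGs erase with
  probability 0.85, reestablish with 0.80, and reestablish below sperm
  with 0.48; 18 of 105 VM-IAPs get per-sample level wobble (SD ≈ 0.2) so
  the SD filter has true positives to find.
* **sncRNA**: negative-binomial counts (size 25) around lognormal means;
  planted differential sequences (60 tsRNA up, 100 miRNA down, 60 rsRNA
  down, fold 3) are drawn at high abundance so the fold change is
  resolvable at n = 3 with ~90 % power. A fraction 0.9 of heritable DMR
  sequences carries 12 embedded 8–10 bp reverse complements of planted
  sequences; with a ~45 % per-pair 7-mer chance-match background between
  a ~30 nt sequence and a 300 bp DMR, fewer embeds would leave the
  planted burden contrast unresolvable at 100 DMRs/arm. These counts are
  generator design, set by that calculation.
* Null-calibration configurations plant nothing at all (including no
  variable VM-IAPs, which are genuine group-independent signal sources).

Everything is driven by one seeded `numpy.random.default_rng` stream and
is bit-reproducible. What the generator does *not* emulate: sequence
context and CpG-island structure beyond spacing, conversion-failure noise,
SNP effects, allele-specific methylation, chromatin covariates, and any
relationship between the DMR FASTA sequences and the methylome
coordinates. Passing tests therefore demonstrate that the statistical
machinery recovers planted truth under its own model assumptions — not
robustness to the full messiness of real bisulfite data.

## Numerical and scale choices

Simulation scales are chosen so the full suite runs in a few minutes on
one CPU: null calibration uses 100k CpGs × 10 seeds, recovery the
2,000-region design above (~250k CpGs, 18 samples), the reprogramming
contrast 20 region-level runs of 300 regions/arm, and the pipeline's
default desk-scale run 202 planted regions. Degenerate inputs are handled
explicitly: zero-coverage totals are absent records; zero-variance tests
return p = 1 at zero effect; empty Fisher margins are flagged degenerate
with p = 1; empty composition directions report NaN percentages; ties at
zero difference use the signed-rank zero-exclusion rule.

## Known limitations

The caller approximates local-FDR thresholding by BH and does not
reproduce any particular reference implementation's internals; the Wald
reference is normal, which is anti-conservative at very low coverage
(mitigated by the variance floor and the ≥ 5× rule). Heritability power
at n = 3 replicates is intrinsically limited by the t distribution's
heavy tail at 2–4 degrees of freedom — see the region-size power note
above. The sncRNA screen uses the conventional uncorrected
p < 0.05 and is not an FDR-controlled discovery procedure. Seed matching
is ungapped and exact; mismatch-tolerant or gapped homology is out of
scope.
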