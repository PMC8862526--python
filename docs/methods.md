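# Methods

## The inbreeding model and its ground truth

Each simulated line descends from one founder pair (4 founder haplotypes)
through an F1 brother–sister pair and then `generations` single
full-sib-pair matings; the sampled individual is the male of the final
brood. Meiosis places a Poisson number of crossovers per chromosome (mean
`length_Mb × rate_cM_per_Mb / 100`, no interference) at uniform positions,
and gametes are recorded as founder-segment mosaics, so the true ancestry
of every base pair of every line is known exactly. A line is *autozygous*
wherever its two haplotypes descend from the same founder haplotype; the
realized genome-wide autozygous fraction has expectation equal to Wright's
full-sib recurrence `F_t = (1 + 2F_{t-1} + F_{t-2})/4` (F₁ = 0.25, F₉ =
0.859375), which the suite verifies per generation over 500 replicate
pedigrees to within ±0.02.

**Founder haplotypes.** Segregating sites are placed uniformly; derived
allele frequencies are drawn from the neutral frequency spectrum
(probability ∝ 1/i on a 2N = 200 grid) and haplotype alleles are
independent Bernoulli draws at those frequencies. Site density is solved
from the target per-site diversity (default π = 0.0037, a realistic value
for a polymorphic wild fish population): with E[2p(1−p)] ≈ 0.169 under this
spectrum, a 24-Mb genome carries ≈ 0.52 M sites. The derived allele is
labelled ALT with probability 0.8 so that polarization against the recorded
true ancestral allele is exercised in both directions.

**Sex region.** Sex is modelled only as an obligate-heterozygous segment:
the founder father's second haplotype is Y-tagged, its alleles inside the
segment redrawn at frequency 1/2 (a diverged non-recombining Y). Sons
always inherit the father's Y ancestry across the segment and daughters the
X ancestry, i.e. recombination is suppressed there, and the sampled males
are therefore heterozygous at roughly half of the segment's sites. There is
no X/Y divergence outside the segment.

**Outcrosses.** With probability `outcross_prob` (default 0.05, matching
the few-percent incidence of unexpectedly heterozygous lines in real
panels) the father of one mid-pedigree generation (uniform on 2..G−1) is
replaced by an individual from an unrelated lineage inbred to the same
depth. The expected final autozygosity then follows the kinship recursion
restarted with inbred-but-unrelated ancestors — the test suite checks this
against an independent implementation of that recursion, since naively
rerunning Wright's recurrence from zero ignores the restart ancestors' own
inbreeding and underestimates the result.

**Genotype error.** Each genotype flips with rate `genotype_error_rate`
(default 10⁻³): heterozygotes to a random homozygote, homozygotes to
heterozygous. In fixed regions this is the only source of heterozygous
calls, giving the HMM's low-rate emission state; in unfixed regions counts
scale with founder π. These are exactly the two regimes the block caller
must separate.

## Homozygosity HMM

Heterozygous-genotype counts per line per 10-kb window are modelled as a
hidden Markov chain with Poisson emissions. Parameters (initial
distribution, K×K transitions, K rates) are shared across the panel: every
line × chromosome sequence is one realization, and Baum–Welch EM pools
sufficient statistics over all of them ("joint training"). Decoding is per
line, chromosomes independent, each restarting from the initial
distribution — windows are not physically adjacent across chromosomes.

Numerical choices: all recursions in log space; emission rates floored at
10⁻³ to avoid log(0); λ initialized from the 25th/97.5th percentiles of the
pooled counts (K = 2) or evenly spaced quantiles (K ≥ 3), with ties broken
by a seeded jitter; transitions start sticky (stay 0.99); convergence at
|Δ log L| < 10⁻⁶ or 500 iterations; states relabelled by ascending λ after
every M-step so "state 0 = most homozygous" is invariant to initialization.
Viterbi ties resolve toward the lower state index. Both Viterbi and
forward–backward posterior decoding are provided; Viterbi is the
block-calling default. Correctness is checked against exhaustive-path
enumeration (all K^T paths) on random chains — up to T = 12 for K = 2 and
T = 8 for K = 4, where 4¹² ≈ 16.7 M paths per chain would make the oracle,
not the decoder, the bottleneck.

**Sex-region refinement.** A 4-state fit gives graded heterozygosity
levels. Two per-window tracks summarize the panel: the fraction of lines
with more than 5 heterozygous SNPs (strict inequality), and a weighted
track in which each line contributes the min–max-normalized emission rate
of its decoded state (w₀ = 0, w_{K−1} = 1) — the normalization is our
choice; any monotone weighting that anchors the extreme states behaves
similarly. The refined region is the longest contiguous run of windows
with weighted value ≥ `min_level` (default 0.8) spanning at least
`min_span`, reported 1-based inclusive; both knobs are exposed rather than
hard-coded because the boundary of an obligate-heterozygous region is a
threshold choice, not a property of the model.

## Population-genetic statistics

- **F_ST**: Hudson's estimator, chosen for robustness at small and unequal
  sample sizes; windows aggregate as ratio-of-averages (Σnum/Σden), the
  alternative mean-of-ratios being exposed for comparison. Windows need
  ≥ 50 usable (polymorphic-in-either) sites.
- **π**: per site 2pq·n/(n−1) summed over sites and divided by the full
  window span (not accessible sites) — the convention available to
  VCF-only input; windows without sites are 0, not missing.
- **LD**: r² is the squared Pearson correlation of unphased genotype
  dosages (composite LD; inbred lines are effectively homozygous and
  unphased), over samples non-missing at both sites, pairs within 10 kb,
  MAF ≥ 0.10, means in 100-bp distance bins.
- **Inbreeding F**: the moment (excess-homozygosity) estimator
  (O_hom − E_hom)/(L − E_hom) against supplied reference frequencies.
- **η²**: exactly SS_between/SS_total from one-way ANOVA — no small-sample
  ω² correction — as the broad-sense heritability proxy appropriate when
  lines are near-isogenic. Its null expectation (k−1)/(N−1) is verified by
  permutation.

## Introgression

Derived-allele frequencies for (((P1, P2), P3), O) come from polarizing ALT
frequencies against a per-site ancestral-allele table (sites with an
unusable ancestral call are dropped and tallied). D is the standard
ABBA−BABA frequency contrast; f̂_d divides the D numerator by the same
numerator evaluated with the donor set to whichever of P2/P3 has the higher
derived frequency at each site, and is reported only in windows with D > 0
(its validity domain); negative-D windows keep D and emit missing f̂_d.
Sliding windows are 500 kb with a 250-kb (half-window) step and ≥ 250 SNPs.
With finite population samples f̂_d underestimates the true admixture
fraction — frequency noise inflates the max(p2, p3) denominator — so the
admixture-recovery check asserts ±0.1 around a true fraction of 0.3 with
30 diploids per population rather than exact recovery; the f̂_d = 1
identity when P2 ≡ P3 holds exactly at the frequency level and is tested
there.

## Relatedness and sibling sharing

IBS between two lines is the mean over co-non-missing sites of
(2 − |dosage difference|)/2; clustering is average linkage on 1 − IBS with
samples pre-sorted lexicographically so exact ties resolve identically
across runs; dendrograms export as Newick.

Two sibling lines — independent G-generation pedigrees from the same
founder pair — are expected to fix the same founder haplotype at 1/4 of
the genome, since each line's fixed haplotype is an independent uniform
draw from the family's four. The windowed estimator counts 10-kb windows
with mean IBS ≥ 0.99 ("identically fixed"), with the identity floor
tolerating residual genotype error. Its denominator is, by default, the
windows in which *both* lines are fixed (per-window heterozygous-genotype
fraction ≤ 0.05): at G = 9 about 14% of each genome is not yet autozygous,
and including those necessarily-non-identical windows would dilute the
estimate to ≈ F₉²/4 ≈ 0.19 — a statement about fixation progress, not
about parental haplotype sharing. The unconditional variant is available
as `denominator="all"`. Both behaviors follow from the pedigree arithmetic
and are verified against a locus-level pedigree simulation.

## Problem sizes and determinism

The default "desk-scale" genome is 24 chromosomes × 1 Mb at a uniform
3 cM/Mb with ≈ 22 sites/kb, chosen so that a full 80-line panel simulates
and analyses in seconds while preserving the pedigree expectations
(autozygosity, sharing, recurrence) exactly; the acceptance script and the
heavier tests use 80–200 lines, 100 sibling pairs, 500 replicate pedigrees,
1000 Viterbi-oracle chains and 20 sex-region seeds at this scale. All
randomness flows from a single seed through `numpy.random.SeedSequence`
spawning (per-family founder streams, pedigree stream, error stream), so
every output is bit-for-bit reproducible given (seed, config).

## Known limitations

- Founder haplotypes carry **no background LD** (sites are independent
  draws), so panel LD reflects only shared-descent block structure and the
  simulated LD-decay curve is much flatter than in real data; LD decay
  functions are exercised for correctness, not for realistic decay shapes.
  A coalescent founder generator (e.g. msprime) could replace the SFS
  sampler where realistic LD matters.
- No mutation, selection or pedigree mortality during inbreeding; pedigree
  expectations are therefore exact rather than merely approximate.
- The allele-frequency spectrum is neutral-equilibrium; no attempt is made
  to mimic a specific population's spectrum beyond the π calibration.
- Sex is a single forced-heterozygous segment; no X/Y sequence divergence
  elsewhere, no XX males.
- f̂_d's small-sample downward bias is inherited from the estimator itself;
  the admixed scenario is frequency-based (Balding–Nichols drift), not a
  genealogical simulation.
- Structural variation, inversions and repeat-driven diversity
  heterogeneity are out of scope.
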