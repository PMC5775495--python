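# Methods

This note records the statistical models the package implements, the
knobs that matter, what the simulator does and does not emulate, and
the design choices made where more than one defensible option existed.

## Genotype data model and filters

A dataset is a samples × sites matrix of alt-allele dosages
({0, 1, 2}, missing = −1) with a parallel read-depth matrix and a site
table (chrom, 1-based pos, ref, alt).  Only biallelic SNPs exist in
the model; multi-allelic and non-SNP VCF records are skipped on input
and counted in the log.  Heterozygous genotypes (0/1, 0|1, 1|0) all
map to dosage 1.

The standard GBS screens, in order:

| filter | default | semantics |
|---|---|---|
| per-genotype depth | ≥ 5 reads | genotype masked, site kept |
| per-site call rate | > 0.80 | **strict** inequality |
| per-site minor-allele frequency | > 0.05 | **strict**, computed from non-missing dosages after depth masking |

The strict inequalities are deliberate and documented so users who
prefer ≥ can nudge the threshold down by an epsilon.  MAF uses only
callable genotypes as the denominator, because masking happens first;
when an analysis runs on a sample subset, MAF is recomputed on that
subset.  Filtering is idempotent, preserves genome order, and never
rewrites a retained value.

As a paralog-collapse diagnostic, per-site observed heterozygosity is
reported with a flag above 0.60; on clean data the flagged fraction is
the binomial tail P(X/n > 0.6) under within-population Hardy–Weinberg
genotype frequencies.

## Ancestry proportion S and interclass heterozygosity H

Diagnostic markers are sites where, after an internal ≥10-read mask,
every called genotype in the species-1 references is homozygous for
one allele and every called genotype in the species-2 references is
homozygous for the other (at least one call per side).  The panel
records orientation (which allele is the species-1 allele) and the
parental frequencies of that allele, fixed at (1, 0).  The likelihood
retains general (p1, p2) support for soft panels, but the default is
the strictly diagnostic (1, 0) because the panel construction already
conditions on fixation; re-estimated frequencies are a user-supplied
extension, not the default.

Per locus, a diploid's two gene copies fall in one of three ancestry
classes with probabilities (S − H/2, H, 1 − S − H/2); genotype
probabilities mix these with the parental allele frequencies.  The
joint MLE is found on a dense grid over the triangle
H ≤ 2·min(S, 1−S) (step 0.005 on both axes) followed by two zoom
rounds (final resolution 5·10⁻⁵).  A grid-plus-refinement search was
chosen over gradient methods because the domain is a small constrained
2-D triangle and the likelihood is cheap after collapsing loci to
sufficient statistics; on strictly diagnostic panels the result is
validated against the closed form Ŝ = (2n₁₁ + n₁₂)/2n, Ĥ = n₁₂/n.
Step 0.005 resolves differences well below the spacing between hybrid
classes.  Samples with no called panel genotype get no estimate (with
a warning); samples with fewer than 20 are flagged low-confidence,
since the standard error of Ĥ (≈ √(H(1−H)/n) ≈ 0.11 at n = 20) then
rivals the 0.25–0.5 spacing between class expectations.

Classification is nearest-anchor in (S, H) space against pure1 (1, 0),
pure2 (0, 0), F1 (0.5, 1), F2 (0.5, 0.5), BC1 (0.75, 0.5),
BC2 (0.25, 0.5).  Ties resolve toward the earlier generation
(pure < F1 < backcross/F2).  Because low-depth data drags observed H
below expectation, the H coordinate of every hybrid anchor can be
scaled by the observed H of a known F1 control (`h_f1_control`).  A
sample farther than `max_distance` (default 0.25, roughly half the
spacing between adjacent anchors) from every anchor is labelled
ambiguous/later-generation.  These thresholds are explicit
configuration, not an inference: visual classification on the triangle
plot remains the field's practice, and the defaults simply formalize
it.

## Weir–Cockerham F_ST

The two-population diploid estimator from the 1984 variance
components: a (among populations), b (among individuals within
populations), c (within individuals, i.e. half the observed
heterozygosity).  Observed heterozygote counts enter directly, so no
within-population Hardy–Weinberg assumption is made.  The multi-locus
estimate is Σa / Σ(a+b+c) (ratio of sums) — the standard multi-locus
combination, chosen over a mean of per-site ratios because the latter
is badly behaved at weakly polymorphic sites.  Negative per-site
components are retained in the sums; truncating them would bias the
global estimate upward.  Site inclusion uses pooled MAF ≥ 0.05 and ≥ 3
genotyped individuals per population — inclusive bounds, unlike the
strict global site filter, matching the different conventions the two
screens follow.

## LD pruning and PCA

LD is the squared dosage correlation (composite LD) over
pairwise-complete observations; haplotype-based measures are out of
scope for unphased GBS genotypes.  Pruning walks sites in genome order
and drops a site whose r² with any of the previous `window − 1`
**retained** sites exceeds the threshold (default 0.2).  Comparing
against retained sites rather than a sliding raw-site window was a
deliberate choice: a step-advanced window is not idempotent (removals
shift subsequent windows), whereas this scheme re-applied to its own
output repeats exactly the comparisons that produced it.  Note that
pooling diverged populations creates genuine mixture LD between
unlinked differentiated loci; pruning thresholds act on that reality,
not only on physical linkage.

PCA mean-imputes missing dosages, centers at 2p̂ and scales by
√(p̂(1−p̂)) (Patterson scaling), then takes the SVD.  It is a
convenience for structure visualization; no downstream stage depends
on it.

## Patterson's D, jackknife, Bonferroni

For quartets (((H1, H2), H3), H4) with per-site sample allele
frequencies, ABBA = (1−p̂1)p̂2p̂3(1−p̂4) and BABA = p̂1(1−p̂2)p̂3(1−p̂4);
D is the ratio of summed differences to summed totals.  The outgroup
enters through (1−p̂4) rather than by forcing polarization, reducing
to the textbook form when the outgroup is fixed ancestral.  Sites
usable only when all four populations have ≥1 called genotype;
ABBA = BABA = 0 sites contribute nothing (D is invariant to them), and
an all-zero denominator is reported as undefined, never as 0.

Significance uses a weighted delete-one-block jackknife (blocks are
contiguous runs of 100 usable sites by default, or one per
chromosome), with block weights proportional to ABBA+BABA mass and the
Busing-style weighted variance, then Z = D/SE and a two-sided normal
p-value.  When the leave-one-out estimates do not vary (SE = 0) a
nonzero D is reported with p = 0 and a degeneracy flag rather than
NaN.  Within a test battery, p-values are Bonferroni-corrected:
p_adj = min(1, m·p), with the family size m explicit configuration
(default: the number of tests run).

Frequency-based D from called genotypes was chosen over
genotype-likelihood weighting deliberately: the pipeline operates
downstream of genotype calling, and the depth filters bound the
miscall rates that likelihood weighting would absorb.  Estimation of
the admixture fraction (f4-ratio and relatives) is out of scope.

## The simulator

Divergence follows the Balding–Nichols model: daughter frequencies are
Beta(p(1−F)/F, (1−p)(1−F)/F) around the parent frequency, so the
divergence parameter *is* (to first order) the Weir–Cockerham θ the
estimator should recover — which makes estimator consistency directly
checkable (recovered within ±0.03 at 5,000 sites and 30+30 samples
across F ∈ 0.05–0.35).  Ancestral frequencies are uniform on
(0.05, 0.95) so the MAF screen has non-degenerate behavior.  Alleles
already fixed stay fixed under further drift.  Sites are unlinked;
there is no recombination map, no selection, and no multi-generation
forward simulation beyond the listed cross types.

Hybrids are built by explicit gamete sampling: an F1 takes one allele
from each species' frequency at every locus; an F1 gamete picks an
ancestry (species 1 or 2) per locus with equal probability and draws
the allele accordingly; F2 = two F1 gametes, backcrosses = one F1
gamete plus one pure gamete.  True (S, H) are recorded at the
ancestry-class level — an F1 is exactly (0.5, 1.0) by construction;
F2 and backcross truths are the realized per-locus tallies.

Read depth is negative-binomial (default mean 15, shape 0.5 — GBS-like
heavy overdispersion; both are conventions, as typical GBS depth
distributions vary widely).  Reads are error-free draws from the true
genotype, so the only artefact modelled is allele sampling: a true
heterozygote covered by d reads is miscalled homozygous with
probability 2·(1/2)^d (0.0625 at d = 5), and depth 0 is a missing
call.  Sequencing error, allelic bias, and paralog collapse are *not*
modelled; passing tests therefore demonstrate correct behavior under
depth-driven dropout, not robustness to those additional artefacts.
The depth-∞ limit is the identity on dosages.

The four-population scenario evolves frequencies along
(((P1, P2), P3), P4) with per-branch Balding–Nichols drift; with
probability f each P3 gene copy is drawn from P2's frequency instead
of P3's own, making f the ground-truth introgression dose.  Under
f = 0 the tree is symmetric in (P1, P2), so D is null-calibrated by
construction; D increases monotonically in f.

The bundled end-to-end study combines both: two species at F = 0.35, a
domestic lineage branching off species 1 with an extra 0.25
bottleneck drift (domestication bottlenecks are strong; this also
makes the donor signal clearly detectable at desk scale), recipient
populations of species 2 receiving f = 0.2 (plus an f = 0 control), a
hybrid zone of known crosses, and a distant outgroup (drift 0.5).  The
study overlay uses depth shape 2.0 rather than 0.5: with shape 0.5 the
zero-inflated depth law pushes per-site call rates below the strict
0.8 screen for essentially every site once ~66+ samples are required
to be covered, leaving nothing downstream; shape 2.0 keeps a realistic
attrition (~25% of sites lost) while preserving heterozygote
undercalling.

All randomness flows through explicit integer seeds; identical
configuration and seed give byte-identical outputs.

## Problem sizes used in the checks

The consistency and calibration experiments are sized for a laptop:
F_ST recovery at 5,000 sites / 30+30 samples; D null calibration over
200 replicates of 4,000 sites in 100 blocks (with ~20 blocks the
normal tail on a jackknife Z shows the usual small-g t-inflation —
empirically ≈ 0.065 at nominal 0.05 — so the calibration experiment
uses enough blocks for the normal reference to hold); power checks at
f = 0.3 with strong sister-branch drift (0.35) at 5,000 sites; S/H
recovery at 500–1,000 diagnostic loci.  The bundled pipeline scenario
(88 samples × 4,000 sites) runs in a few seconds.

## Known limitations

- Panel discovery conditions on observed fixation in finite reference
  samples; with few reference individuals some panel sites are not
  truly fixed, biasing Ĥ slightly downward for hybrids — the same
  effect the F1-control calibration exists to absorb.
- The likelihood treats panel loci as independent; linked panels
  understate uncertainty (no SEs are reported on Ŝ, Ĥ).
- No genotype-likelihood support anywhere: upstream callers' filters
  are trusted.
- Bonferroni is the only multiple-testing correction offered, by
  design fidelity to the reporting convention it reproduces.
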