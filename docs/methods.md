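# Methods

`pgtm` implements preimplantation genetic testing for monogenic disease
(PGT-M) in the setting where no affected family member is available to
phase the parents: an embryo with a positive direct mutation test serves
as the proband.  Two analyses run side by side on each trophectoderm
biopsy: haplotype-based diagnosis of the pathogenic locus from SNP
genotypes, and read-depth CNV screening from low-pass whole-genome
sequencing of the same whole-genome-amplified (WGA) material.

## Haplotype model

### Markers

Only heterozygous SNPs within a window of half-width `window_bp`
(default 5 Mb) around the pathogenic variant are used, limiting both the
recombination risk and the influence of allele dropout (ADO).  Markers are
classed by which parent is heterozygous: `paternal_only` / `maternal_only`
markers can anchor that parent's phase through the proband;
`double_het` markers (both parents heterozygous) carry likelihood
information but no unambiguous anchor, so they are excluded from anchoring
and marginalised over both phase assignments during decoding.

For large deletions an extra class exists, `deletion_hemi`: inside the
deleted interval a carrier parent is hemizygous and appears homozygous.
When *both* parents are deletion carriers (the α-thalassemia --SEA/--SEA
situation), sites inside the deletion where the parents' apparent
homozygous alleles differ identify which parent's deletion a carrier
embryo inherited: the embryo is hemizygous there, and its lone allele can
only have come from the *other* parent's transmitted (non-deleted)
haplotype.

### Anchoring

The proband must demonstrably carry the variant (direct test `carrier` or
`affected`).  For each single-parent-het marker, the allele the
heterozygous parent transmitted to the proband is computed by subtracting
the other parent's contribution from the proband's genotype; if the
carrier parent passed the variant to the proband, the transmitted allele
is labelled M (mutant-linked), the other N.  A non-carrier parent's
haplotypes are labelled H1 (proband-transmitted) / H2.  For a recessive
carrier proband the deletion's parental origin is resolved first via the
`deletion_hemi` likelihood comparison; if no discriminating inside-deletion
marker exists, an affected embryo is required as proband, otherwise the
run aborts with an explanatory error.  Anchoring assumes the proband has
no crossover between marker and variant; this assumption is revisited
after decoding (below).

Observations that contradict the other parent's contribution (possible
proband dropout) never anchor: the marker stays `unresolved`.

### Decoding

Each embryo's hidden state at marker *k* is the pair of transmitted
parental haplotypes, 4 states in total.  Transition probabilities between
adjacent markers factor per parent into switch/stay with switch
probability equal to the recombination fraction

    r = (1 − exp(−2d)) / 2        (Haldane map function)

where *d* is the genetic distance in Morgans obtained by linear
interpolation of the cumulative-cM map (constant beyond the tabulated
range).  Haldane (no interference) matches the simulator's Poisson
crossover process exactly.

Emissions come from a symmetric ADO + genotype-error model with rates
`a = ado_rate` (default 0.05) and `e = genotype_error` (default 0.01):
a true heterozygote is observed het with probability 1 − a − e and as
either homozygote with (a + e)/2 each; a true homozygote is read
correctly with 1 − e; a missing call has probability 1 under every state
(the locus is skipped).  Hemizygous loci are read as the matching
homozygote with error e; loci with no DNA (both haplotypes deleted)
yield any concrete call only through error.  The defaults reflect typical
WGA single-/few-cell genotyping performance and are overridable.

Decoding is exact Viterbi in log space.  Ties are broken deterministically:
maximal log-probability first (tolerance 1e-9 per marker), then fewest
haplotype switches, then the lexicographically smallest state sequence
(M before N), implemented as a suffix DP over (log-prob, −switches) score
pairs with greedy left-to-right reconstruction.  A top-2 Viterbi pass
yields the margin to the second-best path, reported per embryo and
flagged (`low_margin`) below 2 nats.

Phases left unresolved by anchoring are assigned by two rounds of
coordinate ascent: decode all embryos, then set each unresolved marker to
the phase maximising the summed log emission across the embryos' decoded
states, then re-decode.  Afterwards, proband-anchored markers whose
anchor disagrees with the proband's own decoded path — a proband
crossover, or a proband dropout that slipped through anchoring — are
flagged `conflicted`.  When any conflict is found, the conflicted anchors
*and* all inferred phases are dropped and re-inferred from the surviving
anchors through path continuity; without this step a single corrupt
anchor can flip the phase of a whole marker block (observed in
simulation).  `conflicted` markers are excluded from diagnosis.

### Variant-locus call and reconciliation

The call at the variant is the consensus of the decoded indicators at the
nearest usable marker on each side of the variant; disagreement means a
recombination event cannot be placed relative to the variant and yields
an explicit `failure` with the `recombination_in_window` flag — a refusal
to call, never a guess.  For a telomeric variant with no marker on one
side (the --SEA deletion sits 175 kb from the p-terminus), the two nearest
markers on the populated side must agree instead.  Dominant inheritance:
M from the carrier parent ⇒ carrier; recessive: M from both ⇒ affected,
one ⇒ carrier, none ⇒ wild type.

The haplotype call is then reconciled with the direct mutation test:
agreement yields the shared call; a failed direct test defers to the
haplotype (flag `ado_suspect`); a failed haplotype (including ploidy
failure) defers to the direct call; a genuine disagreement reports the
*more severe* status (affected > carrier > wild type) and always sets an
explanatory flag — `ado_suspect` when the direct test is milder (dropout
at the mutation site), `recombination_in_window` when the haplotype is
milder.  Clinical conservatism: a disagreement is never silently resolved
toward the milder call.

### Ploidy gate

Haplotype construction presumes biparental disomy in the window.  Embryos
are gated on four signals, any of which blocks haplotype diagnosis:

1. a reported CNV segment on the variant chromosome (depth module);
2. Mendelian-inconsistency above 10% over *constrained* sites — sites
   where the parental genotypes make at least one offspring class
   impossible.  Restricting the denominator to constrained sites matters:
   for a monosomy, violations concentrate there, and diluting them over
   all markers would sit exactly at the threshold;
3. heterozygosity excess (> 75%, expected 50%) at sites where exactly one
   parent is heterozygous — a meiosis-I-type extra genome contributes both
   of one parent's haplotypes and is Mendel-consistent at *every* site,
   so per-site checks cannot see it;
4. no-call excess (> 10%): triploid biopsies put allelic ratios of 1:2 at
   biallelic SNPs, between the caller's genotype clusters, so hard-call
   data from such samples is missing-rich and haplotype construction has
   too few usable markers.

Checks 2–4 require minimum site counts (10–20) before firing, so sparse
windows cannot produce spurious failures.

## CNV model

The genome is tiled with 400-kb windows at a 200-kb stride (1-based
inclusive; a trailing partial bin is kept only when the full windows leave
an uncovered tail and the partial is at least one stride wide).  Bins with
more than 50% blacklist overlap are excluded.  Depth is GC-corrected by
robust local linear regression of count on GC (span 0.3, 3 robustness
iterations) over retained autosomal bins, each bin rescaled by the ratio
of the mean fitted depth to the fitted depth at its GC; GC values outside
the fitted range use the boundary fit, and a GC spread below 0.05 skips
correction with a warning.

Sample and reference panel are brought onto a common scale by the median
per-bin ratio of sample to panel median, followed by a second median over
bins within ±25% of the first estimate.  The median step keeps aneuploid
chromosomes from dragging the baseline (a mean would); the trimming pass
removes the residual shift a sizeable aberrant fraction still induces.
For a 46,XY sample against a non-male panel the expected depth on X and Y
is halved before ratios are taken.  Per bin, `log2_ratio` and a Z-score
against the panel's per-bin spread are computed; bins with non-positive
panel medians are excluded and logged.

Segmentation is circular binary segmentation: recursively, the arc
(i, j) maximising the two-sample t-statistic of arc versus complement is
accepted as a split when its permutation p-value is below α = 0.01
(1,000 permutations, seeded; permutation stops early once the rejection
bound is reached, which cannot change the accept/reject decision).
Segments of fewer than 4 bins are never split, and adjacent segments with
mean difference below 0.1 are re-merged.

Classification uses the estimated aberrant-cell level

    gain:  level = 2 (2^L − 1),     loss:  level = 2 (1 − 2^L)

(L the segment's mean log2 ratio; level 1 corresponds to a full
single-copy event, clipped to [0, 1]).  Segments with |L| ≤ 0.1 are
neutral.  Full-magnitude events (level ≥ 0.7 and |L| > 0.25) are reported
as gain/loss when whole-chromosome or whole-arm (≥ 90% of the relevant
retained bins) or segmental of at least 4 Mb **and** 20 bins — note that
4 Mb at the 200-kb stride is exactly 20 bin starts, so the two floors are
mutually consistent.  Intermediate states are reported as
mosaic_gain/mosaic_loss when at least 10 Mb long with level above 30%.
The full/intermediate split is made on the level rather than on the 0.25
log2 boundary because common mosaic fractions already exceed it (a 40%
mosaic gain has L = log2 1.2 ≈ 0.263, a 40% mosaic loss |L| ≈ 0.32);
splitting on level keeps single-copy events and intermediate states from
shadowing each other.

## Simulator

The generators produce exactly the data structures the method assumes and
nothing more.  Families: marker positions uniform in the window, allele
frequencies uniform on (0.2, 0.8), a constant-rate genetic map (default
1 cM/Mb), Poisson crossovers on the cM scale with a uniform start phase
(conditioning a transmission at the variant only fixes the start phase and
leaves the crossover process untouched), and the variant riding haplotype
0 of each carrier parent (no alleles inside a deletion).  Observations are
drawn from the *same* emission model the decoder uses, so the likelihood
is well-specified by construction.  Triploid biopsies use a
caller-confusion channel at mixed-allele (2:1) sites — P(no-call) 0.40,
P(het) 0.45, P(hom-major) 0.15 — reflecting how array callers behave
between genotype clusters.

Depth: negative binomial per bin with variance μ + (0.1 μ)², i.e. a 10%
multiplicative overdispersion on top of Poisson, a smooth unimodal GC
amplification-bias curve, base depth 500 per 400-kb bin (about 9 million
reads over a ~15,000-bin genome, matching the protocol's sequencing
budget), and copy-number multipliers cn/2 (mosaics use 2 + level·Δcn).
Reference panels are six GC-normalised diploid controls.

What the simulator does *not* emulate — and what passing tests therefore
do not show about real data: linkage disequilibrium between markers,
site-specific (e.g. GC-rich) dropout hotspots, crossover interference,
segmental-duplication artefacts in depth, caller-specific B-allele-
frequency behaviour, and contamination of biopsies with maternal or
cumulus cells.

The packaged regression fixture contains three families with ten embryos
on small synthetic chromosomes (30–40 Mb) so the deterministic end-to-end
run takes seconds: a both-carrier ~19.3-kb α-globin-cluster deletion
family whose proband is a paternal-origin carrier and whose fourth embryo
is an MII-type digynic triploid (duplicated maternal normal haplotype:
the direct deletion test is negative, genotyping QC fails, and the embryo
is flagged through the SNP-based ploidy call — a uniform triploid is
invisible to depth ratios after rescaling); a de novo maternal dominant
frameshift family; and a de novo paternal dominant frameshift family.
CNV-abnormal embryos carry a whole-chromosome trisomy of a bystander
chromosome.  The two frameshift loci use synthetic genomic coordinates;
the α-globin deletion interval (165,397–184,700) is the published one.

## Problem sizes

The test suite and the acceptance script deliberately run at reduced
scale — 30–200 markers per family, 200-family recovery sweeps, 150–530-bin
genomes, 40–60 seeded CBS replicates — chosen so the statistical
assertions (binomial/χ² comparisons, ±0.1 log2 tolerances) have comfortable
power at these sizes.

## Known limitations

* Absolute phase below/above a telomeric variant can rest on few markers;
  the two-marker agreement rule refuses rather than guesses, but cannot
  manufacture information that is not there.
* Margins, not posteriors: the decoder reports the Viterbi margin rather
  than full forward–backward posteriors per marker.
* The ploidy gate is a screen, not a karyotype: balanced abnormalities and
  low-level mosaic aneuploidy below its thresholds pass through.
* Mosaic level estimation inherits any residual baseline error from the
  panel scaling (a few percent on heavily aberrant genomes).
* The CNV caller starts from binned counts or fragment starts; alignment,
  duplicate marking and mappability-blacklist construction are upstream.
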