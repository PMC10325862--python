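# Methods

## The locus model

The fibromelanosis locus is modelled as five named, contiguous reference
intervals on chicken chromosome 20 — `Flank1, Dup1, Int, Dup2, Flank2` —
with the reference (GRCg6a) coordinates shipped as the default map:
Flank1 10,263,555–10,766,771; Dup1 10,766,772–10,894,151 (127,380 bp);
Int 10,894,152–11,306,685 (412,534 bp); Dup2 11,306,686–11,477,501
(170,816 bp); Flank2 11,477,502–11,980,000.  A candidate locus structure
(an *arrangement*) is an ordered list of oriented segment tokens over those
names, starting with forward `Flank1` and ending with forward `Flank2`.
The model is coordinate-agnostic: synthetic runs use a 1/10-scale map with
the same five names.

Two derived objects carry all the inferential weight:

* **Adjacencies.**  Each consecutive segment pair contributes one junction
  between two segment ends, canonicalised so that a junction and its
  reverse-strand mirror compare equal.  Junctions absent from the wild-type
  arrangement are *novel*; every carrier arrangement creates exactly the
  two carrier-diagnostic junctions
  `A = Dup1.END↔Dup2.END` and `B = Dup1.START↔Dup2.START`.
* **Copy contexts.**  Each copy of a region has a left and right neighbour
  (region + orientation), canonicalised to the copy's forward frame so
  that a copy and its reverse-complement reading yield the same context.
  Junctions are shared by all carrier scenarios; contexts are not, which is
  why phased, anchored haplotypes can discriminate the scenarios.

The three carrier scenarios are encoded as:

    Fm_1: Flank1 + Dup1 + inv-Dup2 + inv-Int + inv-Dup1 + Dup2 + Flank2
    Fm_2: Flank1 + Dup1 + inv-Dup2 + Dup1 + Int + Dup2 + Flank2
    Fm_3: Flank1 + Dup1 + Int + Dup2 + inv-Dup1 + Dup2 + Flank2

`Fm_2` and `Fm_3` are fully constrained by the published haplotype
anchors.  `Fm_1` is only depicted graphically in the source figure; the
layout above is the unique arrangement satisfying every textual
constraint: a single duplication–inversion event, an inverted
(Dup2+Int+Dup1) middle block of ~709 kb, only the first Dup1 and last Dup2
copies in wild-type context, copy numbers Dup1=Dup2=2 and Int=1, the novel
junction set {A, B}, and Dup1 copy contexts identical to `Fm_2` (so that
Dup1-spanning evidence cannot separate `Fm_1` from `Fm_2`, only
Dup2-spanning evidence can).

**Scenario consistency** keeps the subset rule — a candidate arrangement is
consistent when every observed context matches one of its copy contexts —
and additionally records which candidate contexts no observation explains.
Diploid genotype inference uses the union of the pair's context sets and
calls the *unique exact fit* (observed set equals candidate set).  The
exactness requirement is what lets a heterozygote reject both the
carrier-homozygote candidate (which cannot explain the observed native
contexts) and composite candidates such as `Fm_2/Fm_3` (whose context
unions are supersets of the observations).

## Synthetic data

The generator's defaults are the study conditions; they are fixed and not
tuned per experiment.

**Scale.**  1/10 of the real locus (Dup1 12,738 bp, Int 41,253 bp, Dup2
17,081 bp, 50 kb flanks), so a full simulate→resolve cycle runs in a few
seconds and the whole multi-seed validation in minutes.

**Diploid construction.**  A sample is a pair of arrangements.  Each
chromosome's sequence is concatenated from a random base reference in
arrangement order (inverted segments reverse-complemented), with a
projection map from sample to signed reference intervals kept as ground
truth.

**Heterozygous-site planting (single-founder model).**  The rearrangement
arose once, so all chromosomes carrying the same carrier arrangement share
one founder realisation of copy-specific alleles; wild-type chromosomes
receive independent variants.  Inside Dup1/Dup2 every (founder, copy) is
its own allele class and classes are planted independently at 1% density
(the study's observed candidate-site density), subject to each planted
site being genuinely polymorphic.  This is what makes copy-specific
haplotypes separable, and it reproduces the real data's structure: a
carrier homozygote shows exactly two haplotype classes per duplicated
region (the two ancestral copies), a carrier/wild-type heterozygote three.
Outside the duplicated regions, sites are planted at 0.3% between distinct
chromosome lineages — roughly the genome-wide diversity reported for these
breeds.

**Long reads.**  Log-normal lengths (median 20 kb, sigma 0.55: sometimes
shorter than a scaled duplicated region, sometimes spanning it), i.i.d.
substitution errors (default 2%), no indels — the phasing procedure
consumes per-site base calls, and indel realism would only add alignment
ambiguity the procedure never models.  Reads are placed on the reference
through the truth projection rather than run through an aligner: one SAM
record per projection segment overlapped, soft-clip/match CIGARs, SA tags,
primary = longest block.  Read starts may overhang the chromosome start so
coverage is stationary rather than edge-tapered.  Total sample depth
(default 60×) is split evenly between the chromosomes, giving the expected
1.5×/2× relative depth over duplicated regions in het/hom carriers.

**Short reads.**  Paired 150 bp reads, ~400 bp inserts, 30× default.
Blocks that are reference-contiguous on one strand are merged before
alignment (native borders never clip a real short read); a mate straddling
a true junction aligns to its majority side with the remainder
soft-clipped.  That majority rule leaves a half-height depth discontinuity
exactly at each breakpoint flanked by half-read-length ramps — the signal
the breakpoint refiner exploits.

**Haplotype panels.**  Neutral derived-allele counts follow the 1/k
spectrum (folded form ∝ 1/i + 1/(n−i)); with per-population drift F the
population frequencies are Balding–Nichols Beta draws around the ancestral
frequency, so a pair with equal drift F has expected Hudson F_ST ≈ F.  An
optional sweep overwrites a configurable fraction (swept-haplotype
frequency) of one population's haplotypes with a shared template inside the
sweep window.  Defaults mirror the focal two-breed contrast: 2 populations
× 9 diploids, 10,000 sites over 1 Mb.  Not modelled: recombination
gradients, mutation after the split (private alleles arise only by
differential loss), linkage outside the sweep window, ascertainment.
Passing tests therefore show estimator and ranking correctness under a
clean neutral/sweep contrast, not robustness to demography or data
artefacts.

Everything is seeded through `numpy.random.default_rng`; re-runs are
byte-identical.

## Coverage breakpoints

Reads are counted per tiled window (1 kb default) with
bedtools-`coverage` overlap semantics (a read counts in every window it
overlaps) and normalised by the chromosome-wide median — robust to the
duplicated windows themselves.  A boundary is called between adjacent
windows where the case's higher/lower ratio reaches 1.5 (halfway between
single-copy and duplicated relative depth; configurable) while every
control stays below it.  Refinement fits a least-squares two-segment step
to per-base depth in a ±2-window radius; when the data are soft-clipped
short reads, the step is additionally snapped to the sharpest single-base
depth change within one read length — the clip discontinuity sits exactly
on the breakpoint, which localises it to a few bp at high depth.
Confidence is the mean shift over the pooled residual SD.

Carrier classification treats junction evidence as primary: a sample is a
carrier when both junction types have ≥3 supporting reads, or when both
duplicated regions exceed 1.6× the flank depth; when the two criteria
disagree the junction call wins and the sample is flagged discordant.  A
~1.5× heterozygote below the depth threshold is thus still called a
carrier by its junction reads, and an isolated depth gain without junction
support (a shared CNV, not this rearrangement) is not.

## Junction reads

Primary and supplementary records are pooled per read id (secondary
alignments ignored); each block gets a region label when ≥80% of it lies in
one region and it is ≥200 bp (straddlers of native borders take the
majority region).  A read aligning to both Dup1 and Dup2 is classified by
the block pair adjacent in read order: the earlier block's read-exit end
joined to the later block's read-entry end, compared as a canonical
adjacency, is type A, type B, a native adjacency, or unclassified.  An
endpoint farther than 100 bp (configurable) from the region border leaves
the read unclassified with the reason recorded.  The canonical-adjacency
comparison makes calls invariant under reversing the read, and shrinking
the tolerance can only shrink the A/B counts.

## Read-backed phasing

The pipeline per duplicated region:

1. **Pileup** of base support at every position from the parsed alignment
   blocks (substitution-only alignments make this exact; a read whose
   blocks cover the same position twice with disagreeing bases — both
   copies of the region — is dropped at that position as uninformative).
2. **Candidate heterozygous sites**: exactly two bases with ≥10 supporting
   reads; three or more such bases excludes the site as potentially
   tri-allelic.  Thresholds scale with configured depth.
3. **Read labelling**: per site, the read-id set carrying each base.
4. **Seeded extension**: from a seed site, scan outward; the nearest site
   whose 4×4 base-combination matrix against the frontier has one cell per
   current haplotype allele with ≥5 reads, each dominating its row (other
   cells ≤20% of the accepted cell), extends both haplotypes and becomes
   the new frontier; unacceptable sites are skipped.  The dominance rule is
   this package's formalisation of what the original procedure resolved by
   manual inspection of the 16 counts; the 10-read and 5-read floors are
   the procedure's published values.  Ties cannot arise within a scan
   direction; extension is deterministic given sorted candidates, and its
   output is invariant to read input order.
5. **Seed selection** is automated (the original used visual inspection in
   a genome browser): the candidate site nearest a region border with
   balanced allele support (minor ≥25% of major — an error pileup is
   never balanced) and ≥5 border-crossing reads per allele; if a chain
   refuses to extend, the next candidate seed is tried (3 attempts).
6. **Anchoring**: for each haplotype end, reads carrying the terminal
   allele vote with the neighbouring-region context they extend into,
   either through a split block starting at the border (a junction) or
   through the same block continuing across a native border.  Evidence is
   restricted to the block covering the terminal site, and reads visiting
   the position through more than one copy are excluded — both rules exist
   because a single long read can traverse both copies of a scaled region.
   One supported context (≥5 reads) anchors the end; several mark it
   ambiguous; none leaves it unanchored.
7. **Splitting** (diploid carriers): a heterozygous carrier has three copy
   classes in a duplicated region, so the two-haplotype extension yields
   one clean class plus a mixture whose anchors come out ambiguous.
   Extension is then re-run once restricted to the mixture's reads
   (majority vote over chain sites; reads visiting the region twice are
   excluded since they would smuggle the third class back in).  The
   allele-support floor is kept unchanged in the sub-run — removing a copy
   class leaves the remaining classes at full depth.

Fully anchored contexts from both regions feed genotype inference.
Fragmentary or unanchored haplotypes are retained in the output but do not
contribute contexts.

## Population-genetic scan

Windows tile the chromosome from position 1 (50 kb default, short last
window kept but flagged).  A window fails when <80% callable or >10%
repeat-masked; failures are reported but excluded from outlier ranking.
Effective sites per window are its callable bases.

Estimators (folded spectrum throughout): π as mean pairwise differences
2c(n−c)/n(n−1) per effective site; Watterson's θ = S/a_n; Tajima's D with
the standard 1989 variance constants; Fu & Li's D* in the outgroup-free
starred form, singletons being minor-allele-count-1 sites (the folded
pipeline cannot polarise, which is exactly the situation D* was designed
for); Hudson F_ST per Bhatia et al. (2013), windowed as a ratio of
averages over sites polymorphic in the pair (negative estimates are
preserved); D_xy as the mean between-population difference rate.  Missing
genotypes are handled complete-case per site.  All five estimators are
cross-checked in the tests against independent brute-force pairwise-loop
oracles to 1e-9.

Outlier regions are windows above the empirical top-1% (F_ST) or top-10%
(D_xy) quantile of passing windows, merged when bookended.  Fixed sites
are per-site Hudson F_ST > 0.9.  Private alleles are alleles present in
the focal population and absent from all comparison populations, with an
optional site-exclusion mask (e.g. database-known alleles).

EHH statistics are unpolarised: the majority allele plays the ancestral
role.  EHH at distance d is the probability two random carrier haplotypes
are identical from the core to d (partition refinement); iHH integrates
the decay by trapezoid over physical distance, truncated below EHH = 0.05
and at gaps >200 kb.  iHS = ln(iHH_major/iHH_minor), standardised within
20 equal-occupancy minor-allele-frequency bins; XP-EHH compares pooled-core
iHH between populations and is standardised genome-wide.  Sites with a
minor-allele frequency below 0.05 or fewer than two carriers per allele
are skipped.

The sweep report annotates merged F_ST outliers with the focal/reference
diversity ratio, focal Tajima's D, mean |iHS|, mean XP-EHH, a top-decile
D_xy flag and the distance to Dup1, ranked by peak F_ST.

## Validation problem sizes

The shipped validation runs at the desk scale the defaults define: 20
seeded simulations per generating genotype for scenario recovery and for
phasing fidelity (5% error), 20 seeds × 4 breakpoints at 30× and 200×
short-read depth for refinement accuracy, 100 random 10-haplotype panels
for the estimator oracles, 20,000-site panels for drift recovery at
F ∈ {0.05, 0.16, 0.36}, and a 10,000-site neutral panel (≥2,000 scored
sites) for iHS standardisation self-consistency.

## Known limitations

* The simulator writes truth-derived alignments; aligner-specific
  artefacts (reference bias, clipped-base misplacement, mapping-quality
  loss in repeats) are out of scope, so real-data runs should expect more
  unclassified reads and noisier pair matrices than the tests show.
* Substitution-only errors; indel-rich long reads will need external
  realignment before pileup.
* The phasing split step handles one level of class mixture (three copy
  classes); more complex mosaics (e.g. two distinct carrier founders in
  one sample) would need recursive splitting.
* The panel simulator has no linkage outside the sweep template and no
  post-split mutation; absolute private-allele counts are not comparable
  to real data, only their ordering under isolation.
* Full-scale reproduction of the published read-level numbers (the five
  junction-spanning PacBio reads, the 24+25 haplotype-defining sites)
  requires the original multi-hundred-GB accessions and is outside the
  desk-scale scope; the pipeline accepts real SAM/VCF inputs unchanged.
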