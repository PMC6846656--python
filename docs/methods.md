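# Methods

## The measurement problem

AID deaminates C→U on exposed single-stranded DNA; after one round of
copying, each event is a C→T substitution. On a transcribed IgV
amplicon the true per-site rates are of order 10⁻⁵–10⁻³ per sequenced
C, while PCR and Illumina sequencing introduce errors at ~10⁻⁴–10⁻³
per base per read. All downstream biology — strand preference, hotspot
motif usage, processivity — therefore depends on consensus error
suppression, implemented here as maximum-depth sequencing (MDS) with
3′-terminal 24-nt UIDs.

## Consensus calling rules

A read pair is merged into one full-length fragment (the amplicon is
short enough that 150-bp mates overlap; in the overlap the
higher-quality base wins, ties to R1). The caller then applies, in
order:

1. **UID gate** — the UID is the terminal 24 bases; the read is
   discarded if any UID base has Phred quality < 30 (reads failing this
   gate are excluded entirely, not merely left unassigned).
2. **Qualification** — ungapped positional comparison to the strand's
   reference; equal length required (any indel-containing read is
   rejected), fewer than 20 mismatches.
3. **Families** — exact-match UID grouping; families need ≥ 3 reads.
4. **Site verdicts** — at each site, the *qualifying* reads are family
   members with site quality ≥ 30. Fewer than 3 qualifying reads: the
   family does not cover the site. A **supermutant** is called when a
   fraction ≥ 0.95 of qualifying reads share one non-reference base
   (the exact boundary counts: 19 of 20 qualifies). The same consensus
   on the reference base is a reference call; anything else is
   ambiguous. Ambiguous and reference families count in the
   denominator only.
5. **Rates** — per-site rate = supermutant families / covered families;
   library-wide rate = Σ numerators / Σ denominators over C sites for
   C→T. A size-3 family needs three independent identical errors to
   fake a supermutant (probability 3·(e/3)³ ≈ 10⁻¹⁰ per site at
   e = 10⁻³), which is why the false-call tests demand essentially
   zero.

Each strand library is called against its own strand read 5′→3′; no
cross-strand projection happens during calling. Coordinates are
reported 1-based in a fixed "duplex" numbering along the sense (NTS)
strand, with a TS position mapped to the coordinate of its pairing
base, so region labels (FW1 38–65, CDR1 66–106, FW2 107–146, CDR2
147–177, FW3 178–203, scaffold bubble 16–27) apply to both strands.

A deliberate limitation: PCR errors that strike the template copy
*before* amplification propagate to every read of the family and are
indistinguishable from true mutations. The synthetic error model
reproduces this (see the false calls in `analysis/03_call_mutations.py`
at `pcr_error_rate > 0`); no consensus scheme can remove them.

## Motif classes and spectra

Hot = 5′WRC, cold = 5′SYC (IUPAC W=A/T, R=A/G, S=C/G, Y=C/T; the
mutated C is 3′). The classes are decided from the two 5′ neighbours on
the C's own strand, so TS classification equals classifying the reverse
complement of the NTS. WGCW ("overlapping hot", e.g. AGCT) is its own
reverse complement and carries a hot C on each strand. A C with fewer
than two upstream bases cannot be classified and is labelled "other"
with an edge flag.

Spectra report, per C site, the rate (supermutants/covered families)
and the frequency (% of the strand's total mutations; sums to 100
whenever any mutation was scored). Region distributions support a site
exclusion mask so that a single pathological run of sites (e.g. a C-run
adjacent to a strong pause site) can be removed from both numerator and
total. For comparison with published B-cell spectra, which are reported
per sense-strand position, `duplex_projection` merges both strands onto
NTS coordinates as C/G rows.

Transcript 3′-end profiling maps each RNA's terminal 12-mer (U→T) by
exact unique match against the sense strand; ambiguous or absent
anchors are counted as unmapped rather than guessed (alignment is
unnecessary at a 203-nt template scale, and template mutations simply
produce logged unmapped transcripts). Region end-density comparisons
use every template position in each region (zero counts included) and
the pooled t-test below.

## Clone-level processivity statistics

Let h_i ∈ {0,1} indicate a supermutant C→T at C site i of one clone.
Over a clone ensemble, with δh_i = h_i − ⟨h_i⟩ and σ_i = ⟨δh_i²⟩^½:

    c(i,j) = ⟨δh_i δh_j⟩ / (σ_i σ_j)

using population (divide-by-n) moments. Diagonal entries are
meaningless and excluded; pairs with σ_i σ_j = 0 are undefined and
excluded. C(d) averages the defined c(i,j) over all site pairs at
nucleotide separation d (pair counts are retained as weights). The
correlation length comes from weighted nonlinear least squares of
C(d) = e^(−d/L) (free-amplitude variant A·e^(−d/L) available but off
by default); the fit is refused when no C(d) is positive and requires
three positive distances. On exact exponential input the fit returns L
to ≤ 10⁻⁶.

The ensemble for ⟨·⟩ defaults to clones with ≥ 2 mutations — pair
correlations only exist on multiply mutated clones, and this matches
how such analyses are reported — with `scope="all"` available. Note
that conditioning on ≥ 2 mutations introduces weak negative
correlations between distant sites and shortens the fitted L relative
to the generative tract length; the estimator is therefore validated by
*self-consistency* (small runs must recover the L that the same
estimator finds on a 10× larger run, ±30%) and by a monotonicity check
(longer tracts never systematically shorten fitted L), not by equating
L with the tract mean.

Clusters: a mutation pair at coordinates i < j lies within an N-nt
window iff j − i ≤ N − 1; the cluster fraction is computed over clones
carrying 2–5 mutations (configurable). The independence null for both
C(d) and cluster fractions is obtained by permuting matrix columns
independently.

## Replicate statistics

Per-experiment aggregate rate = total C→T supermutants / total
sequenced C's, carried at full precision and rounded only for display
(×10⁻⁵, one decimal). Replicate groups are summarised as mean ±
**population** SD (divide-by-n), while the two-tailed Student's t-test
uses the classical pooled form with **sample** variances and
df = n_A + n_B − 2. This mixed convention is statistically
unconventional but is the unique pair that reproduces the summary
values in the shipped manifest from its raw counts, so it is fixed and
prominently tested; Welch's test is available as an option. Degenerate
zero pooled variance is flagged, with p = 1 for equal means and p = 0
otherwise. One summary p-value in the manifest (the TS ± DSIF
comparison) reproduces to 0.207 from full-precision counts while its
one-decimal display rates give 0.208; the package always uses full
precision.

## Synthetic data generator

The generator emulates the study design — ~203-nt NTS/TS amplicons,
3′ 24-nt UIDs, paired 150-bp reads, UID families of variable size —
with ground truth for every mutation, enabling exact end-to-end
closure tests.

**Reference.** The background is A/T-only, and every C/G is introduced
by planting k-mers (hot "TAC", cold "GTC", other "ATC", WGCW "AGCT")
at random non-adjacent offsets inside named regions, so planted motif
counts are exact by construction (a cold plant's G necessarily adds one
"other" C on the opposite strand; this is accounted for and verified
after construction). Plans that cannot fit raise an error naming the
region. The default plan mirrors the IGHV3-23-like layout: WGCW- and
hot-rich CDRs, sparse FWs. This synthetic reference is a stand-in; it
does not reproduce the real IgV sequence, only its motif statistics at
reduced density (32 NTS / 13 TS C sites versus 48/66 in the real
amplicon).

**Deamination.** Per clone: strand (fixed or Bernoulli-½), then
Poisson(burst_rate) enzyme engagements; each engagement anchors
uniformly, covers a geometric tract (mean tract_mean, random
direction, clipped at the ends), and deaminates each covered C with
its motif-class probability. This engagement-tract family was chosen
because it provably yields near-exponential distance correlations with
a single length knob; the real enzyme's kinetics are not modelled.
Defaults — p_hot 0.30, p_other 0.10, p_cold 0.015, burst_rate 1.0,
tract_mean 15 nt — were calibrated once so the default model matches
the reported study conditions: ~67% of mutated clones carry exactly
one mutation, the rest 2–7 with an approximately exponential decrease,
hot ≫ other ≫ cold site usage, and a tract scale matching a stalled
bubble plus backtrack span (~15 nt).

**Sequencing.** UIDs are drawn uniformly from the 4²⁴ space; collisions
are allowed and logged (they are negligible at this scale, as in real
MDS data). Family sizes are fixed or Poisson (default mean 6; the true
distribution of the emulated libraries is unpublished, so this is a
placeholder, configurable). PCR errors (default 10⁻⁴/base) hit the
family template once, before per-read sequencing errors (default
10⁻³/base); both substitute a uniformly chosen different base — no
indels or chimeras. Qualities are two-component (Q37 with probability
0.98, else Q12), deliberately minimal but sufficient to exercise every
Q ≥ 30 gate. Error and quality draws are independent, so a low-quality
base is not more likely to be wrong; the gates are still exercised
because low-quality correct bases reduce site coverage. All randomness
flows from one seeded generator; identical seeds give byte-identical
FASTQ and truth files.

What passing tests on this generator do **not** show: performance on
real base-caller quality distributions, context-dependent error
spectra, indels, UID errors beyond substitutions, or the real IgV
sequence composition. They do show that the calling rules, the rate
arithmetic and the correlation estimators are implemented exactly, and
that the whole pipeline is closed (truth in = calls out) in the
noiseless limit.

## Problem sizes and numerical choices

Test and acceptance runs use 2,000–20,000 clones (10,000 families for
the caller-correctness runs, 5,000-clone fits against a 50,000-clone
oracle for correlation-length recovery), chosen as the smallest sizes
at which the binomial/multinomial 3-SD tolerances of the property
tests are comfortably informative. The supermutant threshold comparison
subtracts 10⁻⁹ before comparing counts so the exact ≥95% boundary is
immune to floating-point representation of the fraction. Consensus
ties (possible only when the fraction is ≤ 0.5) are ambiguous. The
exponential fit seeds from a log-linear regression on the positive
C(d) points and weights by pair counts. Zero denominators, empty
matrices, all-non-positive C(d) and degenerate t-tests raise or flag
explicitly rather than returning silent NaNs.

## Known limitations

* No indel calling, no UID error-tolerant clustering, no
  quality-weighted consensus (exact rules only, by design).
* The generator's correlation length is controlled but not equal to
  tract_mean; absolute L values from synthetic data are not comparable
  to published estimates from real clone ensembles.
* Transcript-end mapping assumes exact 12-mer anchors; heavily mutated
  transcripts go to the unmapped count.
* The scaffold-bubble region may legitimately overlap other regions;
  non-bubble labels take precedence in per-site region assignment.
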