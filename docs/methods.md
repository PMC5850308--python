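# Methods

This note documents the statistical model, the synthetic data generator,
the numerical choices, and the known limitations of `paleosrna`.

## 1. Damage model and matching

Postmortem cytosine deamination (C→U) appears in sequencing data as C→T
substitutions read in the frame of the originating strand. A fragment
sequenced from the reverse strand therefore shows the substitution as
G→A in forward reference coordinates.

The matcher accepts, per query of length 18–25 nt:

- **modern mode:** exact matches only, both strands;
- **ancient mode:** exact matches, plus alignments with exactly one
  mismatch where the reference base is C and the read base T on the `+`
  strand, or reference G and read A on the `−` strand.

Queries containing ambiguous bases (N) never match. Candidate positions
come from two disjoint 9-mer seeds (query offsets 0 and L−9); by the
pigeonhole principle any alignment with ≤1 mismatch leaves at least one
seed intact, so seeding is lossless for this mismatch budget. Every
candidate is then verified directly. The unit and acceptance suites
check the matcher against a brute-force enumeration over every offset,
strand and mismatch pattern.

When a read matches several references equally well, assignment breaks
ties by (fewest mismatches, class priority miRNA > rRNA > tRNA > mRNA >
retroelement > pri-miRNA > genome, then reference name/position). The
priority encodes that short annotated classes are more informative than
the genomic background that contains them.

## 2. Read preparation

3′ adapter trimming removes the leftmost full adapter occurrence, or
else the leftmost terminal prefix overlap of at least `min_overlap = 5`
bases (shorter overlaps are indistinguishable from sequence). Reads are
kept when the trimmed insert is 18–25 nt, then dereplicated to
(sequence, frequency) pairs. All downstream counts aggregate
frequencies, i.e. they are read-level counts.

## 3. Count model and differential calls

Per-family counts across control libraries are modeled as an extended
Poisson process: variance = `r` × mean with `r ≥ 1`. `r` is estimated as
the mean variance/mean ratio across families (sample variance, families
with zero mean skipped).

For an observed count `x`, the likelihood of the underlying mean `λ` is

- `x < 50`: the exact Poisson likelihood, computed in log space via
  `gammaln`;
- `x ≥ 50`: a Normal density in `x` with mean `λ` and variance `r·λ`,
  which carries the overdispersion into the interval width.

Curves are normalized to unit trapezoid area over a fixed grid (see §6)
and interpreted with a flat prior; the 95% central interval comes from
the interpolated trapezoid CDF. The ancient count is called **up**
(**down**) for a family only when its interval lies entirely above
(below) the interval of the control mean count; otherwise the family is
*indistinguishable*.

### Normalization

Each control's family counts are scaled by
`(total_miRNA_s / total_reads_s)⁻¹ × mean_ratio`, where `mean_ratio` is
the arithmetic mean of the per-sample miRNA-to-reads ratios. With equal
sequencing depths this conserves the cross-sample mean miRNA total
exactly (an acceptance property); with unequal depths the mean
normalized total equals the reported `mean_adjusted_control_total` by
construction but not the raw mean. The ancient library is placed on the
control scale by the adjustment ratio `mean_adjusted_control_total /
ancient_total` (worked inputs 1145.5 / 1938 → 0.59).

## 4. Endogenous content (phylogenetic intersection)

Each unique sequence carries a ranked hit list. Sequences with no hits
or with tied top-two scores are discarded as uninformative. Otherwise
the sequence is assigned the lowest common ancestor (LCA) of its top two
hits (a single hit assigns its own taxon); an LCA at the root, or a hit
taxon absent from the tree, is *unknowable*. A sequence counts as
**exogenous** only if it both fails damage-aware genome mapping *and* is
not lineage-consistent (LCA on the target lineage). The endogenous
proportion is 1 minus the frequency-weighted exogenous share; accuracy
is the on-lineage weight among intersecting, genome-mapping sequences.

## 5. Decay kinetics and GC analysis

First-order decay from per-seed nucleic-acid mass:
`T½ = T·ln 2 / ln(V₁/V₂)` with `T` the elapsed years, `V₁` the modern
and `V₂` the ancient mass (µg/seed). The degradation fold is
`T½(DNA) / T½(RNA)`; the reference DNA half-life (350 yr by default) is
an explicit input, not a constant.

GC content is computed with U canonicalized to T and N excluded from
both numerator and denominator. GC% is binned into half-open,
lower-inclusive 0.1-point bins `[k/10, (k+1)/10)` (100.0 folds into the
top bin); a miRNA family's *GC location* is the bin holding the
plurality of its sequence frequency, ties resolved toward the lower bin.
Plurality, not majority, is used because with 1000 bins a strict
majority rarely exists.

## 6. Numerical choices

- **Likelihood grid:** 2001 points, linear from `max(10⁻³, x/10)` to
  `10·max(x, 1)`. Wide enough that the truncated tail mass is
  negligible for the 95% interval at any count the pipeline produces.
- **Kernel accuracy:** the `x ≥ 50` Normal form with variance `r·λ`
  deviates from the exact Poisson likelihood by about 2.4% of the peak
  pointwise at `x = 100`, `r = 1` — an intrinsic property of that
  functional form, not a numerical error. The quantities that drive
  calls (interval endpoints and mode) agree with the exact-Poisson
  oracle to better than 2%, which is what the tests assert, alongside a
  3% pointwise guard. Interval coverage in λ-recovery is checked
  empirically (95% ± 3% at 2000 replicates).
- **Regime switch:** interval endpoints are continuous (within 10%)
  across the `x = 50` switch at `r = 1`. For `r > 1` the extended branch
  is wider by ≈ √r by design — the Poisson branch deliberately ignores
  overdispersion at low counts, where the variance/mean estimate is
  unstable.
- **Bin edges:** a 10⁻⁷ guard absorbs floating-point representation
  error when a GC percentage sits exactly on a bin edge.
- **Determinism:** every stochastic step draws from
  `numpy.random.SeedSequence(seed, spawn_key=…)` with a fixed spawn key
  per purpose, so one master seed reproduces references, libraries and
  reports byte-identically.

## 7. The synthetic generator

Generator defaults are the study conditions used throughout the tests
and acceptance run.

What it emulates:

- 19 control libraries plus 1 ancient library; read length 50 nt with a
  3′ adapter (`TGGAATTCTCGGGTGCCAAGG`) appended and truncated;
- sRNA-sized insert fractions 0.59 (ancient) / 0.17 (modern), rRNA
  dominance 0.71 / 0.23, retroelement shares 0.0024 / 0.0112 among
  sRNA-sized reads, with 10% relative jitter of the rRNA/retro class
  fractions across controls;
- 23 miRNA families with heavy-tailed (log-normal, σ = 2) abundances;
  three planted effect families fixed at 10% of miRNA weight each:
  `mir159` ×4, `mir319` ×4, `mir396` ×0.25 in the ancient library;
- per-family counts drawn negative-binomially so that variance =
  `r` × mean (`r = 2` by default);
- strand-polarized C→T deamination at rate δ = 0.02 per at-risk base in
  the ancient library only;
- target messenger transcripts (GAMYB, PCF5, PCF6) with an elevated
  PCF:GAMYB fragment ratio (10:1) in the ancient sample;
- a small taxonomy and hit-list generator for the endogenous-content
  stage (default mixture: 90% genome-derived, 10% tie rate).

Read budgets (30,000 per control, 100,000 ancient) are a package choice
to keep a full run fast on one CPU while leaving per-family counts large
enough for the statistics stage; they are not the sequencing depths of
any real experiment, which is why per-sample depth enters the model only
through ratios.

What it does **not** emulate: position-dependent damage profiles (δ is
uniform along the read), fragment-length decay curves, sequencing error,
quality-score variation (all bases written at Q40), PCR duplication
structure, multi-locus miRNA families, isomiRs, or a realistic
metagenomic background (exogenous PIA reads are random sequence, not
real contaminant genomes).

## 8. Limitations

- Calls rely on disjoint 95% intervals with no multiple-testing
  correction across families; the family-wise error rate is not
  analytically controlled. The default-seed acceptance run recovers
  exactly the three planted calls with none spurious, but at other seeds
  a single spurious down-call can appear (the acceptance script reports
  `n_up_calls`/`n_down_calls` for its own seed).
- The flat prior on λ is improper and the interval is central, not
  highest-density; for very small counts the two differ.
- `r` is assumed shared across families; family-specific dispersion is
  averaged away.
- The half-life estimate inherits the single-compartment first-order
  decay assumption and the accuracy of the per-seed mass and dating
  inputs; only the dating bounds are propagated, not mass uncertainty.
- Endogenous-content accuracy depends on the completeness of the hit
  database and taxonomy; *unknowable* assignments are conservative but
  reduce power.
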