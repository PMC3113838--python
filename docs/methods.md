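# Methods

This note documents the models, parameter choices and numerical conventions
behind `mitomir`, and what the synthetic-data tests do and do not establish
about real data.

## Array enrichment model

One hybridization compares the mitochondrial (Hy5-labeled) and cytosolic
(Hy3-labeled) RNA fractions of the same cells on a spotted array in which
every probe appears in quadruplicate and 18 spike-in calibrator oligos are
added in equal amounts to both samples. The processing chain per array is:

1. **Net intensity**: foreground minus local background, per spot and
   channel. Negative nets are possible and always fail the filter.
2. **Detection filter**: a spot is kept iff its net intensity is at or above
   the 50th percentile of that channel's background intensities — in *both*
   channels. The percentile uses the mean-of-middle-two median convention.
   An optional calibrator adjustment scales each channel's threshold by the
   ratio of its median calibrator net to the geometric mean of the two
   channels' median calibrator nets; it is off by default because no precise
   adjustment formula is standard.
3. **Ratio and normalization**: Hy5/Hy3 ratio of nets per kept spot, divided
   by the median calibrator spot ratio. Because calibrators are spiked
   equally into both channels, their median ratio estimates the dye/scanner
   gain asymmetry; after normalization the calibrator median is 1 and any
   global per-channel intensity scaling cancels exactly.
4. **Aggregation**: arithmetic mean of the kept replicate-spot ratios per
   probe (the aggregation the protocol prescribes). A consequence worth
   knowing: swapping the two channels maps each spot ratio r to 1/r exactly,
   but the arithmetic mean of reciprocals is not the reciprocal of the mean,
   so log2 antisymmetry under a channel swap is exact only when replicate
   spots agree (it is tested exactly at zero noise and to 0.05 under noise).
5. **Classification** at fold cutoff c (default 1.5): *mito* iff the
   normalized ratio is ≥ c in every array where the probe passed the filter,
   *cyto* iff 1/ratio ≥ c in every such array, otherwise *unchanged*;
   probes passing in fewer than `min_arrays` arrays (default: all provided
   arrays) are *filtered*. This per-array rule encodes "reproducibly
   enriched"; a mean-based mode (cutoff applied to the cross-array mean) is
   provided because either reading of the cutoff is defensible. The reported
   fold is max(m, 1/m) of the cross-array mean m, i.e. ≥ 1 in the direction
   of the call.

The source protocol's printed filter condition uses "<" where its prose says
"equal or higher"; this implementation keeps spots at-or-above threshold in
both channels and reads the printed "<" as the exclusion condition.

## Synthetic array generator

Per probe, a true abundance is drawn log-normally (median 5000 a.u.,
log-sd 0.5) and shared across arrays (one biological sample, several
hybridizations). Per spot: foreground = background + abundance × fold ×
dye-bias(Hy5 only) × lognormal noise with mean 1 and a chosen CV; the
additive background is drawn per spot (normal, mean 200, sd 40, clipped at
0) and reported exactly in the background column. Calibrators always have
true fold 1. With zero noise the normalized mean ratio equals the planted
fold exactly.

Defaults emulate the study conditions: 1460 miRNA + 97 control probes in
quadruplicate (6228 spots), 18 calibrators, three arrays, noise CV 0.1,
13 probes planted mitochondria-enriched with folds drawn log-uniformly over
[1.5, 56] (the observed enrichment range; a draw rather than a fixed grid,
since per-probe folds are not published, and a probe sitting exactly at the
1.5 decision cutoff is detected only half the time by construction — no
classifier can do better at the boundary). 44 probes are planted
cytosol-enriched with reciprocal folds log-uniform over [1.5, 20].

What these simulations do **not** model: spatial artifacts, print-tip and
intensity-dependent dye bias, saturation, probe cross-hybridization, or
correlated backgrounds. Passing the recovery tests therefore shows the
chain implements its stated rules and is well-behaved under ratio-scale
noise, not that it is robust to every failure mode of physical arrays.
The measured background equals the drawn background (no background
estimation error); real arrays add a small extra variance term there.

## Co-localization statistics

Pearson's rp is computed over all paired pixel intensities without
thresholding or background subtraction (matching common plug-in defaults;
optional thresholds can be applied by the caller before invoking). The CCF
shifts one channel horizontally by dx ∈ [−max_dx, +max_dx] and computes rp
over the cropped valid overlap only — no wrap, no zero padding, which would
bias rp toward 0. The curve convention is CCF(dx) = rp(A(x), B(x + dx)), so
a structure present in B at x + s peaks at dx = +s; ties at the peak resolve
to the smallest |dx|.

Bell/hollow classification is inherently a quantification of a by-eye
judgment, so it is explicit and configurable: *bell* if the curve's maximum
lies within a center window (default max(1, max_dx/5) pixels) of dx = 0 and
exceeds the mean of the outermost 10% of shifts by ≥ 0.1 rp units; *hollow*
symmetrically for the minimum; else *flat*. The image generator places
Gaussian puncta (σ = 2 px); in its mutually-exclusive mode the second
channel's puncta keep ≥ 4σ from the first channel's centers — adjacent but
non-overlapping staining — which produces the characteristic dip at dx = 0.

## Seed scanning and the Poisson null

A site for a miRNA on strand s at forward position p means the s-strand
sequence read 5'→3' over the k-window equals the reverse complement
(RNA→DNA) of the seed. The seed is the 5' heptamer by default
(`k=7, seed_start=1`); `seed_start=2` gives the canonical nucleotide 2–8
seed. Circular genomes are scanned across the origin with a (k−1)-nt wrap;
both strands are scanned by default because both mitochondrial strands are
transcribed. Exact mature mapping is the same machinery at full length.
Coordinates are 1-based inclusive on the forward strand; origin-spanning
hits have end < start and are split into two intervals for annotation
overlap. Annotation overlap is any-overlap and ignores feature strand
(polycistronic mitochondrial transcription means a site need not lie in the
gene it affects); hits outside every feature are labeled *intergenic*.

Significance of n observed hits: λ = n_positions × per-position match
probability, with n_positions = 2L (circular, both strands) or 2(L−k+1)
(linear), and the match probability either ∏ genome mononucleotide
frequencies over the required site bases (default — mitochondrial DNA is
AT-skewed) or uniform 4^−k; p = P(X ≥ n) for X ~ Poisson(λ), p = 1 at
n = 0. Known limitation, deliberately kept: no clumping correction for
self-overlapping seeds, and position dependence is ignored — the plain
Poisson is the stated model. Both composition modes and both position
conventions are exposed so their outputs can be compared; no single
convention is privileged as "the" published one.

## Folding energy model

The engine optimizes over all nested structures with Watson–Crick and G·U
pairs, hairpin loops ≥ 3 nt and no pseudoknots. A structure's energy is

* one stacking term per directly nested pair, constant per unordered
  combination of pair classes (kcal/mol): GC/GC −3.3, GC/AU −2.4, GC/GU
  −1.5, AU/AU −1.1, AU/GU −1.0, GU/GU −0.5 — magnitudes in the spirit of
  nearest-neighbor tables, symmetrized and orientation-free for
  self-containedness;
* one linear hairpin penalty 3.0 + 0.3(L−3) per hairpin loop of length L;
* no bulge/internal/multiloop terms.

The open chain scores 0, so MFE ≤ 0 always. The dynamic program is the
standard interval recursion (V for "closing pair", W1 for "at least one
pair"), O(n³); its energies are verified against exhaustive enumeration of
all valid structures for short sequences. Ties between co-optimal
structures break by a fixed branch-preference order in the traceback (pair
the leftmost base, smallest partner, stacking branch first), which is
deterministic and favors '(' early in the dot-bracket string; it is not a
certified global lexicographic minimum over all co-optimal structures —
only the energy is certified optimal.

This reduced model ranks hairpin stability consistently with a full
Turner-model folder (checked against RNAfold on a stem-length ladder) but
its absolute energies are not Turner energies. For parity with externally
published MFE values, `feature_table` accepts a per-id external MFE file
that overrides the engine and is flagged in the output. AMFE and MFEI are
exact arithmetic identities on whatever MFE is recorded: AMFE =
(−MFE/L)×100, MFEI = AMFE/(G+C)%; MFEI is undefined at GC = 0 and reported
as missing.

The hairpin generator returns left-arm + all-A loop + reverse-complement
right arm; with loop ≥ 3 the full stem is the model optimum, giving planted
structures for the oracle and monotonicity tests.

## Group statistics

* Conservation: 0 iff the species list is exactly {human}; 2 iff more than
  two distinct taxonomic orders are present; else 1. The boundary case of
  exactly two orders is not covered by the published footnote ("conserved in
  primates" vs "more than 2 orders"); it scores 1 here, the conservative
  reading, since the published table contains no two-order row. The bundled
  table transcribes the published presence lists verbatim, including the
  original spelling "Cetertiodactyla" and the printed order assignments.
* Welch t: scipy's unequal-variance two-tailed test
  (Welch–Satterthwaite df), verified against the closed form via the
  incomplete beta and against a permutation test.
* F-test: F = larger/smaller sample variance, p = min(1, 2 × upper tail) —
  symmetric in the arguments by construction.
* Hypergeometric enrichment: upper-tail P(X ≥ k), verified against explicit
  binomial-coefficient sums; optional Benjamini–Hochberg adjustment for
  multi-category screens (off by default for single tests).

## Pipeline and reproducibility

All randomness flows from one seed; generators use a single
`numpy.random.Generator` consumed in a fixed order, so equal seeds give
byte-identical bundles and result CSVs. The run log records the full
configuration and library versions. A stage failure aborts with the stage
name; earlier outputs are kept. When no annotation is supplied the scan
stage degrades to *intergenic* labels with a warning rather than failing.

Problem sizes in the shipped tests are desk-scale by design: recovery
statistics use the full 6228-spot design over 100 simulated experiments;
folding oracles sweep all sequences ≤ 5 nt and sample lengths 6–12; the
synthetic end-to-end bundle uses a 16 569-nt circular genome and
38–48-nt precursors (real pre-miRNAs are ~80 nt; the engine handles them,
the bundle simply keeps the default run fast).

## Known limitations

* The array noise model is a stand-in (no published noise model exists for
  this design); all its parameters are exposed.
* The Poisson null ignores seed self-overlap clumping and composition
  heterogeneity along the genome.
* The folding model omits loop-type-specific and orientation-dependent
  energies; use the external-MFE path when Turner-level accuracy matters.
* Co-localization operates per provided image; it does not segment cells or
  define regions of interest.
* No dye-swap designs and no between-array quantile normalization — the
  calibrator-based scheme is the one implemented.
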