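# Methods

## Positional classification

Each pre-tRNA locus is modeled as 0-based half-open genomic intervals
tiling `leader → mature body (exon blocks ± introns) → trailer` in
transcript orientation (BED12 on disk: thick span = mature body, blocks =
exons).  From the genome, three reference sequences are extracted per
locus — the precursor transcript, the spliced mature body, and mature +
`CCA` — plus any mature-miRNA references; minus-strand loci are
reverse-complemented so all references read 5′→3′.

Collapsed sequences (reads < 15 nt are discarded; identical sequences are
merged with summed counts, distinct-length isoforms kept separate) are
placed end-to-end at every reference position with Hamming distance ≤ 1.
Any `N` counts as a mismatch; exact placements suppress 1-mismatch
placements; placements on the mature+CCA reference are reported only when
the read runs into the appended CCA, because interior placements duplicate
the plain-mature ones.  The CCA bases are part of that reference, so a
non-templated CCA tail never consumes the mismatch budget — without this,
3′-end fragments of mature tRNAs would be unmappable to genomic sequence.

Class rules, applied to transcript-frame offsets with configurable
tolerances (±1 at the mature 5′/3′ ends, ±2 at leader/trailer/intron
boundaries, absorbing ragged endonuclease cleavage):

| class | rule |
|---|---|
| tRF-1 | 5′ end within [0, +2] of the first trailer base (3′ of the discriminator) |
| tRF-leader | 3′ end within [−2, 0] of the last leader base |
| tRF-5 | 5′ end at mature position 0 (±1) |
| tRF-3 | 3′ end at the mature terminus (±1), CCA-softclipped matches allowed |
| intron-tRF | entirely inside an intron block (±2) |
| misc-tRF | any other mature-body overlap |

A sequence satisfying several rules across loci is resolved by a fixed,
configurable precedence: miRNA > tRF-1 > tRF-5 > tRF-3 > tRF-leader >
intron-tRF > misc-tRF.  Counting is sequence-centric: a multi-mapping
sequence is one countable unit, consistent with isoform collapsing.  These
tie-break choices (precedence order, exact boundary tolerances) were
genuinely open; they are exposed in `ClassifierConfig` so alternative
conventions can be evaluated.

## Half-life estimation

Transcription shutoff (actinomycin D) fixes synthesis at zero, so each
sequence follows first-order decay

    A(t) = A0 · exp(−k t),        half-life = ln 2 / k.

Sequencing, however, observes *compositions*: total cellular RNA shrinks
during shutoff while each library is sequenced to a fixed depth, so stable
species apparently rise.  The correction (decay-profile normalization):

1. **Size normalization** — reads-per-million, or spike-in scaling
   (`counts / library spike-in sum × mean spike-in sum`), which restores
   an absolute scale when spike-ins were added in fixed amount per sample.
2. **T0 normalization** — each sequence divided by its mean normalized
   t = 0 level (sequences absent at t = 0 are excluded and reported).
3. **Stable set** — sequences with an apparent increase: positive OLS
   slope of T0-relative values against time (replicates as points) *and*
   detection (raw count > 0) in at least one library of every timepoint.
   The slope>0 operationalization of "apparent increase" is a design
   choice (no printed threshold exists); both pieces are config-exposed.
   An empty stable set is an error, since the correction is undefined.
4. **Decay factors** — per timepoint, the arithmetic mean of the stable
   set's T0-relative values (replicates averaged per sequence first);
   exactly 1 at t = 0.  Dividing every library by its timepoint's factor
   pins the stable-set mean trajectory at 1 — an algebraic identity the
   tests verify to machine precision, and which makes the operation
   idempotent.
5. **Fitting** — nonlinear least squares over A0 > 0, k ≥ 0 on the
   decay-normalized values (so A0 ≈ 1), initialized from a log-linear
   regression on the positive values; zeros stay in the NLS objective but
   not in the initializer.  If the flat model (k = 0, A0 = mean) achieves
   an equal-or-better sum of squares, the boundary solution is reported
   exactly.  Non-convergence falls back to the log-linear estimate,
   flagged.  Fits need ≥ 3 points over ≥ 2 distinct timepoints; shorter
   trajectories are skipped with a reason.  Replicates enter as
   independent points by default (a mean-per-timepoint mode exists).
6. **Reporting** — half-lives beyond the experiment duration (default cap:
   the largest observed timepoint, 12 h) are reported at the cap with a
   `capped` flag.  Expression filters: sequences with < 10 summed raw
   reads are dropped; ≥ 50 normalized counts in any library flags "highly
   expressed" (both inclusive thresholds, both configurable).

Class summaries report n, median half-life (capped values enter at the
cap), median t = 0 expression, and median per-sequence
`log2((mean_b + pc) / (mean_a + pc))` between requested timepoints with a
0.5-count pseudocount guarding fully decayed species.

## RIP enrichment

Fold enrichment = (mean normalized RIP count + pc) / (mean normalized
input count + pc), per condition; class shifts compare RIP means between
conditions per sequence and summarize by median.  No significance testing
is performed — effect sizes and ranks only.  With spike-in normalization
(spike-ins are added at library preparation, after the IP, hence at equal
absolute amount in both fractions) the folds are on an absolute scale;
with plain depth scaling they are only relative, because renormalizing the
RIP library discards the global pull-down efficiency.  Replicate means,
not pooled counts, feed the ratios.

## Metagene profiles

Profiles anchor every gene at a common boundary (mature 3′ end — the RNase
Z cut — or gene 5′ end), flip minus-strand genes into transcript
orientation, and average read coverage per offset over genes.  Offset +1
is the first base downstream of the anchor; there is no offset 0.  Each
read contributes its count to every offset it covers (a 5′-end-only mode
exists for crosslink-style data).  Values are means per gene, optionally
scaled per million summed read counts; windows beyond chromosome ends are
implicitly truncated.  Total profile mass equals overlapping read mass
divided by gene count, and a global reverse-complement of genome, models
and reads leaves profiles unchanged — both are tested against a per-base
brute-force oracle.

## Synthetic data generator

The generator emulates the structure of a shutoff time course and RIP
pairs while keeping every latent variable known:

* **Genome** — non-overlapping pre-tRNA loci (≥ 50 nt gaps, alternating
  strands): leader 8–15 nt, mature 70–90 nt, an optional 16–30 nt intron
  inserted one base 3′ of the anticodon, trailer 8–25 nt ending in `TTTT`
  (the Pol III terminator) on the coding strand.  One fragment per locus,
  an exact substring at its class-defining position; trailer fragments get
  0–3 nt of 3′-end jitter (variable Pol III termination); half the
  tRF-3s carry a non-templated CCA.  miRNAs are random 21–23-mers.
* **Kinetics** — per-class log-normal decay-rate distributions with a
  stable (k = 0) sub-fraction.  Defaults follow the measured biology:
  trailer median half-life 0.3 h (none stable); mature-body fragments ~6 h
  medians with 20% stable; miRNA median 24 h with 50% stable — beyond the
  12 h cap either way.  Abundances are log-normal per class; trailers get
  the highest per-sequence median (400 units) while the miRNA class, with
  a wide sigma of 2 and 120 genes, dominates total library mass — matching
  real libraries where trailers are the top *median* class at a few
  percent of total reads.
* **Libraries** — each library sequences a fixed expected depth (5×10⁵)
  from a pool comprising the simulated species plus an unreported
  background mass (1× the simulated pool at t = 0) decaying at
  `total_rna_decay_k` (default ln 2 / 12 per hour: the bulk pool halves
  over the course).  Counts are negative-binomial with variance
  `μ + 0.05 μ²`; `noise=False` returns exact expectations for closed-form
  tests.  52 spike-in species (the size of a standard miRNA QC spike-in
  panel) keep constant absolute abundance.  Sequencing depth and replicate
  dispersion are not published for the original libraries, so these two
  are free parameters, flagged in the config.
* **RIP pairs** — RIP expected abundance = input abundance × per-sequence
  enrichment fold (log-normal per class: miRNA 8×, tRF-3 1.5×, trailers
  0.5×), renormalized to depth; spike-ins enter both fractions at constant
  absolute abundance.
* **Reproducibility** — one NumPy generator seeded from `SimParams.seed`;
  draw order is genome/annotation → kinetic truth → library counts.

What the generator does *not* emulate — and therefore what passing
recovery tests cannot show about real data: sequence-dependent ligation
and GC bias, RNA modifications blocking reverse transcription, partial
degradation intermediates shortening below the cloning cutoff mid-course,
batch structure across replicates, and genuine multi-locus tRNA gene
families with near-identical bodies.  Classification accuracy on real
libraries will be bounded by annotation quality rather than by the
mapping rules tested here.

## Problem sizes and numerical choices

The default study conditions are ~260 endogenous sequences (40 trailers,
30 + 30 mature-end fragments, 5 leaders, 15 intron, 20 internal, 120
miRNAs) plus 52 spike-ins, six timepoints (0–12 h) in triplicate; the
half-life recovery experiment uses 500 sequences with k log-uniform in
[0.1, 5] /h; oracle-equivalence checks run on toy references under 5 kb.
These sizes keep every ground-truth recovery statistically meaningful
(medians at n ≥ 20, Spearman at n = 500) while the whole suite and the
acceptance script each complete in well under a minute.

Fitting uses scipy's trust-region reflective least squares with bounds
`A0 ∈ (0, ∞)`, `k ∈ [0, ∞)`; the independent check is a profiled grid
search (optimal A0 in closed form per k, k step 10⁻³).  Ties at the k = 0
boundary resolve to exactly 0.  Degenerate inputs are rejected with named
errors: zero library totals, empty stable sets, sub-3-point trajectories,
negative counts (naming the row), malformed BED12/GFF3 lines (naming the
line number).

## Known limitations

* The half-life model is single-exponential; biphasic decay (e.g. a
  protected sub-pool) biases fits toward the slow phase.
* Stable-set detection is slope-sign based; at very low depth, noise can
  admit slowly decaying sequences into the stable set and shrink decay
  factors toward 1.
* Sequence-centric counting cannot apportion multi-mapping fragments
  between paralogous loci; locus-level abundances are therefore not
  produced.
* Differential-expression testing (negative-binomial Wald tests, batch
  correction) is deliberately out of scope; the package emits filters,
  normalized counts and fold changes that such tools consume.
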