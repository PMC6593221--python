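# Methods

## The read-accounting model

The package analyzes checkerboard validation experiments in which every
well's intended content is known: source wells hold one high-biomass
isolate, sink wells hold one shared low-biomass isolate, and blank (NTC)
wells hold nothing.  Three assumptions drive the accounting:

1. **Exact-match identity.** An sOTU tag belongs to a panel isolate iff
   it is identical to one of that isolate's reference sequences over the
   trim length (default 150 bp, read-1 orientation; no mismatch
   tolerance, no reverse-complement search).  A label may own several
   sequences, since one genome can carry several distinct rRNA operons.
   Near-matches (≤2 edits, typically denoiser artifacts) are reported as
   a diagnostic column but never reassigned.
2. **Foreign panel reads are well-to-well transfer.** Any read of a
   panel isolate observed in a well where that isolate was not placed is
   counted as W2W contamination.  The rule is symmetric: sink-isolate
   reads in source wells count as W2W the same way source reads in sink
   wells do.  Reads of the off-plate control isolate are the one
   exception — they can only arrive through index misassignment, so they
   are tallied under background in per-well partitions (keeping
   `expected + w2w + background = total` exact) and counted separately by
   the barcode-leakage analysis.
3. **Counts are analyzed unrarefied.** Dataset-wide singletons are
   removed; everything else is kept at observed depth so contamination
   fractions stay interpretable.  Samples below a configurable
   minimum-read threshold (default 1) are excluded from group summaries.

Group summaries follow the conventional definitions: prevalence is the
percentage of samples with ≥1 W2W read (no read floor); composition
statistics are mean/median/max of per-sample W2W (and background) read
fractions in percent, with midpoint medians for even n; the W2W share of
richness is the mean over samples of (#W2W sOTUs / #observed sOTUs).

## Spatial analysis

A contamination event is a (foreign label, well) pair with ≥1 read.  Its
distance is the Euclidean ("Pythagorean") distance in well units to the
nearest well where the label belongs — the minimum over origin wells is
the conservative choice for labels occupying several wells.  Histograms
are emitted both event-weighted and read-weighted (bin width 1.0 starting
at 0, half-open bins).

`fit_decay_length` estimates the scale ℓ of an exponential transfer
kernel K(d)=exp(−d/ℓ).  Raw read counts cannot be regressed on distance
directly: sequencing normalizes each well to fractions, so a transferred
isolate's reads are divided by the recipient's total template, which
varies with proximity to sources.  Dividing each event's reads by the
*same sample's background reads* cancels that denominator (the background
load is shared across wells), leaving a quantity proportional to K(d).
A least-squares fit of log(reads/background reads) against distance,
weighted by √reads (the appropriate weight for log-Poisson counts, which
also lets well-measured short-range events dominate), returns
ℓ̂ = −1/slope.  Events in samples with fewer than 10 background reads are
excluded as too noisy to normalize.  On ten simulated plates at ℓ=1.0 the
estimator lands within ~8% of truth; a mild upward bias remains because
multi-well labels use minimum distance and very distant events are
presence-censored.

## Rank tests

Group comparisons use the Kruskal-Wallis test (≥2 groups) and the
two-sided Mann-Whitney test (exactly 2), via scipy, with midrank tie
handling.  Mann-Whitney uses the exact null distribution when both groups
have ≤20 tie-free observations and the tie-corrected normal approximation
otherwise; Kruskal-Wallis always uses the chi-square approximation (no
exact mode exists in scipy).  No multiple-testing correction is applied
by default; a Benjamini-Hochberg option is available to users.

## The simulator

`simulate_extraction_plate` generates one extraction plate in four steps:

1. **Layout.** Default checkerboard: 24 source wells drawn round-robin
   from 16 labels, 24 sinks, 48 blanks, with high-biomass wells on one
   grid parity so no two same-label sources are adjacent.  Real plate
   maps load from CSV.
2. **Transfer.** Each occupied well sheds `transfer_mass × cells` during
   extraction; the shed mass lands on other wells with probability
   ∝ K(d), K exponential by default (power-law and nearest-neighbor
   kernels are pluggable).  Realized transferred cell counts are Poisson
   around the kernel means — extraction-stage stochasticity is what makes
   two extractions of the same layout differ more than two PCRs of the
   same extraction.
3. **Background.** A seeded pool (default 200 tags) with heavy-tailed
   lognormal relative abundances (σ=2) mimics a shared kit contaminome;
   every well receives Poisson cells around `background_load ×` profile.
4. **PCR + sequencing.** Per-tag lognormal amplification factors
   (cv `pcr_noise_cv`) multiply the realized composition, then reads are
   drawn multinomially at the sample's depth (itself lognormal across
   samples with cv `depth_cv`).  PCR replicates redraw only this step
   from the same composition.

Every read is tracked by class (expected / w2w / background), so the
quantifier can be checked against ground truth with zero tolerance.
Determinism: the reference panel and background pool depend only on the
master seed; the extraction realization adds the extraction id; the read
draw adds the PCR replicate id.  Sub-seeds are derived by hashing, so any
plate/replicate is reproducible in isolation.

### Parameter defaults

| parameter | default | units | why |
|---|---|---|---|
| `cells_source` | 1e7 | cells/well | stated high-biomass input |
| `cells_sink` | 1e5 | cells/well | stated low-biomass input |
| `cells_blank` | 0 | cells/well | no-template control |
| `transfer_mass` | 1e-3 | fraction of donor cells | calibration, see below |
| `decay_length` | 0.7 | wells | short-range kernel: neighbors dominate |
| `background_load` | 500 | cell-equivalents/well | calibration, see below |
| `background_pool_size` | 200 | tags | typical kit-contaminome richness |
| `depth` | 30,000 | reads/sample | routine MiSeq per-sample depth |
| `depth_cv`, `pcr_noise_cv` | 0.3 | — | moderate library-prep variation |
| `trim_length` | 150 | bp | read-1 exact tags |

No quantitative transfer magnitude is available to copy, so
`transfer_mass` and `background_load` were fixed analytically such that a
blank adjacent to sources receives a few thousand transferred
cell-equivalents against a few hundred background ones, putting the
simulated plate-extraction NTC median W2W fraction in the high
(0.4–0.9) range reported for robot plate extractions.  This calibration
is the package's own choice and is not revisited per run.

### What the simulator does and does not emulate

It reproduces the features the statistics depend on: biomass contrast
across roles, distance-decaying transfer, a shared background pool,
replicate structure (PCR vs extraction), depth variation, and count-level
index leakage.  It does **not** model sequence-level error (chimeras,
per-base miscalls — tags are emitted exactly), taxon-specific
amplification bias, primer mismatch, the physical transfer mechanism
(aerosols, foam), or plate-edge effects.  Passing tests therefore
demonstrate that the *accounting* is correct and that the analysis
recovers known generative structure; they do not certify behavior on
denoiser artifacts or real kit lots, which is what the near-match
diagnostic and the configurable panel are for.

## Numerical and degenerate-input conventions

* Fractions of an empty sample (0 reads) are reported as 0 with an
  explicit `empty` flag; such samples are excluded from composition
  statistics.
* Zero-crossover barcode leakage reports the upper bound `1/total_reads`
  rather than a rate of 0.
* Bray-Curtis and Jaccard raise an explicit error when both vectors are
  empty instead of returning NaN.
* Replicate pairs with a missing or empty member are reported and
  skipped, never silently dropped.
* Layout parsing is strict: 96 distinct wells, labels `A1`–`H12` with no
  zero padding, source wells must carry a label.

## Problem sizes

Tests and the acceptance script run single 96-well plates (≈30k
reads/sample, ≈200 background tags), ten plates for decay-length
recovery, and 2 extractions × 2 PCR plates for the replicate contrast —
sizes at which every statistic of interest is already stable across
seeds.

## Known limitations

* The decay-length estimator assumes an exponential kernel and a shared
  background load; strongly well-specific contaminomes would break the
  normalization.
* Prevalence saturates at 100% quickly in simulation (every blank near a
  source receives some transfer), so prevalence contrasts between
  conditions are better studied via composition fractions.
* Classification is strict exact matching by design; datasets denoised
  with different trim lengths must be re-trimmed to the panel's length.
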