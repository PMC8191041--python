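# Methods

`nanofork` is a desk-scale re-implementation of a two-stage pipeline for
mapping DNA replication on single molecules: detect the thymidine analogue
BrdU (5-bromo-2'-deoxyuridine) in nanopore raw current at single-nucleotide
resolution, then interpret each molecule's BrdU pattern into leftward and
rightward replication-fork probabilities and call origins and termination
sites.  Because the original sequencing datasets and trained weights are not
part of this package, a synthetic-signal generator provides training and
evaluation data with exact per-thymidine ground truth.  This note records the
models, the parameters that matter, and what the synthetic setting does and
does not establish.

## Synthetic pore model

A pore model maps every 6-mer in the pore to the mean and spread (pA) of the
current it produces.  The bundled model is generated once from a fixed seed
(210609):

* canonical 6-mer means ~ Uniform(60, 120) pA; spreads ~ Uniform(1, 2) pA;
* every B-containing 6-mer (B = BrdU in place of a specific thymidine; all
  2^t − 1 substitution patterns of a 6-mer with t thymidines have entries)
  shifts its canonical counterpart's mean by N(0, 3 pA), with the magnitude
  clamped to at least 1.5 pA, keeping the analogue detectable but noisy.

The table (4,096 canonical + 11,529 analogue rows) is produced
programmatically rather than shipped as data; `write_pore_model` /
`load_pore_model` give the TSV form.  Because analogue shifts are drawn
independently per substitution pattern, they carry **no** learnable sequence
structure — this is deliberately harder than real chemistry, where shifts are
systematic in context, and it shapes the feature design below.

## Signal synthesis

Each simulated read walks its reference 6-mers; position `i` contributes a
geometric dwell (mean `dwell_mean` = 8 samples/base, minimum 1) at the
model's expected level plus Gaussian noise of sd = (model spread ×
`noise_sd_scale`, default 1.0).  Basecalls are error-free (basecalling is out
of scope) and all cohorts are forward-strand.  Seeded runs are
bit-reproducible; each read derives its generator from (cohort seed, read
index).

Labelling protocols:

* **uniform** — every thymidine carries BrdU independently with probability
  `substitution_rate` (the titration-experiment regime: 0, 26, 38, 49, 69,
  80%).
* **primer_extension** — a fixed 80 bp forward-strand construct whose
  thymidines at 1-based positions 30 and 36 are always BrdU, all others
  never.
* **g1_release** — all origins fire at the pulse start; the local
  substitution probability ramps linearly from 0 to `p_max` = 0.8 over
  `rise_length` = 10 kb of fork travel, then stays constant.  The ramp is a
  stand-in for analogue-pool equilibration; its in-vivo shape is not known,
  and the chosen length also keeps fork direction locally decodable deep into
  a track.
* **pulse_chase** — asynchronous molecules; each molecule's origins fired
  0–3 min (`firing_offset_max`) before a 4-min pulse; the footprint is a
  plateau of `fork_speed × pulse_duration` = 7.2 kb at `p_max` followed by
  exponential decay with characteristic length `chase_decay_length` = 5 kb
  along the direction of travel.

Fork speed defaults to 1,800 bp/min.  Forks from the origins of one molecule
travel at equal speed, so converging forks stop at inter-origin midpoints.
Per-position fork-direction truth labels are recorded where the local
substitution probability is at least 5% of `p_max`; an origin (termination)
is ground truth *on a molecule* only when both of its diverging (converging)
footprints are visible there — an origin whose footprint decayed away or fell
off the molecule is not recoverable even in principle and is not counted
against the caller.  Truth intervals are the feature midpoint ± 500 bp.

## Signal alignment stage

Raw samples are segmented into events where a two-window mean-shift statistic
(window 2 samples, threshold 1.5 pA) has a supra-threshold local maximum.
The thresholds deliberately over-segment; the aligner absorbs extra events.

Events are aligned to the reference 6-mer sequence by banded Viterbi through
a linear profile HMM with three moves per cell — match (advance both), insert
(extra event, same 6-mer), skip (6-mer without an event) — with fixed
transition probabilities 0.89 / 0.05 / 0.05 and Gaussian match emissions at
the *canonical* expected level (spread pooled with an extra 2 pA so analogue
shifts do not derail the alignment).  The band is ±100 6-mers around the
diagonal; the banded result is tested for equality against an exhaustive
dynamic programme on short reads.  The HMM only localises events; all
BrdU discrimination is left to the network.

## Per-thymidine features and the detection network

For each thymidine whose window fits the aligned span, a fixed tensor of 15
consecutive 6-mers × 13 features is built.  Per 6-mer row: canonical residual
(aggregated event mean − canonical expected level), event spread, log dwell,
scaled expected level, expected spread, one-hot of the starting base,
presence flag, and — for the six 6-mers covering the centre thymidine — the
analogue-hypothesis residual (event mean − expected level with the centre T
replaced by B).  The centre row additionally carries a marginalised
log-likelihood ratio of BrdU vs T at the centre: both hypotheses sum over the
substitution states of up to 8 neighbouring thymidines (flat prior) with a
heavy-tailed emission (93% Gaussian with σ = 0.6 pA on the aggregated event
mean, 7% uniform outlier) that guards against misassigned events.  The
paired-hypothesis features exist because the generator's shifts are
patternless: the network cannot learn shift signatures from sequence, so it
is given the pore-model comparison explicitly and learns to calibrate it
against event quality and neighbour context.

The classifier is a residual network: pointwise stem to 32 channels, six
residual blocks (depthwise convolution of kernel 5 → pointwise convolution →
batch normalisation → ReLU, identity shortcut), global average pooling, and a
two-way softmax (≈9,300 parameters).  Training material is ~2,000 simulated
reads of 800 bp, half unsubstituted and half at 80% substitution, with
per-thymidine labels from simulator truth; 30 thymidines are sampled per
read.  Adam (10⁻³), batch 256, at most 15 epochs with early stopping
(patience 3) on a 15%-of-reads validation split; the best weights are
restored.  The loss weights canonical-T samples 1.5× relative to BrdU
samples: the detector's operating point at the default threshold 0.5 should
favour specificity, because downstream fork calling tolerates missed BrdU
(tracks are smoothed over kilobases) far better than false positives on
unsubstituted DNA.  All randomness is seeded; layers run in float32.

## Fork-direction network and feature calling

The fork stage consumes only the per-read BrdU probability table.  Each track
is summarised into 100-bp bins (mean BrdU probability; capped thymidine
occupancy) and a fully convolutional encoder-decoder maps the 2-channel bin
sequence to per-bin sigmoid probabilities that a leftward / rightward fork
passed: stem, two stride-2 blocks, four dilated residual blocks (dilations
1, 2, 4, 8), two upsample blocks, pointwise head (~26,000 parameters;
receptive field in the tens of kilobases).  Per-position probabilities are
restored by expansion, so the track contract is per-thymidine.  Binning
replaces a per-position spacing channel as the way to handle irregular
thymidine spacing; it is what makes multi-kilobase context affordable here.

The network is trained supervised with per-bin binary cross-entropy (masked
to occupied bins) against simulator fork labels, on fixed-length random
crops of 256 bins from cohorts of both protocols; the "autoencoder" shape is
retained but the target is the fork labelling, not reconstruction.  For
training and for fork-level benchmarks the BrdU probability channel is
emulated directly from truth labels — substituted thymidines draw
probabilities from Beta(8, 2), canonical from Beta(1, 12), approximating the
calibration of the trained detector — because running the full raw-signal
stage over hundreds of ≥25 kb molecules adds cost without changing what the
fork stage sees.  The full signal → detect → forks chain is exercised end to
end at small scale in the CLI tests.

Calling is deliberately tuning-free: per channel, maximal runs of probability
> 0.5 are closed over gaps ≤ 500 bp and kept if they span ≥ 1 kb.  A
leftward-fork segment immediately followed (left to right) by a
rightward-fork segment is a diverging pair and yields an origin call on the
interval between them; the converse ordering yields a termination call;
overlapping paired segments collapse to the overlap midpoint ± 1 bp; lone
segments yield only fork calls.  The interval between diverging inner edges
is reported as the confidence interval — under simultaneous equal-speed
firing it brackets the true origin symmetrically.  Only reads with mapping
length ≥ 20 kb and MAPQ ≥ 20 are used for calling.

## Evaluation conventions

Confusion counts are per-thymidine with call = probability > threshold.
Balanced accuracy is (TPR + TNR)/2 pooled over the held-out cohort;
specificity is TN/(TN + FP) over the thymidines of unsubstituted reads,
mirroring the use of unsubstituted DNA to measure false positives.  ROC
curves sweep 101 even thresholds plus the empirical probability set when it
is small, so small cohorts are exact.  Origin-call distances are measured
from the call-interval midpoint to the nearest known origin interval (0 when
overlapping); signed values are kept for histograms.  Undefined denominators
raise rather than returning silent zeros.

## Problem sizes and determinism

Standard benchmark sizes (the package's defaults, chosen as the smallest
cohorts that give stable estimates): 2,000 training / 300 held-out reads of
800 bp for detection; 273 primer-extension reads; 150 training molecules per
protocol and 200-molecule held-out cohorts of 25–50 kb for fork calling,
with 20% origin-free molecules as negatives.  Every workflow takes a single
seed and derives all stream seeds from it; repeated runs are bit-identical.
Text outputs (detect table, BED, bedgraph) are byte-deterministic; the HDF5
signal container is content-deterministic.

## Known limitations

The generator omits much of what makes real nanopore data hard: systematic,
context-correlated analogue shifts (ours are iid per 6-mer variant),
basecalling and alignment errors, reverse-strand reads, homopolymer dwell
pathology, current drift, and multiple reads disagreeing about the same
locus.  Passing the synthetic benchmarks therefore demonstrates that the
architecture, alignment machinery, feature design and calling logic work and
are internally consistent — not that this exact model would reach the same
accuracy on real flow-cell data, which would require retraining on real
substituted/unsubstituted libraries.  Fork stall/pause calling and
multi-analogue detection are out of scope; the emulated detector channel used
for fork benchmarks is labelled as such wherever it appears.
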