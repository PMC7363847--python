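# Methods

## Overview

`cellcognize` classifies individual flow-cytometry (FCM) events against a
library of predefined cell and bead standards using a small feed-forward
neural network, and converts the resulting per-event class probabilities
into community composition, similarity scores, ecological diversity
indices and biomass estimates. The central assumption is that each
standard — a pure strain culture (possibly split into cytometric
subpopulations) or a calibration bead — occupies a reproducible region of
the seven-parameter optical space (FITC-A/H, FSC-A/H, SSC-A/H, Width), so
that a supervised classifier trained on pure standards can attribute cells
of an unknown community to the most similar standard class.

## Data pretreatment

Raw event tables (CSV export, one row per particle, header naming the
seven parameters) are filtered to a per-parameter intensity window —
lower bound 100 on every parameter, upper bound configurable between 1e5
and 1e7 (default 1e7) — and log10-transformed. Events with any negative
value are dropped at read time. Subpopulations of a standard are isolated
with axis-aligned, inclusive gate boxes in log10(FITC-H) x log10(SSC-H) x
log10(FSC-H); a gate capturing less than 5% of a standard's events
triggers a warning, since smaller clusters are not treated as genuine
subpopulations. Gate boxes are supplied by the user (manifest YAML);
no automatic cluster discovery is attempted, and when boxes overlap the
first matching gate in manifest order wins.

## Anchoring and scaling

Each standard is randomly subsampled to 10,000 events (all events with a
warning if fewer are available). Two synthetic *anchor* events — one at
the log10 lower filter bound on every parameter, one at the upper bound —
are appended to the first standard. Anchors guarantee that the
per-parameter min/max of any concatenated training matrix equal the log
filter bounds, so the [-1, 1] min-max scaling becomes a fixed property of
the filter configuration rather than of the biological data: two
assemblies built from different standards but the same filter share
identical scaling constants, and a stored model can classify any filtered
dataset consistently. Anchors carry the first standard's class label and
take part in scaling, the random split and the training loss, but are
flagged and excluded from every reported metric (their influence is 2
events in ~50,000).

## Network and training

Architecture: 7 input nodes, one hidden layer of 20 logistic-sigmoid
nodes, K softmax output nodes (one per standard class). The loss is the
mean categorical cross-entropy. Optimization is full-batch scaled
conjugate gradient (Møller 1993) — deterministic under a fixed seed, no
learning rate to tune. Weights are initialized from a symmetric uniform
distribution scaled by layer fan (Glorot bounds), biases at zero.

The assembled matrix is randomly partitioned 50% / 25% / 25% into
training, validation and test blocks (counts rounded to nearest).
Training stops at the first of:

* 1000 cycles (`max_cycles`);
* gradient infinity-norm below 1e-6 (`min_gradient`);
* 6 consecutive cycles without improvement of the validation
  cross-entropy (`max_validation_failures`), evaluated once per cycle.

The returned weights are those of the best validation point; the
training log records optimizer, cycles, stop reason and the
cross-entropy on all three blocks. On well-separated synthetic standards
training typically stops by the validation rule after a few dozen
cycles.

The whole procedure — subsampling, anchoring, concatenation, splitting,
initialization, training — is repeated five times with independent seeds
(derived from one base seed via `numpy` seed sequences), giving a
five-member ensemble. Downstream metrics are reported as mean ± SD over
the members, never by pooling confusion counts. Models serialize to JSON
(weights, scaling, labels, training log) and reload bit-exactly.

## Classification and evaluation

Events are classified independently (batch composition cannot affect a
result); each event is assigned to the argmax class, ties broken by
lowest class index. Events outside the scaling bounds are clipped to
[-1, 1] with a warning count. Evaluation reports per-class recall and
precision from confusion matrices (precision of a never-predicted class
is 0, with a warning), plus two accuracy aggregates — the unweighted mean
of per-class recall and the trace/total overall accuracy — because
aggregate "accuracy" is ambiguous between the two conventions. One-vs-rest
ROC curves use a threshold sweep with trapezoidal area.

Spike-in experiments merge a standard subsampled to n events into a
background community (truth label "unknown") and report the correct
predicted classification (CPC): events attributed to the target class(es)
as a percentage of the expected spiked count. CPC can exceed 100% when
background cells are pulled into the target class.

## Similarity and diversity

The winning probability (probability of the assigned class) summarizes
classification confidence. The classification similarity score of a query
population to a standard class is 100 × (mean winning probability of the
query cells in that class) / (mean winning probability of the standard's
own cells), reported at full precision and rounded to whole percent.
Richness counts classes whose relative abundance strictly exceeds 0.05%
(configurable); the Shannon index uses natural log with 0·ln 0 = 0;
Bray–Curtis dissimilarities are computed on counts. Probability
histograms (default 50 bins on [0, 1]) are exposed as data; no additional
histogram-distance statistic is defined.

## Biomass and yield

Per-cell dry weight follows the allometric power law m_b = 435 · V^0.86
(fg, V in µm³); carbon mass is half the dry weight. Community carbon
biomass multiplies each class's mean attributed count (over the ensemble)
by that standard's per-cell carbon mass and sums; lower/upper bounds
propagate the biovolume mean ± SD through the power law before summation.
Bead classes are excluded from biomass sums by default (polystyrene is
not biomass) but can be included with their allometric proxy mass,
flagged in the output. Yields divide produced biomass carbon (end minus
start, floored at 0) by added substrate carbon; both raw and
baseline-subtracted computations are available through the `--baseline-c`
option. Absolute densities rely on volumetric counting:
events / analyzed volume × dilution.

## Synthetic standards

The generator models a standard as a (mixture of) multivariate
Gaussian(s) in log10 space, truncated to the filter bounds by rejection
sampling — matching the ellipsoidal clusters log-transformed FCM
populations form, and guaranteeing zero event loss through preprocessing.
Separation between standards is parameterised in pooled per-axis SD
units. Defaults: per-axis SD 0.15 log10 units (a realistic width for a
stained microbial population spanning roughly half a decade at ±2σ),
10,000 events per standard.

The canned five-standard fixture mirrors the three-strain
proof-of-concept: five classes with centers offset by 1.0 log10 unit on
distinct axes from a common base at 4.0 (pairwise separation ≈ 9.4 SD),
two classes bimodal along a spare axis (subpopulation weights 0.6/0.4) to
emulate within-strain cytometric heterogeneity. Spike-in backgrounds are
mixtures of the non-target standards labelled "unknown", i.e. disjoint
from the target cluster.

What the generator does *not* emulate: instrument noise models, detector
saturation, spectral spillover, doublets, debris continua, and the heavy
non-Gaussian tails of real microbial communities. Passing the synthetic
tests therefore demonstrates the correctness of the pipeline's mechanics
and its behavior as separability varies — not the accuracy attainable on
real lake-water communities, which depends on how well real standards
separate in the seven recorded parameters.

## Numerical choices and degenerate inputs

Softmax and cross-entropy use max-shifted logits (no overflow); the
sigmoid is evaluated piecewise for large |z|. SCG's raise parameter λ is
clamped to [1e-20, 1e20]. Empty event tables classify to empty results
with zero counts; an all-filtered table is a warning, not an error;
subsample shortfalls return everything available with a warning.
Re-anchoring is an idempotent no-op with a warning. Precision of a
never-predicted class is defined as 0. Test problem sizes: the
end-to-end ensemble check trains five replicates at 10,000 events per
standard; the chance-floor and separability checks use 2,000 events per
class, enough for recall estimates with sub-point binomial error.

## Known limitations

* Only delimited event tables are read; FCS containers must be exported
  to CSV first.
* Gates are manual, axis-aligned boxes; irregular subpopulations need
  external gating.
* The classifier is forced-choice: cells unlike every standard are still
  assigned somewhere, visible only through low winning probabilities.
* Probability calibration beyond softmax, hyperparameter search and
  deeper architectures are out of scope.
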