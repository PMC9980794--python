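# Methods

## Text fingerprints and similarity ranking

An entity (drug) is represented by the pooled tokens of its abstracts.
Tokenization lowercases, splits on non-alphanumeric boundaries, and drops
tokens shorter than 3 characters plus a frozen in-package English stopword
list (frozen because the fingerprint definition must not drift with an
external library's stopword list). Weights are TF-IDF with smoothed IDF,

    tf(t)  = raw count of t over the entity's surviving documents,
    idf(t) = ln((1 + E) / (1 + df(t))) + 1,

where `E` is the number of fingerprinted entities (training set plus
candidates surviving the abstract-count filter) and `df(t)` the number of
those entities containing `t`; vectors are L2-normalized. This scheme is an
open, reproducible stand-in for a proprietary text-analytics fingerprint;
no claim of equivalence to any commercial system is made.

Similarity defaults to the cosine against the unit-normalized training
centroid — a single prototype for "similarity to the training set" — with
arithmetic mean of pairwise cosines available as `mean_pairwise`. For
non-negative weights all scores lie in [0, 1]. Ranking sorts by descending
score with ties broken by ascending entity id, so results are invariant to
input order. Candidates with fewer than `min_abstracts` (default 5)
documents are removed before ranking; a `year_cutoff` restricts every
entity to documents published up to and including that year.

Training-set curation removes positives whose literature contains any
exclusion term (case-insensitive whole-token match; multi-word terms must
appear as a contiguous token sequence within one document).

## LOOCV and rank-based ROC

Each training drug is held out in turn, moved into the candidate pool
(subject to the same filters), and ranked against the `N` candidates by
the remaining training set. Tied scores receive the mid-rank:
`rank = #greater + #equal/2 + 1`. Because the pooled entity set is the
same in every fold, the IDF reference and hence all fingerprints are
computed once.

The ROC uses the pairwise Mann-Whitney construction: a positive with rank
`r` gets pseudo-score `N + 1 − r`; the `N` candidate slots get scores
`j − ½`, `j = 1..N`. Sweeping a threshold over the pooled scores gives a
stepwise curve anchored at (0,0) and (1,1) whose trapezoidal area equals
the closed-form concordance AUC `Σᵢ (N + 1 − rᵢ)/(P·N)` to machine
precision, including half-credit for ties (an exact identity, verified on
1000 random fixtures in the test suite). The folds are pooled into a
single curve rather than averaged per fold. An alternative construction
that evaluates FPR only at integer rank thresholds does not satisfy this
identity and was rejected for that reason.

The retrospective mode drops all documents newer than the cutoff year for
every entity, then performs a single hold-out fold. It errors if the
held-out drug has no surviving documents.

## Clearance-screen scoring

Cells are classified cleared/retained by an intensity cutoff derived from
the pooled control cells of each screen replicate. The objective
`frac(neg < τ) + frac(pos ≥ τ)` is piecewise constant between consecutive
pooled unique intensities, so the scan evaluates the midpoint of every
such interval and returns the minimizer (smallest τ on ties); for
well-separated controls this lands midway between the populations. The
selection rule is this package's choice — only the principle that controls
define the cutoff is fixed by the assay.

Per well, clearance = 100 × (#cells below τ)/(#cells). Plate quality is
the Z-factor over control-well clearances, `Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋|`,
with sample (n−1) standard deviations because control wells are few (4 per
role per plate by default). Compound wells are normalized to
percent-of-positive-control per plate (clearance ÷ plate positive-control
mean × 100) to remove plate effects before pooling; a `raw` mode skips
this. MAD z-scores, `z = (x − median)/(1.4826·MAD)`, are computed within
each replicate over the compound values and aggregated per compound by
their mean across replicates (the screen design uses two independent
replicates). Hits are the top-k aggregated z-scores (k = 3 by default,
matching a selection-for-retest design rather than a z threshold); the hit
rate is 100·k/#compounds to one decimal.

## Image quantification

Channels are row-major 2-D rasters sharing one shape. Cell segmentation
passes provided label masks through unchanged (the fixture path); otherwise
it applies Li's minimum cross-entropy global threshold to the cytoplasmic
channel — chosen because it keeps dim cytoplasm above a dark background
where Otsu latches onto the bright organelle mode — fills holes, labels
connected components, and orders labels by descending area.

Red-only (mitolysosome) candidate pixels satisfy mCherry ≥ `mito_threshold`
and `(mCherry + ε)/(GFP + ε) ≥ ρ` with ε = 1 intensity unit to stabilize
the ratio at dark pixels. Components use 4-connectivity (conservative
punctum separation); areas outside [`min_punctum_area`,
`max_punctum_area`] = [4, 400] px are discarded. Defaults ρ = 2.0 and the
area bounds are package choices, exposed in `QuantConfig`. A cell is
mitophagic iff its punctum count strictly exceeds k (default 5); the
strict inequality is configurable because published descriptions of this
rule vary between "more than 5" and "at least 5".

Red-only area fraction = punctum area / mitochondrial mask area, where the
mitochondrial mask is all pixels at or above the mCherry threshold (and so
includes the red-only pixels). Structure (LD/lysosome) area fractions keep
4-connected components of the thresholded structure channel whose
circularity `4πA/P²` — with the Crofton perimeter estimate, under which a
rasterized disk scores ≥ 0.9 — is at least `circularity_min` = 0.6, and
normalize kept area to cell area. Manders coefficients are intensity
fractions: M1 = structure intensity on mitochondrial pixels / structure
intensity in the structure mask; M2 symmetrically for the mitochondrial
channel (hence the mitochondrial channel is an explicit argument).

## Synthetic data

All generators draw from a single `numpy.random.Generator` per call;
identical config + seed gives identical output.

**Corpus.** Background token frequencies are Zipf with exponent 1.0 over
the vocabulary — realistic sparsity for TF-IDF. The signal terms are the
`n_signal_terms` rarest background words (shared specialist vocabulary);
positives draw each token from the signal set with probability β
(default 0.8), decoys from the background only, so β = 0 makes positives
and decoys exchangeable. Defaults: 7 positives (the curated training-set
size typical of this design), 100 decoys, vocabulary 500, 20
docs/entity, 50–150 tokens/doc, years uniform on 2000–2022.

**Plates.** Cell intensities are log-normal (non-negative, right-skewed
like fluorescence): retained exp N(6.2, 0.4²) ≈ 500 AU, cleared
exp N(3.9, 0.4²) ≈ 50 AU. Each well is a binomial mixture with cleared
probability f: negative controls use a floor of 0.02 (exactly zero would
give degenerate zero-variance controls), positive controls 0.78 (the ~78%
clearance typical of depolarizer-treated control wells in this assay),
compound wells 0.35 plus any planted effect Δf. One 96-well plate holds 4
negative-control, 4 positive-control, and up to 88 compound wells; 79
compounds by default, 180–220 cells/well.

**Images.** Cells are disjoint disks (radius 60 px) on a grid with dim
cytoplasmic GFP (20 AU over a 5 AU background) so whole cells are
segmentable; the mitochondrial network is a union of dilated random chords
at 100 AU in both channels; red-only puncta (radius 3) carry mCherry only;
LD spots (radius 5, 80 AU) are placed disjoint from everything, then
mitochondrial signal is painted under exactly `round(f·N)` of each cell's
N LD pixels, so the achieved intensity-overlap fraction (recorded in the
truth) is exact for uniform spots. Spot placement is rejection sampling
with a 2-px clearance; 1000 failed attempts raise a generation error.
Gaussian noise (clipped at 0) is added last.

What the generators do *not* emulate: real abstract language (only
bag-of-token statistics), citation or synonym structure, plate edge
effects and dose-response, photobleaching, out-of-focus light, textured
organelle morphology, or anatomy. Passing tests therefore demonstrate the
correctness and calibration of the *computations* under the stated
statistical assumptions, not performance on real corpora or micrographs.

## Problem sizes and determinism in the checks

Monte-Carlo checks use 100 null corpora (vocabulary 200, 50 decoys, 10
docs/entity), 50 planted-signal corpora at the default configuration, and
100 + 100 simulated two-replicate screens (79 compounds, 200 cells/well) —
sizes at which each suite completes in well under a minute per check while
holding the targeted error rates. Statistical tests are seeded; the
uniformity check of null LOOCV ranks draws one held-out rank per replicate
corpus because folds within a corpus share decoys and are not independent.

## Known limitations

- The fingerprint scheme is one documented choice in a large design space;
  rankings will differ from any proprietary text-analytics system.
- The intensity-cutoff rule assumes the control populations overlap little;
  heavily overlapping controls yield a valid but poorly separating τ
  (reported via the misclassification fractions).
- `segment_cells`'s thresholding path is intended for fixtures and clean
  cytoplasmic stains, not for crowded or textured real micrographs.
- Per-region in-vivo read-outs reuse the per-cell machinery with regions of
  interest supplied as label masks; no anatomy-specific logic exists.
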