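# Methods

## Pipeline overview

A recording S(t) ∈ ℝ^{n_c} is band-pass filtered (default 0.5–30 Hz,
4th-order Butterworth applied forward and backward so phase — and with it
inter-channel correlation structure — is untouched), then cut into
windows of w samples with overlap h; window k starts at sample k·(w−h)
and n_w = ⌊(T − h)/(w − h)⌋ windows fit, trailing samples being dropped.
Defaults follow standard practice for the two study shapes the package
emulates: 2.5 s windows with no overlap for short rest/stress recordings,
10 s for long cognitive-load sessions.  The filter family and order are a
design choice of this package; only the cutoffs are dictated by the
problem.

### Band-power (BF) features

Per window and channel the PSD is estimated by Welch's method — Hann
taper, segment length min(w, fs) samples, 50 % segment overlap — and
integrated over I non-overlapping bands (default I = 8: low/high theta
4.1–5.8 / 5.9–7.4 Hz, low/mid/high alpha 7.4–8.9 / 9.0–11.0 / 11.1–12.9,
low/mid/high beta 13.0–19.9 / 20.0–25.0 / 25.0–30.0).  Band membership of
a PSD bin is half-open, [f_low, f_high), so touching edges never double
count.  Band powers are normalized per channel to sum to 1 (each channel
contributes a composition, not an amplitude), flattened channel-major to
an n_c·I vector, and projected by PCA fit on training windows only.  The
estimator choice (Welch, Hann) is a package decision; any consistent PSD
estimator yields the same normalized features asymptotically.

A channel-window with zero in-scheme power receives the uniform 1/I
block (with a warning) rather than NaNs, keeping window counts aligned
with labels.

### TSG features

Window k induces the graph A⁽ᵏ⁾ = corr(X⁽ᵏ⁾) on the channels (Pearson;
zero-variance channels get zero correlations, unit self-similarity, and a
warning).  The graph-of-graphs similarity matrix is

    B[k,k′] = 1 − (D[k,k′] − d_min) / (d_max − d_min),
    D[k,k′] = ‖A⁽ᵏ⁾ − A⁽ᵏ′⁾‖_F ,

with the extremes taken over all index pairs.  Because the pair k = k′ is
included, d_min = 0 identically; B then has unit diagonal and entries in
[0, 1], which is the reading of "similarity" this package adopts as its
default.  The alternative convention (minimum over distinct pairs) is
available as `distinct_pairs_min=True`; it pushes the diagonal above 1
and is provided for comparison only.

The representation is the adjacency spectral embedding Ẑ = U_d Σ_d^{1/2}
of B.  Singular vectors get a deterministic sign (largest-magnitude entry
positive, ties to the lowest index) so repeated runs and platforms agree
bit-for-bit.  The embedding is transductive; held-out or future windows
are mapped by the out-of-sample extension

    T(X) = Σ_k s′(A, A⁽ᵏ⁾) [(ẐᵀẐ)⁻¹ Ẑᵀ]_k ,

where the similarity vector uses the *training* normalizers d_min, d_max
and is clipped to [0, 1] (`clip_oos=True` default): an unseen window can
be farther from a training graph than any training pair, and clipping
preserves the similarity semantics.  (ẐᵀẐ)⁻¹ is computed as a
pseudo-inverse with relative cutoff 1e-12 to tolerate near-zero retained
singular values.  When B is positive semidefinite and its rank is at most
d, T maps training window k exactly to Ẑ_k; for indefinite B (the usual
case) the identity holds on the retained subspace and the discrepancy is
controlled by ‖B − ẐẐᵀ‖.

### Dimension selection

Both feature families select their dimension at the **second elbow** of
the scree plot: the first elbow maximizes a two-piece Gaussian profile
likelihood with pooled variance over all split points; elbow e+1 recurses
on the values after elbow e.  Numerically-zero singular values (relative
threshold 1e-10) are discarded first.  If an elbow already exhausts the
sequence the recursion stops and the full length is returned — the only
case in which "second elbow > first elbow" can fail.  Exactly tied splits
occur for integer-valued inputs; any maximizer is a correct answer and
the implementation returns the earliest.

### Classifier and transfer

The classifier is a random forest with the long-standing scikit-learn
defaults (100 trees, Gini impurity, unlimited depth, √p split candidates,
bootstrap), wrapped so each leaf's class-1 posterior is explicit.
Prediction is a soft vote: the mean leaf posterior across trees,
thresholded at 0.5 with ties going to class 0.  Soft voting is required
for fine-tuned posteriors to influence predictions smoothly — under hard
voting a 0.5 leaf would be ambiguous.

Fine-tuning for transfer replaces every leaf posterior with the empirical
class-1 fraction of the new labeled samples routed to that leaf; leaves
receiving no samples fall back to the uninformative 0.5.  Split structure
is immutable, and the source model is never modified (fine-tuning returns
a copy sharing the frozen trees).

## Experiment protocols

All protocols score per subject-session over seeded random window splits;
every replicate's seeds derive only from (experiment seed, session index,
replicate), so runs are replayable bit-for-bit and settings sharing a
split are exactly paired (querying at ratio 1 reproduces in-session at
p = 0.8 replicate-for-replicate; self-transfer at fraction 0 reproduces
the in-session score).

- **In-session**: stratified split at training proportion p; the TSG
  embedding and BF PCA are fit on training windows only, test windows are
  mapped out-of-sample.  Feature maps never see labels or test windows.
- **Non-constant querying**: fixed 80/20 split; the unsupervised feature
  maps use the full 80 %, the classifier only a labeled fraction r of it,
  so the labeled share of the session is 0.8·r (r = 0.125 ↔ 10 %).
- **Transfer**: maps and forest come from the source session's 80 %
  training split; target windows pass through the source out-of-sample
  map; a fraction f of the target training split re-estimates the leaf
  posteriors (f = 0 is zero-shot) and the target 20 % is scored.  The
  cross-subject harness evaluates every source session whose subject
  differs from the target's (n−1 sources per target for n single-session
  subjects; 2n−2 for two-session cohorts).

Scores are balanced accuracy (mean of per-class recalls) except the
ablation, which follows the convention of reporting standard accuracy.
Cohort standard errors are sd(per-subject means)/√n_subjects.  Window
splits are random over windows, so adjacent (correlated) windows can fall
on opposite sides of a split and inflate in-session scores; this
reproduces the evaluation design faithfully and is one reason in-session
results should be read as an upper bound.  A `block_split` option (off by
default) instead holds out one contiguous window block per class for a
leakage-averse alternative.  Replicate counts default to 20 and are
configurable (`n_replicates`).

The **sensor ablation** re-runs the in-session protocol on every channel
subset of a pool (size ≥ 2 when TSG is involved — a 1×1 correlation graph
is degenerate — and ≥ 1 for BF alone).  A channel's importance is the
mean accuracy over subsets containing it, likewise for pairs; ranks are
descending with ties broken by channel index.

## Synthetic cohorts

Each synthetic channel is a sum of (i) per-channel band-limited
oscillations — white noise band-passed to each band's edges, scaled so
relative band powers follow the class's profile; (ii) shared low-frequency
(4–12 Hz) latent factor processes mixed through per-class loadings; and
(iii) independent white noise.  Oscillations are filtered noise rather
than sinusoids so PSD estimation is exercised nontrivially.

Band-limited components are normalized by the filter's *theoretical*
zero-phase gain (frequency average of |H|⁴), not by each draw's realized
standard deviation.  Realized-sd normalization would pin every
recording's total band power, negatively correlating held-out windows
with training windows of the same recording and dragging null-cohort
accuracy systematically below chance; with the theoretical gain, disjoint
windows stay independent.

Four preset class structures define the study conditions:

- **correlation effect** (loading 0.2, noise sd 0.6): one shared factor,
  class 1 flips the loading sign on half the channels.  Sign flips leave
  every marginal spectrum untouched — band features carry no class
  information — while half the channel pairs swap correlation sign.
- **band effect** (shift 0.025, noise sd 0.5): power moved between the
  two 5-Hz-wide beta bands, channels independent in both classes; the
  equal bandwidths keep correlation-noise statistics matched, so graphs
  carry no class information.
- **combined**: both effects; **null**: identical classes.

Effect sizes were fixed once by calibrating the desk-scale cohorts
(6 channels, 128 Hz, 150 s per class, 20 replicate splits) to the
balanced-accuracy ranges such studies report — the detecting family near
0.8 at an 80/20 split, the other at chance, and the concatenation above
either — instead of saturating at 1.0, where protocol differences (e.g.
the value of extra unlabeled windows) vanish.  Subject-level jitter
multiplies band profiles entrywise by 1+ε, ε ~ U(−j, +j), renormalizes,
and applies the *same* draw to both class specs: jitter is a subject
trait, so a null cohort stays exactly null.  Sessions of a subject share
parameters and differ only in noise realization, which is the "small
inter-session shift" regime the transfer protocol probes.

### What the cohorts do and do not show

The generator plants exactly the two signal types the feature families
are built to detect, with independent windows and stationary statistics.
It does not model 1/f background, artifacts (blinks, muscle), volume
conduction, non-stationarity, or amplitude co-modulation across bands.
Consequences worth knowing:

- Passing recovery tests shows the pipelines detect correlation-coded and
  band-coded class structure at realistic noise levels — not that they
  work on real EEG with its artifacts and confounds.
- Synthetic band-feature PCA spectra have a flat noise tail (no dominant
  physiological modes), so the automatically selected BF dimension is
  much larger here than the single-digit values seen on real recordings;
  the selection rule itself is verified against exhaustive likelihood
  search, and the single-digit behavior is demonstrated on feature
  matrices with the concentrated (geometrically decaying) spectra real
  EEG produces.
- Small-sample cross-validation of balanced accuracy is slightly
  pessimistic (a percent or two below 0.5 on null data is normal at
  60-window sessions); chance-level assertions are made within standard
  errors, not as equalities.

## Numerical and degenerate-input policy

- Identical graphs across all windows (d_max = 0) raise a degenerate-input
  error naming the condition; there is no similarity structure to embed.
- Zero-variance channels and zero-power channel-windows are retained with
  neutral values (0 correlations, uniform band block) plus warnings, so
  window sets never silently shrink.
- Stratified splits that cannot give both classes to both sides skip the
  replicate with a warning rather than failing the experiment.
- EDF export quantizes to 16 bits over a per-channel symmetric physical
  range held to 4 significant digits so the header string and the scaling
  factor are the same number; round-trips are exact to quantization.

## Desk-scale problem sizes

Tests and the acceptance script run entirely on synthetic cohorts of 1–2
subjects, 6 channels, 150 s per class (60 windows of 2.5 s per class),
20 replicate splits per setting, and a 5-channel ablation pool — sizes at
which every experiment completes in seconds to a couple of minutes while
keeping per-replicate standard errors near 2–3 accuracy points.
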