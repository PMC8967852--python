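# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices made where the design was genuinely open, and the
limits of what the test suite demonstrates.

## Epoching and preprocessing

The unit of computation is a 1 s, single-channel, 400-sample epoch.
Recordings are conditioned by an optional re-reference (common reference
or common average), a zero-phase IIR notch at the mains frequency
(Q = 30, applied forward-backward), an anti-aliasing FIR low-pass with
passband edge 180 Hz and stopband at the target Nyquist (Kaiser design,
60 dB) followed by polyphase resampling to 400 Hz, a zero-phase FIR
high-pass with 1 Hz passband edge (Kaiser, 50 dB, transition 0.5–1 Hz,
centered linear-phase convolution with reflected edge padding), and a
crop to 120 s with seizure onset aligned at 60 s. Epoch windows are
half-open [t, t+1 s); the epoch starting exactly at onset is the first
ictal epoch, giving 60 preictal and 60 ictal epochs per channel. A
50%-overlap epoching mode exists for deployment-side augmentation only;
pretraining uses non-overlapping epochs to avoid replicating
subject-specific patterns across samples.

## Engineered features

Band powers use Welch's method with a single Hann-windowed 400-sample
segment (1 Hz resolution). A 1 s epoch leaves no room for segment
averaging while resolving the 2 Hz delta edge, so the default is a
modified periodogram; segment length is configurable. Band intervals are
half-open, the DC bin is excluded from the total power, and the log
absolute powers use base 10 (the reporting convention in EEG band-power
work; configurable).

EI is computed per epoch with the onset-delay term collapsed
(N_d = N_0), so EI = ER; the generalized `n_delay` parameter is retained.
PLHG band-passes the epoch to composite 4–30 Hz (LF) and 30–150 Hz (HFO)
bands with 4th-order Butterworth filters applied forward-backward before
the Hilbert analytic signal; the phasor uses exp(i(Φ_LF − Φ_HFO)) — the
imaginary unit belongs in the exponent of the phase-locking construction.
An alternative mode averages PLHG over the (theta, alpha, beta) ×
(low gamma, high gamma) band pairs; the composite is the default because
it matches the stated composite-band definition of LF and HFO.

First significant digits are floor(|e| / 10^floor(log10 |e|)); zeros map
to digit 0 and are excluded from the digit distribution, which keeps the
Benford comparison well-defined. The Cho–Gaines N is the epoch sample
rate (400) for both TDCG and FDCG, even though the FDCG digit pool holds
200 spectral magnitudes — a deliberate fidelity choice, with the rate
passed explicitly so either convention is available. FDCG pools the
one-sided FFT *magnitude* with DC dropped; a squared-magnitude flag
exists because either reading of "power spectrum from the FFT magnitude"
is defensible.

## Networks

The three models share one classifier subnetwork (dense
16→14→12→10→8→6→4→2→1, leaky ReLU through width 4, sigmoid on the last
two layers, batch-norm + dropout on the input row and after the width-8
row). Classifier dropout is 0.90 for the TDBB, 0.75 for the FDBB and
0.40 for the EMC. The TDBB encoder is twelve stride-1 convolutions with
"same"-style padding (k = 2p+1, kernels 27 down to 8) and five
max-pooling stages; pooling kernel 6 with stride 2 is the unique
stride-2 geometry that reproduces the intermediate lengths
400→198→97→46→21→8, and the final kernel-8 convolution reduces to one
sample, leaving 16 features. The FDBB encoder consumes the 200-bin
one-sided FFT magnitude (DC dropped, no log scaling) through dense
200→100→50→16 with leaky ReLU and 75% dropout.

Because the architectures require exact layer-level control, the layers
are implemented directly on numpy with hand-written backward passes
(verified by finite differences in the test suite) and an Adam optimizer.
Initialization is uniform fan-in; batch size 128; leaky-ReLU slope 0.01.
Trainable parameter counts are fixed by construction: 8725 (TDBB),
27145 (FDBB), 779 (EMC/classifier).

## Training protocol

Leave-one-subject-out: all epochs of the held-out subject form the test
fold; a seeded random draw of other subjects forms the validation fold
(8 of 24 at full scale; 3 of 9 on the 10-subject synthetic study, keeping
the proportion while leaving 6 training subjects); everything else
trains. Adam at learning rate 0.001 with binary cross-entropy,
early-stopped when validation loss has not improved for 10 epochs, capped
at 200 (the synthetic study caps at 40, which the early-stopping curve
shows is past convergence for these models). The best-validation
checkpoint is restored before test evaluation. AUC, Brier score, PPV,
NPV, recall and accuracy are recorded per fold. Subject-level leakage is
impossible by construction and asserted in tests.

## Narrowband probe

For each center frequency on the grid 2, 4, …, 154 Hz (the stop bound of
155 Hz is inclusive on the grid but never a grid point, since 2 Hz steps
from 2 cannot reach it), the recordings are band-pass filtered with a
biquad (order-1 Butterworth band-pass, 5 Hz bandwidth, applied
forward-backward; ≥ 90% of white-noise power lands within ±5 Hz of the
center). Each filtered *recording* is min-max normalized as a whole and
then scaled so the mean peak-to-peak amplitude of its preictal epochs
matches that of the raw preictal class. Normalizing per recording rather
than per epoch is essential: it standardizes overall scale across
recordings (models are amplitude-sensitive) while preserving the relative
preictal/ictal amplitude contrast inside a recording — the very signal
the probe exposes. Per bin, the probe records the point-biserial
correlation of model outputs and of each encoded feature with the seizure
label, the per-bin AUC, and the mean feature response. The
"negative-class amplitude" statistic is the mean peak-to-peak amplitude
of preictal epochs; other statistics would rescale all bins equally and
not change the correlation structure.

Label correlations of relative band powers are near zero by construction
once all inputs are confined to one narrow band, so the feature-level
localization check (e.g. relative alpha power responding maximally in the
8–12 Hz bins) reads the per-bin mean feature response, not the label
correlation.

## Feature selection and deployment

The 48-feature ensemble concatenates the 16 engineered metrics with the
FDBB (p0..p15) and TDBB (z0..z15) encodings; a subject's epochs are
encoded only by the fold checkpoint that held that subject out, enforced
by a guard that raises rather than silently substituting another fold.
Importances come from random forests (30 trees, entropy splits, depth 5)
fitted on every internal fold of every external held-out-subject fold;
the internal fold count is capped at the sample count, and the synthetic
study uses reduced internal folds (3–5) since the importance distribution
stabilizes quickly at this data size. Ranking ties break by mean
importance then feature name, deterministically. Pearson correlation is
used between features and point-biserial between features and labels;
zero-variance features yield missing correlation entries, not zeros.

Deployment extracts per-channel features, averages encodings over all
fold checkpoints, aggregates channels (concatenation when the channel
count is fixed within a subject; per-feature channel means otherwise) and
fits a per-subject forest with stratified internal cross-validation. The
latency task labels ictal epochs with onset offset < 15 s as positive
(15 of 120 epochs on a standard recording).

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
2-minute, 400 Hz, multi-subject recordings with onset centered at 60 s.
The preictal half is unit-variance 1/f (β = 1) background scaled to
~20 µV plus subject-specific alpha (~10 Hz) and theta (~6 Hz) tones;
the ictal half adds band-limited Gaussian noise calibrated so each gained
band's power ratio is the configured gain (defaults: beta 3×, low gamma
8×, high gamma 5×), plus a ~3 Hz train of biphasic sharp transients whose
amplitude ramps over the first 10 s. Subject parameters are drawn once
per subject (relative spread set by `subject_variability`, default 0.1),
making recordings within a subject correlate. The defaults — 10 subjects
with 4 channels each — define the study conditions used by the test suite
and the acceptance script; they are a deliberate desk-scale stand-in for
clinical cohorts with tens of electrodes per patient.

What the generator does *not* model: biophysical neural-mass dynamics,
artifacts (EMG, electrode pops; line noise only as an optional sinusoid),
non-stationary background drift, seizure-type diversity, and
inter-channel propagation. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that its statistics behave as
designed on signals with known structure — not that the learned features
transfer to clinical iEEG.

Two experiment-design notes. First, the planted-signal recovery
experiment thresholds beta log power *within the preictal class*: planting
across both halves would make the label rule nearly coincide with the
seizure itself, whose power gain correlates all fast-band features and
turns them into legitimate surrogates. Second, the probe benchmark's
expectation that the trained model's peak correlation falls at or above
30 Hz holds for the default gamma-gained generator; configurations with
strong rhythmic discharges additionally carry genuine low-frequency label
information, which the probe correctly reports.

## Known limitations

- Training is CPU-only and single-threaded numpy; the TDBB is therefore
  trained briefly in the nested-importance experiments (its encodings
  enter the ensemble as weakly-trained features) and full-scale TDBB
  pretraining is feasible but slow.
- The multichannel TDBB variant (filter counts multiplied by electrode
  count) is documented but not implemented; channel aggregation happens
  downstream of feature extraction instead.
- EDF export is not provided (no writer dependency); datasets persist as
  per-recording arrays with a JSON manifest, and EDF input is read via
  mne when that package is present.
- Degenerate epochs (exact zeros, zero band power) raise by default;
  batch jobs like the probe run with `strict=False`, which zero-fills
  degenerate entries and is recorded as such.
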