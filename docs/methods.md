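# Methods

## Problem and model

A hybrid brain–computer interface presents, in every trial, both a P300
task (attend the up-center button among 8 buttons flashing in 4 rounds at
120 ms SOA) and a motor-imagery alternative (imagine right-hand movement,
ignore the buttons). The decoding problem is binary: was the trial a
button-attention trial (+1) or an imagery trial (−1)?

The two task signatures live in different statistical orders. The P300 is a
first-order signature: a stimulus-locked deflection visible in the mean
waveform. Event-related desynchronization (ERD) is a second-order
signature: attenuated 8–30 Hz band power over contralateral motor cortex,
visible only in the covariance. Classical hybrid decoders fit one
classifier per modality and fuse scores post hoc; this package instead
fuses the *features* and trains one classifier on both jointly.

Per trial i the package builds

* `X̄⁽ⁱ⁾` (37 × 15): the average of the four target-flash epochs
  (0–600 ms at 60 Hz after 0.1–20 Hz filtering), normalized two-sidedly by
  `Pᵗ X Pˢ` with `Pˢ = Σₛ^{-1/4}`, `Pᵗ = Σₜ^{-1/4}`, where Σₛ, Σₜ are the
  spatial (15×15) and temporal (37×37) covariances averaged over training
  trials;
* `Γ⁽ⁱ⁾` (15 × 15): the channel covariance of the 4 s cue segment
  (8–30 Hz, 100 Hz), whitened by congruence with `Σₛ^{-1/2}` so the mean
  training covariance is exactly the identity;
* the block-diagonal fusion
  `X⁽ⁱ⁾ = blockdiag(X̄⁽ⁱ⁾/ξ₁, Γ⁽ⁱ⁾/ξ₂)` (52 × 30), where ξₖ² is the sum
  over the block's entries of that entry's across-trial variance on the
  training set, so each block enters with unit total variance.

The classifier is linear in the matrix, `f(X) = ⟨W, X⟩ + b`, trained by

```
min_{W,b}  (1/N) Σᵢ log(1 + exp(−yᵢ f(Xᵢ)))   s.t.   ‖W‖* ≤ C
```

where `‖W‖*` is the nuclear (dual spectral) norm — the sum of singular
values. The ball constraint drives W toward low rank: its singular vectors
act as a small set of learned spatial/temporal filter pairs per block, and
the budget C (chosen by stratified 10-fold cross-validation over
0.1, 0.3, …, 9.9) controls how many filters effectively survive and how
the budget is shared between the two modality blocks. Prediction is
`ŷ = +1` iff `f(X) ≥ 0`.

### Solver

Projected gradient descent with Armijo backtracking (halving, constant
1e−4), initial `W = 0, b = 0`, relative-objective tolerance 1e−7,
`max_iter` 2000. Only W is projected; b is unconstrained. Because every
input has exactly-zero off-diagonal blocks, the loss reads only the
diagonal blocks of W, and the pinching inequality guarantees a
block-diagonal optimum: W is therefore parameterized per block and the
projection acts on the concatenated singular values of the blocks
(Euclidean projection onto the nuclear ball = SVD + sort-and-threshold
simplex projection of the spectrum). The recorded objective trace is
monotonically nonincreasing by construction; hitting `max_iter` flags the
model as unconverged rather than raising. Tests certify the trainer
against a Frank–Wolfe solve with a duality-gap optimality certificate and
the projection against an exact KKT enumeration.

Numerical choices: eigenvalues below 1e−10 · λmax are floored before
negative fractional matrix powers (temporal covariances from few trials
can be rank-deficient); covariances subtract the mean and divide by
(n − 1); decision ties (`f = 0` exactly) map to +1, while the PROB baseline
keeps its strict `> 0` rule, so the two tie conventions deliberately
differ.

### Baselines

* **CSP-MI** — generalized eigenproblem `Σ₊w = λ(Σ₊+Σ₋)w`; features are
  normalized log variances of the first/last m = 3 filters; LDA classifier.
* **SL-P300** — stepwise regression (p-enter 0.10, p-remove 0.15, at most
  60 of the 555 flattened ERP dimensions), least-squares weights on the
  selected set. These thresholds are the common P300-speller convention;
  none are prescribed by the source study.
* **PROB-hybrid** — the two LDA scores, each standardized by its
  training-set standard deviation (config switch `raw`/`standardized`),
  averaged and thresholded strictly at zero.

Single-modality ablations (DS-MI, DS-P300) run the same constrained
trainer on one block, scaled by that block's own ξ so the C grid means the
same thing in all three DS variants.

## Synthetic paradigm

Real recordings for this paradigm are not publicly deposited, so the
package ships a seeded generator emulating the acquisition protocol:
15 named channels at 250 Hz; 12 s trials (blank to 2.25 s, fixation cross
to 4 s, cue 4–8 s, 4 s inter-trial); 32 flashes per trial at 120 ms SOA in
4 per-round-random rounds; 50 trials per class per session; two
independent sessions per split.

Signal model: per-channel AR(1) background (a = 0.95, stationary SD
10 µV) mixed across channels by a Gaussian kernel over the electrode grid;
a coherent 10 Hz mu rhythm (6 µV, C3-dominant) with a slow random
envelope; attention trials add a Gaussian ERP (latency 300 ms, width
100 ms, parieto-occipital profile) after each target flash; imagery trials
attenuate the mu envelope by `erd_depth` during the cue window. Flash
schedules are drawn identically for both classes, so timing never leaks
the label.

Default ERP amplitude (8 µV) and ERD depth (0.4) were fixed once so that
each modality *alone* decodes at roughly the 80% level reported for
single-modality decoding of the real recordings — the "moderate SNR, both
modalities informative" regime — and were not revisited afterwards.

What the generator does **not** emulate: eye blinks and other artifacts,
non-stationary noise, inter-subject variability, volume-conduction forward
physics, P300 latency jitter, and overlapping ERP responses to non-target
flashes. A green end-to-end test therefore establishes that the pipeline
recovers the intended first- and second-order structure from realistic
noise at realistic amplitudes — not that it reproduces any subject's
accuracy on real EEG.

## Evaluation protocol

Training statistics (whiteners, ξ, CSP filters, LDA/stepwise weights) are
fitted on training trials only and re-fitted inside every CV fold; fold
assignment is stratified, seeded, and canonicalized by trial id. Ties in
the C search resolve toward the smaller C (stronger regularization).
Per-repetition curves rebuild the ERP block from the average of the first
r ≤ 4 target flashes with ξ₁ re-fitted on the training session's r-epoch
averages (an r-average's variance depends on r); r = 4 reproduces the
standard pipeline exactly, and MI-only methods are flat in r.

Desk-scale protocol in tests and `scripts/acceptance.py`: the C search
runs over the coarse sweep {1, 3, 5, 7, 9} of the standard range (the full
50-point grid costs ~10× more and changes the selected model little at
n = 100 trials).

## Known limitations

* The projected-gradient solver is first-order; very tight tolerances on
  large C need thousands of iterations (use `SolverSettings(max_iter=...)`).
* The stepwise-selection p-values are the classical partial-F ones,
  computed on the ±1-coded label as in the speller literature; they are
  selection heuristics, not valid post-selection inference.
* EDF input is not supported; recordings use the package's delimited
  text + JSON format.
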