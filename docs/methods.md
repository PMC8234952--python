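# Methods

## Pipeline model

The package scores ECG beats for abnormality using only normal data for
training. The processing chain is

    beat window  →  per-lead rescale → PAA → GADF  →  (M′, M′, C) tensor
                 →  MPCA projection → scatter-ranked vec(core)[:p] = ϑ
                 →  one-class score (deep SVDD / classic SVDD / Hotelling T²)

### GADF imaging

A lead window `x` of length `M` is min-max rescaled per lead per cycle
(`x̃ = (x − min x)/(max x − min x)`); a constant lead is a hard error rather
than a silent zero image. The polar angle is `φ = arccos(x̃)` and the
difference field `G[i,j] = sin(φ_i − φ_j)` is evaluated in the closed matrix
form `√(1−x̃²) x̃ᵀ − x̃ √(1−x̃²)ᵀ`. Values are clipped into `[0, 1]` before
`arccos`/`sqrt` to absorb floating-point overshoot, and the diagonal is set
to exactly zero. Pixel `[i, j]` has row `i` = earlier time index; images are
row-major with index 0 at top left.

PAA uses floor boundaries: segment `k` spans indices
`[⌊kM/M′⌋, ⌊(k+1)M/M′⌋)`. For non-divisible lengths this yields near-equal
blocks and is exactly testable by hand; when `M′ | M` the global mean is
preserved, and `M′ = M` is the identity. Rescaling happens before PAA, so
the block means stay in `[0, 1]`.

### Multilinear PCA

Samples are centered by the mean tensor before projection (the underlying
multilinear formulation requires centering even though it is easy to omit).
Mode matrices are initialized from the leading eigenvectors of each mode's
full-projection unfolding scatter; the solver then alternates over modes,
re-solving the mode-k eigenproblem conditioned on the other modes. Each step
maximizes the same objective, so the recorded total scatter is
non-decreasing; iteration stops at a relative change `< 1e−6` or after 20
sweeps. Per-mode dimensions come from a retained-variance fraction (default
0.97) of the initialization eigenvalue mass, or can be given explicitly.
Eigenvector signs are fixed by making each column's largest-magnitude entry
positive, so fits are bit-reproducible across runs.

The single integer `p` (default 10) counts kept entries of the vectorized
core after ranking all `P₁P₂P₃` coordinates by their scatter across the
training samples, descending, ties broken by coordinate index. The
alternative reading — choosing per-mode dims so the whole core has ~p
entries — is available by passing explicit dims; the vectorized reading is
the default because a single integer then describes the feature count
regardless of mode shapes, and because the monitoring chart needs a feature
count far below the Phase-I sample count.

### Deep SVDD

Architecture: bias-free MLP `p → 32 → 16`, leaky-ReLU (slope 0.1) hidden
activations, linear unbounded output, affine-free batch normalization on the
hidden layers. No biases and no bounded output activation remove the trivial
solution in which the network ignores its input; the batch normalization
(normalization only, no learnable shift/scale — the convention of the
reference one-class deep architectures) additionally stops the hidden
representation from contracting uniformly.

Inputs are standardized per dimension with training statistics stored in the
model. The center `c` is the mean initial forward pass over the training
set, with entries below 0.1 in magnitude pushed to ±0.1, and is never
updated. Optimization: mini-batch SGD with momentum 0.9, batch 64, learning
rate 1e−3 with one ×0.1 decay, weight decay λ = 1e−6, all seeded.

**Training length.** The default schedule is 30 epochs with the decay at
epoch 20. With ~10-dimensional inputs and no pretraining, the one-class
objective keeps falling long after detection quality peaks: the network can
progressively map the whole (low-dimensional) input manifold toward `c`,
which shrinks the score contrast between normal and abnormal inputs. We
measured detection degrading monotonically from ~30 epochs onward while the
objective still improved, which is the hypersphere-collapse failure mode in
slow motion; a short schedule is the standard remedy when no autoencoder
pretraining is used. The decision threshold defaults to the 95th percentile
of training scores and is stored explicitly.

An `identity=True` configuration (single layer frozen at the identity,
standardization off, no center floor) reduces the score analytically to the
squared distance to the training-feature mean and serves as the test oracle.

### Classic SVDD

The dual QP (Gaussian kernel; box bound γ, simplex constraint) is solved by
SLSQP from the uniform feasible point with an analytic gradient. γ defaults
to 1.0 and must exceed `1/N₀` for feasibility; the kernel bandwidth defaults
to the median pairwise training distance. `R²` is the kernel-space distance
of the boundary support vectors (those with `0 < α < γ`); their distances
agree at the exact optimum, and the maximum over them is used so solver
round-off at the 1e−7 level cannot push a boundary vector "outside". A point
is anomalous iff its kernel distance² exceeds `R²`.

### Hotelling T² chart

Phase-I mean and covariance (denominator `N₀ − 1`) define
`T² = (ϑ − ϑ̄₀)ᵀ S₀⁻¹ (ϑ − ϑ̄₀)`; the UCL is the empirical `(1 − α)`
linear-interpolation quantile of the Phase-I T² values (α default 0.05).
The empirical quantile is used instead of the F/Beta distributional limit
because the feature distribution after GADF + MPCA is not meaningfully
Gaussian. If the covariance has a zero-variance coordinate or condition
number above 1e10, a ridge `ε = 1e−8 · trace(S₀)/p` is added (features from
thousands of similar cycles can be collinear). T² is affine-invariant when
no ridge is applied. An optional single self-cleaning pass (drop the top 1%
T², recalibrate once) guards unannotated Phase-I data; annotated data should
be filtered by labels instead.

## Synthetic study conditions

The generator emulates what the detectors need from real ECG, not cardiac
electrophysiology. A beat is a sum of five Gaussian deflections with the
default template P(0.15 mV, 0.18, 0.035), Q(−0.10, 0.39, 0.012),
R(1.00, 0.44, 0.016), S(−0.20, 0.49, 0.012), T(0.30, 0.72, 0.060)
(amplitude mV, center and width as beat fractions), 0.8 s period (75 bpm),
period jitter 4 ms, 500 Hz sampling, three leads with gains (1.0, 0.8, 1.2)
and additive white noise of 0.02 mV. The ST shift is an additive plateau
between the S end (center + 2 widths) and the T start, with half-cosine
ramps over 20% of the interval each so no step discontinuity is introduced.

Morphs are deterministic template transformations: AF-like (P amplitude 0,
period jitter 50 ms), BBB-like (Q/R/S widths ×1.8, R amplitude ×0.55),
ST elevation/depression (±0.2 mV added to the resting ST level), T inversion
(T amplitude negated), premature (preceding interval ×0.6 with BBB-like
shape). The ±0.2 mV shift is at the clinical decision threshold for
significant ST deviation; ST shifts add to the subject's resting ST level so
that subjects with nonzero baselines morph consistently.

Two levels of natural variability make the *unsupervised* feature ranking
meaningful, mirroring the two evaluation settings:

* **Patient population** (`sample_patient_spec`): per-subject wave-amplitude
  factors (sd 10%), lognormal width factors (sd 8%), center nudges (sd 0.008
  of the beat), resting ST level (sd 0.03 mV), heart period (sd 0.08 s).
  Cross-patient screening draws every recording from its own subject, takes
  one ensemble cycle (pointwise mean of the segmented beats) per 16-beat
  recording, and segments with a window proportional to the subject's beat
  period (−0.3125 T to +0.5625 T around R, resampled to 128 samples), which
  normalizes heart rate out of the cycle representation.
* **Within-subject cycle variability** (`BeatVariability`): per-beat
  amplitude factors (sd 3%), width factors (sd 2%), ST drift (sd 0.015 mV).
  It is *off by default* — the plain generator renders identical beats given
  identical labels and zero noise/jitter — and is enabled by the monitoring
  protocol, where an in-control distribution would otherwise be degenerate.

What the generator does **not** model: vectorcardiographic 12-lead geometry
(leads differ only by gain, so after per-lead rescaling the lead mode is
nearly redundant), electrode-motion artifacts, baseline wander, respiration
coupling, or beat-to-beat correlation structure. Passing tests therefore
demonstrate that the pipeline recovers morphological deviations exceeding
calibrated natural variability — not that it handles every artifact of field
recordings.

## Evaluation protocol

Screening: per condition, MPCA and the detector are fitted on 300 normal
patients' ensemble tensors (GADF 32 × 32, `p = 10`) and evaluated on 100
held-out normal + 100 single-condition abnormal patients, with the detector's
stored threshold for the confusion metrics and the raw scores for AUROC
(rank-based, ties 0.5). Monitoring: one subject, chart calibrated on 300
normal cycles, Phase II of 400 normal + 100 morphed cycles. Problem sizes
were chosen so the whole grid runs in seconds; all seeds derive from one
integer via a fixed affine hash.

R-peak detection (plumbing, not the contribution) squares the first
difference, smooths over 80 ms, thresholds at `median + 6·MAD` of the
envelope floored at 10% of its maximum (the floor keeps noiseless P/T lobes
sub-threshold and preserves exact scale invariance), enforces a 0.3 s
refractory period, and snaps each candidate to the local extremum of the
signal deviation within ±40 ms. Whenever annotations or generator ground
truth exist they take precedence over the detector.

## Known limitations

* The scatter-based feature ranking is unsupervised: a disease direction
  orthogonal to the normal class's natural variability can be truncated at
  `p = 10`. The cross-patient population makes the relevant directions
  (ST level, QRS shape, T polarity) part of normal variability; on data
  without such variability the ranking, not the detectors, is the bottleneck.
* Deep SVDD results depend on the training length (see above); the package
  default favors score contrast over squeezing the last decades out of the
  one-class objective.
* The SLSQP dual solver is adequate for Phase-I sizes in the hundreds; for
  many thousands of support candidates a dedicated QP solver would be
  preferable.
* UCLs, thresholds and all defaults are calibrated on the synthetic
  conditions above; real deployments must recalibrate per patient.
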