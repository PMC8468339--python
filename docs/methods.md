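# Methods

## Scope and modelling philosophy

`mrisim` targets teaching, not physics research: it evaluates closed-form
steady-state signal expressions on resampled tissue-property maps and
injects artifacts directly in k-space, instead of integrating the Bloch
equations. This is what keeps a 256×256, 10-slice acquisition interactive
(about 2 s on one desktop CPU core, dominated by trilinear resampling), at
the cost of ignoring every time-dependent effect a research simulator would
capture (off-resonance evolution within the readout, chemical shift, flow,
diffusion, eddy currents, parallel imaging).

## Anatomical model

The ground truth is a set of co-registered 3-D volumes: proton density
(dimensionless, in [0, 1]), T1 and T2 (ms), an optional ΔB0 field (ppm) and
an optional integer label map. Geometry follows the NIfTI convention: a
voxel-to-world affine built from voxel spacing (mm), origin (mm) and an
orthonormal direction matrix. Enforced invariants: a single grid for all
components, `0 < T2 ≤ T1` wherever PD > 0, |det| of the direction matrix
equal to 1 within 1e-9.

Phantoms are painted from geometric primitives (ellipsoid, box, slab) in
world coordinates, later tissues overwriting earlier ones; tissue *i* gets
label *i + 1*. The bundled head-like phantom uses literature-typical 1.5 T
values (e.g. CSF ≈ 4000/2000 ms, grey matter ≈ 900/100 ms, white matter
≈ 600/80 ms); these are demonstration defaults, not fitted values. A
pathology is simply an extra tissue primitive painted last.

ΔB0 is synthetic by design — its role is to motivate shimming — and is
generated as white Gaussian noise low-pass filtered with an isotropic
Gaussian kernel whose standard deviation is the requested correlation
length, then rescaled so the peak |ΔB0| equals the requested amplitude.
Any smooth field would do; filtering makes smoothness a single controllable
parameter.

Out-of-volume voxels resolve to PD = ΔB0 = 0 and a 1.0 ms T1/T2 sentinel:
PD = 0 already suppresses all signal, and the positive sentinel keeps every
downstream division finite.

## Planning and reslicing

A plan is an orthonormal frequency/phase/slice triad with in-plane FOV and
matrix, slice thickness and centre-to-centre separation (overlap allowed),
stack centre, and a phase oversampling factor ≥ 1 (the no-phase-wrap
mechanism: the oversampled grid keeps the pixel size and extends the phase
FOV). Sampling is voxel-centred: pixel (i, j) of slice s sits at

    centre + ((i+0.5)/N_f − 0.5)·FOV_f·freq + ((j+0.5)/N_p − 0.5)·FOV_p·phase
           + (s − (n_slices−1)/2)·separation·slice

Canonical axial/sagittal/coronal plans centre on the model and assign the
frequency axis to the longer in-plane extent (wrap-around only occurs along
phase), overridable by the user.

Reslicing is trilinear interpolation of PD/T1/T2/ΔB0 (nearest-neighbour
would be used for labels, which the pipeline does not consume), averaged
over `n_sub = 5` equispaced midpoint-centred sub-planes across the slice
thickness. Averaging property maps *before* evaluating contrast is a
partial-volume approximation: the cheap choice, exact for homogeneous
regions and linear ramps (midpoint rule), slightly wrong across sharp
T1/T2 boundaries where the signal is a nonlinear function of the mixed
properties. The operator is linear in the source volume and invariant under
rigid co-rotation of model and plan (both tested).

## Sequence contrast

Vendor-neutral families: SE, FSE, spoiled GRE, IR-SE. The expressions are
the canonical steady-state forms (README); IR uses magnitude
reconstruction. T2\* follows `1/T2* = 1/T2 + γ′·B0·|ΔB0|` with
γ′ = 42.58 Hz/(T·ppm) expressed per millisecond — a deliberately simple
static-dephasing model whose only purpose is to make field inhomogeneity
and the shimming toggle visible in GRE images. Shimming sets ΔB0 to zero
for contrast purposes. Field strength enters only through this term;
relaxation times are not rescaled with B0 (a documented simplification —
teaching contrast knobs, not field-strength physics).

Saturation bands multiply PD (not the final signal) inside their slab, so
their effect propagates identically through every family; the coil is
either homogeneous (sensitivity 1) or a surface coil decaying as
`exp(−distance-to-reference-plane / falloff)` — the minimal model that
makes coil choice pedagogically visible.

## k-space engine

The transform convention is DC-centred and unitary (`fftshift`-bracketed
orthonormal FFT). That single choice makes Parseval's identity exact, makes
a constant image c concentrate at DC with magnitude c·N, and means complex
Gaussian k-space noise of per-component std σ reappears in the image with
the same σ — hence background magnitude is exactly Rayleigh(σ), which the
tests verify distributionally.

Artifact operators are pure functions; the pipeline applies them in a fixed
order per slice: echo-train attenuation (FSE) → motion → spikes → thermal
noise → partial-Fourier / wrap handling at reconstruction.

- **Motion**: periodic rigid in-plane translation along the frequency axis
  between phase lines (no intra-line motion): line j is multiplied by
  `exp(−2πi·k_f·d(j))`, `d(j) = A·sin(2πj/period)`. Because the modulation
  is periodic in j, ghosts appear at multiples of `N_phase/period` pixels
  along phase. A subtlety: on the exact parent row the odd-order ghosts
  cancel by the parity of the Bessel-series coefficients (J_n is odd in k_f
  for odd n), so ghost peaks should be located by a per-column maximum over
  rows.
- **Spikes** add a complex amplitude at one k-sample; the image gains a
  plane-wave stripe whose cycle counts equal the spike's offset from DC.
- **Echo-train attenuation** is a per-line k-space filter: lines are grouped
  into ETL contiguous segments (linear view ordering, cyclically shifted so
  the central segment is read at the echo nearest TE), and each line is
  scaled by `exp(−t(j)/T2_eff)` with `t(j) = TE + (echo(j) − echo_c)·esp`
  (clipped at 0) and T2_eff the PD-weighted mean T2 of the slice. Keeping
  T2_eff a per-slice scalar keeps the attenuation a pure k-space filter;
  ETL = 1 degenerates to the uniform scale `exp(−TE/T2_eff)`.
- **Partial Fourier** keeps the first `max(ceil(fraction·N_p), N_p/2+1+overscan)`
  phase lines and fills the rest by Hermitian conjugation about DC, with no
  phase-correction stage: exact for zero-phase images, degraded by object
  phase — a failure mode that is itself the teaching point.
- **Wrap-around**: with wrap on, the oversampled reconstruction is folded
  into the nominal phase FOV by periodic summation (a point at FOV/2 + δ
  reappears at −FOV/2 + δ); with no-phase-wrap, the oversampled
  reconstruction is centre-cropped. A warning is emitted when the outermost
  oversampled columns carry as much energy as a typical column (object
  reaching the edge: the fold is then incomplete).

Randomness: one root seed per session; each stochastic stage draws from a
substream derived from the root seed and a stable label
(`entry/sliceN/thermal`) via an FNV-style hash, so runs are bit-reproducible
and inserting an entry does not shift another entry's noise.

## Protocols and provenance

Protocols are JSON documents validated with pydantic; validation returns an
itemized error list with JSON paths rather than raising at the first
problem. Patient position is recorded as session metadata only (it does not
change the physics). Outputs are NIfTI-1 stacks whose affine carries the
plan's orientation, origin and pixel size, plus a provenance sidecar
(resolved configuration, seed, software version) sufficient to re-run
bit-identically.

## Evaluation statistics

The instrument is a 20-item questionnaire (4 options + "I do not know"),
items 1–10 theoretical, 11–20 practical, administered pre and post to a
control and an experimental group. Ratings: **hits** (count of correct
answers) and **null-expectation** (+1 hit, −1/3 error, 0 don't-know), the
−1/3 chosen so uniform guessing over four options has expected score zero.

- **Reliability**: KR-20 for binary hits, Cronbach's alpha for the numeric
  rating. Conventions: item proportions use n, total-score variance uses
  n − 1, alpha's item variances use n − 1 by default. On binary data KR-20
  equals alpha computed with biased (n) item variances, exposed as
  `cronbach_alpha(..., ddof_items=0)`; the convention shifts reliability in
  the third decimal at n ≈ 60.
- **Item selection** is greedy backward elimination maximizing KR-20, with
  ties broken by lowest corrected item-total correlation and then lowest
  item index. The published 10-item subsets ({4,5,6,8,10} and
  {11,12,13,17,20}) are accepted as fixed inputs for reproduction; the
  original selection procedure was described only as a correlation analysis,
  so an exact algorithmic reconstruction is not possible.
- **Inference**: Shapiro–Wilk per group at α = 0.05 gates a pooled-variance
  two-sample t-test versus the two-sided Mann–Whitney rank test. The
  unpaired rank-sum test is used (rather than the paired signed-rank test)
  because the comparisons are explicitly between independent groups.
  Cohen's d always uses the pooled SD,
  `d = (m_EG − m_CG)/sqrt(((n1−1)s1² + (n2−1)s2²)/(n1+n2−2))`; with the
  study's published post-test practical-part summaries (2.53 ± 1.36 vs
  1.63 ± 1.27, n = 30/30) this reproduces the published 0.684. No
  multiple-testing correction is applied (none is part of the methodology).
- **Response files** follow the deposited 23-column layout (id, phase,
  group, 20 cells encoded 1 / −1/3 / 0-or-none), readable from xlsx or
  delimited text with itemized row/column error reporting.

### Synthetic cohort generator

Per item a responder answers "I do not know" with a configured propensity
(default 0.3); otherwise the answer is a hit with probability
`logistic(ability − difficulty)`, else an error. Default difficulties are
1.0 for all items, and default abilities per (group, phase) — pre −0.7 for
both groups, post 0.85 (control) and 1.95 (experimental) — were calibrated
once so mean scores on a 5-item part resemble the classroom study (low,
balanced pre-test; moderate post-test with an experimental advantage).

With the default `ability_sd = 0`, responders within a cell are
exchangeable, so the part score is a sum of independent Bernoulli variables
and the score-scale Cohen's d of a latent shift has a closed form —
`latent_shift_for_effect` inverts it numerically, which is what makes the
calibration studies (type-I error of the full pipeline, recovery of a
configured d = 0.7) well-defined. Setting `ability_sd > 0` adds a
per-participant trait (constant across phases) that induces the inter-item
correlation real cohorts show, and is used when a non-trivial reliability
is wanted. What the generator does **not** emulate: item-specific
discrimination, attrition, learning-by-testing, or response dependence
across items — so passing calibration tests demonstrates the statistical
pipeline's correctness under its stated model, not robustness to the full
messiness of classroom data.

## Problem sizes and numerical choices

Simulator tests run at 32–64³ phantoms and 64–128² matrices; the
calibration studies use 2000 null replicates at the study's n = 30/group
and 200 effect replicates at n = 200/group — sizes chosen to make
stochastic checks decisive at desk scale. Tolerances: machine-precision
properties (round-trip, Parseval, identity reslice) are asserted at 1e-9 to
1e-12; interpolation-mediated identities at 1e-6; distributional checks at
test level 0.01; the type-I band [0.035, 0.065] corresponds to roughly ±3
binomial standard errors around 0.05 at 2000 replicates.

## Known limitations

- Contrast is steady-state only; no transient approach to steady state,
  no slice-profile excitation effects (thickness enters via property-map
  averaging only).
- The FSE filter uses a per-slice scalar T2_eff, so tissue-specific echo
  blurring within one slice is not modelled.
- Partial-Fourier reconstruction deliberately omits phase correction
  (homodyne/POCS), so it degrades on phase-corrupted data.
- Patient position does not transform the anatomy; it is metadata.
- The statistics module reproduces the published effect sizes from summary
  statistics; reproduction of the reliability values on the deposited
  response file requires that file, which is an optional external download
  and is not redistributed here.
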