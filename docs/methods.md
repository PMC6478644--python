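# Methods

This note documents the models, conventions and design choices behind
`phasetree`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not show.

## Temporal preprocessing (`phasetree.spectral`)

The pipeline assumes source-space ROI time series; sensor-level cleaning
(channel rejection, PCA/ICA denoising) and source reconstruction are outside
its scope and must have happened upstream.

* **Broadband filter.** 4th-order Butterworth band-pass, 0.5–48 Hz, applied
  forward–backward (`sosfiltfilt`). Zero phase distortion is essential
  because everything downstream is a phase statistic; the price is a doubled
  effective order (the realized response is |H(f)|²). Consequence worth
  knowing: a 60 Hz interferer is attenuated by ≈17 dB at 1024 Hz — this
  filter is a band definition, not a notch; strong line noise should be
  handled upstream.
* **Resampling.** Anti-aliased decimation to 512 Hz by an integer factor
  (`scipy.signal.decimate` with a linear-phase FIR anti-alias filter,
  delay-compensated). FIR was chosen over the default IIR because it is
  exactly unity at DC and ripple-free in the passband; non-integer factors
  are rejected rather than approximated.
* **Epoching.** The first `n_epochs` consecutive non-overlapping windows
  (default ten 8-s epochs, 4096 samples at 512 Hz) are taken from the start
  of the recording after the settling padding is dropped. Expert artifact
  screening is intentionally not emulated: synthetic recordings contain no
  artifacts, and user-supplied data are assumed pre-screened.
* **Band decomposition.** The same Butterworth family, order 4,
  forward–backward, per band (δ 0.5–4, θ 4–8, α 8–13, β 13–30, γ 30–48 Hz).
  The metric-level results should be robust to the exact filter family; this
  is a stated assumption, not a verified fact.
* **Instantaneous phase.** Angle of the Hilbert analytic signal, wrapped to
  (−π, π]. No edge trimming is applied by default (`trim_samples=0`); the
  8-s epochs make transform edge effects a sub-percent fraction of samples,
  and a configurable symmetric trim exists for shorter epochs.

## Phase lag index (`phasetree.connectivity`)

`PLI(i,j) = |⟨sign(sin(φ_i − φ_j))⟩_t|`. Conventions:

* the sine form is used instead of the sign of the wrapped difference —
  mathematically identical, immune to the wrapping branch at ±π;
* exact ties (`sin Δφ = 0`) contribute 0, so a signal against its own copy
  gives exactly 0 (the estimator's classical tie convention);
* PLI is computed per epoch, never across concatenated epochs;
* under independence the estimator has a positive noise floor:
  |mean of T signs| is approximately half-normal with scale 1/√T
  (≈ 0.016 at T = 4096). Comparisons between conditions must share T.

PLI discards zero-lag coupling by construction, which removes first-order
linear leakage but not secondary leakage effects; no leakage-corrected
variant (wPLI, imaginary coherence) is implemented.

## MST topology (`phasetree.topology`)

Edge weights are 1/PLI; a PLI of exactly 0 maps to an infinite sentinel so
the graph stays structurally complete and a spanning tree always exists.
Kruskal's algorithm with union-find builds the MST; ties are broken by the
stable order (weight, min index, max index), making trees bit-reproducible.

* **Leaf fraction** L = (#degree-1 nodes)/N ∈ [2/N, (N−1)/N].
* **Degree divergence** K = ⟨k²⟩/⟨k⟩. On a tree the mean degree is fixed at
  2(N−1)/N, so K is a pure broadness (second-moment) measure: star N/2,
  path (2N−3)/(N−1).
* **Betweenness centrality** divides each node's through-path count by the
  network's total path count N(N−1)/2, endpoints excluded (leaves are 0).
  This normalization differs by the constant factor (N−1)(N−2)/(N(N−1))
  from the more common pair-normalization; values are comparable within
  this package only. Computed in O(N) from subtree sizes.

Per-epoch metrics are averaged arithmetically per subject and band before
any statistics (average-then-test, including for nodal BC).

## Statistics (`phasetree.stats`)

* **Permutation test.** Difference of group means under label permutation;
  two-sided; add-one estimator p = (1 + #{|Δ*| ≥ |Δ|})/(1 + n_perm), which
  is never 0 and keeps the test valid for any n_perm. An exhaustive mode
  enumerates all label assignments for small cohorts; note that with a
  two-sided statistic the smallest attainable exhaustive p is 2/#assignments
  (the observed split and its mirror), e.g. 0.1 for 3-vs-3.
* **FDR.** Benjamini–Hochberg step-up over the declared family: 2 global
  metrics × 5 bands (10 tests); betweenness additionally across areas
  (N × 5 tests). BH rather than BY: the test statistics are positively
  dependent at worst.
* **Clinical correlation.** Pearson r between per-patient degree divergence
  (carrier band by default) and the clinical score. Outlier policies:
  `none` (default — no exclusion rule is baked in), `explicit-ids`, or
  `studentized` (externally studentized regression residual > 2.5).
* The group comparison is unadjusted for covariates by design; matching is
  assumed to be part of the study design, not the model.

## Synthetic cohorts (`phasetree.synthdata`)

Each subject carries a coupling graph (star, chain, uniform random labelled
tree via Prüfer sequences, or an explicit forest) over `n_rois` nodes. Per
connected component, one band-limited Gaussian carrier (default β, 13–30 Hz,
unit SD) is generated; every node receives the carrier delayed by the sum of
per-edge phase lags along the path from the component root, scaled by the
coupling strength, plus independent 0.5–48 Hz filtered Gaussian noise
(`noise_sd`, default 1). Per-edge lags are drawn uniformly from
[π/8, 3π/8], bounded away from 0 and π where the PLI loses sensitivity.
Recordings are `n_epochs × epoch_length + 2 s` long; the 1-s pads absorb
filter transients and are discarded before epoching. Patients' clinical
scores are `clinical_slope × K(coupling graph) + N(0, clinical_noise_sd)`,
truncated at 0; controls carry none. Cohorts are byte-reproducible from
(spec, seed); each subject consumes an independent child seed stream.

Defaults emulate a small resting-state study: 10 patients + 10 matched
controls, 90 ROIs at 1024 Hz, ten 8-s epochs. Default coupling: patients
random-tree, controls star, strength 0.8 — a configuration whose group
contrast is reliably detectable at n = 10 per group, which is the
generator's calibration goal (no empirical effect size is being matched).
`clinical_slope = 5` and `clinical_noise_sd = 1` put the score's
signal-to-noise near 1.5 for random-tree K spreads.

**What the generator does not emulate.** Real source-space data have
1/f-like broadband spectra, nonstationary coupling, volume-conduction
leakage mixed across many sources, and artifacts; none of these are
simulated. One structural consequence matters for interpretation: because
all coupled nodes are lagged copies of one carrier, *every* within-component
pair is phase-locked, so the estimated MST reflects the per-edge lag
geometry more than the planted tree's fine structure. Coarse topology
classes (star vs chain, and their K/L contrast) are recovered robustly;
the per-subject ranking of K among same-class random trees is not. Passing
tests therefore demonstrate correct mechanics and calibrated statistics,
not per-subject metric recoverability on real data. Validation checks that
need planted-K variability across patients (the score-correlation sign
recovery) pool patients from two contrasting classes for this reason.

## Numerical and calibration choices

* Reduced validation geometry: the stochastic calibration studies (null
  false-positive rate over 200 cohorts; effect-direction recovery over 20)
  run at 15 ROIs, 256 Hz, five 2-s epochs, 10+10 subjects and 1000
  permutations — the full pipeline at a size where a replicate takes about
  a second; the full 90-ROI, 1024 Hz geometry is exercised end-to-end in the
  shape-conservation check. Problem sizes are stated in the test and script
  docstrings.
* Under the null the add-one permutation p is very slightly conservative
  (discrete, floor 1/(n_perm+1)); the family-wise FDR rejection rate over
  null cohorts sits at or below the nominal 0.05.
* Degenerate inputs fail loudly: constant ROI (undefined phase), fewer than
  3 ROIs, non-integer decimation, mismatched lengths, constant metric
  vectors (p = 1 with a warning), zero-variance correlation inputs.

## Known limitations

* No artifact handling or screening; epochs are taken verbatim from the
  recording start.
* PLI's secondary-leakage sensitivity is inherited and uncorrected.
* The BC normalization is package-specific (see above) — compare BC values
  across tools with care.
* The generator's common-carrier mechanism limits fine-grained topology
  recovery (see above); a coupled-oscillator (e.g. Kuramoto) generator
  would relax this and could be added behind the same `CouplingGraph`
  interface.
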