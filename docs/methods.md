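# Methods

This note documents the models implemented in `nirsconn`, the parameter
choices that matter, what the synthetic cohort generator does and does not
emulate, and the numerical decisions taken where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design being modeled

A two-arm longitudinal pain study: subjects randomized 1:1 to an active
treatment or a sham arm, scanned at baseline (week 0) and after each of three
treatment weeks, under two painful stimulus types (thermal, punctate). Each
scan is a block design: a pre-rest of 30 s, then six 20-s stimulation blocks
each followed by 30 s of rest, sampled at ~13.33 Hz. The instrument is a
20-channel continuous-wave fNIRS grid with 8 laser sources (780, 805,
830 nm) and 8 detectors at 30 mm separation, covering the prefrontal cortex
(PFC, 8 channels) and the contralateral primary motor/somatosensory strip
(M1_S1, 12 channels).

The exact optode geometry of such a montage is not fully determined by those
counts. The packaged default probe is a fixture: a 4×4 checkerboard grid at
30 mm pitch in which 20 of the 24 nearest-neighbour source–detector pairings
are enumerated as measured channels (the outer-column vertical pairs in the
PFC patch and at the region boundary are deterministically omitted), giving
the 8/12 regional split. The region map is configurable; nothing downstream
depends on the specific drop rule.

## Synthetic cohort generator

The generator exists so that every downstream stage can be tested against
known ground truth without any recorded data.

**Hemodynamics.** Per channel `c` in region `R`:

    HbO2_c(t) = a_R · (boxcar ⊛ HRF)(t) + σ · x_c(t)
    HbR_c(t)  = −γ · HbO2-structure(t) + independent noise

with a canonical double-gamma HRF (peak 6 s, undershoot 16 s, 1/6 undershoot
ratio), response amplitudes `a_PFC = −0.3 µM` (the PFC deactivates under
pain) and `a_M1S1 = +0.5 µM`, stochastic scale σ = 0.3 µM, and γ = 0.4 (HbR
mirrors HbO2 at reduced amplitude with opposite sign, plus 0.05 µM
independent noise).

**Correlation targeting.** The stochastic part uses a shared-latent-factor
construction: `x_c = √r_R · z_R + √(1−r_R) · ε_c` with unit-variance white
streams, and the two regional latents correlated at
`ρ = r_inter / √(r_PFC · r_M1S1)` so intra- and inter-region channel
correlations equal their targets *analytically* (defaults 0.6 / 0.6 / −0.4;
feasibility constraint `r_inter² ≤ r_PFC·r_M1S1` enforced). All streams then
pass through one common variance-normalized AR(1) filter (φ = 0.4), which
adds realistic autocorrelation without changing any zero-lag correlation —
this is what makes AR prewhitening a genuinely necessary step downstream
rather than a no-op. Negative *intra*-region targets are not representable
for more than two channels (a correlation matrix constraint), so negative
targets are exercised on inter-region pairs.

**Treatment effect.** A group×week multiplicative modulation on the
intra-PFC and |inter-region| targets encodes the qualitative treatment
signature: active arm {week 1: 0.8, week 2: 0.5, week 3: 1.0}, sham always
1.0 — the effect emerges in week 1, peaks mid-treatment, and returns toward
baseline. The ground-truth ledger emitted with every cohort records the
modulated targets per scan; parameter-recovery tests compare against it.

**Optics.** Raw intensity is the Beer–Lambert forward model
`I = I₀·10^(−OD)` with `OD_λ = (ε_HbO2(λ)·ΔHbO2 + ε_HbR(λ)·ΔHbR)·d·DPF`,
plus sinusoidal physiology in OD units — cardiac 1.2 Hz (0.015 OD),
respiration 0.25 Hz (0.004), Mayer waves 0.1 Hz (0.004) — and white
measurement noise (0.003 OD). Each physiological component is split into a
global part (`global_share`, default 0.5) common to all channels and a
channel-specific part modeled as the *same* oscillator with a bounded
arrival-delay phase jitter (±π/2). The jitter model reflects how a cardiac
pulse actually presents across a scalp array; an independent random phase
would let the two parts cancel on some channels and spuriously destroy the
pulse the quality metrics are designed to detect. Channels designated "bad"
lose their cardiac signature and receive 20× noise, emulating detached
optodes. Motion artifacts (optional) are spikes (0.5 s decay) and persisting
baseline shifts at Poisson times, applied coherently to all channels with an
OD-unit magnitude, and logged for test assertions.

**What the generator does not emulate:** photon transport through a head
model (no partial-volume or depth sensitivity), tDCS current flow, serially
correlated physiology beyond AR(1)+sinusoids, habituation across blocks or
weeks, subject-level random effect sizes, or channel-dependent DPF. Passing
tests therefore demonstrate correctness of the *analysis machinery* under a
controlled generative model, not clinical validity on recorded data.

## Preprocessing chain

Fixed order, enforced and logged by the runner:
OD → motion correction → QC/triage → band-pass → MBLL → GSR → HbT.
QC runs *before* the band-pass because the scalp-coupling metrics live in
the cardiac band (0.5–2.5 Hz) that the 0.01–0.2 Hz band-pass removes.

- **Optical density**: `OD = −log10(I / mean(I))` per channel/wavelength;
  non-positive intensities raise an error naming sample and channel.
- **Motion correction** (spline method): samples whose 1-s moving-window
  standard deviation exceeds 5× the scan median — on ≥ 25 % of series
  simultaneously, since head movement is coherent — are flagged and dilated
  by the window; each flagged segment is replaced by (segment − smoothing
  spline), with smoothing weight p = 0.99 (λ = (1−p)/p in sample units), and
  segments are rejoined by junction mean-matching over ~fs/3 samples.
  Clean segments keep their shape; after a baseline-shift artifact they may
  receive a constant DC offset, without which a persisting shift could not
  be removed at all. DC is discarded by the band-pass anyway. Artifact-free
  input passes through bit-identically.
- **Quality control**: 5-s non-overlapping windows (configurable overlap);
  per window and channel the spectrally extreme wavelength pair (780,
  830 nm) is band-passed to 0.5–2.5 Hz; SCI is the zero-lag Pearson
  correlation of the pair, PSP the peak of the power spectrum of their
  normalized cross-correlation inside the band (normalized so a perfect
  shared sinusoid scores ~1). CQS is the fraction of windows with SCI ≥ 0.8
  and PSP ≥ 0.1; a channel is acceptable at CQS ≥ 0.75; a scan is dropped
  when fewer than 5 channels are acceptable. Channels are never pruned
  individually — noisy survivors are handled by the robust correlation.
- **Band-pass**: 4th-order Butterworth 0.01–0.2 Hz, applied
  forward–backward (zero phase). Passband amplitude is preserved within 5 %
  and energy at ≥ 2× the upper edge is attenuated > 99 %.
- **MBLL**: per sample and channel, the 3-wavelength overdetermined linear
  system is solved by least squares for (ΔHbO2, ΔHbR), returned in µM using
  the shipped extinction table (rounded values consistent with the standard
  compiled hemoglobin spectra at 780/805/830 nm), d = 30 mm and DPF = 6.0 at
  all wavelengths; all three are overridable. Since the same table drives
  the synthetic forward model, forward/inverse consistency is exact and is
  tested to 1e−9.
- **Global signal regression**: the across-channel mean series (computed
  over QC-acceptable channels only, applied to all channels) is regressed
  out of every channel per hemoglobin type; residuals are exactly orthogonal
  to the global mean. GSR necessarily also removes whatever part of the
  *neural* shared structure projects on the global mean — with two
  anticorrelated regional latents the projection is partial, and the
  region-contrast structure survives; tests of generative-parameter recovery
  therefore run on the generated hemoglobin, while pipeline tests assert the
  qualitative structure post-GSR.
- **HbT** = HbO2 + HbR, exactly.
- **Block averaging** (reporting utility): epochs around stimulation onsets,
  baseline-corrected to the pre-stimulus mean, averaged within scan;
  out-of-bounds events are skipped with a counted warning.

## Connectivity

**Scan level.** The six stimulation blocks (~120 s total; each block within
one sample of 20 s — per-block rounding makes the concatenation 1599–1602
samples) are concatenated. Each channel is prewhitened by an AR(p) model:
autocovariances → Levinson–Durbin recursion (innovation variance for every
order in one pass) → BIC over orders 0..⌈2·fs⌉ (≈27). The AR filter state is
reset at block boundaries so cross-boundary dynamics never leak into the
innovations. Channels may select different orders; within a scan every
channel drops max(p) initial samples per block so the innovation series
share one time index (`n_effective` = aligned length).

**Robust correlation.** Pairwise correlations use symmetric iteratively
reweighted estimation: given the current weighted correlation r, each
sample's bivariate Mahalanobis distance
`d² = (z_x² − 2r·z_x·z_y + z_y²)/(1−r²)` is computed and Tukey bisquare
weights `w = (1−(d/c)²)² · 1[d<c]` with c = 5 (≈ the 99.9th percentile of a
chi(2) variate) are applied; iteration stops at max|Δw| < 1e−6 or 50
rounds. On clean Gaussian data this tracks plain Pearson within ±0.03; gross
outliers are driven to zero weight. The exact weighting used in the
originating literature is not published; this definition is the package's
own and is isolated behind one function.

**Significance.** `t = r√(n−2)/√(1−r²)`, two-sided p from Student's t with
n−2 df (|r| = 1 maps to t = ±∞, p = 0), Benjamini–Hochberg q over the 190
unique edges, corrected within each network.

**Group level.** Edge correlations are Fisher-z transformed (variance
stabilization) and modeled per edge with a linear mixed-effects model:
fixed effects group, week, group×week; random subject intercept (REML,
L-BFGS). The (group, week) cell estimate is the back-transformed marginal
mean; edge significance is a Wald test of that mean against zero,
BH-corrected across the 190 edges of the cell's network. Singular fits fall
back to the cell mean with a one-sample t-test; a simple cell-mean route is
available as `method="mean"`. Cells with fewer than two observations are
flagged and excluded (NaN).

**DSI.** The differential symmetry index between two networks binarized at
q < 0.05: observed Jaccard overlap S = |A∩B|/|A∪B| minus the overlap
expected from independent random graphs of matched densities,
E[S] = d_A·d_B/(d_A+d_B−d_A·d_B); empty graphs give 0 by convention. The
index is positive when networks share more structure than density alone
explains. The pipeline logs the decision rule: when the mean HbO2–HbR DSI is
below 0.2 (configurable), downstream analysis proceeds on HbT.

## Distribution comparison

Per (group, week), the unique off-diagonal r values of the scan-level
networks of the analyzed hemoglobin type are pooled across subjects
(scan-level pooling; pooling group-level model estimates instead is a
one-line change). Densities are Gaussian KDEs evaluated on a uniform
201-point grid over [−1, 1] and renormalized to unit mass; the bandwidth is
Silverman's rule computed on the *pooled* two-group sample so that both
densities share one kernel width — unequal smoothing would register as
spurious distance. The Hellinger distance

    H(P,Q) = (1/√2) · ‖√P − √Q‖₂

satisfies the metric axioms and lies in [0, 1] (0 iff identical, 1 for
disjoint supports); both properties are verified by property-based tests.
Zero-variance input degrades to a flagged single-bin point mass.

## Subnetwork statistics

Edges surviving q < 0.05 **and** |r| ≥ 0.3 (signs preserved; the absolute
value keeps anticorrelated links) are partitioned into PFC-intra (≤ 28
edges), M1_S1-intra (≤ 66) and PFC–M1_S1 inter (≤ 96) subnetworks. Per
subject and subnetwork: *degree* = surviving-edge count (the printed
magnitudes of the study tables are consistent with counts, not per-node
averages; the field name is kept) and *mean correlation* = signed mean of
surviving r, undefined (NaN) when no edge survives — which genuinely happens
when an injected weakening pushes all inter-region edges below the |r| gate.

Group comparisons per (week, stimulus, subnetwork, metric): Shapiro–Wilk at
α = 0.05 on each group; both normal → two-sample t-test with mean (SD)
reporting; otherwise Wilcoxon rank-sum (Mann–Whitney with tie correction;
all-tied data flagged, p = 1) with median (IQR) reporting. The reported
location/spread follows the test actually used. No correction across the
comparison family by default (matching how such tables are conventionally
presented); a BH-corrected variant is behind a flag. The subject is the
sampling unit throughout.

## Problem sizes and numerical choices

- Statistical test-suite checks run at deliberately moderate sizes chosen as
  the package's own trade-off between Monte-Carlo error and runtime: FDR
  control over 50 null scans; Hellinger week-2 recovery over 20 replicates
  of 6 subjects/arm; subnetwork power over 10 replicates of 50 subjects/arm
  (week-2 cell only, since the comparison uses only that week); type-I error
  of the gated test over 1000 replicates at n = 50/group.
- Degenerate inputs: constant series are rejected by prewhitening and robust
  correlation (zero variance); |r| = 1 produces infinite-t sentinels;
  empty binarized graphs give DSI = 0; all-tied group samples report p = 1
  with a tie flag.
- Ties and boundaries: |r| ≥ 0.3 is inclusive; triage keeps a scan at
  exactly 5 acceptable channels; BIC ties resolve to the smaller order via
  argmin.
- Seeds: one root seed per cohort spawns independent per-scan streams
  (hemodynamics, physiology, motion separately), so any scan can be
  regenerated in isolation and reruns are bit-identical.

## Known limitations

- The robust-correlation weighting and the DSI formula are the package's own
  documented definitions of methods whose originating formulations are not
  fully published; both are isolated behind single functions so alternates
  can be swapped.
- The group-level LME treats weeks as categorical and assumes a common
  residual variance across cells; with very small cohorts the random-effect
  variance frequently hits the boundary and the fit degrades gracefully to
  the cell mean.
- GSR with only long-separation channels removes shared neural variance
  along with systemic physiology; absolute connectivity levels after GSR are
  attenuated relative to the generative targets, and analyses should be read
  as contrasts (group × week), not absolute coupling strengths.
- No directed or frequency-domain connectivity, no graph-theoretic global
  metrics, no short-separation regression, and no image reconstruction.
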