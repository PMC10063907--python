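# nirsconn

Functional-connectivity analysis for block-design fNIRS pain studies.

Functional near-infrared spectroscopy (fNIRS) measures cortical hemodynamics
through multi-wavelength light attenuation between scalp optodes. In
longitudinal pain-treatment studies, a central question is whether treatment
reorganizes the coupling between the prefrontal cortex (PFC) and the primary
motor/somatosensory strip (M1/S1) during painful stimulation. `nirsconn`
implements that analysis as a tested, reusable pipeline:

1. **Synthetic cohorts** — a generator that emulates a two-arm
   (active vs. sham), four-week study with six 20-s stimulation blocks
   interleaved with 30-s rests at ~13.33 Hz on a 20-channel, 3-wavelength
   (780/805/830 nm) probe, with known ground-truth connectivity per scan.
2. **Preprocessing** — optical density, spline motion correction,
   scalp-coupling quality control (SCI/PSP/CQS with scan triage), 0.01–0.2 Hz
   band-pass, modified Beer–Lambert conversion to ΔHbO₂/ΔHbR, global signal
   regression, and HbT = HbO₂ + HbR.
3. **Connectivity** — per scan, stimulation-block samples are concatenated,
   each channel prewhitened by a BIC-selected AR(p) model, and every channel
   pair correlated with an iteratively reweighted (Tukey bisquare) robust
   estimator; significance via t = r√(n−2)/√(1−r²) and Benjamini–Hochberg
   FDR over the 190 unique edges. Group-level networks come from per-edge
   linear mixed-effects models on Fisher-z correlations
   (group × week fixed effects, random subject intercept). The differential
   symmetry index (DSI) decides whether HbO₂/HbR networks are similar enough
   to analyze one of them, or HbT otherwise.
4. **Distribution comparison** — per week, the pooled edge correlations of
   the two arms are summarized by Gaussian kernel densities on a common grid
   over [−1, 1] and compared by the Hellinger distance
   H(P,Q) = (1/√2)‖√P − √Q‖₂ ∈ [0, 1].
5. **Subnetwork statistics** — edges surviving q < 0.05 and |r| ≥ 0.3 are
   partitioned into PFC, M1_S1 and PFC–M1_S1 subnetworks; per-subject mean
   correlation and node degree feed normality-gated group tests
   (Shapiro–Wilk deciding t-test vs. Wilcoxon rank-sum).

## Worked example

```python
import numpy as np
from nirsconn import (BlockDesign, EffectSpec, make_default_probe, simulate_hb,
                      compute_hbt, scan_connectivity, simulate_cohort,
                      balanced_manifest, weekly_distance_table)

probe = make_default_probe()          # 8 sources, 8 detectors, 20 channels
design = BlockDesign()                # 6 x 20 s stimulation, 30 s rests
scan = simulate_hb(design, EffectSpec(), probe, seed=7)
net = scan_connectivity(compute_hbt(scan), "HbT")

manifest = balanced_manifest(6, weeks=(0, 1, 2, 3), stimuli=("thermal",), seed=1)
nets = [scan_connectivity(compute_hbt(s), "HbT")
        for s, _ in simulate_cohort(manifest, as_intensity=False)]
print(weekly_distance_table(nets, stimulus="thermal", hb_type="HbT"))
```

Output:

```
scan-level HbT network: n_effective=1572
mean r  PFC=0.564  M1_S1=0.550  PFC-M1_S1=-0.382
significant edges (q<0.05): 190 / 190

 week  hellinger  n_active  n_sham
    0   0.008961      1140    1140
    1   0.208749      1140    1140
    2   0.532880      1140    1140
    3   0.026451      1140    1140
```

The single-scan network recovers the generator's targets (intra-region
r ≈ 0.6 positive, inter-region r ≈ −0.4 negative; AR prewhitening removes the
evoked-response inflation). The weekly table shows the signature the pipeline
is built to detect: the active arm's connectivity is weakened most at week 2
(treatment mid-point), so the active-vs-sham Hellinger distance peaks there
and returns toward the baseline overlap by week 3.

## Command line

```bash
nirsconn simulate  --workdir run --n-per-group 5 --seed 1   # raw SNIRF cohort
nirsconn preprocess --workdir run                           # QC + hemoglobin
nirsconn connect    --workdir run                           # networks + DSI
nirsconn compare    --workdir run                           # Hellinger table
nirsconn subnet     --workdir run                           # group comparisons
nirsconn run-all    --workdir run --n-per-group 5 --seed 1  # everything
```

Each stage writes CSV/JSON artifacts (quality report, triage manifest,
long-format networks, group-level matrices, DSI summary, weekly distance
table, subnetwork report) plus an effective-config snapshot and run log;
reruns with the same seed are byte-identical.

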