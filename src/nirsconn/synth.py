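"""Synthetic block-design fNIRS cohorts with known ground truth.

Generates oxy/deoxy-hemoglobin time series from a latent-factor model with
analytically exact target correlations, converts them to raw multi-wavelength
intensity through the Beer-Lambert forward model plus cardiac / respiratory /
Mayer-wave physiology, and optionally injects motion artifacts. Every scan
carries a ground-truth ledger entry so parameter-recovery tests can compare
estimates against what was injected.

The generative model per channel c in region R:

    HbO2_c(t) = a_R · (boxcar * HRF)(t) + σ · x_c(t)
    x_c = sqrt(r_R) · z_R + sqrt(1 - r_R) · ε_c          (unit variance)
    HbR_c(t)  = -γ · HbO2-structure + independent noise

where z_PFC and z_M1S1 are correlated latents chosen so intra- and
inter-region channel correlations hit the requested targets exactly, and all
stochastic streams pass through one common AR(1) filter so the series have
realistic low-frequency autocorrelation without disturbing the zero-lag
correlation structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter
from scipy.stats import gamma as gamma_dist

from .mbll import ExtinctionTable, hb_to_od
from .probe import M1S1, PFC, Probe, make_default_probe
from .scan import HB, INTENSITY, OD, Scan


@dataclass(frozen=True)
class BlockDesign:
    """Timing of the stimulation paradigm: pre-rest, then
    n_blocks x (stimulation, rest)."""

    n_blocks: int = 6
    stim_duration: float = 20.0   # s
    rest_duration: float = 30.0   # s
    pre_rest: float = 30.0        # s
    sampling_rate: float = 13.33  # Hz

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if min(self.stim_duration, self.rest_duration, self.pre_rest,
               self.sampling_rate) <= 0:
            raise ValueError("durations and sampling rate must be positive")

    @property
    def total_duration(self) -> float:
        return self.pre_rest + self.n_blocks * (self.stim_duration + self.rest_duration)

    @property
    def n_samples(self) -> int:
        return round(self.total_duration * self.sampling_rate)

    def stim_onsets(self) -> np.ndarray:
        period = self.stim_duration + self.rest_duration
        return self.pre_rest + period * np.arange(self.n_blocks)

    def events(self) -> np.ndarray:
        """(n_blocks, 2) array of (onset_s, duration_s)."""
        on = self.stim_onsets()
        return np.column_stack([on, np.full_like(on, self.stim_duration)])


#: default treatment effect: active-group PFC and inter-region connectivity
#: weakens during treatment, maximally at week 2, back to baseline by week 3.
DEFAULT_MODULATION: dict[tuple[str, int], float] = {
    ("active", 1): 0.8,
    ("active", 2): 0.5,
    ("active", 3): 1.0,
}


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth connectivity targets and evoked-response amplitudes."""

    intra_pfc_r: float = 0.6
    intra_m1s1_r: float = 0.6
    inter_r: float = -0.4
    response_amplitude_pfc: float = -0.3    # µM, HbO2 (PFC deactivates)
    response_amplitude_m1s1: float = 0.5    # µM, HbO2
    latent_sd: float = 0.3                  # µM, stochastic component
    ar_coefficient: float = 0.4             # common AR(1) coloring
    hbr_ratio: float = 0.4                  # γ: HbR = -γ·HbO2 structure
    hbr_noise_sd: float = 0.05              # µM
    group_week_modulation: dict[tuple[str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_MODULATION)
    )

    def __post_init__(self) -> None:
        for name in ("intra_pfc_r", "intra_m1s1_r", "inter_r"):
            v = getattr(self, name)
            if not np.isfinite(v) or not -1 < v < 1:
                raise ValueError(f"{name}={v!r} must be finite and in (-1, 1)")
        for name in ("response_amplitude_pfc", "response_amplitude_m1s1",
                     "latent_sd", "hbr_noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0 < self.hbr_ratio < 1:
            raise ValueError("hbr_ratio must lie in (0, 1)")
        if not -1 < self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in (-1, 1)")
        if any(f <= 0 for f in self.group_week_modulation.values()):
            raise ValueError("modulation factors must be positive")
        a, b = abs(self.intra_pfc_r), abs(self.intra_m1s1_r)
        if self.inter_r != 0 and self.inter_r**2 > a * b:
            raise ValueError(
                "inter_r^2 must not exceed intra_pfc_r * intra_m1s1_r "
                "(latent-factor model constraint)"
            )

    def modulated(self, group: str, week: int) -> "EffectSpec":
        """Apply the group×week multiplicative factor to intra-PFC r and |inter r|."""
        f = self.group_week_modulation.get((group, week), 1.0)
        if f == 1.0:
            return self
        return replace(self, intra_pfc_r=f * self.intra_pfc_r,
                       inter_r=f * self.inter_r)


@dataclass(frozen=True)
class PhysiologySpec:
    """Systemic oscillations added in optical-density units."""

    cardiac_freq: float = 1.2       # Hz
    respiration_freq: float = 0.25  # Hz
    mayer_freq: float = 0.1         # Hz
    cardiac_amp: float = 0.015      # OD
    respiration_amp: float = 0.004  # OD
    mayer_amp: float = 0.004        # OD
    global_share: float = 0.5       # fraction common to all channels
    noise_sd: float = 0.003         # OD, white measurement noise

    def __post_init__(self) -> None:
        if min(self.cardiac_freq, self.respiration_freq, self.mayer_freq) <= 0:
            raise ValueError("physiological frequencies must be positive")
        if not 0 <= self.global_share <= 1:
            raise ValueError("global_share must lie in [0, 1]")

    def components(self) -> list[tuple[float, float]]:
        return [(self.cardiac_freq, self.cardiac_amp),
                (self.respiration_freq, self.respiration_amp),
                (self.mayer_freq, self.mayer_amp)]


@dataclass(frozen=True)
class CohortManifest:
    """Who was scanned when: subjects with group labels, session weeks, stimuli."""

    subjects: tuple[tuple[str, str], ...]       # (id, group)
    weeks: tuple[int, ...] = (0, 1, 2, 3)
    stimuli: tuple[str, ...] = ("thermal", "punctate")
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        groups = {g for _, g in self.subjects}
        if len(groups) > 2:
            raise ValueError(f"expected at most two group labels, got {sorted(groups)}")


def balanced_manifest(n_per_group: int, weeks=(0, 1, 2, 3),
                      stimuli=("thermal", "punctate"), seed: int = 0) -> CohortManifest:
    """1:1 randomized two-arm manifest with ``n_per_group`` subjects per arm."""
    subjects = tuple(
        (f"{g}{i + 1:03d}", g) for g in ("active", "sham") for i in range(n_per_group)
    )
    return CohortManifest(subjects=subjects, weeks=tuple(weeks),
                          stimuli=tuple(stimuli), seed=seed)


def canonical_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                  ratio: float = 6.0) -> np.ndarray:
    """Double-gamma hemodynamic response function, unit peak."""
    h = (gamma_dist.pdf(t, peak, scale=1.0)
         - gamma_dist.pdf(t, undershoot, scale=1.0) / ratio)
    return h / h.max()


def _evoked_response(design: BlockDesign) -> np.ndarray:
    """Unit-amplitude HRF-convolved boxcar over the scan, shape (n_samples,)."""
    fs = design.sampling_rate
    n = design.n_samples
    box = np.zeros(n)
    for onset, dur in design.events():
        i0, i1 = round(onset * fs), round((onset + dur) * fs)
        box[i0:min(i1, n)] = 1.0
    t_hrf = np.arange(0, 30.0, 1.0 / fs)
    resp = np.convolve(box, canonical_hrf(t_hrf))[:n] / fs
    peak = np.abs(resp).max()
    return resp / peak if peak > 0 else resp


def _ar1_color(white: np.ndarray, phi: float) -> np.ndarray:
    """AR(1)-filter columns of ``white``, rescaled to preserve unit variance."""
    if phi == 0:
        return white
    return lfilter([math.sqrt(1 - phi**2)], [1.0, -phi], white, axis=0)


def simulate_hb(design: BlockDesign, effects: EffectSpec, probe: Probe,
                seed: int | np.random.SeedSequence) -> Scan:
    """Simulate an HbO2/HbR scan with exact target correlation structure.

    Returns a hemoglobin Scan whose ``meta["ground_truth"]`` records the
    injected targets. Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    n = design.n_samples
    nch = probe.n_channels
    pfc = probe.region_indices(PFC)
    m1 = probe.region_indices(M1S1)

    a, b = effects.intra_pfc_r, effects.intra_m1s1_r
    # latent correlation required to hit the inter-region target
    if effects.inter_r == 0 or a * b == 0:
        rho = 0.0
    else:
        rho = effects.inter_r / math.sqrt(abs(a) * abs(b))
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
    eps = rng.standard_normal((n, nch))

    x = np.empty((n, nch))
    for idx, (r_target, z) in (( pfc, (a, z1)), (m1, (b, z2))):
        sa = math.sqrt(abs(r_target))
        # negative intra-region targets alternate the latent sign
        signs = np.ones(len(idx)) if r_target >= 0 else (-1.0) ** np.arange(len(idx))
        x[:, idx] = (sa * z[:, None] * signs[None, :]
                     + math.sqrt(1 - abs(r_target)) * eps[:, idx])
    x = _ar1_color(x, effects.ar_coefficient)

    evoked = _evoked_response(design)
    amp = np.zeros(nch)
    amp[pfc] = effects.response_amplitude_pfc
    amp[m1] = effects.response_amplitude_m1s1

    hbo2 = evoked[:, None] * amp[None, :] + effects.latent_sd * x
    hbr = (-effects.hbr_ratio * hbo2
           + effects.hbr_noise_sd * _ar1_color(rng.standard_normal((n, nch)),
                                               effects.ar_coefficient))

    ground_truth = {
        "intra_pfc_r": a, "intra_m1s1_r": b, "inter_r": effects.inter_r,
        "response_amplitude_pfc": effects.response_amplitude_pfc,
        "response_amplitude_m1s1": effects.response_amplitude_m1s1,
        "latent_sd": effects.latent_sd, "hbr_ratio": effects.hbr_ratio,
    }
    return Scan(kind=HB, data={"HbO2": hbo2, "HbR": hbr},
                sampling_rate=design.sampling_rate, probe=probe,
                events=design.events(),
                meta={"ground_truth": ground_truth})


def hb_to_intensity(scan: Scan, physiology: PhysiologySpec | None = None,
                    baseline_intensity: float | np.ndarray = 1.0,
                    table: ExtinctionTable | None = None,
                    seed: int | np.random.SeedSequence = 0,
                    bad_channels=()) -> Scan:
    """Render a hemoglobin scan as raw multi-wavelength intensity.

    Applies the Beer-Lambert forward model, adds sinusoidal physiology
    (partly global, partly channel-specific, per ``global_share``) and white
    measurement noise in OD units, then exponentiates:
    I = I0 · 10^(-OD). Channels listed in ``bad_channels`` lose their cardiac
    signature and receive 20x noise, emulating detached optodes for quality
    control testing.
    """
    if scan.kind != HB:
        raise ValueError("expected a hemoglobin scan")
    physiology = physiology or PhysiologySpec()
    table = table or ExtinctionTable()
    rng = np.random.default_rng(seed)
    probe = scan.probe
    wl = probe.wavelengths
    n, nch, nwl = scan.n_samples, probe.n_channels, len(wl)

    baseline = np.broadcast_to(np.asarray(baseline_intensity, dtype=float),
                               (nch, nwl)).copy()
    if np.any(baseline <= 0):
        raise ValueError("baseline intensity must be positive")

    od = hb_to_od(scan.hb("HbO2"), scan.hb("HbR"), wl, table)

    bad = np.zeros(nch, dtype=bool)
    bad[list(bad_channels)] = True
    t = scan.times
    phys = np.zeros((n, nch))
    for freq, amp in physiology.components():
        if amp == 0:
            continue
        g = physiology.global_share
        phase0 = rng.uniform(0, 2 * np.pi)
        common = np.sin(2 * np.pi * freq * t + phase0)
        # channel-specific part: same oscillator, channel-dependent arrival
        # delay (bounded phase jitter), so it never cancels the global part
        local_phase = phase0 + rng.uniform(-np.pi / 2, np.pi / 2, nch)
        local = np.sin(2 * np.pi * freq * t[:, None] + local_phase[None, :])
        phys += amp * (g * common[:, None] + (1 - g) * local)
    phys[:, bad] = 0.0

    noise_sd = np.full(nch, physiology.noise_sd, dtype=float)
    noise_sd[bad] *= 20.0
    noise = rng.standard_normal((n, nch, nwl)) * noise_sd[None, :, None]

    od_total = od + phys[:, :, None] + noise
    intensity = baseline[None, :, :] * 10.0 ** (-od_total)
    return scan.with_data(intensity, kind=INTENSITY,
                          baseline_intensity=baseline, bad_channels=sorted(
                              int(c) for c in np.flatnonzero(bad)))


def inject_motion(scan: Scan, rate: float = 2.0, magnitude: float = 0.5,
                  seed: int | np.random.SeedSequence = 0) -> tuple[Scan, list[dict]]:
    """Add spike and baseline-shift motion artifacts at Poisson times.

    ``rate`` is events/minute; ``magnitude`` is the artifact size in OD units
    (spikes decay over ~0.5 s, shifts persist to the end of the scan). All
    channels and wavelengths move together with a random sign per event, as a
    head movement would. Returns the contaminated scan and the artifact log.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    log: list[dict] = []
    if rate == 0:
        return scan, log
    n = scan.n_samples
    fs = scan.sampling_rate
    n_events = rng.poisson(rate * scan.duration / 60.0)
    times = np.sort(rng.uniform(0, scan.duration, n_events))

    od_art = np.zeros(n)
    t = scan.times
    for t0 in times:
        kind = "spike" if rng.random() < 0.5 else "shift"
        sign = 1.0 if rng.random() < 0.5 else -1.0
        amp = sign * magnitude * rng.uniform(0.5, 1.5)
        i0 = int(t0 * fs)
        if kind == "spike":
            tau = 0.5
            seg = np.exp(-(t[i0:] - t0) / tau)
            od_art[i0:] += amp * seg
        else:
            od_art[i0:] += amp
        log.append({"time": float(t0), "kind": kind, "amplitude": float(amp)})

    if scan.kind == INTENSITY:
        data = scan.data * 10.0 ** (-od_art[:, None, None])
    elif scan.kind == OD:
        data = scan.data + od_art[:, None, None]
    else:
        raise ValueError("motion injection applies to intensity or OD scans")
    return scan.with_data(data, motion_log=log), log


def simulate_cohort(manifest: CohortManifest,
                    design: BlockDesign | None = None,
                    effects: EffectSpec | None = None,
                    physiology: PhysiologySpec | None = None,
                    probe: Probe | None = None,
                    motion_rate: float = 0.0,
                    as_intensity: bool = True):
    """Simulate one raw scan per (subject, week, stimulus).

    Yields (scan, ledger_row) pairs; the ledger row records subject, group,
    week, stimulus, the per-scan seed and every ground-truth effect value
    after group×week modulation. All randomness descends from
    ``manifest.seed`` through one spawned stream per scan.
    """
    design = design or BlockDesign()
    effects = effects or EffectSpec()
    physiology = physiology or PhysiologySpec()
    probe = probe or make_default_probe()

    root = np.random.SeedSequence(manifest.seed)
    for subject, group in manifest.subjects:
        for week in manifest.weeks:
            for stimulus in manifest.stimuli:
                ss = root.spawn(1)[0]
                eff = effects.modulated(group, week)
                hb_seed, phys_seed, motion_seed = ss.spawn(3)
                scan = simulate_hb(design, eff, probe, hb_seed)
                if as_intensity:
                    scan = hb_to_intensity(scan, physiology, seed=phys_seed)
                    if motion_rate > 0:
                        scan, _ = inject_motion(scan, rate=motion_rate,
                                                seed=motion_seed)
                scan.meta.update(subject=subject, group=group, week=week,
                                 stimulus=stimulus)
                row = {"subject": subject, "group": group, "week": week,
                       "stimulus": stimulus,
                       "modulation": effects.group_week_modulation.get(
                           (group, week), 1.0),
                       **scan.meta["ground_truth"]}
                yield scan, row
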