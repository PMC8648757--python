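"""Synthetic two-wavelength fNIRS recordings with known ground truth.

The generator emulates the statistical structure the analysis assumes:
hemoglobin concentration changes are sums of band-limited oscillators
(cardiac, respiratory, myogenic, VLF) whose amplitudes depend on
source-detector separation class and hemisphere, plus slow polynomial
drift and white noise; raw intensities follow from the forward modified
Beer-Lambert chain ``I = I0 * 10**(-dOD)``; motion spikes and baseline
shifts are injected into the intensity series with a full event log.

Respiratory and myogenic oscillators carry a slowly wandering
instantaneous frequency (bounded random walk reflecting at the band
edges); cardiac and VLF oscillators are near-stationary. Deoxygenated
hemoglobin defaults to ``-0.3 x`` the HbO dynamics plus weak independent
oscillators, so systemic peaks are damped in HbR.

Everything is driven by one top-level seed; per-subject / per-channel
substreams are derived by deterministic counters so any subset of the
cohort is reproducible in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .geometry import ChannelMap, default_channel_map
from .preprocess import WAVELENGTHS, MBLLCoefficients, OpticalRecording, mbll_forward

#: frequency band edges (Hz) used for random-walk reflection
BAND_EDGES: dict[str, tuple[float, float]] = {
    "VLF": (0.009, 0.06),
    "myogenic": (0.06, 0.15),
    "respiratory": (0.15, 0.4),
    "cardiac": (0.4, 2.0),
}

_GROUPS = (("long", "left"), ("long", "right"), ("short", "left"), ("short", "right"))


def _amp(long: float, short: float) -> dict[tuple[str, str], float]:
    return {
        ("long", "left"): long,
        ("long", "right"): long,
        ("short", "left"): short,
        ("short", "right"): short,
    }


@dataclass
class BandOscillator:
    """One physiological oscillator: a band label, a centre frequency and
    per-(SDS class, hemisphere) amplitudes in uM (HbO scale)."""

    band: str
    center_hz: float
    jitter_sd_hz: float
    amplitude: dict[tuple[str, str], float]
    wander: bool = False
    condition_gain: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = BAND_EDGES[self.band]
        if not lo <= self.center_hz <= hi:
            raise ValueError(
                f"{self.band} centre {self.center_hz} Hz outside band [{lo}, {hi}]"
            )
        if any(a < 0 for a in self.amplitude.values()):
            raise ValueError("oscillator amplitudes must be >= 0")


def default_oscillators() -> list[BandOscillator]:
    """Cognitive-like defaults: VLF dominates the long (cerebral+scalp)
    channels while systemic bands dominate the short (scalp) channels."""
    return [
        BandOscillator("VLF", 0.03, 0.004, _amp(long=1.0, short=0.4)),
        BandOscillator("myogenic", 0.10, 0.012, _amp(long=0.5, short=0.6), wander=True),
        BandOscillator("respiratory", 0.25, 0.03, _amp(long=0.15, short=0.35), wander=True),
        BandOscillator("cardiac", 1.10, 0.02, _amp(long=0.3, short=0.8)),
    ]


@dataclass
class ArtifactRates:
    """Motion-artifact event rates (per minute) and magnitudes (counts)."""

    spikes_per_min: float = 0.3
    shifts_per_min: float = 0.05
    spike_amp: float = 150.0
    shift_amp: float = 100.0

    def __post_init__(self) -> None:
        if self.spikes_per_min < 0 or self.shifts_per_min < 0:
            raise ValueError("artifact rates must be >= 0")


def cognitive_schedule(
    condition_s: float = 720.0, lead_in_s: float = 60.0, mid_break_s: float = 900.0
) -> tuple[list[tuple[str, float, float]], float]:
    """Five task conditions (three easy, two hard) of 12 min each, with a
    lead-in rest and a 15-min break between difficulty blocks."""
    schedule = []
    t = lead_in_s
    for label in ("E1", "E2", "E3"):
        schedule.append((label, t, t + condition_s))
        t += condition_s
    t += mid_break_s
    for label in ("H1", "H2"):
        schedule.append((label, t, t + condition_s))
        t += condition_s
    return schedule, t


def hypercapnic_schedule(
    baseline_s: float = 30.0, block_s: float = 60.0, n_blocks: int = 3
) -> tuple[list[tuple[str, float, float]], float]:
    """30-s room-air baseline followed by alternating 60-s hypercapnic /
    normocapnic blocks plus a trailing rest; 7 min total by default."""
    schedule = [("baseline", 0.0, baseline_s)]
    t = baseline_s
    for k in range(n_blocks):
        schedule.append((f"hyper{k + 1}", t, t + block_s))
        t += block_s
        schedule.append((f"normo{k + 1}", t, t + block_s))
        t += block_s
    return schedule, t + baseline_s


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the generator.

    Defaults describe the cognitive protocol: 13 subjects, 10 Hz
    sampling, the four default band oscillators, cubic drift, 0.05 uM
    white noise and mild motion-artifact rates.
    """

    n_subjects: int = 13
    protocol: str = "cognitive"  # "cognitive" | "hypercapnic"
    sampling_rate: float = 10.0
    oscillators: list[BandOscillator] = field(default_factory=default_oscillators)
    drift_order: int = 3
    drift_amp_um: float = 0.5
    noise_sd: float = 0.05
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    baseline_intensity: dict[float, float] = field(
        default_factory=lambda: {730.0: 1200.0, 850.0: 1500.0}
    )
    dark_mean: float = 30.0
    dark_sd: float = 3.0
    age_years: float = 30.0
    hbr_ratio: float = -0.3
    hbr_osc_scale: float = 0.15
    subject_sigma: float = 0.25
    band_subject_sigma: float = 0.15
    dpf_override: float | None = None
    saturation_limit: float = 4500.0
    bad_coupling: tuple[int, float] | None = None  # (channel_id, target r)
    hypercapnic_blocks: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol not in ("cognitive", "hypercapnic"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.protocol == "cognitive" and self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        fmax = max(o.center_hz for o in self.oscillators) if self.oscillators else 0.0
        if self.sampling_rate <= 2 * fmax:
            raise ValueError("sampling_rate must exceed twice the highest centre frequency")

    def schedule(self) -> tuple[list[tuple[str, float, float]], float]:
        if self.protocol == "cognitive":
            return cognitive_schedule()
        return hypercapnic_schedule(n_blocks=self.hypercapnic_blocks)


@dataclass
class GroundTruth:
    """True concentration dynamics and injected structure for one subject."""

    dhbo: np.ndarray  # (n_channels, n_samples), uM
    dhbr: np.ndarray
    channel_ids: list[int]
    injected_amplitude: dict[tuple[str, str, str], float]  # (band, sds, hemi) -> uM
    events: list[dict]
    subject_scale: float
    band_gains: dict[str, float]

    @property
    def dhbt(self) -> np.ndarray:
        return self.dhbo + self.dhbr

    def channel(self, channel_id: int) -> tuple[np.ndarray, np.ndarray]:
        i = self.channel_ids.index(channel_id)
        return self.dhbo[i], self.dhbr[i]


def _rng(seed: int, *counters: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, counters)]))


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by reflection at both edges."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def _condition_gain(
    osc: BandOscillator, schedule: list[tuple[str, float, float]], t: np.ndarray
) -> np.ndarray:
    if not osc.condition_gain:
        return np.ones_like(t)
    g = np.ones_like(t)
    for label, start, end in schedule:
        gain = osc.condition_gain.get(label)
        if gain is not None:
            g[(t >= start) & (t < end)] = gain
    return g


def _oscillator_signal(
    osc: BandOscillator,
    sds: str,
    hemi: str,
    t: np.ndarray,
    fs: float,
    schedule: list[tuple[str, float, float]],
    rng: np.random.Generator,
    scale: float,
) -> np.ndarray:
    base_amp = osc.amplitude.get((sds, hemi), 0.0) * scale
    lo, hi = BAND_EDGES[osc.band]
    if osc.wander:
        # mean-reverting bounded walk: stationary SD = jitter_sd_hz,
        # ~2-min reversion time, reflected at the band edges — a slowly
        # drifting spectral peak rather than a band-filling diffusion
        tau_s = 120.0
        phi = np.exp(-1.0 / (fs * tau_s))
        innov = rng.normal(0.0, osc.jitter_sd_hz * np.sqrt(1 - phi**2), size=t.size)
        start = rng.normal(0.0, osc.jitter_sd_hz)
        dev, _ = sps.lfilter([1.0], [1.0, -phi], innov, zi=[phi * start])
        freq = _reflect(osc.center_hz + dev, lo, hi)
    else:
        freq = np.full(t.size, np.clip(rng.normal(osc.center_hz, osc.jitter_sd_hz), lo, hi))
    phase = 2 * np.pi * np.cumsum(freq) / fs + rng.uniform(0, 2 * np.pi)
    return base_amp * _condition_gain(osc, schedule, t) * np.sin(phase)


def inject_artifacts(
    series: np.ndarray,
    rates: ArtifactRates,
    sampling_rate: float = 10.0,
    seed: int = 0,
    events: list[dict] | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Inject motion spikes (additive transients <= 1 s) and baseline
    shifts (steps persisting to the end of the record).

    With ``events`` given, those exact events are applied; otherwise event
    counts are Poisson draws at the configured per-minute rates from the
    seeded generator. Returns the modified series and the event log.
    """
    x = np.asarray(series, dtype=float).copy()
    n = x.size
    fs = sampling_rate
    dur_min = n / fs / 60.0
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    log: list[dict] = []
    if events is None:
        events = []
        for _ in range(rng.poisson(rates.spikes_per_min * dur_min)):
            events.append(
                {
                    "type": "spike",
                    "time_s": float(rng.uniform(0, n / fs)),
                    "magnitude": float(
                        rng.choice([-1, 1]) * rates.spike_amp * (0.5 + rng.exponential(0.5))
                    ),
                    "duration_s": float(rng.uniform(0.1, 1.0)),
                }
            )
        for _ in range(rng.poisson(rates.shifts_per_min * dur_min)):
            events.append(
                {
                    "type": "shift",
                    "time_s": float(rng.uniform(0, n / fs)),
                    "magnitude": float(
                        rng.choice([-1, 1]) * rates.shift_amp * (0.5 + rng.exponential(0.5))
                    ),
                    "duration_s": 0.0,
                }
            )
        events.sort(key=lambda e: e["time_s"])
    for ev in events:
        i0 = int(round(ev["time_s"] * fs))
        if not 0 <= i0 < n:
            continue
        if ev["type"] == "spike":
            dur = min(float(ev.get("duration_s", 0.5)), 1.0)
            width = max(2, int(round(dur * fs)))
            i1 = min(n, i0 + width)
            u = np.linspace(0, np.pi, i1 - i0)
            x[i0:i1] += ev["magnitude"] * np.sin(u)
        elif ev["type"] == "shift":
            x[i0:] += ev["magnitude"]
        else:
            raise ValueError(f"unknown artifact type {ev['type']!r}")
        log.append(dict(ev))
    return x, log


def generate_recording(
    config: SyntheticConfig,
    subject: int = 0,
    channel_map: ChannelMap | None = None,
) -> tuple[OpticalRecording, GroundTruth]:
    """Generate one subject's raw optical recording plus ground truth.

    The concentration dynamics are shared within each (SDS class,
    hemisphere) group — systemic oscillations are spatially coherent —
    with channel-specific drift and white noise on top. Intensities are
    produced by the forward Beer-Lambert chain using the same coefficient
    construction the preprocessing stage inverts, so the clean round trip
    is exact. Identical (config, subject) gives bit-identical output.
    """
    cmap = channel_map or default_channel_map()
    fs = config.sampling_rate
    schedule, duration = config.schedule()
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    subj_rng = _rng(config.seed, subject, 0)
    subject_scale = float(np.exp(subj_rng.normal(0.0, config.subject_sigma)))
    band_gains = {
        band: float(np.exp(subj_rng.normal(0.0, config.band_subject_sigma)))
        for band in BAND_EDGES
    }

    # group-level oscillatory dynamics
    hbo_group: dict[tuple[str, str], np.ndarray] = {}
    hbr_group: dict[tuple[str, str], np.ndarray] = {}
    injected: dict[tuple[str, str, str], float] = {}
    for gi, (sds, hemi) in enumerate(_GROUPS):
        o_sig = np.zeros(n)
        r_sig = np.zeros(n)
        for oi, osc in enumerate(config.oscillators):
            scale = subject_scale * band_gains[osc.band]
            rng_o = _rng(config.seed, subject, 100 + gi * 10 + oi)
            o_sig += _oscillator_signal(osc, sds, hemi, t, fs, schedule, rng_o, scale)
            if config.hbr_osc_scale:
                rng_r = _rng(config.seed, subject, 200 + gi * 10 + oi)
                r_sig += config.hbr_osc_scale * _oscillator_signal(
                    osc, sds, hemi, t, fs, schedule, rng_r, scale
                )
            injected[(osc.band, sds, hemi)] = osc.amplitude.get((sds, hemi), 0.0) * scale
        hbo_group[(sds, hemi)] = o_sig
        hbr_group[(sds, hemi)] = config.hbr_ratio * o_sig + r_sig

    ids = cmap.channel_ids
    dhbo = np.zeros((len(ids), n))
    dhbr = np.zeros((len(ids), n))
    intensity = np.zeros((len(ids), 2, n))
    dark = np.zeros((len(ids), n))
    events: list[dict] = []
    t_norm = np.linspace(-1.0, 1.0, n)

    for i, cid in enumerate(ids):
        chan = cmap[cid]
        rng_c = _rng(config.seed, subject, 1000 + cid)
        for arr, code in ((dhbo, 0), (dhbr, 1)):
            sig = hbo_group[(chan.sds_class, chan.hemisphere)] if code == 0 else hbr_group[
                (chan.sds_class, chan.hemisphere)
            ]
            drift = np.zeros(n)
            if config.drift_order > 0 and config.drift_amp_um > 0:
                coeffs = rng_c.normal(0.0, 1.0, size=config.drift_order)
                for k, c in enumerate(coeffs, start=1):
                    drift += c * t_norm**k
                drift *= config.drift_amp_um / max(config.drift_order, 1)
            noise = rng_c.normal(0.0, config.noise_sd, size=n) if config.noise_sd else 0.0
            arr[i] = sig + drift + noise

        coef = MBLLCoefficients.for_channel(
            chan.separation_cm, age=config.age_years, dpf_override=config.dpf_override
        )
        od730, od850 = mbll_forward(dhbo[i], dhbr[i], coef)
        for w, (lam, od) in enumerate(zip(WAVELENGTHS, (od730, od850))):
            series = config.baseline_intensity[lam] * 10.0 ** (-od)
            if np.any(series >= config.saturation_limit) or np.any(series <= 0):
                raise ValueError(
                    f"channel {cid} at {lam:.0f} nm leaves the valid intensity range; "
                    "reduce oscillator amplitudes or baseline intensity"
                )
            seed_a = _rng(config.seed, subject, 2000 + cid * 4 + w)
            series, ev = inject_artifacts(
                series, config.artifact_rates, sampling_rate=fs, seed=seed_a
            )
            for e in ev:
                events.append({**e, "channel_id": cid, "wavelength_nm": lam})
            intensity[i, w] = series

        dark[i] = rng_c.normal(config.dark_mean, config.dark_sd, size=n)

    if config.bad_coupling is not None:
        cid, rho = config.bad_coupling
        i = ids.index(cid)
        if not 0 < rho < 1:
            raise ValueError("bad_coupling correlation must lie in (0, 1)")
        dk = dark[i] - dark[i].mean()
        sd_d = dk.std()
        if sd_d > 0:
            rng_b = _rng(config.seed, subject, 5000 + cid)
            for w in range(2):
                base = intensity[i, w]
                sd_e = sd_d * np.sqrt(1 / rho**2 - 1)
                intensity[i, w] = base.mean() + dk + rng_b.normal(0, sd_e, size=n)

    rec = OpticalRecording(
        intensity=intensity,
        dark=dark,
        sampling_rate=fs,
        age=config.age_years,
        schedule=schedule,
        channel_map=cmap,
        baseline_intensity=dict(config.baseline_intensity),
        meta={"seed": config.seed, "subject": subject, "protocol": config.protocol},
    )
    truth = GroundTruth(
        dhbo=dhbo,
        dhbr=dhbr,
        channel_ids=list(ids),
        injected_amplitude=injected,
        events=events,
        subject_scale=subject_scale,
        band_gains=band_gains,
    )
    return rec, truth


def generate_cohort(
    config: SyntheticConfig,
) -> list[tuple[OpticalRecording, GroundTruth]]:
    """All subjects of the configured cohort, one recording each."""
    return [generate_recording(config, subject=s) for s in range(config.n_subjects)]


def clean_config(config: SyntheticConfig | None = None, **overrides) -> SyntheticConfig:
    """A copy of ``config`` with noise, drift and artifacts switched off —
    the setting under which the forward/inverse round trip is exact."""
    cfg = config or SyntheticConfig()
    return replace(
        cfg,
        noise_sd=0.0,
        drift_amp_um=0.0,
        artifact_rates=ArtifactRates(spikes_per_min=0.0, shifts_per_min=0.0),
        bad_coupling=None,
        **overrides,
    )
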