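"""Synthetic EEG generator with known ground truth.

Long-term rodent EEG at ~12 kHz is not publicly deposited, so every
downstream stage (quality control, EMD, event detection, scaling
analysis) is exercised against recordings built here: Gaussian-like
background with optional circadian amplitude modulation, embedded
transient oscillations (ripples, fast ripples, population spikes),
zero-block / repeated-pattern corruption, and on-interval duration
samples drawn from truncated power laws.

Conventions
-----------
* Durations given in seconds are converted to sample counts by rounding
  half away from zero.
* Float signals are quantized to int16 by the same rounding and
  saturated at [-32768, 32767]; clipped-sample counts are recorded in
  the recording's ``meta``.
* One master seed; independent per-file streams are derived by counter
  via :class:`numpy.random.SeedSequence` spawn keys, so any file can be
  regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import special
from scipy.signal.windows import tukey as _tukey_window

from .io import ADC_MAX, ADC_MIN, RawRecording, write_bin, write_json

__all__ = [
    "SyntheticSpec",
    "GroundTruthEvent",
    "CorruptionSpec",
    "gen_background",
    "embed_event",
    "apply_corruption",
    "gen_powerlaw_durations",
    "gen_onoff_amplitude",
    "write_dataset",
    "benchmark_recording",
]


def _round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (np.round rounds half to even)."""
    return np.trunc(x + np.copysign(0.5, x))


def seconds_to_samples(t: float, fs: float) -> int:
    return int(_round_half_away(t * fs))


def quantize(signal: np.ndarray) -> tuple[np.ndarray, int]:
    """Round a float signal to int16, saturating; returns (samples, n_clipped)."""
    rounded = _round_half_away(np.asarray(signal, dtype=np.float64))
    n_clipped = int(np.count_nonzero((rounded < ADC_MIN) | (rounded > ADC_MAX)))
    return np.clip(rounded, ADC_MIN, ADC_MAX).astype(np.int16), n_clipped


@dataclass
class SyntheticSpec:
    """Background-recording parameters.

    duration : seconds; sampling_rate : Hz; background_sigma : ADC counts
    (std of the white Gaussian background); modulation_period : seconds
    of sinusoidal amplitude modulation emulating circadian rhythm (None
    disables it); modulation_depth : relative modulation amplitude;
    one_over_f : shape the background as 1/f instead of white (the
    acquisition background spectrum is not prescribed; white is the
    default, 1/f an option).
    """

    duration: float
    sampling_rate: float = 12207.0
    background_sigma: float = 100.0
    modulation_period: float | None = None
    modulation_depth: float = 0.5
    modulation_phase: float = 0.0
    one_over_f: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.background_sigma < 0:
            raise ValueError("background_sigma must be non-negative")


@dataclass
class GroundTruthEvent:
    """A planted transient oscillation.

    kind is "hfo" for ripples/fast ripples (transient oscillations well
    under 1 s) or "population_spike" for slow ~0.1 s transients whose
    spectral content sits below 80 Hz.
    """

    onset: float
    duration: float
    centre_frequency: float
    peak_amplitude: float
    kind: str = "hfo"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.centre_frequency <= 0:
            raise ValueError("centre_frequency must be positive")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.kind not in ("hfo", "population_spike"):
            raise ValueError(f"unknown event kind: {self.kind}")

    def to_dict(self) -> dict:
        return {
            "onset": self.onset,
            "duration": self.duration,
            "centre_frequency": self.centre_frequency,
            "peak_amplitude": self.peak_amplitude,
            "kind": self.kind,
        }


@dataclass
class CorruptionSpec:
    """Recording defects to plant: zero blocks, a repeated oscillation
    pattern, and/or truncation to a shorter file."""

    zero_blocks: list[tuple[float, float]] = field(default_factory=list)
    repeat_pattern: tuple[int, float] | None = None  # (template samples, span seconds)
    truncate_to: int | None = None


def gen_background(spec: SyntheticSpec) -> RawRecording:
    """White (or 1/f-shaped) Gaussian background, quantized to int16.

    Rejects parameter choices where more than 1% of samples would
    saturate the 16-bit range.
    """
    if spec.background_sigma > 0:
        clip_prob = 2.0 * special.ndtr(-ADC_MAX / spec.background_sigma)
        if clip_prob > 0.01:
            raise ValueError(
                f"background_sigma={spec.background_sigma} would clip "
                f"{100 * clip_prob:.1f}% of samples"
            )
    n = seconds_to_samples(spec.duration, spec.sampling_rate)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    x = rng.standard_normal(n)
    if spec.one_over_f:
        # shape amplitude spectrum as f^{-1/2} (power ~ 1/f), renormalize
        spec_f = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(n, d=1.0 / spec.sampling_rate)
        shaping = np.ones_like(freqs)
        shaping[1:] = 1.0 / np.sqrt(freqs[1:])
        spec_f *= shaping
        x = np.fft.irfft(spec_f, n=n)
        x /= x.std() or 1.0
    x *= spec.background_sigma
    if spec.modulation_period is not None:
        t = np.arange(n) / spec.sampling_rate
        x *= 1.0 + spec.modulation_depth * np.sin(
            2 * np.pi * t / spec.modulation_period + spec.modulation_phase
        )
    samples, n_clipped = quantize(x)
    rec = RawRecording(samples=samples, sampling_rate=spec.sampling_rate)
    rec.meta["spec"] = {
        "duration": spec.duration,
        "sampling_rate": spec.sampling_rate,
        "background_sigma": spec.background_sigma,
        "modulation_period": spec.modulation_period,
        "one_over_f": spec.one_over_f,
        "seed": spec.seed,
    }
    rec.meta["events"] = []
    rec.meta["n_clipped"] = n_clipped
    return rec


def _event_waveform(ev: GroundTruthEvent, fs: float, envelope: str) -> np.ndarray:
    n = seconds_to_samples(ev.duration, fs)
    t = np.arange(n) / fs
    if envelope == "gaussian":
        # sigma = duration/6 keeps the burst visually compact
        env = np.exp(-0.5 * ((t - ev.duration / 2) / (ev.duration / 6)) ** 2)
    elif envelope == "tukey":
        env = _tukey_window(n, alpha=0.5)
    else:
        raise ValueError(f"unknown envelope: {envelope}")
    return ev.peak_amplitude * env * np.sin(2 * np.pi * ev.centre_frequency * t)


def embed_event(
    rec: RawRecording, ev: GroundTruthEvent, envelope: str = "gaussian"
) -> RawRecording:
    """Return a copy of ``rec`` with a windowed sinusoid added.

    The event is logged in ``meta["events"]`` so detector output can be
    scored against ground truth.
    """
    fs = rec.sampling_rate
    i0 = seconds_to_samples(ev.onset, fs)
    wave = _event_waveform(ev, fs, envelope)
    if i0 < 0 or i0 + wave.size > rec.L:
        raise ValueError("event exceeds recording bounds")
    x = rec.astype_float()
    x[i0 : i0 + wave.size] += wave
    samples, n_clipped = quantize(x)
    out = RawRecording(
        samples=samples,
        sampling_rate=fs,
        rat_id=rec.rat_id,
        channel_id=rec.channel_id,
        file_no=rec.file_no,
        meta={**rec.meta},
    )
    out.meta["events"] = list(rec.meta.get("events", [])) + [ev.to_dict()]
    out.meta["n_clipped"] = rec.meta.get("n_clipped", 0) + n_clipped
    return out


def apply_corruption(rec: RawRecording, c: CorruptionSpec) -> RawRecording:
    """Plant acquisition defects: zero blocks (union semantics for
    overlaps), a repeatedly embedded oscillation template, truncation."""
    fs = rec.sampling_rate
    samples = rec.samples.copy()
    for onset, dur in c.zero_blocks:
        if dur < 0 or onset < 0:
            raise ValueError("zero block onset/duration must be non-negative")
        i0 = seconds_to_samples(onset, fs)
        n = seconds_to_samples(dur, fs)
        if i0 + n > samples.size:
            raise ValueError("zero block exceeds recording bounds")
        samples[i0 : i0 + n] = 0
    if c.repeat_pattern is not None:
        tmpl_len, span = c.repeat_pattern
        n = seconds_to_samples(span, fs)
        if tmpl_len <= 0 or tmpl_len > samples.size or n > samples.size:
            raise ValueError("repeat pattern out of range")
        template = samples[:tmpl_len]
        reps = int(np.ceil(n / tmpl_len))
        samples[:n] = np.tile(template, reps)[:n]
    if c.truncate_to is not None:
        if c.truncate_to < 0 or c.truncate_to > samples.size:
            raise ValueError("truncate_to out of range")
        samples = samples[: c.truncate_to]
    out = RawRecording(
        samples=samples,
        sampling_rate=fs,
        rat_id=rec.rat_id,
        channel_id=rec.channel_id,
        file_no=rec.file_no,
        meta={**rec.meta},
    )
    out.meta["corruption"] = {
        "zero_blocks": list(c.zero_blocks),
        "repeat_pattern": list(c.repeat_pattern) if c.repeat_pattern else None,
        "truncate_to": c.truncate_to,
    }
    return out


def gen_powerlaw_durations(
    gamma: float,
    t_min: float,
    t_max: float,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """I.i.d. durations with density ∝ T^(-gamma) on [t_min, t_max].

    Inverse-CDF sampling; ``t_max`` may be ``inf`` for the untruncated
    Pareto case, where T = t_min * (1 - u)^(-1/(gamma-1)).
    """
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    if not (0 < t_min < t_max):
        raise ValueError("need 0 < t_min < t_max")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(seed))
    )
    u = rng.uniform(size=n)
    return powerlaw_inverse_cdf(u, gamma, t_min, t_max)


def powerlaw_inverse_cdf(
    u: np.ndarray | float, gamma: float, t_min: float, t_max: float = np.inf
) -> np.ndarray | float:
    """Quantile function of the (truncated) power-law duration density."""
    g1 = 1.0 - gamma
    if np.isinf(t_max):
        return t_min * (1.0 - np.asarray(u)) ** (1.0 / g1)
    a, b = t_min**g1, t_max**g1
    return (a + np.asarray(u) * (b - a)) ** (1.0 / g1)


def gen_onoff_amplitude(
    gamma: float,
    n_bursts: int,
    seed: int = 0,
    dt: float = 0.005,
    t_min: float = 0.1,
    t_max: float = 10.0,
    off_mean: float = 0.3,
    off_level: float = 10.0,
    off_sd: float = 2.0,
    on_level: float = 50.0,
    on_sd: float = 5.0,
    smooth: int = 7,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic on-off amplitude process with power-law on durations.

    Emulates the amplitude function of an HFO-band IMF: a quiescent
    baseline (off, mean ``off_level``) interrupted by bursts (on, mean
    ``on_level``) whose durations follow a truncated power law with
    exponent ``gamma``; off durations are exponential. The additive
    noise is smoothed over ``smooth`` samples, mirroring the heavy
    autocorrelation of real amplitude functions (neighbouring windows
    share all but one period).

    Returns (x seconds, amplitude values, true on durations).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    on = gen_powerlaw_durations(gamma, t_min, t_max, n_bursts, seed=rng)
    off = rng.exponential(off_mean, n_bursts + 1) + 5 * dt
    lens, kinds = [], []
    for i in range(n_bursts):
        lens.append(max(2, int(round(off[i] / dt))))
        kinds.append(0)
        lens.append(max(2, int(round(on[i] / dt))))
        kinds.append(1)
    lens.append(max(2, int(round(off[-1] / dt))))
    kinds.append(0)
    total = sum(lens)
    noise = rng.standard_normal(total + smooth)
    noise = np.convolve(noise, np.ones(smooth) / smooth, mode="valid")[:total]
    noise /= noise.std()
    level = np.concatenate(
        [np.full(n, on_level if k else off_level) for n, k in zip(lens, kinds)]
    )
    sd = np.concatenate(
        [np.full(n, on_sd if k else off_sd) for n, k in zip(lens, kinds)]
    )
    A = np.clip(level + sd * noise, 0.0, None)
    x = np.arange(total) * dt
    return x, A, on


def write_dataset(recordings: list[RawRecording], outdir: str | Path) -> Path:
    """Write flat .bin files plus a ground_truth.json sidecar.

    The sidecar lists, per file: planted events, corruption spans,
    clipping counts and the generating seed, so detector output can be
    scored without re-deriving anything.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sidecar: dict = {"files": []}
    for rec in recordings:
        path = outdir / rec.filename
        write_bin(rec, path)
        entry = {
            "filename": rec.filename,
            "rat_id": rec.rat_id,
            "channel_id": rec.channel_id,
            "file_no": rec.file_no,
            "sampling_rate": rec.sampling_rate,
            "L": rec.L,
            "empty": rec.L == 0,
            "events": rec.meta.get("events", []),
            "corruption": rec.meta.get("corruption"),
            "n_clipped": rec.meta.get("n_clipped", 0),
            "spec": rec.meta.get("spec"),
        }
        sidecar["files"].append(entry)
    write_json(sidecar, outdir / "ground_truth.json")
    return outdir


def benchmark_recording(
    seed: int = 0,
    duration: float = 60.0,
    sampling_rate: float = 12207.0,
    background_sigma: float = 100.0,
    n_events: int = 20,
    snr: float = 5.0,
) -> RawRecording:
    """The standard planted-event benchmark used by the test suite.

    ``n_events`` transients (a mix of ripples 120-180 Hz, fast ripples
    250-350 Hz, population spikes 30-50 Hz; durations 50-200 ms) at peak
    amplitude >= ``snr`` times the background std, spaced so that
    ground-truth events never overlap.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(999,)))
    rec = gen_background(
        SyntheticSpec(
            duration=duration,
            sampling_rate=sampling_rate,
            background_sigma=background_sigma,
            seed=seed,
        )
    )
    kinds = (["ripple"] * 8 + ["fast_ripple"] * 6 + ["population_spike"] * 6) * (
        n_events // 20 + 1
    )
    slots = np.linspace(1.0, duration - 1.5, n_events)
    for i in range(n_events):
        kind = kinds[i]
        if kind == "ripple":
            f = rng.uniform(120, 180)
        elif kind == "fast_ripple":
            f = rng.uniform(250, 350)
        else:
            f = rng.uniform(30, 50)
        dur = rng.uniform(0.05, 0.2)
        amp = background_sigma * rng.uniform(snr, snr + 3.0)
        ev = GroundTruthEvent(
            onset=float(slots[i] + rng.uniform(0, 0.2)),
            duration=float(dur),
            centre_frequency=float(f),
            peak_amplitude=float(amp),
            kind="population_spike" if kind == "population_spike" else "hfo",
        )
        rec = embed_event(rec, ev)
    return rec
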