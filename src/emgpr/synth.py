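"""Synthetic sEMG session generation.

Each movement activates channels through a spatial weight vector. During a
contraction repetition, every channel carries

    activation[m, c] * mvc_fraction * trapezoidal_envelope(t) * carrier(t)

where the carrier is zero-mean Gaussian noise band-limited to the typical
surface-EMG energy band (20-450 Hz), superposed on baseline instrumentation
noise. Rest periods carry baseline noise only. The composite then passes a
modeled amplifier front end: 1st-order high-pass, 3rd-order Butterworth
low-pass, gain, and mid-tread quantization.

The ``overlap`` knob interpolates the activation matrix between a seeded
set of distinct per-movement spatial patterns (overlap=0) and the zero
pattern (overlap=1). At full overlap no movement-specific information
remains, so every class — including rest — is statistically identical and
downstream classification collapses to chance at 1/n_classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from emgpr.sessions import EmgSession, ProtocolSpec, REST_LABEL

# Pre-gain carrier amplitude (RMS, volts) of a full-effort, fully-activated
# channel; ~1 mV is a typical surface-EMG scale at strong contraction.
CARRIER_RMS_V = 1e-3

CARRIER_BAND_HZ = (20.0, 450.0)


@dataclass(frozen=True)
class ActivationModel:
    """Movement-specific spatial activation and effort/noise parameters."""

    activation: np.ndarray  # [n_movements x n_channels], weights in [0, 1]
    overlap: float = 0.0
    baseline_noise_rms: float = 5e-6  # volts, pre-gain
    mvc_fraction: float = 0.7
    ramp_fraction: float = 0.15
    rng_seed: int = 0
    mixing: np.ndarray | None = None  # optional row-stochastic crosstalk matrix

    def __post_init__(self) -> None:
        act = np.asarray(self.activation, dtype=np.float64)
        object.__setattr__(self, "activation", act)
        if act.ndim != 2:
            raise ValueError("activation must be [n_movements x n_channels]")
        if act.min() < 0 or act.max() > 1:
            raise ValueError("activation weights must lie in [0, 1]")
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError("overlap must lie in [0, 1]")
        if self.baseline_noise_rms < 0:
            raise ValueError("baseline_noise_rms must be >= 0")
        if not (0.0 <= self.ramp_fraction < 0.5):
            raise ValueError("ramp_fraction must lie in [0, 0.5)")
        if self.mixing is not None:
            mix = np.asarray(self.mixing, dtype=np.float64)
            if mix.shape != (act.shape[1], act.shape[1]):
                raise ValueError("mixing must be square [n_channels x n_channels]")
            object.__setattr__(self, "mixing", mix)

    @property
    def n_movements(self) -> int:
        return self.activation.shape[0]

    @property
    def n_channels(self) -> int:
        return self.activation.shape[1]


@dataclass(frozen=True)
class FrontEndSpec:
    """Amplifier front end: analog filters, gain, and ADC quantization."""

    highpass_order: int = 1
    highpass_cutoff_hz: float = 1.0
    lowpass_order: int = 3
    lowpass_cutoff_hz: float = 750.0
    gain: float = 200.0
    quantization_bits: int = 16
    full_scale_v: float = 2.5  # post-gain half range: ADC spans +-full_scale_v

    def validate_against(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2.0
        if self.lowpass_cutoff_hz >= nyquist or self.highpass_cutoff_hz >= nyquist:
            raise ValueError(
                f"front-end cutoffs must be below the Nyquist frequency {nyquist} Hz"
            )


def make_activation_matrix(
    n_movements: int,
    n_channels: int,
    overlap: float = 0.0,
    rng_seed: int = 0,
    baseline_noise_rms: float = 5e-6,
    mvc_fraction: float = 0.7,
    ramp_fraction: float = 0.15,
) -> ActivationModel:
    """Build a seeded ActivationModel.

    The distinct-pattern matrix places a localized activation bump per
    movement (distinct channel groups, like distinct muscle groups around a
    limb) with seeded jitter; ``overlap`` linearly shrinks all patterns
    toward zero, removing movement-specific structure.
    """
    if n_movements < 1 or n_channels < 1:
        raise ValueError("n_movements and n_channels must be >= 1")
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    channels = np.arange(n_channels, dtype=np.float64)
    centers = (np.arange(n_movements) + 0.5) * n_channels / n_movements
    width = max(n_channels / (2.0 * n_movements), 0.75)
    distinct = np.empty((n_movements, n_channels))
    for m in range(n_movements):
        # circular distance so patterns wrap around the limb circumference
        d = np.minimum(np.abs(channels - centers[m]), n_channels - np.abs(channels - centers[m]))
        bump = np.exp(-0.5 * (d / width) ** 2)
        jitter = 0.1 * rng.random(n_channels)
        distinct[m] = np.clip(bump + jitter, 0.0, 1.0)
    activation = (1.0 - overlap) * distinct
    return ActivationModel(
        activation=activation,
        overlap=overlap,
        baseline_noise_rms=baseline_noise_rms,
        mvc_fraction=mvc_fraction,
        ramp_fraction=ramp_fraction,
        rng_seed=rng_seed,
    )


def trapezoid_envelope(n_samples: int, ramp_fraction: float) -> np.ndarray:
    """Unit-plateau trapezoid: linear ramps over *ramp_fraction* at each end."""
    env = np.ones(n_samples)
    n_ramp = int(np.floor(ramp_fraction * n_samples))
    if n_ramp > 0:
        ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        env[:n_ramp] = ramp
        env[n_samples - n_ramp:] = ramp[::-1]
    return env


def _band_limited_noise(rng: np.random.Generator, n_samples: int, fs: float) -> np.ndarray:
    """Unit-RMS zero-mean Gaussian noise band-limited to the sEMG energy band."""
    lo, hi = CARRIER_BAND_HZ
    hi = min(hi, 0.45 * fs)
    white = rng.standard_normal(n_samples)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, white)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def quantize_mid_tread(x: np.ndarray, bits: int, full_scale: float) -> np.ndarray:
    """Mid-tread uniform quantization over [-full_scale, +full_scale].

    Values beyond full scale are clipped with a warning; zero maps to zero.
    """
    n_levels = 2**bits
    step = 2.0 * full_scale / n_levels
    max_code = n_levels // 2 - 1
    min_code = -(n_levels // 2)
    codes = np.round(x / step)
    if codes.max(initial=0) > max_code or codes.min(initial=0) < min_code:
        warnings.warn("signal exceeds ADC full scale; clipping", stacklevel=2)
        codes = np.clip(codes, min_code, max_code)
    return codes * step


def apply_frontend(raw: np.ndarray, frontend: FrontEndSpec, sampling_rate: float) -> np.ndarray:
    """Run raw (pre-gain) volts through filters, gain, and quantization."""
    frontend.validate_against(sampling_rate)
    hp = sps.butter(
        frontend.highpass_order, frontend.highpass_cutoff_hz, btype="highpass",
        fs=sampling_rate, output="sos",
    )
    lp = sps.butter(
        frontend.lowpass_order, frontend.lowpass_cutoff_hz, btype="lowpass",
        fs=sampling_rate, output="sos",
    )
    out = sps.sosfilt(hp, raw, axis=0)
    out = sps.sosfilt(lp, out, axis=0)
    out = out * frontend.gain
    return quantize_mid_tread(out, frontend.quantization_bits, frontend.full_scale_v)


def _raw_contraction(
    rng: np.random.Generator,
    n_samples: int,
    weights: np.ndarray,
    mvc_fraction: float,
    ramp_fraction: float,
    fs: float,
) -> np.ndarray:
    """Pre-gain contraction segment [n_samples x n_channels], without baseline noise."""
    env = trapezoid_envelope(n_samples, ramp_fraction)
    seg = np.empty((n_samples, weights.size))
    for c, w in enumerate(weights):
        carrier = _band_limited_noise(rng, n_samples, fs)
        seg[:, c] = w * mvc_fraction * CARRIER_RMS_V * env * carrier
    return seg


def generate_session(
    protocol: ProtocolSpec,
    model: ActivationModel,
    frontend: FrontEndSpec | None = None,
) -> EmgSession:
    """Synthesize a full recording session following the protocol timing.

    Movements are recorded back to back; each movement contributes
    ``n_repetitions`` blocks of contraction followed by rest. Fully
    deterministic for a fixed ``model.rng_seed``.
    """
    frontend = frontend or FrontEndSpec()
    frontend.validate_against(protocol.sampling_rate)
    if model.n_movements != len(protocol.movements):
        raise ValueError(
            f"activation has {model.n_movements} movements, protocol lists {len(protocol.movements)}"
        )
    if model.n_channels != protocol.n_channels:
        raise ValueError(
            f"activation has {model.n_channels} channels, protocol declares {protocol.n_channels}"
        )
    fs = protocol.sampling_rate
    n_contr = protocol.contraction_samples
    n_rep = protocol.repetition_samples
    total = protocol.total_samples
    rng = np.random.default_rng(model.rng_seed)

    raw = np.zeros((total, protocol.n_channels))
    if model.baseline_noise_rms > 0:
        raw += model.baseline_noise_rms * rng.standard_normal(raw.shape)

    ranges: dict[str, list[tuple[int, int]]] = {}
    cursor = 0
    for m, movement in enumerate(protocol.movements):
        ranges[movement] = []
        for _rep in range(protocol.n_repetitions):
            start, stop = cursor, cursor + n_contr
            raw[start:stop] += _raw_contraction(
                rng, n_contr, model.activation[m], model.mvc_fraction,
                model.ramp_fraction, fs,
            )
            ranges[movement].append((start, stop))
            cursor += n_rep

    if model.mixing is not None:
        raw = raw @ model.mixing.T

    signal = apply_frontend(raw, frontend, fs)
    return EmgSession(
        protocol=protocol,
        signal=signal,
        contraction_ranges=ranges,
        provenance=f"synthetic:seed={model.rng_seed},overlap={model.overlap}",
    )


def generate_stream(
    protocol: ProtocolSpec,
    model: ActivationModel,
    movement: str,
    duration_s: float,
    rng_seed: int,
    frontend: FrontEndSpec | None = None,
) -> np.ndarray:
    """Synthesize a continuous single-movement signal for real-time streaming.

    The effort ramps up over the model's ramp duration (relative to one
    protocol contraction) and then holds at plateau for the rest of
    *duration_s*. Returns [n_samples x n_channels] post-frontend volts.
    """
    frontend = frontend or FrontEndSpec()
    fs = protocol.sampling_rate
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(rng_seed)
    raw = np.zeros((n, protocol.n_channels))
    if model.baseline_noise_rms > 0:
        raw += model.baseline_noise_rms * rng.standard_normal(raw.shape)
    if movement != REST_LABEL:
        m = list(protocol.movements).index(movement)
        n_ramp = int(np.floor(model.ramp_fraction * protocol.contraction_samples))
        env = np.ones(n)
        if n_ramp > 0:
            env[: min(n_ramp, n)] = np.linspace(0.0, 1.0, n_ramp, endpoint=False)[: min(n_ramp, n)]
        for c, w in enumerate(model.activation[m]):
            carrier = _band_limited_noise(rng, n, fs)
            raw[:, c] += w * model.mvc_fraction * CARRIER_RMS_V * env * carrier
    if model.mixing is not None:
        raw = raw @ model.mixing.T
    return apply_frontend(raw, frontend, fs)
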