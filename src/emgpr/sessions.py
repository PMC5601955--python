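"""Session data model and on-disk bundle format for multichannel sEMG recordings.

A session bundle is a directory holding ``session.json`` (protocol,
contraction ranges, provenance, format version) plus one signal file:
``signal.csv`` (human-readable, >= 9 significant digits) or ``signal.f32``
(little-endian float32, bit-exact round trip). Contraction ranges are
0-based half-open sample intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

FORMAT_VERSION = 1

DEFAULT_MOVEMENTS = (
    "knee_flexion",
    "knee_extension",
    "ankle_plantarflexion",
    "ankle_dorsiflexion",
    "hip_rotation_medial",
    "hip_rotation_lateral",
    "tibial_rotation_medial",
    "tibial_rotation_lateral",
)

REST_LABEL = "rest"


class SessionValidationError(ValueError):
    """An EmgSession or ProtocolSpec invariant is violated; names the field."""


class SessionFormatError(ValueError):
    """A bundle on disk is missing, malformed, or of an unknown version."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Recording protocol: what was recorded, how fast, and for how long."""

    sampling_rate: float = 2000.0
    n_channels: int = 16
    bit_depth: int = 16
    movements: tuple[str, ...] = DEFAULT_MOVEMENTS
    n_repetitions: int = 3
    contraction_s: float = 4.0
    rest_s: float = 4.0
    gain: float = 200.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "movements", tuple(self.movements))
        if self.sampling_rate <= 0:
            raise SessionValidationError("sampling_rate must be > 0")
        if self.n_channels < 1:
            raise SessionValidationError("n_channels must be >= 1")
        if self.n_repetitions < 1:
            raise SessionValidationError("n_repetitions must be >= 1")
        if self.contraction_s <= 0:
            raise SessionValidationError("contraction_s must be > 0")
        if self.rest_s < 0:
            raise SessionValidationError("rest_s must be >= 0")
        if not self.movements:
            raise SessionValidationError("movements must be non-empty")
        if len(set(self.movements)) != len(self.movements):
            raise SessionValidationError("movements must be unique")

    @property
    def repetition_samples(self) -> int:
        """Samples in one contraction + rest block."""
        return int(round((self.contraction_s + self.rest_s) * self.sampling_rate))

    @property
    def contraction_samples(self) -> int:
        return int(round(self.contraction_s * self.sampling_rate))

    @property
    def total_samples(self) -> int:
        """Protocol-implied session length: movements x repetitions x (contraction + rest)."""
        return len(self.movements) * self.n_repetitions * self.repetition_samples

    @property
    def total_duration_s(self) -> float:
        return self.total_samples / self.sampling_rate

    def to_dict(self) -> dict:
        return {
            "sampling_rate": self.sampling_rate,
            "n_channels": self.n_channels,
            "bit_depth": self.bit_depth,
            "movements": list(self.movements),
            "n_repetitions": self.n_repetitions,
            "contraction_s": self.contraction_s,
            "rest_s": self.rest_s,
            "gain": self.gain,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(
            sampling_rate=d["sampling_rate"],
            n_channels=d["n_channels"],
            bit_depth=d["bit_depth"],
            movements=tuple(d["movements"]),
            n_repetitions=d["n_repetitions"],
            contraction_s=d["contraction_s"],
            rest_s=d["rest_s"],
            gain=d["gain"],
        )


@dataclass
class EmgSession:
    """A recorded (or synthesized) session: signal matrix plus protocol metadata.

    ``signal`` is [n_samples x n_channels] in volts after the modeled
    amplifier gain. ``contraction_ranges`` maps each movement label to its
    ``n_repetitions`` half-open (start, stop) sample intervals, ordered and
    non-overlapping.
    """

    protocol: ProtocolSpec
    signal: np.ndarray
    contraction_ranges: dict[str, list[tuple[int, int]]]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise SessionValidationError("signal must be a 2-D matrix [samples x channels]")
        self.validate()

    def validate(self) -> None:
        n_samples, n_channels = self.signal.shape
        p = self.protocol
        if n_channels != p.n_channels:
            raise SessionValidationError(
                f"signal has {n_channels} channels but protocol declares n_channels={p.n_channels}"
            )
        if n_samples != p.total_samples:
            raise SessionValidationError(
                f"signal has {n_samples} samples but protocol implies total_samples={p.total_samples}"
            )
        if set(self.contraction_ranges) != set(p.movements):
            raise SessionValidationError("contraction_ranges keys must equal protocol movements")
        all_ranges: list[tuple[int, int]] = []
        for mov, ranges in self.contraction_ranges.items():
            if len(ranges) != p.n_repetitions:
                raise SessionValidationError(
                    f"movement {mov!r} has {len(ranges)} contraction_ranges, expected n_repetitions={p.n_repetitions}"
                )
            for start, stop in ranges:
                if not (0 <= start < stop <= n_samples):
                    raise SessionValidationError(
                        f"contraction range ({start}, {stop}) of {mov!r} falls outside the signal"
                    )
            if ranges != sorted(ranges):
                raise SessionValidationError(f"contraction_ranges of {mov!r} are not ordered")
            all_ranges.extend(ranges)
        all_ranges.sort()
        for (s0, e0), (s1, e1) in zip(all_ranges, all_ranges[1:]):
            if s1 < e0:
                raise SessionValidationError(
                    f"contraction_ranges overlap: ({s0}, {e0}) and ({s1}, {e1})"
                )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    def rest_ranges(self) -> list[tuple[int, int]]:
        """Maximal sample intervals not covered by any contraction, in order."""
        covered = sorted(r for rs in self.contraction_ranges.values() for r in rs)
        gaps = []
        cursor = 0
        for start, stop in covered:
            if start > cursor:
                gaps.append((cursor, start))
            cursor = max(cursor, stop)
        if cursor < self.n_samples:
            gaps.append((cursor, self.n_samples))
        return gaps


def write_session(session: EmgSession, path: str | Path, dialect: str = "f32") -> Path:
    """Write a session bundle to directory *path*.

    dialect "f32" stores little-endian float32 (bit-exact round trip at
    float32 precision); "csv" stores a plain-text matrix with 9+ significant
    digits. Returns the bundle path.
    """
    if dialect not in ("f32", "csv"):
        raise ValueError(f"unknown signal dialect {dialect!r}")
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "protocol": session.protocol.to_dict(),
        "contraction_ranges": {m: [list(r) for r in rs] for m, rs in session.contraction_ranges.items()},
        "provenance": session.provenance,
        "signal": {
            "dialect": dialect,
            "n_samples": session.n_samples,
            "n_channels": session.n_channels,
            "order": "row-major",
        },
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1))
    if dialect == "f32":
        session.signal.astype("<f4").tofile(path / "signal.f32")
    else:
        np.savetxt(path / "signal.csv", session.signal, fmt="%.9e", delimiter=",")
    return path


def read_session(path: str | Path) -> EmgSession:
    """Read a session bundle written by :func:`write_session`."""
    path = Path(path)
    meta_path = path / "session.json"
    if not meta_path.exists():
        raise SessionFormatError(f"no session.json in {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise SessionFormatError(f"session.json does not parse: {exc}") from exc
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise SessionFormatError(f"unknown format_version {version!r} (expected {FORMAT_VERSION})")
    protocol = ProtocolSpec.from_dict(meta["protocol"])
    sig_meta = meta["signal"]
    n_samples, n_channels = sig_meta["n_samples"], sig_meta["n_channels"]
    dialect = sig_meta["dialect"]
    if dialect == "f32":
        sig_path = path / "signal.f32"
        if not sig_path.exists():
            raise SessionFormatError(f"missing signal file {sig_path}")
        raw = np.fromfile(sig_path, dtype="<f4")
        if raw.size != n_samples * n_channels:
            raise SessionFormatError(
                f"signal.f32 holds {raw.size} values, metadata implies {n_samples * n_channels}"
            )
        signal = raw.reshape(n_samples, n_channels).astype(np.float64)
    elif dialect == "csv":
        sig_path = path / "signal.csv"
        if not sig_path.exists():
            raise SessionFormatError(f"missing signal file {sig_path}")
        try:
            signal = np.loadtxt(sig_path, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise SessionFormatError(f"signal.csv does not parse: {exc}") from exc
        if signal.shape != (n_samples, n_channels):
            raise SessionFormatError(
                f"signal.csv has shape {signal.shape}, metadata implies {(n_samples, n_channels)}"
            )
    else:
        raise SessionFormatError(f"unknown signal dialect {dialect!r}")
    ranges = {m: [tuple(r) for r in rs] for m, rs in meta["contraction_ranges"].items()}
    try:
        return EmgSession(
            protocol=protocol,
            signal=signal,
            contraction_ranges=ranges,
            provenance=meta.get("provenance", "unspecified"),
        )
    except SessionValidationError as exc:
        raise SessionFormatError(f"bundle metadata/signal mismatch: {exc}") from exc


def select_channels(session: EmgSession, channel_indices: Sequence[int]) -> EmgSession:
    """Return a new session keeping only *channel_indices*, order preserved.

    The equally-spaced half subset of a 16-channel session is
    ``select_channels(s, range(0, 16, 2))``.
    """
    indices = list(channel_indices)
    n = session.n_channels
    for i in indices:
        if not (0 <= i < n):
            raise IndexError(f"channel index {i} out of range for {n}-channel session")
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate channel indices")
    new_protocol = replace(session.protocol, n_channels=len(indices))
    return EmgSession(
        protocol=new_protocol,
        signal=session.signal[:, indices].copy(),
        contraction_ranges={m: list(rs) for m, rs in session.contraction_ranges.items()},
        provenance=session.provenance + f"|channels={indices}",
    )
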