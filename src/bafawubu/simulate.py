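"""Synthetic six-axis IMU streams for the seven Bafa Wubu motion sets.

No raw recordings of the arm-worn sensor are publicly available, so this
module generates labelled stand-in data.  The signal model per channel is

    static gravity component (accelerometer only)
    + sinusoid at the movement's fundamental frequency
    + one harmonic at twice the fundamental (half amplitude)
    + optional high-frequency interference (above the 5 Hz cutoff)
    + white noise,

clipped to the sensor ranges (accelerometer ±16 g, gyroscope ±2000 °/s)
after noise addition, mimicking saturation.  Fundamentals sit in the tai chi
tempo band (0.2–2 Hz), so all movement content lies below the 5 Hz low-pass
cutoff and the filter removes exactly the injected contamination.

Scripted sessions concatenate movement events with linear cross-fades
labelled ``"transition"``, so window-labelling rules on mixed windows are
exercised downstream.
"""

from __future__ import annotations

import dataclasses
import io
import pathlib
from typing import Sequence

import numpy as np
import pandas as pd

from bafawubu.movements import CLASS_ORDER, TRANSITION_LABEL, MovementClass, as_code

#: Sensor saturation limits: ±16 g accelerometer, ±2000 °/s gyroscope.
ACCEL_RANGE_G = 16.0
GYRO_RANGE_DPS = 2000.0

#: Default raw sampling rate in Hz.  The wearable's native rate is not
#: documented; 200 Hz is assumed so that both the 5 Hz filter and the
#: downsampling to 50 Hz are consequential.
DEFAULT_RAW_RATE_HZ = 200.0

CSV_COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")


@dataclasses.dataclass(frozen=True)
class MovementSignature:
    """Deterministic oscillation profile of one motion set.

    Parameters
    ----------
    movement : MovementClass
    gravity_axis : array-like of 3 floats
        Unit vector giving the orientation of the 1 g static component in
        the sensor frame (arm posture differs per motion set).
    fundamental_hz : float
        Movement tempo in Hz; must lie in [0.2, 2.0].
    accel_amp : array-like of 3 floats, in g
    gyro_amp : array-like of 3 floats, in °/s
    phase : array-like of 3 floats, radians
    """

    movement: MovementClass
    gravity_axis: tuple[float, float, float]
    fundamental_hz: float
    accel_amp: tuple[float, float, float]
    gyro_amp: tuple[float, float, float]
    phase: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not 0.2 <= self.fundamental_hz <= 2.0:
            raise ValueError(
                f"fundamental_hz={self.fundamental_hz} outside the tai chi "
                "tempo band [0.2, 2.0] Hz"
            )
        g = np.asarray(self.gravity_axis, dtype=float)
        if not np.isclose(np.linalg.norm(g), 1.0, atol=1e-6):
            raise ValueError("gravity_axis must be a unit vector")
        # worst-case clean amplitude: gravity + fundamental + harmonic
        if np.max(np.abs(g) + 1.5 * np.asarray(self.accel_amp)) > ACCEL_RANGE_G:
            raise ValueError("clean accelerometer signal exceeds ±16 g")
        if 1.5 * np.max(np.asarray(self.gyro_amp)) > GYRO_RANGE_DPS:
            raise ValueError("clean gyroscope signal exceeds ±2000 °/s")


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Additive contamination: white noise plus a narrowband interferer.

    ``white_sd`` may be a scalar or a length-6 per-channel vector
    (ax, ay, az in g; gx, gy, gz in °/s); likewise ``interference_amp``.
    The interferer frequency must sit strictly above the 5 Hz cutoff so the
    preprocessing filter is consequential.
    """

    white_sd: float | tuple[float, ...] = 0.0
    interference_hz: float = 25.0
    interference_amp: float | tuple[float, ...] = 0.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.white_sd) < 0):
            raise ValueError("white_sd must be non-negative")
        if np.any(np.asarray(self.interference_amp) < 0):
            raise ValueError("interference_amp must be non-negative")
        if self.interference_hz <= 5.0:
            raise ValueError("interference_hz must be strictly above 5 Hz")

    def _vec6(self, value) -> np.ndarray:
        arr = np.broadcast_to(np.asarray(value, dtype=float), (6,)).copy()
        return arr


#: Noise-free spec, convenient for oracle experiments.
ZERO_NOISE = NoiseSpec()


def moderate_noise() -> NoiseSpec:
    """Moderate sensor contamination: broadband white noise (0.1 g accel,
    20 °/s gyro) plus a 25 Hz interferer (0.3 g / 50 °/s), sized so the 5 Hz
    filter removes most but not all of it after decimation."""
    return NoiseSpec(
        white_sd=(0.1, 0.1, 0.1, 20.0, 20.0, 20.0),
        interference_hz=25.0,
        interference_amp=(0.3, 0.3, 0.3, 50.0, 50.0, 50.0),
    )


@dataclasses.dataclass(frozen=True)
class SessionScript:
    """Ordered (movement, duration-in-seconds) events with cross-fades."""

    events: tuple[tuple[MovementClass, float], ...]
    transition_s: float = 1.0

    def __post_init__(self) -> None:
        if len(self.events) == 0:
            raise ValueError("session script must contain at least one event")
        for movement, duration in self.events:
            if duration <= 0:
                raise ValueError(f"non-positive event duration {duration}")
        if self.transition_s < 0:
            raise ValueError("transition_s must be non-negative")

    @property
    def total_duration_s(self) -> float:
        n_trans = max(len(self.events) - 1, 0)
        return sum(d for _, d in self.events) + n_trans * self.transition_s


@dataclasses.dataclass
class ImuStream:
    """Uniformly sampled six-channel IMU series.

    ``samples`` is an (n, 6) array ordered (ax, ay, az, gx, gy, gz) with
    accelerometer channels in g and gyroscope channels in °/s.  ``labels``
    is an optional length-n array of class codes or ``"transition"``.
    """

    rate_hz: float
    samples: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 6:
            raise ValueError("samples must be an (n, 6) array")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.samples):
                raise ValueError("labels must have one entry per sample")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate_hz


def default_signatures() -> dict[MovementClass, MovementSignature]:
    """One deterministic signature per motion set.

    The seven profiles are pairwise distinguishable by gravity orientation
    (arm posture), fundamental tempo and amplitude pattern.  The advancing
    pair (WOF, LF) is sagittally dominant, the retreating pair (RBB, PB)
    mixes sagittal and frontal rotation, the lateral pair (PPS, ELS) is
    frontally dominant, and the static knee raise (SKR) has a strictly
    smaller gyroscope amplitude than every locomotive set.
    """
    M = MovementClass

    def _sig(mv, grav, f, aamp, gamp, phase):
        g = np.asarray(grav, dtype=float)
        g = tuple(g / np.linalg.norm(g))
        return MovementSignature(mv, g, f, tuple(aamp), tuple(gamp), tuple(phase))

    return {
        M.WOF: _sig(M.WOF, (0.00, 0.00, 1.00), 0.50,
                    (0.30, 0.10, 0.15), (60.0, 25.0, 15.0), (0.0, 1.0, 2.0)),
        M.LF: _sig(M.LF, (0.15, 0.00, 0.99), 0.65,
                   (0.35, 0.08, 0.20), (75.0, 20.0, 25.0), (0.5, 1.5, 2.5)),
        M.RBB: _sig(M.RBB, (0.00, 0.15, 0.99), 0.45,
                    (0.25, 0.20, 0.10), (40.0, 55.0, 15.0), (1.0, 2.0, 3.0)),
        M.PB: _sig(M.PB, (-0.15, 0.00, 0.99), 0.80,
                   (0.28, 0.22, 0.12), (45.0, 65.0, 20.0), (1.5, 2.5, 0.5)),
        M.PPS: _sig(M.PPS, (0.12, 0.12, 0.99), 0.55,
                    (0.15, 0.35, 0.12), (25.0, 80.0, 30.0), (2.0, 3.0, 1.0)),
        M.ELS: _sig(M.ELS, (-0.12, 0.12, 0.99), 0.70,
                    (0.12, 0.30, 0.18), (20.0, 70.0, 45.0), (2.5, 0.5, 1.5)),
        M.SKR: _sig(M.SKR, (0.00, 0.00, 1.00), 0.35,
                    (0.05, 0.05, 0.08), (4.0, 4.0, 6.0), (3.0, 1.0, 2.0)),
    }


def _clean_signal(sig: MovementSignature, t: np.ndarray) -> np.ndarray:
    """Noise-free (len(t), 6) signal of a signature over global time t."""
    out = np.empty((len(t), 6))
    w = 2.0 * np.pi * sig.fundamental_hz * t
    grav = np.asarray(sig.gravity_axis)
    aamp = np.asarray(sig.accel_amp)
    gamp = np.asarray(sig.gyro_amp)
    ph = np.asarray(sig.phase)
    for axis in range(3):
        osc = (np.sin(w + ph[axis])
               + 0.5 * np.sin(2.0 * w + 2.0 * ph[axis] + 0.7))
        out[:, axis] = grav[axis] + aamp[axis] * osc
        # gyro leads accel by a quarter cycle (velocity vs displacement-like)
        oscg = (np.cos(w + ph[axis])
                + 0.5 * np.cos(2.0 * w + 2.0 * ph[axis] + 0.7))
        out[:, 3 + axis] = gamp[axis] * oscg
    return out


def _add_noise_and_clip(clean: np.ndarray, t: np.ndarray, noise: NoiseSpec,
                        rng: np.random.Generator) -> np.ndarray:
    samples = clean.copy()
    amp = noise._vec6(noise.interference_amp)
    if np.any(amp > 0):
        iphase = rng.uniform(0.0, 2.0 * np.pi, size=6)
        carrier = np.sin(2.0 * np.pi * noise.interference_hz * t[:, None]
                         + iphase[None, :])
        samples += amp[None, :] * carrier
    sd = noise._vec6(noise.white_sd)
    if np.any(sd > 0):
        samples += rng.standard_normal(samples.shape) * sd[None, :]
    samples[:, :3] = np.clip(samples[:, :3], -ACCEL_RANGE_G, ACCEL_RANGE_G)
    samples[:, 3:] = np.clip(samples[:, 3:], -GYRO_RANGE_DPS, GYRO_RANGE_DPS)
    return samples


def synth_movement(sig: MovementSignature, duration_s: float,
                   rate_hz: float = DEFAULT_RAW_RATE_HZ,
                   noise: NoiseSpec = ZERO_NOISE,
                   seed: int = 0) -> ImuStream:
    """Generate a single-movement stream of ``round(duration_s * rate_hz)``
    samples, labelled with the signature's class.  Identical seeds give
    bit-identical output."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if rate_hz < 100:
        raise ValueError("raw rate_hz must be at least 100 Hz")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    rng = np.random.default_rng(seed)
    samples = _add_noise_and_clip(_clean_signal(sig, t), t, noise, rng)
    labels = np.full(n, sig.movement.value, dtype=object)
    return ImuStream(rate_hz=rate_hz, samples=samples, labels=labels)


def synth_session(script: SessionScript,
                  rate_hz: float = DEFAULT_RAW_RATE_HZ,
                  noise: NoiseSpec = ZERO_NOISE,
                  seed: int = 0,
                  signatures: dict[MovementClass, MovementSignature] | None = None,
                  ) -> ImuStream:
    """Generate a labelled scripted session.

    Events are rendered over a continuous global time base; consecutive
    events are joined by linear cross-fades of ``script.transition_s``
    seconds whose samples are labelled ``"transition"``.  The labelled
    per-class sample count equals the scripted duration exactly (at the
    sample rounding of each event).
    """
    if rate_hz < 100:
        raise ValueError("raw rate_hz must be at least 100 Hz")
    sigs = signatures if signatures is not None else default_signatures()
    n_event = [int(round(d * rate_hz)) for _, d in script.events]
    n_trans = int(round(script.transition_s * rate_hz))

    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    t0 = 0  # global sample index, keeps each signature phase-continuous
    for k, (movement, _) in enumerate(script.events):
        sig = sigs[movement]
        if k > 0 and n_trans > 0:
            # cross-fade from previous signature into this one
            t = (t0 + np.arange(n_trans)) / rate_hz
            prev_sig = sigs[script.events[k - 1][0]]
            w = np.linspace(0.0, 1.0, n_trans, endpoint=False)[:, None]
            blend = (1.0 - w) * _clean_signal(prev_sig, t) + w * _clean_signal(sig, t)
            chunks.append(blend)
            labels.append(np.full(n_trans, TRANSITION_LABEL, dtype=object))
            t0 += n_trans
        t = (t0 + np.arange(n_event[k])) / rate_hz
        chunks.append(_clean_signal(sig, t))
        labels.append(np.full(n_event[k], movement.value, dtype=object))
        t0 += n_event[k]

    clean = np.concatenate(chunks, axis=0)
    t_all = np.arange(len(clean)) / rate_hz
    rng = np.random.default_rng(seed)
    samples = _add_noise_and_clip(clean, t_all, noise, rng)
    return ImuStream(rate_hz=rate_hz, samples=samples,
                     labels=np.concatenate(labels))


def full_set_script(reps: int = 7, movement_s: float = 4.0,
                    transition_s: float = 1.0) -> SessionScript:
    """The designed full Bafa Wubu set: ``reps`` rounds through all seven
    motion sets (default 7 x 7 = 49 events, ~4 min with 4 s events and 1 s
    cross-fades), matching the intervention protocol's designed distribution
    of seven repetitions per movement."""
    events = tuple((mv, movement_s) for _ in range(reps) for mv in CLASS_ORDER)
    return SessionScript(events=events, transition_s=transition_s)


# ---------------------------------------------------------------------------
# CSV interchange


def write_csv(stream: ImuStream, path: str | pathlib.Path | io.TextIOBase) -> None:
    """Write a stream as ``t,ax,ay,az,gx,gy,gz[,label]`` with values printed
    at 9 significant digits (round-trips bit-exactly through read_csv)."""
    frame = pd.DataFrame(stream.samples, columns=CSV_COLUMNS[1:])
    frame.insert(0, "t", stream.times)
    if stream.labels is not None:
        frame["label"] = stream.labels
    frame.to_csv(path, index=False, float_format="%.9g")


def read_csv(path: str | pathlib.Path | io.TextIOBase) -> ImuStream:
    """Read a stream written by :func:`write_csv`; the rate is inferred from
    the time column."""
    frame = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"CSV is missing required columns: {missing}")
    t = frame["t"].to_numpy()
    if len(t) < 2:
        raise ValueError("stream CSV must contain at least two samples")
    rate_hz = 1.0 / np.median(np.diff(t))
    # snap to an integer rate when the time column is a printed arange
    if abs(rate_hz - round(rate_hz)) < 1e-6 * rate_hz:
        rate_hz = float(round(rate_hz))
    labels = frame["label"].to_numpy(dtype=object) if "label" in frame.columns else None
    samples = frame[list(CSV_COLUMNS[1:])].to_numpy(dtype=float)
    return ImuStream(rate_hz=float(rate_hz), samples=samples, labels=labels)
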