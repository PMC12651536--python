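"""Synthetic taste-EEG generator.

Emulates a gustatory-stimulation protocol: a cohort of subjects, six stimulus
classes (sucrose concentration levels 0-5, class 0 being a pure-water
control), several repeated recordings per condition, each recording cut into
1-s epochs of 21 electrodes x 256 samples (10-20 montage, 256 Hz).

Each recording is 1/f background noise per electrode plus, for classes >= 1,
a narrow-band evoked oscillation whose amplitude, spatial spread around a set
of central/temporal focus electrodes, and onset speed all grow with the
concentration class.  Recordings are band-pass filtered 0.5-45 Hz before
segmentation.  Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import h5py
import numpy as np
from scipy import signal as sps

__all__ = [
    "MONTAGE_2D",
    "SyntheticSpec",
    "Recording",
    "EEGSample",
    "EEGDataset",
    "desk_spec",
    "generate_recording",
    "bandpass",
    "segment",
    "generate_dataset",
]

# Approximate 2-D scalp coordinates (unit head radius, x = right, y = front)
# for the 21 electrodes of the 10-20 montage used here.  A1/A2 are the
# earlobe references, placed just outside the ring.
MONTAGE_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.41, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.41, 0.52), "F8": (0.81, 0.59),
    "A1": (-1.15, -0.10), "T3": (-1.0, 0.0), "C3": (-0.5, 0.0),
    "Cz": (0.0, 0.0), "C4": (0.5, 0.0), "T4": (1.0, 0.0), "A2": (1.15, -0.10),
    "T5": (-0.81, -0.59), "P3": (-0.41, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.41, -0.52), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

DEFAULT_MONTAGE = tuple(MONTAGE_2D)


@dataclass
class SyntheticSpec:
    """Parameters of the class-dependent evoked-signal and noise model.

    ``gain_per_class`` sets the evoked oscillation amplitude (a.u.) per
    class; class 0 is the water control and must have gain 0.
    ``spread_radius`` is the Gaussian decay scale (in head-radius units) of
    the evoked amplitude with distance from the nearest focus electrode, and
    ``onset_latency_s`` the evoked onset time — stronger stimuli activate
    wider areas faster.
    """

    n_subjects: int = 20
    n_classes: int = 6
    n_repetitions: int = 6
    epochs_per_recording: int = 15
    fs: float = 256.0
    epoch_s: float = 1.0
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    gain_per_class: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5)
    spread_radius: tuple[float, ...] = (0.2, 0.3, 0.45, 0.6, 0.8, 1.0)
    onset_latency_s: tuple[float, ...] = (0.20, 0.20, 0.16, 0.12, 0.08, 0.05)
    seed_electrodes: tuple[str, ...] = ("C3", "C4", "Cz", "T3", "T4")
    # background amplitude calibrated so the weakest stimulus (class 1) is
    # reliably decodable from 1-s epochs at the reference desk configuration
    noise_sd: float = 0.5
    pink_exponent: float = 1.0
    osc_freq_hz: float = 8.0
    subject_gain_sd: float = 0.2
    ramp_s: float = 0.1
    band: tuple[float, float] = (0.5, 45.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_classes > len(self.gain_per_class):
            raise ValueError("n_classes must fit gain_per_class")
        if self.gain_per_class[0] != 0.0:
            raise ValueError("class 0 is the pure-water control: gain_per_class[0] must be 0")
        gains = self.gain_per_class[1 : self.n_classes]
        if any(b <= a for a, b in zip(gains, gains[1:])):
            raise ValueError("gain_per_class must be strictly increasing for classes >= 1")
        lat = self.onset_latency_s[: self.n_classes]
        if any(b > a for a, b in zip(lat, lat[1:])):
            raise ValueError("onset_latency_s must be non-increasing")
        if abs(self.fs * self.epoch_s - round(self.fs * self.epoch_s)) > 1e-9:
            raise ValueError("fs * epoch_s must be an integer number of samples")
        unknown = set(self.seed_electrodes) - set(self.montage)
        if unknown:
            raise ValueError(f"unknown seed electrodes: {sorted(unknown)}")

    @property
    def n_electrodes(self) -> int:
        return len(self.montage)

    @property
    def duration_s(self) -> float:
        return self.epochs_per_recording * self.epoch_s

    @property
    def epoch_samples(self) -> int:
        return int(round(self.fs * self.epoch_s))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        for key in (
            "montage",
            "gain_per_class",
            "spread_radius",
            "onset_latency_s",
            "seed_electrodes",
            "band",
        ):
            d[key] = tuple(d[key])
        return cls(**d)


def desk_spec(rng_seed: int = 0) -> SyntheticSpec:
    """Reduced-size protocol for single-CPU runs: 10 x 6 x 2 x 10 = 1,200 samples."""
    return SyntheticSpec(
        n_subjects=10, n_repetitions=2, epochs_per_recording=10, rng_seed=rng_seed
    )


@dataclass
class Recording:
    signal: np.ndarray  # (n_electrodes, n_times)
    subject: int
    label: int
    repetition: int


@dataclass
class EEGSample:
    matrix: np.ndarray  # (n_electrodes, epoch_samples)
    label: int
    subject: int
    repetition: int
    epoch_index: int


def _pink_noise(rng: np.random.Generator, n_ch: int, n_t: int, sd: float, exponent: float) -> np.ndarray:
    """1/f^exponent noise per channel, scaled to standard deviation ``sd``."""
    freqs = np.fft.rfftfreq(n_t, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_ch, freqs.size)) + 1j * rng.standard_normal((n_ch, freqs.size))
    ) * amp
    x = np.fft.irfft(spec, n=n_t, axis=1)
    x_sd = x.std(axis=1, keepdims=True)
    x_sd[x_sd == 0] = 1.0
    return x / x_sd * sd


def _electrode_weights(spec: SyntheticSpec, klass: int) -> np.ndarray:
    """Gaussian decay of the evoked amplitude with distance to the nearest focus."""
    coords = np.array([MONTAGE_2D[e] for e in spec.montage])
    seeds = np.array([MONTAGE_2D[e] for e in spec.seed_electrodes])
    d = np.linalg.norm(coords[:, None, :] - seeds[None, :, :], axis=2).min(axis=1)
    r = spec.spread_radius[klass]
    return np.exp(-(d**2) / (2.0 * r**2))


def _subject_gain(spec: SyntheticSpec, subject: int) -> float:
    rng = np.random.default_rng([spec.rng_seed, 104729, subject])
    return float(np.exp(spec.subject_gain_sd * rng.standard_normal()))


def _recording_rng(spec: SyntheticSpec, subject: int, klass: int, rep: int) -> np.random.Generator:
    return np.random.default_rng([spec.rng_seed, subject, klass, rep])


def generate_recording(
    spec: SyntheticSpec,
    subject: int,
    klass: int,
    rep: int,
    rng: np.random.Generator | None = None,
) -> Recording:
    """One continuous multichannel recording for a (subject, class, repetition).

    The evoked component is ``g_subject * gain[class] * w_e * env(t) *
    sin(2*pi*f*t + phi)`` on top of per-electrode pink noise; ``env`` ramps
    up linearly over ``ramp_s`` starting at the class onset latency and holds
    until the end of the recording.  Class 0 has no evoked component.
    """
    if not 0 <= klass < spec.n_classes:
        raise ValueError(f"unknown class {klass} (spec has {spec.n_classes} classes)")
    rng = rng if rng is not None else _recording_rng(spec, subject, klass, rep)
    n_t = int(round(spec.fs * spec.duration_s))
    sig = _pink_noise(rng, spec.n_electrodes, n_t, spec.noise_sd, spec.pink_exponent)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    gain = spec.gain_per_class[klass]
    if gain > 0.0:
        t = np.arange(n_t) / spec.fs
        onset = spec.onset_latency_s[klass]
        env = np.clip((t - onset) / max(spec.ramp_s, 1e-9), 0.0, 1.0)
        osc = np.sin(2.0 * np.pi * spec.osc_freq_hz * t + phi)
        w = _electrode_weights(spec, klass)
        sig = sig + _subject_gain(spec, subject) * gain * w[:, None] * (env * osc)[None, :]
    return Recording(signal=sig, subject=subject, label=klass, repetition=rep)


def bandpass(x: np.ndarray, low: float = 0.5, high: float = 45.0, fs: float = 256.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis."""
    if not 0.0 < low < high < fs / 2.0:
        raise ValueError(f"invalid band ({low}, {high}) for fs={fs}")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x), axis=-1)


def segment(rec: Recording, epoch_s: float = 1.0, fs: float = 256.0) -> list[EEGSample]:
    """Cut a recording into consecutive non-overlapping epochs (floor rule)."""
    n_per = int(round(fs * epoch_s))
    n_t = rec.signal.shape[-1]
    if n_per > n_t:
        raise ValueError(f"epoch of {n_per} samples exceeds recording length {n_t}")
    n_epochs = n_t // n_per
    return [
        EEGSample(
            matrix=rec.signal[:, i * n_per : (i + 1) * n_per],
            label=rec.label,
            subject=rec.subject,
            repetition=rec.repetition,
            epoch_index=i,
        )
        for i in range(n_epochs)
    ]


@dataclass
class EEGDataset:
    """Labelled epoch collection: ``samples`` is ``(N, electrodes, times)``."""

    samples: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    repetitions: np.ndarray
    epoch_indices: np.ndarray
    montage: tuple[str, ...]
    spec_json: str = ""

    def __len__(self) -> int:
        return int(self.samples.shape[0])

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self) else 0

    def select(self, idx) -> "EEGDataset":
        return EEGDataset(
            samples=self.samples[idx],
            labels=self.labels[idx],
            subjects=self.subjects[idx],
            repetitions=self.repetitions[idx],
            epoch_indices=self.epoch_indices[idx],
            montage=self.montage,
            spec_json=self.spec_json,
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=self.samples.astype(np.float32))
            f.create_dataset("labels", data=self.labels.astype(np.int64))
            f.create_dataset("subjects", data=self.subjects.astype(np.int64))
            f.create_dataset("repetitions", data=self.repetitions.astype(np.int64))
            f.create_dataset("epochs", data=self.epoch_indices.astype(np.int64))
            f.create_dataset(
                "montage", data=np.array(self.montage, dtype=h5py.string_dtype())
            )
            f.create_dataset("spec_json", data=self.spec_json)

    @classmethod
    def from_hdf5(cls, path) -> "EEGDataset":
        with h5py.File(path, "r") as f:
            missing = {"samples", "labels"} - set(f.keys())
            if missing:
                raise ValueError(f"corrupt dataset container {path}: missing keys {sorted(missing)}")
            return cls(
                samples=f["samples"][...],
                labels=f["labels"][...],
                subjects=f["subjects"][...],
                repetitions=f["repetitions"][...],
                epoch_indices=f["epochs"][...],
                montage=tuple(s.decode() if isinstance(s, bytes) else s for s in f["montage"][...]),
                spec_json=(
                    f["spec_json"][()].decode()
                    if isinstance(f["spec_json"][()], bytes)
                    else str(f["spec_json"][()])
                ),
            )


def generate_dataset(spec: SyntheticSpec) -> EEGDataset:
    """Full protocol: generate -> band-pass -> segment for every condition.

    Yields exactly ``n_subjects * n_classes * n_repetitions *
    epochs_per_recording`` epochs with exact class balance.
    """
    mats, labels, subjects, reps, epochs = [], [], [], [], []
    low, high = spec.band
    for subject in range(spec.n_subjects):
        for klass in range(spec.n_classes):
            for rep in range(spec.n_repetitions):
                rec = generate_recording(spec, subject, klass, rep)
                rec = Recording(
                    signal=bandpass(rec.signal, low, high, spec.fs),
                    subject=rec.subject,
                    label=rec.label,
                    repetition=rec.repetition,
                )
                for s in segment(rec, spec.epoch_s, spec.fs):
                    mats.append(s.matrix.astype(np.float32))
                    labels.append(s.label)
                    subjects.append(s.subject)
                    reps.append(s.repetition)
                    epochs.append(s.epoch_index)
    return EEGDataset(
        samples=np.stack(mats),
        labels=np.asarray(labels, dtype=np.int64),
        subjects=np.asarray(subjects, dtype=np.int64),
        repetitions=np.asarray(reps, dtype=np.int64),
        epoch_indices=np.asarray(epochs, dtype=np.int64),
        montage=spec.montage,
        spec_json=spec.to_json(),
    )


def load_edf(path, montage: tuple[str, ...] = DEFAULT_MONTAGE):
    """Best-effort EDF ingestion mapping the named channels onto the montage.

    Returns the raw ``(n_electrodes, n_times)`` array and the sampling rate.
    Requires ``mne``; real recordings are outside the tested surface.
    """
    import mne  # local import: optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks = [raw.ch_names.index(ch) for ch in montage if ch in raw.ch_names]
    missing = [ch for ch in montage if ch not in raw.ch_names]
    if missing:
        raise ValueError(f"EDF file lacks montage channels: {missing}")
    data = raw.get_data(picks=picks)
    return data, float(raw.info["sfreq"])
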