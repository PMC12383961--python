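"""Synthetic two-group ERP cohort generator.

Emulates a word-repetition EEG session: each trial is 1/f-weighted
background noise plus two event-related components — a negative component
peaking ~400 ms after word onset (semantic, N400-like) and a positive
component peaking ~600 ms (verbal-memory, P600/LPC-like).  Components are
Gabor-like atoms (Gaussian-windowed cosines) with fixed latency and width,
per-trial latency jitter, condition-dependent gains, and a fixed scalp
topography with midline (Fz/Pz/Cz) maxima.  Group structure enters in one
place only: the late positive component of the "preAD" group is scaled by
``1 - effect_size``, mimicking the reduced word-repetition effect reported
for preclinical Alzheimer's disease.  ``effect_size = 0`` therefore makes
the two groups statistically identical by construction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import CHANNELS, CONDITIONS, MIDLINE_CHANNELS

GROUPS = ("preAD", "NO")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``effect_size`` scales the group difference in the late-component
    amplitude (0 = identical groups, 1 = component absent in preAD).
    ``noise_sd`` is the per-trial background-noise standard deviation in uV.
    """

    n_per_group: int = 20
    channels: tuple[str, ...] = CHANNELS
    conditions: tuple[str, ...] = CONDITIONS
    n_trials: int = 72
    fs: float = 250.0
    epoch_span: tuple[float, float] = (-2.0, 2.0)
    effect_size: float = 0.5
    noise_sd: float = 10.0
    amp_n400: float = -4.0           # uV, negative component peak
    amp_p600: float = 5.0            # uV, late positive component peak
    latency_jitter_sd: float = 0.020  # s, per-trial latency jitter
    subject_amp_sd: float = 0.15      # relative between-subject amplitude sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_span[1] - self.epoch_span[0]) * self.fs))

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to word onset."""
        return self.epoch_span[0] + np.arange(self.n_samples) / self.fs


@dataclass
class EpochSet:
    """All epochs of one subject.

    ``data`` has shape (n_channels, n_conditions, n_trials, n_samples);
    ``times`` is the shared onset-relative time axis in seconds.
    """

    subject_id: str
    group_label: str
    channels: tuple[str, ...]
    conditions: tuple[str, ...]
    data: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.group_label not in GROUPS:
            raise ValueError(f"group_label must be one of {GROUPS}")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("data/channel shape mismatch")
        if self.data.shape[1] != len(self.conditions):
            raise ValueError("data/condition shape mismatch")
        if self.data.shape[3] != self.times.size:
            raise ValueError("data/time-axis shape mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def get(self, channel: str, condition: str) -> np.ndarray:
        """Trials-by-samples matrix for one (channel, condition) cell."""
        return self.data[self.channels.index(channel),
                         self.conditions.index(condition)]


# --- ERP component model ---------------------------------------------------

@dataclass(frozen=True)
class Component:
    """Gabor-like ERP atom: Gaussian envelope times a cosine carrier."""

    latency: float    # s post-onset, envelope centre (cosine phase 0 there)
    width: float      # s, Gaussian sigma
    freq: float       # Hz, carrier frequency

    def waveform(self, t: np.ndarray, latency_shift: float = 0.0) -> np.ndarray:
        tc = t - self.latency - latency_shift
        return np.exp(-0.5 * (tc / self.width) ** 2) * np.cos(
            2.0 * np.pi * self.freq * tc)


N400 = Component(latency=0.400, width=0.120, freq=1.2)
P600 = Component(latency=0.600, width=0.150, freq=0.8)

# Condition gains.  Incongruous new words drive the largest N400; repeated
# (old) words drive the largest late positivity; the pooled "All" conditions
# sit between their congruous/incongruous members.
N400_GAIN = {"NA": 1.00, "NC": 0.70, "NI": 1.30,
             "OA": 0.60, "OC": 0.45, "OI": 0.80}
P600_GAIN = {"NA": 1.00, "NC": 1.10, "NI": 0.90,
             "OA": 1.50, "OC": 1.70, "OI": 1.30}

# Fixed scalp topography with midline maxima; the late component peaks at
# the centro-parietal midline (Pz).
_N400_TOPO = {"Fz": 0.80, "Pz": 0.90, "Cz": 1.00}
_P600_TOPO = {"Fz": 0.70, "Pz": 1.00, "Cz": 0.90}
_OFF_MIDLINE = {
    "F7": 0.40, "F8": 0.40, "Bl": 0.45, "Br": 0.45, "L41": 0.50,
    "R41": 0.50, "Wl": 0.55, "Wr": 0.55, "T5": 0.40, "T6": 0.40,
    "O1": 0.30, "O2": 0.30,
}
N400_TOPO = {**_OFF_MIDLINE, **_N400_TOPO}
P600_TOPO = {**_OFF_MIDLINE, **_P600_TOPO}
assert set(N400_TOPO) == set(CHANNELS)
assert max(N400_TOPO, key=N400_TOPO.get) in MIDLINE_CHANNELS
assert max(P600_TOPO, key=P600_TOPO.get) in MIDLINE_CHANNELS


def one_over_f_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with ~1/f power (1/sqrt(f) amplitude) shaping.

    Realised by spectrally re-weighting white Gaussian noise; the spectrum
    is flattened below 1 Hz so the epoch does not drift unboundedly.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, 1.0))
    shaped = np.fft.irfft(spec * shaping, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _component_sum(spec: CohortSpec, group: str, condition: str,
                   channel: str, latency_shift: float,
                   amplitude_scale: float = 1.0) -> np.ndarray:
    t = spec.times
    late_scale = (1.0 - spec.effect_size) if group == "preAD" else 1.0
    out = (spec.amp_n400 * N400_GAIN[condition] * N400_TOPO[channel]
           * N400.waveform(t, latency_shift))
    out += (spec.amp_p600 * P600_GAIN[condition] * P600_TOPO[channel]
            * late_scale * P600.waveform(t, latency_shift))
    return amplitude_scale * out


def generate_trial(spec: CohortSpec, group: str, condition: str,
                   channel: str, rng: np.random.Generator,
                   amplitude_scale: float = 1.0) -> np.ndarray:
    """One epoch (uV) for the given group/condition/channel.

    Consumes exactly one latency-jitter draw and one noise epoch from
    ``rng``, so identical generator states give bit-identical trials.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if condition not in spec.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if channel not in spec.channels:
        raise ValueError(f"unknown channel {channel!r}")
    jitter = rng.normal(0.0, spec.latency_jitter_sd)
    noise = one_over_f_noise(spec.n_samples, spec.fs, rng)
    signal = _component_sum(spec, group, condition, channel, jitter,
                            amplitude_scale)
    return signal + spec.noise_sd * noise


def _one_over_f_noise_batch(shape: tuple[int, ...], n: int, fs: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Batched 1/f-shaped noise; each row normalised to unit variance."""
    white = rng.standard_normal(shape + (n,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaped = np.fft.irfft(spec / np.sqrt(np.maximum(f, 1.0)), n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def generate_epochset(spec: CohortSpec, subject_id: str, group: str,
                      rng: np.random.Generator) -> EpochSet:
    """All epochs of one subject, with a subject-level amplitude factor.

    The latency jitter of an event is shared across channels (one event,
    one latency); noise is drawn independently per channel and trial.
    """
    amp = rng.normal(1.0, spec.subject_amp_sd)
    amp = max(amp, 0.1)  # keep component polarity
    t = spec.times
    late_scale = (1.0 - spec.effect_size) if group == "preAD" else 1.0
    n400_topo = np.array([N400_TOPO[ch] for ch in spec.channels])
    p600_topo = np.array([P600_TOPO[ch] for ch in spec.channels])
    data = np.empty((len(spec.channels), len(spec.conditions),
                     spec.n_trials, spec.n_samples))
    for ci, cond in enumerate(spec.conditions):
        jitters = rng.normal(0.0, spec.latency_jitter_sd, spec.n_trials)
        n400_wave = np.stack([N400.waveform(t, j) for j in jitters])
        p600_wave = np.stack([P600.waveform(t, j) for j in jitters])
        # (channel, trial, sample) = topo x (trial, sample)
        signal = (spec.amp_n400 * N400_GAIN[cond]
                  * n400_topo[:, None, None] * n400_wave[None]
                  + spec.amp_p600 * P600_GAIN[cond] * late_scale
                  * p600_topo[:, None, None] * p600_wave[None])
        noise = _one_over_f_noise_batch(
            (len(spec.channels), spec.n_trials), spec.n_samples, spec.fs, rng)
        data[:, ci] = amp * signal + spec.noise_sd * noise
    return EpochSet(subject_id=subject_id, group_label=group,
                    channels=spec.channels, conditions=spec.conditions,
                    data=data, times=spec.times)


def generate_cohort(spec: CohortSpec) -> tuple[list[EpochSet], list[str]]:
    """Balanced two-group cohort of ``2 * n_per_group`` subjects.

    Subjects are exchangeable draws: each gets its own amplitude factor and
    noise stream, derived from ``spec.seed`` through independent child
    seeds, so the cohort is reproducible and order-independent.
    """
    children = np.random.SeedSequence(spec.seed).spawn(2 * spec.n_per_group)
    subjects: list[EpochSet] = []
    labels: list[str] = []
    i = 0
    for group in GROUPS:
        for k in range(spec.n_per_group):
            rng = np.random.default_rng(children[i])
            sid = f"{group}-{k:03d}"
            subjects.append(generate_epochset(spec, sid, group, rng))
            labels.append(group)
            i += 1
    return subjects, labels


# --- plain-text epoch container --------------------------------------------

def save_epochset(epochs: EpochSet, path: str | Path) -> None:
    """Write one subject to a plain-text container.

    Layout: a ``#``-prefixed metadata header, then one ``# matrix`` block
    per (channel, condition) holding the trials-by-samples values.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# subject_id: {epochs.subject_id}\n")
        fh.write(f"# group: {epochs.group_label}\n")
        fh.write(f"# channels: {','.join(epochs.channels)}\n")
        fh.write(f"# conditions: {','.join(epochs.conditions)}\n")
        fh.write(f"# n_trials: {epochs.n_trials}\n")
        fh.write(f"# n_samples: {epochs.times.size}\n")
        fh.write(f"# t_start: {float(epochs.times[0]):.9g}\n")
        fh.write(f"# fs: {1.0 / (epochs.times[1] - epochs.times[0]):.9g}\n")
        for ch in epochs.channels:
            for cond in epochs.conditions:
                fh.write(f"# matrix: {ch} {cond}\n")
                np.savetxt(fh, epochs.get(ch, cond), fmt="%.6e")


def load_epochset(path: str | Path) -> EpochSet:
    """Read a container written by :func:`save_epochset`."""
    meta: dict[str, str] = {}
    blocks: dict[tuple[str, str], np.ndarray] = {}
    current: list[str] | None = None
    key: tuple[str, str] | None = None

    def _flush() -> None:
        if key is not None and current:
            blocks[key] = np.loadtxt(io.StringIO("".join(current)), ndmin=2)

    with Path(path).open() as fh:
        for line in fh:
            if line.startswith("# matrix:"):
                _flush()
                ch, cond = line.split(":", 1)[1].split()
                key, current = (ch, cond), []
            elif line.startswith("#"):
                name, value = line[1:].split(":", 1)
                meta[name.strip()] = value.strip()
            elif current is not None:
                current.append(line)
        _flush()

    channels = tuple(meta["channels"].split(","))
    conditions = tuple(meta["conditions"].split(","))
    n_samples = int(meta["n_samples"])
    fs = float(meta["fs"])
    times = float(meta["t_start"]) + np.arange(n_samples) / fs
    data = np.stack([
        np.stack([blocks[(ch, cond)] for cond in conditions])
        for ch in channels
    ])
    return EpochSet(subject_id=meta["subject_id"], group_label=meta["group"],
                    channels=channels, conditions=conditions,
                    data=data, times=times)


def save_cohort(subjects: list[EpochSet], directory: str | Path) -> Path:
    """Write every subject plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.tsv"
    with manifest.open("w") as fh:
        fh.write("subject_id\tgroup\tpath\n")
        for ep in subjects:
            fname = f"{ep.subject_id}.epochs.txt"
            save_epochset(ep, directory / fname)
            fh.write(f"{ep.subject_id}\t{ep.group_label}\t{fname}\n")
    return manifest


def load_cohort(manifest: str | Path) -> tuple[list[EpochSet], list[str]]:
    """Read a cohort back from a manifest written by :func:`save_cohort`."""
    manifest = Path(manifest)
    subjects, labels = [], []
    with manifest.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            subjects.append(load_epochset(manifest.parent / row["path"]))
            labels.append(row["group"])
    return subjects, labels
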