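"""Core data model: channel traces, multimodal recordings, pipeline configuration.

Conventions used throughout the package: sample indices are 0-based and the
time of sample ``i`` is ``i / fs`` seconds.  Amplitudes are in arbitrary units
(au) unless a sensor defines a physical unit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

SCENARIOS = ("city", "highway", "countryside")

#: Channel names of the in-cabin sensor set.  ``reference`` is the chest-belt
#: ground-truth channel and is never fed to a classifier.
KNOWN_CHANNELS = (
    "reference",
    "piezo",
    "acc1_x", "acc1_y", "acc1_z",
    "acc2_x", "acc2_y", "acc2_z",
    "video_belt", "video_chest",
)

#: Channel order used for model input snippets.  Fixed so that trained models
#: are portable across runs; recorded in snippet metadata.
MODEL_CHANNEL_ORDER = ("piezo", "acc", "video_belt", "video_chest")


class RespFusionError(ValueError):
    """Base class for domain errors raised by this package."""


@dataclass(frozen=True)
class ChannelTrace:
    """A single uniformly sampled sensor channel.

    Parameters
    ----------
    name : str
        Channel identifier (e.g. ``piezo``, ``acc1_x``, ``video_belt``).
    samples : ndarray
        1-D array of finite real values.
    fs : float
        Sampling rate in Hz, strictly positive.
    """

    name: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise RespFusionError(f"channel {self.name!r}: samples must be 1-D")
        if samples.size < 1:
            raise RespFusionError(f"channel {self.name!r}: empty trace")
        if not np.all(np.isfinite(samples)):
            raise RespFusionError(f"channel {self.name!r}: non-finite samples")
        if not (self.fs > 0):
            raise RespFusionError(f"channel {self.name!r}: fs must be > 0, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Duration in seconds (n_samples / fs)."""
        return self.samples.size / self.fs

    def replace(self, **kw) -> "ChannelTrace":
        return dataclasses.replace(self, **kw)


@dataclass
class MultimodalRecording:
    """Synchronized multichannel recording of one subject in one scenario.

    Channels may have different native sampling rates (e.g. 100 Hz hub
    channels and 10 fps video); their durations must agree within one sample
    period of the slowest channel.
    """

    subject_id: str
    scenario: str
    channels: Mapping[str, ChannelTrace]

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise RespFusionError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if not self.channels:
            raise RespFusionError("recording has no channels")
        self.channels = dict(self.channels)
        durations = {n: t.duration_s for n, t in self.channels.items()}
        slowest = min(t.fs for t in self.channels.values())
        tol = 1.0 / slowest
        dmin, dmax = min(durations.values()), max(durations.values())
        if dmax - dmin > tol + 1e-12:
            raise RespFusionError(
                "channel durations disagree beyond one sample period of the "
                f"slowest channel: {durations}"
            )

    @property
    def duration_s(self) -> float:
        return max(t.duration_s for t in self.channels.values())

    def __getitem__(self, name: str) -> ChannelTrace:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels


@dataclass
class PipelineConfig:
    """All tunable parameters of the processing and modelling pipeline.

    Defaults follow the processing described for the in-cabin study where
    stated (201-sample snippets, train/test overlaps 190/200, 200 Hz unified
    rate, 4 conv filters of length 20, dropout 0.5); remaining values are the
    package's documented defaults.
    """

    # band of physiological respiration, Hz (6-42 breaths/min)
    bandpass_low_hz: float = 0.1
    bandpass_high_hz: float = 0.7
    bandpass_order: int = 4
    # spectral suppression: segment length in seconds (None = one transform
    # over the whole recording; fine for short records, but leakage makes the
    # per-bin factor ill-conditioned on long ones)
    suppress_window_s: float | None = 30.0
    median_kernel: int = 5
    target_fs: float = 200.0
    snippet_len: int = 201
    train_overlap: int = 190
    test_overlap: int = 200
    # breathing-event label: peak within +-tolerance samples of window center
    label_tolerance: int = 50
    peak_min_distance_s: float = 1.5
    peak_min_prominence: float = 0.1  # fraction of the trace IQR
    # model hyperparameters
    n_filters: int = 4
    filter_len: int = 20
    dropout: float = 0.5
    pool_size: int = 4
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    threshold: float = 0.5
    class_weighting: bool = True
    seed: int = 0
    # I/O
    delimiter: str | None = None  # None = auto-detect
    channel_map: dict = field(default_factory=dict)  # column name -> channel name

    def __post_init__(self) -> None:
        if not (0 < self.bandpass_low_hz < self.bandpass_high_hz < self.target_fs / 2):
            raise RespFusionError(
                "bandpass must satisfy 0 < low < high < target_fs/2, got "
                f"[{self.bandpass_low_hz}, {self.bandpass_high_hz}] at fs {self.target_fs}"
            )
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise RespFusionError("median_kernel must be an odd integer >= 1")
        for name in ("train_overlap", "test_overlap"):
            ov = getattr(self, name)
            if not (0 <= ov < self.snippet_len):
                raise RespFusionError(
                    f"{name}={ov} must satisfy 0 <= overlap < snippet_len={self.snippet_len}"
                )
        if not (0 <= self.dropout < 1):
            raise RespFusionError("dropout must be in [0, 1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise RespFusionError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
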