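"""Reference peak detection, sliding-window snippet extraction, labeling, LOSO splits.

The chest belt provides ground truth: its movement peaks mark breathing
events.  All channels are windowed into 201-sample snippets on the unified
200 Hz timeline; a snippet is labeled 1 when a reference peak falls within a
tolerance of the window center, 0 otherwise.  Training windows use overlap
190 (step 11), test windows overlap 200 (step 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import scipy.signal

from .preprocess import prepare_model_channels
from .types import (
    MODEL_CHANNEL_ORDER,
    ChannelTrace,
    MultimodalRecording,
    PipelineConfig,
    RespFusionError,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakTrain:
    """Strictly increasing sample indices of breathing peaks on one timeline."""

    indices: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise RespFusionError("peak indices must be 1-D")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise RespFusionError("peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class SnippetSet:
    """Stacked fixed-length multichannel windows with labels and provenance.

    ``data`` has shape (n_windows, n_channels, snippet_len); it may be a
    strided view into the underlying traces (step-1 test windows would
    otherwise multiply memory by the window length).  ``labels`` is None for
    an unlabeled set.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    starts: np.ndarray
    subject_ids: np.ndarray
    scenarios: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        if self.data.ndim != 3:
            raise RespFusionError("snippet data must be 3-D (windows, channels, samples)")
        if self.data.shape[1] != len(self.channel_names):
            raise RespFusionError("channel_names do not match data")
        for arr_name in ("starts", "subject_ids", "scenarios"):
            if len(getattr(self, arr_name)) != n:
                raise RespFusionError(f"{arr_name} length does not match window count")
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=np.int64)
            if labels.shape != (n,):
                raise RespFusionError("labels length does not match window count")
            if labels.size and not np.isin(labels, [0, 1]).all():
                raise RespFusionError("labels must be binary")
            self.labels = labels

    def __len__(self) -> int:
        return int(self.data.shape[0])

    @property
    def snippet_len(self) -> int:
        return int(self.data.shape[2])

    @staticmethod
    def concat(sets: Sequence["SnippetSet"]) -> "SnippetSet":
        if not sets:
            raise RespFusionError("cannot concatenate zero snippet sets")
        names = sets[0].channel_names
        if any(s.channel_names != names for s in sets):
            raise RespFusionError("channel order mismatch between snippet sets")
        has_labels = all(s.labels is not None for s in sets)
        return SnippetSet(
            data=np.concatenate([s.data for s in sets], axis=0),
            channel_names=names,
            starts=np.concatenate([s.starts for s in sets]),
            subject_ids=np.concatenate([s.subject_ids for s in sets]),
            scenarios=np.concatenate([s.scenarios for s in sets]),
            labels=np.concatenate([s.labels for s in sets]) if has_labels else None,
        )


def detect_reference_peaks(
    reference: ChannelTrace, config: PipelineConfig | None = None
) -> PeakTrain:
    """Breathing peaks of the chest-belt trace.

    The trace is first low-pass smoothed (zero phase, 1 Hz cutoff) so that
    measurement noise cannot create spurious local maxima, then peaks are
    local maxima with a minimum inter-peak distance (default 1.5 s, i.e. at
    most 40 breaths/min) and a minimum prominence expressed as a fraction of
    the trace's interquartile range (scale-free).  A constant trace yields an
    empty train with a warning.
    """
    config = config or PipelineConfig()
    raw = reference.samples
    q75, q25 = np.percentile(raw, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        log.warning("detect_reference_peaks: constant reference trace; no peaks")
        return PeakTrain(np.empty(0, dtype=np.int64), reference.fs)
    x = raw
    cutoff = min(1.0, 0.4 * reference.fs)
    if len(x) > 30:
        sos = scipy.signal.butter(4, cutoff, btype="lowpass", fs=reference.fs, output="sos")
        x = scipy.signal.sosfiltfilt(sos, x)
    distance = max(1, int(round(config.peak_min_distance_s * reference.fs)))
    prominence = config.peak_min_prominence * iqr
    idx, _ = scipy.signal.find_peaks(x, distance=distance, prominence=prominence)
    # refine each peak to the raw local maximum: zero-phase smoothing still
    # shifts extrema slightly near the record edges
    half = max(1, int(round(0.25 * reference.fs)))
    refined = []
    for p in idx:
        lo, hi = max(0, p - half), min(len(raw), p + half + 1)
        refined.append(lo + int(np.argmax(raw[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=np.int64))
    return PeakTrain(refined, reference.fs)


def snippet_count(n_samples: int, snippet_len: int, overlap: int) -> int:
    """Number of windows: floor((N - L) / step) + 1 with step = L - overlap."""
    if n_samples < snippet_len:
        raise RespFusionError(
            f"trace of {n_samples} samples shorter than snippet_len {snippet_len}"
        )
    step = snippet_len - overlap
    return (n_samples - snippet_len) // step + 1


def make_snippets(
    traces: dict[str, ChannelTrace],
    snippet_len: int = 201,
    overlap: int = 190,
    *,
    subject_id: str = "unknown",
    scenario: str = "city",
    channel_order: Iterable[str] | None = None,
) -> SnippetSet:
    """Slide a window of ``snippet_len`` samples with the given overlap over
    all channels simultaneously; windows start at 0, step, 2*step, ...

    The returned ``data`` is a strided view into the stacked traces (no copy).
    """
    order = tuple(channel_order) if channel_order is not None else tuple(traces)
    missing = [c for c in order if c not in traces]
    if missing:
        raise RespFusionError(f"missing channels for snippet extraction: {missing}")
    lengths = {len(traces[c]) for c in order}
    if len(lengths) != 1:
        raise RespFusionError(f"channels differ in length: {sorted(lengths)}")
    n = lengths.pop()
    if not (0 <= overlap < snippet_len):
        raise RespFusionError(f"overlap must satisfy 0 <= overlap < snippet_len, got {overlap}")
    count = snippet_count(n, snippet_len, overlap)
    step = snippet_len - overlap

    stacked = np.stack([traces[c].samples for c in order])  # (C, N)
    windows = np.lib.stride_tricks.sliding_window_view(stacked, snippet_len, axis=1)
    data = windows[:, ::step, :][:, :count, :].transpose(1, 0, 2)  # (n, C, L) view
    starts = np.arange(count, dtype=np.int64) * step
    return SnippetSet(
        data=data,
        channel_names=order,
        starts=starts,
        subject_ids=np.full(count, subject_id, dtype=object),
        scenarios=np.full(count, scenario, dtype=object),
    )


def label_snippets(snips: SnippetSet, peaks: PeakTrain, tolerance: int = 50) -> SnippetSet:
    """Label 1 iff some peak lies within [center - tolerance, center + tolerance],
    where center = start + (snippet_len - 1) / 2."""
    centers = snips.starts + (snips.snippet_len - 1) // 2
    idx = peaks.indices
    lo = np.searchsorted(idx, centers - tolerance, side="left")
    hi = np.searchsorted(idx, centers + tolerance, side="right")
    labels = (hi > lo).astype(np.int64)
    return replace(snips, labels=labels)


def snippets_from_recording(
    rec: MultimodalRecording,
    config: PipelineConfig,
    overlap: int,
    *,
    prepared: dict[str, ChannelTrace] | None = None,
) -> SnippetSet:
    """Full path from one raw recording to a labeled snippet set.

    ``prepared`` short-circuits the per-sensor conditioning when the caller
    has already run :func:`respfusion.preprocess.prepare_model_channels`
    (the LOSO grid reuses each recording in many folds).
    """
    chans = prepared if prepared is not None else prepare_model_channels(rec, config)
    peaks = detect_reference_peaks(chans["reference"], config)
    snips = make_snippets(
        chans,
        snippet_len=config.snippet_len,
        overlap=overlap,
        subject_id=rec.subject_id,
        scenario=rec.scenario,
        channel_order=MODEL_CHANNEL_ORDER,
    )
    return label_snippets(snips, peaks, config.label_tolerance)


def split_loso(
    recordings: Sequence[MultimodalRecording],
    held_out_subject: str,
    config: PipelineConfig | None = None,
    *,
    prepared: dict[int, dict[str, ChannelTrace]] | None = None,
) -> tuple[SnippetSet, SnippetSet]:
    """Leave-one-subject-out split: test = all snippets of the held-out
    subject at test overlap (step 1); train = all snippets of every other
    subject at train overlap.  Subject sets are disjoint by construction."""
    config = config or PipelineConfig()
    subjects = {r.subject_id for r in recordings}
    if len(subjects) < 2:
        raise RespFusionError("LOSO needs at least 2 subjects")
    if held_out_subject not in subjects:
        raise RespFusionError(
            f"unknown subject {held_out_subject!r}; available: {sorted(subjects)}"
        )
    train_sets, test_sets = [], []
    for i, rec in enumerate(recordings):
        prep = prepared.get(i) if prepared is not None else None
        if rec.subject_id == held_out_subject:
            test_sets.append(
                snippets_from_recording(rec, config, config.test_overlap, prepared=prep)
            )
        else:
            train_sets.append(
                snippets_from_recording(rec, config, config.train_overlap, prepared=prep)
            )
    return SnippetSet.concat(train_sets), SnippetSet.concat(test_sets)
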