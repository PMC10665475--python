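"""Synthetic multimodal in-cabin recordings with exact ground truth.

The simulator emulates the deposited driving-study data at desk scale:
a quasi-periodic respiration waveform (with slow rate wander and a second
harmonic, so inhale/exhale are asymmetric) is embedded in all sensor
channels; the two accelerometers share one band-limited vehicle-noise
process (plus road transients and low-frequency drift), of which the seat
sensor sees only the noise — exactly the situation reference-channel
spectral suppression assumes.  Channels are produced at native rates
(100 Hz hub sensors, 10 fps video) to exercise the resampling path.

The vehicle-noise model (band-limited Gaussian + Poisson transients +
drift) and all gains are simulator choices, configurable per scenario; the
scenario profiles encode the qualitative ordering of road roughness
(highway smoothest, countryside roughest).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .snippets import PeakTrain
from .types import SCENARIOS, ChannelTrace, MultimodalRecording, RespFusionError
from .video import ROISpec, FrameSequence

HUB_FS = 100.0     # channel-hub sensors (accelerometers, piezo, chest belt)
VIDEO_FPS = 10.0   # camera frame rate
MASTER_FS = 200.0  # unified rate; ground-truth peaks live on this timeline


@dataclass(frozen=True)
class SimScenarioProfile:
    """Noise character of one driving scenario.

    The shared vehicle-noise process has three parts, all scaled by
    ``noise_gain``: broadband road/engine vibration in ``noise_band_hz``
    (well above the respiration band), low-frequency body-sway and
    load-shift noise in ``sway_band_hz`` (inside the respiration band but
    above typical resting breathing fundamentals — the component only the
    reference-channel suppression can remove; content exactly on the
    breathing frequency is unrecoverable by a per-bin canceller), and Poisson road transients.
    ``drift_gain`` adds a very slow baseline wander (< 0.05 Hz).
    """

    name: str
    noise_band_hz: tuple[float, float] = (0.8, 20.0)
    noise_gain: float = 1.0
    sway_band_hz: tuple[float, float] = (0.45, 0.7)
    sway_gain: float = 0.35
    transient_rate_per_min: float = 4.0
    drift_gain: float = 0.5

    def __post_init__(self) -> None:
        if min(self.noise_gain, self.sway_gain,
               self.transient_rate_per_min, self.drift_gain) < 0:
            raise RespFusionError("scenario gains must be non-negative")


#: Default per-scenario noise levels: the highway is the smoothest ride,
#: city traffic adds stop-and-go transients and sway, countryside roads are
#: roughest.
SCENARIO_PROFILES: dict[str, SimScenarioProfile] = {
    "highway": SimScenarioProfile("highway", noise_gain=0.8, sway_gain=0.25,
                                  transient_rate_per_min=2.0, drift_gain=0.4),
    "city": SimScenarioProfile("city", noise_gain=1.0, sway_gain=0.4,
                               transient_rate_per_min=6.0, drift_gain=0.5),
    "countryside": SimScenarioProfile("countryside", noise_gain=1.3, sway_gain=0.45,
                                      transient_rate_per_min=4.0, drift_gain=0.7),
}


@dataclass(frozen=True)
class SimSubject:
    """Breathing characteristics and per-channel couplings of one subject."""

    subject_id: str
    breathing_rate_bpm: float = 15.0
    rate_wander: float = 0.05       # relative slow modulation of the rate
    wander_freq_hz: float = 0.02
    harmonic: float = 0.2           # second-harmonic content of the waveform
    piezo_gain: float = 1.0
    acc_resp_gain: float = 0.7
    video_lag_s: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (4.0 <= self.breathing_rate_bpm <= 45.0):
            raise RespFusionError(
                f"breathing rate {self.breathing_rate_bpm} BPM outside the "
                "physiological band"
            )
        if not (0 <= self.rate_wander < 1):
            raise RespFusionError("rate_wander must be in [0, 1)")


@dataclass(frozen=True)
class SimulatedRecording:
    """A synthetic recording with its exact ground truth."""

    recording: MultimodalRecording
    peaks: PeakTrain                 # on the unified MASTER_FS timeline
    clean_respiration: ChannelTrace  # at MASTER_FS


def simulate_respiration(
    subject: SimSubject, duration_s: float, fs: float = MASTER_FS
) -> tuple[ChannelTrace, PeakTrain]:
    """Quasi-periodic respiration and its exact peak train.

    The waveform is sin(phi) - h*cos(2*phi) with a slowly wandering
    instantaneous rate.  Its derivative is cos(phi)*(1 + 4h*sin(phi)), so
    for h < 1/4 the maxima sit exactly at phi = pi/2 (mod 2*pi) and the peak
    train follows from the phase, not from numerical peak picking.
    """
    if duration_s <= 0 or fs <= 0:
        raise RespFusionError("duration and fs must be positive")
    rng = np.random.default_rng(subject.seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    f0 = subject.breathing_rate_bpm / 60.0
    phase0 = rng.uniform(0, 2 * np.pi)
    inst_f = f0 * (1.0 + subject.rate_wander
                   * np.sin(2 * np.pi * subject.wander_freq_hz * t + phase0))
    phi = 2 * np.pi * np.cumsum(inst_f) / fs + rng.uniform(0, 2 * np.pi)
    h = min(subject.harmonic, 0.24)
    wave = np.sin(phi) - h * np.cos(2 * phi)

    m_first = int(np.ceil((phi[0] - np.pi / 2) / (2 * np.pi)))
    m_last = int(np.floor((phi[-1] - np.pi / 2) / (2 * np.pi)))
    peaks = []
    for m in range(m_first, m_last + 1):
        target = np.pi / 2 + 2 * np.pi * m
        i = int(np.searchsorted(phi, target))
        if i > 0 and (i == n or target - phi[i - 1] <= phi[i] - target):
            i -= 1
        peaks.append(i)
    idx = np.unique(np.asarray(peaks, dtype=np.int64))
    return ChannelTrace("respiration", wave, fs), PeakTrain(idx, fs)


def _band_noise(rng, n, fs, band, order=4):
    white = rng.normal(size=n)
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = scipy.signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    out = scipy.signal.sosfiltfilt(sos, white)
    sd = out.std()
    return out / sd if sd > 0 else out


def _vehicle_noise(rng, n, fs, profile: SimScenarioProfile) -> np.ndarray:
    noise = profile.noise_gain * _band_noise(rng, n, fs, profile.noise_band_hz)
    if profile.sway_gain > 0:
        # steep band edges: the sway skirt must not blanket the breathing
        # fundamentals, or no per-bin method could separate them
        noise = noise + (profile.noise_gain * profile.sway_gain
                         * _band_noise(rng, n, fs, profile.sway_band_hz, order=8))
    # road transients: suspension-resonance bursts (smooth Gaussian envelope,
    # so their energy stays near the carrier frequency) at Poisson times
    n_events = rng.poisson(profile.transient_rate_per_min * n / fs / 60.0)
    t = np.arange(n) / fs
    for _ in range(n_events):
        t0 = rng.uniform(0, n / fs)
        f = rng.uniform(3.0, 8.0)
        tau = rng.uniform(0.25, 0.5)
        amp = profile.noise_gain * rng.uniform(1.0, 2.0)
        burst = (amp * np.exp(-0.5 * ((t - t0) / tau) ** 2)
                 * np.sin(2 * np.pi * f * (t - t0)))
        noise = noise + burst
    if profile.drift_gain > 0:
        slow_f = rng.uniform(0.01, 0.04)
        noise = noise + profile.drift_gain * np.sin(
            2 * np.pi * slow_f * t + rng.uniform(0, 2 * np.pi)
        )
    return noise


def _lagged(x: np.ndarray, lag_samples: int) -> np.ndarray:
    if lag_samples <= 0:
        return x
    return np.concatenate([np.full(lag_samples, x[0]), x[:-lag_samples]])


def simulate_recording(
    subject: SimSubject,
    profile: SimScenarioProfile,
    duration_s: float = 180.0,
) -> SimulatedRecording:
    """One subject x scenario recording with all channels at native rates."""
    clean, peaks = simulate_respiration(subject, duration_s, MASTER_FS)
    # noise stream keyed by (subject, scenario name) so scenarios differ but
    # a given profile name is reproducible
    scen_key = zlib.crc32(profile.name.encode())
    rng = np.random.default_rng(np.random.SeedSequence([subject.seed, scen_key]))
    n200 = len(clean)
    clean_hub = clean.samples[::2]          # exact 100 Hz decimation
    n_hub = clean_hub.size
    shared_noise = _vehicle_noise(rng, n_hub, HUB_FS, profile)

    # chest belt: near-noiseless ground-truth channel
    reference = clean_hub + 0.01 * rng.normal(size=n_hub)
    # piezo: direct pressure transduction, used raw downstream
    piezo = (subject.piezo_gain * clean_hub
             + 0.08 * rng.normal(size=n_hub)
             + 0.15 * _band_noise(rng, n_hub, HUB_FS, (0.02, 0.08)))

    # accelerometer 1 (seat belt): respiration mixed into 3 axes + vehicle noise
    mix = rng.normal(size=3)
    mix /= np.linalg.norm(mix)
    couple1 = rng.normal(size=3)
    couple1 /= np.linalg.norm(couple1)
    acc1 = {}
    for i, ax in enumerate("xyz"):
        acc1[f"acc1_{ax}"] = (subject.acc_resp_gain * mix[i] * clean_hub
                              + couple1[i] * shared_noise
                              + 0.02 * rng.normal(size=n_hub))
    # accelerometer 2 (seat): the same vehicle noise, no respiration
    couple2 = rng.normal(size=3)
    couple2 /= np.linalg.norm(couple2)
    acc2 = {}
    for i, ax in enumerate("xyz"):
        acc2[f"acc2_{ax}"] = (couple2[i] * shared_noise
                              + 0.02 * rng.normal(size=n_hub))

    # video traces: lagged, rescaled respiration + illumination drift, 10 fps
    lag200 = int(round(subject.video_lag_s * MASTER_FS))
    t200 = np.arange(n200) / MASTER_FS
    videos = {}
    for name, gain, extra_lag in (("video_belt", 1.0, 0), ("video_chest", 0.8, 10)):
        lagged = _lagged(clean.samples, lag200 + extra_lag)
        illum = 0.3 * np.sin(2 * np.pi * rng.uniform(0.005, 0.02) * t200
                             + rng.uniform(0, 2 * np.pi))
        trace10 = (gain * lagged + illum)[::20] + 0.04 * rng.normal(size=(n200 + 19) // 20)
        videos[name] = ChannelTrace(name, trace10, VIDEO_FPS)

    channels = {
        "reference": ChannelTrace("reference", reference, HUB_FS),
        "piezo": ChannelTrace("piezo", piezo, HUB_FS),
        **{k: ChannelTrace(k, v, HUB_FS) for k, v in acc1.items()},
        **{k: ChannelTrace(k, v, HUB_FS) for k, v in acc2.items()},
        **videos,
    }
    rec = MultimodalRecording(subject.subject_id, profile.name, channels)
    return SimulatedRecording(rec, peaks, clean)


def simulate_frames(
    belt: ChannelTrace,
    resolution: tuple[int, int] = (1280, 720),
    roi: ROISpec | None = None,
    square: int = 5,
    background: int = 40,
) -> FrameSequence:
    """Render frames whose chessboard belt band slides with the belt trace.

    The band is a black-and-white chessboard (period ``2*square`` px) whose
    upper edge moves vertically through the ROI; the ROI green mean is then
    an affine function of the trace (up to 1-pixel quantization), so
    :func:`respfusion.video.frames_to_trace` recovers the input.
    """
    roi = roi or ROISpec(x=20, y=20, w=2 * square, h=40)
    w, hgt = resolution
    if roi.x + roi.w > w or roi.y + roi.h > hgt:
        raise RespFusionError("ROI outside the requested resolution")
    x = belt.samples
    rng_span = x.max() - x.min()
    norm = (x - x.min()) / rng_span if rng_span > 0 else np.full_like(x, 0.5)
    # band top edge position inside the ROI; high trace value = raised belt
    pos = roi.y + np.round((roi.h - 1) * (1.0 - norm)).astype(int)

    yy, xx = np.meshgrid(np.arange(hgt), np.arange(w), indexing="ij")
    chess = (((yy // square) + (xx // square)) % 2).astype(np.uint8) * 255
    # band bounded to the ROI rectangle: its visible rows grow and shrink
    # with the trace, and the local contrast peaks exactly at the nominal
    # ROI position (what verify_roi assumes)
    in_band_x = (xx >= roi.x) & (xx < roi.x + roi.w)
    below_roi_top = yy < roi.y + roi.h

    frames = np.full((len(x), hgt, w, 3), background, dtype=np.uint8)
    for k, p in enumerate(pos):
        mask = in_band_x & below_roi_top & (yy >= p)
        frames[k, ..., 1][mask] = chess[mask]
    return FrameSequence(frames, belt.fs)


def draw_subjects(n: int, master_seed: int) -> list[SimSubject]:
    """Deterministic cohort with distinct breathing rates (12-20 BPM)."""
    if n < 1:
        raise RespFusionError("need at least one subject")
    rng = np.random.default_rng(master_seed)
    base = np.linspace(12.0, 20.0, n)
    rates = rng.permutation(base) + rng.uniform(-0.3, 0.3, size=n)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    subjects = []
    for i in range(n):
        subjects.append(
            SimSubject(
                subject_id=f"s{i + 1:02d}",
                breathing_rate_bpm=float(rates[i]),
                rate_wander=float(rng.uniform(0.03, 0.08)),
                wander_freq_hz=float(rng.uniform(0.01, 0.03)),
                harmonic=float(rng.uniform(0.1, 0.24)),
                piezo_gain=float(rng.uniform(0.8, 1.2)),
                acc_resp_gain=float(rng.uniform(0.6, 0.9)),
                video_lag_s=float(rng.uniform(0.1, 0.5)),
                seed=int(seeds[i]),
            )
        )
    return subjects


def simulate_study(
    n_subjects: int,
    scenarios: tuple[str, ...] = SCENARIOS,
    duration_s: float = 180.0,
    master_seed: int = 0,
) -> list[MultimodalRecording]:
    """Full cohort: one recording per subject per scenario, reproducible
    bit-for-bit from ``master_seed``."""
    unknown = [s for s in scenarios if s not in SCENARIO_PROFILES]
    if unknown:
        raise RespFusionError(f"unknown scenarios: {unknown}")
    subjects = draw_subjects(n_subjects, master_seed)
    recordings = []
    for subj in subjects:
        for sc in scenarios:
            sim = simulate_recording(subj, SCENARIO_PROFILES[sc], duration_s)
            recordings.append(sim.recording)
    return recordings
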