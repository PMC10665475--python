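"""Per-sensor conditioning and the unified fusion pre-processing.

The piezoelectric belt signal is used raw.  The two 3-axis accelerometers go
through band-pass filtering and PCA axis combination, after which the
seat-belt sensor (respiration + vehicle noise) is denoised against the seat
sensor (vehicle noise only) by reference-channel spectral suppression:

    SF(k)     = exp(-|X2(k)| / mu(|X1|))          per frequency bin k
    X_supp(k) = SF(k) * X1(k)

with X1, X2 the FFTs of the two combined accelerometer signals and mu(|X1|)
the mean magnitude of X1.  Since SF is computed from magnitudes it is
conjugate-symmetric for real inputs, so the inverse FFT is real up to
round-off.  All signals are then brought to a unified rate, median filtered
and amplitude-normalized to [-1, 1] before windowing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.ndimage
import scipy.signal

from .types import ChannelTrace, PipelineConfig, RespFusionError

log = logging.getLogger(__name__)

_IMAG_TOL = 1e-9


def piezo_passthrough(trace: ChannelTrace) -> ChannelTrace:
    """The piezo sensor already outputs a voltage proportional to belt
    pressure; no conditioning is applied."""
    return trace


def bandpass(trace: ChannelTrace, low_hz: float, high_hz: float, order: int = 4) -> ChannelTrace:
    """Zero-phase Butterworth band-pass; same length and rate as the input."""
    if not (0 < low_hz < high_hz < trace.fs / 2):
        raise RespFusionError(
            f"invalid band [{low_hz}, {high_hz}] Hz for fs={trace.fs} Hz"
        )
    sos = scipy.signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=trace.fs, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, trace.samples)
    return trace.replace(samples=filtered)


def pca_axis_combine(x: ChannelTrace, y: ChannelTrace, z: ChannelTrace) -> ChannelTrace:
    """Project the mean-centered 3-axis cloud onto its first principal axis.

    Sign convention: the principal axis is flipped, if needed, so that its
    loading on the axis of largest variance is positive (deterministic).
    A rank-0 cloud (all axes constant) yields a zero trace with a warning.
    """
    if not (len(x) == len(y) == len(z)):
        raise RespFusionError("axis traces differ in length")
    if not (x.fs == y.fs == z.fs):
        raise RespFusionError("axis traces differ in sampling rate")
    data = np.column_stack([x.samples, y.samples, z.samples])
    centered = data - data.mean(axis=0)
    var = centered.var(axis=0)
    if np.all(var == 0):
        log.warning("pca_axis_combine: constant axes (rank-0 covariance); zero output")
        return x.replace(name="acc_pc1", samples=np.zeros(len(x)))
    # SVD of the centered cloud: right singular vectors = principal axes
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = vt[0]
    j = int(np.argmax(var))
    if pc1[j] < 0 or (pc1[j] == 0 and pc1[np.flatnonzero(pc1)[0]] < 0):
        pc1 = -pc1
    return x.replace(name="acc_pc1", samples=centered @ pc1)


def axis_norm_combine(x: ChannelTrace, y: ChannelTrace, z: ChannelTrace) -> ChannelTrace:
    """Euclidean 3-axis magnitude, mean-removed — alternative to PCA."""
    if not (len(x) == len(y) == len(z)) or not (x.fs == y.fs == z.fs):
        raise RespFusionError("axis traces differ in length or sampling rate")
    mag = np.sqrt(x.samples**2 + y.samples**2 + z.samples**2)
    return x.replace(name="acc_norm", samples=mag - mag.mean())


def suppression_factor(abs_x1: np.ndarray, abs_x2: np.ndarray) -> np.ndarray:
    """Per-bin suppression factor SF(k) = exp(-|X2(k)| / mu(|X1|)) in (0, 1]."""
    abs_x1 = np.asarray(abs_x1, dtype=float)
    abs_x2 = np.asarray(abs_x2, dtype=float)
    if abs_x1.shape != abs_x2.shape:
        raise RespFusionError("spectra have different lengths")
    mu = abs_x1.mean()
    if mu == 0:
        raise RespFusionError("degenerate signal: mean magnitude of X1 is zero")
    return np.exp(-abs_x2 / mu)


@dataclass(frozen=True)
class SpectralSuppression:
    """Spectra and result of one reference-channel suppression step."""

    x1_spectrum: np.ndarray  # complex FFT of the signal+noise channel
    x2_spectrum: np.ndarray  # complex FFT of the noise-only channel
    mu_abs_x1: float
    sf: np.ndarray           # per-bin factor in (0, 1]
    suppressed_spectrum: np.ndarray
    denoised: ChannelTrace


def spectral_suppress(x1: ChannelTrace, x2: ChannelTrace) -> SpectralSuppression:
    """Suppress the frequency content of ``x1`` using the noise reference ``x2``.

    Both channels are transformed with the FFT, the per-bin suppression factor
    is computed from the magnitudes, applied to the complex spectrum of ``x1``
    (phase preserved), and the result inverse-transformed.  The output is real
    within numerical tolerance and has the length of the input.
    """
    if len(x1) != len(x2):
        raise RespFusionError("x1 and x2 differ in length")
    if x1.fs != x2.fs:
        raise RespFusionError("x1 and x2 differ in sampling rate")
    spec1 = np.fft.fft(x1.samples)
    spec2 = np.fft.fft(x2.samples)
    sf = suppression_factor(np.abs(spec1), np.abs(spec2))
    supp = sf * spec1
    denoised_c = np.fft.ifft(supp)
    scale = max(np.max(np.abs(x1.samples)), 1.0)
    resid = np.max(np.abs(denoised_c.imag))
    if resid > _IMAG_TOL * scale:
        raise RespFusionError(f"inverse transform not real: imaginary residue {resid:g}")
    denoised = x1.replace(name=f"{x1.name}_denoised", samples=denoised_c.real)
    return SpectralSuppression(spec1, spec2, float(np.abs(spec1).mean()), sf, supp, denoised)


def spectral_suppress_windowed(
    x1: ChannelTrace, x2: ChannelTrace, window_len: int, hop: int | None = None
) -> ChannelTrace:
    """Overlap-add variant of :func:`spectral_suppress` for long signals.

    Applies the suppression per windowed segment and reconstructs by
    overlap-add with the normalizing window-power sum.  A Blackman window is
    used: its low sidelobes keep spectral leakage from strong out-of-band or
    narrowband components from raising the noise floor at the breathing
    bins, which would otherwise drive the exponential suppression factor to
    zero exactly where the signal lives.
    """
    if hop is None:
        hop = window_len // 2
    n = len(x1)
    if n < window_len:
        return spectral_suppress(x1, x2).denoised
    # reflect-pad so every original sample has full multi-window coverage:
    # the taper regions of the first/last window would otherwise be
    # reconstructed from a single ill-conditioned segment
    pad = window_len
    s1 = np.pad(x1.samples, pad, mode="reflect")
    s2 = np.pad(x2.samples, pad, mode="reflect")
    total = s1.size
    win = np.blackman(window_len)
    out = np.zeros(total)
    norm = np.zeros(total)
    starts = list(range(0, total - window_len + 1, hop))
    if starts[-1] + window_len < total:
        starts.append(total - window_len)
    for s in starts:
        seg1 = x1.replace(samples=s1[s : s + window_len] * win)
        seg2 = x2.replace(samples=s2[s : s + window_len] * win)
        try:
            d = spectral_suppress(seg1, seg2).denoised.samples
        except RespFusionError:  # all-zero windowed segment
            d = np.zeros(window_len)
        out[s : s + window_len] += d * win
        norm[s : s + window_len] += win**2
    # floor the window-power sum: residual near-zero values at the padded
    # ends would amplify FFT round-off without bound
    floor = 1e-6 * norm.max()
    denoised = (out / np.maximum(norm, floor))[pad : pad + n]
    return x1.replace(name=f"{x1.name}_denoised", samples=denoised)


def denoise_accelerometer(
    acc1_xyz: tuple[ChannelTrace, ChannelTrace, ChannelTrace],
    acc2_xyz: tuple[ChannelTrace, ChannelTrace, ChannelTrace],
    config: PipelineConfig | None = None,
    combine: str = "pca",
) -> ChannelTrace:
    """Full accelerometer pipeline: band-pass -> axis combination per sensor,
    then spectral suppression of the seat-belt sensor against the seat sensor.

    ``combine`` selects the axis combination: ``"pca"`` (first principal
    component, default) or ``"norm"`` (Euclidean magnitude).
    """
    config = config or PipelineConfig()
    fss = {t.fs for t in (*acc1_xyz, *acc2_xyz)}
    if len(fss) != 1:
        raise RespFusionError(f"accelerometers have mismatched sampling rates: {fss}")
    combiner = {"pca": pca_axis_combine, "norm": axis_norm_combine}.get(combine)
    if combiner is None:
        raise RespFusionError(f"unknown axis combination {combine!r}")

    def _one(axes):
        bp = [bandpass(t, config.bandpass_low_hz, config.bandpass_high_hz,
                       config.bandpass_order) for t in axes]
        return combiner(*bp)

    a1 = _one(acc1_xyz)
    a2 = _one(acc2_xyz)
    out = _suppress(a1, a2, config)
    return out.replace(name="acc")


def _suppress(a1: ChannelTrace, a2: ChannelTrace, config: PipelineConfig) -> ChannelTrace:
    if config.suppress_window_s is None:
        return spectral_suppress(a1, a2).denoised
    window_len = int(round(config.suppress_window_s * a1.fs))
    return spectral_suppress_windowed(a1, a2, window_len)


def resample_to(trace: ChannelTrace, target_fs: float = 200.0) -> ChannelTrace:
    """Polyphase resampling to ``target_fs``; length scales by target_fs/fs.

    Upsampling is the expected direction; downsampling is allowed (with
    anti-alias filtering built into the polyphase design) and logged.
    """
    if not (target_fs > 0):
        raise RespFusionError(f"target_fs must be > 0, got {target_fs}")
    if target_fs == trace.fs:
        return trace
    if target_fs < trace.fs:
        log.info("resample_to: downsampling %s from %g to %g Hz", trace.name, trace.fs, target_fs)
    frac = Fraction(target_fs / trace.fs).limit_denominator(10_000)
    resampled = scipy.signal.resample_poly(trace.samples, frac.numerator, frac.denominator)
    return trace.replace(samples=resampled, fs=target_fs)


def median_filter(trace: ChannelTrace, kernel: int = 5) -> ChannelTrace:
    """Sliding-median despike; odd kernel, edges handled by reflection."""
    if kernel < 1 or kernel % 2 == 0:
        raise RespFusionError(f"median kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return trace
    filtered = scipy.ndimage.median_filter(trace.samples, size=kernel, mode="reflect")
    return trace.replace(samples=filtered)


def normalize_amplitude(trace: ChannelTrace) -> ChannelTrace:
    """Affine map of [min, max] onto [-1, 1]; a constant trace maps to zeros."""
    lo, hi = trace.samples.min(), trace.samples.max()
    if hi == lo:
        log.warning("normalize_amplitude: constant trace %r mapped to zeros", trace.name)
        return trace.replace(samples=np.zeros(len(trace)))
    scaled = 2.0 * (trace.samples - lo) / (hi - lo) - 1.0
    return trace.replace(samples=scaled)


def prepare_model_channels(rec, config: PipelineConfig | None = None, combine: str = "pca"):
    """From a raw multimodal recording to the unified model channels.

    Applies the per-sensor conditioning (piezo passthrough; accelerometer
    band-pass -> axis combination -> spectral suppression; video traces used
    as-is) and then the fusion pre-processing (resample to the unified rate,
    median filter, normalize).  Returns a dict with keys ``piezo``, ``acc``,
    ``video_belt``, ``video_chest`` and ``reference`` on a common timeline.

    Accelerometers may be stored as three axes (``acc1_x/y/z``) or as a
    pre-combined scalar (``acc1``); both layouts are accepted.
    """
    config = config or PipelineConfig()

    def _acc(sensor: str) -> tuple[ChannelTrace, ...] | ChannelTrace:
        axes = [f"{sensor}_{a}" for a in "xyz"]
        if all(a in rec for a in axes):
            return tuple(rec[a] for a in axes)
        if sensor in rec:
            return rec[sensor]
        raise RespFusionError(
            f"recording lacks accelerometer channels {axes} (or scalar {sensor!r})"
        )

    a1, a2 = _acc("acc1"), _acc("acc2")
    if isinstance(a1, ChannelTrace) or isinstance(a2, ChannelTrace):
        # pre-combined magnitudes: band-pass then suppress directly
        if isinstance(a1, tuple) or isinstance(a2, tuple):
            raise RespFusionError("accelerometers must both be 3-axis or both scalar")
        bp1 = bandpass(a1, config.bandpass_low_hz, config.bandpass_high_hz, config.bandpass_order)
        bp2 = bandpass(a2, config.bandpass_low_hz, config.bandpass_high_hz, config.bandpass_order)
        acc = _suppress(bp1, bp2, config).replace(name="acc")
    else:
        acc = denoise_accelerometer(a1, a2, config, combine=combine)

    needed = ("piezo", "video_belt", "video_chest", "reference")
    missing = [c for c in needed if c not in rec]
    if missing:
        raise RespFusionError(f"recording lacks channels: {missing}")
    chans = {
        "piezo": piezo_passthrough(rec["piezo"]),
        "acc": acc,
        "video_belt": rec["video_belt"],
        "video_chest": rec["video_chest"],
        "reference": rec["reference"],
    }
    return unify_channels(chans, config)


def unify_channels(
    channels: dict[str, ChannelTrace], config: PipelineConfig | None = None
) -> dict[str, ChannelTrace]:
    """Bring a set of traces onto the unified timeline: resample to
    ``target_fs``, median filter, normalize to [-1, 1], and crop all channels
    to the shortest common length."""
    config = config or PipelineConfig()
    out = {}
    for name, t in channels.items():
        t = resample_to(t, config.target_fs)
        t = median_filter(t, config.median_kernel)
        t = normalize_amplitude(t)
        out[name] = t
    n = min(len(t) for t in out.values())
    return {name: t.replace(samples=t.samples[:n]) for name, t in out.items()}
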