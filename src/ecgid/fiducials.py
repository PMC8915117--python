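"""Per-beat fiducial-point delineation.

Nine landmarks are located on each beat: P-wave onset/peak/offset, Q, R, S,
and T-wave onset/peak/offset.  The QRS complex is found first with the
classical dyadic (a-trous) quadratic-spline wavelet transform: the R peak
produces a pair of opposite-sign modulus maxima at small scales, and the zero
crossing between them marks the peak.  P and T waves are then delineated
inside physiological search windows relative to each R peak; each wave's
width is estimated from its scale-16 (2^4) transform modulus lobes (the 2^4
band best matches P/T wave widths, keeping the broadband-noise floor well
below the lobes) and its onset/offset placed a fixed number of widths from
the peak.

All window lengths and thresholds are expressed in seconds/relative units so
detection is invariant to amplitude scaling and (up to edge effects)
translation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "BeatFiducials",
    "DetectorConfig",
    "spline_wavelet_transform",
    "detect_r_peaks",
    "detect_qrs_bounds",
    "detect_p_t_waves",
    "LANDMARK_NAMES",
]

LANDMARK_NAMES = ("PBegin", "P", "PEnd", "Q", "R", "S", "TBegin", "T", "TEnd")


@dataclass(frozen=True)
class BeatFiducials:
    """Nine per-beat landmark indices (0-based) and their amplitudes."""

    PBegin: int
    P: int
    PEnd: int
    Q: int
    R: int
    S: int
    TBegin: int
    T: int
    TEnd: int
    amplitudes: dict[str, float]
    fs: float

    def __post_init__(self) -> None:
        idx = self.indices()
        # strict ordering; PEnd==Q, S==TBegin tolerated at the boundary
        if not (
            idx[0] < idx[1] < idx[2] <= idx[3] < idx[4] < idx[5] <= idx[6] < idx[7] < idx[8]
        ):
            raise ValueError(f"landmark ordering violated: {dict(zip(LANDMARK_NAMES, idx))}")

    def indices(self) -> tuple[int, ...]:
        return tuple(getattr(self, n) for n in LANDMARK_NAMES)

    def interval(self, a: str, b: str) -> float:
        """|index(a) - index(b)| in seconds."""
        return abs(getattr(self, a) - getattr(self, b)) / self.fs


@dataclass(frozen=True)
class DetectorConfig:
    """Search windows (seconds) and thresholds; physiologically standard."""

    refractory: float = 0.200
    # max spacing between successive slope extrema of one QRS complex; the
    # chained window groups a complex's extrema while P/T-wave lobes (and the
    # gaps between waves) are wider and fall apart into single-sign groups
    qrs_pair_max_sep: float = 0.045
    threshold_fraction: float = 0.3  # of the local RMS of the scale-4 transform
    rms_window: float = 2.0
    # absolute floor as a fraction of the record's peak transform modulus,
    # rejecting residual-noise pairs in quiet stretches
    threshold_floor_fraction: float = 0.15
    q_window: float = 0.080
    s_window: float = 0.080
    p_search: tuple[float, float] = (0.300, 0.060)  # before R: [R-300ms, R-60ms]
    t_search: tuple[float, float] = (0.060, 0.450)  # [S+60ms, R+450ms]
    # onset/offset sit this many estimated wave widths from the wave peak;
    # the width is read off the spacing of the transform's modulus-maxima
    # lobes after deconvolving the transform kernel's own width
    boundary_widths: float = 2.5
    # a wave is declared present only when its transform lobe modulus
    # exceeds this multiple of the record's median modulus (the noise
    # floor); an absent wave leaves only tails and noise in its window,
    # whose lobes sit at the floor
    wave_presence_ratio: float = 1.5


# Mallat-Zhang quadratic-spline filter pair: smoothing h, derivative-like g.
_H = np.array([0.125, 0.375, 0.375, 0.125])
_G = np.array([2.0, -2.0])


def _atrous_conv(x: np.ndarray, taps: np.ndarray, dilation: int) -> np.ndarray:
    """'same'-aligned convolution with a dilated filter (half-sample rounding)."""
    up = np.zeros((len(taps) - 1) * dilation + 1)
    up[::dilation] = taps
    full = np.convolve(x, up)
    delay = (len(up) - 1) / 2
    start = int(round(delay))
    return full[start : start + len(x)]


def spline_wavelet_transform(signal: np.ndarray, max_level: int = 4) -> list[np.ndarray]:
    """Undecimated quadratic-spline wavelet transform W_{2^1}..W_{2^k}.

    Each output approximates a smoothed derivative of the signal at dyadic
    scale 2^j; extrema of the signal appear as zero crossings flanked by
    opposite-sign modulus maxima.
    """
    x = np.asarray(signal, dtype=float)
    w: list[np.ndarray] = []
    a = x
    for j in range(1, max_level + 1):
        dil = 2 ** (j - 1)
        w.append(_atrous_conv(a, _G, dil))
        a = _atrous_conv(a, _H, dil)
    return w


def _local_rms(x: np.ndarray, window: int) -> np.ndarray:
    sq = uniform_filter1d(x**2, size=max(window, 1), mode="nearest")
    return np.sqrt(np.clip(sq, 0.0, None))  # rounding can leave tiny negatives


def detect_r_peaks(
    signal: np.ndarray, fs: float, config: DetectorConfig | None = None
) -> np.ndarray:
    """R-peak indices via modulus-maxima pairs of the spline transform.

    A QRS complex is accepted where the scale-4 transform shows a
    positive/negative modulus-maxima pair exceeding an adaptive (local-RMS)
    threshold; the R index is the signal maximum near the zero crossing
    between the pair.  Candidates closer than the refractory period keep the
    larger modulus.  Returns an empty array for records shorter than one
    analysis window.
    """
    config = config or DetectorConfig()
    x = np.asarray(signal, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    min_len = int(config.refractory * fs) + 2
    if len(x) < min_len or not np.any(x != 0):
        return np.array([], dtype=int)

    w2 = spline_wavelet_transform(x, max_level=2)[1]
    peak_mod = np.max(np.abs(w2))
    if peak_mod == 0:
        return np.array([], dtype=int)
    thr = config.threshold_fraction * _local_rms(w2, int(config.rms_window * fs))
    thr = np.maximum(thr, config.threshold_floor_fraction * peak_mod)

    aw = np.abs(w2)
    above = aw > thr
    is_ext = np.zeros(len(w2), dtype=bool)
    is_ext[1:-1] = above[1:-1] & (aw[1:-1] >= aw[:-2]) & (aw[1:-1] > aw[2:])
    cand = np.flatnonzero(is_ext)

    # cluster candidate extrema: one QRS yields several slope extrema within
    # the pair window, while consecutive complexes are separated by >> that
    pair_sep = int(config.qrs_pair_max_sep * fs)
    refine = int(0.030 * fs)
    peaks: list[tuple[int, float]] = []  # (index, pair modulus)
    start = 0
    while start < len(cand):
        stop = start
        while stop + 1 < len(cand) and cand[stop + 1] - cand[stop] <= pair_sep:
            stop += 1
        cluster = cand[start : stop + 1]
        start = stop + 1
        pos = cluster[w2[cluster] > 0]
        neg = cluster[w2[cluster] < 0]
        if len(pos) == 0 or len(neg) == 0:
            continue  # no opposite-sign pair: not a QRS
        i = pos[int(np.argmax(w2[pos]))]
        jx = neg[int(np.argmin(w2[neg]))]
        lo_i, hi_i = min(i, jx), max(i, jx)
        zc = lo_i + int(np.argmin(np.abs(w2[lo_i : hi_i + 1])))
        lo = max(zc - refine, 0)
        hi = min(zc + refine + 1, len(x))
        r = lo + int(np.argmax(x[lo:hi]))
        peaks.append((r, aw[i] + aw[jx]))

    if not peaks:
        return np.array([], dtype=int)

    # two-level adaptive modulus threshold (Pan-Tompkins style): running
    # QRS-level and noise-level estimates separate QRS pairs from the
    # smaller P/T-wave pairs that also clear the static floor
    peaks.sort()
    moduli = np.array([m for _, m in peaks])
    s_level = float(np.percentile(moduli, 90))
    n_level = float(np.percentile(moduli, 30)) if len(moduli) > 3 else 0.0
    if n_level > 0.5 * s_level:
        n_level = 0.0  # unimodal moduli: everything is QRS-level
    accepted: list[tuple[int, float]] = []
    for r, m in peaks:
        if m > n_level + 0.25 * (s_level - n_level):
            accepted.append((r, m))
            s_level = 0.125 * m + 0.875 * s_level
        else:
            n_level = 0.125 * m + 0.875 * n_level
    peaks = accepted

    # refractory resolution: keep the larger-modulus pair
    refractory = int(config.refractory * fs)
    kept: list[tuple[int, float]] = []
    for r, m in peaks:
        if kept and r - kept[-1][0] < refractory:
            if m > kept[-1][1]:
                kept[-1] = (r, m)
        else:
            kept.append((r, m))
    return np.array([r for r, _ in kept], dtype=int)


def _nearest_trough(x: np.ndarray, r: int, stop: int, step: int) -> int:
    """Index of the trough nearest to R, walking from R towards ``stop``.

    Descends the R flank to the first local minimum (two non-descending
    successors required, so an isolated noise notch on the flank does not
    stop the walk early); falls back to the window minimum if the flank
    never turns."""
    i = r + step
    last = stop - step
    while (i - last) * step < 0:
        if x[i] <= x[i + step] and x[i] <= x[i + 2 * step]:
            return i
        i += step
    lo, hi = (stop, r) if step < 0 else (r + 1, stop + 1)
    return lo + int(np.argmin(x[lo:hi]))


def detect_qrs_bounds(
    signal: np.ndarray,
    fs: float,
    r_peaks: np.ndarray,
    config: DetectorConfig | None = None,
) -> list[tuple[int, int] | None]:
    """Q and S indices per beat: nearest troughs inside the QRS windows.

    Beats whose search window would leave the record are reported as ``None``
    (and logged) rather than truncated.
    """
    config = config or DetectorConfig()
    x = np.asarray(signal, dtype=float)
    # light symmetric smoothing so residual mid-band noise cannot stop the
    # flank walk in a false micro-trough; unbiased for symmetric troughs
    xs = uniform_filter1d(x, size=5, mode="nearest")
    qw = int(config.q_window * fs)
    sw = int(config.s_window * fs)
    out: list[tuple[int, int] | None] = []
    for r in np.asarray(r_peaks, dtype=int):
        if r - qw < 0 or r + sw >= len(x):
            logger.info("beat at %d dropped: QRS window exceeds record", r)
            out.append(None)
            continue
        q = _nearest_trough(xs, r, r - qw, step=-1)
        s = _nearest_trough(xs, r, r + sw, step=+1)
        out.append((q, s))
    return out


def _kernel_width(level: int = 4) -> float:
    """Smoothing width (samples) of the spline transform at one scale.

    The transform is convolution with the derivative of a smoothing kernel
    Phi; integrating the impulse response recovers Phi, whose standard
    deviation is the width that blurs every wave the transform sees.
    """
    n = 257
    delta = np.zeros(n)
    delta[n // 2] = 1.0
    k = spline_wavelet_transform(delta, max_level=level)[level - 1]
    phi = np.cumsum(k)
    phi = np.abs(phi)
    phi /= phi.sum()
    t = np.arange(n)
    mu = float(phi @ t)
    return float(np.sqrt(phi @ (t - mu) ** 2))


_W4_KERNEL_WIDTH = _kernel_width(4)


def _wave_lobes(
    w4: np.ndarray, signal: np.ndarray, lo: int, hi: int
) -> tuple[int, int, int] | None:
    """(left lobe, refined peak, right lobe) of the dominant wave in [lo, hi).

    The peak is refined to the transform zero crossing between the wave's two
    modulus lobes (the extremum of the smoothed wave), which is far less
    sensitive to noise on a flat wave crest than a plain argmax.
    """
    if hi - lo < 3:
        return None
    peak0 = lo + int(np.argmax(signal[lo:hi]))
    if not (lo < peak0 < hi - 1):
        return None
    aw = np.abs(w4)
    l_ext = lo + int(np.argmax(aw[lo:peak0]))
    # right lobe: the first local modulus maximum past the peak that is
    # commensurate with the left lobe — a global argmax could instead catch
    # QRS transform energy bleeding over the window edge
    r_ext = None
    r_floor = 0.3 * aw[l_ext]
    for i in range(peak0 + 1, hi - 1):
        if aw[i] >= r_floor and aw[i] >= aw[i - 1] and aw[i] > aw[i + 1]:
            r_ext = i
            break
    if r_ext is None:
        r_ext = peak0 + int(np.argmax(aw[peak0:hi]))
    if aw[l_ext] == 0 or aw[r_ext] == 0 or r_ext - l_ext < 2:
        return None
    peak = l_ext + 1 + int(np.argmin(aw[l_ext + 1 : r_ext]))
    return l_ext, peak, r_ext


def _boundary_half_widths(spacings: list[int], boundary_widths: float) -> list[int]:
    """Per-beat boundary half-widths (samples) from the lobe spacings.

    The modulus lobes sit one effective width either side of the peak.  Wave
    morphology is stable within a record, so each beat's spacing is
    winsorised at the record median +/- 2 samples — rejecting the occasional
    gross mislocalisation without flattening genuine beat-to-beat variation —
    before deconvolving the transform kernel's own width.
    """
    med = float(np.median(spacings))
    halves = []
    for spacing in spacings:
        sigma_eff = float(np.clip(spacing, med - 2.0, med + 2.0)) / 2.0
        sigma = np.sqrt(
            max(sigma_eff**2 - _W4_KERNEL_WIDTH**2, (0.25 * sigma_eff) ** 2)
        )
        halves.append(int(round(boundary_widths * sigma)))
    return halves


def detect_p_t_waves(
    signal: np.ndarray,
    fs: float,
    r_peaks: np.ndarray,
    config: DetectorConfig | None = None,
) -> list[BeatFiducials]:
    """Full nine-landmark delineation for each beat.

    P is the dominant positive extremum in the pre-R window, T in the post-S
    window; onsets/offsets are placed a fixed number of wave widths from the
    peak, the width read from the transform's modulus-maxima lobe spacing and
    pooled (median) over the record's beats.  The T onset is constrained to
    lie after S, so it can never fall inside the QRS complex.  Beats missing
    any landmark (absent wave, window off the record, ordering violation) are
    dropped and counted in the log.
    """
    config = config or DetectorConfig()
    x = np.asarray(signal, dtype=float)
    r_peaks = np.asarray(r_peaks, dtype=int)
    w4 = spline_wavelet_transform(x, max_level=4)[3]
    noise_floor = float(np.median(np.abs(w4)))
    bounds = detect_qrs_bounds(x, fs, r_peaks, config)

    # pass 1: locate wave peaks and modulus lobes per beat
    located: list[tuple[int, int, int, tuple, tuple]] = []  # r, q, s, p-lobes, t-lobes
    dropped = 0
    for r, qs in zip(r_peaks, bounds):
        if qs is None:
            dropped += 1
            continue
        q, s = qs
        p_lo = r - int(config.p_search[0] * fs)
        p_hi = min(r - int(config.p_search[1] * fs), q)  # never inside the QRS
        t_lo = max(s + int(config.t_search[0] * fs), s + 1)
        t_hi = r + int(config.t_search[1] * fs)
        if p_lo < 0 or t_hi >= len(x):
            dropped += 1
            continue
        pw = _wave_lobes(w4, x, p_lo, p_hi)
        tw = _wave_lobes(w4, x, t_lo, t_hi)
        if pw is None or tw is None:
            dropped += 1
            continue
        floor = config.wave_presence_ratio * noise_floor
        if abs(w4[pw[0]]) < floor or abs(w4[tw[2]]) < floor:
            dropped += 1  # wave absent: lobes indistinguishable from noise
            continue
        located.append((int(r), q, s, pw, tw))

    if not located:
        if dropped:
            logger.info("dropped all %d beats during delineation", len(r_peaks))
        return []

    # pass 2: robust width estimates -> boundaries.  Each wave's width is
    # read from the lobe on its far side from the QRS (left for P, right for
    # T), where no QRS transform energy bleeds into the estimate.
    p_halves = _boundary_half_widths(
        [2 * (pw[1] - pw[0]) for _, _, _, pw, _ in located], config.boundary_widths
    )
    t_halves = _boundary_half_widths(
        [2 * (tw[2] - tw[1]) for _, _, _, _, tw in located], config.boundary_widths
    )
    out: list[BeatFiducials] = []
    for (r, q, s, (_, p, _), (_, t, _)), p_half, t_half in zip(
        located, p_halves, t_halves
    ):
        idx = dict(
            PBegin=p - p_half,
            P=p,
            PEnd=min(p + p_half, q),
            Q=q,
            R=r,
            S=s,
            TBegin=max(t - t_half, s),  # T onset never inside the QRS
            T=t,
            TEnd=t + t_half,
        )
        try:
            out.append(
                BeatFiducials(
                    **idx,
                    amplitudes={k: float(x[v]) for k, v in idx.items()},
                    fs=float(fs),
                )
            )
        except ValueError:
            dropped += 1
    if dropped:
        logger.info("dropped %d/%d beats during delineation", dropped, len(r_peaks))
    return out
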