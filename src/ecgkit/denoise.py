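"""Three-stage ECG denoising: zero-phase Butterworth -> robust LOESS
baseline removal -> non-local-means (NLM) smoothing.

The stage order is fixed.  A low-pass Butterworth filter (passband 50 Hz,
stopband 60 Hz, <= 1.0 dB passband ripple, >= 2.5 dB stopband attenuation)
removes out-of-band high-frequency content and is applied forward and
backward so the net phase shift is zero; a robust LOESS smoother estimates
the slow baseline-wander trend, which is subtracted; NLM removes the
residual broadband noise by averaging samples whose surrounding patches
look alike:

    S(i) = (1/Z(i)) * sum_{j in N(i)} w(i,j) D(j),      Z(i) = sum_j w(i,j)
    w(i,j) = exp( - sum_{d in patch} g(d) [D(i+d) - D(j+d)]^2 / (2 L λ^2) )

with λ the smoothness parameter, the patch containing L samples, and g an
optional Gaussian taper over patch offsets (g ≡ 1 reproduces the plain
patch distance).  Near the signal ends, patches and search windows are
truncated to valid samples — nothing is padded — and L is replaced by the
retained kernel mass, keeping λ on the same scale everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import ECGRecord


class FilterDesignError(ValueError):
    """Infeasible low-pass specification."""


@dataclass(frozen=True)
class LowpassSpec:
    """Low-pass design constraints (frequencies in Hz, levels in dB)."""

    fs: float = 500.0
    passband_hz: float = 50.0
    stopband_hz: float = 60.0
    max_passband_ripple_db: float = 1.0
    min_stopband_atten_db: float = 2.5

    def __post_init__(self) -> None:
        if not 0 < self.passband_hz < self.stopband_hz:
            raise FilterDesignError(
                f"need 0 < passband ({self.passband_hz}) < stopband ({self.stopband_hz})"
            )
        if self.stopband_hz >= self.fs / 2:
            raise FilterDesignError("stopband must lie below the Nyquist frequency")
        if self.max_passband_ripple_db <= 0 or self.min_stopband_atten_db <= 0:
            raise FilterDesignError("ripple and attenuation bounds must be positive")


@dataclass(frozen=True)
class ButterworthFilter:
    """Designed filter: order plus cascaded second-order sections."""

    order: int
    sos: np.ndarray
    fs: float

    def magnitude_db(self, freq_hz: float | np.ndarray) -> np.ndarray:
        """Single-pass magnitude response in dB at the given frequencies."""
        _, h = sps.freqz_sos(self.sos, worN=np.atleast_1d(np.asarray(freq_hz, float)),
                             fs=self.fs)
        return 20.0 * np.log10(np.abs(h))


def butterworth_min_order(spec: LowpassSpec) -> int:
    """Minimum order from the analytic Butterworth formula on the edge
    frequencies: n >= log10((10^(A/10)-1)/(10^(R/10)-1)) / (2 log10(fs/fp))."""
    num = (10 ** (spec.min_stopband_atten_db / 10) - 1)
    den = (10 ** (spec.max_passband_ripple_db / 10) - 1)
    ratio = spec.stopband_hz / spec.passband_hz
    return int(math.ceil(math.log10(num / den) / (2 * math.log10(ratio))))


def design_lowpass(spec: LowpassSpec = LowpassSpec()) -> ButterworthFilter:
    """Design the minimum-order low-pass Butterworth meeting both edges.

    The order comes from the analytic formula on the printed edge
    frequencies; the digital cutoff is placed (after bilinear prewarping)
    so the passband edge meets the ripple bound exactly, which leaves the
    stopband edge with attenuation at or beyond the requirement.
    """
    n = butterworth_min_order(spec)
    warped_p = math.tan(math.pi * spec.passband_hz / spec.fs)
    wc = warped_p * (10 ** (spec.max_passband_ripple_db / 10) - 1) ** (-1.0 / (2 * n))
    wn = 2.0 / math.pi * math.atan(wc)  # normalized, Nyquist = 1
    sos = sps.butter(n, wn, btype="low", output="sos")
    return ButterworthFilter(order=n, sos=sos, fs=spec.fs)


def apply_zero_phase(filt: ButterworthFilter, x: np.ndarray) -> np.ndarray:
    """Forward-backward filtering: zero net phase, squared magnitude response.

    Uses reflective edge padding of 3x the filter order to suppress
    start/end transients.
    """
    x = np.asarray(x, dtype=float)
    padlen = 3 * filt.order
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"signal length {x.shape[-1]} too short for zero-phase filtering "
            f"(needs > {padlen} samples)"
        )
    return sps.sosfiltfilt(filt.sos, x, padtype="even", padlen=padlen)


# ---------------------------------------------------------------------------
# robust LOESS

@dataclass(frozen=True)
class LoessSpec:
    """Local-regression parameters for baseline estimation.

    ``span`` is the fraction of the record used per local fit (default 0.15,
    i.e. a 1.5 s window on a 10 s record at 500 Hz — wider than one beat, so
    QRS complexes act as outliers to the trend); ``degree`` the local
    polynomial degree; robustness iterations zero-weight points whose
    residual exceeds ``mad_cut`` absolute deviations and bisquare-downweight
    the rest.  The robust scale is the median absolute residual, the
    classical robust-lowess ("rloess") convention — whose documentation
    habitually calls the six-scale cut "six mean absolute deviations" —
    because the median is what actually rejects the cardiac waves as
    outliers to the slow trend.
    """

    span: float = 0.15
    degree: int = 2
    robust_iterations: int = 4
    mad_cut: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError("span must be in (0, 1]")
        if self.degree < 0 or self.robust_iterations < 0:
            raise ValueError("degree and robust_iterations must be >= 0")
        if self.mad_cut <= 0:
            raise ValueError("mad_cut must be positive")


def _loess_window(n: int, spec: LoessSpec) -> int:
    w = int(round(spec.span * n))
    if w < spec.degree + 2:
        raise ValueError(
            f"span window of {w} points cannot support a degree-{spec.degree} fit"
        )
    return min(w, n)


def _loess_pass(y: np.ndarray, w: int, degree: int, robust_w: np.ndarray) -> np.ndarray:
    """One weighted local-polynomial pass, evaluated at every sample."""
    n = y.size
    half = w // 2
    centers = np.arange(n)
    starts = np.clip(centers - half, 0, n - w)
    idx = starts[:, None] + np.arange(w)[None, :]  # (n, w) window indices
    x = (idx - centers[:, None]).astype(float)
    dmax = np.abs(x).max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    u = x / dmax
    tricube = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    wgt = tricube * robust_w[idx]

    p = degree
    yy = y[idx]
    # weighted normal equations in the scaled regressor u, evaluated at u=0
    powers = [np.ones_like(u)]
    for _ in range(2 * p):
        powers.append(powers[-1] * u)
    s = np.stack([(wgt * powers[k]).sum(axis=1) for k in range(2 * p + 1)], axis=1)
    t = np.stack([(wgt * powers[k] * yy).sum(axis=1) for k in range(p + 1)], axis=1)
    a = np.empty((n, p + 1, p + 1))
    for r in range(p + 1):
        for c in range(p + 1):
            a[:, r, c] = s[:, r + c]
    # ridge of epsilon guards windows where robust weights wiped out support
    a += 1e-12 * np.eye(p + 1)[None, :, :]
    coef = np.linalg.solve(a, t[:, :, None])[:, :, 0]
    return coef[:, 0]  # value at u = 0


def loess_baseline(x: np.ndarray, spec: LoessSpec = LoessSpec()) -> np.ndarray:
    """Robust LOESS trend evaluated at every sample.

    Tricube distance weights within the span window; after each robustness
    iteration residuals are scored against the median absolute deviation:
    points beyond ``mad_cut`` x MAD get zero weight, points within get
    bisquare weights.
    """
    y = np.asarray(x, dtype=float)
    n = y.size
    w = _loess_window(n, spec)
    robust_w = np.ones(n)
    trend = _loess_pass(y, w, spec.degree, robust_w)
    for _ in range(spec.robust_iterations):
        resid = y - trend
        mad = np.median(np.abs(resid))
        if mad <= 0:
            break
        u = resid / (spec.mad_cut * mad)
        robust_w = np.where(np.abs(u) < 1.0, (1.0 - u * u) ** 2, 0.0)
        trend = _loess_pass(y, w, spec.degree, robust_w)
    return trend


def remove_baseline(x: np.ndarray, spec: LoessSpec = LoessSpec()) -> np.ndarray:
    """Subtract the robust LOESS trend (baseline-wander removal)."""
    return np.asarray(x, dtype=float) - loess_baseline(x, spec)


# ---------------------------------------------------------------------------
# non-local means

@dataclass(frozen=True)
class NLMConfig:
    """NLM parameters.

    ``lambda_uv`` is the smoothness parameter λ in uV; ``None`` selects
    0.6 x a robust noise-SD estimate from the median absolute successive
    difference, making the stage scale-free.  The patch holds
    ``2*patch_half_width + 1`` samples; the search neighborhood N(i) spans
    ``±search_half_width`` samples.  ``kernel`` is the weight function over
    patch offsets: ``uniform`` is the plain patch distance, ``gaussian``
    tapers offsets with SD ``patch_half_width / 2`` (normalized to the same
    total mass as the uniform kernel, so λ is comparable between the two).
    """

    lambda_uv: float | None = None
    patch_half_width: int = 10
    search_half_width: int = 300
    kernel: str = "gaussian"

    def __post_init__(self) -> None:
        if self.lambda_uv is not None and self.lambda_uv <= 0:
            raise ValueError("lambda must be positive")
        if self.patch_half_width < 1:
            raise ValueError("patch_half_width must be >= 1")
        if self.search_half_width < self.patch_half_width:
            raise ValueError("search_half_width must be >= patch_half_width")
        if self.kernel not in ("uniform", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @property
    def patch_len(self) -> int:
        return 2 * self.patch_half_width + 1

    def kernel_weights(self) -> np.ndarray:
        """Taper g(d) over patch offsets d = -h..h, with sum(g) = patch_len."""
        d = np.arange(-self.patch_half_width, self.patch_half_width + 1, dtype=float)
        if self.kernel == "uniform":
            return np.ones_like(d)
        sd = self.patch_half_width / 2.0
        g = np.exp(-0.5 * (d / sd) ** 2)
        return g * (self.patch_len / g.sum())


def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust noise SD: 1.4826 * median|successive difference| / sqrt(2)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return 1.4826 * float(np.median(np.abs(np.diff(x)))) / math.sqrt(2.0)


def nlm_denoise(x: np.ndarray, cfg: NLMConfig = NLMConfig()) -> np.ndarray:
    """Non-local-means smoothing of a 1-D series.

    Vectorized over search shifts: for each shift s the squared patch
    distance for all centers is a short convolution, after which weights
    and the running weighted average accumulate in O(n) per shift.  Output
    values are convex combinations of input values inside each search
    window, so min/max bounds of the input are never exceeded.
    """
    d = np.asarray(x, dtype=float)
    n = d.size
    if n <= 2 * (cfg.search_half_width + cfg.patch_half_width):
        raise ValueError(
            f"signal length {n} too short for search_half_width "
            f"{cfg.search_half_width} and patch_half_width {cfg.patch_half_width}"
        )
    lam = cfg.lambda_uv
    if lam is None:
        lam = 0.6 * estimate_noise_sd(d)
        if lam <= 0:
            lam = 1e-12  # constant/degenerate input: all weights become 1
    g = cfg.kernel_weights()
    h = cfg.patch_half_width

    num = np.zeros(n)
    den = np.zeros(n)
    inv = 1.0 / (2.0 * lam * lam)
    for s in range(-cfg.search_half_width, cfg.search_half_width + 1):
        lo = max(0, -s)
        hi = n - 1 - max(0, s)  # centers i with both i and j = i+s in range
        m = hi - lo + 1
        if m <= 0:
            continue
        diff = d[lo:hi + 1] - d[lo + s:hi + s + 1]
        sq = diff * diff
        # conv[i - lo + h] = sum_d g(d) * sq[i - lo + d], with offsets whose
        # sample for either patch falls off the signal contributing nothing
        dist2 = np.convolve(sq, g, mode="full")[h:h + m]
        mass = np.convolve(np.ones(m), g, mode="full")[h:h + m]
        w = np.exp(-dist2 * inv / mass)
        num[lo:hi + 1] += w * d[lo + s:hi + s + 1]
        den[lo:hi + 1] += w
    return num / den


def denoise_signal(
    x: np.ndarray,
    lowpass: LowpassSpec | None = None,
    loess: LoessSpec | None = None,
    nlm: NLMConfig | None = None,
    fs: float = 500.0,
) -> np.ndarray:
    """Run one lead through the fixed stage order Butterworth -> LOESS -> NLM."""
    lp = lowpass if lowpass is not None else LowpassSpec(fs=fs)
    filt = design_lowpass(lp)
    y = apply_zero_phase(filt, x)
    y = remove_baseline(y, loess if loess is not None else LoessSpec())
    return nlm_denoise(y, nlm if nlm is not None else NLMConfig())


def denoise_record(
    record: ECGRecord,
    lowpass: LowpassSpec | None = None,
    loess: LoessSpec | None = None,
    nlm: NLMConfig | None = None,
) -> ECGRecord:
    """Denoise every lead independently; shape and lead order are preserved."""
    lp = lowpass if lowpass is not None else LowpassSpec(fs=record.fs)
    out = np.empty_like(record.samples)
    for j, name in enumerate(record.leads):
        try:
            out[:, j] = denoise_signal(record.samples[:, j], lp, loess, nlm, fs=record.fs)
        except Exception as exc:
            raise RuntimeError(f"denoising failed on lead {name}: {exc}") from exc
    return record.with_samples(out)
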