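"""ERP front end: filtering, epoching, denoising, and instantaneous phase.

Turns a continuous EEG channel (or a ready-made trials-by-samples epoch
matrix) into the circular series the smoother consumes: each trial's
instantaneous phase at a chosen post-stimulus latency, obtained from the
complex wavelet coefficient at a fixed scale,

    p_{k,b} = atan2(Im w_{k,b}, Re w_{k,b})  in [-pi, pi),

with the sixth derivative of the complex Gaussian as the analyzing wavelet.
The column of the phase matrix at one latency, read down the trials, is a
circular time series whose concentration tracks trial-to-trial phase
locking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import uniform_filter
from scipy.signal import filtfilt, firwin

from .circular import wrap_angle

__all__ = [
    "ERPImage",
    "PhaseMatrix",
    "bandpass_and_segment",
    "reject_artifacts",
    "nlm_denoise",
    "extract_phase",
    "column_series",
    "make_synthetic_erp",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ERPImage:
    """Stacked post-stimulus epochs: rows are trials, columns samples (uV)."""

    trials: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        t = np.atleast_2d(np.asarray(self.trials, float))
        if not np.all(np.isfinite(t)):
            raise ValueError("epoch matrix must be finite")
        object.__setattr__(self, "trials", t)

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[1]

    @property
    def epoch_length_ms(self) -> float:
        return 1000.0 * self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class PhaseMatrix:
    """Instantaneous phase per trial and latency, in [-pi, pi).

    ``mask`` flags entries whose wavelet coefficient had zero magnitude
    (phase undefined, stored as 0).
    """

    phases: np.ndarray
    scale: float
    sampling_rate: float
    mask: np.ndarray

    @property
    def latencies_ms(self) -> np.ndarray:
        return 1000.0 * np.arange(self.phases.shape[1]) / self.sampling_rate


def bandpass_and_segment(
    raw: np.ndarray,
    events: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = (1.0, 30.0),
    filter_order: int = 1000,
    epoch_ms: float = 800.0,
) -> ERPImage:
    """Zero-phase FIR bandpass, then cut post-stimulus epochs.

    The FIR filter (default order 1000, 1-30 Hz) is applied forward and
    backward (filtfilt) so the passband has exactly zero phase distortion —
    essential when the quantity of interest *is* the phase.  Epochs cover
    ``epoch_ms`` after each event onset (410 samples at 512 Hz and the
    default 800 ms); events whose epoch would run past the end of the
    recording are dropped with a logged count.
    """
    raw = np.asarray(raw, float)
    events = np.asarray(events, int)
    if raw.ndim != 1:
        raise ValueError("raw must be a single channel (1-D)")
    m = int(round(epoch_ms / 1000.0 * sampling_rate))
    taps = firwin(
        filter_order + 1, band, pass_zero=False, fs=sampling_rate
    )
    filtered = filtfilt(taps, [1.0], raw)
    keep = events[(events >= 0) & (events + m <= raw.size)]
    dropped = events.size - keep.size
    if dropped:
        logger.info("dropped %d events too close to the recording edge", dropped)
    if keep.size == 0:
        raise ValueError("no event leaves room for a full epoch")
    epochs = np.stack([filtered[e: e + m] for e in keep])
    return ERPImage(trials=epochs, sampling_rate=sampling_rate)


def reject_artifacts(image: ERPImage, threshold_uv: float = 50.0) -> ERPImage:
    """Drop trials containing any sample with |amplitude| > threshold."""
    bad = np.any(np.abs(image.trials) > threshold_uv, axis=1)
    if bad.all():
        raise ValueError("artifact rejection removed every trial")
    if bad.any():
        logger.info("rejected %d/%d trials above %.1f uV",
                    int(bad.sum()), image.n_trials, threshold_uv)
    return ERPImage(trials=image.trials[~bad], sampling_rate=image.sampling_rate)


def nlm_denoise(
    image: ERPImage,
    patch_size: int = 3,
    search_window: int = 11,
    bandwidth: float | None = None,
) -> ERPImage:
    """Non-local means denoising of the 2-D ERP image.

    Time-locked stimulation makes ERP images highly self-similar across
    trials, which is exactly the structure NLM exploits: each pixel becomes
    a weighted average of pixels whose surrounding patches look alike,
    w ∝ exp(-d2/bandwidth^2) with d2 the patch-mean squared difference,
    taken over a (search_window x search_window) neighbourhood.

    ``bandwidth`` defaults to an estimate of the noise standard deviation
    (residual of a small local mean).  bandwidth -> 0 returns the input
    (only the identical self-patch keeps weight); bandwidth -> inf averages
    the whole search window.
    """
    if patch_size < 1 or patch_size % 2 == 0:
        raise ValueError("patch_size must be odd and positive")
    if search_window < 1 or search_window % 2 == 0:
        raise ValueError("search_window must be odd and positive")
    x = image.trials
    if min(x.shape) < patch_size:
        raise ValueError("image smaller than one patch")
    if bandwidth is None:
        bandwidth = float(np.std(x - uniform_filter(x, size=3))) or 1.0
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    half = search_window // 2
    pad = half + patch_size // 2
    xp = np.pad(x, pad, mode="reflect")
    num = np.zeros_like(x)
    den = np.zeros_like(x)
    n0, n1 = x.shape
    c = pad  # origin of the unpadded image inside xp
    base = xp[c: c + n0, c: c + n1]
    for dy in range(-half, half + 1):
        for dx in range(-half, half + 1):
            shifted = xp[c + dy: c + dy + n0, c + dx: c + dx + n1]
            d2 = uniform_filter((base - shifted) ** 2, size=patch_size)
            with np.errstate(over="ignore", under="ignore"):
                w = np.exp(-d2 / bandwidth**2)
            num += w * shifted
            den += w
    return ERPImage(trials=num / den, sampling_rate=image.sampling_rate)


def extract_phase(
    image: ERPImage, scale: float = 40.0, wavelet: str = "cgau6"
) -> PhaseMatrix:
    """Instantaneous phase of every trial at a fixed wavelet scale.

    Complex wavelet coefficients are computed per trial at translations on
    every sample (continuous wavelet transform at the single scale ``a``),
    with the complex Gaussian derivative family; phase is the atan2 of the
    coefficient's imaginary and real parts, canonically in [-pi, pi).
    Magnitude does not enter, so the phase matrix is invariant to per-trial
    amplitude scaling.  Zero-magnitude coefficients get phase 0 and a mask
    flag.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    coeffs, _ = pywt.cwt(image.trials, [scale], wavelet, axis=-1)
    w = coeffs[0]
    mask = w == 0
    phases = np.where(mask, 0.0, wrap_angle(np.angle(w)))
    return PhaseMatrix(
        phases=phases,
        scale=float(scale),
        sampling_rate=image.sampling_rate,
        mask=mask,
    )


def column_series(pm: PhaseMatrix, latency_ms: float) -> np.ndarray:
    """The N phases at the sample nearest to ``latency_ms`` — the smoother's
    observation sequence for that analysis latency."""
    idx = int(round(latency_ms / 1000.0 * pm.sampling_rate))
    if not 0 <= idx < pm.phases.shape[1]:
        raise ValueError(
            f"latency {latency_ms} ms outside the epoch "
            f"(0..{1000.0 * (pm.phases.shape[1] - 1) / pm.sampling_rate:.1f} ms)"
        )
    return pm.phases[:, idx].copy()


def make_synthetic_erp(
    n_trials: int = 200,
    sampling_rate: float = 512.0,
    epoch_ms: float = 800.0,
    jitter_growth_ms: float = 12.0,
    noise_uv: float = 2.0,
    rng: np.random.Generator | None = None,
) -> ERPImage:
    """Synthetic ERP image for pipeline tests (no recordings involved).

    Each trial is an N1-P2-like template — a negative deflection near
    100 ms followed by a positive one near 200 ms — whose latency jitter
    grows linearly over trials (late trials are less phase-locked,
    mimicking a habituation-like loss of synchronization), plus white
    Gaussian noise.
    """
    rng = rng or np.random.default_rng(0)
    m = int(round(epoch_ms / 1000.0 * sampling_rate))
    t = np.arange(m) / sampling_rate * 1000.0  # ms
    rows = []
    for k in range(n_trials):
        jitter = rng.normal(0.0, jitter_growth_ms * (k + 1) / n_trials)
        template = -8.0 * np.exp(-((t - 100.0 - jitter) ** 2) / (2 * 20.0**2))
        template += 6.0 * np.exp(-((t - 200.0 - jitter) ** 2) / (2 * 30.0**2))
        rows.append(template + rng.normal(0.0, noise_uv, m))
    return ERPImage(trials=np.array(rows), sampling_rate=sampling_rate)
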