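"""Reference-based neurogram intelligibility metrics.

Two classic indices comparing a degraded neurogram with a clean reference
(same token, normal-hearing periphery, no background noise):

* NSIM — an SSIM-style local comparison of intensity and structure over
  3x3 Gaussian-weighted windows.
* STMI — one minus the normalized residual between the spectro-temporal
  modulation energies of reference and degraded neurograms (rates 2-32 Hz,
  scales 0.25-8 cycles/octave).

Both operate on un-normalized spike-count neurograms and return values on a
0-1 scale. Neither is a calibrated predictor of absolute human
intelligibility; they are descriptive annotations of degradation severity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate

from .periphery import Neurogram

__all__ = ["MetricResult", "nsim", "stmi"]


@dataclass(frozen=True)
class MetricResult:
    name: str
    value: float
    reference_id: str = ""
    degraded_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError("metric value must lie in [0, 1]")


def _as_count_array(ng) -> np.ndarray:
    if isinstance(ng, Neurogram):
        if ng.normalized:
            raise ValueError("metrics operate on un-normalized count neurograms")
        return np.asarray(ng.values, dtype=np.float64)
    return np.asarray(ng, dtype=np.float64)


def _ids(ref, deg) -> tuple[str, str]:
    rid = ref.metadata.get("state_id", "") if isinstance(ref, Neurogram) else ""
    did = deg.metadata.get("state_id", "") if isinstance(deg, Neurogram) else ""
    return rid, did


def _gaussian_kernel_3x3(sigma: float = 0.5) -> np.ndarray:
    ax = np.arange(-1, 2, dtype=np.float64)
    k = np.exp(-0.5 * (ax[:, None] ** 2 + ax[None, :] ** 2) / sigma**2)
    return k / k.sum()


def nsim(reference, degraded, c1_scale: float = 0.01, c3_scale: float = 0.03) -> MetricResult:
    """Neurogram similarity: mean local intensity x structure agreement.

    Local means, variances, and covariance are computed under a 3x3 Gaussian
    window (sigma 0.5). With r the reference and d the degraded window
    statistics, each window scores l * s with

        l = (2 mu_r mu_d + C1) / (mu_r^2 + mu_d^2 + C1)
        s = (cov_rd + C3) / (sd_r sd_d + C3)

    where C1 = (0.01 L)^2 and C3 = (0.03 L)^2 / 2 scale with the reference
    dynamic range L, so joint rescaling of both inputs leaves the result
    unchanged. Constant equal inputs score 1 (the stabilizing constants
    prevent 0/0).
    """
    r = _as_count_array(reference)
    d = _as_count_array(degraded)
    if r.shape != d.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {d.shape}")

    L = float(r.max() - r.min())
    if L == 0.0:
        L = 1.0  # constant reference: constants only set the 0/0 limit
    c1 = (c1_scale * L) ** 2
    c3 = (c3_scale * L) ** 2 / 2.0

    k = _gaussian_kernel_3x3()
    mu_r = correlate(r, k, mode="nearest")
    mu_d = correlate(d, k, mode="nearest")
    var_r = np.maximum(correlate(r * r, k, mode="nearest") - mu_r**2, 0.0)
    var_d = np.maximum(correlate(d * d, k, mode="nearest") - mu_d**2, 0.0)
    cov = correlate(r * d, k, mode="nearest") - mu_r * mu_d

    luminance = (2.0 * mu_r * mu_d + c1) / (mu_r**2 + mu_d**2 + c1)
    structure = (cov + c3) / (np.sqrt(var_r * var_d) + c3)
    value = float(np.clip(np.mean(luminance * structure), 0.0, 1.0))
    rid, did = _ids(reference, degraded)
    return MetricResult(name="NSIM", value=value, reference_id=rid, degraded_id=did)


def _modulation_energy(values: np.ndarray, frame_rate_hz: float,
                       channels_per_octave: float,
                       rate_band: tuple, scale_band: tuple) -> np.ndarray:
    """Spectro-temporal modulation energy restricted to the passband.

    2-D Fourier magnitude-squared of the mean-removed neurogram; temporal
    axis in Hz, spectral axis in cycles/octave (the CF grid is log-spaced,
    so channel index is linear in octaves).
    """
    x = values - values.mean()
    spec = np.abs(np.fft.fft2(x)) ** 2
    rates = np.fft.fftfreq(values.shape[1], d=1.0 / frame_rate_hz)
    scales = np.fft.fftfreq(values.shape[0], d=1.0 / channels_per_octave)
    rate_ok = (np.abs(rates) >= rate_band[0]) & (np.abs(rates) <= rate_band[1])
    scale_ok = (np.abs(scales) >= scale_band[0]) & (np.abs(scales) <= scale_band[1])
    return spec[np.ix_(scale_ok, rate_ok)]


def stmi(reference, degraded, rate_band: tuple = (2.0, 32.0),
         scale_band: tuple = (0.25, 8.0)) -> MetricResult:
    """Spectro-temporal modulation index.

    Both neurograms are projected onto modulation energy over rates 2-32 Hz
    and scales 0.25-8 cyc/oct; STMI = 1 - ||T - N||^2 / ||T||^2 with T the
    reference energy, clamped to [0, 1]. Identical inputs give 1; an all-zero
    degraded input gives 0; an all-zero reference is undefined and rejected.
    """
    ref_ng = reference if isinstance(reference, Neurogram) else None
    r = _as_count_array(reference)
    d = _as_count_array(degraded)
    if r.shape != d.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {d.shape}")
    if not np.any(r):
        raise ValueError("all-zero reference: STMI undefined")

    frame_rate = ref_ng.frame_rate_hz if ref_ng is not None else 100.0
    if ref_ng is not None:
        octaves = np.log2(ref_ng.cf_grid.cfs[-1] / ref_ng.cf_grid.cfs[0])
    else:
        octaves = np.log2(8000.0 / 100.0)
    channels_per_octave = (r.shape[0] - 1) / octaves

    T = _modulation_energy(r, frame_rate, channels_per_octave, rate_band, scale_band)
    N = _modulation_energy(d, frame_rate, channels_per_octave, rate_band, scale_band)
    t_norm = float(np.sum(T**2))
    if t_norm == 0.0:
        raise ValueError("reference has no modulation energy in the passband")
    value = float(np.clip(1.0 - np.sum((T - N) ** 2) / t_norm, 0.0, 1.0))
    rid, did = _ids(reference, degraded)
    return MetricResult(name="STMI", value=value, reference_id=rid, degraded_id=did)
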