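"""Orthogonalized power-envelope connectivity, frequency resolved.

ROI time courses are decomposed with a short-time Fourier transform (1 s
Hann window, 50% hop, 1 Hz bins).  For each ROI pair and frequency bin the
connectivity is the Pearson correlation between log power envelopes after
pairwise orthogonalization: the component of one complex coefficient series
collinear with the other is removed per time frame, so zero-lag field
spread (volume conduction / leakage) cannot produce spurious coupling.
Correlations are Fisher z-transformed and averaged over the bins of the
canonical delta/theta/alpha/beta/gamma bands.

Degenerate pairs (e.g. exactly collinear signals, whose orthogonalized part
vanishes) yield NaN sentinels that are excluded from band averages and
propagated when nothing remains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .inverse import ROITimecourses
from .simulate import BANDS

MIN_FRAMES = 30
MIN_VALID_FRACTION = 0.9


@dataclass
class TimeFrequencyRepresentation:
    """Complex STFT coefficients per ROI, frequency bin and time frame."""

    coeffs: np.ndarray      # (n_roi, n_bins, n_frames)
    freqs: np.ndarray       # bin centres, Hz
    times: np.ndarray       # frame centres, s
    rate: float
    window_s: float
    hop_s: float
    roi_names: tuple[str, ...]
    roi_networks: tuple[str, ...]

    @property
    def n_frames(self) -> int:
        return self.coeffs.shape[2]


@dataclass
class BandConnectivity:
    """ROI x ROI Fisher-z envelope correlations per frequency band."""

    z: dict[str, np.ndarray]
    bands: dict[str, tuple[float, float]]
    roi_names: tuple[str, ...]
    roi_networks: tuple[str, ...]
    subject: str = ""
    session: str = ""


def stft_decompose(
    roi_tc: ROITimecourses, window_s: float = 1.0, hop_s: float = 0.5
) -> TimeFrequencyRepresentation:
    """Hann-tapered STFT with 1 Hz bin spacing; only full frames are kept."""
    n = roi_tc.data.shape[1]
    nwin = int(round(window_s * roi_tc.rate))
    if nwin > n:
        raise ValueError("STFT window is longer than the recording")
    if n / roi_tc.rate < 60.0:
        warnings.warn(
            "recording shorter than 60 s; envelope correlations may be unstable",
            RuntimeWarning,
        )
    hop = int(round(hop_s * roi_tc.rate))
    sft = ShortTimeFFT(
        hann(nwin, sym=False), hop, fs=roi_tc.rate, mfft=nwin, fft_mode="onesided"
    )
    p0 = sft.lower_border_end[1]
    p1 = sft.upper_border_begin(n)[1]
    coeffs = sft.stft(roi_tc.data, p0=p0, p1=p1, axis=1)
    times = sft.t(n, p0=p0, p1=p1)
    freqs = sft.f
    keep = (freqs >= 1.0) & (freqs <= 80.0)
    return TimeFrequencyRepresentation(
        coeffs=coeffs[:, keep, :],
        freqs=freqs[keep],
        times=times,
        rate=roi_tc.rate,
        window_s=window_s,
        hop_s=hop_s,
        roi_names=roi_tc.names,
        roi_networks=roi_tc.networks,
    )


class _EnvelopeCache:
    """Per-ROI magnitudes and log powers shared across the pair loop.

    Stored in single precision: the sampling error of envelope correlations
    over O(100) frames dwarfs float32 rounding by many orders of magnitude.
    """

    def __init__(self, coeffs: np.ndarray):
        self.coeffs = np.asarray(coeffs, np.complex64)
        self.power = np.abs(self.coeffs) ** 2
        self.mag = np.sqrt(self.power)
        with np.errstate(divide="ignore"):
            self.log_power = np.where(
                self.power > 0, np.log(self.power), np.float32(np.nan)
            )
        self.mean_power = self.power.mean(axis=2, keepdims=True)


def _directed_log_env(
    cache: _EnvelopeCache, i: int, j: int
) -> tuple[np.ndarray, np.ndarray]:
    """Log power of ROI i and of ROI j orthogonalized on i, NaN where undefined.

    Frames with (numerically) zero magnitude in either series, or where the
    orthogonalized part vanishes, become NaN and are later dropped pairwise
    per frequency bin.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ortho = np.imag(cache.coeffs[j] * np.conj(cache.coeffs[i])) / cache.mag[i]
        portho = ortho**2
        ly = np.where(portho > 1e-15 * cache.mean_power[j], np.log(portho), np.nan)
    lx = cache.log_power[i].copy()
    bad = ~(np.isfinite(lx) & np.isfinite(ly))
    if bad.any():
        lx[bad] = np.nan
        ly[bad] = np.nan
    return lx, ly


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per row over pairwise-finite entries; NaN when degenerate."""
    valid = np.isfinite(a) & np.isfinite(b)
    n = valid.sum(axis=1)
    if valid.all():
        da = a - a.mean(axis=1, keepdims=True)
        db = b - b.mean(axis=1, keepdims=True)
    else:
        a = np.where(valid, a, 0.0)
        b = np.where(valid, b, 0.0)
        with np.errstate(invalid="ignore"):
            da = np.where(valid, a - (a.sum(1) / n)[:, None], 0.0)
            db = np.where(valid, b - (b.sum(1) / n)[:, None], 0.0)
    cov = (da * db).sum(1)
    va = (da**2).sum(1)
    vb = (db**2).sum(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.sqrt(va * vb)
    enough = n >= np.maximum(MIN_FRAMES, MIN_VALID_FRACTION * a.shape[1])
    r[~enough | (va <= 0) | (vb <= 0)] = np.nan
    return r


def _pair_bins(cache: _EnvelopeCache, i: int, j: int) -> np.ndarray:
    lx, ly_on_x = _directed_log_env(cache, i, j)
    ly, lx_on_y = _directed_log_env(cache, j, i)
    r_xy = _rowwise_pearson(lx, ly_on_x)
    r_yx = _rowwise_pearson(ly, lx_on_y)
    return (r_xy + r_yx) / 2.0


def orthogonalized_envelope_correlation_bins(
    tfr: TimeFrequencyRepresentation, roi_i: int, roi_j: int
) -> np.ndarray:
    """Symmetrized orthogonalized log-power-envelope correlation per bin."""
    return _pair_bins(_EnvelopeCache(tfr.coeffs), roi_i, roi_j)


def _all_pairs_r_bins(cache: _EnvelopeCache) -> np.ndarray | None:
    """Vectorized (n_roi, n_roi, n_bins) symmetrized r for the generic case.

    Returns None when any frame is degenerate (zero magnitude or vanishing
    orthogonalized power), in which case the caller falls back to the
    per-pair path with pairwise frame dropping.
    """
    Z = cache.coeffs
    lx = cache.log_power
    if not np.isfinite(lx).all():
        return None
    n_roi = Z.shape[0]
    cross = np.einsum("jft,ift->ijft", Z, np.conj(Z))
    ortho = np.imag(cross) / cache.mag[:, None]
    portho = ortho**2
    off = ~np.eye(n_roi, dtype=bool)
    ok = portho > 1e-15 * cache.mean_power[None, :]
    if not ok[off].all():
        return None
    idx = np.arange(n_roi)
    portho[idx, idx] = 1.0  # self-pairs are discarded; keep the log finite
    ly = np.log(portho)
    dx = (lx - lx.mean(-1, keepdims=True)).astype(np.float32)
    vx = (dx.astype(np.float64) ** 2).sum(-1)
    dy = ly - ly.mean(-1, keepdims=True)
    cov = np.einsum("ift,ijft->ijf", dx, dy, dtype=np.float64)
    vy = np.einsum("ijft,ijft->ijf", dy, dy, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_xy = cov / np.sqrt(vx[:, None] * vy)
    return (r_xy + r_xy.transpose(1, 0, 2)) / 2.0


def orthogonalized_envelope_correlation(
    tfr: TimeFrequencyRepresentation, roi_pair: tuple[int, int], f_bin: float
) -> float:
    """Correlation for one ROI pair at one frequency bin (NaN sentinel)."""
    if tfr.n_frames < MIN_FRAMES:
        raise ValueError(f"need at least {MIN_FRAMES} frames, got {tfr.n_frames}")
    k = int(np.argmin(np.abs(tfr.freqs - f_bin)))
    return float(orthogonalized_envelope_correlation_bins(tfr, *roi_pair)[k])


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing z = atanh(r); NaN sentinels pass through."""
    r_arr = np.asarray(r, float)
    if np.any(np.abs(r_arr[np.isfinite(r_arr)]) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r_arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def band_connectivity_matrix(
    tfr: TimeFrequencyRepresentation,
    bands: dict[str, tuple[float, float]] | None = None,
    subject: str = "",
    session: str = "",
) -> BandConnectivity:
    """Symmetric ROI x ROI matrix of band-averaged Fisher-z correlations.

    Bin membership is half-open [lo, hi); NaN bins are excluded from the
    band mean and propagate only when a whole band is empty.
    """
    if tfr.n_frames < MIN_FRAMES:
        raise ValueError(f"need at least {MIN_FRAMES} frames, got {tfr.n_frames}")
    bands = bands or dict(BANDS)
    n_roi = tfr.coeffs.shape[0]
    band_sel = {
        name: (tfr.freqs >= lo) & (tfr.freqs < hi) for name, (lo, hi) in bands.items()
    }
    for name, sel in band_sel.items():
        if not sel.any():
            raise ValueError(f"band {name!r} covers no frequency bins")
    z = {name: np.full((n_roi, n_roi), np.nan) for name in bands}
    cache = _EnvelopeCache(tfr.coeffs)
    r_all = _all_pairs_r_bins(cache)
    if r_all is not None:
        z_all = np.arctanh(r_all)
        for name, sel in band_sel.items():
            mat = z_all[:, :, sel].mean(axis=2)
            np.fill_diagonal(mat, np.nan)
            z[name] = mat
    else:
        for i in range(n_roi):
            for j in range(i + 1, n_roi):
                r_bins = _pair_bins(cache, i, j)
                z_bins = fisher_z(r_bins)
                for name, sel in band_sel.items():
                    vals = z_bins[sel]
                    vals = vals[np.isfinite(vals)]
                    if len(vals):
                        z[name][i, j] = z[name][j, i] = vals.mean()
    return BandConnectivity(
        z=z,
        bands=bands,
        roi_names=tfr.roi_names,
        roi_networks=tfr.roi_networks,
        subject=subject,
        session=session,
    )
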