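"""Sensor-level cleaning: bad channels, filtering, referencing, ICA.

The stages mirror standard hdEEG resting-state practice: flag low-quality
channels, rebuild them from spatial neighbours, band-pass 1-80 Hz, switch to
the average reference, and attenuate ocular/muscular activity by zeroing the
corresponding independent components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve, firwin, welch
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .recording import SensorRecording


@dataclass
class BadChannelCriteria:
    """Thresholds for the three bad-channel rules (all configurable)."""

    variance_z: float = 4.0          # robust z-score of channel variance
    flat_fraction: float = 1e-3      # variance below this fraction of median
    neighbor_corr: float = 0.2       # correlation with mean of neighbours
    n_neighbors: int = 6


@dataclass
class ICADecomposition:
    """Fitted ICA with per-component artifact labels.

    ``mixing @ unmixing`` is the identity on the retained subspace.
    """

    mixing: np.ndarray       # (n_channels, n_components)
    unmixing: np.ndarray     # (n_components, n_channels)
    sources: np.ndarray      # (n_components, n_samples)
    channel_mean: np.ndarray
    labels: list[str]        # ocular | muscle | none
    scores: dict[str, np.ndarray]


def detect_bad_channels(
    rec: SensorRecording, criteria: BadChannelCriteria | None = None
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Flag channels by variance outliers, flatness and neighbour decorrelation.

    Returns the boolean mask plus per-channel diagnostics.  The variance rule
    is a median/MAD robust z-score of the *log* variance: channel variance is
    multiplicatively spread across a scalp topography, and robust statistics
    keep a single extreme channel from masking itself.
    """
    if rec.n_channels < 8:
        raise ValueError("need at least 8 channels for bad-channel statistics")
    criteria = criteria or BadChannelCriteria()
    var = rec.data.var(axis=1)
    with np.errstate(divide="ignore"):
        log_var = np.log(var)
    med = np.median(log_var)
    z = np.zeros_like(var)
    if np.isfinite(med):
        mad = np.median(np.abs(log_var - med))
        if mad > 0:
            z = (log_var - med) / (1.4826 * mad)
    flat = var < criteria.flat_fraction * np.median(var)

    pre_flagged = (z > criteria.variance_z) | flat
    ncorr = np.ones(rec.n_channels)
    if rec.positions is not None and not pre_flagged.all():
        dist = np.linalg.norm(
            rec.positions[:, None, :] - rec.positions[None, :, :], axis=-1
        )
        np.fill_diagonal(dist, np.inf)
        # channels already failing the variance rules cannot serve as
        # neighbours, or one noisy channel would drag its whole region down
        dist[:, pre_flagged] = np.inf
        for ch in range(rec.n_channels):
            nbrs = np.argsort(dist[ch])[: criteria.n_neighbors]
            ref = rec.data[nbrs].mean(axis=0)
            sd = rec.data[ch].std() * ref.std()
            ncorr[ch] = (
                float(np.corrcoef(rec.data[ch], ref)[0, 1]) if sd > 0 else 0.0
            )
    mask = pre_flagged | (ncorr < criteria.neighbor_corr)
    if mask.all():
        raise ValueError("no usable channels: every channel was flagged")
    return mask, {"variance_z": z, "flat": flat, "neighbor_corr": ncorr}


def interpolate_bad_channels(
    rec: SensorRecording, bad_mask: np.ndarray, k: int = 6
) -> SensorRecording:
    """Rebuild each bad channel as an inverse-distance mean of good neighbours.

    Weights are 1/distance over the ``k`` nearest good channels, normalized
    to sum to 1.  Good channels pass through unchanged and the mask is
    cleared, with provenance noted in the history.
    """
    bad_mask = np.asarray(bad_mask, bool)
    if not bad_mask.any():
        return rec.copy_with(bad_mask=bad_mask.copy())
    if rec.positions is None:
        raise ValueError("channel positions are required for interpolation")
    good = np.nonzero(~bad_mask)[0]
    data = rec.data.copy()
    for ch in np.nonzero(bad_mask)[0]:
        d = np.linalg.norm(rec.positions[good] - rec.positions[ch], axis=1)
        if len(good) < 3:
            raise ValueError(
                f"channel {rec.labels[ch]} has fewer than 3 good neighbours"
            )
        order = np.argsort(d)[:k]
        w = 1.0 / np.maximum(d[order], 1e-9)
        w /= w.sum()
        data[ch] = w @ rec.data[good[order]]
    return rec.copy_with(
        data=data,
        bad_mask=np.zeros_like(bad_mask),
        history=rec.history
        + [f"interpolated channels {[rec.labels[i] for i in np.nonzero(bad_mask)[0]]}"],
    )


def _bandpass_kernel(rate: float, low: float, high: float) -> np.ndarray:
    """Linear-phase FIR band-pass, Hamming window, 25% transition widths."""
    trans = 0.25 * low
    ntaps = int(np.ceil(3.3 * rate / trans))
    ntaps += 1 - ntaps % 2  # odd length -> exactly zero-phase when centred
    return firwin(ntaps, [low, high], fs=rate, pass_zero=False, window="hamming")


def filter_and_rereference(
    rec: SensorRecording, low: float = 1.0, high: float = 80.0
) -> SensorRecording:
    """Zero-phase 1-80 Hz band-pass, then subtract the per-sample channel mean."""
    if rec.rate <= 2 * high:
        raise ValueError(
            f"sampling rate {rec.rate} Hz violates Nyquist for a {high} Hz band edge"
        )
    h = _bandpass_kernel(rec.rate, low, high)
    # symmetric (linear-phase) kernel applied centred == zero-phase filtering;
    # demeaning plus reflect padding keeps DC rejection exact at the edges
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    pad = (len(h) - 1) // 2
    padded = np.pad(data, ((0, 0), (pad, pad)), mode="reflect")
    data = fftconvolve(padded, h[None, :], mode="valid", axes=1)
    data -= data.mean(axis=0, keepdims=True)
    return rec.copy_with(
        data=data,
        reference="average",
        history=rec.history + [f"bandpass {low}-{high} Hz; average reference"],
    )


def rereference_average(rec: SensorRecording) -> SensorRecording:
    """Average reference only (idempotent)."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data, reference="average")


def remove_artifact_components(
    rec: SensorRecording,
    eog_reference_channels: list[str] | None,
    seed: int,
    eog_corr_threshold: float = 0.7,
    muscle_band: tuple[float, float] = (30.0, 80.0),
    muscle_power_fraction: float = 0.6,
    max_iter: int = 1000,
) -> tuple[SensorRecording, ICADecomposition]:
    """Fit ICA, label ocular/muscle components, remix the rest.

    A component is ocular when its absolute correlation with any EOG
    reference channel exceeds ``eog_corr_threshold``, and muscular when more
    than ``muscle_power_fraction`` of its power lies in 30-80 Hz.  Labelled
    components are zeroed and the remainder mixed back with the estimated
    weights.
    """
    if rec.reference != "average":
        raise ValueError("run filter_and_rereference before ICA")
    n_comp = min(rec.n_channels - 1, 40)
    # deflation converges component-by-component, which is far more robust
    # than the parallel update when trailing components are near-Gaussian
    ica = FastICA(
        n_components=n_comp,
        algorithm="deflation",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=1e-3,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            sources = ica.fit_transform(rec.data.T).T  # (n_comp, n_samples)
        except ConvergenceWarning as err:
            raise RuntimeError(
                f"ICA did not converge within {max_iter} iterations: {err}"
            ) from err

    eog_refs = np.empty((0, rec.n_samples))
    if eog_reference_channels:
        idx = [rec.labels.index(lbl) for lbl in eog_reference_channels]
        eog_refs = rec.data[idx]

    labels: list[str] = []
    eog_scores = np.zeros(n_comp)
    muscle_scores = np.zeros(n_comp)
    for c in range(n_comp):
        if len(eog_refs):
            cors = [abs(np.corrcoef(sources[c], ref)[0, 1]) for ref in eog_refs]
            eog_scores[c] = max(cors)
        f, pxx = welch(sources[c], fs=rec.rate, nperseg=min(1024, rec.n_samples))
        band = (f >= muscle_band[0]) & (f < muscle_band[1])
        total = pxx[(f >= 1.0)].sum()
        muscle_scores[c] = pxx[band].sum() / total if total > 0 else 0.0
        if eog_scores[c] > eog_corr_threshold:
            labels.append("ocular")
        elif muscle_scores[c] > muscle_power_fraction:
            labels.append("muscle")
        else:
            labels.append("none")

    keep = np.array([lbl == "none" for lbl in labels])
    mixing = ica.mixing_  # (n_channels, n_comp)
    cleaned = mixing[:, keep] @ sources[keep] + ica.mean_[:, None]
    cleaned -= cleaned.mean(axis=0, keepdims=True)  # restore average reference
    removed = [f"{lbl}:{i}" for i, lbl in enumerate(labels) if lbl != "none"]
    out = rec.copy_with(
        data=cleaned,
        history=rec.history + [f"ICA seed={seed} removed={removed or 'none'}"],
    )
    decomp = ICADecomposition(
        mixing=mixing,
        unmixing=ica.components_,
        sources=sources,
        channel_mean=ica.mean_,
        labels=labels,
        scores={"eog_corr": eog_scores, "muscle_power_fraction": muscle_scores},
    )
    return out, decomp
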