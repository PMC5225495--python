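"""Narrowband filtering, analytic-signal phases, and tSNR quality control.

The processing chain mirrors standard low-frequency BOLD phase analysis:
linear detrend, zero-phase Butterworth band-pass inside the band of
interest (default 0.04-0.07 Hz), Hilbert transform to the analytic signal
z(t) = x(t) + i H[x(t)], and removal of a few points at each end to
suppress transform border effects.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .panels import PhasePanel, TimeSeriesPanel

__all__ = [
    "bandpass_filter",
    "bandpass_values",
    "analytic_phase",
    "analytic_phase_values",
    "phase_pipeline_values",
    "tsnr",
]

#: Butterworth order used for the zero-phase band-pass (applied
#: forward-backward, so the effective attenuation is doubled).
DEFAULT_FILTER_ORDER = 4

#: Points removed from each end of the analytic signal.
DEFAULT_TRIM = 10


def _bandpass_sos(low_hz: float, high_hz: float, tr_seconds: float, order: int):
    nyq = 1.0 / (2.0 * tr_seconds)
    if not (0.0 < low_hz < high_hz):
        raise ValueError(
            f"band edges must satisfy 0 < low < high; got ({low_hz}, {high_hz})"
        )
    if high_hz >= nyq:
        raise ValueError(
            f"high band edge {high_hz} Hz is at or above the Nyquist frequency "
            f"{nyq:.6g} Hz for TR = {tr_seconds} s"
        )
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds,
                      output="sos")


def bandpass_values(
    values: np.ndarray,
    tr_seconds: float,
    low_hz: float,
    high_hz: float,
    order: int = DEFAULT_FILTER_ORDER,
    detrend: bool = True,
) -> np.ndarray:
    """Zero-phase band-pass along the last axis of an arbitrary-shape array.

    Detrends linearly first (the narrow pass-band makes the result
    insensitive to slow drifts, but detrending suppresses leakage through
    the filter transient).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    sos = _bandpass_sos(low_hz, high_hz, tr_seconds, order)
    min_len = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                              (sos[:, 5] == 0).sum()))
    if n <= min_len:
        raise ValueError(f"series too short to filter: {n} <= {min_len}")
    if detrend:
        values = sps.detrend(values, axis=-1, type="linear")
    # the narrow band has long transients: pad with the full series length
    # (also makes the forward-backward pass exactly time-reversal symmetric)
    out = sps.sosfiltfilt(sos, values, axis=-1, padlen=n - 1)
    # a band-pass passes no DC; remove the numerical residual exactly
    return out - out.mean(axis=-1, keepdims=True)


def bandpass_filter(
    panel: TimeSeriesPanel,
    low_hz: float = 0.04,
    high_hz: float = 0.07,
    order: int = DEFAULT_FILTER_ORDER,
    detrend: bool = True,
) -> TimeSeriesPanel:
    """Band-pass every node series of a panel (zero-phase Butterworth)."""
    filtered = bandpass_values(
        panel.values, panel.tr_seconds, low_hz, high_hz, order=order, detrend=detrend
    )
    return panel.with_values(filtered)


def analytic_phase_values(values: np.ndarray, trim: int = DEFAULT_TRIM):
    """Instantaneous phase and envelope along the last axis.

    Returns ``(phase, envelope)`` with ``trim`` points dropped from each
    end.  Phase is the argument of the analytic signal, wrapped to
    (-pi, pi]; envelope is its modulus.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[-1]
    if trim < 0:
        raise ValueError("trim must be nonnegative")
    if n <= 2 * trim + 1:
        raise ValueError(
            f"series of length {n} too short for trim {trim} per end"
        )
    z = sps.hilbert(values, axis=-1)
    sl = slice(trim, n - trim) if trim else slice(None)
    z = z[..., sl]
    phase = np.angle(z)
    # np.angle returns [-pi, pi]; map -pi to +pi for the half-open convention
    phase = np.where(phase <= -np.pi, np.pi, phase)
    return phase, np.abs(z)


def analytic_phase(panel: TimeSeriesPanel, trim: int = DEFAULT_TRIM) -> PhasePanel:
    """Analytic-signal phase/envelope of a (band-passed) panel.

    The caller is responsible for narrowband filtering first; a panel
    whose node means are large relative to their spread triggers a
    warning, as phases of non-zero-mean signals are not meaningful.
    """
    means = panel.values.mean(axis=1)
    sds = panel.values.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(means) / np.where(sds > 0, sds, np.inf)
    if np.any(ratio > 0.1):
        warnings.warn(
            "panel does not look band-passed (non-zero node means); "
            "instantaneous phases may be meaningless",
            stacklevel=2,
        )
    phase, envelope = analytic_phase_values(panel.values, trim=trim)
    return PhasePanel(
        phase=phase,
        envelope=envelope,
        tr_seconds=panel.tr_seconds,
        trim=trim,
        subject_id=panel.subject_id,
        group=panel.group,
        node_labels=list(panel.node_labels),
    )


def phase_pipeline_values(
    values: np.ndarray,
    tr_seconds: float,
    low_hz: float = 0.04,
    high_hz: float = 0.07,
    trim: int = DEFAULT_TRIM,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Filter -> analytic signal -> trim, returning phases only.

    Works on arrays of shape ``(..., n_nodes, n_timepoints)`` so that
    surrogate ensembles are pushed through exactly the same code path as
    the measured data.
    """
    filtered = bandpass_values(values, tr_seconds, low_hz, high_hz, order=order)
    phase, _ = analytic_phase_values(filtered, trim=trim)
    return phase


def tsnr(panel: TimeSeriesPanel, ddof: int = 1):
    """Temporal signal-to-noise ratio per node, and its subject mean.

    tSNR is the temporal mean divided by the temporal standard deviation.
    Zero-variance nodes are reported as NaN and excluded from the subject
    mean, with a warning.

    Returns
    -------
    per_node : ndarray of shape (n_nodes,)
    subject_mean : float
    """
    means = panel.values.mean(axis=1)
    sds = panel.values.std(axis=1, ddof=ddof)
    per_node = np.full(panel.n_nodes, np.nan)
    ok = sds > 0
    per_node[ok] = means[ok] / sds[ok]
    if not np.all(ok):
        bad = [panel.node_labels[k] for k in np.flatnonzero(~ok)]
        warnings.warn(
            f"zero-variance node(s) excluded from tSNR for "
            f"{panel.subject_id}: {bad}",
            stacklevel=2,
        )
    if not np.any(ok):
        raise ValueError("all nodes have zero temporal variance")
    return per_node, float(per_node[ok].mean())
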