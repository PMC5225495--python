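"""Phase-randomized Fourier surrogates and tests for genuine dynamics.

Surrogates are built by rotating the Fourier phases of the *unfiltered*
multivariate series with one common random phase sequence per surrogate
(the Prichard-Theiler construction): every node's amplitude spectrum —
hence its autocorrelation — is preserved exactly, and because all nodes
receive the same rotation the cross-spectra (hence lagged
cross-correlations) are preserved too.  Each surrogate is then pushed
through the identical filter -> analytic phase -> dFC pipeline as the
measured data.

Two tests compare measured one-sample T statistics with their surrogate
counterparts T*; in both, p = 1 - (#{T > T*} / n_surrogates), exactly the
strict-inequality count (an optional +1 correction is available but off
by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .dynamic_fc import coupling_cv_from_phases
from .panels import TimeSeriesPanel
from .signal_phase import phase_pipeline_values
from .static_fc import edge_columns

__all__ = [
    "SurrogateEnsemble",
    "phase_randomize",
    "phase_randomize_values",
    "build_surrogate_ensemble",
    "whole_brain_dynamics_curve",
    "edge_dynamics_test",
]


def phase_randomize_values(
    values: np.ndarray, n_surrogates: int, rng: np.random.Generator
) -> np.ndarray:
    """Common-rotation phase-randomized surrogates of a node x time matrix.

    Returns an array of shape ``(n_surrogates, n_nodes, n_timepoints)``.
    DC and (for even lengths) Nyquist bins are left untouched so the
    inverse transform is real.
    """
    values = np.asarray(values)
    if np.iscomplexobj(values):
        raise ValueError("phase randomization requires real-valued series")
    values = values.astype(float)
    n_time = values.shape[-1]
    spec = np.fft.rfft(values, axis=-1)  # (n_nodes, n_freq)
    n_freq = spec.shape[-1]
    # rotatable bins: positive frequencies excluding DC and the real
    # Nyquist bin of even-length series
    lo, hi = 1, n_freq - 1 if n_time % 2 == 0 else n_freq
    rot = np.ones((n_surrogates, 1, n_freq), dtype=complex)
    rot[:, 0, lo:hi] = np.exp(
        1j * rng.uniform(0.0, 2.0 * np.pi, size=(n_surrogates, hi - lo))
    )
    return np.fft.irfft(spec[None] * rot, n=n_time, axis=-1)


def phase_randomize(
    panel: TimeSeriesPanel, n_surrogates: int, seed: int
) -> Iterator[TimeSeriesPanel]:
    """Yield surrogate panels of one subject; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    surro = phase_randomize_values(panel.values, n_surrogates, rng)
    for s in range(n_surrogates):
        yield TimeSeriesPanel(
            values=surro[s],
            tr_seconds=panel.tr_seconds,
            subject_id=f"{panel.subject_id}_surr{s + 1:05d}",
            group=panel.group,
            node_labels=list(panel.node_labels),
        )


@dataclass
class SurrogateEnsemble:
    """dFC summaries of a surrogate ensemble over a cohort.

    ``dfc_sums`` has shape (n_surrogates, n_subjects): the per-subject sum
    of all unique dFC values in each surrogate dataset.  ``dfc`` holds the
    full (n_surrogates, n_kept_subjects, n_edges) coefficient-of-variation
    matrices for the subjects selected with ``keep_edges_for`` (typically
    the reference group), or None.
    """

    n_surrogates: int
    dfc_sums: np.ndarray
    subject_ids: list[str]
    seed: int
    dfc: Optional[np.ndarray] = None
    kept_subject_ids: Optional[list[str]] = None


def build_surrogate_ensemble(
    panels: Sequence[TimeSeriesPanel],
    n_surrogates: int,
    seed: int,
    low_hz: float = 0.04,
    high_hz: float = 0.07,
    trim: int = 10,
    keep_edges_for: Optional[Sequence[str]] = None,
    chunk_size: int = 200,
    ddof: int = 1,
) -> SurrogateEnsemble:
    """Generate surrogates for every subject and run the dFC pipeline.

    Surrogates are drawn from each subject's unfiltered panel and then
    filtered, Hilbert-transformed, trimmed and reduced to coefficients of
    variation with the same functions the measured data go through.
    ``keep_edges_for`` selects subject ids whose full per-edge surrogate
    matrices are retained (needed for the per-edge test); all subjects
    contribute dfc sums.
    """
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    keep = set(keep_edges_for) if keep_edges_for is not None else set()
    n_subj = len(panels)
    tr = panels[0].tr_seconds
    sums = np.empty((n_surrogates, n_subj))
    kept: list[np.ndarray] = []
    kept_ids: list[str] = []
    children = np.random.SeedSequence(seed).spawn(n_subj)
    for i, panel in enumerate(panels):
        rng = np.random.default_rng(children[i])
        keep_this = panel.subject_id in keep
        per_subj: list[np.ndarray] = []
        done = 0
        while done < n_surrogates:
            m = min(chunk_size, n_surrogates - done)
            surro = phase_randomize_values(panel.values, m, rng)
            phases = phase_pipeline_values(surro, tr, low_hz, high_hz, trim=trim)
            cv = coupling_cv_from_phases(phases, ddof=ddof)  # (m, n_edges)
            sums[done : done + m, i] = cv.sum(axis=-1)
            if keep_this:
                per_subj.append(cv)
            done += m
        if keep_this:
            kept.append(np.concatenate(per_subj, axis=0))
            kept_ids.append(panel.subject_id)
    dfc = np.stack(kept, axis=1) if kept else None
    return SurrogateEnsemble(
        n_surrogates=n_surrogates,
        dfc_sums=sums,
        subject_ids=[p.subject_id for p in panels],
        seed=seed,
        dfc=dfc,
        kept_subject_ids=kept_ids or None,
    )


def _t_stat(x: np.ndarray, mu, axis: int, ddof: int = 1) -> np.ndarray:
    n = x.shape[axis]
    mean = x.mean(axis=axis)
    sd = x.std(axis=axis, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (mean - mu) / (sd / np.sqrt(n))


def whole_brain_dynamics_curve(
    dfc_sums: np.ndarray,
    surrogate_dfc_sums: np.ndarray,
    mu_grid: Optional[np.ndarray] = None,
    n_grid: int = 50,
    plus_one: bool = False,
) -> pd.DataFrame:
    """Detection-probability curve for whole-brain dynamics.

    For each candidate population mean mu, the one-sample T statistic of
    the measured per-subject dFC sums is compared with the same statistic
    computed in every surrogate dataset; p(mu) is one minus the fraction
    of surrogates the measured T exceeds.  The default grid spans 0 to the
    maximum surrogate dFC sum.
    """
    real = np.asarray(dfc_sums, dtype=float)
    surro = np.asarray(surrogate_dfc_sums, dtype=float)
    if real.ndim != 1 or real.size < 2:
        raise ValueError("need at least 2 subjects")
    if surro.ndim != 2 or surro.shape[1] != real.size:
        raise ValueError("surrogate sums must be (n_surrogates, n_subjects)")
    if mu_grid is None:
        mu_grid = np.linspace(0.0, float(surro.max()), n_grid)
    mu_grid = np.asarray(mu_grid, dtype=float)
    if mu_grid.size == 0:
        raise ValueError("mu grid is empty")
    n_surr = surro.shape[0]
    n_subj = real.size
    scale_real = real.std(ddof=1) / np.sqrt(n_subj)
    t_real = (real.mean() - mu_grid) / scale_real  # (M,)
    scale_surr = surro.std(axis=1, ddof=1) / np.sqrt(n_subj)  # (S,)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_surr = (surro.mean(axis=1)[None, :] - mu_grid[:, None]) / scale_surr[None, :]
    wins = (t_real[:, None] > t_surr).sum(axis=1)
    if plus_one:
        p = 1.0 - (wins + 1) / (n_surr + 1)
    else:
        p = 1.0 - wins / n_surr
    return pd.DataFrame({"mu": mu_grid, "t": t_real, "p": p})


def edge_dynamics_test(
    group_dfc: np.ndarray,
    surrogate_group_dfc: np.ndarray,
    plus_one: bool = False,
) -> pd.DataFrame:
    """Per-edge surrogate test for genuine dynamics in a reference group.

    For each edge, the one-sample T statistic of the group's dFC values
    against a population mean of zero is compared with the matching
    statistic in every surrogate dataset; p_e is one minus the fraction of
    surrogates the measured T_e exceeds.  Edges with zero within-group
    variance are reported as NaN with status ``degenerate``.
    """
    real = np.asarray(group_dfc, dtype=float)
    surro = np.asarray(surrogate_group_dfc, dtype=float)
    if real.ndim != 2:
        raise ValueError("group_dfc must be subjects x edges")
    if surro.ndim != 3 or surro.shape[1:] != real.shape:
        raise ValueError(
            "surrogate_group_dfc must be (n_surrogates,) + group_dfc.shape"
        )
    n_surr = surro.shape[0]
    t_real = _t_stat(real, 0.0, axis=0)  # (E,)
    t_surr = _t_stat(surro, 0.0, axis=1)  # (S, E)
    wins = (t_real[None, :] > t_surr).sum(axis=0).astype(float)
    if plus_one:
        p = 1.0 - (wins + 1) / (n_surr + 1)
    else:
        p = 1.0 - wins / n_surr
    degenerate = ~np.isfinite(t_real)
    p[degenerate] = np.nan
    n = real.shape[1]
    edges = edge_columns(_infer_n_nodes(n))
    return pd.DataFrame(
        {
            "edge": edges,
            "t": t_real,
            "p": p,
            "status": np.where(degenerate, "degenerate", "ok"),
        }
    )


def _infer_n_nodes(m: int) -> int:
    n = int((1 + np.sqrt(1 + 8 * m)) / 2)
    if n * (n - 1) // 2 != m:
        raise ValueError(f"{m} is not a triangular number of edges")
    return n
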