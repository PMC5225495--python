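"""Phase-based dynamic connectivity: Kuramoto order, metastability, C(t).

Given instantaneous phases phi_k(t), the Kuramoto order parameter
R(t) = |(1/N) sum_k exp(i phi_k(t))| measures whole-network synchrony at
each instant; metastability is the temporal standard deviation of R(t).
Pairwise coupling is C_ij(t) = 1 - dphi_ij(t)/pi, where dphi is the
circular distance between the two phases (in [0, pi]), and the per-edge
dynamic metric is the coefficient of variation of C_ij(t) over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panels import PhasePanel
from .static_fc import EdgeVector, edge_columns, n_edges

__all__ = [
    "DynamicState",
    "CouplingTrajectory",
    "kuramoto_order",
    "metastability",
    "pairwise_coupling",
    "dfc_cv",
    "coupling_cv_from_phases",
    "dynamics_cohort",
]

#: An edge whose temporal mean coupling falls at or below this tolerance
#: has an undefined coefficient of variation and is reported as NaN.
MEAN_TOLERANCE = 1e-6


@dataclass
class DynamicState:
    """Per-subject synchrony trace R(t) and its metastability."""

    order_parameter: np.ndarray
    metastability: float
    n_nodes: int
    subject_id: str = "sub-001"


@dataclass
class CouplingTrajectory:
    """Edge x time instantaneous coupling C_ij(t) in canonical edge order."""

    coupling: np.ndarray  # (n_edges, n_timepoints), values in [0, 1]
    n_nodes: int

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape[0] != n_edges(self.n_nodes):
            raise ValueError("coupling row count does not match the node count")


def kuramoto_order(phases: np.ndarray) -> np.ndarray:
    """R(t) = |mean_k exp(i phi_k(t))| along the node axis.

    ``phases`` has shape (..., n_nodes, n_timepoints); a single node is
    rejected because R would be identically 1.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.ndim < 2 or phases.shape[-2] < 2:
        raise ValueError("kuramoto_order needs at least 2 nodes")
    r = np.abs(np.exp(1j * phases).mean(axis=-2))
    return np.minimum(r, 1.0)


def metastability(order_parameter: np.ndarray, ddof: int = 1) -> float:
    """Sample standard deviation of the synchrony trace R(t)."""
    r = np.asarray(order_parameter, dtype=float)
    if r.shape[-1] < 2:
        raise ValueError("metastability needs at least 2 timepoints")
    out = r.std(axis=-1, ddof=ddof)
    return float(out) if np.ndim(out) == 0 else out


def _circular_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.abs(a - b)
    return np.minimum(d, 2.0 * np.pi - d)


def pairwise_coupling(phases: np.ndarray) -> CouplingTrajectory:
    """Instantaneous coupling C_ij(t) = 1 - dphi_ij(t)/pi for all pairs."""
    phases = np.asarray(phases, dtype=float)
    if phases.ndim != 2:
        raise ValueError("phases must be a node x time matrix")
    n = phases.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    dphi = _circular_distance(phases[iu], phases[ju])
    return CouplingTrajectory(coupling=1.0 - dphi / np.pi, n_nodes=n)


def _cv(values: np.ndarray, ddof: int) -> np.ndarray:
    """Coefficient of variation along the last axis; NaN where mean ~ 0."""
    mean = values.mean(axis=-1)
    sd = values.std(axis=-1, ddof=ddof)
    out = np.full(mean.shape, np.nan)
    ok = mean > MEAN_TOLERANCE
    out[ok] = sd[ok] / mean[ok]
    return out


def dfc_cv(trajectory: CouplingTrajectory, ddof: int = 1) -> EdgeVector:
    """Per-edge coefficient of variation of C_ij(t) (the dFC metric).

    Edges whose temporal mean coupling is at or below ``MEAN_TOLERANCE``
    are reported as NaN rather than silently zero.
    """
    values = _cv(trajectory.coupling, ddof=ddof)
    return EdgeVector(values=values, metric="dfc_cv", n_nodes=trajectory.n_nodes)


def coupling_cv_from_phases(phases: np.ndarray, ddof: int = 1) -> np.ndarray:
    """dFC coefficients of variation straight from phases.

    Accepts shape ``(..., n_nodes, n_timepoints)`` and returns
    ``(..., n_edges)``; identical (to rounding) to
    ``dfc_cv(pairwise_coupling(...))`` per subject, but computes the
    temporal moments of C in two reductions without materializing C,
    so surrogate ensembles can be pushed through in one call.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.shape[-2]
    t = phases.shape[-1]
    out = np.empty(phases.shape[:-2] + (n_edges(n),))
    inv_pi = 1.0 / np.pi
    offset = 0
    # canonical row-major order: row i holds the contiguous block of pairs
    # (i, j) for j > i, so plain slices suffice (no gather)
    for i in range(n - 1):
        width = n - 1 - i
        d = phases[..., i + 1 :, :] - phases[..., i : i + 1, :]
        np.abs(d, out=d)
        # circular distance in [0, pi]: min(d, 2pi - d) == pi - |d - pi|
        d -= np.pi
        np.abs(d, out=d)
        # C = 1 - dphi/pi = d/pi  (d is now pi - dphi)
        d *= inv_pi
        m1 = d.mean(axis=-1)
        m2 = np.einsum("...t,...t->...", d, d) / t
        var = (m2 - m1 * m1) * (t / (t - ddof)) if ddof else m2 - m1 * m1
        sd = np.sqrt(np.maximum(var, 0.0))
        cv = np.full(m1.shape, np.nan)
        ok = m1 > MEAN_TOLERANCE
        cv[ok] = sd[ok] / m1[ok]
        out[..., offset : offset + width] = cv
        offset += width
    return out


def dynamics_cohort(phase_panels: list[PhasePanel], ddof: int = 1):
    """Stack per-subject dynamics over a cohort.

    Returns
    -------
    states : list of DynamicState
    dfc : DataFrame (subject x edge) of coefficients of variation
    summary : DataFrame with columns ``metastability`` and ``dfc_sum``
        (the per-subject sum over all unique edges), indexed by subject.
    """
    if not phase_panels:
        raise ValueError("no phase panels given")
    n = phase_panels[0].n_nodes
    states = []
    rows = {}
    for pp in phase_panels:
        if pp.n_nodes != n:
            raise ValueError(
                f"panel {pp.subject_id} has {pp.n_nodes} nodes, expected {n}"
            )
        r = kuramoto_order(pp.phase)
        states.append(
            DynamicState(
                order_parameter=r,
                metastability=metastability(r, ddof=ddof),
                n_nodes=n,
                subject_id=pp.subject_id,
            )
        )
        rows[pp.subject_id] = coupling_cv_from_phases(pp.phase, ddof=ddof)
    dfc = pd.DataFrame.from_dict(rows, orient="index", columns=edge_columns(n))
    dfc.index.name = "subject_id"
    summary = pd.DataFrame(
        {
            "metastability": [s.metastability for s in states],
            "dfc_sum": dfc.sum(axis=1, skipna=False).to_numpy(),
        },
        index=dfc.index,
    )
    return states, dfc, summary
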