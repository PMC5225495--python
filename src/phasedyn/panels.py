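"""Core in-memory containers for node-by-time signal panels.

A :class:`TimeSeriesPanel` holds one subject's node x time matrix of raw
(or band-passed) signals together with the sampling interval.  A
:class:`PhasePanel` holds the instantaneous phase and envelope obtained
from the analytic signal, after end-trimming.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["TimeSeriesPanel", "PhasePanel", "default_node_labels"]


def default_node_labels(n_nodes: int) -> list[str]:
    """Canonical node labels ``node_1 .. node_N``."""
    return [f"node_{k}" for k in range(1, n_nodes + 1)]


@dataclass
class TimeSeriesPanel:
    """One subject's node x time real-valued signal matrix.

    Parameters
    ----------
    values
        Array of shape ``(n_nodes, n_timepoints)``; finite reals.
    tr_seconds
        Sampling interval (repetition time) in seconds.
    subject_id
        Identifier used in file names and cohort tables.
    group
        Optional diagnostic-group label (e.g. ``"AD"``).
    node_labels
        One label per node; defaults to ``node_1 .. node_N``.
    """

    values: np.ndarray
    tr_seconds: float
    subject_id: str = "sub-001"
    group: Optional[str] = None
    node_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(
                f"panel values must be 2-D (nodes x time), got {self.values.ndim}-D"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("panel values must be finite")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        if self.node_labels is None:
            self.node_labels = default_node_labels(self.n_nodes)
        if len(self.node_labels) != self.n_nodes:
            raise ValueError("node_labels length does not match node count")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist_hz(self) -> float:
        """Highest representable frequency, 1 / (2 TR)."""
        return 1.0 / (2.0 * self.tr_seconds)

    @property
    def duration_seconds(self) -> float:
        """Total scan duration, ``n_timepoints * tr_seconds``."""
        return self.n_timepoints * self.tr_seconds

    def with_values(self, values: np.ndarray) -> "TimeSeriesPanel":
        """Copy of this panel with ``values`` replaced (metadata kept)."""
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class PhasePanel:
    """Instantaneous phase and envelope of one subject's analytic signals.

    ``phase`` is wrapped to (-pi, pi]; ``envelope`` is nonnegative; both
    have ``trim`` points removed from each end of the original series.
    """

    phase: np.ndarray
    envelope: np.ndarray
    tr_seconds: float
    trim: int = 10
    subject_id: str = "sub-001"
    group: Optional[str] = None
    node_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.envelope = np.asarray(self.envelope, dtype=float)
        if self.phase.shape != self.envelope.shape or self.phase.ndim != 2:
            raise ValueError("phase and envelope must be matching 2-D arrays")
        if not (np.all(self.phase > -np.pi) and np.all(self.phase <= np.pi)):
            raise ValueError("phase values must lie in (-pi, pi]")
        if np.any(self.envelope < 0):
            raise ValueError("envelope must be nonnegative")
        if self.trim < 0:
            raise ValueError("trim must be nonnegative")
        if self.node_labels is None:
            self.node_labels = default_node_labels(self.n_nodes)

    @property
    def n_nodes(self) -> int:
        return self.phase.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.phase.shape[1]
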