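"""Synthetic cohorts with known ground truth.

Two generators cover the two regimes the downstream statistics must
distinguish:

* :func:`simulate_kuramoto_bold` — noisy Kuramoto phase oscillators with
  natural frequencies inside the analysis band, whose global coupling
  strength K controls whole-network metastability (maximal near the
  critical coupling, vanishing in the full-synchrony limit).  Group
  effects are encoded by giving each diagnostic group its own K.
* :func:`simulate_stationary_null` — a stationary linear Gaussian
  vector-AR(1) process with a prescribed instantaneous cross-covariance.
  Its distribution is invariant under phase-randomized Fourier
  surrogates, so it carries no genuine time-varying coupling.

:func:`generate_cohort` assembles a multi-group study: per-subject
oscillator panels plus a covariate table (age, sex, head-coil dummy,
in-scanner motion) with a group-dependent age imbalance, so that
covariate adjustment is exercised realistically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .panels import TimeSeriesPanel

__all__ = [
    "SimulationConfig",
    "CohortSpec",
    "simulate_kuramoto_bold",
    "simulate_stationary_null",
    "generate_cohort",
    "generate_null_cohort",
    "uniform_coupling_matrix",
]

#: Group age distributions (mean, SD in years) used by the covariate
#: generator; unknown labels fall back to (65, 10).
AGE_BY_GROUP = {"AD": (71.5, 7.9), "MCI": (63.5, 11.1), "SCI": (63.6, 9.6)}

#: Fraction of subjects scanned with the reference (8-channel) head coil.
HEADCOIL_8CH_FRACTION = 0.73


def _default_coupling() -> dict[str, float]:
    # Global coupling per group, on the subcritical branch where
    # metastability increases with K (see docs/methods.md): the healthier
    # the group, the closer to the critical coupling, hence the higher
    # the metastability (SCI > MCI > AD).
    return {"SCI": 0.08, "MCI": 0.05, "AD": 0.02}


@dataclass
class SimulationConfig:
    """Study dimensions and generator parameters.

    Defaults mirror a resting-state protocol with 26 network nodes,
    202 retained volumes at TR = 2.638 s, and a 0.04-0.07 Hz band.
    """

    n_subjects: int = 26  # per group
    n_nodes: int = 26
    n_timepoints: int = 202
    tr_seconds: float = 2.638
    freq_band: tuple[float, float] = (0.04, 0.07)
    coupling_by_group: dict[str, float] = field(default_factory=_default_coupling)
    noise_sd: float = 0.1  # measurement noise on the unit-amplitude signal
    phase_noise_sd: float = 0.15  # rad / sqrt(s), intrinsic phase diffusion
    coupling_jitter: float = 0.10  # per-subject SD of K, as a fraction of K
    steps_per_tr: int = 20  # Euler-Maruyama substeps per TR
    burn_in_seconds: float = 120.0
    trim: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.n_subjects < 1:
            raise ValueError("need at least 1 subject per group")
        if self.n_timepoints <= 2 * self.trim:
            raise ValueError(
                f"n_timepoints ({self.n_timepoints}) must exceed twice the "
                f"trim length ({2 * self.trim})"
            )
        low, high = self.freq_band
        nyq = 1.0 / (2.0 * self.tr_seconds)
        if not (0.0 < low < high < nyq):
            raise ValueError(
                f"freq_band must satisfy 0 < low < high < Nyquist ({nyq:.6g} Hz)"
            )
        if any(k < 0 for k in self.coupling_by_group.values()):
            raise ValueError("coupling strengths must be nonnegative")
        if self.noise_sd < 0 or self.phase_noise_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.steps_per_tr < 10:
            raise ValueError(
                "steps_per_tr < 10 gives an unstable integration step "
                "(internal step must be at most TR/10)"
            )

    @property
    def dt(self) -> float:
        return self.tr_seconds / self.steps_per_tr

    @property
    def groups(self) -> list[str]:
        return list(self.coupling_by_group)


@dataclass
class CohortSpec:
    """Per-subject covariate table: subject_id, group, age, sex, headcoil, motion."""

    table: pd.DataFrame

    REQUIRED = ("subject_id", "group", "age", "sex", "headcoil", "motion")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"cohort table is missing column(s): {missing}")
        numeric = self.table[["age", "sex", "headcoil", "motion"]].to_numpy(float)
        if not np.all(np.isfinite(numeric)):
            raise ValueError("cohort covariates must be finite")
        if self.table["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids in cohort table")

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())


def uniform_coupling_matrix(n_nodes: int, strength: float) -> np.ndarray:
    """All-to-all Kuramoto weights K/N off the diagonal (mean-field scaling)."""
    mat = np.full((n_nodes, n_nodes), strength / n_nodes)
    np.fill_diagonal(mat, 0.0)
    return mat


def _integrate_kuramoto(
    rng: np.random.Generator,
    omega: np.ndarray,  # (B, N) rad/s
    coupling: np.ndarray,  # (B, N, N)
    theta0: np.ndarray,  # (B, N)
    n_timepoints: int,
    steps_per_tr: int,
    dt: float,
    phase_noise_sd: float,
    burn_in_steps: int,
) -> np.ndarray:
    """Euler-Maruyama integration of a batch of Kuramoto systems.

    Returns phases sampled once per TR, shape (B, N, n_timepoints).
    """
    b, n = theta0.shape
    theta = theta0.copy()
    sqrt_dt = np.sqrt(dt)
    out = np.empty((b, n, n_timepoints))
    total = burn_in_steps + (n_timepoints - 1) * steps_per_tr
    sample_at = burn_in_steps
    idx = 0
    for step in range(total + 1):
        if step == sample_at:
            out[:, :, idx] = theta
            idx += 1
            sample_at += steps_per_tr
            if idx == n_timepoints:
                break
        z = np.exp(1j * theta)
        drive = np.einsum("bij,bj->bi", coupling, z)
        pull = (drive * np.conj(z)).imag  # sum_j K_ij sin(theta_j - theta_i)
        theta = theta + dt * (omega + pull)
        if phase_noise_sd > 0:
            theta = theta + sqrt_dt * phase_noise_sd * rng.standard_normal((b, n))
    return out


def simulate_kuramoto_bold(
    config: SimulationConfig,
    coupling_matrix: np.ndarray,
    seed: int,
    subject_id: str = "sub-001",
    group: Optional[str] = None,
) -> TimeSeriesPanel:
    """One subject's panel from coupled noisy phase oscillators.

    Natural frequencies are drawn uniformly so that omega/2pi lies in the
    configured band; the observed signal is sin(theta_k(t)) sampled every
    TR plus Gaussian measurement noise.  Deterministic given ``seed``.
    """
    k = np.asarray(coupling_matrix, dtype=float)
    n = config.n_nodes
    if k.shape != (n, n):
        raise ValueError(f"coupling matrix must be {n}x{n}, got {k.shape}")
    if not np.allclose(k, k.T):
        raise ValueError("coupling matrix must be symmetric")
    if np.any(k < 0):
        raise ValueError("coupling weights must be nonnegative")
    if np.any(np.diag(k) != 0):
        raise ValueError("coupling matrix must have a zero diagonal")
    rng = np.random.default_rng(seed)
    low, high = config.freq_band
    omega = rng.uniform(2 * np.pi * low, 2 * np.pi * high, size=(1, n))
    theta0 = rng.uniform(-np.pi, np.pi, size=(1, n))
    theta = _integrate_kuramoto(
        rng,
        omega,
        k[None],
        theta0,
        config.n_timepoints,
        config.steps_per_tr,
        config.dt,
        config.phase_noise_sd,
        burn_in_steps=int(round(config.burn_in_seconds / config.dt)),
    )[0]
    x = np.sin(theta)
    if config.noise_sd > 0:
        x = x + config.noise_sd * rng.standard_normal(x.shape)
    return TimeSeriesPanel(
        values=x, tr_seconds=config.tr_seconds, subject_id=subject_id, group=group
    )


def simulate_stationary_null(
    config: SimulationConfig,
    cross_covariance: np.ndarray,
    ar_coefficient: float,
    seed: int,
    subject_id: str = "sub-001",
    group: Optional[str] = None,
    n_timepoints: Optional[int] = None,
) -> TimeSeriesPanel:
    """Stationary linear Gaussian panel with no genuine dynamics.

    A vector AR(1) process x_t = a x_{t-1} + e_t whose innovations are
    scaled so the stationary cross-covariance equals ``cross_covariance``
    exactly.  Every node has lag-1 autocorrelation ``a``.
    """
    if not (-1.0 < ar_coefficient < 1.0):
        raise ValueError("ar_coefficient must lie in (-1, 1)")
    sigma = np.asarray(cross_covariance, dtype=float)
    n = config.n_nodes
    if sigma.shape != (n, n) or not np.allclose(sigma, sigma.T):
        raise ValueError(f"cross_covariance must be a symmetric {n}x{n} matrix")
    try:
        chol = np.linalg.cholesky(sigma * (1.0 - ar_coefficient**2))
    except np.linalg.LinAlgError as exc:
        raise ValueError("cross_covariance must be positive definite") from exc
    rng = np.random.default_rng(seed)
    t = n_timepoints if n_timepoints is not None else config.n_timepoints
    burn = 100
    eps = rng.standard_normal((burn + t, n)) @ chol.T
    x = np.empty((burn + t, n))
    x[0] = rng.multivariate_normal(np.zeros(n), sigma)
    for i in range(1, burn + t):
        x[i] = ar_coefficient * x[i - 1] + eps[i]
    return TimeSeriesPanel(
        values=x[burn:].T,
        tr_seconds=config.tr_seconds,
        subject_id=subject_id,
        group=group,
    )


def _draw_covariates(rng: np.random.Generator, labels: list[str]) -> pd.DataFrame:
    ages, sexes, coils, motions = [], [], [], []
    for g in labels:
        mean, sd = AGE_BY_GROUP.get(g, (65.0, 10.0))
        ages.append(rng.normal(mean, sd))
        sexes.append(int(rng.random() < 0.5))
        coils.append(int(rng.random() < HEADCOIL_8CH_FRACTION))
        motions.append(float(np.exp(rng.normal(np.log(0.10), 0.5))))
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(len(labels))],
            "group": labels,
            "age": ages,
            "sex": sexes,
            "headcoil": coils,
            "motion": motions,
        }
    )


def _group_labels(config: SimulationConfig) -> list[str]:
    if not config.coupling_by_group:
        raise ValueError("coupling_by_group must name at least one group")
    labels = []
    for g in config.groups:
        labels.extend([g] * config.n_subjects)
    return labels


def generate_cohort(config: SimulationConfig, spec_seed: int):
    """Multi-group oscillator cohort plus covariate table.

    Each subject's panel is simulated with its group's global coupling
    strength (plus per-subject multiplicative jitter).  Returns
    ``(panels, cohort_spec)``; byte-identical across runs for the same
    seeds.
    """
    labels = _group_labels(config)
    b = len(labels)
    n = config.n_nodes
    ss = np.random.SeedSequence(spec_seed)
    rng_cov, rng_dyn = [np.random.default_rng(s) for s in ss.spawn(2)]
    cohort = CohortSpec(table=_draw_covariates(rng_cov, labels))

    strengths = np.array(
        [
            max(
                config.coupling_by_group[g]
                * (1.0 + config.coupling_jitter * rng_dyn.standard_normal()),
                0.0,
            )
            for g in labels
        ]
    )
    coupling = np.stack([uniform_coupling_matrix(n, s) for s in strengths])
    low, high = config.freq_band
    omega = rng_dyn.uniform(2 * np.pi * low, 2 * np.pi * high, size=(b, n))
    theta0 = rng_dyn.uniform(-np.pi, np.pi, size=(b, n))
    theta = _integrate_kuramoto(
        rng_dyn,
        omega,
        coupling,
        theta0,
        config.n_timepoints,
        config.steps_per_tr,
        config.dt,
        config.phase_noise_sd,
        burn_in_steps=int(round(config.burn_in_seconds / config.dt)),
    )
    x = np.sin(theta)
    if config.noise_sd > 0:
        x = x + config.noise_sd * rng_dyn.standard_normal(x.shape)
    panels = [
        TimeSeriesPanel(
            values=x[i],
            tr_seconds=config.tr_seconds,
            subject_id=cohort.table["subject_id"].iloc[i],
            group=labels[i],
        )
        for i in range(b)
    ]
    return panels, cohort


def generate_null_cohort(
    config: SimulationConfig,
    spec_seed: int,
    cross_covariance: Optional[np.ndarray] = None,
    ar_coefficient: float = 0.4,
):
    """Stationary-null cohort with the same design as :func:`generate_cohort`.

    Group labels and covariates are drawn exactly as for the oscillator
    cohort, but every panel comes from the linear null process, so no
    genuine dynamics and no group signal exist.
    """
    labels = _group_labels(config)
    ss = np.random.SeedSequence(spec_seed)
    rng_cov, _ = [np.random.default_rng(s) for s in ss.spawn(2)]
    cohort = CohortSpec(table=_draw_covariates(rng_cov, labels))
    sigma = (
        np.eye(config.n_nodes)
        if cross_covariance is None
        else np.asarray(cross_covariance, dtype=float)
    )
    child = ss.spawn(2 + len(labels))[2:]
    panels = [
        simulate_stationary_null(
            config,
            sigma,
            ar_coefficient,
            seed=child[i],
            subject_id=cohort.table["subject_id"].iloc[i],
            group=labels[i],
        )
        for i in range(len(labels))
    ]
    return panels, cohort
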