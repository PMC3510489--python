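"""Harmonic and two-state elastic energy models for base-pair-step deformations.

The classic mesoscopic picture treats each step as a harmonic well,

    E(x) = ½ (x − X0)ᵀ K (x − X0),

whose stiffness matrix K is estimated from an equilibrium ensemble as
kT times the inverse sample covariance. When a helical parameter is
bimodal this picture fails: the right model has two wells i and j,

    E_i(x) = ½ ΔX_iᵀ K_i ΔX_i,
    E_j(x) = ½ ΔX_jᵀ K_j ΔX_j + ΔG_ij,

with ΔG_ij the free-energy offset between the two minima, and the energy
surface is the lower of the two branches. Taking the hard minimum leaves
a derivative discontinuity at the branch crossing, so for optimization or
dynamics the branches are coupled in the style of two-state
surface-crossing problems: the surface is the lower eigenvalue of
[[E_i, ε], [ε, E_j]],

    E(x) = ½ (E_i + E_j) − ½ sqrt((E_i − E_j)² + 4ε²),

which is smooth everywhere and approaches min(E_i, E_j) as ε → 0⁺.
When n parameters of one step are bimodal the number of required state
models grows as 2^(n−1) (each extra bimodal coordinate doubles the well
count relative to a shared reference).

Energies are kept in kT internally; conversion to kcal/mol (0.593 at
298 K) belongs in the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mixture import BinormalFit
from .synthetic import HarmonicSpec

#: kcal/mol per kT at 298 K, for report-layer unit conversion.
KCAL_PER_KT_298 = 0.593


class RankError(ValueError):
    """Sample covariance is singular; stiffness cannot be derived."""


@dataclass(frozen=True)
class ElasticState:
    """One harmonic well: equilibrium vector, stiffness matrix and energy unit."""

    x0: np.ndarray
    stiffness: np.ndarray
    kT: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x0", np.atleast_1d(np.asarray(self.x0, dtype=float)))
        object.__setattr__(self, "stiffness",
                           np.atleast_2d(np.asarray(self.stiffness, dtype=float)))
        k = self.stiffness
        if k.shape != (self.x0.size, self.x0.size):
            raise ValueError("stiffness must be d×d matching x0")
        if not np.allclose(k, k.T, atol=1e-8 * max(1.0, float(np.abs(k).max()))):
            raise ValueError("stiffness must be symmetric")
        if np.linalg.eigvalsh(k).min() <= 0:
            raise ValueError("stiffness must be positive definite")

    @property
    def d(self) -> int:
        return int(self.x0.size)


@dataclass(frozen=True)
class BimodalElastic:
    """Two-well elastic model with free-energy offset and smooth coupling.

    ``delta_g_ij`` raises well j's minimum relative to well i's; ``epsilon``
    is the (small, positive) coupling that smooths the branch crossing.
    """

    state_i: ElasticState
    state_j: ElasticState
    delta_g_ij: float = 0.0
    epsilon: float = 0.25

    def __post_init__(self) -> None:
        if self.state_i.d != self.state_j.d:
            raise ValueError("states must share dimensionality")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def d(self) -> int:
        return self.state_i.d


def required_state_count(n_bimodal: int) -> int:
    """Number of distinct state models needed for n bimodal coordinates: 2^(n−1)."""
    if n_bimodal < 1:
        raise ValueError("need at least one bimodal coordinate")
    return 2 ** (n_bimodal - 1)


@dataclass(frozen=True)
class MultiStateElastic:
    """Container for the wells of a step with several bimodal coordinates.

    Enforces the 2^(n−1) scaling of the state count with the number of
    bimodal coordinates.
    """

    states: tuple[ElasticState, ...]
    n_bimodal: int
    delta_g: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        expected = required_state_count(self.n_bimodal)
        if len(self.states) != expected:
            raise ValueError(
                f"{self.n_bimodal} bimodal coordinate(s) require "
                f"{expected} state model(s), got {len(self.states)}")
        dims = {s.d for s in self.states}
        if len(dims) > 1:
            raise ValueError("all states must share dimensionality")
        if self.delta_g and len(self.delta_g) != len(self.states):
            raise ValueError("delta_g must have one offset per state")


def stiffness_from_covariance(
    samples: np.ndarray,
    kT: float = 1.0,
    cond_limit: float = 1e12,
) -> ElasticState:
    """Estimate a harmonic well from an equilibrium ensemble.

    ``samples`` is (n, d); x0 is the sample mean and the stiffness is
    kT × inverse(sample covariance), producing both diagonal and
    off-diagonal force constants. A singular (or numerically collinear)
    covariance raises :class:`RankError` naming the offending coordinates.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.ndim != 2:
        raise ValueError("samples must be a 2-D (n, d) array")
    n, d = samples.shape
    if n <= 10 * d:
        raise ValueError(f"need n > 10·d samples (got n={n}, d={d})")
    x0 = samples.mean(axis=0)
    cov = np.cov(samples, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    sd = np.sqrt(np.diag(cov))
    if np.any(sd <= 0):
        bad = np.where(sd <= 0)[0].tolist()
        raise RankError(f"constant coordinate(s) {bad}: covariance singular")
    corr = cov / np.outer(sd, sd)
    if d > 1:
        cnum = np.linalg.cond(corr)
        if not np.isfinite(cnum) or cnum > cond_limit:
            off = np.abs(corr - np.eye(d))
            i, j = np.unravel_index(np.argmax(off), off.shape)
            raise RankError(
                f"covariance numerically singular (condition {cnum:.3g}); "
                f"coordinates {i} and {j} are collinear "
                f"(|corr| = {off[i, j]:.6f})")
    stiffness = kT * np.linalg.inv(cov)
    stiffness = 0.5 * (stiffness + stiffness.T)  # enforce exact symmetry
    return ElasticState(x0=x0, stiffness=stiffness, kT=kT)


def energy_harmonic(state: ElasticState, x: np.ndarray) -> float | np.ndarray:
    """Harmonic deformation energy ½ ΔXᵀ K ΔX (vectorized over rows of x)."""
    x = np.asarray(x, dtype=float)
    if x.ndim <= 1:
        dx = np.atleast_1d(x) - state.x0
        if dx.size != state.d:
            raise ValueError(f"expected a {state.d}-vector")
        return float(0.5 * dx @ state.stiffness @ dx)
    if x.shape[-1] != state.d:
        raise ValueError(f"expected rows of length {state.d}")
    dx = x - state.x0
    return 0.5 * np.einsum("...i,ij,...j->...", dx, state.stiffness, dx)


def energy_two_state(
    model: BimodalElastic, x: np.ndarray
) -> tuple[float | np.ndarray, float | np.ndarray, float | np.ndarray]:
    """Both branch energies and their hard minimum (kinked at the crossing)."""
    e_i = energy_harmonic(model.state_i, x)
    e_j = energy_harmonic(model.state_j, x) + model.delta_g_ij
    return e_i, e_j, np.minimum(e_i, e_j)


def energy_smooth(model: BimodalElastic, x: np.ndarray) -> float | np.ndarray:
    """Smoothly coupled two-well energy: lower eigenvalue of [[E_i, ε], [ε, E_j]].

    Continuous with continuous first derivatives; equals E − ε exactly at
    a branch crossing and lies at most ε below min(E_i, E_j) everywhere.
    """
    e_i, e_j, _ = energy_two_state(model, x)
    e_i = np.asarray(e_i, dtype=float)
    e_j = np.asarray(e_j, dtype=float)
    out = 0.5 * (e_i + e_j) - 0.5 * np.sqrt((e_i - e_j) ** 2
                                            + 4.0 * model.epsilon ** 2)
    if out.ndim == 0:
        return float(out)
    return out


def delta_g_from_mixture(fit: BinormalFit, kT: float = 1.0) -> float:
    """Free-energy offset between the two wells by Boltzmann inversion.

    With component i the more populated one, ΔG_ij = −kT·ln(p_minor/p_major)
    ≥ 0. The mixture weights of the BIC fit are the populations.
    """
    p = fit.model.p_r
    if not (0.0 < p < 1.0):
        raise ValueError("mixture proportion must be strictly inside (0, 1)")
    p_major = max(p, 1.0 - p)
    return float(-kT * np.log((1.0 - p_major) / p_major))


def per_state_split(
    samples: np.ndarray,
    fit: BinormalFit,
    split_parameter: int | str = 0,
    parameters: tuple[str, ...] | None = None,
    min_per_dim: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign joint snapshots to the two mixture components of one coordinate.

    Each row goes to the component with the larger posterior responsibility
    under ``fit`` evaluated on the splitting coordinate (ties → state i,
    the ascending-mean first component). The two returned sample blocks
    feed :func:`stiffness_from_covariance` to yield per-state stiffness
    matrices.
    """
    if not fit.converged:
        raise ValueError("refusing to split on a non-converged fit")
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n, d = samples.shape
    if isinstance(split_parameter, str):
        if parameters is None:
            raise ValueError("parameter names not supplied")
        split_idx = parameters.index(split_parameter)
    else:
        split_idx = int(split_parameter)
    x = samples[:, split_idx]
    m = fit.model
    log1 = (np.log(max(m.p_r, 1e-300)) - np.log(m.sigma1)
            - 0.5 * ((x - m.mu1) / m.sigma1) ** 2)
    log2 = (np.log(max(1.0 - m.p_r, 1e-300)) - np.log(m.sigma2)
            - 0.5 * ((x - m.mu2) / m.sigma2) ** 2)
    in_i = log1 >= log2  # tie goes to state i
    part_i, part_j = samples[in_i], samples[~in_i]
    for name, part in (("i", part_i), ("j", part_j)):
        if part.shape[0] < min_per_dim * d:
            raise ValueError(
                f"state {name} has only {part.shape[0]} snapshots; "
                f"need at least {min_per_dim * d} for a {d}-D stiffness")
    return part_i, part_j


def unimodal_error_profile(
    fit_uni: ElasticState,
    model: BimodalElastic,
    grid: np.ndarray,
) -> np.ndarray:
    """Energy error of a unimodal model applied to a bimodal landscape (1-D).

    Returns a (len(grid), 4) array of columns (x, e_uni, e_bi, difference)
    with difference = e_bi − e_uni: positive where the unimodal model
    underestimates the true energy. For a genuinely two-well landscape the
    unimodal minimum sits at the barrier top (difference > 0 there), while
    the inflated unimodal σ makes the deformation penalty in the tails too
    small.
    """
    if fit_uni.d != 1 or model.d != 1:
        raise ValueError("profile comparison is defined for 1-D states")
    grid = np.asarray(grid, dtype=float).ravel()
    e_uni = np.array([energy_harmonic(fit_uni, np.array([g])) for g in grid])
    e_bi = np.array([energy_smooth(model, np.array([g])) for g in grid])
    return np.column_stack([grid, e_uni, e_bi, e_bi - e_uni])
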