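"""Asymmetric Gabor-like dictionary atoms.

An atom is a windowed oscillation ``N * Omega(t) * cos(omega*(t - mu) + phase)``
whose envelope ``Omega`` is a Gaussian on one side of the center ``mu`` and an
atan-modulated Gaussian on the other::

    Omega(t) = exp( - (t-mu)^2 / (2 sigma) * [1 + alpha*(t-mu) * w(t-mu)] )
    w(u)     = (atan(beta*u) + pi/2) / pi

With ``beta`` very large (default 1e16) the weight ``w`` is a numerically sharp
step: for ``t < mu`` the envelope is exactly Gaussian, for ``t > mu`` the decay
is modulated by the factor ``1 + alpha*(t - mu)``.  ``alpha > 0`` steepens the
decay, ``alpha < 0`` slows it down.  The construction is continuous together
with its first derivative.  ``sigma`` is a variance-like scale (seconds^2), so
``alpha = 0`` recovers the classical Gabor atom
``N * exp(-(t-mu)^2 / (2 sigma)) * cos(...)`` exactly.

For ``alpha < 0`` the exponent factor ``1 + alpha*u`` changes sign at
``u = 1/|alpha|`` and the raw formula re-grows; the envelope is therefore
clamped to zero beyond the monotonicity boundary ``u* = 2/(3|alpha|)``, the
last point where the envelope is non-increasing away from ``mu``.  A ``mirror``
flag time-reflects the atom about ``mu`` so that both steep-rise/slow-decay
shapes and their reversals are representable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AtomParams",
    "DEFAULT_BETA",
    "evaluate_envelope",
    "evaluate_atom",
    "evaluate_analytic",
    "normalize",
    "sample_grid",
]

#: atan sharpness making the side-selecting step numerically exact in float64
DEFAULT_BETA = 1e16


class AtomParameterError(ValueError):
    """Raised for atoms outside the admissible parameter domain."""


class DegenerateAtomError(ValueError):
    """Raised when an atom has (numerically) zero energy on the window."""


@dataclass(frozen=True)
class AtomParams:
    """Full parameter set of one dictionary waveform.

    Parameters
    ----------
    mu : float
        Time position of the envelope maximum, seconds.
    omega : float
        Circular frequency of the carrier, rad/s (reported externally in Hz).
    sigma : float
        Variance-like time scale, seconds^2; the effective (Gaussian-side)
        width is ``sqrt(sigma)``.
    alpha : float
        Asymmetry slope of the decaying side, 1/s; 0 gives a symmetric Gabor.
    beta : float
        atan sharpness constant, 1/s.  Fixed global constant, not fitted.
    phase : float
        Phase of the real carrier at ``t = mu``, radians.
    coefficient : float
        Real amplitude assigned by matching pursuit, signal units.
    mirror : bool
        If True the waveform is time-reflected about ``mu`` (the modulated
        side becomes the rising side).
    norm : float
        Normalization factor ``N``; set by :func:`normalize` so that the
        sampled waveform with ``coefficient = 1`` has unit discrete L2 norm.
    """

    mu: float
    omega: float
    sigma: float
    alpha: float = 0.0
    beta: float = DEFAULT_BETA
    phase: float = 0.0
    coefficient: float = 1.0
    mirror: bool = False
    norm: float = 1.0

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise AtomParameterError(f"sigma must be > 0, got {self.sigma}")
        if not (self.beta > 0):
            raise AtomParameterError(f"beta must be > 0, got {self.beta}")
        if not np.isfinite(self.coefficient):
            raise AtomParameterError("coefficient must be finite")

    @property
    def frequency_hz(self) -> float:
        """Carrier frequency in Hz (= omega / 2 pi)."""
        return self.omega / (2.0 * np.pi)

    @property
    def relative_alpha(self) -> float:
        """Scale-free asymmetry ``alpha * sqrt(sigma)``."""
        return self.alpha * np.sqrt(self.sigma)


def sample_grid(n_samples: int, fs: float, t0: float = 0.0) -> np.ndarray:
    """Uniform time grid with sample 0 at ``t = t0`` (seconds)."""
    return t0 + np.arange(int(n_samples)) / float(fs)


def _raw_envelope(p: AtomParams, t: np.ndarray) -> np.ndarray:
    """Unnormalized envelope with the monotone-decay clamp applied."""
    u = np.asarray(t, dtype=float) - p.mu
    if p.mirror:
        u = -u
    # side weight: ~0 for u<0, ~1 for u>0 at large beta
    w = (np.arctan(p.beta * u) + 0.5 * np.pi) / np.pi
    factor = 1.0 + p.alpha * u * w
    with np.errstate(over="ignore"):
        env = np.exp(-(u * u) * factor / (2.0 * p.sigma))
    if p.alpha < 0.0:
        # beyond u* = 2/(3|alpha|) the envelope would re-grow; clamp to zero
        u_star = 2.0 / (3.0 * abs(p.alpha))
        env = np.where(u > u_star, 0.0, env)
    return env


def evaluate_envelope(p: AtomParams, t: np.ndarray) -> np.ndarray:
    """Envelope ``N * Omega(t)`` of the atom on the time grid ``t``.

    Non-negative everywhere; maximum ``N`` attained at ``t = mu``.
    """
    return p.norm * _raw_envelope(p, t)


def evaluate_atom(p: AtomParams, t: np.ndarray) -> np.ndarray:
    """Real waveform ``coefficient * N * Omega(t) * cos(omega (t-mu) + phase)``.

    With ``coefficient = 1`` and ``norm`` set by :func:`normalize`, the result
    has unit discrete L2 norm on the normalization window.
    """
    t = np.asarray(t, dtype=float)
    carrier = np.cos(p.omega * (t - p.mu) + p.phase)
    return p.coefficient * evaluate_envelope(p, t) * carrier


def evaluate_analytic(p: AtomParams, t: np.ndarray) -> np.ndarray:
    """Complex (analytic-carrier) waveform ``coeff * N * Omega * e^{i(...)}``."""
    t = np.asarray(t, dtype=float)
    carrier = np.exp(1j * (p.omega * (t - p.mu) + p.phase))
    return p.coefficient * evaluate_envelope(p, t) * carrier


def normalize(p: AtomParams, window: int, fs: float, t0: float = 0.0) -> AtomParams:
    """Absorb the normalization factor ``N`` so the sampled waveform has unit norm.

    The norm is taken over the ``window``-sample grid at rate ``fs``; atoms
    truncated by the window edge therefore still come out with norm exactly 1
    on the window.

    Raises
    ------
    DegenerateAtomError
        If the atom carries no energy on the window.
    """
    t = sample_grid(window, fs, t0)
    wave = _raw_envelope(p, t) * np.cos(p.omega * (t - p.mu) + p.phase)
    nrm = float(np.linalg.norm(wave))
    if nrm <= 0.0 or not np.isfinite(nrm):
        raise DegenerateAtomError(
            f"atom (mu={p.mu}, sigma={p.sigma}) has no energy on the window"
        )
    return replace(p, norm=1.0 / nrm)
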