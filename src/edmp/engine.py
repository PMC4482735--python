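"""Greedy matching pursuit over the enriched dictionary.

Each iteration selects, over all grid atoms, the waveform with the largest
absolute inner product with the current residual.  The search over all time
positions is carried out by FFT cross-correlation, one transform per
(scale, asymmetry, frequency) combination; the search over phase is exact and
closed-form: the best real atom over all phases is the orthogonal projection
onto the span of the quadrature pair (see :func:`_projection`), computed in
the grid search from residual-independent window sums.  The grid winner is
then polished by a
derivative-free local search of its continuous parameters, accepted only if it
does not decrease the inner product, projected out of the residual, and the
procedure repeats until an energy-fraction or atom-count stopping rule fires.

The recursion ``||R^n f||^2 = |<R^n f, g>|^2 + ||R^(n+1) f||^2`` holds exactly
(up to rounding) because the selected atom has unit norm on the window and the
signed projection is subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.fft import fft, ifft, next_fast_len
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .atoms import AtomParams, evaluate_atom, sample_grid
from .dictionary import DictionarySpec, dictionary_size
from .signals import SignalRecord

__all__ = [
    "StopRule",
    "Decomposition",
    "MatchingPursuit",
    "best_match",
    "refine_parameters",
    "decompose",
    "reconstruct",
]

# relative residual-energy floor below which the residual counts as zero
_ZERO_ENERGY_REL = 1e-14


@dataclass(frozen=True)
class StopRule:
    """Stopping criteria: energy fraction explained and/or atom count.

    Iteration halts as soon as either active criterion is met.
    """

    energy_fraction: float | None = 0.95
    max_atoms: int | None = 50

    def __post_init__(self) -> None:
        if self.energy_fraction is None and self.max_atoms is None:
            raise ValueError("at least one stopping criterion must be active")
        if self.energy_fraction is not None and not (0 < self.energy_fraction <= 1):
            raise ValueError("energy_fraction must lie in (0, 1]")
        if self.max_atoms is not None and self.max_atoms < 1:
            raise ValueError("max_atoms must be a positive integer")


@dataclass
class Decomposition:
    """Ordered result of a matching-pursuit run.

    ``atoms[k].coefficient`` is the signed projection of the k-th residual on
    the (unit-norm) selected atom; ``energy_ledger[k]`` is the pair
    (energy captured at iteration k, cumulative explained fraction).
    """

    atoms: list[AtomParams]
    residual: SignalRecord
    energy_ledger: list[tuple[float, float]]
    signal_energy: float
    stop_reason: str = ""
    dictionary_size: int | None = None

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([a.coefficient for a in self.atoms])

    @property
    def explained_fraction(self) -> float:
        if not self.energy_ledger:
            return 0.0
        return self.energy_ledger[-1][1]

    @property
    def fs(self) -> float:
        return self.residual.fs


def reconstruct(d: Decomposition, t: np.ndarray | None = None) -> np.ndarray:
    """Sum of the fitted waveforms (coefficient x unit-norm atom) on grid ``t``."""
    if t is None:
        t = d.residual.times
    out = np.zeros(np.shape(t), dtype=float)
    for p in d.atoms:
        out += evaluate_atom(p, t)
    return out


# ---------------------------------------------------------------------------
# exact single-atom projection (shared by selection, refinement and subtraction)


def _projection(x: np.ndarray, t: np.ndarray, p: AtomParams):
    """Project ``x`` on the atom shape ``p`` with the exactly optimal phase.

    Returns ``(value, coefficient, phase, unit_waveform)`` where ``value`` is
    the captured energy ``coefficient**2`` and ``unit_waveform`` the unit-norm
    real atom.  Maximizing over the phase is the orthogonal projection onto
    the two-dimensional span of the quadrature pair (env cos, env sin); the
    projected vector is itself of the form ``r env cos(theta + phase)``, so
    the optimum is read off a 2x2 Gram solve.
    """
    from .atoms import _raw_envelope  # internal, unnormalized

    env = _raw_envelope(p, t)
    theta = p.omega * (t - p.mu)
    ec = env * np.cos(theta)
    es = env * np.sin(theta)
    p1, p2 = float(x @ ec), float(x @ es)
    g11, g22, g12 = float(ec @ ec), float(es @ es), float(ec @ es)
    if not np.isfinite(g11 + g22) or g11 + g22 <= 0.0:
        return 0.0, 0.0, 0.0, None
    det = g11 * g22 - g12 * g12
    if det > 1e-12 * (g11 + g22) ** 2:
        c1 = (g22 * p1 - g12 * p2) / det
        c2 = (g11 * p2 - g12 * p1) / det
    elif g11 >= g22:  # degenerate pair (e.g. omega = 0): even part only
        c1, c2 = (p1 / g11 if g11 > 0 else 0.0), 0.0
    else:
        c1, c2 = 0.0, (p2 / g22 if g22 > 0 else 0.0)
    energy = c1 * p1 + c2 * p2  # = <x, proj x> >= 0
    if energy <= 0.0 or not np.isfinite(energy):
        return 0.0, 0.0, 0.0, None
    wave = c1 * ec + c2 * es  # = r * env * cos(theta + phase)
    nrm = np.sqrt(energy)  # ||wave|| = sqrt(c^T G c) = sqrt(c^T p)
    coef = nrm  # = <x, wave/||wave||>
    phase = float(np.arctan2(-c2, c1))
    return energy, coef, phase, wave / nrm


# ---------------------------------------------------------------------------
# FFT grid search


class _ShapeBank:
    """Per-(scale, asymmetry-level) correlation templates and window norms."""

    def __init__(self, spec: DictionarySpec, n: int, sigma: float, level: float):
        fs = spec.sampling_rate
        self.sigma = sigma
        self.level = level
        half = min(int(np.ceil(5.0 * np.sqrt(sigma) * fs)), n - 1)
        tau_idx = np.arange(-half, half + 1)
        tau = tau_idx / fs
        proto = spec.atom_from_level(0.0, spec.freq_grid[0], sigma, level)
        from .atoms import _raw_envelope

        env = _raw_envelope(replace(proto, mu=0.0), tau)
        keep = env > 0.0
        tau_idx, tau, env = tau_idx[keep], tau[keep], env[keep]
        self.tau_idx = tau_idx
        self.env = env
        self.m = next_fast_len(n + int(tau_idx.max() - tau_idx.min()) + 1)
        omega = 2.0 * np.pi * np.asarray(spec.freq_grid)
        # correlation kernels: A(mu) = sum_tau x(mu+tau) env(tau) e^{i w tau}
        pos = (-tau_idx) % self.m
        kern = np.zeros((omega.size, self.m), dtype=complex)
        kern[:, pos] = env[None, :] * np.exp(1j * omega[:, None] * tau[None, :])
        self.kernel_fft = fft(kern, axis=1)
        # window-truncated norms, residual-independent:
        #   S0(mu) = sum env^2 over the window, B(mu) = sum env^2 e^{2 i w tau}
        grid_idx = np.arange(0, n, spec.time_step)
        ones = np.zeros(self.m)
        ones[:n] = 1.0
        ones_fft = fft(ones)
        kern2 = np.zeros((omega.size + 1, self.m), dtype=complex)
        kern2[:-1, pos] = (env * env)[None, :] * np.exp(
            2j * omega[:, None] * tau[None, :])
        kern2[-1, pos] = env * env
        nb = ifft(ones_fft[None, :] * fft(kern2, axis=1), axis=1)[:, :n]
        self.B = nb[:-1, grid_idx]
        self.S0 = nb[-1, grid_idx].real


class _MatchContext:
    """Cached FFT machinery for one (dictionary, signal length) pair."""

    def __init__(self, spec: DictionarySpec, n: int):
        self.spec = spec
        self.n = n
        self.grid_idx = np.arange(0, n, spec.time_step)
        self.times = sample_grid(n, spec.sampling_rate)
        self.banks = [
            _ShapeBank(spec, n, sigma, level)
            for level in spec.alpha_levels
            for sigma in spec.scale_grid
        ]
        self._xfft: dict[int, np.ndarray] = {}

    def _x_fft(self, x: np.ndarray, m: int) -> np.ndarray:
        key = m
        cached = self._xfft.get(key)
        if cached is None or cached[0] is not x:
            xp = np.zeros(m)
            xp[: self.n] = x
            cached = (x, fft(xp))
            self._xfft[key] = cached
        return cached[1]

    def search(self, x: np.ndarray):
        """Best grid atom: maximize |<x, atom>| over grid and analytic phase.

        Returns ``(value, AtomParams)`` or ``None`` for a zero residual.
        Ties resolve to the smallest |asymmetry|, then scale, then frequency,
        then time position (scan order + strict improvement).
        """
        best_val = 0.0
        best = None
        spec = self.spec
        for bank in self.banks:
            xf = self._x_fft(x, bank.m)
            A = ifft(xf[None, :] * bank.kernel_fft, axis=1)[:, : self.n]
            A = A[:, self.grid_idx]
            a2 = A.real ** 2 + A.imag ** 2
            # exact phase-optimal captured energy: the projection onto the
            # 2-D span of the quadrature pair, via the Gram identities
            #   G = [[S0+ReB, ImB], [ImB, S0-ReB]] / 2,  p = (ReA, ImA):
            #   p^T G^{-1} p = 2 (S0 |A|^2 - Re(B conj(A)^2)) / (S0^2 - |B|^2)
            S0 = bank.S0[None, :]
            B = bank.B
            numer = S0 * a2 - (B * np.conj(A) ** 2).real
            denom = 0.5 * (S0 * S0 - B.real ** 2 - B.imag ** 2)
            np.maximum(denom, 1e-12 * S0 * S0, out=denom)
            with np.errstate(divide="ignore", invalid="ignore"):
                val = np.where(a2 > 0, numer / denom, 0.0)
            k = int(np.argmax(val))
            if val.flat[k] > best_val * (1 + 1e-12):
                fi, ti = np.unravel_index(k, val.shape)
                best_val = float(val.flat[k])
                best = (bank, fi, ti)
        if best is None or best_val <= 0.0:
            return None
        bank, fi, ti = best
        mu = self.grid_idx[ti] / spec.sampling_rate
        p = spec.atom_from_level(mu, spec.freq_grid[fi], bank.sigma, bank.level)
        return best_val, p


@lru_cache(maxsize=8)
def _get_context(spec: DictionarySpec, n: int) -> _MatchContext:
    return _MatchContext(spec, n)


# ---------------------------------------------------------------------------
# local refinement


def refine_parameters(candidate: AtomParams, residual: SignalRecord,
                      spec: DictionarySpec | None = None,
                      refine_alpha: bool = True,
                      maxiter: int = 400) -> AtomParams:
    """Polish (mu, freq, scale, asymmetry) of a grid winner by Nelder-Mead.

    The phase is re-derived analytically at every trial point.  The refined
    atom is returned only if its inner product with the residual is at least
    the candidate's; on any optimizer failure the candidate is returned.
    """
    x = residual.samples
    t = residual.times
    fs = residual.fs
    if spec is not None:
        dt = spec.time_step_s
        df = spec.freq_step_hz
        if not np.isfinite(df):
            df = fs / (4.0 * x.size)
    else:
        dt = 1.0 / fs
        df = fs / (4.0 * x.size)
    mu0, f0 = candidate.mu, candidate.frequency_hz
    lns0 = np.log(candidate.sigma)
    a0 = candidate.relative_alpha
    free_alpha = refine_alpha and not (
        spec is not None and spec.alpha_levels == (0.0,))

    def build(z):
        mu = mu0 + z[0] * dt
        f = f0 + z[1] * df
        sigma = np.exp(lns0 + z[2])
        a = z[3] if free_alpha else a0
        return replace(candidate, mu=mu, omega=2 * np.pi * f, sigma=sigma,
                       alpha=a / np.sqrt(sigma))

    def neg_value(z):
        val, _, _, _ = _projection(x, t, build(z))
        return -val

    z0 = np.array([0.0, 0.0, 0.0, a0])
    base_val = -neg_value(z0)
    bounds = [(-2.0, 2.0), (-2.0, 2.0), (-np.log(4.0), np.log(4.0)),
              (min(a0 - 2.0 * max(1.0, abs(a0)), -40.0 if free_alpha else a0),
               max(a0 + 2.0 * max(1.0, abs(a0)), 40.0 if free_alpha else a0))]
    # explicit initial simplex: Nelder-Mead's default perturbation of
    # zero-valued coordinates is ~2.5e-4, far too small to leave the grid
    # cell; a second pass with a fresh (smaller) simplex escapes the flat
    # valleys of the asymmetry/scale trade-off
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def one_pass(z_start, steps):
        simplex = np.vstack([z_start] + [z_start + steps[i] * np.eye(4)[i]
                                         for i in range(4)])
        simplex = np.clip(simplex, lo, hi)
        return minimize(neg_value, z_start, method="Nelder-Mead",
                        bounds=bounds,
                        options={"maxiter": maxiter, "xatol": 1e-4,
                                 "initial_simplex": simplex,
                                 "fatol": base_val * 1e-12 + 1e-300})

    steps = np.array([0.5, 0.5, 0.25, 0.5 * max(1.0, abs(a0))])
    try:
        res = one_pass(z0, steps)
        res2 = one_pass(res.x, 0.5 * steps)
        if res2.fun < res.fun:
            res = res2
        if -res.fun >= base_val:
            return build(res.x)
    except (ValueError, FloatingPointError):  # fall back to the grid winner
        pass
    return candidate


# ---------------------------------------------------------------------------
# public functional API


def _as_record(signal, fs: float | None) -> SignalRecord:
    if isinstance(signal, SignalRecord):
        return signal
    if fs is None:
        raise ValueError("a sampling rate is required for array input")
    return SignalRecord(samples=np.asarray(signal, dtype=float), fs=fs)


def best_match(residual: SignalRecord, spec: DictionarySpec):
    """Dictionary atom maximizing |<residual, atom>| over grid and phase.

    Returns ``(AtomParams, coefficient)`` with the signed projection stored in
    both, or ``None`` when the residual is (numerically) zero.
    """
    ctx = _get_context(spec, residual.n)
    hit = ctx.search(residual.samples)
    if hit is None:
        return None
    _, p = hit
    _, coef, phase, _ = _projection(residual.samples, ctx.times, p)
    p = replace(p, phase=phase, coefficient=coef)
    return p, coef


def decompose(signal, spec: DictionarySpec, stop: StopRule | None = None, *,
              fs: float | None = None, refine: bool = True) -> Decomposition:
    """Greedy matching-pursuit decomposition (functional front end).

    Thin wrapper over :class:`MatchingPursuit`; see its documentation.
    """
    record = _as_record(signal, fs)
    stop = stop or StopRule()
    mp = MatchingPursuit(dictionary=spec, fs=record.fs,
                         energy_fraction=stop.energy_fraction,
                         max_atoms=stop.max_atoms, refine=refine)
    mp.fit(record)
    return mp.decomposition_


# ---------------------------------------------------------------------------
# estimator


class MatchingPursuit(BaseEstimator):
    """Greedy matching pursuit with an enriched (asymmetric) Gabor dictionary.

    Parameters
    ----------
    dictionary : DictionarySpec
        The discrete dictionary to search.  Use
        :func:`edmp.dictionary.gabor_variant` for the symmetric-only baseline.
    fs : float, optional
        Sampling rate; required when ``fit`` receives a bare array.
    energy_fraction : float or None, default 0.95
        Stop once this fraction of the signal energy is explained.
    max_atoms : int or None, default 50
        Stop after this many atoms.
    refine : bool, default True
        Locally polish each grid winner's continuous parameters.

    Attributes
    ----------
    atoms_ : list of AtomParams
        Selected atoms in order, with phases and signed coefficients.
    coefficients_ : ndarray
        Projections ``<R^n f, g_n>``.
    residual_ : SignalRecord
        Final residual.
    energy_ledger_ : list of (float, float)
        Per-iteration (captured energy, cumulative explained fraction).
    explained_fraction_ : float
    n_iter_ : int
    dictionary_size_ : int
    stop_reason_ : str

    Examples
    --------
    >>> from edmp import MatchingPursuit, oae_dictionary, asymmetric_transient
    >>> sig = asymmetric_transient()
    >>> mp = MatchingPursuit(oae_dictionary(), max_atoms=1).fit(sig)
    >>> mp.explained_fraction_ > 0.95
    True
    """

    def __init__(self, dictionary: DictionarySpec | None = None, *,
                 fs: float | None = None,
                 energy_fraction: float | None = 0.95,
                 max_atoms: int | None = 50,
                 refine: bool = True):
        self.dictionary = dictionary
        self.fs = fs
        self.energy_fraction = energy_fraction
        self.max_atoms = max_atoms
        self.refine = refine

    def _resolve(self, X) -> tuple[SignalRecord, DictionarySpec]:
        record = _as_record(X, self.fs)
        if record.n == 0:
            raise ValueError("cannot decompose an empty signal")
        spec = self.dictionary
        if spec is None:
            spec = _generic_dictionary(record.fs, record.n)
        if abs(spec.sampling_rate - record.fs) > 1e-9 * record.fs:
            raise ValueError(
                f"signal rate {record.fs} Hz does not match dictionary rate "
                f"{spec.sampling_rate} Hz")
        return record, spec

    def fit(self, X, y=None):
        """Decompose the signal ``X`` (1-D array or SignalRecord)."""
        record, spec = self._resolve(X)
        stop = StopRule(self.energy_fraction, self.max_atoms)  # validates
        ctx = _get_context(spec, record.n)
        x = record.samples.copy()
        e0 = float(x @ x)
        atoms: list[AtomParams] = []
        ledger: list[tuple[float, float]] = []
        reason = "max_atoms"
        if e0 <= 0.0:
            reason = "zero_signal"
        else:
            n_max = stop.max_atoms if stop.max_atoms is not None else np.inf
            while len(atoms) < n_max:
                hit = ctx.search(x)
                if hit is None:
                    reason = "zero_residual"
                    break
                _, cand = hit
                if self.refine:
                    cand = refine_parameters(cand, SignalRecord(x, record.fs),
                                             spec)
                val, coef, phase, wave = _projection(x, ctx.times, cand)
                if wave is None or val <= _ZERO_ENERGY_REL * e0:
                    reason = "zero_residual"
                    break
                x = x - coef * wave
                p = replace(cand, phase=phase, coefficient=coef)
                # absorb the window normalization so evaluate_atom(p) is the
                # coefficient-scaled unit-norm waveform
                from .atoms import _raw_envelope

                raw = _raw_envelope(p, ctx.times) * np.cos(
                    p.omega * (ctx.times - p.mu) + phase)
                p = replace(p, norm=1.0 / float(np.linalg.norm(raw)))
                atoms.append(p)
                e_res = float(x @ x)
                ledger.append((coef * coef, 1.0 - e_res / e0))
                if stop.energy_fraction is not None and \
                        ledger[-1][1] >= stop.energy_fraction:
                    reason = "energy_fraction"
                    break
                if e_res <= _ZERO_ENERGY_REL * e0:
                    reason = "zero_residual"
                    break

        self.atoms_ = atoms
        self.coefficients_ = np.array([a.coefficient for a in atoms])
        self.residual_ = SignalRecord(x, record.fs, record.t0)
        self.energy_ledger_ = ledger
        self.signal_energy_ = e0
        self.explained_fraction_ = ledger[-1][1] if ledger else 0.0
        self.n_iter_ = len(atoms)
        self.dictionary_ = spec
        self.dictionary_size_ = dictionary_size(spec)
        self.stop_reason_ = reason
        self.decomposition_ = Decomposition(
            atoms=atoms, residual=self.residual_, energy_ledger=ledger,
            signal_energy=e0, stop_reason=reason,
            dictionary_size=self.dictionary_size_)
        return self

    def reconstruct(self, t: np.ndarray | None = None) -> np.ndarray:
        """Sum of the fitted waveforms; ``reconstruct() + residual == input``."""
        return reconstruct(self.decomposition_, t)

    def score(self, X=None, y=None) -> float:
        """Explained energy fraction of the fitted decomposition."""
        return self.explained_fraction_


def _generic_dictionary(fs: float, n: int) -> DictionarySpec:
    """Fallback dictionary spanning the window when none is supplied."""
    duration = n / fs
    f_lo = 2.0 / duration
    f_hi = 0.45 * fs
    freqs = np.linspace(f_lo, f_hi, 48)
    widths = np.geomspace(4.0 / fs, duration / 4.0, 6)
    return DictionarySpec(
        sampling_rate=fs, window_length=n,
        freq_grid=tuple(freqs), scale_grid=tuple(w * w for w in widths),
        time_step=max(1, n // 256),
    )
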