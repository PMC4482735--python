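"""Synthetic test signals and fixtures.

All generators are pure functions of their arguments (including the seed), so
every experiment in the test-suite and the acceptance runs is reproducible
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atoms import AtomParams, evaluate_atom, normalize, sample_grid

__all__ = [
    "SignalRecord",
    "asymmetric_transient",
    "transient_envelope",
    "three_component_signal",
    "single_atom_fixture",
    "write_signal_text",
]


@dataclass
class SignalRecord:
    """One real-valued, uniformly sampled channel.

    Attributes
    ----------
    samples : ndarray
        Signal values.
    fs : float
        Sampling rate, Hz.
    t0 : float
        Time of sample 0, seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not (self.fs > 0):
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return sample_grid(self.n, self.fs, self.t0)

    @property
    def energy(self) -> float:
        """Discrete L2 energy (sum of squared samples)."""
        return float(self.samples @ self.samples)


def transient_envelope(t: np.ndarray) -> np.ndarray:
    """Envelope ``t / (1e-6 + t^2)`` of the asymmetric test transient.

    Rises steeply (~linearly) from zero, peaks at ``t = 1e-3`` s with value
    500, then decays slowly as ``~1/t``.
    """
    t = np.asarray(t, dtype=float)
    return t / (1e-6 + t * t)


def asymmetric_transient(carrier_hz: float = 2000.0, fs: float = 25600.0,
                         duration: float = 5e-3) -> SignalRecord:
    """The asymmetric test signal ``f(t) = t/(1e-6 + t^2) * cos(2 pi f0 t)``.

    This waveform is *not* a member of the dictionary: its 1/t decay probes
    how sparsely a steep-rise/slow-decay transient can be encoded.  Defaults
    place a 2 kHz carrier (mid TEOAE band) at the OAE sampling rate of
    25600 Hz on a 5 ms window, i.e. 10 carrier cycles under the envelope.
    """
    if not (0 < carrier_hz < fs / 2):
        raise ValueError("carrier must lie below Nyquist")
    t = sample_grid(int(round(duration * fs)), fs)
    x = transient_envelope(t) * np.cos(2.0 * np.pi * carrier_hz * t)
    return SignalRecord(samples=x, fs=fs)


def _component_atoms(fs: float) -> list[tuple[str, float, AtomParams]]:
    """Ground-truth components of the three-component simulation.

    One long-lasting asymmetric 15 Hz oscillation with a steep onset (mirrored
    atom, scale-free asymmetry 10, 2 s Gaussian decay) plus two ~1 s
    spindle-like Gabor bursts at 12 Hz and 10 Hz.
    """
    ssvep = AtomParams(mu=1.5, omega=2 * np.pi * 15.0, sigma=2.0 ** 2,
                       alpha=10.0 / 2.0, mirror=True)
    spindle12 = AtomParams(mu=3.0, omega=2 * np.pi * 12.0, sigma=0.25 ** 2)
    spindle10 = AtomParams(mu=5.5, omega=2 * np.pi * 10.0, sigma=0.25 ** 2)
    return [("asymmetric", 1.0, ssvep),
            ("spindle", 1.0, spindle12),
            ("spindle", 1.0, spindle10)]


def three_component_signal(fs: float = 128.0, duration: float = 8.0,
                           noise_fraction: float = 0.1,
                           seed: int | None = None,
                           ) -> tuple[SignalRecord, pd.DataFrame]:
    """Composite of an asymmetric 15 Hz wave and 12/10 Hz spindles plus noise.

    The 15 Hz component emulates a steady-state evoked response: steep onset
    at ~1.5 s and a slow decay lasting several seconds.  The spindles are
    symmetric Gabor bursts of ~1 s span.  Seeded white Gaussian noise is
    added with RMS amplitude ``noise_fraction`` times the clean signal RMS.

    Returns the signal and a ground-truth table (one row per component:
    frequency, center time, envelope type, peak amplitude, scale).
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    t = sample_grid(int(round(duration * fs)), fs)
    clean = np.zeros_like(t)
    rows = []
    for kind, amplitude, p in _component_atoms(fs):
        # peak envelope amplitude = `amplitude` (norm left at 1)
        clean += amplitude * evaluate_atom(p, t)
        rows.append({
            "component": kind,
            "frequency_hz": p.frequency_hz,
            "center_s": p.mu,
            "amplitude": amplitude,
            "sigma": p.sigma,
            "alpha": p.alpha,
            "mirror": p.mirror,
        })
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(t.size)
        rms = np.sqrt(np.mean(clean ** 2))
        noise *= noise_fraction * rms / np.sqrt(np.mean(noise ** 2))
        samples = clean + noise
    else:
        samples = clean
    return SignalRecord(samples=samples, fs=fs), pd.DataFrame(rows)


def single_atom_fixture(p: AtomParams, coefficient: float, fs: float,
                        duration: float, noise_variance_ratio: float = 0.0,
                        seed: int | None = None,
                        ) -> tuple[SignalRecord, pd.DataFrame]:
    """``coefficient x unit-norm atom`` plus seeded Gaussian noise.

    ``noise_variance_ratio`` is the noise-to-signal variance ratio (the
    robustness experiments use ratio 2, i.e. noise variance twice the clean
    signal variance over the window).
    """
    n = int(round(duration * fs))
    p = normalize(p, n, fs)
    t = sample_grid(n, fs)
    clean = coefficient * evaluate_atom(p, t)
    if noise_variance_ratio < 0:
        raise ValueError("noise_variance_ratio must be >= 0")
    if noise_variance_ratio > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(n)
        target_var = noise_variance_ratio * float(np.var(clean))
        noise *= np.sqrt(target_var / np.var(noise))
        samples = clean + noise
    else:
        samples = clean
    truth = pd.DataFrame([{
        "frequency_hz": p.frequency_hz,
        "center_s": p.mu,
        "coefficient": coefficient,
        "sigma": p.sigma,
        "alpha": p.alpha,
        "mirror": p.mirror,
        "phase": p.phase,
    }])
    return SignalRecord(samples=samples, fs=fs), truth


def write_signal_text(record: SignalRecord, path, truth: pd.DataFrame | None = None,
                      truth_path=None) -> None:
    """Write a signal as single-column text, optionally with a truth sidecar CSV."""
    np.savetxt(path, record.samples)
    if truth is not None:
        if truth_path is None:
            raise ValueError("truth_path required when truth is given")
        truth.to_csv(truth_path, index=False)
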