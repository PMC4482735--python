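"""Discrete dictionaries over the asymmetric atom family.

A dictionary is the Cartesian product of four grids: time positions, carrier
frequencies, scales, and asymmetry levels.  Asymmetry levels are *scale-free*:
a level ``a`` maps to an absolute slope ``alpha = a / sqrt(sigma)``, so a
given level produces the same envelope *shape* at every scale.  The sign of a
level selects the shape family:

* ``a = 0``  — symmetric Gabor atom;
* ``a < 0``  — Gaussian rise, slower-than-Gaussian decay (clamped at the
  monotonicity boundary);
* ``a > 0``  — mirrored atom: steeper-than-Gaussian rise, Gaussian decay.

The Gabor dictionary (GD) is the ``alpha_levels == (0,)`` special case of the
enriched dictionary (ED); the default ED carries 13 levels, i.e. it is 13
times larger than the GD over the same time/frequency/scale grids.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np

from .atoms import DEFAULT_BETA, AtomParams

__all__ = [
    "DictionarySpec",
    "DEFAULT_ALPHA_LEVELS",
    "enumerate_dictionary",
    "dictionary_size",
    "gabor_variant",
    "oae_dictionary",
    "eeg_dictionary",
    "read_dictionary_config",
    "write_dictionary_config",
]

#: 13 default asymmetry levels (Gabor + 6 slow-decay + 6 steep-rise shapes)
DEFAULT_ALPHA_LEVELS = (
    0.0, -0.1, 0.1, -0.25, 0.25, -0.5, 0.5, -1.0, 1.0, -3.0, 3.0, -10.0, 10.0
)


class ConfigurationError(ValueError):
    """Raised for inconsistent dictionary configurations."""


def _as_sorted_tuple(values) -> tuple[float, ...]:
    return tuple(float(v) for v in np.sort(np.unique(np.asarray(values, float))))


@dataclass(frozen=True)
class DictionarySpec:
    """Grids generating a discrete enriched dictionary.

    Parameters
    ----------
    sampling_rate : float
        Sampling rate in Hz.
    window_length : int
        Analysis window length in samples; atom time positions and
        normalization live on this window.
    freq_grid : tuple of float
        Carrier frequencies in Hz; all must be below Nyquist.
    scale_grid : tuple of float
        Scales ``sigma`` in seconds^2.
    alpha_levels : tuple of float
        Scale-free asymmetry levels (see module docstring); must contain 0 so
        the Gabor dictionary is a strict subset.
    time_step : int
        Spacing of the time-position grid in samples.
    beta : float
        Shared atan sharpness constant.
    """

    sampling_rate: float
    window_length: int
    freq_grid: tuple[float, ...]
    scale_grid: tuple[float, ...]
    alpha_levels: tuple[float, ...] = DEFAULT_ALPHA_LEVELS
    time_step: int = 1
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        object.__setattr__(self, "freq_grid", _as_sorted_tuple(self.freq_grid))
        object.__setattr__(self, "scale_grid", _as_sorted_tuple(self.scale_grid))
        # order alpha levels by |a| (Gabor first), slow-decay before steep-rise,
        # so "first maximum wins" implements the simplest-shape tie-break
        levels = sorted(set(float(a) for a in self.alpha_levels),
                        key=lambda a: (abs(a), a))
        object.__setattr__(self, "alpha_levels", tuple(levels))
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if self.window_length < 1 or self.time_step < 1:
            raise ConfigurationError("window_length and time_step must be >= 1")
        if not self.freq_grid or not self.scale_grid or not self.alpha_levels:
            raise ConfigurationError("all parameter grids must be non-empty")
        if 0.0 not in self.alpha_levels:
            raise ConfigurationError("alpha_levels must contain 0 (Gabor subset)")
        nyquist = self.sampling_rate / 2.0
        if max(self.freq_grid) >= nyquist:
            raise ConfigurationError(
                f"frequency grid reaches {max(self.freq_grid)} Hz, "
                f">= Nyquist {nyquist} Hz"
            )
        if min(self.freq_grid) < 0:
            raise ConfigurationError("frequencies must be non-negative")
        if min(self.scale_grid) <= 0:
            raise ConfigurationError("scales must be > 0")

    @property
    def time_grid(self) -> np.ndarray:
        """Atom time positions in seconds (sample 0 maps to t = 0)."""
        idx = np.arange(0, self.window_length, self.time_step)
        return idx / self.sampling_rate

    @property
    def freq_step_hz(self) -> float:
        """Spacing of the frequency grid (grid-step unit for recovery checks)."""
        if len(self.freq_grid) < 2:
            return np.inf
        return float(np.min(np.diff(self.freq_grid)))

    @property
    def time_step_s(self) -> float:
        return self.time_step / self.sampling_rate

    def atom_from_level(self, mu: float, freq_hz: float, sigma: float,
                        level: float) -> AtomParams:
        """Instantiate the (unnormalized) atom for one grid combination."""
        return AtomParams(
            mu=float(mu),
            omega=2.0 * np.pi * float(freq_hz),
            sigma=float(sigma),
            alpha=float(level) / np.sqrt(float(sigma)),
            beta=self.beta,
            mirror=level > 0,
        )


def dictionary_size(spec: DictionarySpec) -> int:
    """Cardinality = |time grid| * |freq grid| * |scale grid| * |alpha levels|."""
    return (len(spec.time_grid) * len(spec.freq_grid)
            * len(spec.scale_grid) * len(spec.alpha_levels))


def enumerate_dictionary(spec: DictionarySpec) -> Iterator[AtomParams]:
    """Yield every (mu, omega, sigma, alpha) combination exactly once.

    Atoms are yielded unnormalized (normalization depends on the analysis
    window; see :func:`edmp.atoms.normalize`).  Order: asymmetry level by
    increasing |a|, then scale, then frequency, then time position.
    """
    for level in spec.alpha_levels:
        for sigma in spec.scale_grid:
            for freq in spec.freq_grid:
                for mu in spec.time_grid:
                    yield spec.atom_from_level(mu, freq, sigma, level)


def gabor_variant(spec: DictionarySpec) -> DictionarySpec:
    """The Gabor-only (symmetric) dictionary over the same grids."""
    return replace(spec, alpha_levels=(0.0,))


def oae_dictionary(fs: float = 25600.0, window_length: int = 128, *,
                   freq_range: tuple[float, float] = (500.0, 5000.0),
                   freq_step: float = 12.5,
                   time_step_s: float = 2e-4,
                   scale_widths_s: tuple[float, ...] = (
                       0.25e-3, 0.5e-3, 1e-3, 2e-3, 4e-3),
                   alpha_levels: tuple[float, ...] = DEFAULT_ALPHA_LEVELS,
                   ) -> DictionarySpec:
    """Dictionary preset for otoacoustic-emission-like transients.

    Defaults follow click-evoked OAE practice: 25600 Hz sampling, a 0.5-5 kHz
    band with 12.5 Hz frequency resolution, 0.2 ms time resolution, and a
    dyadic ladder of sub-millisecond to few-millisecond envelope widths.
    """
    f_lo, f_hi = freq_range
    freqs = np.arange(f_lo, f_hi + freq_step / 2, freq_step)
    scales = tuple(w * w for w in scale_widths_s)
    return DictionarySpec(
        sampling_rate=fs,
        window_length=window_length,
        freq_grid=tuple(freqs),
        scale_grid=scales,
        alpha_levels=alpha_levels,
        time_step=max(1, int(round(time_step_s * fs))),
    )


def eeg_dictionary(fs: float = 128.0, window_length: int = 1024, *,
                   freq_range: tuple[float, float] = (2.0, 30.0),
                   freq_step: float = 0.5,
                   scale_widths_s: tuple[float, ...] = (
                       0.125, 0.25, 0.5, 1.0, 2.0, 4.0),
                   alpha_levels: tuple[float, ...] = DEFAULT_ALPHA_LEVELS,
                   ) -> DictionarySpec:
    """Dictionary preset for EEG-band signals (spindles, SSVEP-like responses)."""
    f_lo, f_hi = freq_range
    freqs = np.arange(f_lo, f_hi + freq_step / 2, freq_step)
    scales = tuple(w * w for w in scale_widths_s)
    return DictionarySpec(
        sampling_rate=fs,
        window_length=window_length,
        freq_grid=tuple(freqs),
        scale_grid=scales,
        alpha_levels=alpha_levels,
        time_step=1,
    )


# ---------------------------------------------------------------------------
# flat key=value configuration files


def write_dictionary_config(spec: DictionarySpec, path) -> None:
    """Write a dictionary specification as a flat key=value text file."""
    lines = [
        f"fs = {spec.sampling_rate}",
        f"window_length = {spec.window_length}",
        f"time_step = {spec.time_step}",
        f"freq_grid = {','.join(repr(f) for f in spec.freq_grid)}",
        f"scale_grid = {','.join(repr(s) for s in spec.scale_grid)}",
        f"alpha_levels = {','.join(repr(a) for a in spec.alpha_levels)}",
        f"beta = {spec.beta}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dictionary_config(path) -> DictionarySpec:
    """Read a flat key=value dictionary configuration file."""
    kv: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"malformed config line: {raw!r}")
            key, val = line.split("=", 1)
            kv[key.strip()] = val.strip()
    try:
        return DictionarySpec(
            sampling_rate=float(kv["fs"]),
            window_length=int(kv["window_length"]),
            freq_grid=tuple(float(x) for x in kv["freq_grid"].split(",")),
            scale_grid=tuple(float(x) for x in kv["scale_grid"].split(",")),
            alpha_levels=tuple(float(x) for x in kv["alpha_levels"].split(",")),
            time_step=int(kv.get("time_step", 1)),
            beta=float(kv.get("beta", DEFAULT_BETA)),
        )
    except KeyError as exc:
        raise ConfigurationError(f"missing config key: {exc}") from exc
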