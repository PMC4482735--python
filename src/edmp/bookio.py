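"""Readers and writers: signals in, "book" tables out.

A *book* is the tabular serialization of a decomposition, one row per atom in
selection order, with the clinically quoted columns (amplitude, width,
latency, frequency) plus the full parameter set needed to rebuild each
waveform exactly.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .atoms import AtomParams
from .engine import Decomposition
from .signals import SignalRecord
from .tfmaps import atom_width

__all__ = ["read_signal", "write_book", "read_book", "book_table"]

#: user-facing columns; the trailing ones make the round trip exact
BOOK_COLUMNS = [
    "Amplitude", "Width [s]", "Latency [s]", "Frequency [Hz]", "Alpha",
    "Phase [rad]", "ExplainedFraction",
    "Coefficient", "Mu [s]", "Sigma [s^2]", "Mirror", "Norm", "Beta",
]


class SignalParseError(ValueError):
    """Raised when a signal file cannot be parsed."""


def read_signal(path, fs: float | None = None,
                column: str | None = None) -> SignalRecord:
    """Load a single-channel signal.

    Supported formats: single-column delimited text, CSV with a named column
    (``column=``), and WAV.  Text and CSV input require ``fs``; for WAV the
    header rate is used unless ``fs`` overrides it.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".wav":
        from scipy.io import wavfile

        header_fs, data = wavfile.read(path)
        data = np.asarray(data, dtype=float)
        if data.ndim > 1:
            data = data[:, 0]
        return SignalRecord(samples=data, fs=float(fs or header_fs))
    if ext == ".csv" or column is not None:
        if fs is None:
            raise SignalParseError("a sampling rate is required for CSV input")
        frame = pd.read_csv(path)
        if column is None:
            if frame.shape[1] != 1:
                raise SignalParseError(
                    "CSV has several columns; pass column= to choose one")
            column = frame.columns[0]
        if column not in frame.columns:
            raise SignalParseError(
                f"column {column!r} not found in {path} "
                f"(available: {list(frame.columns)})")
        return SignalRecord(samples=frame[column].to_numpy(float), fs=float(fs))
    # plain delimited text, one sample per line
    if fs is None:
        raise SignalParseError("a sampling rate is required for text input")
    values = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                values.append(float(line.split()[0]))
            except ValueError as exc:
                raise SignalParseError(
                    f"{path}:{lineno}: non-numeric value {line!r}") from exc
    return SignalRecord(samples=np.asarray(values), fs=float(fs))


def book_table(d: Decomposition) -> pd.DataFrame:
    """The book as a DataFrame (one row per atom in selection order).

    ``Amplitude`` is the peak amplitude of the fitted waveform's envelope
    (|coefficient| x normalized envelope maximum), ``Latency`` the time of
    that maximum (= the atom center ``mu``), ``Width`` the central-95%%
    envelope-energy duration, ``Frequency`` the carrier in Hz.
    """
    rows = []
    for p, (captured, cumfrac) in zip(d.atoms, d.energy_ledger):
        rows.append({
            "Amplitude": abs(p.coefficient) * p.norm,
            "Width [s]": atom_width(p),
            "Latency [s]": p.mu,
            "Frequency [Hz]": p.frequency_hz,
            "Alpha": p.alpha,
            "Phase [rad]": p.phase,
            "ExplainedFraction": cumfrac,
            "Coefficient": p.coefficient,
            "Mu [s]": p.mu,
            "Sigma [s^2]": p.sigma,
            "Mirror": int(p.mirror),
            "Norm": p.norm,
            "Beta": p.beta,
        })
    return pd.DataFrame(rows, columns=BOOK_COLUMNS)


def write_book(d: Decomposition, path) -> None:
    """Serialize a decomposition as a book CSV (header-only when empty)."""
    book_table(d).to_csv(path, index=False, float_format="%.17g")


def read_book(path, fs: float, n_samples: int) -> Decomposition:
    """Rebuild a Decomposition from a book CSV.

    ``fs`` and ``n_samples`` recreate the analysis window; the residual is
    left as zeros (a book stores the model, not the residual), so
    ``reconstruct`` of the result reproduces the modeled signal part.
    """
    frame = pd.read_csv(path)
    atoms = []
    ledger = []
    for _, row in frame.iterrows():
        atoms.append(AtomParams(
            mu=float(row["Mu [s]"]),
            omega=2.0 * np.pi * float(row["Frequency [Hz]"]),
            sigma=float(row["Sigma [s^2]"]),
            alpha=float(row["Alpha"]),
            beta=float(row["Beta"]),
            phase=float(row["Phase [rad]"]),
            coefficient=float(row["Coefficient"]),
            mirror=bool(int(row["Mirror"])),
            norm=float(row["Norm"]),
        ))
        ledger.append((float(row["Coefficient"]) ** 2,
                       float(row["ExplainedFraction"])))
    residual = SignalRecord(samples=np.zeros(int(n_samples)), fs=float(fs))
    energy = float(sum(c for c, _ in ledger))
    if ledger and ledger[-1][1] > 0:
        energy = float(sum(c for c, _ in ledger)) / ledger[-1][1]
    return Decomposition(atoms=atoms, residual=residual, energy_ledger=ledger,
                         signal_energy=energy, stop_reason="from_book")
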