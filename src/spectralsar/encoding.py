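"""Numeric encoding of protein sequences and FFT protein spectra.

A protein sequence becomes a discrete signal s(0..N−1) by replacing each
residue with its value from an encoding index.  The discrete Fourier
transform

    S(k) = sum_{n=0}^{N-1} s(n) exp(-2 i pi k n / N)

turns that signal into an energy-versus-frequency representation, the
*protein spectrum*.  Because the input is real, the spectrum is
Hermitian-symmetric and only bins k = 0..floor(M/2) are kept.

The spectrum is the feature vector used for sequence–activity
regression.  Energies are quadratic in the signal, so a single-residue
substitution perturbs every frequency bin, and features of a
multi-point variant are *not* the sum of the single-variant features —
the mechanism that lets spectrum-based models represent epistasis.
Encoding without the transform ("no-FFT" mode) keeps the raw
per-position values, which are exactly linear in substitutions.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .aaindex import EncodingIndex

Mode = Literal["fft", "no_fft"]
Energy = Literal["squared", "magnitude"]


class EncodingError(ValueError):
    """A sequence could not be encoded with the given index."""


@dataclass(frozen=True)
class NumericSignal:
    """A numerically encoded sequence, possibly zero-padded.

    ``values[n]`` is the index value of residue n+1; any padded tail is
    exactly zero.  ``source_length`` is the residue count before padding.
    """

    values: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.values) < self.source_length:
            raise ValueError("signal shorter than its source length")
        if not np.all(self.values[self.source_length :] == 0.0):
            raise ValueError("padded tail must be exactly zero")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ProteinSpectrum:
    """Energy per frequency bin k = 0..floor(M/2) of an encoded sequence."""

    energies: np.ndarray
    signal_length: int
    index_accession: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "energies", np.asarray(self.energies, dtype=float))
        if np.any(self.energies < 0):
            raise ValueError("spectrum energies must be non-negative")


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-variant feature vectors (spectrum energies or raw signals)."""

    values: np.ndarray  # shape (n_variants, n_features)
    row_ids: tuple[str, ...]
    columns: tuple[str, ...]
    mode: Mode
    index_accession: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length mismatch")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("row_ids must be unique")
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("columns length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_ids), columns=list(self.columns))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("id").to_csv(path)


def encode_sequence(seq: str, index: EncodingIndex) -> NumericSignal:
    """Replace each residue of ``seq`` by its value in ``index``.

    Raises
    ------
    EncodingError
        If the sequence is empty or contains a residue absent from the
        index (non-canonical letters, or residues the index marks NA);
        the message names the 1-based position and the residue.
    """
    if not seq:
        raise EncodingError("cannot encode an empty sequence")
    values = np.empty(len(seq))
    for pos, aa in enumerate(seq, start=1):
        try:
            values[pos - 1] = index.values[aa]
        except KeyError:
            raise EncodingError(
                f"residue {aa!r} at position {pos} has no value in index "
                f"{index.accession}"
            ) from None
    return NumericSignal(values=values, source_length=len(seq))


def protein_spectrum(
    signal: NumericSignal,
    pad_to: int | None = None,
    energy: Energy = "squared",
    index_accession: str | None = None,
) -> ProteinSpectrum:
    """Compute the protein spectrum of a numeric signal.

    Energies are |S(k)|² per default (``energy="squared"``) or |S(k)|
    (``energy="magnitude"``); either way only the non-redundant half
    spectrum k = 0..floor(M/2) is kept, DC bin included.  ``pad_to``
    zero-pads the signal to length M before the transform.
    """
    if pad_to is not None and pad_to < len(signal):
        raise ValueError(f"pad_to={pad_to} is shorter than the signal ({len(signal)})")
    values = signal.values
    if pad_to is not None and pad_to > len(values):
        values = np.concatenate([values, np.zeros(pad_to - len(values))])
    spectrum = np.fft.rfft(values)
    mag = np.abs(spectrum)
    energies = mag**2 if energy == "squared" else mag
    return ProteinSpectrum(
        energies=energies,
        signal_length=len(values),
        index_accession=index_accession,
    )


def next_power_of_two(n: int) -> int:
    """Smallest power of two >= n (convenience pad_to value)."""
    return 1 << (int(n) - 1).bit_length()


def encode_dataset(
    seqs: Sequence[str],
    ids: Sequence[str],
    index: EncodingIndex,
    mode: Mode = "fft",
    pad_to: int | None = None,
    energy: Energy = "squared",
) -> FeatureMatrix:
    """Encode equal-length sequences into a feature matrix.

    ``mode="fft"`` rows are protein-spectrum energies (columns
    ``f0..fK``); ``mode="no_fft"`` rows are the raw per-position index
    values (columns ``p1..pN``).  Row order follows input order.

    Raises
    ------
    ValueError
        If sequences differ in length (the method is defined for
        substitution-only variant sets), ids are not unique, or the
        mode is unknown.
    """
    seqs = list(seqs)
    ids = [str(i) for i in ids]
    if not seqs:
        raise ValueError("empty dataset")
    if len(seqs) != len(ids):
        raise ValueError("seqs and ids must have equal length")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(
            f"all sequences must have equal length, got lengths {sorted(lengths)}"
        )
    if mode not in ("fft", "no_fft"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for seq in seqs:
        signal = encode_sequence(seq, index)
        if mode == "fft":
            rows.append(protein_spectrum(signal, pad_to=pad_to, energy=energy).energies)
        else:
            rows.append(signal.values)
    values = np.vstack(rows)
    if mode == "fft":
        columns = tuple(f"f{k}" for k in range(values.shape[1]))
    else:
        columns = tuple(f"p{n}" for n in range(1, values.shape[1] + 1))
    return FeatureMatrix(
        values=values,
        row_ids=tuple(ids),
        columns=columns,
        mode=mode,
        index_accession=index.accession,
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_wildtype(path: str | Path) -> str:
    """Read the single wild-type sequence from a FASTA file."""
    records = read_fasta(path)
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record in {path}, got {len(records)}")
    return records[0][1]
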