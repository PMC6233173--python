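"""Amino-acid encoding indices in AAindex1 flat-file format.

An *encoding index* assigns one real number to each of the 20 canonical
amino acids — a hydropathy scale, an electron–ion interaction potential,
a molecular weight, and so on.  Replacing every residue of a protein
sequence by its index value turns the sequence into a numeric signal,
the first step of spectral sequence–activity modelling.

The AAindex1 flat file is a line-tagged record format: ``H`` carries the
accession, ``D`` a free-text description, and the ``I`` block a header
line followed by two rows of ten values in the fixed residue order
``A R N D C Q E G H I`` / ``L K M F P S T W Y V``.  Records end with
``//``.  Only H, D and I are interpreted here; the remaining blocks
(R, A, T, J, C, ...) are retained verbatim so that records round-trip.
Missing values are written ``NA`` in the distribution and flag the
index as unusable for encoding.
"""
from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

#: Residue order of the AAindex1 I block (first row then second row).
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_RESIDUES = frozenset(AA_ORDER)

_INTERPRETED_TAGS = {"H", "D", "I"}


class AAindexParseError(ValueError):
    """A record in an AAindex1 stream could not be parsed."""


class IndexLookupError(KeyError):
    """No encoding index with the requested accession exists."""


@dataclass(frozen=True)
class EncodingIndex:
    """One per-amino-acid numeric property table (one AAindex1 record).

    Parameters
    ----------
    accession : str
        Database identifier, e.g. ``"KYTJ820101"``.
    description : str
        Free-text description from the D line.
    values : mapping of str to float
        Value per one-letter residue code.  Residues whose source value
        was ``NA`` are absent.
    extra_blocks : tuple of (str, str)
        Uninterpreted blocks (tag, text) preserved for round-tripping.
    """

    accession: str
    description: str = ""
    values: Mapping[str, float] = field(default_factory=dict)
    extra_blocks: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        unknown = set(self.values) - CANONICAL_RESIDUES
        if unknown:
            raise ValueError(f"non-canonical residues in index: {sorted(unknown)}")

    @property
    def has_missing(self) -> bool:
        """True when any of the 20 canonical residues lacks a value."""
        return len(self.values) < len(AA_ORDER)

    @property
    def is_constant(self) -> bool:
        """True when every residue maps to the same value (no signal)."""
        vals = list(self.values.values())
        return len(vals) > 0 and min(vals) == max(vals)

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def to_record(self) -> str:
        """Serialize back to one AAindex1 record (terminated by ``//``)."""
        lines = [f"H {self.accession}"]
        if self.description:
            lines.append(f"D {self.description}")
        for tag, text in self.extra_blocks:
            lines.append(f"{tag} {text}" if text else tag)
        lines.append(
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V"
        )
        tokens = [
            format(self.values[aa], ".17g") if aa in self.values else "NA"
            for aa in AA_ORDER
        ]
        lines.append("  " + "  ".join(tokens[:10]))
        lines.append("  " + "  ".join(tokens[10:]))
        lines.append("//")
        return "\n".join(lines) + "\n"


def _parse_record(lines: list[str]) -> EncodingIndex:
    accession = ""
    description_parts: list[str] = []
    extra: list[tuple[str, str]] = []
    value_tokens: list[str] = []
    tag = None
    for line in lines:
        if line[:1].isalpha() or line[:1] == "*":
            tag = line[0]
            body = line[1:].strip()
            if tag == "H":
                accession = body
            elif tag == "D":
                description_parts.append(body)
            elif tag == "I":
                pass  # header only; residue order is fixed by the format
            else:
                extra.append((tag, body))
        else:  # continuation line of the current block
            body = line.strip()
            if tag == "I":
                value_tokens.extend(body.split())
            elif tag == "D":
                description_parts.append(body)
            elif tag is not None and extra:
                prev_tag, prev_body = extra[-1]
                extra[-1] = (prev_tag, (prev_body + " " + body).strip())
    label = accession or "<record without H line>"
    if not accession:
        raise AAindexParseError(f"{label}: missing H (accession) line")
    if len(value_tokens) != len(AA_ORDER):
        raise AAindexParseError(
            f"{label}: I block has {len(value_tokens)} value tokens, expected 20"
        )
    values: dict[str, float] = {}
    for aa, token in zip(AA_ORDER, value_tokens):
        if token.upper() == "NA":
            continue
        try:
            values[aa] = float(token)
        except ValueError as exc:
            raise AAindexParseError(f"{label}: bad value {token!r} for {aa}") from exc
    return EncodingIndex(
        accession=accession,
        description=" ".join(description_parts),
        values=values,
        extra_blocks=tuple(extra),
    )


def parse_aaindex(text: str) -> list[EncodingIndex]:
    """Parse an AAindex1-format character stream into encoding indices.

    Records are delimited by ``//`` lines; an empty stream yields an
    empty list.  Record order is preserved.  ``NA`` value tokens leave
    the residue absent and set :attr:`EncodingIndex.has_missing`.

    Raises
    ------
    AAindexParseError
        If any record's I block does not hold exactly 20 tokens, or a
        record lacks an accession.
    """
    indices: list[EncodingIndex] = []
    record: list[str] = []
    for raw in text.splitlines():
        if raw.strip() == "//":
            if any(line.strip() for line in record):
                indices.append(_parse_record(record))
            record = []
        else:
            record.append(raw)
    if any(line.strip() for line in record):
        indices.append(_parse_record(record))
    return indices


def write_aaindex(indices: Iterable[EncodingIndex]) -> str:
    """Serialize indices to AAindex1 text (inverse of :func:`parse_aaindex`)."""
    return "".join(ix.to_record() for ix in indices)


def load_aaindex(path: str | Path) -> list[EncodingIndex]:
    """Read an AAindex1 flat file from disk."""
    return parse_aaindex(Path(path).read_text())


def bundled_indices() -> list[EncodingIndex]:
    """Load the fixture indices shipped with the package.

    Three complete published scales (hydropathy, electron–ion
    interaction potential, molecular weight) plus one synthetic record
    containing an ``NA`` value, for exercising the missing-value path.
    """
    text = (
        resources.files("spectralsar").joinpath("data/fixture_indices.aaindex1")
    ).read_text()
    return parse_aaindex(text)


def get_index(db: Iterable[EncodingIndex], accession: str) -> EncodingIndex:
    """Return the index with the given accession (case-sensitive).

    Raises
    ------
    IndexLookupError
        If absent; the message lists near-matching accessions.
    """
    db = list(db)
    for ix in db:
        if ix.accession == accession:
            return ix
    known = [ix.accession for ix in db]
    near = difflib.get_close_matches(accession, known, n=3, cutoff=0.4)
    hint = f" (near matches: {', '.join(near)})" if near else ""
    raise IndexLookupError(f"no index {accession!r} in collection of {len(known)}{hint}")


def usable_indices(db: Iterable[EncodingIndex]) -> list[EncodingIndex]:
    """Filter to indices usable for encoding, preserving input order.

    Drops indices with missing residues and constant indices (all 20
    values identical — a constant signal carries no sequence
    information, so such an index cannot discriminate variants).
    """
    return [ix for ix in db if not ix.has_missing and not ix.is_constant]
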