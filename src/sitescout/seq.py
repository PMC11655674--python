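"""Nucleotide sequences, IUPAC degenerate patterns and FASTA I/O.

All coordinates are 0-based, half-open. Sequences are stored uppercase over
the alphabet ``{A, C, G, T, N}``; degenerate patterns use the full 15-letter
IUPAC nucleotide code.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlphabetError",
    "NucSequence",
    "IUPACPattern",
    "revcomp",
    "match_pattern",
    "read_fasta",
    "write_fasta",
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
]

DNA_BASES = "ACGT"
SEQ_ALPHABET = frozenset("ACGTN")

#: base set denoted by each IUPAC nucleotide symbol
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: symbol whose base set is exactly the given frozenset
SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "W": "W", "S": "S", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


class AlphabetError(ValueError):
    """A character outside the allowed alphabet, reporting its position."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


def _validate(seq: str, alphabet: frozenset[str], what: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise AlphabetError(
                f"invalid character {ch!r} at position {i} in {what}", position=i
            )


@dataclass(frozen=True)
class NucSequence:
    """A named DNA sequence over ``{A, C, G, T, N}``.

    Lowercase input is accepted and uppercased; anything outside the
    alphabet raises :class:`AlphabetError`.
    """

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        _validate(self.seq, SEQ_ALPHABET, f"sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def __getitem__(self, key) -> str:
        return self.seq[key]

    def revcomp(self) -> "NucSequence":
        return NucSequence(self.id, _revcomp_str(self.seq), self.circular)


_COMPACT_RUN = re.compile(r"\(([A-Za-z])(\d+)\)")


@dataclass(frozen=True)
class IUPACPattern:
    """A degenerate nucleotide pattern over the 15 IUPAC symbols."""

    symbols: str

    def __post_init__(self):
        object.__setattr__(self, "symbols", self.symbols.upper())
        _validate(self.symbols, frozenset(IUPAC_SETS), f"pattern {self.symbols!r}")
        if not self.symbols:
            raise ValueError("pattern must be nonempty")

    @property
    def width(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    @classmethod
    def parse(cls, text: str) -> "IUPACPattern":
        """Parse a pattern, expanding run-length groups like ``(N6)``."""
        expanded = _COMPACT_RUN.sub(lambda m: m.group(1) * int(m.group(2)), text)
        return cls(expanded)

    def base_sets(self) -> list[frozenset[str]]:
        return [IUPAC_SETS[s] for s in self.symbols]

    def revcomp(self) -> "IUPACPattern":
        return IUPACPattern(_revcomp_str(self.symbols))


def _revcomp_str(s: str) -> str:
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(s))
    except KeyError:
        for i, c in enumerate(s):
            if c not in IUPAC_COMPLEMENT:
                raise AlphabetError(
                    f"invalid character {c!r} at position {i}", position=i
                ) from None
        raise


def revcomp(obj: Union[str, NucSequence, IUPACPattern]):
    """Reverse complement using the full IUPAC complement table.

    Returns the same kind as the input (string, :class:`NucSequence` or
    :class:`IUPACPattern`); ``revcomp(revcomp(x)) == x``.
    """
    if isinstance(obj, NucSequence):
        return obj.revcomp()
    if isinstance(obj, IUPACPattern):
        return obj.revcomp()
    return _revcomp_str(obj.upper())


def _symbol_matches(symbol: str, base: str, permissive_n: bool) -> bool:
    if base == "N":
        # an unknown genome base only matches the fully degenerate symbol
        return permissive_n or symbol == "N"
    return base in IUPAC_SETS[symbol]


def match_pattern(
    pattern: Union[str, IUPACPattern],
    seq: Union[str, NucSequence],
    strands: str = "forward",
    permissive_n: bool = False,
) -> list[tuple[int, str]]:
    """Find all occurrences of a degenerate pattern in a sequence.

    Parameters
    ----------
    pattern:
        IUPAC pattern; strings are parsed with run-length expansion.
    seq:
        Subject sequence over ``{A,C,G,T,N}``.
    strands:
        ``"forward"`` or ``"both"``. Minus-strand matches are reported at
        the forward-coordinate start of the matched window.
    permissive_n:
        If True, an ``N`` in the subject matches any pattern symbol. By
        default it matches only the pattern symbol ``N``.

    Returns
    -------
    list of ``(offset, strand)`` sorted by offset then strand.
    """
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    pat = pattern if isinstance(pattern, IUPACPattern) else IUPACPattern.parse(pattern)
    s = seq.seq if isinstance(seq, NucSequence) else seq.upper()
    _validate(s, SEQ_ALPHABET, "subject sequence")
    w = pat.width
    if w > len(s):
        return []

    hits: list[tuple[int, str]] = []
    patterns = [(pat.symbols, "+")]
    if strands == "both":
        patterns.append((pat.revcomp().symbols, "-"))
    for symbols, strand in patterns:
        for off in range(len(s) - w + 1):
            if all(
                _symbol_matches(symbols[i], s[off + i], permissive_n)
                for i in range(w)
            ):
                hits.append((off, strand))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def read_fasta(path, on_invalid: str = "error") -> list[NucSequence]:
    """Read a multi-FASTA file into :class:`NucSequence` records.

    ``on_invalid`` is ``"error"`` (reject characters outside ACGTN) or
    ``"map"`` (replace them with N). Duplicate ids are an error; an empty
    file yields an empty list with a warning.
    """
    if on_invalid not in ("error", "map"):
        raise ValueError(f"on_invalid must be 'error' or 'map', got {on_invalid!r}")
    records: list[NucSequence] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq).upper()
        if on_invalid == "map":
            raw = "".join(c if c in SEQ_ALPHABET else "N" for c in raw)
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append(NucSequence(rec.id, raw))
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate FASTA ids: {', '.join(dups)}")
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[NucSequence], path, width: int = 70) -> None:
    """Write records as wrapped multi-FASTA."""
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)
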