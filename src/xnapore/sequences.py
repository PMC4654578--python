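"""DNA sequences over an expanded, six-letter genetic alphabet.

The alphabet is the four canonical deoxynucleotides plus the hydrophobic
unnatural base pair partners dNaM and d5SICS, written ``Z`` and ``Q``
respectively, and the abasic residue ``X`` (a backbone position with no
base).  Sequences are always stored and indexed 5'->3'.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical bases plus Z (dNaM), Q (d5SICS) and X (abasic).
ALPHABET = frozenset("ACGTZQX")

#: The six letters that participate in the k-mer current table (X is handled
#: by a constant override, not by table entries).
TABLE_ALPHABET = "ACGQTZ"  # lexicographic: A < C < G < Q < T < Z


class SequenceValidationError(ValueError):
    """A record contains a symbol outside the expanded alphabet, or is empty."""


@dataclass(frozen=True)
class ExtendedSequence:
    """An identified DNA sequence over ``{A,C,G,T,Z,Q,X}``, 5'->3'.

    Parameters
    ----------
    id : str
        Non-empty, whitespace-free record label.
    residues : str
        Upper-case symbols, each in the 7-letter alphabet.
    """

    id: str
    residues: str = field(repr=True)

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceValidationError(
                f"sequence id must be non-empty and free of whitespace: {self.id!r}"
            )
        if len(self.residues) < 1:
            raise SequenceValidationError(f"record {self.id!r} is empty")
        up = self.residues.upper()
        for pos, sym in enumerate(up, start=1):
            if sym not in ALPHABET:
                raise SequenceValidationError(
                    f"record {self.id!r}: invalid symbol {sym!r} at position {pos}"
                )
        object.__setattr__(self, "residues", up)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __getitem__(self, position: int) -> str:
        """Return the residue at 1-based ``position`` (5'->3')."""
        self._check_position(position)
        return self.residues[position - 1]

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= len(self):
            raise IndexError(
                f"position {position} out of range for {self.id!r} "
                f"(length {len(self)}; positions are 1-based)"
            )

    def substitute(self, position: int, symbol: str) -> "ExtendedSequence":
        """Return a copy with ``symbol`` placed at 1-based ``position``.

        The input sequence is unmodified; the result differs from it at most
        at the one substituted position (exactly zero positions when
        ``symbol`` equals the existing residue).
        """
        self._check_position(position)
        symbol = symbol.upper()
        if symbol not in ALPHABET:
            raise SequenceValidationError(f"invalid substitution symbol {symbol!r}")
        res = self.residues[: position - 1] + symbol + self.residues[position:]
        return ExtendedSequence(self.id, res)

    def kmers(self, k: int) -> Iterator[str]:
        """Yield all length-``k`` windows, 5'->3'."""
        for i in range(len(self) - k + 1):
            yield self.residues[i : i + k]


def substitute(seq: ExtendedSequence, position: int, symbol: str) -> ExtendedSequence:
    """Functional form of :meth:`ExtendedSequence.substitute`."""
    return seq.substitute(position, symbol)


def parse_extended_fasta(source) -> list[ExtendedSequence]:
    """Parse FASTA text (string, path, or handle) into validated sequences.

    Layout is ordinary FASTA (line breaks inside a record are joined,
    lower-case letters are up-cased); only the alphabet is extended.  A symbol
    outside ``{A,C,G,T,Z,Q,X}`` raises :class:`SequenceValidationError`
    naming the record, position and symbol.
    """
    if isinstance(source, str) and (
        source.lstrip().startswith(">") or "\n" in source or not source.strip()
    ):
        handle = io.StringIO(source)
    else:
        handle = source
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise SequenceValidationError("no FASTA records found")
    out = []
    for rec in records:
        out.append(ExtendedSequence(rec.id, str(rec.seq)))
    return out


def write_extended_fasta(seqs: Iterable[ExtendedSequence], handle_or_path) -> None:
    """Write sequences as FASTA with 60-column wrapped sequence lines."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, handle_or_path, "fasta")
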