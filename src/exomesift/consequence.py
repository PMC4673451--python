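"""Classify codon changes: synonymous, missense, stop-gained, stop-lost.

Codon changes arrive as printed in variant tables: slash-separated codon pair
with the substituted base uppercase and the unchanged context lowercase, e.g.
``tTa/tGa`` (Leu codon TTA becoming stop codon TGA). Codons are taken as
printed, already oriented to the coding strand — no strand or reading-frame
resolution is attempted here.

Protein-change notation follows the usual single-letter convention:
``L89*`` for a stop gain at residue 89, ``G332D`` for a missense change, and
for synonymous changes just the residue and index (``G1026``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Optional

from Bio.Seq import Seq

from .errors import ParseError

Klass = Literal["synonymous", "missense", "stop_gained", "stop_lost"]

_CODON_RE = re.compile(r"^[acgtACGT]{3}$")


@dataclass(frozen=True, slots=True)
class CodonChange:
    """A single-base codon substitution at a given protein residue.

    Both codons are three letters over ACGT in either case; exactly one
    position differs between them, and that position is the uppercase one in
    both codons (the lowercase context is identical).
    """

    ref_codon: str
    alt_codon: str
    residue_index: int

    def __post_init__(self) -> None:
        for codon in (self.ref_codon, self.alt_codon):
            if not _CODON_RE.match(codon):
                raise ParseError(f"invalid codon {codon!r}")
        if self.residue_index < 1:
            raise ParseError(f"residue index must be >= 1, got {self.residue_index}")
        diffs = [i for i in range(3) if self.ref_codon[i].upper() != self.alt_codon[i].upper()]
        if len(diffs) != 1:
            raise ParseError(
                f"{self.ref_codon}/{self.alt_codon}: exactly one base must differ "
                f"({len(diffs)} do)"
            )
        upper_ref = [i for i in range(3) if self.ref_codon[i].isupper()]
        upper_alt = [i for i in range(3) if self.alt_codon[i].isupper()]
        if upper_ref != diffs or upper_alt != diffs:
            raise ParseError(
                f"{self.ref_codon}/{self.alt_codon}: the changed base must be the "
                "uppercase one in both codons"
            )
        ctx = [i for i in range(3) if i != diffs[0]]
        if any(self.ref_codon[i] != self.alt_codon[i] for i in ctx):
            raise ParseError(
                f"{self.ref_codon}/{self.alt_codon}: lowercase context differs"
            )

    @property
    def changed_position(self) -> int:
        """1-based position of the substituted base within the codon."""
        return next(
            i + 1
            for i in range(3)
            if self.ref_codon[i].upper() != self.alt_codon[i].upper()
        )


@dataclass(frozen=True, slots=True)
class ConsequenceCall:
    """Predicted protein-level consequence of a codon change."""

    ref_aa: str
    alt_aa: str
    klass: Klass
    notation: str


def parse_codon_change(text: str, residue_index: int) -> CodonChange:
    """Parse a printed codon-change string like ``"gGc/gAc"``."""
    parts = text.split("/")
    if len(parts) != 2:
        raise ParseError(f"codon change {text!r} is not slash-separated")
    return CodonChange(parts[0], parts[1], residue_index)


def translate_codon(codon: str) -> str:
    """Standard-genetic-code translation of one codon; ``*`` for stop."""
    if not _CODON_RE.match(codon):
        raise ParseError(f"invalid codon {codon!r}")
    return str(Seq(codon.upper()).translate())


def classify(change: CodonChange) -> ConsequenceCall:
    """Translate both codons and classify the substitution."""
    ref_aa = translate_codon(change.ref_codon)
    alt_aa = translate_codon(change.alt_codon)
    if ref_aa == alt_aa:
        klass: Klass = "synonymous"
        notation = f"{ref_aa}{change.residue_index}"
    else:
        if alt_aa == "*":
            klass = "stop_gained"
        elif ref_aa == "*":
            klass = "stop_lost"
        else:
            klass = "missense"
        notation = f"{ref_aa}{change.residue_index}{alt_aa}"
    return ConsequenceCall(ref_aa=ref_aa, alt_aa=alt_aa, klass=klass, notation=notation)


_NOTATION_RE = re.compile(r"^([A-Z])(\d+)(\*|[A-Z])?$")


def parse_protein_notation(text: str) -> tuple[str, int, Optional[str]]:
    """Split notation like ``L89*`` / ``G332D`` / ``G1026`` into its parts.

    Returns (ref_aa, residue_index, alt_aa); alt_aa is None for the synonymous
    form. This is the inverse of the notation emitted by :func:`classify`.
    """
    m = _NOTATION_RE.match(text.strip())
    if not m:
        raise ParseError(f"cannot parse protein-change notation {text!r}")
    ref_aa, idx, alt_aa = m.groups()
    return ref_aa, int(idx), alt_aa
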