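"""PROSITE-style motif parsing and scanning.

Candidate fatty-acid-desaturase (FAD) sequences are curated by requiring the
tripartite histidine-box motif that coordinates the di-iron catalytic
center.  The default pattern (:data:`TRIPARTITE_HISTIDINE_MOTIF`) spans the
three His boxes plus the extra HH cluster, with wide wildcard spacers
because the FAD family is "long-spaced".

Scan semantics: matches are enumerated leftmost-start; at each start the
variable-length elements are explored shortest-first and only the first
(shortest-expansion) match is reported, so overlapping matches with distinct
starts are all reported but each start yields at most one.  This mirrors
ScanProsite's single-hit-per-site reporting and is deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from .seqio import ProteinSequence

#: The tripartite histidine-box pattern used to curate FAD candidates.
TRIPARTITE_HISTIDINE_MOTIF = (
    "H-x(3,4)-H-x(3,150)-H-x(2,3)-H-H-x(50,250)-[HQ]-x(2,3)-H-H"
)

_AA = "ACDEFGHIKLMNPQRSTVWYX"


@dataclass(frozen=True)
class PatternElement:
    """One element of a PROSITE pattern with its repeat range.

    kind: "literal" (one residue), "class" ([..]), "negated" ({..}) or
    "wildcard" (x).  residues holds the class members for class/negated.
    """

    kind: str
    residues: str
    min_repeat: int
    max_repeat: int

    def matches(self, residue: str) -> bool:
        if self.kind == "wildcard":
            return True
        if self.kind == "literal":
            return residue == self.residues
        if self.kind == "class":
            return residue in self.residues
        return residue not in self.residues  # negated


@dataclass(frozen=True)
class PrositePattern:
    elements: Tuple[PatternElement, ...]
    text: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("empty pattern")

    def min_length(self) -> int:
        return sum(e.min_repeat for e in self.elements)


@dataclass(frozen=True)
class MotifMatch:
    """A motif hit; coordinates are 0-based, half-open."""

    sequence_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid match coordinates [{self.start}, {self.end})")


_RANGE_RE = re.compile(r"^\((\d+)(?:,(\d+))?\)$")


def _parse_element(token: str) -> PatternElement:
    token = token.strip()
    if not token:
        raise ValueError("empty pattern element (stray dash?)")
    # split off a trailing repeat spec "(n)" or "(min,max)"
    min_rep = max_rep = 1
    m = re.search(r"\(.*$", token)
    body = token
    if m:
        spec = m.group(0)
        body = token[: m.start()].strip()
        rm = _RANGE_RE.match(spec)
        if not rm:
            raise ValueError(f"malformed repeat range {spec!r} in element {token!r}")
        min_rep = int(rm.group(1))
        max_rep = int(rm.group(2)) if rm.group(2) is not None else min_rep
        if min_rep > max_rep:
            raise ValueError(f"repeat range minimum exceeds maximum in {token!r}")
    if body.lower() == "x":
        if min_rep < 0:
            raise ValueError(f"negative repeat in {token!r}")
        return PatternElement("wildcard", "", min_rep, max_rep)
    if min_rep < 1:
        raise ValueError(f"repeat minimum must be >= 1 for non-wildcard element {token!r}")
    if body.startswith("[") and body.endswith("]"):
        members = body[1:-1].strip()
        if not members:
            raise ValueError(f"empty residue class in {token!r}")
        return PatternElement("class", members, min_rep, max_rep)
    if body.startswith("{") and body.endswith("}"):
        members = body[1:-1].strip()
        if not members:
            raise ValueError(f"empty negated class in {token!r}")
        return PatternElement("negated", members, min_rep, max_rep)
    if len(body) == 1 and body.upper() in _AA:
        return PatternElement("literal", body.upper(), min_rep, max_rep)
    raise ValueError(f"unrecognized pattern element {token!r}")


def parse_pattern(text: str) -> PrositePattern:
    """Parse a dash-separated PROSITE-style pattern.

    Whitespace inside the pattern is tolerated (published patterns often
    contain stray spaces, e.g. ``"H-x (3,4)-H"``).

    >>> parse_pattern("H-x(3,4)-H").elements[1].max_repeat
    4
    """
    compact = re.sub(r"\s+", "", text)
    compact = compact.rstrip(".")
    if not compact:
        raise ValueError("empty pattern")
    tokens = compact.split("-")
    # A class like [HQ] never contains '-' for the patterns in scope; tokens
    # map 1:1 to elements.
    elements = tuple(_parse_element(tok) for tok in tokens)
    return PrositePattern(elements=elements, text=text)


def _to_regex(pattern: PrositePattern) -> "re.Pattern[str]":
    parts = []
    for el in pattern.elements:
        if el.kind == "wildcard":
            atom = "."
        elif el.kind == "literal":
            atom = re.escape(el.residues)
        elif el.kind == "class":
            atom = "[" + re.escape(el.residues) + "]"
        else:
            atom = "[^" + re.escape(el.residues) + "]"
        if el.min_repeat == el.max_repeat:
            rep = "" if el.min_repeat == 1 else f"{{{el.min_repeat}}}"
        else:
            # lazy quantifier == shortest-first exploration
            rep = f"{{{el.min_repeat},{el.max_repeat}}}?"
        parts.append(atom + rep)
    return re.compile("".join(parts))


def scan(pattern: PrositePattern, protein: ProteinSequence) -> List[MotifMatch]:
    """All motif matches under leftmost-start, shortest-expansion-first rules."""
    rx = _to_regex(pattern)
    seq = protein.residues
    matches: List[MotifMatch] = []
    min_len = pattern.min_length()
    for start in range(0, len(seq) - min_len + 1):
        m = rx.match(seq, start)
        if m and m.start() == start:
            matches.append(MotifMatch(protein.id, start, m.end()))
    return matches


def filter_by_motif(
    proteins: Sequence[ProteinSequence], pattern: PrositePattern
) -> Tuple[List[ProteinSequence], List[ProteinSequence]]:
    """Partition proteins into (kept, discarded) by presence of >=1 motif hit."""
    kept: List[ProteinSequence] = []
    discarded: List[ProteinSequence] = []
    for prot in proteins:
        (kept if scan(pattern, prot) else discarded).append(prot)
    return kept, discarded
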