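"""Compact PROSITE-style protein motif patterns: parsing and scanning.

The OleA screen uses the pattern ``EPxx[AS]x(14,18)DxxNACL``: literal
residues, ``x`` wildcards, ``[..]`` choice sets, ``{..}`` exclusion sets,
and ``(n)`` / ``(n,m)`` repeat suffixes bound to the preceding element.
Coordinates are 0-based half-open throughout; 1-based only at the TSV/CLI
reporting boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class PatternError(ValueError):
    """Malformed motif pattern; carries the offending character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class PatternElement:
    kind: str  # literal | choice | exclusion | wildcard
    residue_set: frozenset[str]
    repeat_min: int = 1
    repeat_max: int = 1

    def __post_init__(self):
        if self.kind not in ("literal", "choice", "exclusion", "wildcard"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if not self.residue_set or not self.residue_set <= _AA_SET:
            raise ValueError("residue_set must be a non-empty subset of the 20 amino acids")
        if self.kind == "literal" and len(self.residue_set) != 1:
            raise ValueError("literal element must have exactly one residue")
        if self.kind == "wildcard" and self.residue_set != _AA_SET:
            raise ValueError("wildcard element must carry the full alphabet")
        if not (1 <= self.repeat_min <= self.repeat_max):
            raise ValueError("need 1 <= repeat_min <= repeat_max")

    def accepts(self, residue: str) -> bool:
        """Whether one sequence character satisfies this element.

        Wildcards accept anything (including ambiguity codes B/Z/X);
        literal/choice/exclusion elements accept only their residue set,
        so ambiguity codes never satisfy them — conservative screening.
        """
        if self.kind == "wildcard":
            return True
        return residue in self.residue_set


@dataclass(frozen=True)
class MotifPattern:
    source_text: str
    elements: tuple[PatternElement, ...]

    def to_string(self) -> str:
        """Canonical compact form; parsing it again reproduces the pattern."""
        parts = []
        for el in self.elements:
            if el.kind == "literal":
                core = next(iter(el.residue_set))
            elif el.kind == "wildcard":
                core = "x"
            elif el.kind == "choice":
                core = "[" + "".join(sorted(el.residue_set)) + "]"
            else:
                excluded = sorted(_AA_SET - el.residue_set)
                core = "{" + "".join(excluded) + "}"
            if el.repeat_min == el.repeat_max:
                suffix = "" if el.repeat_min == 1 else f"({el.repeat_min})"
            else:
                suffix = f"({el.repeat_min},{el.repeat_max})"
            parts.append(core + suffix)
        return "".join(parts)


@dataclass(frozen=True)
class MotifMatch:
    record_id: str
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start


def parse_pattern(text: str) -> MotifPattern:
    """Parse a compact PROSITE-style pattern string.

    Repeat suffixes ``(n)`` / ``(n,m)`` bind to the immediately preceding
    element. Errors name the offset of the offending character.
    """
    if not text:
        raise PatternError("empty pattern", 0)
    elements: list[PatternElement] = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c == "x":
            elements.append(PatternElement("wildcard", _AA_SET))
            i += 1
        elif c in _AA_SET:
            elements.append(PatternElement("literal", frozenset(c)))
            i += 1
        elif c in "[{":
            closer = "]" if c == "[" else "}"
            j = text.find(closer, i + 1)
            if j < 0:
                raise PatternError(f"unclosed '{c}'", i)
            members = text[i + 1 : j]
            if not members:
                raise PatternError("empty residue set", i)
            bad = [k for k, ch in enumerate(members) if ch not in _AA_SET]
            if bad:
                raise PatternError(f"invalid residue {members[bad[0]]!r} in set", i + 1 + bad[0])
            if c == "[":
                elements.append(PatternElement("choice", frozenset(members)))
            else:
                allowed = _AA_SET - frozenset(members)
                if not allowed:
                    raise PatternError("exclusion set excludes every residue", i)
                elements.append(PatternElement("exclusion", allowed))
            i = j + 1
        elif c == "(":
            if not elements:
                raise PatternError("repeat suffix with no preceding element", i)
            j = text.find(")", i + 1)
            if j < 0:
                raise PatternError("unclosed '('", i)
            body = text[i + 1 : j]
            try:
                if "," in body:
                    lo_s, hi_s = body.split(",", 1)
                    lo, hi = int(lo_s), int(hi_s)
                else:
                    lo = hi = int(body)
            except ValueError:
                raise PatternError(f"malformed repeat {body!r}", i) from None
            if lo < 1:
                raise PatternError("repeat minimum must be >= 1", i)
            if lo > hi:
                raise PatternError(f"repeat min {lo} exceeds max {hi}", i)
            prev = elements[-1]
            if (prev.repeat_min, prev.repeat_max) != (1, 1):
                raise PatternError("element already has a repeat suffix", i)
            elements[-1] = PatternElement(prev.kind, prev.residue_set, lo, hi)
            i = j + 1
        else:
            raise PatternError(f"unknown character {c!r}", i)
    return MotifPattern(source_text=text, elements=tuple(elements))


def match_bounds(pattern: MotifPattern) -> tuple[int, int]:
    """(min_span, max_span): total residues any match of the pattern can span."""
    return (
        sum(el.repeat_min for el in pattern.elements),
        sum(el.repeat_max for el in pattern.elements),
    )


def _min_match_end(elements: tuple[PatternElement, ...], seq: str, start: int) -> int | None:
    """Smallest end index such that seq[start:end] satisfies the elements, else None.

    Depth-first over repeat counts with memoised failure; repeat counts are
    tried ascending so the first complete match found is the lazy (shortest)
    one, but a full min is taken to stay correct for any element mix.
    """
    n = len(seq)

    best: int | None = None
    dead: set[tuple[int, int]] = set()

    def walk(e: int, pos: int) -> int | None:
        nonlocal best
        if e == len(elements):
            return pos
        if (e, pos) in dead:
            return None
        el = elements[e]
        # residues satisfying el available contiguously from pos
        run = 0
        limit = min(el.repeat_max, n - pos)
        while run < limit and el.accepts(seq[pos + run]):
            run += 1
        found: int | None = None
        for r in range(el.repeat_min, run + 1):
            sub = walk(e + 1, pos + r)
            if sub is not None and (found is None or sub < found):
                found = sub
        if found is None:
            dead.add((e, pos))
        return found

    best = walk(0, start)
    return best


def scan_sequence(pattern: MotifPattern, seq: str, record_id: str = "") -> list[MotifMatch]:
    """All distinct start positions admitting a match, shortest span per start.

    Ordered by start; empty sequence yields an empty list.
    """
    lo, _ = match_bounds(pattern)
    out: list[MotifMatch] = []
    for start in range(0, len(seq) - lo + 1):
        end = _min_match_end(pattern.elements, seq, start)
        if end is not None:
            out.append(MotifMatch(record_id=record_id, start=start, end=end))
    return out


def scan_fasta(pattern: MotifPattern, path: str | Path) -> dict[str, list[MotifMatch]]:
    """Scan every record of a FASTA file (plain or gzip); duplicate IDs rejected.

    Records without hits are present with empty lists.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    results: dict[str, list[MotifMatch]] = {}
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in results:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            results[rec.id] = scan_sequence(pattern, str(rec.seq).upper(), record_id=rec.id)
    return results


def verify_match(pattern: MotifPattern, seq: str, match: MotifMatch) -> bool:
    """Re-check a reported match by a direct walk over the element list."""
    sub = seq[match.start : match.end]

    def walk(e: int, pos: int) -> bool:
        if e == len(pattern.elements):
            return pos == len(sub)
        el = pattern.elements[e]
        run = 0
        limit = min(el.repeat_max, len(sub) - pos)
        while run < limit and el.accepts(sub[pos + run]):
            run += 1
        return any(walk(e + 1, pos + r) for r in range(el.repeat_min, run + 1))

    return walk(0, 0)


#: The OleA screening pattern used throughout the pipeline.
OLEA_PATTERN_TEXT = "EPxx[AS]x(14,18)DxxNACL"


def olea_pattern() -> MotifPattern:
    return parse_pattern(OLEA_PATTERN_TEXT)
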