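"""Sequence input, phosphopeptide notation, and motif scanning.

Reads protein FASTA and phosphopeptide strings in the conventional assay
notation (``Fluorescein-GYGGPVLVKDpTPEDKYGI``; the bracketed dialect
``(pS)``/``(pT)`` is also accepted), enumerates candidate S/T
phosphoacceptors, applies either the strict Prosite patterns or the scored
BRCT1/BRCT2 compatibility classifier, and serialises match tables as TSV.

Coordinates are 1-based and anchored on the phosphoacceptor, matching the
residue numbering used for sites such as RAD9-Ser387 or RHNO1-Thr202.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, TextIO, Union

from Bio import SeqIO

from .motif import (
    AMINO_ACIDS,
    PAD,
    WINDOW_OFFSETS,
    DomainCompatibility,
    MotifPattern,
    PhosphoWindow,
    builtin_patterns,
    classify_compatibility,
    match_window,
    subsite_score,
)

__all__ = [
    "SequenceRecord",
    "PhosphoPeptide",
    "MotifMatch",
    "FastaError",
    "PeptideParseError",
    "read_fasta",
    "parse_phosphopeptide",
    "extract_window",
    "peptide_window",
    "scan_sequence",
    "motif_score",
    "write_matches",
    "read_matches",
]

#: Ranking bonus for the proline-directed kinase +1 proline.  The +1 residue
#: points away from the BRCT surface and is not required for binding, so it
#: contributes to prioritisation only, not to compatibility.
PLUS1_PROLINE_BONUS = 0.25

#: Maximum subsite total (four offsets, TIGHT=2 each); used to normalise.
MAX_SUBSITE_TOTAL = 8


class FastaError(ValueError):
    """Raised for unusable FASTA input."""


class PeptideParseError(ValueError):
    """Raised for unparseable phosphopeptide notation."""


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with 1-based residue positions.

    Residues are restricted to the 20 standard codes plus ``X``; ``X`` never
    matches any pattern element.
    """

    id: str
    description: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise FastaError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - AMINO_ACIDS - {"X"}
        if bad:
            raise FastaError(
                f"record {self.id!r} contains non-standard codes {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PhosphoPeptide:
    """A peptide with marked phosphosites.

    ``label`` keeps any leading tag (``Fluorescein``, ``Flu``, ``Biotin``);
    ``phospho_positions`` are 1-based indices into the cleaned ``residues``
    string, each of which must carry S or T.
    """

    label: Optional[str]
    residues: str
    phospho_positions: frozenset

    def __post_init__(self):
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise PeptideParseError(f"non-standard residues {sorted(bad)}")
        for pos in self.phospho_positions:
            if not 1 <= pos <= len(self.residues):
                raise PeptideParseError(f"phospho position {pos} out of bounds")
            if self.residues[pos - 1] not in {"S", "T"}:
                raise PeptideParseError(
                    f"phospho position {pos} is {self.residues[pos - 1]}, not S/T"
                )

    def to_text(self) -> str:
        """Serialise in the inline ``pS``/``pT`` dialect (canonical output)."""
        parts = []
        for i, res in enumerate(self.residues, start=1):
            if i in self.phospho_positions:
                parts.append("p")
            parts.append(res)
        body = "".join(parts)
        return f"{self.label}-{body}" if self.label else body


@dataclass(frozen=True)
class MotifMatch:
    """One scan hit at a phosphoacceptor position."""

    sequence_id: str
    phospho_position: int
    phospho_residue: str
    window: PhosphoWindow
    patterns_matched: frozenset
    compatibility: DomainCompatibility
    score: float
    flags: tuple = ()


def read_fasta(source: Union[str, TextIO]) -> List[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` objects, order preserved.

    ``source`` is a path or an open text handle.  Ids are the first
    whitespace-delimited token of the header; sequences are upper-cased.
    Wrapped lines are fine.  An empty file or a record with an empty
    sequence raises :class:`FastaError` naming the record.
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as handle:
            return read_fasta(handle)
    records = []
    for rec in SeqIO.parse(source, "fasta"):
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description,
                residues=str(rec.seq).upper(),
            )
        )
    if not records:
        raise FastaError("no FASTA records found in input")
    return records


_TAG_RE = re.compile(r"^([A-Za-z][A-Za-z0-9]*)-")
_MARKER_RE = re.compile(r"\(p([A-Z])\)|p([A-Z])")


def parse_phosphopeptide(text: str) -> PhosphoPeptide:
    """Parse assay-notation peptide text into a :class:`PhosphoPeptide`.

    Accepts an optional leading ``<Tag>-`` (stored as the label), inline
    ``pS``/``pT`` markers and the bracketed ``(pS)``/``(pT)`` dialect.

    >>> pep = parse_phosphopeptide("Fluorescein-GYGGPVLVKDpTPEDKYGI")
    >>> pep.residues, sorted(pep.phospho_positions)
    ('GYGGPVLVKDTPEDKYGI', [11])

    All-lowercase input is rejected as ambiguous (after case folding a
    literal Pro-Ser cannot be told apart from a phospho-S marker), as is a
    ``p`` marker in front of anything but S or T.
    """
    text = text.strip()
    if not text:
        raise PeptideParseError("empty peptide string")
    label = None
    m = _TAG_RE.match(text)
    if m:
        label = m.group(1)
        text = text[m.end():]
    if text.islower():
        raise PeptideParseError(
            "all-lowercase peptide is ambiguous ('ps' could be Pro-Ser or "
            "phospho-S); use uppercase residues with 'p' or '(p…)' markers"
        )

    residues = []
    positions = set()
    i = 0
    while i < len(text):
        m = _MARKER_RE.match(text, i)
        if m:
            res = m.group(1) or m.group(2)
            if res not in {"S", "T"}:
                raise PeptideParseError(
                    f"phospho marker on {res!r} at position {i + 1}; only S/T "
                    "can be phosphorylated here"
                )
            residues.append(res)
            positions.add(len(residues))
            i = m.end()
            continue
        ch = text[i]
        if ch in AMINO_ACIDS:
            residues.append(ch)
            i += 1
        else:
            raise PeptideParseError(f"unexpected character {ch!r} at position {i + 1}")
    return PhosphoPeptide(
        label=label, residues="".join(residues), phospho_positions=frozenset(positions)
    )


def extract_window(
    record: SequenceRecord, position: int, context_mode: str = "short"
) -> PhosphoWindow:
    """Extract the −6..+2 window around a 1-based S/T position.

    Offsets falling outside the sequence are padded with ``-`` and the
    window reports itself truncated.
    """
    if not 1 <= position <= len(record):
        raise ValueError(
            f"position {position} out of bounds for {record.id!r} "
            f"(length {len(record)})"
        )
    res0 = record.residues[position - 1]
    if res0 not in {"S", "T"}:
        raise ValueError(
            f"residue at {record.id}:{position} is {res0!r}, not a phosphoacceptor"
        )
    residues = {}
    for off in WINDOW_OFFSETS:
        idx = position - 1 + off
        residues[off] = record.residues[idx] if 0 <= idx < len(record) else PAD
    return PhosphoWindow(residues, context_mode=context_mode)


def peptide_window(
    peptide: PhosphoPeptide, position: int, context_mode: str = "short"
) -> PhosphoWindow:
    """Window around a phosphosite of a parsed peptide."""
    record = SequenceRecord(
        id=peptide.label or "peptide", description="", residues=peptide.residues
    )
    return extract_window(record, position, context_mode=context_mode)


def motif_score(window: PhosphoWindow) -> float:
    """Motif component of the ranking score.

    Normalised subsite-tolerance total (0..1) plus a small bonus when the
    +1 residue is the proline of the proline-directed kinase consensus.
    """
    score = subsite_score(window).total / MAX_SUBSITE_TOTAL
    if window[+1] == "P":
        score += PLUS1_PROLINE_BONUS
    return score


def scan_sequence(
    record: SequenceRecord,
    patterns: Optional[Mapping[str, MotifPattern]] = None,
    mode: str = "strict",
    context_mode: str = "short",
) -> List[MotifMatch]:
    """Scan every S/T position of *record* for candidate binding motifs.

    In ``strict`` mode a position is reported when it matches at least one
    Prosite pattern; in ``scored`` mode when the rule-based classifier finds
    a non-empty BRCT1/BRCT2 compatibility set.  Both the strict pattern hits
    and the classifier output are recorded on every match.  Output order is
    deterministic (ascending position).
    """
    if mode not in {"strict", "scored"}:
        raise ValueError("mode must be 'strict' or 'scored'")
    patterns = builtin_patterns() if patterns is None else patterns
    matches = []
    for pos0, res in enumerate(record.residues):
        if res not in {"S", "T"}:
            continue
        position = pos0 + 1
        window = extract_window(record, position, context_mode=context_mode)
        hit_names = frozenset(
            name for name, pat in patterns.items() if match_window(window, pat)
        )
        compat = classify_compatibility(window)
        keep = bool(hit_names) if mode == "strict" else bool(compat.compatible)
        if not keep:
            continue
        matches.append(
            MotifMatch(
                sequence_id=record.id,
                phospho_position=position,
                phospho_residue=res,
                window=window,
                patterns_matched=hit_names,
                compatibility=compat,
                score=motif_score(window),
                flags=compat.flags,
            )
        )
    return matches


# --- TSV serialisation -----------------------------------------------------

_COLUMNS = (
    "sequence_id",
    "position",
    "residue",
    "window",
    "patterns_matched",
    "compatibility",
    "score",
    "flags",
)


def _join(items: Iterable[str]) -> str:
    items = sorted(items)
    return ",".join(items) if items else "."

def _split(cell: str) -> frozenset:
    return frozenset() if cell == "." else frozenset(cell.split(","))


def write_matches(matches: Sequence[MotifMatch], stream: TextIO) -> None:
    """Write a match table as TSV (header + one row per match).

    Output is bit-stable for a fixed match list; empty set-valued cells are
    written as ``.``.
    """
    stream.write("\t".join(_COLUMNS) + "\n")
    for m in matches:
        row = (
            m.sequence_id,
            str(m.phospho_position),
            m.phospho_residue,
            m.window.as_text(),
            _join(m.patterns_matched),
            _join(m.compatibility.compatible),
            f"{m.score:.4f}",
            _join(m.flags),
        )
        stream.write("\t".join(row) + "\n")


def read_matches(stream: TextIO, context_mode: str = "short") -> List[MotifMatch]:
    """Read a TSV written by :func:`write_matches` back into matches.

    The classifier rule trace is not serialised; it is recomputed from the
    window so a written-then-read table is equivalent to the original.
    """
    header = stream.readline().rstrip("\n").split("\t")
    if tuple(header) != _COLUMNS:
        raise ValueError(f"unexpected match-table header: {header}")
    matches = []
    for raw in stream:
        if not raw.strip():
            continue
        cells = raw.rstrip("\n").split("\t")
        if len(cells) != len(_COLUMNS):
            raise ValueError(f"malformed match row: {raw!r}")
        window = PhosphoWindow.from_string(cells[3], context_mode=context_mode)
        matches.append(
            MotifMatch(
                sequence_id=cells[0],
                phospho_position=int(cells[1]),
                phospho_residue=cells[2],
                window=window,
                patterns_matched=_split(cells[4]),
                compatibility=classify_compatibility(window),
                score=float(cells[6]),
                flags=tuple(sorted(_split(cells[7]))),
            )
        )
    return matches
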