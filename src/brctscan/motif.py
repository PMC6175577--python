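"""Consensus patterns and BRCT1/BRCT2 compatibility rules for TOPBP1/Rad4.

The N-terminal BRCT1 and BRCT2 domains of TOPBP1 (and its fission-yeast
homologue Rad4) recognise phosphoserine/phosphothreonine peptides through
distinct binding modes.  BRCT1 ligands fold the residues upstream of the
phosphoacceptor into a tight turn that buries two consecutive hydrophobic
side chains (positions −4 and −3) in an extended recess; BRCT2 ligands stay
in a β-sheet-like extended conformation and bury only the −3 side chain, so
the −4 position tolerates large polar residues that BRCT1 cannot accept.

This module encodes that specificity model three ways:

* strict Prosite-style consensus patterns
  (``BRCT1: [FILMV]-[FILMV]-[FILMV]-x-x-[ST]-P``,
  ``BRCT2: [FILMV]-x-x-[ST]-P``),
* a substitution-tolerance table for the RAD9 tail pull-down panel
  (offsets −5, −4, −3 and −1 relative to the phosphoacceptor), and
* a rule-based classifier that reports which of {BRCT1, BRCT2} a
  phosphoacceptor window is sequence-compatible with, with a full rule trace.

Offsets are numbered relative to the phosphoacceptor: negative towards the
N-terminus, 0 the phosphorylated S/T, positive towards the C-terminus.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "AMINO_ACIDS",
    "PAD",
    "HYDROPHOBIC",
    "Category",
    "PrositeElement",
    "MotifPattern",
    "PhosphoWindow",
    "ToleranceTable",
    "DomainCompatibility",
    "RuleRecord",
    "SubsiteScore",
    "PatternParseError",
    "parse_prosite_pattern",
    "builtin_patterns",
    "load_pattern_config",
    "match_window",
    "count_matching_kmers",
    "subsite_score",
    "default_tolerance_table",
    "classify_compatibility",
]

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Padding symbol used where a window extends past the end of a sequence.
PAD = "-"

#: Hydrophobic residue class, taken verbatim from the consensus patterns.
HYDROPHOBIC = frozenset("FILMV")

# Rule sets of the BRCT1/BRCT2 decision table.  BRCT1 additionally admits
# alanine at −3 (the RAD9 precedent: Ala at −3 binds the BRCT1 recess), but
# never at −4.  Large/charged polar residues at −4 are incompatible with the
# buried −4 position of the BRCT1 tight turn; arginine and glutamate are the
# experimentally observed exclusions, the rest are extrapolated by charge and
# size analogy and flagged as such in the rule trace.
BRCT1_MINUS3 = HYDROPHOBIC | {"A"}
MINUS4_POLAR_EXCLUDED = frozenset("RKEDQN")
MINUS4_POLAR_OBSERVED = frozenset("RE")
MINUS4_SMALL_POLAR = frozenset("STGA")
MINUS1_EXCLUDED = frozenset("LIFMWKR")

WINDOW_OFFSETS = tuple(range(-6, 3))
SCORED_OFFSETS = (-5, -4, -3, -1)


class PatternParseError(ValueError):
    """Raised for malformed Prosite-style pattern text."""


class Category(str, enum.Enum):
    """Binding tolerance of a residue at a scored sub-site.

    Scores are an ordinal encoding (TIGHT=2, REDUCED=1, ABOLISHED=0);
    untested residues are UNKNOWN and scored like REDUCED.
    """

    TIGHT = "TIGHT"
    REDUCED = "REDUCED"
    ABOLISHED = "ABOLISHED"
    UNKNOWN = "UNKNOWN"

    @property
    def score(self) -> int:
        return {"TIGHT": 2, "REDUCED": 1, "ABOLISHED": 0, "UNKNOWN": 1}[self.value]


@dataclass(frozen=True)
class PrositeElement:
    """A single position of a Prosite-style pattern.

    kind is one of ``residue-class`` (``[XYZ]``), ``any`` (``x``) or
    ``literal`` (a single fixed residue).
    """

    kind: str
    allowed: frozenset = frozenset()

    def __post_init__(self):
        if self.kind not in {"residue-class", "any", "literal"}:
            raise ValueError(f"unknown element kind: {self.kind!r}")
        if not self.allowed <= AMINO_ACIDS:
            raise ValueError(f"non-standard codes in element: {sorted(self.allowed)}")
        if self.kind == "literal" and len(self.allowed) != 1:
            raise ValueError("literal element must have exactly one allowed code")
        if self.kind == "any" and self.allowed:
            raise ValueError("'any' element carries no explicit allowed set")
        if self.kind == "residue-class" and not self.allowed:
            raise ValueError("empty residue class")

    def matches(self, residue: str) -> bool:
        """True if *residue* satisfies this element.

        Padding (``-``) and the ambiguity code ``X`` never match, including
        'any' elements.
        """
        if self.kind == "any":
            return residue in AMINO_ACIDS
        return residue in self.allowed

    @property
    def n_allowed(self) -> int:
        return 20 if self.kind == "any" else len(self.allowed)

    def to_prosite(self) -> str:
        if self.kind == "any":
            return "x"
        if self.kind == "literal":
            return next(iter(self.allowed))
        return "[" + "".join(sorted(self.allowed)) + "]"


@dataclass(frozen=True)
class MotifPattern:
    """A parsed consensus pattern anchored on its phosphoacceptor element."""

    name: str
    elements: tuple
    phospho_index: int

    def __post_init__(self):
        if len(self.elements) < 2:
            raise ValueError("pattern length must be >= 2")
        phos = self.elements[self.phospho_index]
        if not phos.allowed <= {"S", "T"} or not phos.allowed:
            raise ValueError("phospho element must be a subset of {S, T}")

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def offsets(self) -> range:
        """Window offsets covered by the pattern (phospho element at 0)."""
        return range(-self.phospho_index, len(self.elements) - self.phospho_index)

    def to_prosite(self) -> str:
        """Canonical serialisation; parse → serialise is a fixed point."""
        return "-".join(e.to_prosite() for e in self.elements)


@dataclass(frozen=True)
class PhosphoWindow:
    """Residues at offsets −6..+2 around a phosphoacceptor.

    ``residues`` maps offset → one-letter code (``-`` where the source
    sequence ends); the residue at offset 0 is the phosphoacceptor and must
    be S or T.  ``context_mode`` records whether the window was taken from a
    short synthetic peptide or a longer protein context, which matters for
    the BRCT1 small-polar −4 rule.
    """

    residues: Mapping[int, str]
    context_mode: str = "short"

    def __post_init__(self):
        if tuple(sorted(self.residues)) != WINDOW_OFFSETS:
            raise ValueError("window must cover offsets -6..+2 exactly")
        if self.context_mode not in {"short", "long"}:
            raise ValueError("context_mode must be 'short' or 'long'")
        for off, res in self.residues.items():
            if res not in AMINO_ACIDS and res not in {PAD, "X"}:
                raise ValueError(f"invalid residue {res!r} at offset {off}")
        if self.residues[0] not in {"S", "T"}:
            raise ValueError(
                f"phosphoacceptor must be S or T, got {self.residues[0]!r}"
            )

    @classmethod
    def from_string(cls, text: str, context_mode: str = "short") -> "PhosphoWindow":
        """Build a window from a 9-character string spanning offsets −6..+2."""
        if len(text) != len(WINDOW_OFFSETS):
            raise ValueError("window string must be 9 characters (-6..+2)")
        return cls(dict(zip(WINDOW_OFFSETS, text.upper())), context_mode)

    def __getitem__(self, offset: int) -> str:
        return self.residues[offset]

    @property
    def phospho_residue(self) -> str:
        return self.residues[0]

    @property
    def truncated(self) -> bool:
        """True when padding intrudes into the scored core (offsets −5..−1)."""
        return any(self.residues[o] == PAD for o in range(-5, 0))

    def as_text(self) -> str:
        return "".join(self.residues[o] for o in WINDOW_OFFSETS)


@dataclass(frozen=True)
class RuleRecord:
    """One fired classifier rule: (rule id, offset, residue, effect)."""

    rule_id: str
    offset: Optional[int]
    residue: Optional[str]
    effect: str


@dataclass(frozen=True)
class DomainCompatibility:
    """Classifier output: the BRCT domains a window is sequence-compatible with.

    Sequence compatibility is necessary but not sufficient for an in-vivo
    interaction; windows passing these rules in proteins that bind other
    TOPBP1 modules (e.g. BLM, FANCJ) are not thereby BRCT1/2 partners.
    """

    compatible: frozenset
    preferred: str = "none"
    trace: tuple = ()
    flags: tuple = ()

    def __post_init__(self):
        if not self.compatible <= {"BRCT1", "BRCT2"}:
            raise ValueError("compatible must be a subset of {BRCT1, BRCT2}")
        if self.preferred != "none" and self.preferred not in self.compatible:
            raise ValueError("preferred domain must be in the compatible set")


@dataclass(frozen=True)
class ToleranceTable:
    """Substitution tolerance at offsets −5, −4, −3, −1 of the RAD9 tail.

    ``entries`` maps (offset, residue) to a Category for residues probed in
    the pull-down panel; ``native`` gives the RAD9 reference residues
    (−5:V, −4:L, −3:A, −1:D), each TIGHT by definition.
    """

    entries: Mapping[tuple, Category]
    native: Mapping[int, str]

    def __post_init__(self):
        for (off, res) in self.entries:
            if off not in SCORED_OFFSETS:
                raise ValueError(f"tolerance entries restricted to {SCORED_OFFSETS}")
            if res not in AMINO_ACIDS:
                raise ValueError(f"non-standard residue {res!r}")
        if dict(self.native) != {-5: "V", -4: "L", -3: "A", -1: "D"}:
            raise ValueError("native reference must be the RAD9 context V/L/A/D")

    def category(self, offset: int, residue: str) -> Category:
        if residue == self.native.get(offset):
            return Category.TIGHT
        return self.entries.get((offset, residue), Category.UNKNOWN)


@dataclass(frozen=True)
class SubsiteScore:
    """Per-offset tolerance categories and their summed ordinal score."""

    categories: Mapping[int, Category]
    total: int


# --- Prosite parsing -------------------------------------------------------


def parse_prosite_pattern(pattern_text: str, name: str = "") -> MotifPattern:
    """Parse a Prosite-style consensus string into a :class:`MotifPattern`.

    Supported syntax: ``[XYZ]`` residue classes, ``x`` wildcards, single
    uppercase literals, ``-`` separators.  Exactly one element must be a
    class drawn from {S, T}; it becomes the phosphoacceptor anchor.

    >>> p = parse_prosite_pattern("[FILMV]-x-x-[ST]-P", name="BRCT2")
    >>> len(p), p.phospho_index
    (5, 3)
    """
    tokens = pattern_text.strip().split("-")
    if any(not t for t in tokens):
        raise PatternParseError(f"empty token in pattern: {pattern_text!r}")
    elements = []
    for tok in tokens:
        if tok == "x":
            elements.append(PrositeElement("any"))
        elif tok.startswith("["):
            if not tok.endswith("]") or len(tok) < 3:
                raise PatternParseError(f"unbalanced or empty bracket: {tok!r}")
            body = tok[1:-1]
            if not set(body) <= AMINO_ACIDS:
                bad = sorted(set(body) - AMINO_ACIDS)
                raise PatternParseError(f"non-standard code {bad} in token {tok!r}")
            elements.append(PrositeElement("residue-class", frozenset(body)))
        elif len(tok) == 1 and tok in AMINO_ACIDS:
            elements.append(PrositeElement("literal", frozenset(tok)))
        else:
            if "]" in tok:
                raise PatternParseError(f"unbalanced bracket: {tok!r}")
            raise PatternParseError(f"unrecognised token {tok!r}")
    phospho = [
        i
        for i, e in enumerate(elements)
        if e.kind == "residue-class" and e.allowed <= {"S", "T"}
    ]
    if len(phospho) != 1:
        raise PatternParseError(
            f"pattern must contain exactly one [ST] element, found {len(phospho)}: "
            f"{pattern_text!r}"
        )
    return MotifPattern(name or pattern_text, tuple(elements), phospho[0])


#: The two published consensus strings.
BUILTIN_PATTERN_TEXT = {
    "BRCT1": "[FILMV]-[FILMV]-[FILMV]-x-x-[ST]-P",
    "BRCT2": "[FILMV]-x-x-[ST]-P",
}


def builtin_patterns() -> dict:
    """The two built-in consensus patterns, keyed BRCT1 / BRCT2."""
    return {
        name: parse_prosite_pattern(text, name=name)
        for name, text in BUILTIN_PATTERN_TEXT.items()
    }


def load_pattern_config(stream) -> dict:
    """Load ``name = prosite-string`` lines from a key-value config file.

    Blank lines and ``#`` comments are ignored.  Returns name → MotifPattern.
    """
    patterns = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise PatternParseError(f"line {lineno}: expected 'name = pattern'")
        name, text = (part.strip() for part in line.split("=", 1))
        patterns[name] = parse_prosite_pattern(text, name=name)
    return patterns


# --- Matching and counting -------------------------------------------------


def match_window(window: PhosphoWindow, pattern: MotifPattern) -> bool:
    """Strict match of *pattern* against *window*, phospho element at offset 0.

    Every element's allowed set must contain the residue at its aligned
    offset; padding and ``X`` never match.
    """
    offs = pattern.offsets
    if offs.start < WINDOW_OFFSETS[0] or offs.stop - 1 > WINDOW_OFFSETS[-1]:
        raise ValueError("pattern does not fit the -6..+2 window frame")
    return all(
        element.matches(window[off]) for off, element in zip(offs, pattern.elements)
    )


def count_matching_kmers(pattern: MotifPattern) -> int:
    """Number of length-L words over the 20-letter alphabet matching *pattern*.

    Analytic product over elements; an independent brute-force enumeration
    oracle lives in the test suite.
    """
    if len(pattern) > 7:
        raise ValueError("count restricted to patterns of length <= 7")
    return math.prod(e.n_allowed for e in pattern.elements)


# --- Tolerance table -------------------------------------------------------

_PANEL = {
    # −1: Asp native; serine retains tight binding, leucine/lysine abolish.
    (-1, "S"): Category.TIGHT,
    (-1, "K"): Category.ABOLISHED,
    (-1, "L"): Category.ABOLISHED,
    # −3: Ala native; only valine retains tight binding.
    (-3, "V"): Category.TIGHT,
    (-3, "S"): Category.REDUCED,
    (-3, "F"): Category.REDUCED,
    (-3, "D"): Category.REDUCED,
    (-3, "G"): Category.REDUCED,
    (-3, "I"): Category.REDUCED,
    # −4: Leu native; Phe/Ile tolerated with reduced binding, polar not.
    (-4, "F"): Category.REDUCED,
    (-4, "I"): Category.REDUCED,
    (-4, "S"): Category.ABOLISHED,
    (-4, "N"): Category.ABOLISHED,
    (-4, "A"): Category.ABOLISHED,
    # −5: Val native; broad tolerance, Asp penalised (electrostatic clash).
    (-5, "Q"): Category.TIGHT,
    (-5, "S"): Category.TIGHT,
    (-5, "F"): Category.TIGHT,
    (-5, "A"): Category.TIGHT,
    (-5, "D"): Category.REDUCED,
}

_NATIVE = {-5: "V", -4: "L", -3: "A", -1: "D"}


def default_tolerance_table() -> ToleranceTable:
    """The RAD9-tail substitution-scanning tolerance table."""
    return ToleranceTable(entries=dict(_PANEL), native=dict(_NATIVE))


def subsite_score(
    window: PhosphoWindow, table: Optional[ToleranceTable] = None
) -> SubsiteScore:
    """Score a window against the substitution-tolerance table.

    Returns the per-offset category (UNKNOWN for residues never probed) over
    offsets −5, −4, −3 and −1, and the total ordinal score (max 8).
    """
    table = table or default_tolerance_table()
    cats = {off: table.category(off, window[off]) for off in SCORED_OFFSETS}
    return SubsiteScore(categories=cats, total=sum(c.score for c in cats.values()))


# --- Compatibility classifier ---------------------------------------------


def classify_compatibility(
    window: PhosphoWindow,
    context_mode: Optional[str] = None,
    preferred_evidence: Optional[str] = None,
) -> DomainCompatibility:
    """Decide which of {BRCT1, BRCT2} a phosphoacceptor window can bind.

    Rules (residues named by their offset from the phosphoacceptor):

    * BRCT2 requires a hydrophobic residue (FILMV) at −3 — the single side
      chain buried by the extended-conformation pocket.
    * BRCT1 requires the tight-turn signature: −3 hydrophobic (alanine also
      accepted — the RAD9 precedent), −4 hydrophobic (small polar S/T/G/A is
      tolerated only in a long peptide context), no large polar residue
      (R/K/E/D/Q/N) at −4, and no bulky/basic residue (L/I/F/M/W/K/R) at −1,
      which would clash with the BRCT1 surface.
    * The +1 proline of the proline-directed kinase consensus makes no
      direct contact and is not required here; only the strict Prosite
      patterns enforce it.

    ``preferred_evidence`` supplies external (e.g. phosphate-pocket
    charge-reversal mutant FP) evidence of which compatible domain actually
    dominates binding; relative affinity is not derivable from the rules.
    Windows with padding inside offsets −5..−1 are classified but flagged
    ``truncated context``.
    """
    mode = context_mode or window.context_mode
    if mode not in {"short", "long"}:
        raise ValueError("context_mode must be 'short' or 'long'")

    r1, r3, r4 = window[-1], window[-3], window[-4]
    trace = []
    compatible = set()
    flags = ("truncated context",) if window.truncated else ()

    # BRCT2: extended conformation, only the −3 side chain is buried.
    if r3 in HYDROPHOBIC:
        compatible.add("BRCT2")
        trace.append(RuleRecord("brct2:-3-hydrophobic", -3, r3, "admitted"))
    else:
        trace.append(RuleRecord("brct2:-3-not-hydrophobic", -3, r3, "excluded BRCT2"))

    # BRCT1: tight turn burying both −4 and −3.
    brct1 = True
    if r3 in BRCT1_MINUS3:
        trace.append(RuleRecord("brct1:-3-turn", -3, r3, "admitted"))
    else:
        brct1 = False
        trace.append(RuleRecord("brct1:-3-not-turn", -3, r3, "excluded BRCT1"))
    if r4 in MINUS4_POLAR_EXCLUDED:
        brct1 = False
        effect = (
            "excluded BRCT1"
            if r4 in MINUS4_POLAR_OBSERVED
            else "excluded BRCT1 (extrapolated)"
        )
        trace.append(RuleRecord("brct1:-4-large-polar", -4, r4, effect))
    elif r4 in HYDROPHOBIC:
        trace.append(RuleRecord("brct1:-4-hydrophobic", -4, r4, "admitted"))
    elif r4 in MINUS4_SMALL_POLAR and mode == "long":
        trace.append(
            RuleRecord("brct1:-4-small-polar-long-context", -4, r4, "admitted")
        )
    else:
        brct1 = False
        rule = (
            "brct1:-4-small-polar-short-context"
            if r4 in MINUS4_SMALL_POLAR
            else "brct1:-4-incompatible"
        )
        trace.append(RuleRecord(rule, -4, r4, "excluded BRCT1"))
    if r1 in MINUS1_EXCLUDED:
        brct1 = False
        trace.append(RuleRecord("brct1:-1-clash", -1, r1, "excluded BRCT1"))
    if brct1:
        compatible.add("BRCT1")

    preferred = "none"
    if preferred_evidence is not None:
        if preferred_evidence not in {"BRCT1", "BRCT2"}:
            raise ValueError("preferred_evidence must be BRCT1 or BRCT2")
        if preferred_evidence in compatible:
            preferred = preferred_evidence
            trace.append(
                RuleRecord("evidence:preferred", None, None, f"prefers {preferred}")
            )

    return DomainCompatibility(
        compatible=frozenset(compatible),
        preferred=preferred,
        trace=tuple(trace),
        flags=flags,
    )
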