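"""Synthetic inputs for benchmarking the scan/classify/fit pipeline.

Provides everything needed to exercise the pipeline without downloads:

* random proteomes with consensus motifs planted at known positions (and an
  exhaustive truth table), for recall / false-positive benchmarking;
* orthologue window sets with a controlled motif-preservation rate, for the
  conservation score;
* the packaged fixture panel: the fluorescent assay peptides, the
  crystallisation peptides, a synthetic −4-arginine window standing in for
  the Crb2-pT235 class of BRCT2-restricted ligands, and the 21-peptide RAD9
  tail substitution pull-down panel, each with its expected outcome.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, TextIO, Tuple

import numpy as np

from .motif import (
    AMINO_ACIDS,
    Category,
    MotifPattern,
    PhosphoWindow,
    WINDOW_OFFSETS,
    builtin_patterns,
    classify_compatibility,
)
from .scan import SequenceRecord, parse_phosphopeptide

__all__ = [
    "PlantedTruth",
    "FixturePeptide",
    "generate_proteome",
    "generate_orthologue_set",
    "fixture_panel",
    "fluorescent_fixtures",
    "pulldown_panel",
    "write_truth_table",
    "RAD9_TAIL",
    "RAD9_TAIL_START",
    "RAD9_PHOSPHO_POSITION",
]

_ALPHABET = sorted(AMINO_ACIDS)

#: Approximate human proteome residue frequencies (Swiss-Prot averages),
#: available behind ``background_composition="human"``.
HUMAN_COMPOSITION: Dict[str, float] = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.100, "K": 0.057, "M": 0.021, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.054, "W": 0.012, "Y": 0.027, "V": 0.060,
}


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth location of one planted motif."""

    sequence_id: str
    position: int  # 1-based phosphoacceptor index
    planted_pattern: str


@dataclass(frozen=True)
class FixturePeptide:
    """A packaged peptide with its expected classification outcome.

    ``site`` is the 1-based phosphosite index in the cleaned peptide
    sequence.  For substitution pull-down entries, ``expected_category`` and
    ``varied_offset`` carry the expected sub-site tolerance instead of a
    compatibility set.
    """

    name: str
    origin: str
    peptide: str
    site: Optional[int] = None
    expected_compat_short: Optional[frozenset] = None
    expected_compat_long: Optional[frozenset] = None
    expected_strict: Optional[frozenset] = None
    preferred_evidence: Optional[str] = None
    expected_category: Optional[Category] = None
    varied_offset: Optional[int] = None


# --- proteome generation ---------------------------------------------------

#: Margin (residues) kept clear of sequence ends when planting.
_END_MARGIN = 6
#: Minimum spacing between planted phosphoacceptors within one protein.
_MIN_SPACING = 9


def _background_probs(background_composition) -> np.ndarray:
    if background_composition in (None, "uniform"):
        return np.full(20, 1.0 / 20.0)
    if background_composition == "human":
        comp = HUMAN_COMPOSITION
    elif isinstance(background_composition, dict):
        comp = background_composition
    else:
        raise ValueError(
            "background_composition must be 'uniform', 'human' or a dict"
        )
    probs = np.array([comp[a] for a in _ALPHABET], dtype=float)
    return probs / probs.sum()


def _sample_pattern_window(pattern: MotifPattern, rng) -> Dict[int, str]:
    """Draw residues uniformly from each element's allowed set."""
    out = {}
    for off, element in zip(pattern.offsets, pattern.elements):
        pool = _ALPHABET if element.kind == "any" else sorted(element.allowed)
        out[off] = pool[rng.integers(len(pool))]
    return out


def generate_proteome(
    n_proteins: int,
    length_range: Tuple[int, int] = (200, 600),
    n_planted: int = 0,
    patterns: Optional[Dict[str, MotifPattern]] = None,
    background_composition="uniform",
    seed: int = 0,
) -> Tuple[List[SequenceRecord], List[PlantedTruth]]:
    """Generate a random proteome with motifs planted at known positions.

    Background residues are i.i.d. from the chosen composition (uniform by
    default, so the analytic false-positive rate of a pattern is exact).
    Planted windows are drawn uniformly from each pattern element's allowed
    set — including the wildcard positions, so planted sites also exercise
    classifier edge cases.  Planting stays at least 6 residues from either
    sequence end and planted sites never overlap.  Returns the records and
    an exhaustive truth table.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be positive")
    lo, hi = length_range
    if not (_END_MARGIN * 2 + 3) <= lo <= hi:
        raise ValueError(f"length_range minimum must be at least {2 * _END_MARGIN + 3}")
    patterns = builtin_patterns() if patterns is None else patterns
    pattern_names = sorted(patterns)
    rng = np.random.default_rng(seed)
    probs = _background_probs(background_composition)

    lengths = rng.integers(lo, hi + 1, size=n_proteins)
    sequences = [
        "".join(np.asarray(_ALPHABET)[rng.choice(20, size=length, p=probs)])
        for length in lengths
    ]

    # Assign planted sites round-robin over proteins, then place them.
    per_protein: List[List[str]] = [[] for _ in range(n_proteins)]
    for k in range(n_planted):
        per_protein[k % n_proteins].append(pattern_names[k % len(pattern_names)])

    truths: List[PlantedTruth] = []
    records: List[SequenceRecord] = []
    for idx, (seq, plant_list) in enumerate(zip(sequences, per_protein)):
        seq_id = f"syn{idx + 1:04d}"
        chars = list(seq)
        used: List[int] = []
        lo_pos, hi_pos = 1 + _END_MARGIN, len(chars) - _END_MARGIN
        for pattern_name in plant_list:
            pattern = patterns[pattern_name]
            placed = False
            for _ in range(200):
                pos = int(rng.integers(lo_pos, hi_pos + 1))
                if all(abs(pos - u) >= _MIN_SPACING for u in used):
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place {len(plant_list)} motifs in {seq_id}; "
                    "n_planted exceeds proteome capacity"
                )
            window = _sample_pattern_window(pattern, rng)
            for off, res in window.items():
                chars[pos - 1 + off] = res
            used.append(pos)
            truths.append(PlantedTruth(seq_id, pos, pattern_name))
        records.append(
            SequenceRecord(id=seq_id, description="synthetic", residues="".join(chars))
        )
    truths.sort(key=lambda t: (t.sequence_id, t.position))
    return records, truths


def write_truth_table(truths: Sequence[PlantedTruth], stream: TextIO) -> None:
    """Write a planted-motif truth table as TSV."""
    stream.write("sequence_id\tposition\tplanted_pattern\n")
    for t in truths:
        stream.write(f"{t.sequence_id}\t{t.position}\t{t.planted_pattern}\n")


# --- orthologue sets -------------------------------------------------------


def generate_orthologue_set(
    window: PhosphoWindow,
    n_species: int,
    preservation_rate: float,
    seed: int = 0,
) -> List[PhosphoWindow]:
    """Orthologue windows preserving compatibility with a given probability.

    Each orthologue independently preserves the query's BRCT compatibility
    with probability ``preservation_rate`` (preserving orthologues copy the
    query window); the rest receive a disqualifying substitution — −3→Asp
    (removes both domains) or, when the query is BRCT1-compatible,
    −4→Arg (removes BRCT1).  A query with an empty compatibility set cannot
    be disqualified further; such orthologues are returned unmodified.
    """
    if not 0.0 <= preservation_rate <= 1.0:
        raise ValueError("preservation_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    query_compat = classify_compatibility(window).compatible
    orthologues = []
    for _ in range(n_species):
        if rng.random() < preservation_rate or not query_compat:
            orthologues.append(window)
            continue
        residues = dict(window.residues)
        if "BRCT1" in query_compat and rng.random() < 0.5:
            residues[-4] = "R"
        else:
            residues[-3] = "D"
        orthologues.append(PhosphoWindow(residues, window.context_mode))
    return orthologues


# --- packaged fixture panel ------------------------------------------------

#: C-terminal 45 residues of human RAD9 (347–391) used in the pull-down
#: panel; the phosphoacceptor Ser387 sits at panel position 41.
RAD9_TAIL = "AEPSTVPGTPPPKKFRSLFFGSILAPVRSPQGPSPVLAEDSEGEG"
RAD9_TAIL_START = 347
RAD9_PHOSPHO_POSITION = 41

# Substitution rows of the pull-down panel: (label, offset, residue,
# expected tolerance).  The native pS387 row is TIGHT at every scored
# offset; the unphosphorylated S387 row is the no-binding control.
_PULLDOWN_VARIANTS: List[Tuple[str, int, str, Category]] = [
    ("S-1", -1, "S", Category.TIGHT),
    ("K-1", -1, "K", Category.ABOLISHED),
    ("L-1", -1, "L", Category.ABOLISHED),
    ("S-3", -3, "S", Category.REDUCED),
    ("F-3", -3, "F", Category.REDUCED),
    ("D-3", -3, "D", Category.REDUCED),
    ("G-3", -3, "G", Category.REDUCED),
    ("I-3", -3, "I", Category.REDUCED),
    ("V-3", -3, "V", Category.TIGHT),
    ("S-4", -4, "S", Category.ABOLISHED),
    ("N-4", -4, "N", Category.ABOLISHED),
    ("A-4", -4, "A", Category.ABOLISHED),
    ("F-4", -4, "F", Category.REDUCED),
    ("I-4", -4, "I", Category.REDUCED),
    ("Q-5", -5, "Q", Category.TIGHT),
    ("S-5", -5, "S", Category.TIGHT),
    ("D-5", -5, "D", Category.REDUCED),
    ("F-5", -5, "F", Category.TIGHT),
    ("A-5", -5, "A", Category.TIGHT),
]


def _variant_peptide(offset: int, residue: str) -> str:
    """RAD9 tail with one substitution, phosphomarked at the acceptor."""
    chars = list(RAD9_TAIL)
    chars[RAD9_PHOSPHO_POSITION - 1 + offset] = residue
    p = RAD9_PHOSPHO_POSITION
    return "".join(chars[: p - 1]) + "p" + "".join(chars[p - 1 :])


def pulldown_panel() -> List[FixturePeptide]:
    """The 21-peptide RAD9 tail substitution panel with expected tolerances."""
    p = RAD9_PHOSPHO_POSITION
    native = (
        "".join(RAD9_TAIL[: p - 1]) + "p" + "".join(RAD9_TAIL[p - 1 :])
    )
    panel = [
        FixturePeptide(
            name="pS387",
            origin="pulldown",
            peptide=native,
            site=p,
            expected_category=Category.TIGHT,
            varied_offset=None,
            expected_compat_short=frozenset({"BRCT1"}),
            preferred_evidence="BRCT1",
        ),
        # Unphosphorylated control: no phosphosite, no binding expected.
        FixturePeptide(name="S387", origin="pulldown", peptide=RAD9_TAIL),
    ]
    for label, offset, residue, category in _PULLDOWN_VARIANTS:
        panel.append(
            FixturePeptide(
                name=label,
                origin="pulldown",
                peptide=_variant_peptide(offset, residue),
                site=p,
                expected_category=category,
                varied_offset=offset,
            )
        )
    return panel


def _parse_set(cell: str) -> frozenset:
    return frozenset() if cell == "." else frozenset(cell.split(","))


def fluorescent_fixtures() -> List[FixturePeptide]:
    """Fluorescent-assay, crystallisation and synthetic fixture peptides."""
    text = (
        importlib.resources.files("brctscan.data")
        .joinpath("fixture_peptides.tsv")
        .read_text(encoding="utf-8")
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    fixtures = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        fixtures.append(
            FixturePeptide(
                name=row["name"],
                origin=row["origin"],
                peptide=row["peptide"],
                site=int(row["site"]),
                expected_compat_short=_parse_set(row["compat_short"]),
                expected_compat_long=_parse_set(row["compat_long"]),
                expected_strict=_parse_set(row["strict"]),
                preferred_evidence=(
                    None if row["preferred"] == "none" else row["preferred"]
                ),
            )
        )
    return fixtures


def fixture_panel() -> List[FixturePeptide]:
    """All packaged fixtures: assay peptides plus the pull-down panel.

    Every peptide string parses with :func:`parse_phosphopeptide`; the
    expectations are regression-locked against the classifier by the test
    suite.
    """
    return fluorescent_fixtures() + pulldown_panel()
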