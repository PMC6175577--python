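"""Triage of scan hits: disorder, phospho-annotation and conservation.

Candidate binding sites found by scanning are prioritised for experimental
follow-up on three kinds of evidence: occurrence in non-structured
(intrinsically disordered) regions, prior annotation as phosphorylated, and
conservation of the motif across species.  Conservation is counted at the
level of compatibility-class preservation, not residue identity — what
matters is whether an orthologue's window would still bind the same BRCT
domains, not whether every flanking residue is identical.

Disorder uses the TOP-IDP per-residue disorder-propensity scale (Campen et
al., 2008), smoothed over a sliding window and min-max rescaled so that the
scale's extremes (Trp, most order-promoting; Pro, most disorder-promoting)
map to 0 and 1.  Callers with access to a dedicated disorder predictor can
supply precomputed per-residue scores instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, TextIO, Tuple

import numpy as np

from .motif import PhosphoWindow, classify_compatibility
from .scan import MotifMatch, SequenceRecord

__all__ = [
    "TOP_IDP",
    "EvidenceRecord",
    "CandidateSite",
    "RankWeights",
    "disorder_profile",
    "window_disorder",
    "conservation_score",
    "rank_candidates",
    "load_phospho_annotations",
    "load_disorder_scores",
]

#: TOP-IDP disorder propensities; higher = more disorder-promoting.
TOP_IDP: Dict[str, float] = {
    "A": 0.06, "R": 0.180, "N": 0.007, "D": 0.192, "C": 0.02,
    "Q": 0.318, "E": 0.736, "G": 0.166, "H": 0.303, "I": -0.486,
    "L": -0.326, "K": 0.586, "M": -0.397, "F": -0.697, "P": 0.987,
    "S": 0.341, "T": 0.059, "W": -0.884, "Y": -0.510, "V": -0.121,
}

_SCALE_MIN = min(TOP_IDP.values())
_SCALE_MAX = max(TOP_IDP.values())

#: Rescaled propensities in [0, 1].
_TOP_IDP_01 = {
    res: (v - _SCALE_MIN) / (_SCALE_MAX - _SCALE_MIN) for res, v in TOP_IDP.items()
}
# Ambiguous residues contribute the scale midpoint.
_TOP_IDP_01["X"] = 0.5


@dataclass(frozen=True)
class EvidenceRecord:
    """Per-candidate triage evidence.

    ``conservation`` may be ``None`` when no orthologues were available;
    ranking then falls back to an uninformative 0.5.
    """

    phospho_annotated: bool = False
    disorder_mean: float = 0.0
    conservation: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.disorder_mean <= 1.0:
            raise ValueError("disorder_mean must lie in [0, 1]")
        if self.conservation is not None and not 0.0 <= self.conservation <= 1.0:
            raise ValueError("conservation must lie in [0, 1] when defined")


@dataclass(frozen=True)
class RankWeights:
    """Weights of the four ranking terms; must sum to 1."""

    motif: float = 0.4
    disorder: float = 0.2
    conservation: float = 0.2
    phospho: float = 0.2

    def __post_init__(self):
        total = self.motif + self.disorder + self.conservation + self.phospho
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"ranking weights must sum to 1, got {total}")
        if min(self.motif, self.disorder, self.conservation, self.phospho) < 0:
            raise ValueError("ranking weights must be non-negative")


@dataclass(frozen=True)
class CandidateSite:
    """A ranked scan hit; rank 1 is the top candidate."""

    match: MotifMatch
    evidence: EvidenceRecord
    rank_score: float
    rank: int


def disorder_profile(record: SequenceRecord, half_window: int = 10) -> np.ndarray:
    """Per-residue disorder scores in [0, 1] for a protein sequence.

    Each residue's score is the mean rescaled TOP-IDP propensity over the
    residues within ``half_window`` of it (truncated at the ends), so a
    homopolymer scores a flat profile at that residue's propensity.
    Deterministic; profile length equals sequence length.
    """
    if half_window < 0:
        raise ValueError("half_window must be non-negative")
    values = np.array([_TOP_IDP_01[res] for res in record.residues])
    n = len(values)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(idx - half_window, 0)
    hi = np.minimum(idx + half_window + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def window_disorder(
    record: SequenceRecord, position: int, half_window: int = 10
) -> float:
    """Disorder score of a single 1-based position (convenience wrapper)."""
    return float(disorder_profile(record, half_window)[position - 1])


def conservation_score(
    window: PhosphoWindow, orthologue_windows: Sequence[PhosphoWindow]
) -> Optional[float]:
    """Fraction of orthologue windows preserving the query's compatibility.

    An orthologue "preserves" the motif when its BRCT compatibility set is a
    superset of the query's — the orthologous site could still bind every
    domain the query can.  Returns ``None`` for an empty orthologue list
    (absence of data is not evidence of conservation).
    """
    if not orthologue_windows:
        return None
    query = classify_compatibility(window).compatible
    preserved = sum(
        1
        for orth in orthologue_windows
        if classify_compatibility(orth).compatible >= query
    )
    return preserved / len(orthologue_windows)


#: Conservation value used when no orthologue data exist.
MISSING_CONSERVATION = 0.5


def rank_candidates(
    matches: Sequence[MotifMatch],
    evidence: Mapping[Tuple[str, int], EvidenceRecord],
    weights: Optional[RankWeights] = None,
) -> List[CandidateSite]:
    """Rank scan hits by weighted triage evidence.

    ``evidence`` is keyed by (sequence_id, position); every match must have
    an entry.  The rank score is::

        w_motif · motif_score + w_dis · disorder_mean
        + w_cons · conservation + w_phos · [phospho_annotated]

    where ``motif_score`` is the normalised subsite-tolerance total plus the
    +1-proline bonus (as stored on the match), and missing conservation is
    treated as 0.5.  The sort is stable with ties broken by
    (sequence_id, position), so input order never affects the output.
    """
    weights = weights or RankWeights()
    scored = []
    for m in matches:
        key = (m.sequence_id, m.phospho_position)
        if key not in evidence:
            raise KeyError(f"no evidence record for match {key}")
        ev = evidence[key]
        cons = MISSING_CONSERVATION if ev.conservation is None else ev.conservation
        rank_score = (
            weights.motif * m.score
            + weights.disorder * ev.disorder_mean
            + weights.conservation * cons
            + weights.phospho * (1.0 if ev.phospho_annotated else 0.0)
        )
        scored.append((m, ev, rank_score))
    scored.sort(key=lambda t: (-t[2], t[0].sequence_id, t[0].phospho_position))
    return [
        CandidateSite(match=m, evidence=ev, rank_score=s, rank=i)
        for i, (m, ev, s) in enumerate(scored, start=1)
    ]


# --- evidence-file loaders -------------------------------------------------


def load_phospho_annotations(stream: TextIO) -> set:
    """Read a (sequence_id, position) phospho-annotation TSV into a set.

    Lines starting with ``#`` are ignored; a header line reading
    ``sequence_id<TAB>position`` is skipped if present.
    """
    annotated = set()
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")
        if cells[:2] == ["sequence_id", "position"]:
            continue
        if len(cells) < 2:
            raise ValueError(f"annotation line needs 2 columns: {raw!r}")
        annotated.add((cells[0], int(cells[1])))
    return annotated


def load_disorder_scores(stream: TextIO) -> Dict[Tuple[str, int], float]:
    """Read precomputed per-residue disorder scores from TSV.

    Columns: sequence_id, position (1-based), score in [0, 1].
    """
    scores: Dict[Tuple[str, int], float] = {}
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")
        if cells[0] == "sequence_id":
            continue
        if len(cells) < 3:
            raise ValueError(f"disorder line needs 3 columns: {raw!r}")
        value = float(cells[2])
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"disorder score out of [0, 1]: {value}")
        scores[(cells[0], int(cells[1]))] = value
    return scores
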