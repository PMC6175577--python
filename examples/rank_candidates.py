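"""Rank candidate sites in the RAD9 tail by triage evidence.

Scans the RAD9 C-terminal tail in scored mode, attaches evidence (disorder
from the smoothed TOP-IDP profile, a phospho-annotation for Ser387, and
synthetic orthologue conservation), and ranks the candidates.  The known
site, S387 — annotated, disordered and conserved — should outrank the
incidental matches.
"""

from brctscan import (
    EvidenceRecord,
    SequenceRecord,
    conservation_score,
    rank_candidates,
    scan_sequence,
)
from brctscan.prioritise import window_disorder
from brctscan.synthetic import RAD9_TAIL, RAD9_TAIL_START, generate_orthologue_set

record = SequenceRecord("RAD9", "C-terminal tail 347-391", RAD9_TAIL)
matches = scan_sequence(record, mode="scored")

annotated = {41}  # Ser387 is a documented CK2 site
evidence = {}
for m in matches:
    is_site = m.phospho_position in annotated
    orths = generate_orthologue_set(
        m.window, n_species=12, preservation_rate=0.9 if is_site else 0.3, seed=7
    )
    evidence[(m.sequence_id, m.phospho_position)] = EvidenceRecord(
        phospho_annotated=is_site,
        disorder_mean=window_disorder(record, m.phospho_position),
        conservation=conservation_score(m.window, orths),
    )

for site in rank_candidates(matches, evidence):
    pos = site.match.phospho_position
    residue_number = RAD9_TAIL_START + pos - 1
    compat = ",".join(sorted(site.match.compatibility.compatible))
    print(
        f"rank {site.rank}: residue {residue_number} ({site.match.phospho_residue})"
        f"  score {site.rank_score:.3f}  compatible {compat}"
    )
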