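"""Classify the packaged assay peptides for BRCT1/BRCT2 compatibility.

Each fluorescent peptide is parsed from its assay notation, the window
around each phosphosite extracted, and the rule-based classifier applied.
The printed set is the BRCT domains the sequence is compatible with —
empty means neither domain is predicted to bind (as for the Mdb1 SDT site,
which is an Nbs1 ligand, not a Rad4 ligand).
"""

from brctscan import classify_compatibility, parse_phosphopeptide, peptide_window
from brctscan.synthetic import fluorescent_fixtures

for fx in fluorescent_fixtures():
    pep = parse_phosphopeptide(fx.peptide)
    window = peptide_window(pep, fx.site)
    compat = classify_compatibility(window)
    domains = ", ".join(sorted(compat.compatible)) or "neither"
    print(f"{fx.name:28s} window {window.as_text()}  ->  {domains}")

print()
print("A window like VLAED-pS (RAD9-pS387) is BRCT1-only: its -3 alanine is")
print("too small for the BRCT2 pocket but fits the BRCT1 tight-turn recess.")
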