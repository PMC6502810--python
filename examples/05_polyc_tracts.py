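"""Scan a 3'-UTR fragment for poly-C tracts.

Poly-C binding proteins such as hnRNPK recognize runs of cytosines;
scanning a UTR for maximal C-runs of a minimum length is the first step
in locating candidate binding sites to mutagenize.
"""

from ribostate import find_polyc_tracts

# a synthetic 3'-UTR-like fragment with several embedded poly-C tracts
utr = (
    "AUGGUAACCCCCUAGGAUUCGAUCCCCAAUGGCUUACGGAUC"
    "CCCCCCGUAAUGCAUGGAUUACGCAUCCCGUAAGCUA"
)

for min_run in (3, 4, 6):
    tracts = find_polyc_tracts(utr, min_run=min_run)
    pretty = ", ".join(f"{s}-{e} ({utr[s:e]})" for s, e in tracts)
    print(f"min_run={min_run}: {len(tracts)} tract(s)  {pretty}")

# Raising the threshold keeps only the longer runs: the tract list is
# maximal (runs cannot be extended), disjoint, and ordered 5' to 3', so
# positions can be used directly to design C->A/U mutants.
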