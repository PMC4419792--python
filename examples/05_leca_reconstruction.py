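"""Dollo reconstruction of the LECA's COPII complement.

Loads the shipped text-encoded presence/absence matrix (22 eukaryotes x 8
components) and its rooted taxonomy, places each component's single gain at
the MRCA of its carriers, and reports which components trace to the root.
"""
import copiievo as cv

matrix = cv.load_reference_presence()
taxonomy = cv.load_reference_taxonomy()
result = cv.leca_complement(matrix, taxonomy)

for comp in matrix.components:
    r = result.per_component[comp]
    where = "LECA" if comp in result.components else r.gain_node
    print(f"{comp:6s} gain at {where:12s} secondary losses: {r.loss_count}")
print(f"\nLECA complement: {result.count} components -> {', '.join(result.components)}")
# Sar1/Sec23/Sec24/Sec13/Sec31 are universal (0 losses); Sec12 and Sec16
# each need 7 independent losses but still gain at the root; Sed4's gain
# sits inside the Saccharomycetaceae, so it is excluded from the LECA.
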