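"""Assign generic residue labels to receptor loop sequences.

Builds the shipped (reconstructed) D2R/D3R extracellular-loop alignment and
prints the anchored labels: the conserved EL1 Trp is EL1.50 and the
disulfide-bonded EL2 Cys is EL2.50; neighbours step by one per alignment
column, so a receptor with a deletion skips indices.
"""

from importlib import resources

from gpcrdyn.numbering import assign_generic_numbers, read_alignment_block


def data(name):
    return resources.files("gpcrdyn.data").joinpath(name)


for region in ("el1", "el2"):
    block = read_alignment_block(data(f"{region}_alignment_synthetic.fasta"),
                                 data(f"{region}_anchors_synthetic.json"))
    print(f"--- {region.upper()} window ---")
    for receptor in ("D2R", "D3R"):
        m = assign_generic_numbers(block, receptor)
        labelled = [(p, aa, l) for p, aa, l in m.entries if l is not None]
        text = ", ".join(f"{aa}{p}={l}" for p, aa, l in labelled)
        print(f"{receptor}: {text}")

# The anchor residues (D2R Trp100/Cys182, D3R Trp96/Cys181) receive the same
# generic label despite different sequence positions -- that is the point of
# the scheme: aligned positions are comparable across receptors.
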