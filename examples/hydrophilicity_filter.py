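"""Per-peptide hydrophilicity under the packaged interface scale.

The screen keeps only peptides whose summed per-residue hydrophilicity
is strictly positive (a water-solubility proxy).  The packaged scale is
the Wimley-White water->bilayer-interface transfer free-energy scale
with charged side chains (positive = hydrophilic).  Shown here on six
candidate CEST-contrast peptides and on the K12 gold standard.
"""

from regexgp import hydrophilicity, wimley_white_interface

scale = wimley_white_interface()
candidates = [
    "ICKLLKLLKLLK",
    "QSLKQSIKKLKK",
    "RLKSMQLKLDKL",
    "QDGSKKSLKSCK",
    "QSCKYCQSLKFD",
    "SEVEKPFWEQDK",
]
print(f"{'peptide':<14} hydrophilicity  soluble?")
for pep in candidates + ["K" * 12]:
    h = hydrophilicity(pep, scale)
    print(f"{pep:<14} {h:13.2f}  {'yes' if h > 0 else 'no'}")
# all-leucine stretches drag the sum toward zero; lysine- and
# glutamate-rich peptides sum strongly positive
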