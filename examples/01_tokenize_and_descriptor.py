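"""Tokenize a quasi-SMILES string and compute its optimal descriptor.

A quasi-SMILES is an ordinary SMILES extended with bracketed condition
codes — here the nanoparticle concentration.  The descriptor DCW is the
sum of per-code correlation weights, counted with multiplicity.
"""

import quasicw as q

string = "O=[Al]O[Al]=O[c25,00]"  # nano-alumina at 25 µg/mL
codes = q.tokenize(string)
print(f"{string} -> {codes}")

wt = q.WeightTable(weights={"O": 1.0, "=": 1.0, "[Al]": 2.0, "[c25,00]": 3.0})
dcw = q.compute_dcw(codes, wt)
print(f"DCW = {dcw}")
# 12.0: three O's and two ='s at weight 1, two [Al]'s at weight 2, plus
# the concentration code at weight 3 — each occurrence counts once.

model = q.LinearModel(c0=20.0, c1=5.0)
rec = q.QuasiSmilesRecord(id=1, quasi_smiles=string, endpoint=102.78)
print(f"predicted viability = {q.predict(rec, wt, model):.1f} %")
# c0 + c1 * DCW = 20 + 5*12 = 80.0 % with these illustrative weights.
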