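"""Fold a candidate miRNA precursor and judge it by MFE and MFEI.

A genuine pre-miRNA folds into a stable stem-loop (MFE well below
-18 kcal/mol) and has a high minimal folding free energy index
(MFEI >= 0.85); most other transcribed sequence fails one of the two.
"""

from mulmir.rnafold import amfe, fold, gc_percent, mfei
from mulmir.seqio import revcomp

mature = "TGGAGAAGCAGGGCACGTGCA"
loop = "CAACAATC"
flank5, flank3 = "AACCAACAACAACCAA", "CAACAACCAAACAACA"
precursor = flank5 + mature + loop + revcomp(mature) + flank3

res = fold(precursor)
print("precursor:", precursor)
print("structure:", res.structure)
print(f"MFE  = {res.mfe:.2f} kcal/mol   (stable hairpin if < -18)")
print(f"AMFE = {amfe(precursor, res.mfe):.1f}   (|MFE| per 100 nt)")
print(f"GC%  = {gc_percent(precursor):.1f}")
print(f"MFEI = {mfei(precursor, res.mfe):.2f}   (miRNA-precursor-like if >= 0.85)")

shuffled = "AACAGGACACAGTGAGCGGACTGAAGCAGGACGTGCCACACCAGTGAAGCAACCACAACAACCAAACAACAACCAAAC"
res2 = fold(shuffled)
print(f"\nshuffled control: MFE = {res2.mfe:.2f}, MFEI = {mfei(shuffled, res2.mfe):.2f}")
# The control may still fold weakly, but its MFEI stays far below 0.85.
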