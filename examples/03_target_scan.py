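"""Scan a transcript for miRNA target sites under the six duplex rules.

Positions are numbered from the miRNA 5' end; G:U wobbles cost half a
mismatch; the cleavage-site positions 10-11 must pair perfectly and the
duplex must reach 75% of the perfect-complement binding energy.
"""

from mulmir.seqio import SequenceRecord, revcomp
from mulmir.target_pred import scan, score_site

mirna = "TGGAGAAGCAGGGCACGTGCA"

# transcript with one compliant site (a single G:U at position 17)
site = list(revcomp(mirna))
site[21 - 17] = "T"  # miRNA G at position 17 now faces U
transcript = SequenceRecord(
    id="Morus_demo_001",
    seq="ACAACCAACAACAAACCAAC" + "".join(site) + "CAACAAACCAACAACACAAC",
)

for hit in scan(mirna, transcript):
    print(f"site on {hit.transcript_id} at {hit.start}-{hit.end}")
    print(f"  miRNA 5'-{mirna}-3'")
    print(f"  pairing  {hit.duplex.alignment_string()}   (| WC, o G:U, . mismatch)")
    print(f"  weighted mismatches: {hit.weighted_total}")
    print(f"  energy ratio vs perfect complement: {hit.energy_ratio:.2f}")

# a mismatch at position 10 kills the site regardless of everything else
bad = list(revcomp(mirna))
bad[21 - 10] = "C"
verdict = score_site(mirna, "".join(bad))
print(f"\nmismatch at position 10 -> accepted={verdict.accepted}, "
      f"first violated rule = {verdict.first_violated}")
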