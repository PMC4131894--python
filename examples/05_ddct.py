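"""Relative expression from stem-loop qRT-PCR Cts by the 2^-ddCt method.

Triplicate Cts for a target miRNA and two reference genes in three
tissues; leaf is the calibrator, so its RQ is exactly 1 and the other
tissues are fold changes relative to leaf.
"""

import pandas as pd

from mulmir.expression import ddct

rows = []
for sample, ct in (("leaf", 21.3), ("bark", 22.3), ("male_flower", 19.0)):
    for rep in (1, 2, 3):
        rows.append(("rRNA5.8S", sample, rep, 15.9))
        rows.append(("RPL15", sample, rep, 16.1))
        rows.append(("miR901", sample, rep, ct))
table = pd.DataFrame(rows, columns=["assay", "sample", "replicate", "Ct"])

for res in ddct(table, "miR901", ["rRNA5.8S", "RPL15"], "leaf"):
    print(f"{res.sample:12s} dCt={res.delta_ct:6.2f} "
          f"ddCt={res.delta_delta_ct:6.2f}  RQ={res.rq:.3f}")

# One cycle later than the calibrator halves the quantity (bark); 2.3
# cycles earlier is a ~4.9-fold induction (male flower).
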