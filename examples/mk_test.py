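"""Unpolarized McDonald-Kreitman test from a polymorphism/divergence table.

Each row is a gene's 2x2 table: synonymous/nonsynonymous changes that are
polymorphic within the ingroup (pS, pN) or fixed against the outgroup
(dS, dN).  alpha = 1 - (dS*pN)/(dN*pS) estimates the fraction of fixed
amino-acid substitutions driven by positive selection; the p-value is
Fisher's exact test on the table (two-sided).
"""

import pandas as pd

from condevol import mk_from_counts_table, mk_table_frame

counts = pd.DataFrame(
    [
        ("Cap-D3", 544, 231, 25, 53),
        ("Cap-D2", 565, 130, 39, 19),
        ("Barren", 145, 57, 33, 15),
        ("SMC2", 150, 44, 24, 6),
    ],
    columns=["gene", "pS", "pN", "dS", "dN"],
)

results = mk_from_counts_table(counts)
print(mk_table_frame(results).to_string(index=False))
print()
print("alpha near 0.8 with a tiny p-value (Cap-D3) is strong evidence of "
      "recurrent adaptive protein evolution; a negative alpha (SMC2) is "
      "consistent with segregating weakly deleterious variants instead.")
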