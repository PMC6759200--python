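"""Count independent gene-loss events on a phylogeny with Dollo parsimony.

Presence/absence of three condensin II subunits across insect orders is
mapped onto a rooted order-level tree.  Under Dollo parsimony a gene is
gained once (complete ancestral complex) and only ever lost; the minimal
reconstruction pins each loss to an edge.
"""

from condevol import Phylogeny, TipStateMatrix, loss_summary

tree = Phylogeny.from_newick(
    "((((((Diptera,Lepidoptera),Coleoptera),Hymenoptera),Hemiptera),"
    "Odonata),Collembola);"
)

orders = ["Diptera", "Lepidoptera", "Coleoptera", "Hymenoptera",
          "Hemiptera", "Odonata", "Collembola"]
presence = {
    #              Dip  Lep  Col  Hym  Hem  Odo  Collembola
    "Cap-G2":     ["0", "0", "0", "1", "1", "0", "0"],
    "Cap-H2":     ["1", "0", "1", "1", "1", "0", "0"],
    "Cap-D3":     ["1", "1", "0", "1", "1", "1", "0"],
}
state = {}
for gene, cells in presence.items():
    for taxon, cell in zip(orders, cells):
        state[(taxon, gene)] = "present" if cell == "1" else "absent"
matrix = TipStateMatrix(orders, list(presence), state)

maps, table = loss_summary(tree, matrix)
print(table.to_string(index=False))
print()
print("Each row counts the independent loss events the tip pattern forces; "
      "e.g. Cap-G2 absent in Diptera+Lepidoptera+Coleoptera and again in "
      "Odonata and Collembola cannot descend from one ancestral event.")
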