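"""Synthetic-data generators for every pipeline stage.

Each generator draws from a named substream of one root seed (adding a
generator never perturbs the draws of another) and returns its ground truth
alongside the data, so end-to-end tests can compare pipeline output to the
simulated history.  The generators emulate the statistical structure the
analyses assume — Dollo loss histories on a tree, genomes with implanted /
deleted / diverged orthologs (plus decoy paralogs and exact-repeat
artifacts), codon alignments with controlled polymorphism, divergence and
adaptive-substitution fraction, and Bernoulli nucleus-pairing counts — not
the full texture of real assemblies or coalescent histories.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .dollo import ROOT_EDGE, LossMap, _edge_key
from .mk import STOP_CODONS, _CODON_TABLE, translate_codon
from .model import MKCounts, Phylogeny, SequenceRecord, TipStateMatrix

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# fixed back-translation table: one canonical (high-usage) codon per residue
PREFERRED_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

# codon neighbor tables (single-base changes to sense codons)
SYN_NEIGHBORS: dict[str, list[str]] = {}
NONSYN_NEIGHBORS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.items():
    if _aa == "*":
        continue
    syn, nonsyn = [], []
    for _pos in range(3):
        for _b in "ACGT":
            if _b == _codon[_pos]:
                continue
            _alt = _codon[:_pos] + _b + _codon[_pos + 1:]
            if _alt in STOP_CODONS:
                continue
            (syn if _CODON_TABLE[_alt] == _aa else nonsyn).append(_alt)
    SYN_NEIGHBORS[_codon] = syn
    NONSYN_NEIGHBORS[_codon] = nonsyn

_VERSATILE_CODONS = sorted(
    c for c in SYN_NEIGHBORS
    if SYN_NEIGHBORS[c] and NONSYN_NEIGHBORS[c]
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named child stream of a root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                zlib.crc32(name.encode())])
    )


@dataclass
class MKSimParams:
    """Per-codon-site event rates for the MK alignment generator.

    theta_* set the chance of a segregating synonymous / nonsynonymous
    change; div_* the chance of a neutral fixed change.  The neutral
    nonsynonymous:synonymous ratio is equal (1:3) in both compartments so
    the null expectation of alpha is 0; adaptive fixed nonsynonymous
    changes are added so that the expected adaptive fraction of dN equals
    ``adaptive_fraction``.
    """

    n_ingroup: int = 20
    n_outgroup: int = 1
    n_codons: int = 2000
    theta_syn: float = 0.15
    theta_nonsyn: float = 0.05
    div_syn: float = 0.06
    div_nonsyn: float = 0.02
    adaptive_fraction: float = 0.0


@dataclass
class SimConfig:
    seed: int = 0
    loss_prob: float = 0.1
    divergence_ladder: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3)
    mk: MKSimParams = field(default_factory=MKSimParams)
    p_pair: float = 0.285
    n_nuclei: int = 200


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def random_protein(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def mutate_protein(residues: str, divergence: float,
                   rng: np.random.Generator) -> str:
    """Substitute a ``divergence`` fraction of residues (distinct sites)."""
    n_sub = int(round(divergence * len(residues)))
    if n_sub == 0:
        return residues
    sites = rng.choice(len(residues), size=min(n_sub, len(residues)),
                       replace=False)
    out = list(residues)
    for i in sites:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def back_translate(protein: str) -> str:
    return "".join(PREFERRED_CODON[a] for a in protein)


# ---------------------------------------------------------------------------
# loss histories
# ---------------------------------------------------------------------------

def simulate_presence_history(tree: Phylogeny, loss_prob: float, seed: int,
                              gene: str = "gene"
                              ) -> tuple[TipStateMatrix, LossMap]:
    """Drop a gene down the tree under a Dollo loss process.

    Present at the root; each edge under a still-present parent loses the
    gene with probability ``loss_prob``; once lost it stays lost.  Returns
    the tip states and the true loss edges.
    """
    rng = substream(seed, f"presence:{gene}")
    present: dict[int, bool] = {}
    losses = []
    root = tree.tree.seed_node
    present[id(root)] = True
    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        if not present[id(parent)]:
            present[id(node)] = False
        elif rng.random() < loss_prob:
            present[id(node)] = False
            losses.append(_edge_key(node))
        else:
            present[id(node)] = True
    state = {}
    taxa = []
    for leaf in tree.tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        state[(leaf.taxon.label, gene)] = (
            "present" if present[id(leaf)] else "absent"
        )
    ancestral = {
        _edge_key(node): "present" if present[id(node)] else "absent"
        for node in tree.tree.preorder_node_iter()
    }
    truth = LossMap(gene=gene, ancestral_state=ancestral,
                    loss_edges=tuple(sorted(losses)))
    return TipStateMatrix(taxa, [gene], state), truth  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

@dataclass
class GenomeTruth:
    divergence: dict[str, float]            # taxon -> ladder step used
    protein: dict[tuple[str, str], str]     # (taxon, gene) -> true protein
    locus: dict[tuple[str, str], tuple[str, int, int]]  # contig, span


def embed_gene(protein: str, rng: np.random.Generator, contig_id: str,
               flank: int = 500, intron: bool = True
               ) -> tuple[SequenceRecord, tuple[int, int]]:
    """Back-translate a protein into a random-background contig.

    With ``intron`` the coding sequence is split into two exons around a
    random non-coding spacer, so a full-length query produces two aligned
    regions — the hallmark of a strong multi-region hit.
    """
    cds = back_translate(protein)
    left = random_dna(flank, rng)
    right = random_dna(flank, rng)
    if intron and len(cds) >= 60:
        cut = 3 * int(rng.integers(len(protein) // 4, 3 * len(protein) // 4))
        spacer_len = int(rng.integers(120, 240))
        if spacer_len % 3 == 0:  # shift the frame so the exons stay two HSPs
            spacer_len += 1
        spacer = random_dna(spacer_len, rng)
        body = cds[:cut] + spacer + cds[cut:]
    else:
        body = cds
    residues = left + body + right
    span = (flank, flank + len(body))
    return SequenceRecord(id=contig_id, alphabet="dna",
                          residues=residues), span


def simulate_genomes(tree: Phylogeny,
                     tip_states: TipStateMatrix,
                     family_proteins: dict[str, SequenceRecord],
                     divergence_ladder: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3),
                     seed: int = 0,
                     intron: bool = True,
                     decoy_paralogs: bool = False
                     ) -> tuple[dict[str, list[SequenceRecord]], GenomeTruth]:
    """Per-taxon contig sets with implanted / deleted / diverged orthologs.

    Each taxon is assigned one divergence step from the ladder; genes the
    tip-state matrix marks present are mutated from the family's ancestral
    protein by that step and embedded in a random-background contig; absent
    genes are simply omitted.  ``decoy_paralogs`` injects one heavily
    diverged (60%) extra copy per taxon as a validation decoy.
    """
    truth = GenomeTruth(divergence={}, protein={}, locus={})
    genomes: dict[str, list[SequenceRecord]] = {}
    for taxon in tip_states.taxa:
        rng = substream(seed, f"genome:{taxon}")
        step = float(divergence_ladder[rng.integers(len(divergence_ladder))])
        truth.divergence[taxon] = step
        contigs: list[SequenceRecord] = []
        for gene in tip_states.genes:
            if tip_states[(taxon, gene)] != "present":
                continue
            prot = mutate_protein(family_proteins[gene].residues, step, rng)
            contig_id = f"{taxon}|{gene}|contig"
            contig, span = embed_gene(prot, rng, contig_id, intron=intron)
            contigs.append(contig)
            truth.protein[(taxon, gene)] = prot
            truth.locus[(taxon, gene)] = (contig_id, *span)
        if decoy_paralogs and tip_states.genes:
            gene = tip_states.genes[int(rng.integers(len(tip_states.genes)))]
            decoy = mutate_protein(family_proteins[gene].residues, 0.6, rng)
            contig, _ = embed_gene(decoy, rng, f"{taxon}|decoy|contig",
                                   intron=intron)
            contigs.append(contig)
        if not contigs:  # keep every taxon searchable
            contigs.append(SequenceRecord(
                id=f"{taxon}|background|contig", alphabet="dna",
                residues=random_dna(1200, rng)))
        genomes[taxon] = contigs
    return genomes, truth


def make_duplication_fixture(gene_protein: str, seed: int,
                             kind: str = "tandem",
                             duplicate_divergence: float = 0.10
                             ) -> tuple[list[SequenceRecord],
                                        tuple[str, int, int]]:
    """Genome for the duplication screen with a known implant.

    ``tandem``: a second, diverged (default 10%) full-length copy on its own
    contig — a legitimate duplication.  ``artifact``: only an exact 300 nt
    fragment of the gene copied elsewhere, which the >200 nt / >98% identity
    rule must reject.  ``none``: just the self locus.  Returns the contigs
    and the gene's own (contig, start, end) locus.
    """
    rng = substream(seed, f"dup:{kind}")
    self_contig, span = embed_gene(gene_protein, rng, "self|contig",
                                   intron=False)
    contigs = [self_contig]
    if kind == "tandem":
        dup = mutate_protein(gene_protein, duplicate_divergence, rng)
        contigs.append(embed_gene(dup, rng, "dup|contig", intron=False)[0])
    elif kind == "artifact":
        cds = back_translate(gene_protein)
        frag = cds[:300]
        filler = random_dna(400, rng)
        contigs.append(SequenceRecord(
            id="artifact|contig", alphabet="dna",
            residues=filler + frag + random_dna(400, rng)))
    elif kind != "none":
        raise ValueError("kind must be tandem, artifact or none")
    return contigs, (self_contig.id, *span)


def make_tier_escalation_fixture(seed: int, length: int = 150):
    """A target genome whose ortholog only a close-relative bait can see.

    The implanted gene sits a short step (6%) from its closest relative but
    the tier-1/2 baits are ancient homologs diverged far beyond the
    detectable band (90% / 85% substituted), so only the tier-3 bait scores
    a strong hit.  Returns (genome, tiers-as-proteins, reference set).
    """
    rng = substream(seed, "escalation")
    ancestor = random_protein(length, rng)
    close = mutate_protein(ancestor, 0.06, rng)
    target = mutate_protein(close, 0.06, rng)
    tier1 = mutate_protein(ancestor, 0.90, rng)
    tier2 = mutate_protein(ancestor, 0.85, rng)
    genome_contig, span = embed_gene(target, rng, "target|contig")
    baits = {
        1: SequenceRecord("bait_t1", "protein", tier1),
        2: SequenceRecord("bait_t2", "protein", tier2),
        3: SequenceRecord("bait_t3", "protein", close),
    }
    reference = [
        ("expected_gene", SequenceRecord("ref_expected", "protein", close)),
        ("other_gene", SequenceRecord("ref_other", "protein",
                                      random_protein(length, rng))),
    ]
    return [genome_contig], baits, reference


# ---------------------------------------------------------------------------
# MK alignments
# ---------------------------------------------------------------------------

def simulate_mk_alignment(params: MKSimParams, seed: int
                          ) -> tuple[list[SequenceRecord],
                                     list[SequenceRecord], MKCounts]:
    """Codon alignment with known polymorphism/divergence/adaptive counts.

    Each codon site independently takes at most one role: a segregating
    synonymous or nonsynonymous change in the ingroup, a neutral fixed
    synonymous/nonsynonymous difference to the outgroup, or an adaptive
    fixed nonsynonymous difference.  The adaptive per-site rate is
    div_nonsyn * a / (1 - a), making the expected adaptive fraction of all
    fixed nonsynonymous changes equal to ``adaptive_fraction``.  Realized
    (true) counts are returned with the sequences.
    """
    if params.n_ingroup < 2:
        raise ValueError("need at least two ingroup haplotypes")
    a = params.adaptive_fraction
    if not 0.0 <= a < 1.0:
        raise ValueError("adaptive_fraction must lie in [0, 1)")
    rng = substream(seed, "mk")
    rate_adapt = params.div_nonsyn * a / (1.0 - a)
    probs = np.array([params.theta_syn, params.theta_nonsyn,
                      params.div_syn, params.div_nonsyn, rate_adapt])
    if probs.sum() >= 1.0:
        raise ValueError("per-site event rates sum to >= 1")
    probs = np.append(probs, 1.0 - probs.sum())
    roles = rng.choice(6, size=params.n_codons, p=probs)

    base = [
        _VERSATILE_CODONS[i]
        for i in rng.integers(len(_VERSATILE_CODONS), size=params.n_codons)
    ]
    ingroup_cols: list[list[str]] = []
    outgroup_codons: list[str] = []
    counts = {"pS": 0, "pN": 0, "dS": 0, "dN": 0}
    n = params.n_ingroup
    for site, role in enumerate(roles):
        codon = base[site]
        column = [codon] * n
        out_codon = codon
        if role in (0, 1):  # segregating change
            pool = SYN_NEIGHBORS[codon] if role == 0 else NONSYN_NEIGHBORS[codon]
            alt = pool[int(rng.integers(len(pool)))]
            k = int(rng.integers(1, n))  # minor/derived carrier count
            carriers = rng.choice(n, size=k, replace=False)
            for idx in carriers:
                column[idx] = alt
            counts["pS" if role == 0 else "pN"] += 1
        elif role in (2, 3, 4):  # fixed difference
            pool = SYN_NEIGHBORS[codon] if role == 2 else NONSYN_NEIGHBORS[codon]
            out_codon = pool[int(rng.integers(len(pool)))]
            counts["dS" if role == 2 else "dN"] += 1
        ingroup_cols.append(column)
        outgroup_codons.append(out_codon)

    ingroup = [
        SequenceRecord(
            id=f"ingroup_{i:03d}", alphabet="dna",
            residues="".join(col[i] for col in ingroup_cols))
        for i in range(n)
    ]
    outgroup = [
        SequenceRecord(id=f"outgroup_{j:03d}", alphabet="dna",
                       residues="".join(outgroup_codons))
        for j in range(params.n_outgroup)
    ]
    return ingroup, outgroup, MKCounts(**counts)


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def simulate_pairing(p_pair: float, n_nuclei: int,
                     seed: int) -> tuple[int, int]:
    """Bernoulli nucleus scoring: paired ~ Binomial(n_nuclei, p_pair)."""
    if not 0.0 <= p_pair <= 1.0:
        raise ValueError("p_pair must lie in [0, 1]")
    rng = substream(seed, "pairing")
    return int(rng.binomial(n_nuclei, p_pair)), n_nuclei
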