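"""Shared domain types.

Every stage of the toolkit exchanges data through the small set of value
objects defined here: sequences, homology-search hits, rooted phylogenies,
presence/absence matrices, McDonald–Kreitman count tables and nucleus-pairing
observations.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Optional

import dendropy

DNA_ALPHABET = set("ACGTUNRYSWKMBDHV-")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZXU O*-")


class FormatError(ValueError):
    """Raised when an input file or record violates its declared format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA or protein sequence (residues stored upper-case)."""

    id: str
    alphabet: Literal["dna", "protein"]
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r}: residues {sorted(bad)} not in IUPAC "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignedRegion:
    """One maximal local-alignment segment (HSP) between query and subject.

    Spans are 0-based half-open on the *original* sequences; for minus-strand
    nucleotide hits ``subject_span`` is given on the forward strand and
    ``strand`` is ``"-"``.  ``length_nt`` is the subject span length in
    nucleotides (equal to the span length for protein subjects).
    """

    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    identity_fraction: float
    length_nt: int
    strand: Literal["+", "-"] = "+"
    score: float = 0.0
    evalue: float = math.inf

    def __post_init__(self) -> None:
        qs, qe = self.query_span
        ss, se = self.subject_span
        if qe <= qs or se <= ss:
            raise ValueError("aligned spans must have positive length")
        if not 0.0 <= self.identity_fraction <= 1.0:
            raise ValueError("identity_fraction must lie in [0, 1]")
        if self.length_nt <= 0:
            raise ValueError("length_nt must be positive")


@dataclass(frozen=True)
class SearchHit:
    """All aligned regions of one query against one subject sequence.

    ``evalue`` is the E-value of the best region; ``regions`` are sorted by
    subject start so output is deterministic.
    """

    query_id: str
    subject_id: str
    evalue: float
    regions: tuple[AlignedRegion, ...]

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")
        if not self.regions:
            raise ValueError("a SearchHit must contain at least one region")
        object.__setattr__(
            self,
            "regions",
            tuple(sorted(self.regions, key=lambda r: r.subject_span)),
        )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def to_dict(self) -> dict:
        return asdict(self)


class Phylogeny:
    """A rooted tree with uniquely labeled leaves (thin dendropy wrapper)."""

    def __init__(self, tree: dendropy.Tree):
        root = tree.seed_node
        if len(root.child_nodes()) > 2:
            raise FormatError(
                "tree root has more than two children; the tree is unrooted "
                "or has a basal polytomy — supply a rooted tree"
            )
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if any(lbl is None for lbl in labels):
            raise FormatError("every leaf must carry a taxon label")
        if len(labels) != len(set(labels)):
            raise FormatError("leaf labels must be unique")
        tree.is_rooted = True
        self.tree = tree

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", rooting="force-rooted"
            )
        except Exception as exc:  # dendropy raises its own taxon errors
            raise FormatError(f"invalid Newick (leaf labels must be unique "
                              f"and the tree well-formed): {exc}") from exc
        return cls(tree)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def to_newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick", suppress_rooting=True, suppress_edge_lengths=True
            ).strip()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Phylogeny):
            return NotImplemented
        # topology comparison via symmetric difference on a shared taxon set
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=self.to_newick(), schema="newick",
                               taxon_namespace=tns, rooting="force-rooted")
        t2 = dendropy.Tree.get(data=other.to_newick(), schema="newick",
                               taxon_namespace=tns, rooting="force-rooted")
        return (
            dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0
        )


State = Literal["present", "absent", "unknown"]


class TipStateMatrix:
    """Binary (plus unknown) gene states per taxon, backed by a dict grid."""

    def __init__(self, taxa: list[str], genes: list[str],
                 state: dict[tuple[str, str], State]):
        if len(set(taxa)) != len(taxa):
            raise FormatError("duplicate taxa in state matrix")
        if len(set(genes)) != len(genes):
            raise FormatError("duplicate genes in state matrix")
        for t in taxa:
            for g in genes:
                if (t, g) not in state:
                    raise FormatError(f"missing state for ({t}, {g})")
                if state[(t, g)] not in ("present", "absent", "unknown"):
                    raise FormatError(f"bad state {state[(t, g)]!r}")
        self.taxa = list(taxa)
        self.genes = list(genes)
        self.state = dict(state)

    def __getitem__(self, key: tuple[str, str]) -> State:
        return self.state[key]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TipStateMatrix):
            return NotImplemented
        return (self.taxa == other.taxa and self.genes == other.genes
                and self.state == other.state)


@dataclass(frozen=True)
class MKCounts:
    """The 2x2 McDonald–Kreitman table: polymorphic/fixed x syn/nonsyn."""

    pS: int
    pN: int
    dS: int
    dN: int

    def __post_init__(self) -> None:
        if min(self.pS, self.pN, self.dS, self.dN) < 0:
            raise ValueError("MK counts must be non-negative")

    def as_table(self) -> list[list[int]]:
        """2x2 layout [[dN, dS], [pN, pS]] used by the exact test."""
        return [[self.dN, self.dS], [self.pN, self.pS]]


@dataclass(frozen=True)
class MKResult:
    gene: str
    counts: MKCounts
    alpha: Optional[float]  # None when dN*pS == 0 (estimator undefined)
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class PairingObservation:
    """Paired-nucleus count with its Wilson 95% (by default) interval."""

    species: str
    probe: str
    paired: int
    total: int
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.total < 1 or not 0 <= self.paired <= self.total:
            raise ValueError("need 0 <= paired <= total, total >= 1")
        phat = self.paired / self.total
        if not (self.ci_low - 1e-12 <= phat <= self.ci_high + 1e-12):
            raise ValueError("interval must contain the point estimate")

    @property
    def proportion(self) -> float:
        return self.paired / self.total


def unique_ids(records: Iterable[SequenceRecord]) -> None:
    """Raise FormatError if two records share an id."""
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
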