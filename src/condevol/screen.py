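"""Tiered presence/absence calling of condensin subunits.

The protocol escalates through up to three bait tiers: (1) distant canonical
baits (fly/human), (2) an annotated within-order relative, (3) the closest
relative retaining the subunit.  A subunit is called present as soon as a
tier yields a strong hit (E <= 1e-10 with multiple aligned regions) or a
weaker hit (E <= 0.05, or a single region at any E) that survives reciprocal
validation against an annotated reference; it is called absent only when
every supplied tier fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

from .engine import (
    SearchEngine,
    extract_hit_protein,
    extract_hit_segment,
    sort_hits,
)
from .model import SearchHit, SequenceRecord

STRONG_EVALUE = 1e-10
WEAK_EVALUE = 0.05

HitClass = Literal["strong", "weak", "none"]


@dataclass(frozen=True)
class BaitTier:
    tier: int
    baits: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if self.tier not in (1, 2, 3):
            raise ValueError("tier must be 1, 2 or 3")
        if self.tier == 1 and not self.baits:
            raise ValueError("tier 1 must carry at least one bait")


@dataclass(frozen=True)
class ReciprocalCheck:
    reference_taxon: str
    best_match_gene: str  # "none" when nothing aligns at E <= 0.05
    confirmed: bool


@dataclass(frozen=True)
class PresenceCall:
    taxon: str
    gene: str
    verdict: Literal["present", "absent"]
    evidence_tier: Literal[1, 2, 3, None]
    hit_class: Literal["strong", "weak_validated", "none"]
    validation: Optional[ReciprocalCheck] = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.verdict == "present" and self.hit_class == "none":
            raise ValueError("a present call needs a supporting hit")
        if self.verdict == "absent" and self.evidence_tier is not None:
            raise ValueError("an absent call carries no evidence tier")

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "gene": self.gene,
            "verdict": self.verdict,
            "evidence_tier": self.evidence_tier,
            "hit_class": self.hit_class,
            "validation": None if self.validation is None
            else vars(self.validation),
            "warnings": list(self.warnings),
        }


def classify_hit(hits: Sequence[SearchHit]) -> HitClass:
    """Grade a hit list: strong / weak (needs validation) / none.

    Strong requires E <= 1e-10 *and* multiple (>= 2) aligned regions on the
    same subject; a single-region hit forces validation no matter how good
    its E-value.  Anything above E = 0.05 is no hit at all.  Classification
    looks at every hit, so adding a better hit can only upgrade the class.
    """
    if not hits:
        return "none"
    best = min(h.evalue for h in hits)
    if any(h.evalue <= STRONG_EVALUE and h.n_regions >= 2 for h in hits):
        return "strong"
    if best <= WEAK_EVALUE:
        return "weak"
    return "none"


ReferenceSet = Sequence[tuple[str, SequenceRecord]]


def reciprocal_validate(candidate: SequenceRecord,
                        annotated_reference: ReferenceSet,
                        expected_gene: str,
                        engine: SearchEngine,
                        reference_taxon: str = "reference") -> ReciprocalCheck:
    """Search the candidate against an annotated gene set of a relative.

    A nucleotide candidate (the putative genomic locus) is compared against
    protein references by translated search of all six frames — so a locus
    is credited to whatever it really encodes, on either strand.  Confirmed
    iff the top-scoring reference gene (lowest E-value, ties by highest
    total aligned score) is the expected subunit; no reference hit at
    E <= 0.05 leaves the check unconfirmed with best match "none".
    """
    scored: list[tuple[float, float, str]] = []
    for gene_id, record in annotated_reference:
        if candidate.alphabet == "dna" and record.alphabet == "protein":
            hits = engine.search(record, [candidate])
        else:
            hits = engine.search(candidate, [record])
        for hit in hits:
            if hit.evalue <= WEAK_EVALUE:
                total_score = sum(r.score for r in hit.regions)
                scored.append((hit.evalue, -total_score, gene_id))
    if not scored:
        return ReciprocalCheck(reference_taxon, "none", False)
    scored.sort()
    best_gene = scored[0][2]
    return ReciprocalCheck(reference_taxon, best_gene,
                           confirmed=best_gene == expected_gene)


def tiered_search(genome: Sequence[SequenceRecord],
                  tiers: Sequence[BaitTier],
                  reference_sets: Mapping[str, ReferenceSet],
                  engine: SearchEngine,
                  taxon: str,
                  gene: str) -> PresenceCall:
    """Run the bait-escalation protocol for one (taxon, subunit) pair.

    Tiers are consulted in ascending order and the cascade stops at the
    first strong hit or validated weak hit.  A weak hit that fails
    reciprocal validation does not stop the cascade; later tiers are still
    tried.  All tiers failing yields an absent call.
    """
    if not genome:
        return PresenceCall(taxon, gene, "absent", None, "none",
                            warnings=("empty genome",))
    for bait_tier in sorted(tiers, key=lambda t: t.tier):
        for bait in bait_tier.baits:
            hits = sort_hits(engine.search(bait, genome))
            grade = classify_hit(hits)
            if grade == "strong":
                return PresenceCall(taxon, gene, "present", bait_tier.tier,
                                    "strong")  # type: ignore[arg-type]
            if grade == "weak":
                check = _validate_best_weak_hit(
                    hits, genome, reference_sets, engine, gene)
                if check is not None and check.confirmed:
                    return PresenceCall(
                        taxon, gene, "present", bait_tier.tier,
                        "weak_validated",  # type: ignore[arg-type]
                        validation=check)
    return PresenceCall(taxon, gene, "absent", None, "none")


def _validate_best_weak_hit(hits: Sequence[SearchHit],
                            genome: Sequence[SequenceRecord],
                            reference_sets: Mapping[str, ReferenceSet],
                            engine: SearchEngine,
                            expected_gene: str) -> Optional[ReciprocalCheck]:
    if not reference_sets:
        return None
    subjects = {rec.id: rec for rec in genome}
    callable_hits = [h for h in hits if h.evalue <= WEAK_EVALUE]
    if not callable_hits:
        return None
    best_hit = callable_hits[0]
    subject = subjects[best_hit.subject_id]
    if subject.alphabet == "dna":
        # validate the genomic locus itself (with context), not just the
        # translated aligned columns
        candidate = extract_hit_segment(best_hit, subject, flank_nt=300)
    else:
        candidate = extract_hit_protein(best_hit, subject)
    # first reference set in insertion order is the designated relative
    ref_taxon = next(iter(reference_sets))
    return reciprocal_validate(candidate, reference_sets[ref_taxon],
                               expected_gene, engine,
                               reference_taxon=ref_taxon)


def screen_matrix(genomes: Mapping[str, Sequence[SequenceRecord]],
                  bait_plan: Mapping[str, Sequence[BaitTier]],
                  reference_sets: Mapping[str, ReferenceSet],
                  engine: SearchEngine) -> list[PresenceCall]:
    """Screen every (taxon, gene) combination; genes from the bait plan."""
    calls = []
    for taxon in genomes:
        for gene, tiers in bait_plan.items():
            calls.append(tiered_search(genomes[taxon], tiers, reference_sets,
                                       engine, taxon, gene))
    return calls
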