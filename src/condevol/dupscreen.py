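"""Condensin I duplication screen.

A putative subunit coding sequence is searched (nucleotide space, blastn
semantics) against its own genome; candidate duplicate loci are the hits
below E = 0.001 other than the query's own locus.  Hits carrying a long
(> 200 nt) near-perfect (> 98% identity) region are discarded as likely
assembly/sequencing artifacts, and the survivors must either already be
annotated as a condensin I paralog or win reciprocal validation against a
close relative's annotated gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .engine import (
    SearchEngine,
    extract_hit_protein,
    extract_hit_segment,
    sort_hits,
)
from .model import SearchHit, SequenceRecord
from .screen import ReferenceSet, reciprocal_validate

DUP_EVALUE = 0.001
ARTIFACT_MIN_NT = 200
ARTIFACT_MIN_IDENTITY = 0.98


@dataclass(frozen=True)
class SelfLocus:
    """The query gene's own annotated location in its genome."""

    contig: str
    span: tuple[int, int]  # 0-based half-open


@dataclass(frozen=True)
class DuplicationCall:
    gene: str
    taxon: str
    candidate_hits: tuple[SearchHit, ...]
    retained: tuple[SearchHit, ...]
    duplicated: bool
    cross_complex: tuple[str, ...] = ()  # e.g. Cap-D3 hit by a Cap-D2 bait

    def __post_init__(self) -> None:
        if self.duplicated != bool(self.retained):
            raise ValueError("duplicated must mirror a non-empty retained set")


def _overlaps_self(hit: SearchHit, self_locus: Optional[SelfLocus]) -> bool:
    if self_locus is None or hit.subject_id != self_locus.contig:
        return False
    lo, hi = self_locus.span
    return any(r.subject_span[0] < hi and lo < r.subject_span[1]
               for r in hit.regions)


def threshold_hits(hits: Sequence[SearchHit],
                   self_locus: Optional[SelfLocus] = None) -> list[SearchHit]:
    """Keep hits with E < 0.001, dropping the query's own locus."""
    return [h for h in sort_hits(hits)
            if h.evalue < DUP_EVALUE and not _overlaps_self(h, self_locus)]


def filter_artifact_hits(hits: Sequence[SearchHit]) -> list[SearchHit]:
    """Drop hits with any region > 200 nt at > 98% identity.

    Both inequalities are strict: a 200 nt region at exactly 0.98 identity
    is retained as a legitimate duplicate candidate.
    """
    return [
        h for h in hits
        if not any(r.length_nt > ARTIFACT_MIN_NT
                   and r.identity_fraction > ARTIFACT_MIN_IDENTITY
                   for r in h.regions)
    ]


def validate_duplication(hit_sequence: SequenceRecord,
                         close_relative_reference: ReferenceSet,
                         expected_gene: str,
                         annotated_as_paralog: bool,
                         engine: SearchEngine) -> bool:
    """A candidate stands if annotated as a paralog or reciprocally confirmed."""
    if annotated_as_paralog:
        return True
    check = reciprocal_validate(hit_sequence, close_relative_reference,
                                expected_gene, engine)
    return check.confirmed


def duplication_screen(gene: SequenceRecord,
                       taxon: str,
                       genome: Sequence[SequenceRecord],
                       close_relative_reference: ReferenceSet,
                       engine: SearchEngine,
                       self_locus: Optional[SelfLocus] = None,
                       annotated_paralogs: Sequence[str] = ()) -> DuplicationCall:
    """Full screen for one subunit: search, threshold, de-artifact, validate.

    The stage order threshold -> artifact filter -> reciprocal validation is
    fixed.  ``gene`` is normally the subunit coding sequence (DNA) paired
    with a nucleotide engine and a reference of relative coding sequences;
    a protein query with a translated engine works the same way.
    ``annotated_paralogs`` lists subject contig ids already known to carry
    an annotated condensin I paralog (those skip validation).
    """
    raw_hits = []
    for contig in genome:
        raw_hits.extend(engine.search(gene, [contig]))
    candidates = threshold_hits(raw_hits, self_locus)
    survivors = filter_artifact_hits(candidates)
    subjects = {rec.id: rec for rec in genome}
    extract = (extract_hit_segment if gene.alphabet == "dna"
               else extract_hit_protein)
    retained: list[SearchHit] = []
    cross: list[str] = []
    for hit in survivors:
        annotated = hit.subject_id in annotated_paralogs
        if annotated:
            retained.append(hit)
            continue
        candidate_seq = extract(hit, subjects[hit.subject_id])
        check = reciprocal_validate(candidate_seq, close_relative_reference,
                                    gene.id, engine)
        if check.confirmed:
            retained.append(hit)
        elif check.best_match_gene != "none":
            cross.append(check.best_match_gene)
    return DuplicationCall(
        gene=gene.id,
        taxon=taxon,
        candidate_hits=tuple(candidates),
        retained=tuple(retained),
        duplicated=bool(retained),
        cross_complex=tuple(cross),
    )
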