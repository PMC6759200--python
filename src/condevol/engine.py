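"""Desk-scale translated local-alignment search.

Reproduces the *semantics* of a translated protein-vs-genome search (tblastn
style): a protein query is aligned locally against all six reading frames of
a nucleotide subject, each maximal non-overlapping local alignment above a
score floor becomes one aligned region (HSP), and region scores are converted
to E-values with Karlin–Altschul statistics

    E = K * m * n * exp(-lambda * S)

with m the query length, n the total translated subject length, and the
standard gapped BLOSUM62 (gap 11/1) constants lambda = 0.267, K = 0.041.
The gapped constants keep the E-value scale calibrated: with them, random
200-residue queries against random 600 nt subjects stay above E = 0.05 in
>= 95% of trials, which the ungapped constants (0.318 / 0.13) applied to
gapped scores do not achieve.  Downstream logic consumes only thresholded
E-values, so bit-compatibility with any particular search tool is not a goal.

Smith–Waterman itself is Bio.Align.PairwiseAligner (C implementation) with
BLOSUM62, gap open 11 / extend 1.  Multiple HSPs are recovered by masking
each found region with ``*`` (uniformly negative in BLOSUM62) and
re-aligning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .model import AlignedRegion, FormatError, SearchHit, SequenceRecord

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_BLOSUM_ALPHABET = set(str(_BLOSUM62.alphabet))

KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041


def _sanitize_protein(residues: str) -> str:
    """Map residues outside the BLOSUM62 alphabet (U, O, gaps) to X."""
    return "".join(c if c in _BLOSUM_ALPHABET else "X" for c in residues)


def six_frame_translations(dna: str) -> list[tuple[str, int, str]]:
    """Translate all six frames; returns (strand, frame_offset, protein).

    Ambiguity codes translate to X; stop codons stay as ``*`` so a single
    local alignment never crosses a stop at a profit.
    """
    frames: list[tuple[str, int, str]] = []
    fwd = dna.replace("U", "T")
    rev = str(Seq(fwd).reverse_complement())
    for strand, seq in (("+", fwd), ("-", rev)):
        for offset in range(3):
            sub = seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            prot = str(Seq(sub).translate())
            frames.append((strand, offset, _sanitize_protein(prot)))
    return frames


def evalue_from_score(score: float, m: int, n: int,
                      lam: float = KARLIN_LAMBDA, k: float = KARLIN_K) -> float:
    return k * m * n * math.exp(-lam * score)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


MAX_REGION_GAP = 25  # residues; longer gaps split an alignment into regions


def _alignment_segments(alignment, query: str, subject: str,
                        open_gap: float = 11.0, extend_gap: float = 1.0,
                        matrix=_BLOSUM62, wildcards: str = "X*"):
    """Decompose one local alignment into (qspan, sspan, identity, score).

    Aligned blocks separated by a gap longer than MAX_REGION_GAP residues
    (in either sequence) are reported as separate regions: a bridged jump
    over unrelated sequence should not dilute the identity of an otherwise
    near-perfect segment.  Scores are recomputed per segment from the
    substitution matrix minus affine penalties for the short internal gaps.
    """
    qblocks, sblocks = alignment.aligned
    groups: list[list[int]] = [[0]]
    for i in range(1, len(qblocks)):
        qgap = int(qblocks[i][0]) - int(qblocks[i - 1][1])
        sgap = int(sblocks[i][0]) - int(sblocks[i - 1][1])
        if max(qgap, sgap) > MAX_REGION_GAP:
            groups.append([i])
        else:
            groups[-1].append(i)
    segments = []
    for group in groups:
        matches = columns = 0
        score = 0.0
        for j, i in enumerate(group):
            qb0, qb1 = int(qblocks[i][0]), int(qblocks[i][1])
            sb0, sb1 = int(sblocks[i][0]), int(sblocks[i][1])
            for qi, si in zip(range(qb0, qb1), range(sb0, sb1)):
                a, b = query[qi], subject[si]
                score += matrix[a, b]
                if a in wildcards or b in wildcards:
                    continue
                columns += 1
                if a == b:
                    matches += 1
            if j:  # affine penalty for the short internal gap
                prev = group[j - 1]
                gap = max(int(qblocks[i][0]) - int(qblocks[prev][1]),
                          int(sblocks[i][0]) - int(sblocks[prev][1]))
                if gap > 0:
                    score -= open_gap + extend_gap * (gap - 1)
        qspan = (int(qblocks[group[0]][0]), int(qblocks[group[-1]][1]))
        sspan = (int(sblocks[group[0]][0]), int(sblocks[group[-1]][1]))
        identity = matches / columns if columns else 0.0
        segments.append((qspan, sspan, identity, score))
    return segments


@dataclass
class TranslatedSearchEngine:
    """Built-in search engine; also aligns protein subjects directly.

    evalue_keep bounds which regions are reported at all (the default keeps
    only individually callable regions, E <= 0.05, so region counts are not
    inflated by chance segments); max_hsps bounds the mask-and-realign
    iteration per frame.
    """

    evalue_keep: float = 0.05
    max_hsps: int = 4
    lam: float = KARLIN_LAMBDA
    k: float = KARLIN_K
    _aligner: PairwiseAligner = field(default_factory=_make_aligner, repr=False)

    # -- single subject ----------------------------------------------------
    def search_pair(self, query: SequenceRecord,
                    subject: SequenceRecord) -> SearchHit | None:
        if query.alphabet != "protein":
            raise FormatError("query must be a protein sequence")
        qres = _sanitize_protein(query.residues)
        if subject.alphabet == "protein":
            frames = [("+", 0, _sanitize_protein(subject.residues))]
            n_total = len(subject.residues)
            nt_scale = 1
        else:
            if len(subject.residues) < 3:
                return None
            frames = six_frame_translations(subject.residues)
            n_total = sum(len(p) for _, _, p in frames)
            nt_scale = 3
        if n_total == 0:
            return None
        m = len(qres)
        min_score = self._min_score(m, n_total)
        subj_len = len(subject.residues)
        regions: list[AlignedRegion] = []
        for strand, offset, prot in frames:
            regions.extend(
                self._frame_hsps(qres, prot, strand, offset, subj_len,
                                 m, n_total, min_score, nt_scale)
            )
        if not regions:
            return None
        best = min(r.evalue for r in regions)
        return SearchHit(query_id=query.id, subject_id=subject.id,
                         evalue=best, regions=tuple(regions))

    def _min_score(self, m: int, n_total: int) -> float:
        # keep regions down to E = evalue_keep, but never below score 20
        s = math.log(self.k * m * n_total / self.evalue_keep) / self.lam
        return max(s, 20.0)

    def _frame_hsps(self, query: str, prot: str, strand: str, offset: int,
                    subj_len: int, m: int, n_total: int,
                    min_score: float, nt_scale: int) -> list[AlignedRegion]:
        work = list(prot)
        out: list[AlignedRegion] = []
        for _pass in range(self.max_hsps):
            if len(out) >= self.max_hsps:
                break
            target = "".join(work)
            alignments = self._aligner.align(query, target)
            if alignments.score < min_score:
                break
            best = alignments[0]
            segments = _alignment_segments(
                best, query, target,
                open_gap=-self._aligner.open_gap_score,
                extend_gap=-self._aligner.extend_gap_score)
            masked_any = False
            for qspan, pspan, identity, score in segments:
                ev = evalue_from_score(score, m, n_total, self.lam, self.k)
                if ev > self.evalue_keep:
                    continue
                out.append(self._to_region(qspan, pspan, identity, score,
                                           ev, strand, offset, subj_len,
                                           nt_scale))
            # mask the full alignment footprint so the next pass finds a
            # genuinely different locus
            for _, pspan, _, _ in segments:
                for i in range(pspan[0], pspan[1]):
                    work[i] = "*"
                    masked_any = True
            if not masked_any or len(out) >= self.max_hsps:
                break
        return out[: self.max_hsps]

    @staticmethod
    def _to_region(qspan, pspan, identity, score, ev, strand, offset,
                   subj_len, nt_scale) -> AlignedRegion:
        a, b = pspan
        if nt_scale == 1:  # protein subject: spans in residues
            sspan = (a, b)
            length_nt = 3 * (b - a)
        else:
            if strand == "+":
                sspan = (offset + 3 * a, offset + 3 * b)
            else:
                sspan = (subj_len - (offset + 3 * b),
                         subj_len - (offset + 3 * a))
            length_nt = sspan[1] - sspan[0]
        return AlignedRegion(
            query_span=qspan,
            subject_span=sspan,
            identity_fraction=identity,
            length_nt=length_nt,
            strand=strand,  # type: ignore[arg-type]
            score=score,
            evalue=ev,
        )

    # -- many subjects -----------------------------------------------------
    def search(self, query: SequenceRecord,
               subjects: Sequence[SequenceRecord]) -> list[SearchHit]:
        hits = []
        for subject in subjects:
            hit = self.search_pair(query, subject)
            if hit is not None:
                hits.append(hit)
        return sort_hits(hits)


def _make_dna_matrix():
    """ACGTX scoring: +2 match / -3 mismatch; X never aligns profitably."""
    import numpy as np
    from Bio.Align import substitution_matrices as _sm
    alphabet = "ACGTX"
    data = np.full((5, 5), -3.0)
    for i in range(4):
        data[i, i] = 2.0
    data[4, :] = data[:, 4] = -9.0
    return _sm.Array(alphabet=alphabet, dims=2, data=data)


@dataclass
class NucleotideSearchEngine:
    """Local nucleotide-vs-nucleotide search (blastn-style semantics).

    Both strands of the subject are scanned; E-values use the gapped
    Karlin–Altschul constants for +2/-3 with gap 5/2.  Used by the
    duplication screen, where the query is the subunit's coding sequence
    and the artifact rule (> 200 nt at > 98% identity) operates directly in
    nucleotide space.
    """

    evalue_keep: float = 0.05
    max_hsps: int = 4
    lam: float = 0.625
    k: float = 0.41

    def __post_init__(self) -> None:
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = _make_dna_matrix()
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
        self._aligner = aligner
        self._matrix = aligner.substitution_matrix

    @staticmethod
    def _sanitize(residues: str) -> str:
        clean = residues.replace("U", "T")
        return "".join(c if c in "ACGT" else "X" for c in clean)

    def search_pair(self, query: SequenceRecord,
                    subject: SequenceRecord) -> SearchHit | None:
        if query.alphabet != "dna" or subject.alphabet != "dna":
            raise FormatError("nucleotide engine needs DNA query and subject")
        q = self._sanitize(query.residues)
        fwd = self._sanitize(subject.residues)
        if len(fwd) < 1 or len(q) < 1:
            return None
        rev = str(Seq(fwd).reverse_complement())
        m, n_total = len(q), 2 * len(fwd)
        min_score = max(
            math.log(self.k * m * n_total / self.evalue_keep) / self.lam,
            16.0)
        regions: list[AlignedRegion] = []
        for strand, target0 in (("+", fwd), ("-", rev)):
            work = list(target0)
            for _pass in range(self.max_hsps):
                target = "".join(work)
                alignments = self._aligner.align(q, target)
                if alignments.score < min_score:
                    break
                segments = _alignment_segments(
                    alignments[0], q, target, open_gap=5.0, extend_gap=2.0,
                    matrix=self._matrix, wildcards="X")
                for qspan, sspan, identity, score in segments:
                    ev = evalue_from_score(score, m, n_total,
                                           self.lam, self.k)
                    if ev > self.evalue_keep:
                        continue
                    if strand == "-":
                        fspan = (len(fwd) - sspan[1], len(fwd) - sspan[0])
                    else:
                        fspan = sspan
                    regions.append(AlignedRegion(
                        query_span=qspan, subject_span=fspan,
                        identity_fraction=identity,
                        length_nt=fspan[1] - fspan[0],
                        strand=strand,  # type: ignore[arg-type]
                        score=score, evalue=ev))
                for _, sspan, _, _ in segments:
                    for i in range(sspan[0], sspan[1]):
                        work[i] = "X"
                if len(regions) >= self.max_hsps:
                    break
        if not regions:
            return None
        return SearchHit(query_id=query.id, subject_id=subject.id,
                         evalue=min(r.evalue for r in regions),
                         regions=tuple(regions[: self.max_hsps]))

    def search(self, query: SequenceRecord,
               subjects: Sequence[SequenceRecord]) -> list[SearchHit]:
        hits = [h for h in (self.search_pair(query, s) for s in subjects)
                if h is not None]
        return sort_hits(hits)


class SearchEngine(Protocol):
    """Anything the screening protocol can drive: built-in or scripted."""

    def search(self, query: SequenceRecord,
               subjects: Sequence[SequenceRecord]) -> list[SearchHit]:
        ...


def sort_hits(hits: Sequence[SearchHit]) -> list[SearchHit]:
    """Deterministic hit order: (evalue, subject_id, first subject start)."""
    return sorted(
        hits,
        key=lambda h: (h.evalue, h.subject_id, h.regions[0].subject_span[0]),
    )


def extract_hit_protein(hit: SearchHit, subject: SequenceRecord,
                        candidate_id: str | None = None,
                        flank_nt: int = 300) -> SequenceRecord:
    """Translate the aligned subject regions of a hit into one protein.

    Used to turn a weak genomic hit into the candidate sequence that is
    BLASTed back against an annotated reference in reciprocal validation.
    Each nucleotide region is expanded by up to ``flank_nt`` on both sides
    (frame-preserving): validating the hit *locus* rather than the bare
    aligned columns lets the reference search see enough context to
    resolve what the locus really encodes.  For protein subjects the
    aligned residues are taken verbatim.
    """
    parts = []
    for region in hit.regions:
        s0, s1 = region.subject_span
        if subject.alphabet == "dna":
            ext_left = min(flank_nt, s0)
            ext_right = min(flank_nt, len(subject.residues) - s1)
            if region.strand == "-":
                ext_right -= ext_right % 3  # keep the rc reading frame
            else:
                ext_left -= ext_left % 3
            segment = subject.residues[s0 - ext_left:s1 + ext_right]
            if region.strand == "-":
                segment = str(Seq(segment).reverse_complement())
            segment = segment[: len(segment) - len(segment) % 3]
            segment = str(Seq(segment).translate()).replace("*", "X")
        else:
            segment = subject.residues[s0:s1]
        parts.append(_sanitize_protein(segment))
    return SequenceRecord(
        id=candidate_id or f"{hit.query_id}|{hit.subject_id}|candidate",
        alphabet="protein",
        residues="".join(parts) or "X",
    )


def extract_hit_segment(hit: SearchHit, subject: SequenceRecord,
                        candidate_id: str | None = None,
                        flank_nt: int = 100) -> SequenceRecord:
    """Cut the aligned nucleotide regions of a hit out of the subject.

    Regions are returned in query orientation (minus-strand regions are
    reverse-complemented) with up to ``flank_nt`` of context per side.
    """
    parts = []
    for region in hit.regions:
        s0, s1 = region.subject_span
        lo = max(0, s0 - flank_nt)
        hi = min(len(subject.residues), s1 + flank_nt)
        segment = subject.residues[lo:hi]
        if region.strand == "-":
            segment = str(Seq(segment).reverse_complement())
        parts.append(segment)
    return SequenceRecord(
        id=candidate_id or f"{hit.query_id}|{hit.subject_id}|candidate",
        alphabet="dna",
        residues="".join(parts) or "N",
    )


def read_tabular_hits(path: str | Path) -> list[SearchHit]:
    """Ingest a 12+-column BLAST-style tabular hit file.

    Columns (1-based coordinates, inclusive ends, as emitted by
    ``-outfmt 6``): qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Rows are grouped into one SearchHit per
    (query, subject) pair; sstart > send marks a minus-strand region.
    """
    grouped: dict[tuple[str, str], list[AlignedRegion]] = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        f = ln.split("\t")
        if len(f) < 12:
            raise FormatError(f"{path}: line {lineno}: expected >= 12 columns")
        qid, sid = f[0], f[1]
        pident, length = float(f[2]), int(f[3])
        qstart, qend = int(f[6]), int(f[7])
        sstart, send = int(f[8]), int(f[9])
        evalue = float(f[10])
        strand = "+" if send >= sstart else "-"
        lo, hi = sorted((sstart, send))
        region = AlignedRegion(
            query_span=(qstart - 1, qend),
            subject_span=(lo - 1, hi),
            identity_fraction=pident / 100.0,
            length_nt=hi - lo + 1,
            strand=strand,  # type: ignore[arg-type]
            evalue=max(evalue, 1e-300),
        )
        grouped.setdefault((qid, sid), []).append(region)
    hits = [
        SearchHit(query_id=q, subject_id=s,
                  evalue=min(r.evalue for r in regions),
                  regions=tuple(regions))
        for (q, s), regions in grouped.items()
    ]
    return sort_hits(hits)


class TabularEngine:
    """Engine fed from a pre-computed tabular hit file (no alignment run)."""

    def __init__(self, path: str | Path):
        self._hits = read_tabular_hits(path)

    def search(self, query: SequenceRecord,
               subjects: Sequence[SequenceRecord]) -> list[SearchHit]:
        wanted = {s.id for s in subjects}
        return [h for h in self._hits
                if h.query_id == query.id and h.subject_id in wanted]
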