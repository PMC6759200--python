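"""Tiered presence/absence protocol: hit grading, validation, escalation."""

import itertools

import pytest

from condevol import (
    AlignedRegion,
    BaitTier,
    SearchHit,
    SequenceRecord,
    classify_hit,
    reciprocal_validate,
    tiered_search,
)
from condevol.simulate import (
    back_translate,
    embed_gene,
    make_tier_escalation_fixture,
    mutate_protein,
    random_dna,
    random_protein,
    substream,
)


def make_hit(evalue, n_regions=1, subject="s1", query="q"):
    regions = tuple(
        AlignedRegion(query_span=(0, 50), subject_span=(i * 200, i * 200 + 150),
                      identity_fraction=0.8, length_nt=150, evalue=evalue)
        for i in range(n_regions)
    )
    return SearchHit(query_id=query, subject_id=subject, evalue=evalue,
                     regions=regions)


class TestClassifyHit:
    @pytest.mark.parametrize(
        "evalue,n_regions,expected",
        [
            (1e-12, 3, "strong"),   # low E, multiple regions
            (1e-3, 1, "weak"),      # validation band
            (0.2, 1, "none"),       # above the 0.05 cutoff
            (1e-12, 1, "weak"),     # single region forces validation
            (0.04, 2, "weak"),      # multiple regions but E too high
        ],
    )
    def test_grading(self, evalue, n_regions, expected):
        assert classify_hit([make_hit(evalue, n_regions)]) == expected

    def test_empty_is_none(self):
        assert classify_hit([]) == "none"

    def test_adding_better_hit_never_downgrades(self):
        """Monotonicity: a lower-E extra hit cannot demote the grade."""
        rank = {"none": 0, "weak": 1, "strong": 2}
        base_sets = [
            [make_hit(1e-12, 2)],
            [make_hit(1e-3, 1)],
            [make_hit(0.2, 1)],
        ]
        extras = [make_hit(1e-13, 1, subject="s2"),
                  make_hit(1e-13, 2, subject="s2")]
        for hits, extra in itertools.product(base_sets, extras):
            assert rank[classify_hit(hits + [extra])] >= rank[classify_hit(hits)]


@pytest.fixture(scope="module")
def subunit_reference():
    """Annotated mini-proteome: three distinct subunit families."""
    rng = substream(21, "ref")
    genes = {}
    for name in ("Cap-H", "Cap-H2", "Cap-G"):
        genes[name] = SequenceRecord(f"ref_{name}", "protein",
                                     random_protein(120, rng))
    return [(name, rec) for name, rec in genes.items()]


class TestReciprocalValidate:
    def test_self_match_confirms(self, engine, subunit_reference):
        cap_h2 = dict(subunit_reference)["Cap-H2"]
        candidate = SequenceRecord("cand", "protein", cap_h2.residues)
        check = reciprocal_validate(candidate, subunit_reference, "Cap-H2",
                                    engine)
        assert check.confirmed and check.best_match_gene == "Cap-H2"

    def test_wrong_paralog_rejected(self, engine, subunit_reference):
        """A candidate copied from Cap-H must not validate as Cap-H2.

        Cross-check: exhaustive pairwise alignment confirms Cap-H really is
        the top reference match for the decoy candidate.
        """
        cap_h = dict(subunit_reference)["Cap-H"]
        candidate = SequenceRecord("cand", "protein", cap_h.residues)
        check = reciprocal_validate(candidate, subunit_reference, "Cap-H2",
                                    engine)
        assert not check.confirmed
        best = min(
            subunit_reference,
            key=lambda item: engine.search_pair(candidate, item[1]).evalue
            if engine.search_pair(candidate, item[1]) else float("inf"),
        )
        assert best[0] == "Cap-H" == check.best_match_gene

    def test_random_candidate_matches_nothing(self, engine,
                                              subunit_reference):
        rng = substream(22, "rand")
        candidate = SequenceRecord("cand", "protein", random_protein(120, rng))
        check = reciprocal_validate(candidate, subunit_reference, "Cap-H2",
                                    engine)
        assert not check.confirmed and check.best_match_gene == "none"


class TestTieredSearch:
    def test_exact_tier1_copy_is_present_strong(self, engine):
        rng = substream(23, "t")
        prot = random_protein(120, rng)
        contig, _ = embed_gene(prot, rng, "c1")
        bait = SequenceRecord("bait", "protein", prot)
        call = tiered_search([contig], [BaitTier(1, (bait,))], {}, engine,
                             "taxX", "Cap-G2")
        assert call.verdict == "present"
        assert call.evidence_tier == 1 and call.hit_class == "strong"

    def test_deleted_ortholog_all_tiers_fail(self, engine):
        rng = substream(24, "t")
        bait = SequenceRecord("bait", "protein", random_protein(120, rng))
        background = SequenceRecord("bg", "dna", random_dna(1500, rng))
        call = tiered_search([background], [BaitTier(1, (bait,))], {}, engine,
                             "taxX", "Cap-G2")
        assert call.verdict == "absent"
        assert call.evidence_tier is None and call.hit_class == "none"

    def test_empty_genome_absent_with_warning(self, engine):
        bait = SequenceRecord("bait", "protein", "MKVLWAAR")
        call = tiered_search([], [BaitTier(1, (bait,))], {}, engine, "t", "g")
        assert call.verdict == "absent" and "empty genome" in call.warnings

    def test_escalation_resolves_at_tier3(self, engine):
        """Heavily diverged tier-1/2 baits miss; the close relative scores
        strong — the call lands at tier 3, confirmed by direct engine calls."""
        genome, baits, reference = make_tier_escalation_fixture(seed=101)
        t1_hits = engine.search(baits[1], genome)
        t3_hits = engine.search(baits[3], genome)
        assert all(h.evalue > 1e-10 for h in t1_hits)
        assert min(h.evalue for h in t3_hits) <= 1e-10
        tiers = [BaitTier(t, (baits[t],)) for t in (1, 2, 3)]
        call = tiered_search(genome, tiers, {"relative": reference}, engine,
                             "taxY", "expected_gene")
        assert call.verdict == "present" and call.evidence_tier == 3


class ScriptedEngine:
    """Stub engine returning canned hits; counts searches per bait id."""

    def __init__(self, hits_by_query):
        self.hits_by_query = hits_by_query
        self.calls = []

    def search(self, query, subjects):
        self.calls.append(query.id)
        return self.hits_by_query.get(query.id, [])


def _bait(tier):
    return SequenceRecord(f"bait{tier}", "protein", "MKVLWAARNDC")


GENOME = [SequenceRecord("contig1", "dna", "ATG" * 200)]


def test_tier_precedence_skips_later_tiers():
    engine = ScriptedEngine({"bait1": [make_hit(1e-20, 2, "contig1")]})
    tiers = [BaitTier(t, (_bait(t),)) for t in (1, 2, 3)]
    call = tiered_search(GENOME, tiers, {}, engine, "t", "g")
    assert call.evidence_tier == 1
    assert engine.calls == ["bait1"]  # tiers 2-3 never consulted


def test_protocol_is_engine_agnostic():
    """Identical SearchHit lists from any engine give identical calls."""
    hits = {"bait1": [make_hit(0.2, 1, "contig1")],
            "bait2": [make_hit(1e-15, 3, "contig1")]}
    tiers = [BaitTier(t, (_bait(t),)) for t in (1, 2)]
    calls = [
        tiered_search(GENOME, tiers, {}, ScriptedEngine(dict(hits)), "t", "g")
        for _ in range(2)
    ]
    assert calls[0] == calls[1]
    assert calls[0].evidence_tier == 2 and calls[0].hit_class == "strong"


def test_failed_weak_validation_does_not_stop_cascade():
    """An unvalidatable weak hit at tier 1 still lets tier 2 decide."""
    engine = ScriptedEngine({"bait1": [make_hit(1e-3, 1, "contig1")],
                             "bait2": [make_hit(1e-20, 2, "contig1")]})
    tiers = [BaitTier(t, (_bait(t),)) for t in (1, 2)]
    call = tiered_search(GENOME, tiers, {}, engine, "t", "g")
    assert call.evidence_tier == 2 and call.hit_class == "strong"
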