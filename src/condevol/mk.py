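"""Codon-aware unpolarized McDonald–Kreitman test.

Segregating (polymorphic) and fixed codon changes between an ingroup
alignment and an outgroup are classified as synonymous or nonsynonymous
under the standard genetic code.  Codons differing at k positions are
resolved by averaging the per-step labels over all k! mutational pathways
that avoid stop codons; the fractional weights are summed per cell and
rounded half-up only in the final table.  From the 2x2 table

        syn   nonsyn
 fixed   dS     dN
 poly    pS     pN

the adaptive-substitution fraction is estimated as

    alpha = 1 - (dS * pN) / (dN * pS)      (one minus the neutrality index)

and departure from neutrality is scored with Fisher's exact test on
[[dN, dS], [pN, pS]] (two-sided by default; this is the convention that
reproduces published MK tables computed this way).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Literal, Optional, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .model import FormatError, MKCounts, MKResult, SequenceRecord

_BASES = "TCAG"
_CODON_TABLE: dict[str, str] = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _CODON_TABLE[_b1 + _b2 + _b3] = ""
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, _codon in enumerate(_CODON_TABLE):
    _CODON_TABLE[_codon] = _AA[_i]
STOP_CODONS = {c for c, aa in _CODON_TABLE.items() if aa == "*"}


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


def is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in "ACGT" for b in codon) \
        and codon not in STOP_CODONS


Effect = Literal["synonymous", "nonsynonymous"]


def classify_codon_pair(codon_a: str, codon_b: str
                        ) -> Optional[list[tuple[Effect, float]]]:
    """Pathway-averaged syn/nonsyn weights for a codon substitution.

    Enumerates all orderings of the differing positions, drops pathways
    passing through a stop codon, and averages the per-step labels over the
    survivors; the returned weights sum to the number of differing
    positions.  Identical codons give [].  Returns None when every pathway
    is blocked by a stop (the caller tallies the site as skipped).
    """
    for c in (codon_a, codon_b):
        if not is_valid_codon(c):
            raise FormatError(f"invalid or stop codon {c!r}")
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return []
    syn_total = 0.0
    nonsyn_total = 0.0
    n_paths = 0
    for order in permutations(diffs):
        cur = codon_a
        steps: list[Effect] = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            steps.append("synonymous"
                         if translate_codon(cur) == translate_codon(nxt)
                         else "nonsynonymous")
            cur = nxt
        if blocked:
            continue
        n_paths += 1
        syn_total += sum(1 for s in steps if s == "synonymous")
        nonsyn_total += sum(1 for s in steps if s == "nonsynonymous")
    if n_paths == 0:
        return None
    out: list[tuple[Effect, float]] = []
    if syn_total:
        out.append(("synonymous", syn_total / n_paths))
    if nonsyn_total:
        out.append(("nonsynonymous", nonsyn_total / n_paths))
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class MKTabulation:
    """Raw (weighted) and rounded MK counts plus the QC skip report."""

    raw_pS: float = 0.0
    raw_pN: float = 0.0
    raw_dS: float = 0.0
    raw_dN: float = 0.0
    skipped_sites: dict[str, int] = field(default_factory=dict)

    def _skip(self, reason: str) -> None:
        self.skipped_sites[reason] = self.skipped_sites.get(reason, 0) + 1

    @property
    def counts(self) -> MKCounts:
        return MKCounts(
            pS=_round_half_up(self.raw_pS), pN=_round_half_up(self.raw_pN),
            dS=_round_half_up(self.raw_dS), dN=_round_half_up(self.raw_dN),
        )


def _major_allele(codons: Sequence[str]) -> Optional[str]:
    """Most frequent codon; ties broken lexicographically.  None on no data."""
    if not codons:
        return None
    freq: dict[str, int] = {}
    for c in codons:
        freq[c] = freq.get(c, 0) + 1
    best = max(freq.values())
    return sorted(c for c, n in freq.items() if n == best)[0]


def _strict_major(codons: Sequence[str]) -> Optional[str]:
    """Unique most frequent codon, or None when the top count ties."""
    freq: dict[str, int] = {}
    for c in codons:
        freq[c] = freq.get(c, 0) + 1
    best = max(freq.values())
    tops = [c for c, n in freq.items() if n == best]
    return tops[0] if len(tops) == 1 else None


def tabulate_mk(ingroup: Sequence[SequenceRecord],
                outgroup: Sequence[SequenceRecord]) -> MKTabulation:
    """Walk a codon alignment and fill the 2x2 MK table.

    Per codon column: segregating ingroup changes (each non-major allele vs
    the major allele) feed pN/pS; a monomorphic ingroup differing from the
    outgroup consensus feeds dN/dS; a column both polymorphic and divergent
    contributes its polymorphic changes plus the fixed component only when
    no ingroup allele matches the outgroup allele.  Columns containing a
    gap, an ambiguous base or a stop codon in any sequence are skipped and
    tallied, as are columns where the outgroup has no majority allele.
    """
    if len(ingroup) < 2:
        raise FormatError("need at least two ingroup haplotypes")
    lengths = {len(r.residues) for r in [*ingroup, *outgroup]}
    if len(lengths) != 1:
        raise FormatError("all sequences must be aligned to the same length")
    (length,) = lengths
    if length % 3:
        raise FormatError("alignment length must be divisible by 3")

    tab = MKTabulation()
    for site in range(0, length, 3):
        in_codons = [r.residues[site:site + 3] for r in ingroup]
        out_codons = [r.residues[site:site + 3] for r in outgroup]
        if any(not is_valid_codon(c) for c in [*in_codons, *out_codons]):
            tab._skip("gap_ambiguous_or_stop")
            continue
        out_allele = _strict_major(out_codons)
        if out_allele is None:
            tab._skip("outgroup_no_major_allele")
            continue
        alleles = set(in_codons)
        major = _major_allele(in_codons)
        assert major is not None
        # polymorphic component
        for allele in sorted(alleles - {major}):
            changes = classify_codon_pair(major, allele)
            if changes is None:
                tab._skip("all_pathways_through_stop")
                continue
            for effect, weight in changes:
                if effect == "synonymous":
                    tab.raw_pS += weight
                else:
                    tab.raw_pN += weight
        # fixed component: outgroup allele absent from the ingroup pool
        if out_allele not in alleles:
            changes = classify_codon_pair(major, out_allele)
            if changes is None:
                tab._skip("all_pathways_through_stop")
                continue
            for effect, weight in changes:
                if effect == "synonymous":
                    tab.raw_dS += weight
                else:
                    tab.raw_dN += weight
    return tab


def alpha_from_counts(c: MKCounts) -> Optional[float]:
    """alpha = 1 - (dS*pN)/(dN*pS); None (undefined) when dN*pS == 0."""
    if c.dN == 0 or c.pS == 0:
        return None
    return 1.0 - (c.dS * c.pN) / (c.dN * c.pS)


Tail = Literal["two-sided", "greater", "less"]


def mk_fisher(c: MKCounts, tail: Tail = "two-sided") -> float:
    """Exact hypergeometric p-value of [[dN, dS], [pN, pS]].

    The default two-sided test is the convention under which published MK
    tables of this layout reproduce; 'greater' tests specifically for an
    excess of nonsynonymous divergence.  An all-zero table gives p = 1.
    """
    if c.pS + c.pN + c.dS + c.dN == 0:
        return 1.0
    _, p = fisher_exact(c.as_table(), alternative=tail)
    return float(min(p, 1.0))


def mk_result(gene: str, counts: MKCounts,
              tail: Tail = "two-sided") -> MKResult:
    return MKResult(gene=gene, counts=counts,
                    alpha=alpha_from_counts(counts),
                    p_value=mk_fisher(counts, tail))


def mk_from_counts_table(df: pd.DataFrame,
                         tail: Tail = "two-sided") -> list[MKResult]:
    """Batch MK results from a gene,pS,pN,dS,dN table."""
    if (df[["pS", "pN", "dS", "dN"]] < 0).any().any():
        raise FormatError("negative counts are not allowed")
    return [
        mk_result(row.gene,
                  MKCounts(pS=int(row.pS), pN=int(row.pN),
                           dS=int(row.dS), dN=int(row.dN)),
                  tail)
        for row in df.itertuples(index=False)
    ]


def mk_table_frame(results: Sequence[MKResult]) -> pd.DataFrame:
    """Serialize results in the published table layout."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "pS": [r.counts.pS for r in results],
            "pN": [r.counts.pN for r in results],
            "dS": [r.counts.dS for r in results],
            "dN": [r.counts.dN for r in results],
            "alpha": [None if r.alpha is None else round(r.alpha, 4)
                      for r in results],
            "p_value": [r.p_value for r in results],
        }
    )
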