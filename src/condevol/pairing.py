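"""Homolog-pairing statistics and probe-window selection.

Pairing is scored per nucleus as a Bernoulli trial (one FISH signal =
paired); per-probe proportions carry Wilson score intervals, which behave
well at the near-zero pairing rates typical outside Diptera.  FISH targets
are chosen as the fixed-length genomic window (300 kb by default) holding
the most candidate oligos.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import norm

from .model import PairingObservation

DEFAULT_WINDOW = 300_000


def wilson_interval(paired: int, total: int,
                    confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    center = (p + z^2/2n) / (1 + z^2/n),
    halfwidth = z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n).
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= paired <= total:
        raise ValueError("need 0 <= paired <= total")
    z = float(norm.ppf(1.0 - (1.0 - confidence) / 2.0))
    p = paired / total
    denom = 1.0 + z * z / total
    center = (p + z * z / (2 * total)) / denom
    half = z * ((p * (1 - p) / total + z * z / (4 * total * total)) ** 0.5) \
        / denom
    # the score-test inversion hits the boundary exactly at 0 and n
    low = 0.0 if paired == 0 else max(0.0, center - half)
    high = 1.0 if paired == total else min(1.0, center + half)
    return low, high


def pairing_table(observations: Sequence[tuple[str, str, int, int]],
                  confidence: float = 0.95
                  ) -> tuple[list[PairingObservation], pd.DataFrame, dict]:
    """Per-probe pairing proportions with Wilson CIs and probe concordance.

    Input rows are (species, probe, paired, total); duplicate
    (species, probe) keys are an error.  The concordance report gives, per
    species with more than one probe, the largest absolute difference
    between probe proportions (similar probes indicate genome-wide rather
    than locus-specific pairing behavior).
    """
    seen: set[tuple[str, str]] = set()
    obs: list[PairingObservation] = []
    for species, probe, paired, total in observations:
        key = (species, probe)
        if key in seen:
            raise ValueError(f"duplicate (species, probe) key {key}")
        seen.add(key)
        low, high = wilson_interval(paired, total, confidence)
        obs.append(PairingObservation(species=species, probe=probe,
                                      paired=paired, total=total,
                                      ci_low=low, ci_high=high))
    frame = pd.DataFrame(
        {
            "species": [o.species for o in obs],
            "probe": [o.probe for o in obs],
            "paired": [o.paired for o in obs],
            "total": [o.total for o in obs],
            "proportion": [o.proportion for o in obs],
            "ci_low": [o.ci_low for o in obs],
            "ci_high": [o.ci_high for o in obs],
        }
    )
    concordance: dict[str, float] = {}
    for species in frame["species"].unique():
        props = frame.loc[frame["species"] == species, "proportion"]
        if len(props) > 1:
            concordance[species] = float(props.max() - props.min())
    return obs, frame, concordance


@dataclass(frozen=True)
class WindowSelection:
    contig: str
    span: tuple[int, int]
    oligo_count: int
    window_size: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.span[1] - self.span[0] != self.window_size:
            raise ValueError("span length must equal window_size")
        if self.oligo_count < 0:
            raise ValueError("oligo_count must be non-negative")


def best_window(oligo_starts: Sequence[int],
                window_size: int = DEFAULT_WINDOW,
                contig: str = "",
                mode: str = "sliding") -> WindowSelection:
    """The window of fixed length holding the most oligo start positions.

    ``sliding`` anchors candidate windows at oligo positions (sufficient
    for optimality of a max-count fixed window); ``tiled`` restricts starts
    to multiples of the window size.  Ties break to the smallest start.
    """
    pos = list(oligo_starts)
    if not pos:
        raise ValueError("no oligo positions supplied")
    if any(p < 0 for p in pos):
        raise ValueError("positions must be non-negative")
    if sorted(pos) != pos:
        raise ValueError("positions must be sorted ascending")
    if mode == "sliding":
        candidates = pos
    elif mode == "tiled":
        candidates = sorted({(p // window_size) * window_size for p in pos})
    else:
        raise ValueError("mode must be 'sliding' or 'tiled'")
    best_start, best_count = candidates[0], -1
    for s in candidates:
        lo = bisect_left(pos, s)
        hi = bisect_left(pos, s + window_size)
        count = hi - lo
        if count > best_count:
            best_start, best_count = s, count
    return WindowSelection(contig=contig, span=(best_start,
                                                best_start + window_size),
                           oligo_count=best_count, window_size=window_size)


def best_windows_per_contig(starts_by_contig: dict[str, list[int]],
                            window_size: int = DEFAULT_WINDOW,
                            mode: str = "sliding") -> list[WindowSelection]:
    return [
        best_window(starts, window_size, contig=contig, mode=mode)
        for contig, starts in sorted(starts_by_contig.items())
    ]
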