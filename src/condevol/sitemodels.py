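"""Likelihood-ratio test for nested codon site models and multiple-testing
thresholds.

The neutral model (M7, beta-distributed omega on [0, 1]) is compared with
the positive-selection model (M8, beta plus a class with omega > 1) through
2 * (lnL_M8 - lnL_M7), referred to a chi-square distribution with two
degrees of freedom (the conventional df for this nested pair).  Whether to
divide the family alpha across subunits is left to the caller: testing
different subunits of one complex arguably probes one hypothesis, so both
the uncorrected and the Bonferroni-corrected readout are first-class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2


@dataclass(frozen=True)
class LRTResult:
    gene: str
    lnL_neutral: float
    lnL_selection: float
    statistic: float
    df: int
    p_value: float
    significant_bonferroni: bool

    def __post_init__(self) -> None:
        if self.statistic < 0 or not 0.0 <= self.p_value <= 1.0:
            raise ValueError("invalid LRT result")


def lrt_m7_m8(gene: str, lnL_neutral: float, lnL_selection: float,
              df: int = 2, bonferroni: float | None = None) -> LRTResult:
    """LRT p-value from the two log-likelihoods.

    The statistic is clipped at zero when the selection model fits worse
    (boundary case), giving p = 1.  ``bonferroni`` is the significance
    threshold used for flagging (None flags nothing).
    """
    if not (math.isfinite(lnL_neutral) and math.isfinite(lnL_selection)):
        raise ValueError("log-likelihoods must be finite")
    stat = max(0.0, 2.0 * (lnL_selection - lnL_neutral))
    p = float(chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(
        gene=gene, lnL_neutral=lnL_neutral, lnL_selection=lnL_selection,
        statistic=stat, df=df, p_value=p,
        significant_bonferroni=bonferroni is not None and p < bonferroni,
    )


def round_sig(x: float, sig_figs: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig_figs - 1)


def bonferroni_threshold(family_alpha: float, n_tests: int,
                         sig_figs: int = 3) -> float:
    """family_alpha / n_tests, reported at 3 significant figures.

    With the default family alpha of 0.05 across 12 subunit tests the
    threshold is 0.00417.
    """
    if not 0.0 < family_alpha < 1.0:
        raise ValueError("family_alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return round_sig(family_alpha / n_tests, sig_figs)


def lrt_table(df_in: pd.DataFrame, df: int = 2, family_alpha: float = 0.05,
              n_tests: int = 12, correct: bool = True) -> pd.DataFrame:
    """Per-gene LRT grid from a gene,lnL_M7,lnL_M8 table.

    ``correct=False`` flags at the raw family alpha instead (no correction),
    matching analyses that treat the complex as a single hypothesis.
    """
    for col in ("gene", "lnL_M7", "lnL_M8"):
        if col not in df_in.columns:
            raise ValueError(f"missing column {col!r}")
    threshold = (bonferroni_threshold(family_alpha, n_tests)
                 if correct else family_alpha)
    results = [
        lrt_m7_m8(row.gene, float(row.lnL_M7), float(row.lnL_M8),
                  df=df, bonferroni=threshold)
        for row in df_in.itertuples(index=False)
    ]
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "lnL_M7": [r.lnL_neutral for r in results],
            "lnL_M8": [r.lnL_selection for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_value": [r.p_value for r in results],
            "threshold": threshold,
            "significant": [r.significant_bonferroni for r in results],
        }
    )
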