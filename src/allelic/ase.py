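"""Allele-specific expression calling from diagnostic-SNP counts.

A locus is summarised by the counts of transcripts supporting each parental
allele at a diagnostic 3'UTR SNP (A1 = 129P2, A2 = FVB/N).  The observed A1
fraction is tested against a null fraction — 0.5 for a balanced diploid, or
a copy-number-adjusted value otherwise — with an exact binomial test, and the
locus is called biased toward the over-represented allele when p < alpha,
else balanced.  Loci below the depth gate get a withheld verdict.  This
abstracts restriction-site/Sanger scoring of amplified cDNA to allele counts,
which is the quantity such assays ultimately report.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VERDICTS = ("A1_biased", "A2_biased", "balanced", "withheld")

DEFAULT_MIN_DEPTH = 20
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class AseLocus:
    """Allele-specific expression estimate for one gene."""

    gene: str
    c1: int
    c2: int
    fraction: float
    ci_low: float
    ci_high: float
    p: float
    verdict: str


def ase_call(
    gene: str,
    c1: int,
    c2: int,
    null_fraction: float = 0.5,
    alpha: float = DEFAULT_ALPHA,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> AseLocus:
    """Classify one locus as A1-biased, A2-biased or balanced.

    Exact binomial test of ``c1`` of ``c1 + c2`` observations against
    ``null_fraction``; the CI is exact (Clopper–Pearson) at level
    ``1 - alpha``.  Below ``min_depth`` the verdict is withheld.
    """
    if c1 < 0 or c2 < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 < null_fraction < 1.0:
        raise ValueError("null_fraction must lie in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    n = c1 + c2
    if n < min_depth:
        logger.info("ase_call: %s withheld (depth %d < %d)", gene, n, min_depth)
        frac = c1 / n if n else float("nan")
        return AseLocus(gene, c1, c2, frac, float("nan"), float("nan"), float("nan"), "withheld")
    bt = stats.binomtest(c1, n, null_fraction)
    ci = bt.proportion_ci(confidence_level=1.0 - alpha, method="exact")
    frac = c1 / n
    if bt.pvalue < alpha:
        verdict = "A1_biased" if frac > null_fraction else "A2_biased"
    else:
        verdict = "balanced"
    return AseLocus(gene, c1, c2, frac, float(ci.low), float(ci.high), float(bt.pvalue), verdict)


def ase_table(
    counts: pd.DataFrame,
    null_fraction: float = 0.5,
    alpha: float = DEFAULT_ALPHA,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Vector version of :func:`ase_call` over a (gene, c1, c2) table.

    Returns columns gene, c1, c2, fraction, ci_lo, ci_hi, p, verdict.
    """
    required = {"gene", "c1", "c2"}
    if not required.issubset(counts.columns):
        raise ValueError(f"ASE table needs columns {sorted(required)}")
    rows = []
    for row in counts.itertuples(index=False):
        locus = ase_call(
            str(row.gene), int(row.c1), int(row.c2), null_fraction, alpha, min_depth
        )
        d = asdict(locus)
        d["ci_lo"] = d.pop("ci_low")
        d["ci_hi"] = d.pop("ci_high")
        rows.append(d)
    return pd.DataFrame(
        rows, columns=["gene", "c1", "c2", "fraction", "ci_lo", "ci_hi", "p", "verdict"]
    )
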