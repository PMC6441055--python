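"""Backcross genetics: marker association, interval mapping and penetrance.

A backcross cohort (F1 hybrid × FVB/N parent) carries two genotype classes
at each microsatellite marker — heterozygous 129P2/FVB/N or homozygous
FVB/N.  Linkage of a binary phenotype to a marker is scored with a two-sided
Fisher exact test on the genotype × phenotype 2×2 table, ranked across the
panel with Bonferroni flagging (the association statistic is this package's
choice; classical panels report linkage without naming one).  The candidate
interval is delineated from recombinants: the smallest marker-bounded
interval at which every affected mouse carries the 129P2 allele, expanded to
the flanking markers.  Unaffected carriers are not used to exclude regions
(incomplete penetrance), mirroring recombinant-panel practice.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import HET_129, HOM_FVB, CrossCohort

logger = logging.getLogger(__name__)


def contingency_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2×2 table [[a, b], [c, d]].

    Hypergeometric enumeration with minimum-likelihood two-siding; an
    all-zero table gives p = 1.
    """
    for x in (a, b, c, d):
        if not isinstance(x, (int, np.integer)) or x < 0:
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        return 1.0
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(res.pvalue)


@dataclass(frozen=True)
class PenetranceEstimate:
    """Penetrance as a percentage with an exact (Clopper–Pearson) CI."""

    percent: float
    ci_low: float
    ci_high: float
    affected: int
    total: int
    confidence: float

    def to_dict(self) -> dict:
        return asdict(self)


def penetrance(
    affected_carriers: int, total_carriers: int, confidence: float = 0.95
) -> PenetranceEstimate:
    """Penetrance = 100 × affected/total with an exact binomial CI."""
    if total_carriers <= 0:
        raise ValueError("total_carriers must be positive")
    if not 0 <= affected_carriers <= total_carriers:
        raise ValueError("affected_carriers must lie in [0, total_carriers]")
    ci = stats.binomtest(
        affected_carriers, total_carriers, 0.5
    ).proportion_ci(confidence_level=confidence, method="exact")
    return PenetranceEstimate(
        percent=100.0 * affected_carriers / total_carriers,
        ci_low=100.0 * ci.low,
        ci_high=100.0 * ci.high,
        affected=affected_carriers,
        total=total_carriers,
        confidence=confidence,
    )


def marker_scan(cohort: CrossCohort) -> pd.DataFrame:
    """Genotype–phenotype association at every marker, ranked by p-value.

    Columns: marker, chrom, pos, the 2×2 counts (het/hom × affected/
    unaffected), p (two-sided Fisher exact), direction, monomorphic flag and
    a Bonferroni significance flag at 0.05 / n_markers.  Monomorphic markers
    get p = 1.  P-values are invariant to mouse ordering.
    """
    geno = cohort.genotypes.to_numpy()
    aff = cohort.phenotype.to_numpy(dtype=bool)
    n_markers = geno.shape[1]
    rows = []
    for j, marker in enumerate(cohort.genotypes.columns):
        g = geno[:, j]
        het = g == HET_129
        het_aff = int(np.sum(het & aff))
        het_un = int(np.sum(het & ~aff))
        hom_aff = int(np.sum(~het & aff))
        hom_un = int(np.sum(~het & ~aff))
        monomorphic = het.all() or (~het).all()
        if monomorphic:
            p = 1.0
        else:
            p = contingency_exact(het_aff, het_un, hom_aff, hom_un)
        rate_het = het_aff / max(het_aff + het_un, 1)
        rate_hom = hom_aff / max(hom_aff + hom_un, 1)
        rows.append(
            {
                "marker": marker,
                "chrom": cohort.marker_map.iloc[j]["chrom"],
                "pos": int(cohort.marker_map.iloc[j]["pos"]),
                "het_affected": het_aff,
                "het_unaffected": het_un,
                "hom_affected": hom_aff,
                "hom_unaffected": hom_un,
                "p": p,
                "direction": "HET_129" if rate_het >= rate_hom else "HOM_FVB",
                "monomorphic": bool(monomorphic),
            }
        )
    out = pd.DataFrame(rows)
    out["bonferroni_significant"] = out["p"] < 0.05 / n_markers
    out = out.sort_values("p", kind="stable").reset_index(drop=True)
    logger.info(
        "marker scan: top marker %s (p = %.3g) of %d markers",
        out.iloc[0]["marker"],
        out.iloc[0]["p"],
        n_markers,
    )
    return out


def candidate_interval(cohort: CrossCohort, target_chrom: str) -> tuple[int, int]:
    """Delineate the candidate interval on ``target_chrom`` from affected mice.

    The interval is the run of consecutive markers at which *every* affected
    mouse carries the 129P2 allele (intersection of carrier segments),
    expanded to the flanking markers; among several runs, the one containing
    the most associated marker is taken.  With an empty intersection the top
    marker ± one marker is reported instead.
    """
    on_chrom = cohort.marker_map[cohort.marker_map["chrom"] == target_chrom]
    if len(on_chrom) < 2:
        raise ValueError(f"need >= 2 markers on {target_chrom}")
    aff = cohort.phenotype.to_numpy(dtype=bool)
    if not aff.any():
        raise ValueError("no affected mice in cohort")
    markers = list(on_chrom["marker"])
    pos = on_chrom["pos"].to_numpy(dtype=np.int64)
    geno = cohort.genotypes[markers].to_numpy()
    all_het = (geno[aff] == HET_129).all(axis=0)

    scan = marker_scan(cohort)
    scan_chrom = scan[scan["chrom"] == target_chrom]
    best = scan_chrom.iloc[0]["marker"]
    best_idx = markers.index(best)

    if not all_het.any():
        logger.warning(
            "candidate_interval: empty carrier intersection on %s; "
            "falling back to top marker ± one marker",
            target_chrom,
        )
        lo = max(best_idx - 1, 0)
        hi = min(best_idx + 1, len(markers) - 1)
        return int(pos[lo]), int(pos[hi])

    # contiguous runs of all-carrier markers
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(all_het):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(all_het) - 1))

    def run_key(run):
        s, e = run
        if s <= best_idx <= e:
            return (0, -(e - s))
        return (1, min(abs(best_idx - s), abs(best_idx - e)))

    s, e = min(runs, key=run_key)
    lo = max(s - 1, 0)
    hi = min(e + 1, len(markers) - 1)
    return int(pos[lo]), int(pos[hi])
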