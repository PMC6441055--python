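"""Sliding-window allelic-imbalance statistics.

The analysis asks, per genomic window and per clone, whether the ratio of
reads supporting the A1 (129P2) versus the A2 (FVB/N) haplotype deviates from
the chromosome-wide expectation, and then aggregates evidence across clones:

1. multi-scale sliding windows (default sizes 250/500/1000 bp, step = size/2)
   tile each chromosome; a read belongs to a window iff its start coordinate
   lies inside it, which prevents double counting within a size tier;
2. the expected allelic ratio ``rho`` is the median window fraction
   ``c1/(c1+c2)`` per chromosome and clone — a robust, aneuploidy-aware
   baseline (one 129P2 + two FVB/N copies gives rho ≈ 1/3);
3. each window/clone is tested with the exact conditional Poisson test:
   comparing two Poisson counts against a fixed rate ratio, conditioned on
   their sum, reduces to an exact binomial test of ``c1`` successes in
   ``c1+c2`` trials at probability ``rho``.  Two-sidedness follows the
   minimum-likelihood rule (sum of all outcome probabilities no larger than
   the observed outcome's);
4. per-window p-values are combined across clones with Fisher's method
   (``-2 Σ ln p ~ χ²`` with ``2k`` df) and adjusted by Benjamini–Hochberg;
5. windows below the FDR threshold with a consistent direction are merged
   into regions when they overlap or are book-ended.

Directionality is applied post hoc: the test itself is two-sided (a deviance
in either direction), while region calling selects the requested direction
(``A1_up``: pooled fraction above baseline).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .assign import CALL_A1, CALL_A2, AlleleCall, CallSet, assign_reads
from .simulate import ReadSet, SnpTable

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300
_RHO_CLAMP = 1e-6

DIRECTIONS = ("A1_up", "A2_up")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the imbalance pipeline in one place.

    Attributes
    ----------
    sizes
        Window sizes in bp (multi-scale scan).
    step_fraction
        Step between window starts as a fraction of the window size.
    min_total
        Minimum informative reads (c1+c2) for a window to enter the baseline
        and the test; windows lacking this in any clone are dropped.
    q_threshold
        BH FDR threshold for region calling.
    direction
        ``A1_up`` selects windows with pooled fraction above baseline.
    conflict_policy
        Passed to read assignment (``drop`` or ``majority``).
    per_chromosome_fdr
        Apply BH per chromosome instead of once across all windows.
    pooled_baseline
        Compute the median baseline from clone-pooled counts instead of per
        clone.
    n_clones
        Expected clone count; mismatch with the reads is rejected.  ``None``
        infers it from the reads.
    """

    sizes: tuple[int, ...] = (250, 500, 1000)
    step_fraction: float = 0.5
    min_total: int = 10
    q_threshold: float = 0.05
    direction: str = "A1_up"
    conflict_policy: str = "drop"
    per_chromosome_fdr: bool = False
    pooled_baseline: bool = False
    n_clones: int | None = None

    def __post_init__(self) -> None:
        if not self.sizes or any(s <= 0 for s in self.sizes):
            raise ValueError("window sizes must be positive")
        if not 0 < self.step_fraction <= 1:
            raise ValueError("step_fraction must lie in (0, 1]")
        if self.min_total < 1:
            raise ValueError("min_total must be >= 1")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")


@dataclass
class PipelineResult:
    windows: pd.DataFrame
    regions: pd.DataFrame
    baselines: pd.DataFrame
    report: dict


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


def make_windows(
    chrom_length: int,
    sizes: Sequence[int] = (250, 500, 1000),
    step_fraction: float = 0.5,
) -> pd.DataFrame:
    """Tile ``[0, chrom_length)`` with windows of each size.

    For size ``s`` the step is ``s × step_fraction`` and starts are its
    multiples; windows extending past the chromosome end are dropped (no
    partial windows).  Returns a DataFrame (start, end, size); empty with a
    warning when the chromosome is shorter than every size.
    """
    if not 0 < step_fraction <= 1:
        raise ValueError("step_fraction must lie in (0, 1]")
    frames = []
    for size in sizes:
        if size <= 0:
            raise ValueError("window size must be positive")
        if chrom_length < size:
            continue
        step = max(int(round(size * step_fraction)), 1)
        n = (chrom_length - size) // step + 1
        starts = np.arange(n, dtype=np.int64) * step
        frames.append(pd.DataFrame({"start": starts, "end": starts + size, "size": size}))
    if not frames:
        warnings.warn(
            f"chromosome length {chrom_length} below smallest window size", stacklevel=2
        )
        return pd.DataFrame(columns=["start", "end", "size"]).astype(np.int64)
    return pd.concat(frames, ignore_index=True)


def count_window(
    calls: Iterable[AlleleCall], window: tuple[int, int]
) -> tuple[int, int]:
    """Count A1/A2 reads whose start lies in ``[window[0], window[1])``.

    Scalar reference for the vectorised counting used by the pipeline; only
    A1 and A2 calls contribute.
    """
    ws, we = window
    c1 = c2 = 0
    for call in calls:
        if ws <= call.start < we:
            if call.call == "A1":
                c1 += 1
            elif call.call == "A2":
                c2 += 1
    return c1, c2


def _count_block_windows(
    starts_a1_sorted: np.ndarray,
    starts_a2_sorted: np.ndarray,
    windows: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    ws = windows["start"].to_numpy()
    we = windows["end"].to_numpy()
    c1 = np.searchsorted(starts_a1_sorted, we) - np.searchsorted(starts_a1_sorted, ws)
    c2 = np.searchsorted(starts_a2_sorted, we) - np.searchsorted(starts_a2_sorted, ws)
    return c1.astype(np.int64), c2.astype(np.int64)


def count_windows(
    calls: CallSet, windows_by_chrom: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-window, per-clone summed A1/A2 counts (long format).

    Returns a DataFrame (chrom, start, end, size, clone, c1, c2).
    """
    frames = []
    for (clone, chrom), block in sorted(calls.blocks.items()):
        windows = windows_by_chrom.get(chrom)
        if windows is None or windows.empty:
            continue
        s1 = np.sort(block.starts[block.call == CALL_A1])
        s2 = np.sort(block.starts[block.call == CALL_A2])
        c1, c2 = _count_block_windows(s1, s2, windows)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": windows["start"].to_numpy(),
                    "end": windows["end"].to_numpy(),
                    "size": windows["size"].to_numpy(),
                    "clone": clone,
                    "c1": c1,
                    "c2": c2,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "size", "clone", "c1", "c2"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------


def chromosome_baseline(
    window_counts: pd.DataFrame, min_total: int = 10, pooled_clones: bool = False
) -> pd.DataFrame:
    """Median allelic ratio per chromosome (and clone): the expected ratio.

    Only windows with ``c1 + c2 >= min_total`` qualify; the median is clamped
    to ``[1e-6, 1 - 1e-6]``.  Chromosome/clone combinations without any
    qualifying window are skipped with a logged reason.  With
    ``pooled_clones`` the window counts are summed over clones first and the
    same baseline is assigned to every clone.
    """
    if window_counts.empty:
        return pd.DataFrame(columns=["chrom", "clone", "rho"])
    clones = sorted(window_counts["clone"].unique())
    rows = []
    if pooled_clones:
        pooled = (
            window_counts.groupby(["chrom", "start", "end", "size"], sort=False)[
                ["c1", "c2"]
            ]
            .sum()
            .reset_index()
        )
        for chrom, sub in pooled.groupby("chrom", sort=False):
            total = sub["c1"] + sub["c2"]
            qual = sub[total >= min_total]
            if qual.empty:
                logger.info(
                    "baseline: chromosome %s skipped (no window with >= %d pooled reads)",
                    chrom,
                    min_total,
                )
                continue
            rho = float(np.median(qual["c1"] / (qual["c1"] + qual["c2"])))
            rho = min(max(rho, _RHO_CLAMP), 1 - _RHO_CLAMP)
            rows.extend({"chrom": chrom, "clone": c, "rho": rho} for c in clones)
    else:
        for (chrom, clone), sub in window_counts.groupby(["chrom", "clone"], sort=False):
            total = sub["c1"] + sub["c2"]
            qual = sub[total >= min_total]
            if qual.empty:
                logger.info(
                    "baseline: chromosome %s clone %s skipped (no window with >= %d reads)",
                    chrom,
                    clone,
                    min_total,
                )
                continue
            rho = float(np.median(qual["c1"] / (qual["c1"] + qual["c2"])))
            rho = min(max(rho, _RHO_CLAMP), 1 - _RHO_CLAMP)
            rows.append({"chrom": chrom, "clone": clone, "rho": rho})
    return pd.DataFrame(rows, columns=["chrom", "clone", "rho"])


# ---------------------------------------------------------------------------
# Exact conditional test
# ---------------------------------------------------------------------------


def binom_twosided(k, n, rho, rel_tol: float = 1e-12) -> np.ndarray:
    """Exact two-sided binomial p-value by the minimum-likelihood rule.

    ``p = Σ P(X = i)`` over all outcomes ``i`` with
    ``P(X = i) <= P(X = k) (1 + rel_tol)``, for ``X ~ Binomial(n, rho)``.
    Vectorised over ``k``, ``n`` and ``rho``; the opposite tail's cut point
    is located by bisection on the unimodal pmf, so the cost per element is
    ``O(log n)`` pmf evaluations rather than full enumeration.  The small
    relative tolerance absorbs floating-point jitter between mathematically
    tied outcome probabilities (e.g. the mirror outcome at rho = 1/2).
    """
    k = np.atleast_1d(np.asarray(k, dtype=np.int64))
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    k, n = np.broadcast_arrays(k, n)
    rho_arr = np.broadcast_to(np.asarray(rho, dtype=np.float64), k.shape)
    if np.any((k < 0) | (k > n)) or np.any(n < 1):
        raise ValueError("need 0 <= k <= n and n >= 1")
    if np.any((rho_arr <= 0) | (rho_arr >= 1)):
        raise ValueError("rho must lie in (0, 1)")

    pk = stats.binom.pmf(k, n, rho_arr)
    thresh = pk * (1.0 + rel_tol)
    mode = np.clip(np.floor((n + 1) * rho_arr).astype(np.int64), 0, n)
    pmode = stats.binom.pmf(mode, n, rho_arr)

    p = np.ones(k.shape, dtype=np.float64)

    def _bisect_decreasing(lo, hi, nn, rr, th):
        # invariant: pmf(lo) > th, pmf(hi) <= th (hi may be n+1, pmf 0)
        while True:
            active = (hi - lo) > 1
            if not active.any():
                break
            mid = (lo + hi) // 2
            pm = stats.binom.pmf(np.minimum(mid, nn), nn, rr)
            go_right = active & (pm > th)
            lo = np.where(go_right, mid, lo)
            hi = np.where(active & ~go_right, mid, hi)
        return hi

    def _bisect_increasing(lo, hi, nn, rr, th):
        # invariant: pmf(lo) <= th (lo may be -1, pmf 0), pmf(hi) > th
        while True:
            active = (hi - lo) > 1
            if not active.any():
                break
            mid = (lo + hi) // 2
            pm = stats.binom.pmf(np.maximum(mid, 0), nn, rr)
            ok = active & (pm <= th)
            lo = np.where(ok, mid, lo)
            hi = np.where(active & ~ok, mid, hi)
        return lo

    left = (k < mode) & (pmode > thresh)
    if left.any():
        nn, rr, th = n[left], rho_arr[left], thresh[left]
        j = _bisect_decreasing(mode[left].copy(), nn + 1, nn, rr, th)
        p[left] = stats.binom.cdf(k[left], nn, rr) + stats.binom.sf(j - 1, nn, rr)

    right = (k > mode) & (pmode > thresh)
    if right.any():
        nn, rr, th = n[right], rho_arr[right], thresh[right]
        j = _bisect_increasing(
            np.full(nn.shape, -1, dtype=np.int64), mode[right].copy(), nn, rr, th
        )
        tail = stats.binom.sf(k[right] - 1, nn, rr)
        low = np.where(j >= 0, stats.binom.cdf(np.maximum(j, 0), nn, rr), 0.0)
        p[right] = tail + low

    return np.clip(p, np.finfo(np.float64).tiny, 1.0)


def exact_allelic_test(c1: int, c2: int, rho: float) -> float:
    """Exact conditional Poisson test of counts ``(c1, c2)`` against ratio ``rho``.

    The exact comparison of two Poisson rates conditioned on the total
    reduces to the exact two-sided binomial test of ``c1`` successes in
    ``c1 + c2`` trials at success probability ``rho``.
    """
    if c1 < 0 or c2 < 0 or c1 + c2 < 1:
        raise ValueError("need non-negative counts with c1 + c2 >= 1")
    return float(binom_twosided(c1, c1 + c2, rho)[0])


# ---------------------------------------------------------------------------
# Combination and FDR
# ---------------------------------------------------------------------------


def fisher_combine(pvalues) -> tuple[np.ndarray, int, np.ndarray]:
    """Fisher's combined probability test over the last axis.

    ``chi2 = -2 Σ ln p`` is referred to the upper tail of the chi-square
    distribution with ``2k`` degrees of freedom.  P-values of zero (after
    underflow) are floored at 1e-300 with a warning.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0 or p.shape[-1] < 1:
        raise ValueError("need at least one p-value per combination")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p < _P_FLOOR):
        warnings.warn("p-value(s) below 1e-300 floored before combination", stacklevel=2)
        p = np.maximum(p, _P_FLOOR)
    k = p.shape[-1]
    chi2 = -2.0 * np.log(p).sum(axis=-1)
    df = 2 * k
    p_combined = stats.chi2.sf(chi2, df)
    p_combined = np.clip(p_combined, np.finfo(np.float64).tiny, 1.0)
    return chi2, df, p_combined


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values (capped at 1)."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return np.empty(0, dtype=np.float64)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Region calling
# ---------------------------------------------------------------------------


def call_regions(
    tests: pd.DataFrame, q_threshold: float = 0.05, direction: str = "A1_up"
) -> pd.DataFrame:
    """Merge significant same-direction windows into regions.

    Windows with ``q < q_threshold`` whose pooled fraction lies on the
    requested side of the baseline are merged (across size tiers) when they
    overlap or are book-ended.  Each region reports its minimum q and the
    read-weighted mean fold.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    cols = ["chrom", "start", "end", "n_windows", "min_q", "mean_fold", "direction"]
    if tests.empty:
        return pd.DataFrame(columns=cols)
    if direction == "A1_up":
        oriented = tests["pooled_fraction"] > tests["rho_bar"]
    else:
        oriented = tests["pooled_fraction"] < tests["rho_bar"]
    sig = tests[(tests["q"] < q_threshold) & oriented]
    if sig.empty:
        return pd.DataFrame(columns=cols)
    sig = sig.sort_values(["chrom", "start", "end"], kind="stable")
    rows = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        qs = sub["q"].to_numpy()
        folds = sub["fold"].to_numpy()
        weights = sub["n_total"].to_numpy().astype(np.float64)
        cur_start, cur_end = int(starts[0]), int(ends[0])
        acc = [0]
        for i in range(1, len(sub)):
            if starts[i] <= cur_end:  # overlapping or book-ended
                cur_end = max(cur_end, int(ends[i]))
                acc.append(i)
            else:
                rows.append(
                    _region_row(chrom, cur_start, cur_end, qs, folds, weights, acc, direction)
                )
                cur_start, cur_end = int(starts[i]), int(ends[i])
                acc = [i]
        rows.append(_region_row(chrom, cur_start, cur_end, qs, folds, weights, acc, direction))
    return pd.DataFrame(rows, columns=cols)


def _region_row(chrom, start, end, qs, folds, weights, acc, direction):
    idx = np.array(acc)
    w = weights[idx]
    return {
        "chrom": chrom,
        "start": start,
        "end": end,
        "n_windows": len(idx),
        "min_q": float(qs[idx].min()),
        "mean_fold": float(np.average(folds[idx], weights=w) if w.sum() > 0 else folds[idx].mean()),
        "direction": direction,
    }


def write_regions_bed(regions: pd.DataFrame, path: str) -> None:
    """Write regions as BED6: name = mean fold, score = -10·log10(min q)."""
    with open(path, "w") as fh:
        for row in regions.itertuples(index=False):
            score = int(round(min(-10.0 * np.log10(max(row.min_q, 1e-100)), 1000.0)))
            strand = "+" if row.direction == "A1_up" else "-"
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.mean_fold:.4f}\t{score}\t{strand}\n"
            )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_pipeline(
    reads: ReadSet, snps: SnpTable, config: PipelineConfig = PipelineConfig()
) -> PipelineResult:
    """Run the whole imbalance analysis: assignment, windows, baseline,
    per-clone exact test, Fisher combination, BH FDR and region calling.

    Deterministic given inputs and config.  The report records per-stage
    read/window attrition.
    """
    if config.n_clones is not None and config.n_clones != reads.n_clones:
        raise ValueError(
            f"clone count mismatch: config expects {config.n_clones}, reads have {reads.n_clones}"
        )
    report: dict = {"config": asdict(config), "stages": {}}
    calls = assign_reads(reads, snps, conflict_policy=config.conflict_policy)
    n_reads = calls.n_reads()
    call_counts = {
        name: int(sum(np.sum(b.call == code) for b in calls.blocks.values()))
        for code, name in enumerate(["a1", "a2", "conflict", "noninformative"])
    }
    report["stages"]["assignment"] = {"reads": n_reads, **call_counts}

    lengths = snps.chrom_lengths or {}
    windows_by_chrom: dict[str, pd.DataFrame] = {}
    for chrom in calls.chroms:
        length = lengths.get(chrom)
        if length is None:
            length = int(
                max(b.ends.max() for (cl, ch), b in calls.blocks.items() if ch == chrom)
            )
        windows_by_chrom[chrom] = make_windows(length, config.sizes, config.step_fraction)

    counts = count_windows(calls, windows_by_chrom)
    report["stages"]["windows"] = {
        "windows_per_chrom": {
            ch: int(len(w)) for ch, w in windows_by_chrom.items()
        },
        "counted_rows": int(len(counts)),
    }

    baselines = chromosome_baseline(
        counts, min_total=config.min_total, pooled_clones=config.pooled_baseline
    )
    if counts.empty or baselines.empty:
        logger.warning("no windows or no baseline: empty result")
        empty = pd.DataFrame()
        return PipelineResult(empty, call_regions(empty), baselines, report)

    clones = sorted(counts["clone"].unique())
    k = len(clones)
    wide = counts.pivot_table(
        index=["chrom", "start", "end", "size"],
        columns="clone",
        values=["c1", "c2"],
        fill_value=0,
    )
    wide.columns = [f"{v}_{c}" for v, c in wide.columns]
    wide = wide.reset_index()

    c1_cols = [f"c1_{c}" for c in clones]
    c2_cols = [f"c2_{c}" for c in clones]
    c1m = wide[c1_cols].to_numpy(dtype=np.int64)
    c2m = wide[c2_cols].to_numpy(dtype=np.int64)
    totals = c1m + c2m
    eligible = (totals >= config.min_total).all(axis=1)

    rho_map = {(r.chrom, r.clone): r.rho for r in baselines.itertuples(index=False)}
    has_baseline = np.array(
        [all((ch, c) in rho_map for c in clones) for ch in wide["chrom"]]
    )
    keep = eligible & has_baseline
    report["stages"]["testing"] = {
        "windows_total": int(len(wide)),
        "windows_dropped_min_total": int((~eligible).sum()),
        "windows_dropped_no_baseline": int((eligible & ~has_baseline).sum()),
        "windows_tested": int(keep.sum()),
    }
    logger.info(
        "testing %d of %d windows (%d below min_total, %d without baseline)",
        int(keep.sum()),
        len(wide),
        int((~eligible).sum()),
        int((eligible & ~has_baseline).sum()),
    )
    tested = wide[keep].reset_index(drop=True)
    if tested.empty:
        empty = pd.DataFrame()
        return PipelineResult(tested, call_regions(tested) if len(tested) else pd.DataFrame(), baselines, report)

    c1m = c1m[keep]
    c2m = c2m[keep]
    totals = totals[keep]
    rho_cols = np.column_stack(
        [
            np.array([rho_map[(ch, c)] for ch in tested["chrom"]])
            for c in clones
        ]
    )
    pmat = np.empty_like(rho_cols)
    for j in range(k):
        pmat[:, j] = binom_twosided(c1m[:, j], totals[:, j], rho_cols[:, j])
        tested[f"p_{clones[j]}"] = pmat[:, j]

    chi2, df, p_combined = fisher_combine(pmat)
    tested["chi2"] = chi2
    tested["df"] = df
    tested["p_combined"] = p_combined

    if config.per_chromosome_fdr:
        q = np.empty(len(tested))
        for chrom, sub in tested.groupby("chrom", sort=False):
            q[sub.index.to_numpy()] = bh_fdr(sub["p_combined"].to_numpy())
        tested["q"] = q
    else:
        tested["q"] = bh_fdr(p_combined)

    tested["n_total"] = totals.sum(axis=1)
    tested["pooled_fraction"] = c1m.sum(axis=1) / np.maximum(totals.sum(axis=1), 1)
    tested["rho_bar"] = rho_cols.mean(axis=1)
    tested["fold"] = tested["pooled_fraction"] / tested["rho_bar"]

    regions = call_regions(tested, config.q_threshold, config.direction)
    report["stages"]["regions"] = {
        "significant_windows": int((tested["q"] < config.q_threshold).sum()),
        "regions": int(len(regions)),
    }
    return PipelineResult(tested, regions, baselines, report)
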