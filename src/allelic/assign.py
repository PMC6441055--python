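"""Haplotype assignment of reads from strain-informative SNPs.

Each read is assigned to haplotype A1 (129P2), A2 (FVB/N), CONFLICT or
NONINFORMATIVE by collecting one vote per informative SNP it overlaps: an
observed base equal to the A1 base votes A1, equal to the A2 base votes A2,
and any other base is a silent non-vote (treated as sequencing error, not as
evidence).  Unanimous non-empty votes give the haplotype; mixed votes give
CONFLICT; no votes give NONINFORMATIVE.  ``n_snps_seen`` counts voting SNPs,
so CONFLICT requires at least two of them.

CONFLICT reads are discarded by default (conservative: a read either supports
one allele or it is not counted); a ``majority`` policy re-assigns them by
majority vote with ties kept as CONFLICT.  CONFLICT and NONINFORMATIVE reads
never contribute to downstream window counts.  Duplicate reads are not
collapsed.

Coordinates are 0-based half-open internally; VCF positions are converted on
load and all emitted intervals follow the BED convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .simulate import (
    A1,
    A2,
    ReadBlock,
    ReadSet,
    SnpTable,
    encode_base,
)

logger = logging.getLogger(__name__)

# call codes
CALL_A1 = 0
CALL_A2 = 1
CALL_CONFLICT = 2
CALL_NONINFORMATIVE = 3
CALL_NAMES = np.array(["A1", "A2", "CONFLICT", "NONINFORMATIVE"])

CONFLICT_POLICIES = ("drop", "majority")


@dataclass(frozen=True)
class Read:
    """A single read with its observed bases at SNP positions it covers."""

    read_id: str
    chrom: str
    start: int
    end: int
    clone: int
    obs: tuple[tuple[int, str], ...] = ()


@dataclass(frozen=True)
class AlleleCall:
    """A read's haplotype assignment.

    ``n_snps_seen`` is the number of SNPs that produced a vote; the call is
    NONINFORMATIVE exactly when it is zero, and CONFLICT requires >= 2.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    clone: int
    call: str
    n_snps_seen: int


def load_snps(path: str) -> SnpTable:
    """Load a strain-SNP table from a minimal VCF.

    REF is the A2 (FVB/N) base and ALT the A1 (129P2) base.  Multiallelic and
    indel records are skipped with a logged count, as are records with
    REF == ALT.  Input must be position-sorted with unique positions per
    chromosome; the first violation is reported.
    """
    rows: list[tuple[str, int, str, str]] = []
    skipped_indel = 0
    skipped_multi = 0
    skipped_ref_eq_alt = 0
    last: dict[str, int] = {}
    finished: set[str] = set()
    prev_chrom: str | None = None
    with pysam.VariantFile(path) as vf:
        lengths = {
            name: contig.length
            for name, contig in vf.header.contigs.items()
            if contig.length
        }
        for rec in vf:
            chrom = rec.chrom
            if chrom != prev_chrom:
                if chrom in finished:
                    raise ValueError(
                        f"unsorted VCF: chromosome {chrom} re-appears at position {rec.pos}"
                    )
                if prev_chrom is not None:
                    finished.add(prev_chrom)
                prev_chrom = chrom
            if chrom in last and rec.pos <= last[chrom]:
                raise ValueError(f"unsorted VCF at {chrom}:{rec.pos}")
            last[chrom] = rec.pos
            alts = rec.alts
            if alts is None or len(alts) != 1:
                skipped_multi += 1
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
                skipped_indel += 1
                continue
            if ref == alt:
                skipped_ref_eq_alt += 1
                continue
            rows.append((chrom, rec.pos - 1, alt, ref))  # ALT=A1, REF=A2; 0-based
    if skipped_indel or skipped_multi or skipped_ref_eq_alt:
        logger.info(
            "load_snps: skipped %d indel, %d multiallelic, %d REF==ALT record(s)",
            skipped_indel,
            skipped_multi,
            skipped_ref_eq_alt,
        )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "a1", "a2"])
    return SnpTable(df, chrom_lengths=lengths or None)


def assign_read(read: Read, snps: SnpTable) -> AlleleCall:
    """Assign a single read; reference implementation of the voting rule."""
    pos_arr, a1c, a2c = snps.by_chrom(read.chrom)
    n_a1 = n_a2 = 0
    for pos, base in read.obs:
        if not read.start <= pos < read.end:
            raise ValueError(
                f"read {read.read_id}: observed base at {pos} outside [{read.start}, {read.end})"
            )
        idx = np.searchsorted(pos_arr, pos)
        if idx >= pos_arr.size or pos_arr[idx] != pos:
            continue  # not an informative SNP: ignore
        code = encode_base(base.upper())
        if code == a1c[idx]:
            n_a1 += 1
        elif code == a2c[idx]:
            n_a2 += 1
        # other base: silent non-vote
    if n_a1 and n_a2:
        call = CALL_CONFLICT
    elif n_a1:
        call = CALL_A1
    elif n_a2:
        call = CALL_A2
    else:
        call = CALL_NONINFORMATIVE
    return AlleleCall(
        read_id=read.read_id,
        chrom=read.chrom,
        start=read.start,
        end=read.end,
        clone=read.clone,
        call=str(CALL_NAMES[call]),
        n_snps_seen=n_a1 + n_a2,
    )


@dataclass
class CallBlock:
    """Vectorised calls for one (clone, chromosome) block."""

    starts: np.ndarray
    ends: np.ndarray
    call: np.ndarray  # uint8 call codes
    n_snps: np.ndarray


@dataclass
class CallSet:
    """All calls, keyed by (clone, chrom)."""

    blocks: dict[tuple[int, str], CallBlock]
    n_clones: int

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(ch for (_, ch) in self.blocks))

    @property
    def clones(self) -> list[int]:
        return sorted({c for (c, _) in self.blocks})

    def n_reads(self) -> int:
        return sum(b.starts.size for b in self.blocks.values())

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for (clone, chrom) in sorted(self.blocks):
            b = self.blocks[(clone, chrom)]
            frames.append(
                pd.DataFrame(
                    {
                        "read_id": [f"{clone}:{chrom}:{i}" for i in range(b.starts.size)],
                        "chrom": chrom,
                        "start": b.starts,
                        "end": b.ends,
                        "clone": clone,
                        "call": CALL_NAMES[b.call],
                        "n_snps_seen": b.n_snps,
                    }
                )
            )
        if not frames:
            return pd.DataFrame(
                columns=["read_id", "chrom", "start", "end", "clone", "call", "n_snps_seen"]
            )
        return pd.concat(frames, ignore_index=True)

    def to_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def assign_reads(
    reads: ReadSet, snps: SnpTable, conflict_policy: str = "drop"
) -> CallSet:
    """Assign every read in a :class:`ReadSet` (vectorised).

    ``conflict_policy='majority'`` re-assigns mixed-vote reads to the
    majority haplotype, keeping exact ties as CONFLICT.  The result is
    independent of read order and deterministic.
    """
    if conflict_policy not in CONFLICT_POLICIES:
        raise ValueError(f"conflict_policy must be one of {CONFLICT_POLICIES}")
    blocks: dict[tuple[int, str], CallBlock] = {}
    for key, block in reads.blocks.items():
        _, chrom = key
        pos_arr, a1c, a2c = snps.by_chrom(chrom)
        n = block.n_reads
        n1 = np.zeros(n, dtype=np.int32)
        n2 = np.zeros(n, dtype=np.int32)
        if block.obs_pos.size and pos_arr.size:
            idx = np.searchsorted(pos_arr, block.obs_pos)
            idx_clipped = np.minimum(idx, pos_arr.size - 1)
            valid = pos_arr[idx_clipped] == block.obs_pos
            v1 = valid & (block.obs_base == a1c[idx_clipped])
            v2 = valid & (block.obs_base == a2c[idx_clipped])
            n1 = np.bincount(block.obs_read[v1], minlength=n).astype(np.int32)
            n2 = np.bincount(block.obs_read[v2], minlength=n).astype(np.int32)
        call = np.full(n, CALL_NONINFORMATIVE, dtype=np.uint8)
        call[(n1 > 0) & (n2 == 0)] = CALL_A1
        call[(n2 > 0) & (n1 == 0)] = CALL_A2
        mixed = (n1 > 0) & (n2 > 0)
        if conflict_policy == "majority":
            call[mixed & (n1 > n2)] = CALL_A1
            call[mixed & (n2 > n1)] = CALL_A2
            call[mixed & (n1 == n2)] = CALL_CONFLICT
        else:
            call[mixed] = CALL_CONFLICT
        blocks[key] = CallBlock(
            starts=block.starts,
            ends=block.read_ends(),
            call=call,
            n_snps=(n1 + n2),
        )
    return CallSet(blocks=blocks, n_clones=reads.n_clones)


def assignment_summary(calls: CallSet) -> pd.DataFrame:
    """Per-chromosome, per-clone tallies of A1/A2/CONFLICT/NONINFORMATIVE.

    Counts conserve the input: the categories sum to the number of reads.
    """
    if not calls.blocks:
        raise ValueError("assignment_summary: no calls")
    rows = []
    for (clone, chrom) in sorted(calls.blocks):
        b = calls.blocks[(clone, chrom)]
        counts = np.bincount(b.call, minlength=4)
        rows.append(
            {
                "chrom": chrom,
                "clone": clone,
                "a1": int(counts[CALL_A1]),
                "a2": int(counts[CALL_A2]),
                "conflict": int(counts[CALL_CONFLICT]),
                "noninformative": int(counts[CALL_NONINFORMATIVE]),
                "total": int(b.call.size),
            }
        )
        logger.info(
            "assignment %s clone %d: A1=%d A2=%d conflict=%d noninformative=%d",
            chrom,
            clone,
            rows[-1]["a1"],
            rows[-1]["a2"],
            rows[-1]["conflict"],
            rows[-1]["noninformative"],
        )
    return pd.DataFrame(rows)


# SAM text ingestion ---------------------------------------------------------

# CIGAR operation codes accepted when extracting per-SNP observed bases:
# M(0), =(7), X(8) consume both query and reference; S(4) consumes query only.
_ALLOWED_CIGAR = {0, 4, 7, 8}


def reads_from_sam(path: str, snps: SnpTable, clone: int = 0) -> ReadSet:
    """Ingest aligned reads from SAM text, extracting observed bases at
    informative-SNP positions from sequence + POS + CIGAR.

    Reads whose CIGAR contains operations other than M/=/X/S (insertions,
    deletions, splices, ...) are skipped with a logged count, as are unmapped
    reads and reads without a stored sequence.
    """
    per_chrom: dict[str, dict[str, list]] = {}
    skipped = 0
    max_len = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as af:
        for aln in af:
            if aln.is_unmapped or aln.query_sequence is None:
                skipped += 1
                continue
            ops = {op for op, _ in (aln.cigartuples or [])}
            if not ops or not ops.issubset(_ALLOWED_CIGAR):
                skipped += 1
                continue
            chrom = aln.reference_name
            start, end = aln.reference_start, aln.reference_end
            store = per_chrom.setdefault(
                chrom, {"starts": [], "ends": [], "obs": []}
            )
            i = len(store["starts"])
            store["starts"].append(start)
            store["ends"].append(end)
            max_len = max(max_len, end - start)
            pos_arr, _, _ = snps.by_chrom(chrom)
            lo = np.searchsorted(pos_arr, start)
            hi = np.searchsorted(pos_arr, end)
            if hi > lo:
                wanted = set(pos_arr[lo:hi].tolist())
                seq = aln.query_sequence
                for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                    if rpos in wanted:
                        base = seq[qpos].upper()
                        if base in "ACGT":
                            store["obs"].append((i, rpos, encode_base(base)))
    if skipped:
        logger.info("reads_from_sam: skipped %d read(s)", skipped)
    blocks: dict[tuple[int, str], ReadBlock] = {}
    for chrom, store in per_chrom.items():
        obs = store["obs"]
        blocks[(clone, chrom)] = ReadBlock(
            starts=np.array(store["starts"], dtype=np.int64),
            read_length=max_len,
            obs_read=np.array([o[0] for o in obs], dtype=np.int64),
            obs_pos=np.array([o[1] for o in obs], dtype=np.int64),
            obs_base=np.array([o[2] for o in obs], dtype=np.uint8),
            ends=np.array(store["ends"], dtype=np.int64),
        )
    return ReadSet(blocks=blocks, read_length=max_len, n_clones=1)
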