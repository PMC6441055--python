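"""Synthetic data generation for allele-specific ChIP-seq and backcross studies.

This module produces every input the rest of the package consumes:

* allele-informative sequencing reads over simulated chromosomes with a
  configurable number of copies of each parental haplotype (A1 = 129P2,
  A2 = FVB/N) and optional implanted enhancer windows whose A1 allelic
  fraction and coverage differ from background;
* the strain-SNP table that makes reads informative, written as minimal VCF;
* ground-truth sidecars (BED intervals for implanted enhancers);
* backcross cohorts genotyped at a microsatellite-style marker panel, with a
  binary phenotype linked to one marker at set penetrance.

The read model is deliberately minimal: a read is an interval of fixed length
plus the observed base at each strain-informative SNP it overlaps.  The
downstream statistics consume only allele-informative evidence, so full
sequences, fragment-length effects and GC bias are omitted.  Sequencing error
is modelled as the worst case for haplotype assignment: with probability
``error_rate`` an observed SNP base is flipped to the *other* haplotype's
base, which stresses the conflict-handling rule rather than producing silent
non-votes.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence`; re-running any simulator with the same
seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Shared constants and base-code helpers
# ---------------------------------------------------------------------------

#: Haplotype codes used throughout the package.
A1 = 0  # 129P2
A2 = 1  # FVB/N

_BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(_BASES)}
_CODE_TO_BASE = np.array(list(_BASES))


def encode_base(base: str) -> int:
    """Map a single upper-case nucleotide to its integer code (A=0..T=3)."""
    try:
        return _BASE_TO_CODE[base]
    except KeyError:
        raise ValueError(f"not a nucleotide: {base!r}") from None


def decode_bases(codes: np.ndarray) -> np.ndarray:
    return _CODE_TO_BASE[np.asarray(codes, dtype=np.int64)]


# ---------------------------------------------------------------------------
# SNP table
# ---------------------------------------------------------------------------


@dataclass
class SnpTable:
    """Positions where the two parental haplotypes carry different bases.

    This is the sole source of allele informativeness for read assignment.
    Positions are stored 0-based internally; VCF I/O converts to/from the
    1-based VCF convention.  In the VCF representation REF is the A2 (FVB/N)
    base and ALT the A1 (129P2) base.

    Parameters
    ----------
    df
        DataFrame with columns ``chrom`` (str), ``pos`` (0-based int),
        ``a1`` and ``a2`` (single-character strings), sorted by
        ``(chrom, pos)`` with positions unique per chromosome.
    chrom_lengths
        Optional chromosome lengths, used when writing VCF contig headers.
    """

    df: pd.DataFrame
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "a1", "a2"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"SnpTable needs columns {sorted(required)}")
        self.df = self.df.reset_index(drop=True)
        if len(self.df):
            if (self.df["a1"] == self.df["a2"]).any():
                raise ValueError("SNP with identical haplotype bases (a1 == a2)")
            grouped = self.df.groupby("chrom", sort=False)["pos"]
            if not grouped.apply(lambda s: s.is_monotonic_increasing and s.is_unique).all():
                raise ValueError("SNP positions must be sorted and unique per chromosome")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def by_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(positions, a1_codes, a2_codes)`` arrays for one chromosome.

        Empty arrays if the chromosome carries no informative SNPs.
        """
        if chrom not in self._by_chrom:
            sub = self.df[self.df["chrom"] == chrom]
            pos = sub["pos"].to_numpy(dtype=np.int64)
            a1 = np.array([_BASE_TO_CODE[b] for b in sub["a1"]], dtype=np.uint8)
            a2 = np.array([_BASE_TO_CODE[b] for b in sub["a2"]], dtype=np.uint8)
            self._by_chrom[chrom] = (pos, a1, a2)
        return self._by_chrom[chrom]

    def to_vcf(self, path: str) -> None:
        """Write the table as a minimal VCF (REF = A2/FVB/N, ALT = A1/129P2)."""
        header = pysam.VariantHeader()
        lengths = self.chrom_lengths or {}
        for chrom in self.chroms or lengths.keys():
            length = lengths.get(chrom)
            if length is None and len(self.df):
                length = int(self.df.loc[self.df["chrom"] == chrom, "pos"].max()) + 2
            header.contigs.add(chrom, length=length)
        with pysam.VariantFile(path, "w", header=header) as out:
            for row in self.df.itertuples(index=False):
                rec = out.new_record(
                    contig=row.chrom,
                    start=int(row.pos),
                    stop=int(row.pos) + 1,
                    alleles=(row.a2, row.a1),
                    id=f"snp_{row.chrom}_{int(row.pos) + 1}",
                )
                out.write(rec)


# ---------------------------------------------------------------------------
# Read containers
# ---------------------------------------------------------------------------


@dataclass
class ReadBlock:
    """Reads of one clone on one chromosome.

    ``starts`` holds 0-based read start positions; reads are fixed-length
    unless ``ends`` is given (SAM-derived reads may vary in span).  The
    observations are a flat (read, SNP) pair list: ``obs_read[i]`` indexes
    into ``starts``, ``obs_pos[i]`` is the 0-based genomic position and
    ``obs_base[i]`` the observed base code at that position.
    """

    starts: np.ndarray
    read_length: int
    obs_read: np.ndarray
    obs_pos: np.ndarray
    obs_base: np.ndarray
    ends: np.ndarray | None = None
    origin: np.ndarray | None = None  # truth haplotype per read (simulation only)

    @property
    def n_reads(self) -> int:
        return int(self.starts.size)

    def read_ends(self) -> np.ndarray:
        if self.ends is not None:
            return self.ends
        return self.starts + self.read_length


@dataclass
class ReadSet:
    """All simulated (or ingested) reads, keyed by ``(clone, chrom)``."""

    blocks: dict[tuple[int, str], ReadBlock]
    read_length: int
    n_clones: int

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(ch for (_, ch) in self.blocks))

    def n_reads(self) -> int:
        return sum(b.n_reads for b in self.blocks.values())

    def to_tsv(self, path: str) -> None:
        """Write reads as TSV: read_id, chrom, start, end, clone, obs.

        ``obs`` is a semicolon-joined list of ``pos:base`` with 0-based
        positions, or ``.`` when the read overlaps no informative SNP.
        """
        with open(path, "w") as fh:
            fh.write("read_id\tchrom\tstart\tend\tclone\tobs\n")
            for (clone, chrom) in sorted(self.blocks):
                block = self.blocks[(clone, chrom)]
                ends = block.read_ends()
                obs_strings = ["."] * block.n_reads
                if block.obs_read.size:
                    order = np.argsort(block.obs_read, kind="stable")
                    bases = decode_bases(block.obs_base[order])
                    reads = block.obs_read[order]
                    pos = block.obs_pos[order]
                    parts: dict[int, list[str]] = {}
                    for r, p, b in zip(reads.tolist(), pos.tolist(), bases.tolist()):
                        parts.setdefault(r, []).append(f"{p}:{b}")
                    for r, items in parts.items():
                        obs_strings[r] = ";".join(items)
                for i in range(block.n_reads):
                    fh.write(
                        f"{clone}:{chrom}:{i}\t{chrom}\t{block.starts[i]}\t"
                        f"{ends[i]}\t{clone}\t{obs_strings[i]}\n"
                    )

    @classmethod
    def from_tsv(cls, path: str) -> "ReadSet":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "clone": np.int64},
        )
        required = {"read_id", "chrom", "start", "end", "clone", "obs"}
        if not required.issubset(df.columns):
            raise ValueError(f"reads TSV needs columns {sorted(required)}")
        blocks: dict[tuple[int, str], ReadBlock] = {}
        read_length = 0
        for (clone, chrom), sub in df.groupby(["clone", "chrom"], sort=True):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            obs_read: list[int] = []
            obs_pos: list[int] = []
            obs_base: list[int] = []
            for i, obs in enumerate(sub["obs"].astype(str)):
                if obs in (".", "nan", ""):
                    continue
                for item in obs.split(";"):
                    p, b = item.split(":")
                    obs_read.append(i)
                    obs_pos.append(int(p))
                    obs_base.append(encode_base(b))
            lengths = ends - starts
            read_length = max(read_length, int(lengths.max()) if lengths.size else 0)
            blocks[(int(clone), str(chrom))] = ReadBlock(
                starts=starts,
                read_length=int(lengths.max()) if lengths.size else 0,
                obs_read=np.array(obs_read, dtype=np.int64),
                obs_pos=np.array(obs_pos, dtype=np.int64),
                obs_base=np.array(obs_base, dtype=np.uint8),
                ends=ends,
            )
        n_clones = len({c for (c, _) in blocks}) or 1
        return cls(blocks=blocks, read_length=read_length, n_clones=n_clones)


# ---------------------------------------------------------------------------
# Simulation specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromSpec:
    """A simulated chromosome with per-haplotype copy numbers.

    ``copies_a1 = 1, copies_a2 = 2`` reproduces the trisomic design in which
    one 129P2 and two FVB/N copies give an expected allelic fraction of 1/3.
    """

    name: str
    length: int
    copies_a1: int = 1
    copies_a2: int = 1
    snp_density: float = 2.0  # expected informative SNPs per kb

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("chromosome length must be positive")
        if self.copies_a1 < 0 or self.copies_a2 < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.copies_a1 + self.copies_a2 < 1:
            raise ValueError("at least one haplotype copy required")
        if not self.snp_density > 0:
            raise ValueError("snp_density must be > 0")

    @property
    def baseline_fraction(self) -> float:
        """Expected A1 fraction outside enhancers: copies_a1 / total copies."""
        return self.copies_a1 / (self.copies_a1 + self.copies_a2)


@dataclass(frozen=True)
class EnhancerSpec:
    """An implanted allele-biased window (0-based, half-open coordinates).

    ``a1_fraction = 2 × baseline`` reproduces a two-fold allelic enrichment;
    ``coverage_mult`` scales the total read rate inside the window.
    """

    chrom: str
    start: int
    end: int
    a1_fraction: float
    coverage_mult: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("enhancer end must exceed start")
        if not 0.0 < self.a1_fraction < 1.0:
            raise ValueError("a1_fraction must lie in (0, 1)")
        if self.coverage_mult < 1.0:
            raise ValueError("coverage_mult must be >= 1")


@dataclass(frozen=True)
class ReadSim:
    """Read-model parameters shared by all chromosomes and clones."""

    read_length: int = 100
    background_rate: float = 1.0  # expected read starts per bp per clone
    error_rate: float = 0.001  # P(SNP base flipped to the other haplotype's base)
    n_clones: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if not self.background_rate > 0:
            raise ValueError("background_rate must be > 0")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")


# ---------------------------------------------------------------------------
# ChIP-read simulator
# ---------------------------------------------------------------------------


def _simulate_snps(
    spec: ChromSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = rng.poisson(spec.length / 1000.0 * spec.snp_density)
    pos = np.unique(rng.integers(0, spec.length, size=n))
    a1 = rng.integers(0, 4, size=pos.size).astype(np.uint8)
    a2 = ((a1 + rng.integers(1, 4, size=pos.size)) % 4).astype(np.uint8)
    return pos, a1, a2


def _simulate_block(
    spec: ChromSpec,
    enhancers: Sequence[EnhancerSpec],
    sim: ReadSim,
    snp_pos: np.ndarray,
    snp_a1: np.ndarray,
    snp_a2: np.ndarray,
    rng: np.random.Generator,
) -> ReadBlock:
    span = max(spec.length - sim.read_length + 1, 1)
    n_bg = rng.poisson(sim.background_rate * span)
    starts = rng.integers(0, span, size=n_bg)
    if enhancers:
        outside = np.ones(starts.size, dtype=bool)
        for e in enhancers:
            outside &= (starts < e.start) | (starts >= e.end)
        start_parts = [starts[outside]]
        p1_parts = [np.full(start_parts[0].size, spec.baseline_fraction)]
        for e in enhancers:
            lo = max(e.start, 0)
            hi = min(e.end, span)
            if hi <= lo:
                continue
            n_e = rng.poisson(sim.background_rate * e.coverage_mult * (hi - lo))
            start_parts.append(rng.integers(lo, hi, size=n_e))
            p1_parts.append(np.full(n_e, e.a1_fraction))
        starts = np.concatenate(start_parts)
        p1 = np.concatenate(p1_parts)
    else:
        p1 = np.full(starts.size, spec.baseline_fraction)

    origin = np.where(rng.random(starts.size) < p1, A1, A2).astype(np.uint8)

    lo = np.searchsorted(snp_pos, starts)
    hi = np.searchsorted(snp_pos, starts + sim.read_length)
    counts = hi - lo
    total = int(counts.sum())
    obs_read = np.repeat(np.arange(starts.size, dtype=np.int64), counts)
    if total:
        offsets = np.arange(total, dtype=np.int64) - np.repeat(
            np.cumsum(counts) - counts, counts
        )
        obs_snp = lo[obs_read] + offsets
    else:
        obs_snp = np.empty(0, dtype=np.int64)
    pair_origin = origin[obs_read]
    obs_base = np.where(pair_origin == A1, snp_a1[obs_snp], snp_a2[obs_snp]).astype(
        np.uint8
    )
    if sim.error_rate > 0 and total:
        flip = rng.random(total) < sim.error_rate
        other = np.where(pair_origin == A1, snp_a2[obs_snp], snp_a1[obs_snp])
        obs_base[flip] = other[flip]
    return ReadBlock(
        starts=starts.astype(np.int64),
        read_length=sim.read_length,
        obs_read=obs_read,
        obs_pos=snp_pos[obs_snp],
        obs_base=obs_base,
        origin=origin,
    )


def simulate_chip_reads(
    chroms: Sequence[ChromSpec],
    enhancers: Sequence[EnhancerSpec] = (),
    sim: ReadSim = ReadSim(),
) -> tuple[ReadSet, SnpTable, pd.DataFrame]:
    """Simulate allele-informative ChIP-seq reads for ``sim.n_clones`` clones.

    Outside enhancers a read's haplotype of origin is drawn proportional to
    the chromosome's copy numbers; inside an enhancer ``P(A1) = a1_fraction``
    and the total read-start rate is ``coverage_mult × background_rate``.

    Returns
    -------
    (reads, snps, truth)
        ``reads`` — a :class:`ReadSet`; ``snps`` — the informative-SNP table;
        ``truth`` — a BED-like DataFrame (chrom, start, end, name,
        a1_fraction, coverage_mult) recording the implanted regions.

    Raises
    ------
    ValueError
        For enhancers outside their chromosome or overlapping on one
        chromosome.  A chromosome that receives zero informative SNPs is
        emitted anyway with a warning.
    """
    by_name = {c.name: c for c in chroms}
    if len(by_name) != len(chroms):
        raise ValueError("duplicate chromosome names")
    enh_by_chrom: dict[str, list[EnhancerSpec]] = {c.name: [] for c in chroms}
    for e in enhancers:
        if e.chrom not in by_name:
            raise ValueError(f"enhancer on unknown chromosome {e.chrom!r}")
        if e.start < 0 or e.end > by_name[e.chrom].length:
            raise ValueError(f"enhancer {e} outside chromosome bounds")
        enh_by_chrom[e.chrom].append(e)
    for chrom, lst in enh_by_chrom.items():
        lst.sort(key=lambda e: e.start)
        for prev, nxt in zip(lst, lst[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"overlapping enhancers on {chrom}")

    ss = np.random.SeedSequence(sim.seed)
    children = ss.spawn(len(chroms) * (1 + sim.n_clones))
    child_iter = iter(children)

    snp_frames = []
    snp_arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for spec in chroms:
        rng = np.random.default_rng(next(child_iter))
        pos, a1, a2 = _simulate_snps(spec, rng)
        if pos.size == 0:
            warnings.warn(
                f"chromosome {spec.name} received zero informative SNPs", stacklevel=2
            )
        snp_arrays[spec.name] = (pos, a1, a2)
        snp_frames.append(
            pd.DataFrame(
                {
                    "chrom": spec.name,
                    "pos": pos,
                    "a1": decode_bases(a1) if pos.size else np.array([], dtype=str),
                    "a2": decode_bases(a2) if pos.size else np.array([], dtype=str),
                }
            )
        )
    snps = SnpTable(
        pd.concat(snp_frames, ignore_index=True)
        if snp_frames
        else pd.DataFrame(columns=["chrom", "pos", "a1", "a2"]),
        chrom_lengths={c.name: c.length for c in chroms},
    )

    blocks: dict[tuple[int, str], ReadBlock] = {}
    for clone in range(sim.n_clones):
        for spec in chroms:
            rng = np.random.default_rng(next(child_iter))
            pos, a1, a2 = snp_arrays[spec.name]
            blocks[(clone, spec.name)] = _simulate_block(
                spec, enh_by_chrom[spec.name], sim, pos, a1, a2, rng
            )
    reads = ReadSet(blocks=blocks, read_length=sim.read_length, n_clones=sim.n_clones)

    truth = pd.DataFrame(
        [
            {
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "name": f"enh{i}",
                "a1_fraction": e.a1_fraction,
                "coverage_mult": e.coverage_mult,
            }
            for i, e in enumerate(enhancers)
        ],
        columns=["chrom", "start", "end", "name", "a1_fraction", "coverage_mult"],
    )
    logger.info(
        "simulated %d reads over %d chromosome(s), %d clones, %d SNPs",
        reads.n_reads(),
        len(chroms),
        sim.n_clones,
        len(snps),
    )
    return reads, snps, truth


def write_truth_bed(truth: pd.DataFrame, path: str) -> None:
    """Write implanted regions as BED6 with the true a1_fraction as score."""
    with open(path, "w") as fh:
        for row in truth.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.name}\t"
                f"{row.a1_fraction:.6g}\t.\n"
            )


def write_sim_config(
    path: str,
    chroms: Sequence[ChromSpec],
    enhancers: Sequence[EnhancerSpec],
    sim: ReadSim,
) -> None:
    """Record every spec plus seed as one JSON config (reproducibility sidecar)."""
    payload = {
        "chromosomes": [asdict(c) for c in chroms],
        "enhancers": [asdict(e) for e in enhancers],
        "read_sim": asdict(sim),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Backcross cohort simulator
# ---------------------------------------------------------------------------

#: Genotype codes in backcross cohorts (F1 × FVB/N: two classes only).
HOM_FVB = 0
HET_129 = 1

# Approximate mouse autosome lengths in Mb, chr1..chr19, used to lay out a
# genome-wide marker panel at a configurable mean spacing.
_MOUSE_AUTOSOME_MB = (
    195, 182, 160, 157, 152, 150, 145, 130, 124, 131,
    122, 120, 121, 125, 104, 98, 95, 91, 61,
)


def default_marker_panel(spacing_mb: float = 18.5, start_mb: float = 9.0) -> list[tuple[str, int]]:
    """A genome-wide panel of (chrom, position-bp) markers over the 19 mouse
    autosomes; the defaults yield 134 markers at ~18-20 Mb mean spacing
    (~10 cM), the classical genome-wide microsatellite design."""
    markers: list[tuple[str, int]] = []
    for i, length in enumerate(_MOUSE_AUTOSOME_MB, start=1):
        pos = start_mb
        while pos < length:
            markers.append((f"chr{i}", int(pos * 1_000_000)))
            pos += spacing_mb
    return markers


@dataclass(frozen=True)
class CrossSpec:
    """A backcross cohort design.

    ``markers`` is an ordered list of (chrom, bp); ``linked_marker`` indexes
    the causal marker; penetrances give P(affected | genotype at that marker);
    ``recomb_per_mb`` is the per-Mb recombination probability between adjacent
    markers (0.005/Mb ≈ 10 cM per 20 Mb).
    """

    n_mice: int
    markers: tuple[tuple[str, int], ...]
    linked_marker: int
    penetrance_carrier: float
    penetrance_noncarrier: float = 0.0
    recomb_per_mb: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if len(self.markers) == 0:
            raise ValueError("marker list must not be empty")
        if not 0 <= self.linked_marker < len(self.markers):
            raise ValueError("linked_marker out of range")
        for p in (self.penetrance_carrier, self.penetrance_noncarrier):
            if not 0.0 <= p <= 1.0:
                raise ValueError("penetrances must lie in [0, 1]")
        if self.penetrance_carrier < self.penetrance_noncarrier:
            raise ValueError("penetrance_carrier must be >= penetrance_noncarrier")
        if self.recomb_per_mb < 0:
            raise ValueError("recomb_per_mb must be >= 0")
        seen: dict[str, int] = {}
        for chrom, pos in self.markers:
            if chrom in seen and pos <= seen[chrom]:
                raise ValueError("markers must be sorted by position within chromosome")
            seen[chrom] = pos


@dataclass
class CrossCohort:
    """A genotyped backcross cohort with per-mouse phenotype.

    ``genotypes`` is mice × markers with values ``HOM_FVB`` (0) or
    ``HET_129`` (1); ``marker_map`` maps marker name to (chrom, pos).
    """

    genotypes: pd.DataFrame
    phenotype: pd.Series
    tumour_count: pd.Series
    marker_map: pd.DataFrame
    truth_marker: str | None = None

    def __post_init__(self) -> None:
        if self.phenotype.isna().any():
            raise ValueError("phenotypes must not be missing")
        order = self.marker_map.sort_values(["chrom", "pos"], kind="stable")
        if list(order["marker"]) != list(self.marker_map["marker"]):
            # marker_map is expected in (chrom, pos) order within chromosomes
            by_chrom = self.marker_map.groupby("chrom", sort=False)["pos"]
            if not by_chrom.apply(lambda s: s.is_monotonic_increasing).all():
                raise ValueError("marker map must be ordered by position within chromosome")

    @property
    def n_mice(self) -> int:
        return len(self.genotypes)

    def to_tsv(self, cohort_path: str, markers_path: str) -> None:
        out = self.genotypes.copy()
        out.insert(0, "mouse_id", self.genotypes.index)
        out.insert(1, "affected", self.phenotype.astype(int).to_numpy())
        out.insert(2, "tumour_count", self.tumour_count.to_numpy())
        out.to_csv(cohort_path, sep="\t", index=False)
        self.marker_map.to_csv(markers_path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, cohort_path: str, markers_path: str, truth_marker: str | None = None
    ) -> "CrossCohort":
        df = pd.read_csv(cohort_path, sep="\t")
        marker_map = pd.read_csv(markers_path, sep="\t")
        meta = ["mouse_id", "affected", "tumour_count"]
        for col in meta:
            if col not in df.columns:
                raise ValueError(f"cohort TSV missing column {col!r}")
        genotypes = df.drop(columns=meta).astype(np.int8)
        genotypes.index = df["mouse_id"]
        return cls(
            genotypes=genotypes,
            phenotype=pd.Series(df["affected"].astype(bool).to_numpy(), index=genotypes.index),
            tumour_count=pd.Series(df["tumour_count"].to_numpy(), index=genotypes.index),
            marker_map=marker_map,
            truth_marker=truth_marker,
        )


def marker_name(chrom: str, pos: int, index: int) -> str:
    return f"mk{index:03d}_{chrom}_{pos // 1_000_000}Mb"


def simulate_cross(spec: CrossSpec) -> CrossCohort:
    """Simulate a backcross cohort (F1 × FVB/N).

    Each mouse is heterozygous (129P2/FVB/N) or homozygous FVB/N at each
    marker; adjacent markers on a chromosome co-segregate except with
    probability ``recomb_per_mb × distance``; the phenotype is drawn from the
    penetrance of the genotype at ``linked_marker``.  Affected mice receive a
    positive tumour count (1 + Poisson(4), emulating multifocal disease).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_mice
    m = len(spec.markers)
    geno = np.zeros((n, m), dtype=np.int8)

    # group marker indices by chromosome, preserving panel order
    by_chrom: dict[str, list[int]] = {}
    for j, (chrom, _pos) in enumerate(spec.markers):
        by_chrom.setdefault(chrom, []).append(j)

    for chrom, idx in by_chrom.items():
        first = idx[0]
        geno[:, first] = rng.integers(0, 2, size=n, dtype=np.int8)
        for prev, cur in zip(idx, idx[1:]):
            d_mb = (spec.markers[cur][1] - spec.markers[prev][1]) / 1_000_000.0
            p_rec = min(spec.recomb_per_mb * d_mb, 0.5)
            switch = rng.random(n) < p_rec
            geno[:, cur] = np.where(switch, 1 - geno[:, prev], geno[:, prev])

    carrier = geno[:, spec.linked_marker] == HET_129
    pen = np.where(carrier, spec.penetrance_carrier, spec.penetrance_noncarrier)
    affected = rng.random(n) < pen
    tumours = np.where(affected, 1 + rng.poisson(4.0, size=n), 0)

    names = [marker_name(c, p, j) for j, (c, p) in enumerate(spec.markers)]
    mice = pd.Index([f"m{i:04d}" for i in range(n)], name="mouse_id")
    genotypes = pd.DataFrame(geno, index=mice, columns=names)
    marker_map = pd.DataFrame(
        {
            "marker": names,
            "chrom": [c for c, _ in spec.markers],
            "pos": [p for _, p in spec.markers],
        }
    )
    logger.info(
        "simulated backcross cohort: %d mice, %d markers, %d affected",
        n,
        m,
        int(affected.sum()),
    )
    return CrossCohort(
        genotypes=genotypes,
        phenotype=pd.Series(affected, index=mice),
        tumour_count=pd.Series(tumours, index=mice),
        marker_map=marker_map,
        truth_marker=names[spec.linked_marker],
    )
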