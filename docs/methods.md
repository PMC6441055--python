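# Methods

## Scope and model

The package analyses allele-specific read evidence in a two-haplotype
(129P2 × FVB/N) mouse system. Three statistical layers are implemented:

1. **Read-level haplotype assignment.** A read is informative only through
   the strain-SNPs it overlaps. Votes are collected per SNP (observed base
   equals the A1 base → A1 vote; equals the A2 base → A2 vote; anything else
   is a silent non-vote attributed to sequencing error). Unanimous votes
   assign the read; mixed votes mark it CONFLICT; no votes mark it
   NONINFORMATIVE. CONFLICT and NONINFORMATIVE reads never enter any count.
   `n_snps_seen` counts *voting* SNPs, which makes "NONINFORMATIVE iff
   n_snps_seen = 0" and "CONFLICT needs ≥ 2" both hold by construction.
2. **Window-level imbalance.** Multi-scale sliding windows are tested
   against a per-chromosome, per-clone baseline ρ (median window allelic
   fraction) with the exact conditional Poisson test — equivalently an exact
   two-sided binomial test of c₁ in c₁+c₂ trials at probability ρ, two-sided
   by the minimum-likelihood rule. Clone p-values are combined with Fisher's
   method (χ², 2k df), adjusted by Benjamini–Hochberg across all windows of
   all chromosomes and size tiers in one pass, and significant
   same-direction windows are merged into regions when overlapping or
   book-ended.
3. **Cross genetics and ASE.** Marker association in a backcross is a
   two-sided Fisher exact test per marker (the classical panels report
   linkage without naming a statistic; the choice is labelled in output
   headers). Candidate intervals are the run of markers carried by *all*
   affected mice, expanded to flanking markers; unaffected carriers do not
   exclude regions, because penetrance is incomplete. Penetrance and ASE use
   exact binomial tests with Clopper–Pearson intervals.

Assumptions: reads are independent given their origin; counts are
Poisson/binomial with no overdispersion; the baseline captures all
chromosome-scale biases (copy number, immunoprecipitation efficiency); no
mapping bias between haplotypes (no N-masked remapping is performed).

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| window sizes | 250, 500, 1000 | bp | multi-scale scan over the stated size range; the scan scheme (step = size/2, union over sizes) is this package's interpretation of a "variable size" sliding window |
| `step_fraction` | 0.5 | – | half-overlapping windows balance resolution against test count |
| `min_total` | 10 | informative reads | below ~10 reads the exact test has essentially no power and window fractions are noise; value exposed in config |
| `q_threshold` | 0.05 | FDR | standard selection threshold; region calling at 0.01 reproduces the stricter "FDR < 1%" setting |
| conflict policy | `drop` | – | conservative: a read either supports one allele or is not counted; `majority` available |
| `snp_density` | 2 | SNPs/kb | realistic divergence between distantly related inbred strains (~1 informative SNP per 500 bp) |
| `read_length` | 100 | bp | short-read single-end design |
| `background_rate` | 1.0 | read starts/bp/clone | ~100× raw coverage; per-clone sequencing depth is not dictated by any published design and is this package's default |
| `error_rate` | 0.001 | per SNP base | Illumina-scale substitution error |
| `recomb_per_mb` | 0.005 | 1/Mb | ≈ 0.5 cM/Mb, the mouse genome-wide average (10 cM ≈ 20 Mb) |
| ASE `min_depth`, `alpha` | 20, 0.05 | – | verdicts are withheld below 20 observations; alpha-based calling is this package's convention for "primarily expressed from one allele" |

## What the generator emulates — and what it does not

The simulator produces exactly the features the statistics consume:
per-haplotype copy number (read origin drawn proportional to copies, e.g.
1:2 → P(A1) = 1/3), implanted enhancer windows with their own allelic
fraction and coverage multiplier, independent replicate clones, Poisson read
counts with uniform start positions, and worst-case sequencing error (a SNP
base flips to the *other* haplotype's base, stressing conflict handling
rather than producing silent non-votes). Reads are interval + per-SNP
observed bases; no sequences, fragment-length, GC or mappability structure,
no PCR duplicates, no overdispersion between clones beyond sampling noise,
no mapping bias. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the stated generative model,
not robustness to alignment artefacts or count overdispersion in real
ChIP-seq. The backcross generator draws each chromosome's genotype vector as
a two-state Markov chain (recombination probability per interval
= rate × distance, capped at 0.5) and the phenotype from the penetrance at
the causal marker; marker informativeness and genotyping error are not
modelled. A genome-wide panel helper lays 134 markers over the 19 mouse
autosomes at ~18–20 Mb mean spacing, the classical microsatellite design.

## Numerical choices

* **Exact test.** The two-sided p-value sums all outcome probabilities not
  exceeding the observed one. The implementation locates the opposite-tail
  cut point by bisection on the unimodal pmf (O(log n) pmf evaluations,
  vectorised over windows) and adds the two tail masses from `binom.cdf`/
  `binom.sf`. Outcomes are admitted with a relative tolerance of 1e-12 so
  that mathematically tied probabilities (the mirror outcome at ρ = 1/2)
  are included despite floating-point jitter; the tests verify agreement
  with exact integer enumeration to 1e-10 relative for all totals ≤ 200 at
  ρ ∈ {0.1, 1/3, 0.5}.
* **Baseline.** The median window fraction is used (not the mean): one
  aberrant window moves the estimate by at most one order statistic. The
  baseline is clamped to [1e-6, 1−1e-6]; chromosome/clone pairs without any
  qualifying window are skipped with a logged reason. The default baseline
  is per clone; a pooled-clone variant is a flag.
* **Combination.** p-values are floored at 1e-300 before taking logs (with
  a warning); the combined p is referred to the χ² upper tail with even df.
* **Window membership.** A read belongs to a window iff its *start* lies
  inside it — reads spanning a boundary are not double counted within a
  size tier. Windows that would extend past the chromosome end are dropped.
* **Attrition.** Windows lacking `min_total` informative reads in *any*
  clone are dropped before combination rather than imputed; counts of
  dropped windows appear in the run report.
* **Determinism.** All randomness flows from one integer seed through
  `numpy.random.SeedSequence` children spawned in a fixed order; re-runs
  are byte-identical, and results are invariant to read order and clone
  relabelling.

## Open design points resolved here

* The exact scan scheme behind a "variable size" sliding window, and the
  rule by which significant windows become region boundaries, are not fully
  specified by the motivating analysis; the multi-scale union with
  overlap/book-end merging used here is documented as this package's
  convention.
* Whether the median baseline is computed per clone or pooled is likewise
  open; per clone is the default, pooling is a flag.
* Handling of reads overlapping discordant SNPs is not specified anywhere;
  dropping them is the conservative default, majority voting the
  alternative.
* In the backcross interval logic, mice with ambiguous crossover positions
  contribute no information inside the ambiguous segment (segments are
  marker-bounded; the interval is expanded to flanking markers).

## Problem sizes

The test-suite works at reduced scale so the full run stays in tens of
seconds: 0.4–4 Mb chromosomes, 20-replicate null and linkage batches. The
acceptance script uses the study-scale setup — a 10 Mb trisomic chromosome
at ~225 informative reads per 500 bp window for the baseline target
("informative coverage" is read here as informative reads per window, since
at realistic SNP density an informative *depth* of 200× would require an
implausible >1000× raw coverage), and a three-clone 10 Mb run with one 5 kb
implanted enhancer (fraction 2/3, coverage ×5) for the recovery targets.

## Known limitations

Single-end fixed-length reads only; no FASTQ/BAM emission (SAM text can be
ingested); no input-track normalisation, peak calling or super-enhancer
annotation; no overdispersion model, so q-values on real data with
clone-to-clone variability beyond sampling noise will be anti-conservative;
Fisher's method assumes independent clones; no N-masked-genome remapping,
so reference mapping bias in real alignments is not corrected; the exact
Fisher marker scan ignores tumour multiplicity (counts are available in the
cohort table but only the binary phenotype is tested).
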