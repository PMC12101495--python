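# Methods

## Model and decision logic

`fstrack` treats fecal source tracking as a genome-resolved mixture
problem. A *source database* assigns each reference genome to a
category: fecal sources proper, an optional environmental screen
(autochthonous genomes that absorb background signal), and optional
aggregated categories whose signal is folded into a target (the
canonical case: human-specific genomes reported under wastewater).
For a metagenome with total sequenced bases `total_bp` and average
genome size `AGS`, the genome equivalents `GEQ = total_bp / AGS`
approximate the total number of genome (≈ cell) copies sequenced.
If genome *i* has mean filtered depth `X_i`, then `X_i / GEQ` estimates
the fraction of all cells carrying genome *i*, and a category's cell
fraction is the sum over its genomes. Apportionment renormalizes the
cell fractions of *present* categories to sum to one, which makes the
portions invariant to any uniform error in the GEQ — a property the
tests pin explicitly.

Presence requires two conditions simultaneously: at least one detected
genome of the category that carries no cross-reactivity flag, and a
total category fraction (specific plus cross-reactive) strictly above
the limit of detection. Cross-reactive-only signal is therefore
reported but never converts to a presence call, which is the package's
main guard against the false positives that plague profile-based FST
tools.

## Parameters, defaults, and why

| parameter | default | meaning |
|---|---|---|
| `min_identity` | 93 % | minimum read-to-genome alignment identity, `100·(aligned_len − NM)/aligned_len` |
| `min_overlap` | 70 % | minimum alignment-to-read overlap, `aligned_len / read_len` |
| `masking_percent` | 0 % | symmetric coverage trimming before the depth mean |
| `lod_percent` | 0.01 % | relative-abundance floor a category must *exceed* |
| ANI flag threshold | 95 % | cross-category pairs at or above it are flagged |
| detection rule | ≥ 1 filtered read | per-genome detection; optional minimum breadth (default 0) |

The identity/overlap/masking/LOD defaults are the tuned operating
point of this workflow's published ancestry; the 95 % ANI cutoff is
the conventional prokaryotic species boundary. Filter thresholds are
*inclusive* (a "minimum" is met at the boundary) while the LOD is
*strict* ("exceed"); both conventions are pinned by boundary tests.
Identity uses the SAM NM tag over aligned query bases (M/=/X CIGAR
columns); gap-compressed identity is deliberately not used. Only
primary alignments are consumed, so each read contributes at most one
record and multi-mapping resolution stays with the aligner. Paired
mates are treated as independent reads.

The tuning grid defaults to identities {85…99} × overlaps
{30,50,70,90} × maskings {0,25,50,75} × LODs {0.1…0.00001} — 640
combinations bracketing the default operating point; every axis is
overridable. The objective ranks by NPV, breaking ties by higher
sensitivity, then higher specificity, then the parameter tuple, which
makes the ranking a total deterministic order. Filtering is computed
once per (identity, overlap) pair and depth once per masking value; a
test asserts equality with the recompute-everything loop.

## Numerical choices

* **Depth** is accumulated with a per-genome difference array
  (+1/−1 at alignment bounds, 0-based half-open after conversion from
  SAM 1-based closed), then cumulative-summed — exact and linear-time,
  and checked against a naive per-base array oracle. Masking `m`
  drops `⌊L·m/200⌋` positions from each end of the coverage
  distribution before both depth and breadth (trimmed-mean semantics);
  `m = 0` reduces to the plain mean `aligned_bp / genome_length`.
  Alignments overhanging a genome end are clipped with a counted
  warning. A genome's length is the sum of its contig lengths.
* **ANI** is estimated fragment-wise: non-overlapping 1 kb query
  fragments, 15-mer shared-seed diagonals (most-seeded first, ties to
  the leftmost reference position), ungapped scoring on both strands,
  identity = matches / fragment length, fragments under 80 % identity
  discarded, ANI = mean of the rest. No indel alignment: flagging only
  needs coarse discrimination around 95 %, and the synthetic genomes
  are substitution-only. For asymmetric inputs the database builder
  flags on the max of the two directions.
* **GEQ backends**: a supplied AGS, or the median over universal
  single-copy markers of `aligned_bp_marker / marker_len`. Markers
  with zero hits are excluded from the median; all-zero is an error,
  not a zero.
* **Undefined statistics** (zero-denominator rates, constant-vector
  correlations) are reported as missing, never as 0, and missing NPV
  ranks last in tuning.
* The **calibration** of predicted against true cell fractions
  (ordinary least squares of truth on prediction) is a diagnostic
  only; it is computed during scoring and never applied to reported
  fractions.

## The synthetic benchmark

The generator emulates a spike-in mesocosm study. Genomes are uniform
random nucleotide sequences (default 20 kb) per category; engineered
*shared species* clone one genome into a second category with i.i.d.
substitutions at ≤ 5 % divergence, guaranteeing the pair sits above
the 95 % ANI flag threshold. Universal single-copy markers (default
three of 400 bp) are embedded exactly once per genome at evenly spaced
positions; the spacing and length ensure a marker can never dominate
an ANI fragment, so unrelated genomes stay below the reporting floor.
Mixtures are specified by cell densities and volumes and reduced to
fractions by the mesocosm mixing equations; reads (default 150 bp,
constant Phred-33 quality) draw their origin genome proportional to
cell fraction (uniform within category; a geometric-skew option
exists), position and strand uniformly, with i.i.d. substitution
errors only — so the truth SAM has all-M CIGARs and analytically known
NM tags and the pipeline runs without an external aligner. All
randomness flows from one seed; outputs are byte-reproducible, and SAM
and TSV outputs record the seed in header comments (FASTQ has no
header field, so it carries none).

Because genomes are equal-length and copies uniform, read proportions
equal cell fractions exactly, which is what makes recovery checks
sharp. What the simulator does *not* model — real rank-abundance
skew inside sources, incomplete databases, indels, chimeras, quality
variation, mis-mapping — bounds what passing tests show: they validate
the decision logic, normalization and arithmetic, not performance on
real environmental metagenomes. Database-ablation helpers emulate the
aligner's behaviour for genomes missing from the database (reads
either fail to align or re-place onto a near-identical relative with
NM recomputed against the new target), which is how the
false-negative and environmental-screen ablation directions are
exercised.

## Problem sizes

The test suite and acceptance script use 20 kb genomes, 6–8 categories
of 2–4 genomes, and 2×10⁵-read samples for end-to-end recovery (1–2×10⁴
for plumbing tests); these sizes give per-genome coverages and marker
hit counts deep enough that recovery tolerances (portions within 10 %
relative, GEQ within 10 %) are comfortably met, while a full run of
suite plus acceptance completes in a couple of minutes on one CPU.

## Known limitations

* The ANI estimator is substitution-oriented; genomes differing by
  large indels or rearrangements will under-align (fragments fail the
  identity floor) rather than report a lower ANI.
* Masking interpretation (coverage-extreme trimming) only matters on
  the tuning grid; the default operating point is 0 %.
* Detection defaults to "any filtered read", which is permissive; on
  shallow real data a minimum-breadth rule is advisable and supported.
* Aggregated categories are wholly cross-reactive by construction; a
  per-genome aggregation rule is not supported.
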