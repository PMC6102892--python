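# Methods

## Model

`strexpand` screens a genome for STR loci whose repeat content in a test
sample is an outlier relative to control samples, using the count of reads
that are almost pure repeat as the signal.

**Canonical repeat units.** Two repeat units describe the same tract if one
is a circular permutation of the other or of its reverse complement.  Each
equivalence class is represented by its lexicographically smallest member;
units expressible as k ≥ 2 copies of a shorter unit are reduced to their
primitive root (`canonical_unit("ATAT") == "AT"`, making the function total
rather than filtering periodic units at the set level).  Enumerating
lengths 1–6 yields 2, 4, 10, 33, 102 and 350 classes respectively — 501
canonical units, each given a decoy chromosome `STR-<unit>` of the unit
repeated in tandem to 2000 bp (configurable; the length need only exceed
the fragment size so a whole read pair can sit inside pure repeat).
Ambiguity codes (N) are rejected: annotation rows whose motif cannot be
canonicalized are skipped with a warning.

**Allocation.** Reads mapping to a decoy (primary, non-duplicate,
non-supplementary alignments only, to avoid double counting; mapping
quality is not filtered since decoy hits are inherently repetitive) are
allocated to a genomic STR locus through their mate: the mate must map
within `max_dist` (default 500 bp, matching typical insert sizes) of a
locus with the same canonical unit, measured edge-to-edge between the mate
interval and the locus (0 when overlapping), ties broken toward the
smaller start coordinate.  Hits whose mate is unmapped, itself on a decoy,
or near no matching locus are tallied per unit as unassigned, so that
assigned + unassigned exactly equals the decoy total for every unit — an
invariant asserted throughout the tests.  The mate interval is taken from
the record's mate fields plus the read length; no second pass is made.

**Normalization and outlier test.** Per-locus counts are normalized to a
median sample coverage of 100×:

    y = log2(100 · (count + 1) / median_coverage).

Across controls, each locus gets a robust location `M` and scale `σ_M`
from Huber's joint location/scale M-estimator ("Proposal 2", tuning
constant k = 1.5, normal-consistency constant κ(k) = E[min(|Z|,k)²]),
iterated from the median and normalized MAD.  The robust estimator keeps
genuine expansions present among controls from inflating the null.  A test
sample's z-score is `z = (y − M)/σ_M` with a one-sided upper-tail normal
p-value (the alternative is an excess of repeat reads; depletion is not
tested, so z ≤ 0 simply yields p > 0.5 rather than NA).  Benjamini–
Hochberg adjustment runs across exactly the loci with ≥ 1 assigned read in
the tested sample; adjusted p < α (default 0.05) is significant.  Reports
are sorted by adjusted p, ties by descending z then locus id.

**Allele size.** On simulated single-locus data the total decoy read count
grows linearly with the expanded tract length, so a least-squares line

    log2(normalized count) = β₀ + β · log2(inserted bp) + ε

is fitted and inverted for new samples:
`inserted_bp = 2^((y − β₀)/β)`; total size in units adds the reference
copy number.  The shipped default calibration
(`src/strexpand/data/calibration_default.json`, labelled synthetic) was
produced by `strexpand calibrate` on the package's own simulator — a
16×AGC / N×AGC diploid locus, N uniform on 0–500 units, 150 bp paired
reads, insert 500 ± 50 bp, 30× coverage — giving β₀ ≈ −2.52, β ≈ 1.11.
Users with different read lengths, inserts or depths should refit.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `decoy_length` | 2000 bp | decoy chromosome length; must exceed fragment size |
| `flank` (extraction) | 800 bp | widening of annotated loci when extracting candidate read pairs |
| `max_dist` | 500 bp | mate-to-locus edge gap for allocation; of the hg19 annotation only ~1% of loci have a same-unit neighbour this close |
| `tuning_k` | 1.5 | Huber clipping constant |
| `scale_floor` | 0.01 (log2 units) | minimum σ_M; without it a constant-count locus gives infinite z for one extra read |
| `alpha` | 0.05 | FDR threshold on adjusted p |
| `stride` | 1000 bp | sampling grid for median coverage |

Median coverage is the median depth on a deterministic position grid
(every `stride` bp) over non-decoy contigs or a supplied target region
(exome-style); a user-supplied value bypasses computation.  On uniform
depth the estimate is exact for any stride.

## Synthetic data generator

`strexpand.simulate` emulates what a decoy-aware aligner would emit for a
diploid locus with one possibly-expanded allele, writing SAM directly:
fragments are placed uniformly along each haplotype (flank + tract +
flank), fragment length ~ Normal(insert_mean, insert_sd) rounded and
clipped, each haplotype sequenced at half the total coverage so fragment
counts are proportional to haplotype length.  A read with ≥ 90% of its
bases inside the repeat tract (configurable) is emitted on the decoy of
the locus's unit; other reads are placed at reference-projected genomic
coordinates.  Pairs wholly inside a long tract land entirely on the decoy
and are unallocatable — reproducing the saturation that makes very large
alleles (beyond the insert size) systematically under-sized; this is
documented, not corrected.  Flanks are 1000 bp of deterministic
pseudo-random sequence keyed on the locus coordinates (identical across
samples); 1000 bp exceeds the insert mean + 4 SD, so no fragment can
escape the simulated window.

Cohort simulation adds, per sample: a uniformly covered 6 kb background
contig (`chrBG`) anchoring the median coverage; Poisson(rate 1.0 per
locus) ambient decoy read pairs whose mates localize to the locus,
emulating stray repeat-bearing reads in real data; and, for spiked
samples, the full fragment simulation.  Reference-length loci whose tract
cannot yield a ≥ 90%-repeat read are provably decoy-free and skip fragment
simulation.  Base-call errors are not modelled (they do not alter the
counting logic); the generator does not model GC bias, chimeras, PCR
duplicates, soft-clipped partial alignments, or mapping ambiguity between
similar units — so passing tests demonstrate the statistical machinery
under idealized alignment behavior, not robustness to those artifacts.

## Numerical choices

- Huber fixed point: iterate location and scale jointly from median /
  normalized MAD; tolerance 1e-6 relative to the scale, up to 200
  iterations (convergence is linear at rate ≈ 0.85 on discrete count
  data, so 50 iterations would not suffice).  When ≥ half the values are
  identical the scale equation collapses geometrically to zero; collapse
  is detected once s drops below the floor while still shrinking, and the
  floor is applied.  Genuine non-convergence falls back to median / MAD
  with a warning.
- Loci absent from the control table are still testable (annotations get
  updated): they receive `M = normalize_count(0, 100)` and the median
  control σ_M.
- Control estimation fills missing loci with raw count 0 — absence of
  decoy reads is informative, not missing data.  Internal-control mode
  includes the tested sample in its own null (no leave-one-out); the
  robust estimator tolerates a minority of expanded samples.
- Coordinates are 0-based half-open everywhere, including reports (noted
  in the report header).
- OLS calibration uses the normal equations via `numpy.linalg.lstsq`;
  residual SD uses n − 2 degrees of freedom, defined as 0 for n = 2.

## Problem sizes used in the test suite

Statistical checks run at sizes chosen to give stable pass/fail behavior
with fast feedback: null calibration uses 20-sample × 200-locus Poisson
cohorts over 20 seeds at the count-table level; spike-in recovery runs the
full SAM pipeline at 20 samples × 20 loci per seed with a 300-unit spike;
calibration/size-recovery checks use 100 simulated individuals.  The
observed type-I rate on null cohorts is far below the nominal 0.05 — the
scale floor and the discreteness of small counts make the test
conservative, which for a rare-disease screen is the right side to err on.

## Known limitations

- Allele sizes saturate near the insert size; very large expansions are
  flagged reliably but under-sized.
- Small control sets (≲ 10 samples) make singleton stray reads at
  otherwise silent loci look extreme (the scale floor bounds but does not
  remove this); larger control sets or the reference-control mode are
  preferred.
- Expansions shorter than ~90% of a read never reach the decoys and are
  invisible here (tools that genotype within-read indels cover that
  regime).
- The same-unit proximity statistics of an annotation (~1% of hg19 loci
  within 500 bp of a same-unit neighbour) bound the opportunity for
  mate misallocation; loci violating it can exchange reads.
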