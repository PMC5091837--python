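# Methods

This note records the models implemented by `satrep`, the defaults and the
reasoning behind them, what the synthetic data does and does not emulate,
and the numerical conventions. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and annotation

All intervals are 0-based half-open internally; conversion happens only at
parse/write boundaries. The UCSC `rmsk` table dialect is read as-is
(`genoStart`/`genoEnd` are already half-open); RepeatMasker `.out` rows
(1-based inclusive, `C` for the minus strand) are converted on input. The
family unit is the repName column by default, because satellite families
(major, minor) are distinguished at that level; a repClass-level grouping
is exposed behind `level="class"` for the coarser LINE/SINE categories,
since enrichment summaries in this field mix both units and the correct
unit for a given figure-style analysis is the analyst's choice. Overlapping
instances are kept verbatim — the concatenation procedure this mirrors
never merges annotation.

## Repeat genomes

A family's repeat genome is the concatenation of its instance sequences
separated by an `NNNNN` spacer. With ungapped alignment and N counted as a
mismatch on either side, a 5-N spacer guarantees at least
`min(left_overhang, right_overhang, 5)` mismatches for any read laid across
a junction; reads overhanging a boundary by ≥ 5 nt on each side therefore
can never map at ≤ 4 mismatches, which is the property the spacer exists to
enforce. Because a spacer shorter than the read length cannot block reads
that overhang by less than the allowed mismatch count, the builder emits a
warning when `spacer_len < max_read_length` is declared.

Minus-strand instances are reverse-complemented by default
(`reverse_complement_minus`), so all segments read in repeat-consensus
orientation; the original construction is silent on strand, so the literal
`as_plus` policy is selectable and the choice is recorded in the segments
sidecar. The offset→source index (`map_offset`) inverts the construction
exactly, including the strand flip, and labels spacer positions as such.

The 120-nt minor-satellite consensus is shipped as a constant and appended
via `add_consensus` as a named segment after one spacer, reflecting the
manual addition used when assembly annotation under-represents centromeric
sequence.

## Alignment and hit counting

The production path is any SAM-emitting aligner run against the
repeat-genome FASTA. The internal aligner exists so the test loop closes
without external binaries: it is ungapped, scans every offset in both
orientations, counts every N as a mismatch, and breaks ties by fewest
mismatches, then forward orientation, then smallest offset. A batched
implementation (one-hot match counting over all offsets) returns
mapped/unmapped flags for whole libraries; tests pin its agreement with a
literal per-offset scan.

"Hits" count distinct read ids with at least one reported alignment, never
alignment records: record-level counting would depend on the aligner's
report mode, while read-level counting is invariant to it. A read may
count in several families (each family is aligned independently); no
reassignment is attempted, matching the per-family alignment procedure.
Fold enrichment divides per-library hit fractions (library-size
normalisation); a raw-ratio mode exists behind `normalized=False` for
pipelines that assumed equal library sizes. The 95% CI uses the
two-proportion log-ratio normal approximation
`exp(log f ± 1.96·sqrt(1/h_c − 1/T_c + 1/h_i − 1/T_i))`; the CI is the
package's addition — the fold-enrichment summaries it mirrors report
none — and zero input hits yield an explicit "undefined" flag rather than
a number.

## Chromocentre counting

Only the 2.75-px equivalent-radius rule is inherited from the instrument
analysis this reproduces; the segmentation itself is this package's
design, as the instrument's internal algorithm is proprietary. The
pipeline is deterministic: Gaussian smooth (σ = 1 px) → per-nucleus
background (median within the nuclear mask; mean selectable) → threshold
at background × 1.3 → 8-connected components → one spot per component.
Smoothing plus a low threshold dilates the detection footprint of a sharp
spot by roughly the blur width, so each component's area is re-measured on
the unsmoothed image at half amplitude (midpoint between background and
the component's peak): for a sharp-edged spot the half-amplitude contour
sits at the physical edge, making the equivalent radius `sqrt(area/π)`
track the true radius instead of the blurred footprint. The radius filter
is strictly `> 2.75` px, reading the rule literally. The nuclear mask is
an input; without one, Otsu thresholding of the whole image stands in,
assuming single-cell crops as produced by imaging flow cytometry.

Count distributions are compared with Pearson's chi-squared on the 2×k
table of per-cell counts. Count values observed in neither arm carry no
information and are dropped; tail bins (lowest and highest values) are
pooled until every tail expected cell reaches 5 (Cochran's rule) —
interior cells cannot be fixed by tail pooling and are left as-is. A table
that collapses below two columns raises a degenerate-table error.

## qPCR quantification

ΔΔCt uses amplification efficiency 2.0 (perfect doubling) since no
efficiency calibration is available; it is a parameter everywhere.
Replicates are paired by replicate index; the summary fold is
`E^(−mean ΔΔCt)` — the geometric mean of replicate folds — so
vehicle-vs-vehicle is exactly 1, with the SEM reported across replicate
folds. Spike-in normalisation is handled by using the spike as the
reference target; the arithmetic is identical, so there is no separate
code path.

Percent input first adjusts the input Ct for its dilution
(`Ct' = Ct_input − log_E(1/fraction)`), then
`100·E^(Ct' − Ct_chip)`; the no-antibody background is subtracted on the
percent scale (not the Ct scale) and the result floored at zero. The input
dilution fraction has no silent default — it is a required argument.
Histone-mark levels are normalised to total H3 as a ratio of percent-input
values, undefined (NaN) when H3 is zero.

Decay fits minimise least squares for `y = A·e^(−kt)` (optionally `+ C`)
with `scipy.optimize.curve_fit`, bounds `A, k, C ≥ 0`, parameter/function
tolerances 1e-8, initialised from the earliest observation (A), a
log-linear regression slope (k, clipped at 0) and `min(y)` (C). A fit
pinned at the `k ≥ 0` bound (k < 1e-8) is flagged "no decay" with infinite
half-life. The 2-parameter model is the default; the plateau variant
covers transcripts with a stable fraction.

## Synthetic data

The generators define the study conditions for all tests. Defaults:

- **Toy genome** — two satellite-like families of 4 instances each
  (consensus lengths 140–160 and 110–130 nt, 5% per-base divergence, 30%
  of instances embedded on the minus strand) separated by 11-kb random
  background (~100 kb total). The repeat fraction is kept below ~1% of
  valid read-start positions deliberately: the generative model multiplies
  region weights by the enrichment factor e, so the ChIP/input
  hit-fraction ratio equals `e/(qe + 1 − q)` for repeat fraction q and
  approaches e only in the dilute-repeat limit. At q ≈ 0.5% the residual
  attenuation is under 1% even at e = 3, well inside counting noise at
  100,000 reads.
- **Reads** — 100,000 reads per library, 36 nt (typical of the
  single-end ChIP-seq era this emulates), substitution error rate 0.002,
  both strands sampled equally. Substitution-only errors, no indels: the
  test aligner is ungapped, and indel realism belongs to the external
  aligner path. The truth table records each read's origin interval; a
  read is attributed to a family only if it lies entirely within an
  instance. For estimator-calibration studies the generator can skip
  sequence assembly (`with_sequences=False`) — origin sampling is
  identical, only the per-read strings are omitted.
- **Nucleus images** — 192×192 px, elliptical mask (semi-axes 42% of the
  frame), background 50, spot intensity 200, spots as uniform disks with
  centres rejection-sampled at pairwise separation ≥ r_i + r_j + 6 px so
  thresholded components stay disjoint after smoothing; infeasible
  packings raise an error after bounded retries. Optional Gaussian image
  noise.
- **Ct tables** — reference Ct ~ N(20, sd), target vehicle Ct ~ N(26, sd),
  treated-condition target shifted down by `log_E(fold)`; sd 0.1 cycles,
  6 replicates.

What passing tests on these data do **not** show: robustness to indels and
quality-dependent errors, GC/fragmentation bias, PCR duplicates, real
satellite higher-order repeat structure (toy consensi are i.i.d. random,
so cross-family homology is absent), out-of-focus or overlapping
chromocentres, intensity gradients across nuclei, or primer-efficiency
deviations from 2.0. Those belong to the external-aligner and real-data
paths.

## Problem sizes and determinism

The acceptance-scale checks use 1,000 random alignment pairs (references
up to 2 kb), 10,000 boundary-spanning plus 10,000 within-instance reads,
100 replicates of 100,000-read library pairs per enrichment setting
(1, 1.2, 1.9, 3), 200 synthetic nuclei with 0–25 spots of radii
{2, 3, 4, 6} px, 500 random 2×k contingency tables, and 50 noisy decay
replicates — sizes at which every check's sampling error is far below its
acceptance margin. All randomness flows through
`numpy.random.default_rng` with explicit seeds; the same seed reproduces
outputs byte-for-byte.
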