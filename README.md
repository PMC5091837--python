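# satrep

Analysis toolkit for quantifying protein binding and transcriptional
de-repression at mouse pericentromeric satellite repeats. It bundles, as
tested reusable components, the computational procedures used to study
proteasome association with heterochromatic repeats:

- **Repeat annotation** — parse RepeatMasker annotation (UCSC `rmsk` table
  or native `.out`) into a uniform 0-based half-open instance model and
  group instances by repeat family (repName) or class (repClass).
- **Repeat genomes** — concatenate every annotated instance of a family
  into a single artificial reference, instances separated by an `NNNNN`
  spacer so reads cannot align across instance boundaries; a named
  consensus (e.g. the 120-nt mouse minor-satellite consensus, shipped as
  `MINOR_SATELLITE_CONSENSUS`) can be appended manually, and every offset
  maps back to its genomic source.
- **Hit counting and enrichment** — count distinct reads with at least one
  alignment to each family's repeat genome (from any SAM/BAM-emitting
  aligner, or the built-in naive ungapped aligner for closed-loop tests)
  and compute input-normalised fold enrichment
  `(h_c/T_c) / (h_i/T_i)` with a 95% CI from the two-proportion log-ratio
  normal approximation.
- **Chromocentre counting** — segment DRAQ5/DAPI-bright nuclear spots and
  count those with equivalent radius `sqrt(area/π) > 2.75 px` as
  chromocentres; compare per-cell count distributions between conditions
  with a Pearson chi-squared test (tail bins pooled to expected ≥ 5).
- **qPCR quantification** — ΔΔCt relative expression
  (`fold = E^(−ΔΔCt)`, spike-in or Gapdh reference), ChIP-qPCR percent
  input with no-antibody background subtraction, enrichment relative to
  total H3, and exponential-decay fits `y = A·e^(−kt) (+C)` with
  half-life `ln2/k`.
- **Synthetic data** — seeded generators for toy genomes with embedded
  repeat instances, ChIP/input read libraries with a known per-family
  enrichment factor, single-nucleus images with known spot counts and
  radii, and Ct tables with known fold changes, so every stage is testable
  against ground truth without any downloads.

## Worked example

Simulate ChIP and input libraries (100,000 reads each) over a toy genome in
which major-satellite regions are enriched 1.2-fold and minor-satellite
regions 1.9-fold in the ChIP sample, then recover those factors through the
full pipeline — repeat-genome construction, alignment, hit counting,
enrichment:

```python
from satrep import simulate as sim
from satrep import build_repeat_genome, count_hits_naive, enrichment, group_by_family

genome, catalog, _ = sim.make_toy_genome(seed=1)
reads = sim.simulate_reads(
    genome, catalog,
    sim.ReadSpec(n_reads=100_000, enrichment={"major_sat": 1.2, "minor_sat": 1.9}),
    seed=2,
)
for family in ("major_sat", "minor_sat"):
    rg = build_repeat_genome(genome, group_by_family(catalog)[family])
    chip = count_hits_naive(reads.chip, rg, max_mismatches=2)
    inp = count_hits_naive(reads.input, rg, max_mismatches=2)
    res = enrichment(chip, inp)
    print(f"{family}: fold = {res.fold:.2f} "
          f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), "
          f"hits {res.hits_chip}/{res.hits_input}")
```

prints

```
major_sat: fold = 1.23 (95% CI 1.09-1.40), hits 538/437
minor_sat: fold = 1.78 (95% CI 1.57-2.01), hits 707/398
```

Both confidence intervals cover the generative enrichment factors: at this
library size the pipeline resolves modest (1.2–1.9-fold) satellite
enrichment above input, with hit counts of a few hundred per family driving
the interval widths.

A `satrep` command-line tool exposes the same stages
(`satrep annot parse`, `satrep build`, `satrep count`, `satrep enrich`,
`satrep spots`, `satrep spots-compare`, `satrep qpcr rel|decay`,
`satrep sim genome|reads|images|qpcr`); run `satrep --help` for details.

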