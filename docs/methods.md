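# Methods

## Model and assumptions

mixscan infers subgenome structure in an allopolyploid from the mapping
behaviour of parental short reads on the hybrid assembly. The underlying
assumptions are:

* Reads from the *true* parent of a region map there with fewer mismatches
  and gaps than reads from the other parent, producing a higher mean depth
  and a larger covered fraction. Over a whole genome this yields a bimodal
  depth distribution per parent: a high mode over the own subgenome and a
  low mode over homologous tracts of the other subgenome.
* Repetitive sequence attracts multi-mapping reads and is uninformative;
  the analysis therefore runs only on non-repetitive, non-gap positions
  ("informative positions"), provided as an include BED built from a repeat
  annotation (complemented internally) with assembly N-gaps removed.
* Homoeologous exchange splices material of one subgenome into a chromosome
  of the other. Inside an affected window, tracts covered by one parent
  alternate with tracts covered by the other, so *both* parents contribute
  accepted coverage to the same sub-window bins.

All coordinates are 0-based half-open internally (BED convention); GFF
input is shifted at parse time. Adjacent regions merge (bedtools-merge
semantics). Soft-masked lowercase sequence is *not* treated as repeat; only
the explicit repeat/include coordinates count.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `min_coverage` | 5× | minimum per-position depth, per parent, inclusive |
| `interval_size` | 250 000 bp | analysis window width W |
| `bin_count` | 10 | bins per window for the intermixing index |
| `bin_min_frac` | 0.10 | minimum bin covered fraction for presence |
| `coverage_band` | 0.25 | relative band of the normalized bin-depth comparison |
| `interval_min_positions` | 1000 | minimum informative positions per window |
| `interval_min_covered` | 1000 | minimum union-covered positions per window |
| `interval_min_covered_frac` | 0.10 | union-covered / informative minimum |
| `assign_max_jaccard` | 0.2 | J ceiling for unequivocal window assignment |
| `gene_assign_max_jaccard` | 0.5 | J ceiling for the gene-oriented rule |
| `assign_min_frac` | 0.5 | coverage fraction a parent must exceed |

Depth counts alignments that are mapped and not secondary (SAM flags 0x4,
0x100 excluded); duplicate-marked and supplementary records are kept. A
position is covered by an alignment when a reference-consuming CIGAR block
(M/=/X) spans it; deletions and splices advance the reference without
covering. No MAPQ filter is applied. The expected own-subgenome depth band
(roughly 15–45× after downsampling parental libraries to 10–15× of the
hybrid genome) is a diagnostic expectation, never enforced.

## Numerical choices

* **Sufficiency union clause.** "At least 1000 covered positions" counts
  positions covered by *either* parent (the least restrictive consistent
  reading); windows failing sufficiency get J = NA and are never assigned.
* **Bin layout.** Bin width is ceil(window width / B); the terminal bin of
  a partial window may be short and uses its own informative-position count
  in the 10% filter. Bins with zero informative positions are absent for
  both parents and drop out of both union and intersection.
* **Coverage band.** After multiplying the second parent's bin mean by the
  genome-wide ratio r = μ₁/μ₂ (means over covered positions only), both
  parents survive iff the lower normalized mean is ≥ 0.75× the higher
  (boundary inclusive). The comparison is evaluated in the cross-multiplied
  form c₁μ₂ vs c₂μ₁, which makes swapping the parental declaration order
  provably bit-identical — r never has to be inverted in floating point.
* **Exclusivity.** "Exclusively covered by parent i" is per position:
  depth ≥ min_coverage from parent i and < min_coverage (or absent) from
  the other, aggregated per window before any binning.
* **Exact test.** The two-sided Fisher p is the total hypergeometric mass
  of tables (same margins) whose point probability is ≤ that of the
  observed table, accumulated in log space (`hypergeom.logpmf` +
  `logsumexp`) with a 1e-7 relative slack on the comparison to absorb
  floating-point noise. Tests cross-check it against an exact rational
  enumeration oracle and against an independent library implementation.
* **Counting unit.** Sizes entering the retention table are rounded
  half-up to integer units of `unit_bp` (default 1 Mbp), the scale at which
  sub-unit size changes are considered negligible for Gb-scale genomes.
  For the ~10-Mb-per-subgenome synthetic fixtures the analyses use a 10-kb
  unit — the same unit-to-genome ratio, preserving the count magnitudes
  (and hence the statistical behaviour) of Gb-scale tables. The default is
  deliberately left at 1 Mbp; the unit is an explicit argument.
* **Ties.** A window where both parents satisfy an assignment clause
  (possible only under the gene rule) stays unassigned, as does a gene
  spanning windows with different labels or whose best homology hits to the
  two parents tie exactly on e-value, identity and score.
* **Degenerate inputs.** Empty masks, all-insufficient genomes and empty
  tracks produce NA summaries and warnings, not crashes; a retention test
  with zero assigned material on both sides is skipped with a warning.

## Synthetic data: what it emulates, and what not

`mixscan.simulate` generates, per seed: an ancestor sequence; two parents
by independent substitutions whose per-parent rate is solved from
2p − (4/3)p² = d so the *pairwise* parent divergence matches the configured
d (default 0.05) without double-hit bias; a hybrid carrying one chromosome
from each parent, with reciprocal exchange blocks (Poisson event count,
exponential lengths, default mean 100 kb) and block deletions per subgenome;
a random repeat mask (default 20%); and per-parent depth tracks. Depth is
Poisson — mean `lambda_own` = 30× where the parent is the true origin and
`lambda_cross` = 8× over the homoeologous subgenome, thinned by dropping a
fraction `cross_dropout` = 0.6 of ~2-kb tracts entirely (diverged tracts
where cross-parent reads fail to align; this leaves the wrong parent
covering ~35–40% of positions, matching what mapping a non-parent read set
onto a hybrid typically shows). Depth is drawn once per 50-bp tile:
read-length-scale correlation, and run-length-compressible bedGraph output.

The generator reproduces the *coverage geometry* the pipeline consumes. It
does not emulate read mapping itself (mismatch-driven MAPQ/score effects),
sequencing error, indels (substitution-only divergence keeps parental
coordinates aligned, which is what makes reciprocal exchange and truth
labels trivially exact), realistic repeat families, or GC/coverage bias.
Passing recovery tests therefore demonstrates that the windowed statistics,
normalization, intermixing index and tests behave correctly given coverage
with the assumed two-mode structure — not that any particular aligner will
deliver that structure on real data. FASTQ emission and the paired-read
downsampler are provided for integration with an external mapper.

Default fixture sizes were chosen to exercise every code path at desk
scale: recovery analyses run on 10-Mb-per-subgenome hybrids (80 windows of
250 kb), the exchange-response curve at levels {0, 0.1, 0.2, 0.4} averaged
over a fixed three-seed set (individual levels differ by only tens of
exchange events, so single-run means are noisy), and the null calibration
of the retention test on 1000 replicates of equal-rate binomial unit loss
(rate 0.3) on two 1000-unit genomes.

## Known limitations

* Coverage semantics are purely positional; allele-aware separation (e.g.
  variant phasing) is out of scope, as is homoeolog expression bias.
* Windows are fixed-size and unphased; breakpoints are localized only to
  bin resolution, and single-gene conversion events are invisible to the
  coverage route (the homology route exists precisely to flag them).
* The exact test treats window assignment as if units were independent;
  spatial autocorrelation of assignment errors is not modelled.
* With more than two candidate parents, runs must be performed pairwise.
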