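# Methods

This note documents the models, conventions and design choices behind
hornmap: what each stage assumes, what the synthetic-data generator does and
does not emulate, and where the design was genuinely open.

## Trait model and study designs

The trait is autosomal dominant and fully penetrant: one copy of the causal
allele produces the affected (polled) phenotype. Three classic designs are
implemented around it:

1. **Cross-breed diversity scan** — many horned breeds genotyped on a dense
   SNP array over a candidate region; a selective sweep that predates the
   causal mutation inflates haplotype sharing in *all* breeds and defeats
   naive IBD mapping. The scan quantifies this.
2. **Paternal half-sib fine mapping** — heterozygous carrier sires with
   large progeny groups; meiotic recombinants in the progeny, classified by
   phenotype, bracket the causal position.
3. **Case/control sequencing** — whole-genome variant catalogs from
   affected homozygotes, filtered against unaffected control genomes and a
   multi-breed concordance panel.

Only the dominant model is wired into interval refinement and concordance
filtering; a recessive mode is out of scope.

## Sweep scan

* Within-breed haplotype frequencies are computed per window over complete
  haplotypes only: a haplotype with a missing allele anywhere in the window
  is excluded from numerator and denominator. Upstream studies impute
  missing array genotypes before phasing; this package does not impute, so
  exclusion is the only option that never fabricates data.
* The normalized statistic attaches to a single haplotype identity: it
  maximizes, over haplotypes, the across-breed mean frequency — not the
  mean of per-breed maxima. The distinction matters because the biological
  claim is about *one* haplotype shared across breeds.
* The divisor defaults to the number of panels scanned but can be pinned
  (e.g. to a fixed historical breed count) when breeds are withheld; the
  statistic is then monotone non-increasing in added breeds that lack the
  haplotype.
* Flagging uses strict inequality against mean + k·σ with the population
  (ddof = 0) SD and k = 4 by default. Strictness makes the degenerate
  all-identical scan (σ = 0) flag nothing. Window indexing is unit-step by
  default so window *i* starts at marker *i*.
* Mean and SD are computed over all windows of the scan, including any
  flagged ones; with ~10³ windows a single outlier moves μ and σ little,
  and the rule stays simple and reproducible.

## IBD segments

Identity is exact marker-wise equality of phased haplotypes; a missing
allele cannot confirm identity and breaks the run. The maximal run
containing an anchor marker (or the longest run, leftmost on ties) is
returned. For trait-homozygous cohorts both chromosomes of each animal
enter the input, which is the homozygosity assumption of the design; a
heterozygous mode simply passes one chromosome per carrier. Frequencies of
the shared haplotype in control panels exclude haplotypes with missing data
in the span; a breed with no complete haplotype reports NaN rather than a
fabricated zero.

## Recombination fine mapping

* **Founder haplotype discovery.** A founder haplotype qualifies when no
  unaffected founder matches it end-to-end. Absence from controls is
  monotone under span extension (a longer segment is at least as private),
  so qualifying haplotypes are reported at full map span; the interesting
  ranking signal is how many *affected* founders share the haplotype
  identically by descent. Results are therefore deduplicated by haplotype
  key, annotated with all affected carriers, and sorted by carrier count;
  `min_affected_carriers` (pipeline default 2) restricts to haplotypes
  shared by several affected founders, which separates the causal haplotype
  from private founder backgrounds.
* **Paternal-gamete identification.** For each descendant, the haplotype
  with fewer violations at sire-homozygous markers is taken as paternally
  inherited (a true paternal gamete has zero). Classification then uses
  only the sire's informative (heterozygous) markers.
* **Breakpoints** are carried as the pair of adjacent informative markers
  flanking the crossover plus the bp gap strictly between them. Interval
  updates use the conservative outer edge of the gap, so marker sparsity
  can never exclude the true position; the price is an interval one gap
  wider than the information-theoretic optimum on each refined side.
* **Phenotype rules.** Only validated polled/horned phenotypes count;
  scurs and unknown are logged and ignored (scurs is a distinct phenotype,
  never merged). A recombinant haplotype must be seen in
  `min_concordant_carriers` (default 2) individuals with identical
  phenotypes before it moves a boundary — single observations and
  internally discordant groups are logged and ignored. An empty interval
  raises a conflict error naming the two boundary-setting observations
  rather than resolving silently.
* Multi-breakpoint (double-crossover) chromosomes are reported but excluded
  from mapping by default; the refinement logic is only defined for simple
  recombinants. Phase errors are not modelled: input phases are trusted.

## Variant prioritization

* Subtraction identity is exact `(chromosome, position, ref, alt)`; no
  fuzzy indel matching. Left-normalization is the ingester's job. This
  keeps the operation commutative, idempotent and auditable — every input
  variant ends with a terminal disposition in the audit trail.
* "Complete concordance" is absolute by default (`max_discordant = 0`):
  one discordant call in the homozygous-affected panel removes a candidate.
  Missing calls reduce the tested count and never count either way; a
  candidate with zero informative calls is retained but flagged untested.
* Bisection selects the untested candidate nearest the current interval's
  bp midpoint (ties toward the smaller position). When the interval is the
  candidate hull and its endpoint candidates have known status — as when
  the interval ends were fixed by array markers — any interior boundary
  among 8 candidates is isolated in ⌈log₂ 8⌉ = 3 rounds; a blind search
  needs at most ⌈log₂ n⌉ + 1.
* The coverage audit is plain interval arithmetic (sort, merge, subtract)
  over covered regions and already-resolved assembly gaps.

## Coordinates and descriptors

Internally every interval is 0-based half-open (BED convention); all
printed and HGVS-style coordinates are 1-based inclusive and converted only
at the boundary. Segment lengths from coordinate pairs are inclusive:
end − start + 1. Published duplication lengths are not always consistent
with a single convention — the duplication-delins arithmetic
(212 bp replacing 10 bp) implies inclusive lengths, while one printed
80,128-bp figure for `g.1909352_1989480dup` equals end − start; this
package follows the inclusive convention throughout (80,129 for that
descriptor) and notes the 1-bp discrepancy rather than special-casing it.

## Quality control

Per-panel QC applies, in order: sample call rate (default 0.95, genotype
level), Mendelian-consistency edits (an offspring sharing no allele with a
genotyped parent at a marker has that call set to missing, logged),
marker call rate (default 0.90), optional monomorphism removal, and a
within-breed Hardy–Weinberg chi-square test (1 df) at alpha 1e-4 — a loose
default chosen to avoid over-pruning small breeds, since the appropriate
alpha depends on panel size. The pass iterates to a fixed point, which
makes the filter exactly idempotent (marker removal can shift sample call
rates and vice versa). The multi-breed pipeline removes monomorphic markers
at the dataset level instead of per breed — a marker fixed in one breed but
segregating elsewhere is informative for cross-breed comparison — and then
restricts all panels to the markers surviving QC everywhere, since the scan
and IBD lookups require one shared map.

## Synthetic data

* **Breed panels.** Each breed has its own allele-frequency spectrum
  (uniform on [0.05, 0.95] per marker by default) and a background founder
  pool (default 30 haplotypes). Sampled haplotypes are mosaics of pool
  members with a per-marker switch probability (default 0.01), which
  produces the long-range within-breed haplotype sharing that makes a
  windowed top-haplotype statistic meaningful and decays between windows
  like LD. The sweep is planted by overwriting the window with one
  haplotype shared across breeds, independently per chromosome with the
  breed's sweep frequency; when no frequencies are given they are drawn
  uniformly on [0.443, 0.885], the range reported for real horned breed
  panels. Default scale is 17 breeds × 200 haplotypes × 1,000 markers at
  3-kb spacing — the cross-breed array design at the scale of a ~3-Mb
  chromosome tip.
* **Pedigrees.** Heterozygous carrier sires share one causal founder
  haplotype (identical by descent); crossover counts per meiosis are
  Poisson (default mean 1 for the simulated segment, standing in for one
  chromosome) with breakpoints uniform in bp and no interference; maternal
  gametes are random panel haplotypes, dams unrecorded, as in a half-sib
  design. Background draws reject content equal to the causal haplotype so
  that the founder haplotype is genuinely absent from unaffected founders —
  the defining property of the design. Phenotypes follow dominance exactly,
  then flip with `phenotype_error_rate`. Defaults: 9 polled + 5 horned
  founder sires, 50 progeny each, ten being the inclusion minimum.
* **Variant catalogs.** Case lists hold the causal variant plus decoy SNVs
  at distinct positions; a chosen number of decoys is planted into 1–3
  random control sets each, the causal into none; controls also carry
  private variants. The genotype panel spans 7 breeds × 32
  homozygous-affected animals by default; the causal is homozygous
  alternate everywhere while each decoy is forced discordant in at least
  one animal, with a 2% missing-call rate.
* **What is not emulated:** coalescent genealogies, mutation-rate realism,
  genetic-map heterogeneity, phasing or genotyping error in the array data,
  genotype imputation, and calibration of the LD structure to any real
  777K panel. Passing tests therefore demonstrate correctness of the
  *operations* under a faithful but idealized population model, not
  population-genetic realism; on real data, phase errors and imputation
  artifacts would add noise these tests do not exercise.

## Problem sizes and determinism

Simulation-backed tests run at reduced scale chosen to keep the full suite
fast while leaving each property overwhelmingly determined (4–5 breeds,
60–100 haplotypes, 300 markers, 50–100 seeds); the sweep-recovery
acceptance check runs at the full 17 × 200 × 1,000 design. All randomness
flows through numpy Generators seeded from scenario fields; the pipeline
expands one global seed into per-stage substreams, so re-running an
unchanged configuration reproduces byte-identical primary artifacts, and
every reported number is recomputed at run time by
`scripts/acceptance.py`.
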