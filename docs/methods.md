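# Methods

## Coordinates and formats

Internal coordinates are 1-based, fully closed; `length = end − start + 1`.
This is the convention under which a read-depth call spanning
136,813,001–136,815,100 has length exactly 2100 bp, consistent with the
caller's 100 bp bin grid. BED is the only 0-based half-open surface, and the
conversion (`bed_start = start − 1`) happens exactly at the I/O boundary, so
read∘write is the identity on all written fields. Chromosome names are
opaque labels — no "chr" normalization is applied, matching the numeric/BTA
naming of bovine assemblies. Parsers never silently drop lines: every line
is a record, a comment, or an error naming the file and line number.

## Coverage QC

Fold coverage is `Σᵢ rᵢ / d` over aligned reads; with one read length per
sample this is `N·r/d`. The exclusion rule is strict: samples *below* the
threshold (default 7×) are dropped, so a sample at exactly 7.0 is kept.
Alignment-rate and properly-paired percentages are carried through to the QC
report but never auto-exclude, since no defensible universal threshold
exists; a study that wants one can filter the QC table.

## Consensus validation

Read-depth calls are the baseline; split-read calls are the validator. The
only same-CNV criterion used anywhere in the package is the breakpoint
tolerance rule: same chromosome, same type, `|Δstart| ≤ tol` and
`|Δend| ≤ tol`, with `tol = 100 bp` by default — the breakpoint accuracy of
a 100 bp-binned read-depth caller. With `tol = 0` the rule degenerates to
exact coordinate equality.

Length filters run before matching: read-depth calls longer than 5 Mb are
treated as alignment artefacts and removed; split-read calls must lie in
[50 bp, 5 Mb]. Boundaries are inclusive on the admissible side. The 200 bp
lower bound of read-depth calls is a property of the caller, not
re-imposed here.

Each split-read call validates at most one baseline call. Candidate pairs
are consumed greedily by smallest total breakpoint displacement
(`|Δstart| + |Δend|`), ties to the smaller baseline start. On calls
separated by more than twice the tolerance this one-to-one greedy matching
provably equals exhaustive maximum matching; the test suite checks the
equality by brute force on random small instances without the separation
guarantee.

Known-CNV flagging against a reference database considers only gain/loss
records (inversions and other classes are excluded) and matches class to
type (DUP↔gain, DEL↔loss). The default match mode is `overlap` (≥ 1 bp
intersection), which is the natural reading of "fell within or overlapped";
a strict `breakpoint` mode (both breakpoints within tolerance) is available.

## Clustering and breed-specific CNVs

Cross-sample clustering anchors members to a representative rather than
chaining transitively: calls are visited in (chrom, start, end, type) sort
order, and each call joins the first existing cluster whose *representative*
it matches, else founds a new cluster. Every member is therefore within
tolerance of one fixed interval. Under chained jitter the result can differ
from transitive closure; when distinct loci are separated by more than twice
the tolerance (as the simulator guarantees) the two rules coincide, and the
tests assert that equivalence on 1000 random instances. A sample counts at
most once toward a cluster's sharing count.

A breed-specific CNV is a cluster whose members all belong to one breed,
with at least `min_shared = 2` distinct carriers, and with *no* call from
any sample of any other breed matching the representative under tolerance —
the absence check scans all calls, not just the cluster's own members, so a
near-miss call that clustering assigned elsewhere still disqualifies.
Candidate breeds default to the five most numerous kept breeds, but absence
is checked against every breed.

Printed sharing percentages are `100·n/breed size` rounded to two decimals,
half away from zero. The breed-specific percentage for a breed uses as
denominator the clusters of that type in which the breed has at least one
member; this denominator is a declared convention, not the only possible
one. Per-sample genome-covered percentages use union semantics — overlapping
intervals count once.

## Annotation

Six consequence categories, ranked by severity: coding_sequence >
non_coding_exon > intron > upstream > downstream > intergenic. A call
overlapping any coding exon is coding_sequence regardless of what else it
touches (multi-term calls report at top severity); inside a gene span
without exon overlap is intron. Upstream/downstream are strand-aware within
a 5 kb flank (a common annotation-tool default; no value is standard in the
literature). A call reachable from several genes takes the most severe
category, ties to the smaller gene start. Genic = {coding_sequence,
non_coding_exon, intron}. A parser for free-text location descriptions
("intron of …", "upstream gene variant of …", "start lost, coding
sequence, …") maps published annotation strings onto the same six
categories; whole-transcript amplifications of non-coding genes are treated
as non-coding-exon overlaps.

Term enrichment is a self-contained hypergeometric test over a user-supplied
gene→term map: it emulates the *role* of GO/KEGG enrichment tools without
shipping or fetching database content. Over- and under-representation tails
are computed per term, the reported two-sided p is `min(1, 2·min(tails))`,
and adjustment across terms is Benjamini–Hochberg. Bonferroni is reserved
for the genome-coverage proportion tests across breeds, where the analysis
prescribes it. The two-sided doubling rule is conservative for very discrete
tails; the null-calibration test asserts non-anti-conservativeness, not
exact uniformity.

## Test statistics

* **Count dispersion**: `χ² = Σ (Oᵢ − E)²/E`, `E` the mean count (cohort- or
  breed-wide), df = m − 1. With counts far more dispersed than Poisson the
  statistic is astronomically significant on real-scale data; that is the
  intended behaviour of the test, not a defect.
* **Kruskal–Wallis**: `H = 12/(n(n+1)) Σ Rᵢ²/kᵢ − 3(n+1)` with mid-ranks,
  df = m − 1, and the standard tie correction `1 − Σ(t³−t)/(n³−n)` applied
  by default; CNV counts are heavily tied and the uncorrected statistic is
  anti-conservative. The uncorrected variant is available behind
  `tie_correction=False` for strict formula replication. Agreement with an
  independent reference implementation is asserted to 1e-8.
* **Shapiro–Wilk**: W from Royston's approximation to the order-statistic
  coefficients (Blom scores, polynomial corrections to the two extreme
  coefficients; exact coefficients at n = 3) and Royston's normalizing
  transformations for p-values (exact at n = 3, log-based for 4 ≤ n ≤ 11,
  log-log for n ≥ 12). Valid for 3 ≤ n ≤ 5000; the variation suite
  down-samples larger length vectors with a seeded generator.
* **Multiple-proportion test**: F as given in the README; the null is
  F(l − 1, t) with t → ∞, evaluated as the chi-square of `(l−1)·F` on l − 1
  df. Proportions must lie strictly in (0, 1): a sample with no CNVs of a
  type has pᵢ = 0 and is dropped from that test with a logged warning
  rather than crashing, since the statistic's denominator term vanishes.

The variation suite applies, per CNV type: count dispersion across all kept
individuals and within each breed; Kruskal–Wallis on counts across breeds
and on lengths across individuals and across breeds; Shapiro–Wilk on pooled
lengths; and the proportion test within each breed with Bonferroni across
breeds. Breeds with fewer than two usable samples are skipped with a logged
warning. By default the suite runs on validated calls (the consensus set is
the analysis substrate); `validated_only=False` switches to the baseline.

## The simulator

The toy genome is 5 × 10 Mb — small enough that full-pipeline tests run in
seconds, large enough to pack hundreds of loci. True CNV loci come in three
pools: cohort-wide shared (carriers drawn per kept sample with probability
0.8), breed-private (same draw within the breed, topped up to the
≥ 2-carrier minimum that makes a locus discoverable as breed-specific), and
individual-private. Default cohort: five breeds of 12/8/7/5/4 samples, 10
global loci, 4 breed-private loci per breed, 20 private calls per sample,
and Poisson(2) spurious read-depth calls per sample — a scaled-down version
of a cohort in which ~80–85% of loci are private to one animal. Lengths are
log-normal (median 2 kb, σ = 1) truncated to [200 bp, 5 Mb] and snapped to
the 100 bp grid. Loci are packed along chromosomes with gaps ≥ 1 kb, which
separates the breakpoints of distinct loci by more than twice the matching
tolerance; greedy clustering then equals transitive closure and
breed-specific recovery can be evaluated sharply.

Read-depth observations sit exactly on the bin grid (the bin edges are a
property of the genome, shared by all carriers); optional grid-quantized
jitter is available. Split-read observations occur with probability
`validator_sensitivity` (default 0.8) and jitter each breakpoint
independently and uniformly up to ±100 bp at base resolution — within the
matching tolerance, so a re-observed call always validates. A jitter
magnitude floor can force every jitter beyond tolerance for negative
controls. Coverage inputs are drawn so a configured number of samples falls
below the 7× cut; shared-pool carriers are drawn from the kept samples only,
so ground-truth labels stay evaluable after QC.

What the simulator does *not* model: read-level noise, caller-specific error
profiles beyond dropout/jitter/uniform false positives, overlapping or
nested CNVs, genotype (copy-number) values, pedigree structure, and
breed-level length differences. Passing recovery tests therefore shows the
post-detection machinery is correct under its stated matching model — not
that the upstream callers are accurate on real data.

Ground-truth scoring (`truth_eval`) matches cluster representatives to true
loci under the tolerance: the validated fraction is computed over true
baseline observations of kept samples (spurious calls are excluded — they
can never validate); breed-specific sensitivity is the fraction of
breed-private loci with ≥ 2 kept carriers recovered as breed-specific for
the right breed; the false-discovery proportion counts reported
breed-specific clusters matching no such locus. Recovery experiments cluster
the baseline call set: with validator dropout at 0.8 a two-carrier cluster
would lose a carrier from the validated set 36% of the time, so requiring
perfect recovery there would conflate validation sensitivity with
clustering correctness — the two are scored separately.

## Problem sizes and determinism

Default test-suite sizes: simulated cohorts of 20–36 samples on the 50 Mb
toy genome; 1000 random instances for the clustering oracle; 2000 replicates
(n = 100) for Shapiro–Wilk calibration; 500 replicates (l = 10, d = 10⁵) for
the proportion-test calibration; 100 replicate cohorts for the
between-breed null suite. Every random draw flows from an explicit seed
through `numpy.random.default_rng`; coordinates use integer arithmetic, so
simulator output is byte-identical across platforms for a fixed config, and
pipeline reruns on the same config produce identical reports.

## Known limitations

* Representative-anchored clustering depends on the canonical sort order;
  under adversarial chained jitter (loci closer than twice the tolerance) it
  can split what transitive closure would merge.
* The bundled cohort tables carry published location *descriptions*; the
  category tallies exercise the label classifier, while the interval-based
  annotator is exercised against synthetic GFF3 gene models.
* The multiple-proportion test's chi-square limit is the prescribed null; no
  exact small-sample distribution is offered.
* Reciprocal-overlap merging, >2-caller consensus, CNV genotyping and
  liftover are out of scope.
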