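# Methods

## Data model and conventions

A SNP call is one single-base substitution observed in one library: chromosome,
1-based position, reference base (`A/C/G/T/N`), alternate base, total read
depth, alternate-supporting depth, and the sample identifier. Coordinates are
1-based inclusive throughout; BED input is converted at the parsing boundary
and converted back on writing, so the conversion is an identity round trip.
Chromosome labels are normalized (leading `chr`/`BTA` stripped, upper-cased)
so `chr25`, `BTA25` and `25` compare equal. A site's identity across samples
is `(chrom, pos, alt)`: the reference base is carried but deliberately not
part of the key, so calls at unknown-reference (`N`) positions participate in
the same set algebra as ordinary calls. Multi-allelic VCF records split into
one call per alternate allele; indel records are parsed, counted and excluded
from all downstream stages. Parsers reject invariant-violating records
(zero alternate depth, inverted intervals, undeclared genotype alleles)
rather than repairing them, naming the offending line.

## Stringent filters

"At least 10 reads" is interpreted as reads supporting the *alternate*
allele, not total site coverage — the quantity the accuracy percentage is
built from — with `depth_mode="total"` available for the other reading; under
the 100 %-accuracy filter the two coincide. The exact-accuracy criterion is
implemented as the integer comparison `alt_depth == total_depth`, never a
floating-point equality. Reported percentages use round-half-up at the
conventional printed precisions (one decimal for retention/reduction, two
for mapping percentages); per-animal averages truncate the division, the
convention that reproduces the published per-animal figure from the raw
total. Per-breed averages divide by the breed's sample count taken from the
cohort metadata, never a hard-coded 6.

Filtering is a pure per-record predicate, hence idempotent and monotone:
raising either threshold can only shrink the retained set, and the
100 %-filter output is always a subset of the 90 %-filter output at equal
read-count thresholds. Tests assert both, plus equality with a naive
record-by-record scan.

## Categorization and uniqueness

For each site and breed, with `c` carriers among `n` breed samples:
*any* (`c ≥ 1`), *all* (`c = n`), and the unique variants additionally
require zero carriers in every other breed. Uniqueness is evaluated against
the **unfiltered** other-breed presence by default: a site seen in another
breed at any depth is not unique. This is the stricter reading — a
low-coverage carrier in another breed is evidence against uniqueness even if
it fails the filter — and `unique_vs="filtered"` gives the laxer one. The
implication chain (*all unique* ⇒ *all* ⇒ *any*; *all unique* ⇒ *any
unique*) is asserted as a property over random cohorts.

De-novo flagging selects filter-passing calls whose reference base is `N`.
Reference-error candidates are sites where *every* sample of *every* breed
carries the *same single* alternate allele at filter-passing quality;
discordant alternates at the position disqualify it, since a wrong assembly
base implies one true base. This all-samples-same-alt rule is this package's
explicit operationalization of reference-error screening and is labelled as
such in output.

## Candidate-gene hits

A call hits a gene when the normalized chromosomes match and
`start ≤ pos ≤ end` (inclusive on both ends — boundary behaviour is tested at
`start`, `end` and `end+1`). Overlapping genes each receive the hit. Counts
are kept per (gene, breed, age) and ranked by total with alphabetical
tie-breaking for determinism. Because per-age hit tables can be read either
as call-level events or as distinct sites, both counting modes are exported
(`mode="call"` default, `mode="distinct_site"`). The packaged 76-locus
bovine growth/development interval table is a **synthetic** schema fixture
(real gene symbols, plausible coordinates) intended to be replaced by a
user-supplied curated table.

## Exact tests

The implemented criterion is the *probability test*: the p-value is the total
conditional probability of outcomes no more probable than the observed one.
For Hardy–Weinberg, outcomes are genotype arrays sharing the observed allele
counts; the conditional probability is
`n!/(n_AA! n_AB! n_BB!) · 2^n_AB · n_A! n_B!/(2n)!`, and enumeration iterates
the heterozygote count over its feasible parity class. For differentiation,
outcomes are contingency tables sharing the observed margins, with the
multivariate hypergeometric probability
`∏r_i! ∏c_j! / (N! ∏n_ij!)`. All probabilities are computed as
log-factorials; the "no more probable" comparison uses a relative tolerance
of 1e-12 so exactly tied tables are never dropped to floating-point noise.
Monomorphic loci return p = 1 with a flag; breeds with no scored genotypes at
a locus are dropped with a warning (complete-case handling of missing
genotypes throughout).

Markov-chain estimation mirrors the classical samplers: a genotype-switching
chain (`AA+BB ↔ 2·AB`) for Hardy–Weinberg, and ±1 moves on random 2×2
subtables for contingency tables, both with Metropolis acceptance from the
closed-form probability ratios. The schedule follows the common default —
1000 dememorization steps, 20 batches of 5000 iterations — and the standard
error is the standard deviation of batch means over √batches. Chains are
deterministic given a seed. Chain-vs-enumeration agreement is asserted
within three reported standard errors, floored at the chain's Poisson
resolution (3/total iterations): below that, a tail probability smaller than
one expected hit cannot be distinguished from zero and the batch SE itself
degenerates.

Fisher's combined test is `−2 Σ ln p` against χ² with 2L degrees of freedom;
p-values of exactly zero (possible only from rounding upstream) are floored
at a configurable 1e-16 with a warning. With a single locus the statistic
reduces to the identity `p_global = p`, which is tested. No per-locus
multiple-testing correction is applied; the combined test is the global
summary.

## Phylogeny

Per-sample databases are presence/allele call sets, not genotypes, so the
distance is the Hamming fraction between site-presence vectors over the
union of filtered sites — in [0, 1], zero iff identical call sets over the
universe. Tree building is classical neighbor joining: Q-matrix
minimization, standard branch-length formulas, ties broken by the smallest
index pair so results are deterministic. A negative cherry branch length is
clamped to zero with the deficit transferred to its sister edge (preserving
the cherry's path length); final trifurcation lengths are clamped at zero.
NJ is exact on additive distances, which the suite verifies on random 5–8
taxon trees, cross-checking topology against an independent NJ
implementation. Branch support is the percentage of site-bootstrap
replicates containing the same bipartition; breed cohesion is tested as
monophyly (the breed's leaves forming a bipartition of the unrooted tree).
Likelihood tree search was deliberately not used: distance-based NJ with
bootstrap is deterministic, desk-scale, and sufficient for the clustering
question this pipeline asks; output headers say so.

## Synthetic cohort generator

The generator emulates the structure of a multi-breed RNA-seq SNP survey,
with defaults matching the study layout (3 breeds × ages 6/9/12 months × 2
replicates = 18 libraries):

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 1000 | variant sites |
| `frac_breed_unique_fixed` | 0.10 | sites fixed-alternate in exactly one breed |
| `frac_ref_N` | 0.02 | unknown-reference (`N`) sites, fixed alternate everywhere |
| `fst` | 0.3 | Balding–Nichols divergence of breed frequencies |
| `mean_depth` | 50 | negative-binomial mean reads/site/sample |
| `depth_dispersion` | 5 | NB size parameter (RNA-seq-style overdispersion) |
| `min_depth` | 0 | lower truncation of the depth draw |
| `error_rate` | 0.002 | per-read miscall probability (uniform to other bases) |

Shared sites draw an ancestral frequency uniformly on [0.05, 0.95] and breed
frequencies from `Beta(p(1−F_ST)/F_ST, (1−p)(1−F_ST)/F_ST)`; genotypes are
Hardy–Weinberg within breed; the alternate read count is binomial with
success probability `(g/2)(1−e) + (1−g/2)(e/3)`; a call is emitted when at
least one read shows the alternate. One global seed drives everything, with
per-sample substreams derived from (seed, sample id) so results do not
depend on generation order. F_ST = 0.3 for the recovery studies reflects the
strong between-breed differentiation of planted-unique-site designs; a
5000-site cohort keeps every stage comfortably within interactive runtimes.

Two consequences of this model matter for interpreting recovery results.
First, exact recovery of planted breed-unique sites requires every carrier
sample to reach the filter's read threshold; the truncated-depth option
(`min_depth=10`) realizes that regime, and it is the regime the recovery
studies use — with an untruncated NB(mean 50, size 5) about 0.6 % of
sample-site depths fall below 10 and recall drops accordingly. Second, the
Balding–Nichols draw itself occasionally realizes fixation in one breed at
"shared" sites; the categorizer correctly flags these, so recovery is scored
as 100 % recall of planted sites plus a check that every extra flagged site
is genuinely breed-unique in the simulated genotypes. The generator does
not model linkage disequilibrium, expression-level variation in coverage
across genes, mapping artifacts, or allele-specific expression — so passing
recovery tests demonstrates correctness of the set algebra and thresholds
under the stated model, not robustness to those real-data effects.

## Published-summary inputs

`breedsnp.datasets` ships the published per-breed summary numbers of the
source cohort (mapping totals in millions of reads, per-animal average SNP
counts raw and after each filter, the raw database total). They are inputs:
every percentage is recomputed through the filtering module at run time.
The per-age mapping rows were rounded independently in the source, so their
sums can sit 0.01M below the printed totals row; derived percentages use the
printed totals. The Hereford mapping table's properly-paired column is
internally inconsistent (shifted columns in the source), so no percentage is
derived for Hereford.

## Known limitations

- The pipeline consumes variant calls, not reads; alignment and pileup
  artifacts are out of scope.
- Exact differentiation tests enumerate only small tables; larger ones fall
  back to the Markov chain, whose error is statistical (reported as a batch
  standard error).
- The phylogeny treats absence of a call as informative state, which
  conflates biological absence with dropout at low depth; it is intended for
  filtered, well-covered call sets.
- The packaged candidate-gene intervals are schema stand-ins, not curated
  annotation.
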