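# Methods

## Scope and model

`pedcraft` analyses pedigrees of closed founder populations — populations
(such as Anabaptist isolates) whose present-day genetic variation traces to
a fixed, modest set of founders because essentially no new genetic material
has entered for many generations. The pedigree is a directed acyclic graph
of biological parent→child links over person records; adoptive links are
stored but excluded from analysis pedigrees. A *founder* is any person with
no recorded parents in the pedigree under analysis — a property of the
(possibly trimmed) genealogy, not of geography.

## Kinship and inbreeding

The kinship coefficient φ(i, j) is the probability that an allele sampled
at random from i is IBD to one sampled at random from j at the same locus.
We compute it with the standard recursion

    φ(f, f) = (1 + F_f) / 2                         (founder f)
    φ(i, i) = (1 + φ(father_i, mother_i)) / 2
    φ(i, j) = (φ(father_i, j) + φ(mother_i, j)) / 2  for id(i) > id(j),

with founders contributing zero cross-terms. The inbreeding coefficient
F_i is the kinship of i's parents (an assigned value, default 0, for
founders). Recursing always on the higher-numbered member is well-founded
only on an *ancestor-first* numbering (every parent id smaller than every
child id), which is why `renumber()` is a prerequisite: it performs a
stable Kahn topological sort (ties by ascending original pid, spouse
placeholders ordered after originals among simultaneously ready nodes) and
completes every one-parent person with a placeholder mate so downstream
tools can assume zero-or-two parents. Results are memoized per context;
`exact=True` switches the arithmetic to `fractions.Fraction` for
verification on small pedigrees.

## Relative founder representation

The RFR of founder f in descendant d is the expected proportion of d's
alleles inherited IBD from f: RFR(f, d) = 2·φ(f, d), evaluated with **all
founder inbreeding forced to zero**. Founders' ancestors are outside the
genealogy by definition, so the Mendelian-sampling expectation must not be
mixed with a founder's internal IBD — otherwise a fully inbred founder
parent (2φ = 1.0) would out-weigh its non-inbred spouse; the RFR of any
parent in any offspring is 0.5. Consequently, for every descendant, RFR
summed over the founders of its ancestor closure is exactly 1; we enforce
this at 1e-9 in `rfr_table` and report a deficit when the supplied founder
set is incomplete. Mean RFR per founder averages over the full descendant
set (so the means again sum to 1), and the ranked cumulative curve answers
"how many founders account for share q of the gene pool"
(`count_for_threshold`: smallest k with cumulative share ≥ q, ties in the
ranking broken by ascending pid).

## Founder trimming

A nuclear family at the top of the pedigree whose two parents are both
founders and have exactly one child — and no child by anyone else — is
collapsed: the child replaces the parents as a *trimmed founder*, since it
carries all genomic information derived from them. The no-other-child
condition is what makes the replacement lossless for a remarried founder.
All eligible families are collapsed simultaneously within a round; rounds
repeat to the fixed point, and a child made parentless in one round may be
collapsed in the next. Trimming conserves representation: for the
collapsed couple (f, m) and child c, RFR(f,d) + RFR(m,d) before equals
RFR(c,d) after, for every surviving descendant d; per-descendant
normalization is unchanged.

## Birth-year imputation

Missing birth years are imputed leaf-upward with a generation interval G
(default 25 years): a person lacking a year whose children include at least
one known *or already-estimated* year receives (minimum such child year)
− G, flagged as estimated. Processing in reverse ancestor-first order
resolves children before parents, so estimates chain through estimated
oldest children; known years are never overwritten. The interval can be
re-calibrated on any dataset with `generation_gap`, which measures the
parent-to-oldest-known-child year difference (founder parents only by
default). Estimates are monotone in G and always respect parent ≤ oldest
child − G.

## Affiliation prediction

Group-membership flags in genealogy sources are often recorded on only one
member of a family record, so membership of an individual is inferred from
relatives. A rule list partitions birth years into cohorts; each rule names
the relative sets to inspect (self, parents, grandparents, spouses,
spouses' parents — spouses being co-parents of at least one child). The
prediction is positive iff any inspected record carries the flag; it is
therefore monotone in the flag set. The shipped default has three cohorts:
through 1971 (self, parents, spouses), 1972–1986 (adding spouses'
parents), and 1987 onward (self, parents, grandparents, spouses).
Individuals with unknown birth year fall back to the earliest-cohort rule.

## Consanguinity statistics

Couples are pairs sharing at least one child. A marriage is consanguineous
when the spouses' kinship exceeds 0 (any detected relationship; no
threshold). Cohort rows report couple count, mean, and 25/50/75th
percentiles of kinship (linear-interpolation percentiles, stated for
reproducibility), with the cohort indexed by the earlier-born spouse's
known-or-estimated year by default (`index_spouse="later"` available);
couples with no usable year fall outside the bins but still count in the
overall consanguineous fraction.

## Gene-dropping

The analytic coefficients are single-locus expectations and carry no
Mendelian-sampling variance — parent-offspring and full-sib kinship are
both 0.25, yet realized parent-offspring sharing is exactly ½ in every
meiosis while full-sib sharing varies. Closed forms for these variances do
not exist for complex pedigrees, so `gene_drop` estimates them by
simulation: each founder receives two unique allele labels, and each
non-founder inherits one uniformly random allele from each parent in a
single ancestor-first sweep per replicate. Empirical RFR is the
across-replicate mean share of a descendant's two alleles tracing to a
founder (with its Monte-Carlo standard error and across-replicate
variance); empirical kinship is the mean fraction of the four cross-person
allele pairs sharing a label. Both converge to the analytic values, and the
3-SE band used in the oracle tests balances power against flakiness. One
seeded generator drives all replicates; identical seed, pedigree and
replicate count reproduce results bit-for-bit. Single-locus drops only: no
recombination or linked segments.

## Synthetic pedigrees

Real genealogy databases of this kind are access-restricted, so the test
bed is generated. The generator emulates the demographic features that
shape founder representation: a founding cohort of married couples; an
immigration schedule of new founders that declines to zero (default: a
halving schedule, emulating the near-total cutoff of genetic influx after
the early generations); sibship sizes drawn from a zero-truncated Poisson
(default mean 4 — closed, high-fertility populations have large families);
within-generation mating that avoids pairs above a kinship ceiling
(default 0.0625, first-cousin level) but relaxes with a warning when the
pool is exhausted, which is exactly how consanguinity rises in a closed
population; birth years at 25-year generation spacing from 1700 with ±3
years of jitter; and configurable missing-year (default 10%) and
affiliation-flag rates. Pids are assigned in birth order, so generated
pedigrees are already ancestor-first.

What the generator does **not** emulate: mortality and marriage-age
structure, population-specific sibship distributions, surname ambiguity,
record errors, or the scale of real databases (hundreds of thousands of
records). Passing tests therefore demonstrate correctness of the
algorithms on structurally realistic closed-population pedigrees, not
demographic fidelity to any particular population.

## Numerical and design choices

- Floats throughout; RFR normalization checked at 1e-9; exact rational
  mode available for verification.
- LINKAGE output is the 5-column pre-makeped skeleton (family, individual,
  father, mother, sex with 1/2/0 codes, 0 the missing-parent sentinel),
  rows ancestor-first; extra columns are accepted and ignored on input.
  Half-specified parent pairs are rejected on both sides.
- `subset` tie-breaks prefer couples over single ancestors, then the
  smallest pid; `asp` measures distance in parent→child edges, uses the
  minimum over the two members of an ancestor couple (including all paths
  of that length from either member), and marks spouse-completion persons,
  which enter as founders of the output.
- Problem sizes in the test suite: property sweeps use 3–5-generation
  pedigrees of roughly 30–700 persons (200 pedigrees for normalization, 50
  for trimming conservation, 10,000 gene-drop replicates), sizes at which
  the exhaustive and Monte-Carlo oracles are exact or tight while the whole
  suite stays fast.

## Known limitations

- Autosomal kinship only: no X-linked/mitochondrial coefficients, no
  condensed identity (Jacquard) states.
- `average_r` averages over the full supplied descendant set (including
  descendants unrelated to the founder), which is what makes per-founder
  means sum to 1 across the closure.
- The trimming rule is the founder-couple/only-child rule only; general
  marker-informativeness pruning is out of scope.
- Performance targets desk-scale pedigrees (10^2–10^4 persons); the
  recursion is memoized but not vectorized for millions of records.
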