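# pedcraft

Pedigree analytics for closed founder populations.

Medical-genetics studies of population isolates (Amish, Mennonite,
Hutterite and similar communities) rest on large written genealogies in
which tens of thousands of living individuals connect into a single
multi-generation pedigree descending from a modest set of founders.
`pedcraft` provides the computational toolkit for working with such
pedigrees: storage and validation, the classic query catalog (ancestry and
descent closures, founder identification, living/age filters, maximal
common-ancestor subsets, all-shortest-paths connecting pedigrees), kinship
and inbreeding coefficients, relative founder representation, recursive
founder trimming, ancestor-first renumbering, birth-year imputation,
affiliation prediction, consanguinity statistics, and a gene-dropping
simulator — exercised on synthetic closed-population pedigrees generated by
the package itself.

## The quantities at the core

- **Kinship coefficient** φ(i, j): the probability that an allele sampled
  at random from i is identical by descent (IBD) to an allele sampled at
  random from j at the same locus, computed by the standard recursion
  φ(i, j) = [φ(father_i, j) + φ(mother_i, j)]/2 on an ancestor-first
  numbering (parents always carry smaller ids than children), with
  φ(f, f) = (1 + F_f)/2 for founders.
- **Inbreeding coefficient** F_i = φ(father_i, mother_i).
- **Relative founder representation (RFR)**: the expected proportion of a
  descendant's alleles inherited IBD from a given founder — twice the
  founder-descendant kinship, computed with founder inbreeding forced to
  zero. For every descendant the RFRs over the founders of its ancestor
  closure sum to 1; ranking founders by mean RFR yields the cumulative
  curve that quantifies how closed a population is ("k founders account
  for share q of the gene pool").
- **Gene-dropping**: Monte-Carlo segregation of distinct founder alleles
  through the pedigree, giving empirical RFR/kinship estimates and the
  Mendelian-sampling variance that the analytic expectations cannot express
  (parent-offspring sharing is exactly ½ every meiosis; full-sib sharing
  varies, though both kinships are 0.25).

See `docs/methods.md` for the full model description, defaults, and
limitations.

## Worked example

The five-person example pedigree has a married founder couple (pids 1, 2)
whose only son (3) marries a female founder (4); their only son is 5.

```sh
$ pedcraft kinship --ped fig1.linkage --i 1 --j 5
0.125
```

Grandparent-grandchild kinship is 1/8, so founder 1's representation in
person 5 is 2 × 0.125 = 0.25:

```sh
$ pedcraft rfr --ped fig1.linkage --descendants ids.txt   # ids.txt: "5"
founder_pid	mean_rfr	cumulative_share
4	0.5	0.5
1	0.25	0.75
2	0.25	1
```

Founder 4 is a parent of 5 (RFR 0.5); the three founders together account
for all of person 5's expected genome (cumulative share 1). Trimming
collapses the two top only-child nuclear families in two recursive rounds,
leaving a single trimmed founder:

```sh
$ pedcraft trim --ped fig1.linkage
rounds	2
trimmed_founders	1
FAM 1 0 0 1
```

Gene-dropping 10,000 replicates confirms the analytic RFR of founder 1 in
person 5 and measures its Mendelian-sampling spread:

```sh
$ pedcraft genedrop --ped fig1.linkage --reps 10000 --seed 42 --founder 1 --descendant 5
n_reps	10000
seed	42
empirical_rfr	0.24735
mc_se	0.002499984548
variance	0.06249922742
```

The estimate 0.24735 ± 0.0025 brackets the expected 0.25; the nonzero
across-replicate variance is the grandparental sampling noise that is
exactly zero for a parent-offspring pair.

The same operations are available as library calls
(`pedcraft.KinshipContext`, `pedcraft.calculate_r`, `pedcraft.trim`,
`pedcraft.gene_drop`, ...); synthetic study populations come from
`pedcraft.SynthConfig` / `pedcraft.generate`.

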