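# Methods

## The problem

Obligate cave-dwelling fishes lose vision-related genes once they no
longer need sight: purifying selection on those genes is relaxed, and
loss-of-function (LoF) mutations — premature stop codons, frameshifting
indels, splice-site (GT-AG) disruptions, start- and stop-codon losses —
accumulate and fix neutrally. Because LoF mutations arrive at a roughly
clock-like rate once selection is relaxed, the *fraction* of a candidate
gene set that is pseudogenized carries information about *when* a lineage
moved underground. This package implements that inference chain for
amblyopsid-style data: screen coding sequences for LoF mutations,
genotype them from read support, build a per-site LoF rate model, invert
the pseudogene count for the number of generations since relaxation,
convert generations to years, and map shared losses onto a phylogeny.

## LoF screening

Observed coding sequences are compared to reference gene models in the
reference's CDS-local coordinate system (1-based, introns excised).
Deletions are gap columns in the observed string; insertions require the
gapped reference of the pairwise alignment. Five disruption classes are
called:

* **frameshift** — any indel whose length mod 3 is nonzero, reported per
  indel run;
* **premature stop** — an in-frame stop strictly before the terminal
  codon. The reading frame is tracked *cumulatively* through indels by
  reading the ungapped observed sequence codon-by-codon from its start,
  so a +1 and a +2 indel restore frame downstream, and a stop created in
  the shifted frame after an uncompensated indel is reported alongside
  the frameshift (mutation types are tallied separately);
* **splice site** — an intron donor != GT or acceptor != AG, from
  caller-supplied observed dinucleotides;
* **start loss / stop loss** — first codon != ATG, terminal codon not in
  {TAA, TAG, TGA}, both evaluated at the reference's codon positions
  after alignment (not on the longest ORF).

An `N` at any diagnostic position suppresses that call with a warning —
the conservative choice a human inspector would make. Genes are then
classified *pseudogenized* (>= 1 LoF mutation, taking precedence),
*incomplete* (truncated but clean; the truncation flag is caller-supplied
because assembly completeness is not decidable from the CDS string), or
*complete*.

## Genotyping

At a site with `a` reads supporting the LoF allele and `b` opposing it,
heterozygosity is the null: each read comes from either allele with
probability 1/2. With `n = a + b` and `k = min(a, b)`, the one-sided
cumulative binomial probability `p = P(X <= k)`, `X ~ Binomial(n, 1/2)`,
is the probability that the minor allele is real; `p < alpha` (default
0.05) calls the site homozygous for the majority allele, otherwise
heterozygous. Ties give `p >= 0.5` and are always heterozygous. Below 5
reads even `k = 0` gives `p = 0.5^n > 0.05`, so homozygous calls are
unreachable; such calls carry a `low_depth` flag rather than being
suppressed. A two-sided variant (doubling `p`) is available behind a
flag but off by default, matching the one-sided reading of the test.

## The LoF rate model

The per-site per-generation LoF rate is a multiplier on the point
mutation rate mu:

    mu_LoF = (p_FS + p_STOP + p_SS + p_SL + p_ML) * mu

* `p_STOP`: for every sense codon, all nine single-nucleotide neighbours
  are enumerated; each change is weighted kappa (transition) or 1
  (transversion) and the usage-weighted fraction of weight landing on
  TAA/TAG/TGA is taken. Stop codons are excluded from the usage vector so
  that terminal-stop mutations are not double-counted against `p_SL`.
* `p_FS = (N_FS / N_PSC) * p_STOP`: frameshifts are not modelled
  mechanistically; their rate is scaled off `p_STOP` by the observed
  frameshift-to-premature-stop count ratio. Which lineages those counts
  come from is the caller's choice — the ratio is an explicit input.
* `p_SS = 4 * introns / total CDS bp` (four GT/AG bases per intron).
* `p_ML = 3 * genes / total CDS bp` (three start-codon bases per gene).
* `p_SL = 0.852 * p_ML`, where 0.852 = 23/27 to three decimals: of the
  27 single-base changes to a stop codon, 4 yield another stop (TAA has
  two stop neighbours, TAG and TGA one each), so 23/27 destroy it. The
  constant is used as printed rather than kappa-weighted (a
  kappa-weighted average over the three stops would give ~0.79 at
  kappa = 1.76); the component is ~0.003, so the difference is below
  0.1% of the multiplier and the printed constant keeps the preset
  arithmetic exact.

Components are carried at full precision; rounding to three decimals
happens only in reports. The named preset `paper2025` ships the
published amblyopsid component values (0.046, 0.030, 0.021, 0.003,
0.003; multiplier 0.103, so mu_LoF = 1.03e-9 at mu = 1e-8), letting the
clock run without the underlying codon-usage table. Defaults:
kappa = 1.76, mu = 1e-8 per site per generation (with 0.5e-8 as the
standard sensitivity setting).

## The pseudogene clock

LoF arrival in a gene of length `L` is a Poisson process with rate
`mu_LoF * L` per generation, so

    P(pseudogenized after g generations) = 1 - exp(-mu_LoF * L * g).

Under strict neutrality the fixation rate equals the mutation rate, so
no effective-population-size term appears. Observing `D` pseudogenized
genes among `T` with lengths `L_i`, the likelihood of `g` is the
Poisson-binomial probability of exactly `D` successes with per-gene
probabilities `p_i(g)`, computed by the standard convolution recursion
(O(T^2); exact binomial fast path for equal lengths). The recursion is
run in plain probability space — at the gene-set sizes this model is
used for (tens to hundreds of genes) the convolution stays far from
underflow; log-likelihoods are floored at 1e-300 for reporting.

The ML estimate maximizes the count likelihood over `g >= 0` by
golden-section search on log g after bracketing on a 121-point log grid
spanning two decades around the equal-length closed form
`g = -ln(1 - D/T) / (mu_LoF * mean L)`. For equal lengths the numeric
optimum matches the closed form to better than 1e-6 relative. `D = 0`
sits on the boundary (`g = 0`); `D = T` has no finite maximum and is
reported as infinity with a warning. Because `mu_LoF` and `g` enter only
through their product, every estimate is *exactly* inversely
proportional to `mu_LoF`: halving mu doubles the estimate.

Two gene-set assumptions are supported, mirroring the analysis choices:
all candidate genes relaxed, or only genes pseudogenized somewhere in
the cave lineages (the caller selects which genes enter the
observation). The default likelihood uses the count `D` only; a
per-gene-indicator likelihood (product of `p_i` and `1 - p_i`) sits
behind the `use_indicators` flag. `T` is always an explicit input —
per-species denominators vary with how many genes each genome yields —
and both per-gene lengths and a single average length are accepted.

Confidence intervals invert the count distribution: a depth `g` is
accepted when the observed `D` lies inside the central 95% mass of the
count distribution at `g` (both tail probabilities above 0.025). The
count is stochastically increasing in `g`, so the accepted set is an
interval; its ends are found on a log-spaced grid with bisection
refinement. The default evaluates the tails by seeded simulation
(per-gene Bernoulli draws; direct Binomial(T, p) draws for equal
lengths), matching the simulation-based construction of the original
analysis; `method="exact"` uses the Poisson-binomial CDF instead and is
used wherever determinism matters more than fidelity to the simulation
procedure. All simulation entry points require a seed.

## Age conversion and cave-age bracketing

Years = generations x generation time, exactly; report values are
rounded to 3 significant figures, half up (so 7.5e5 x 15 = 11.25e6
prints as 11.3 Ma and 7.68e5 x 3 = 2.304e6 as 2.30 Ma). Amblyopsid
generation times are poorly known; the range 3-15 years is carried as an
explicit (min, median, max) triple, and the median is never derived
from the endpoints. A cave system's age is bracketed between the
pseudogene-clock minimum (the lineage has been underground at least this
long) and the dated-phylogeny divergence upper bound (it cannot predate
its split from surface relatives); a clock minimum exceeding the
divergence maximum is flagged as inconsistent, never clipped.

## Dollo mapping

A specific LoF allele, or a gene-level pseudogenization, is assumed to
arise once and never revert. Its origin is therefore the branch
subtending the MRCA of its carriers (the terminal branch for a single
carrier; the polytomy's branch when the MRCA is a polytomy). Gene-level
and mutation-level matrices are mapped independently. Missing matrix
entries default to absent, with a warning noting that resolving them as
present could only move the origin rootward. The homoplasy screen flags
characters whose carriers are non-monophyletic, and gene losses whose
exact allele differs among carriers — both signal independent losses
rather than shared ancestry, the signature used to argue for independent
cave colonizations. Species assignment of samples is input metadata,
never inferred.

## The synthetic-data generator

The generator emulates the data the pipeline consumes, under the study
conditions: 88 genes of 999 bp (five GT/AG introns each, matching a
splice component of 4*5/999 ≈ 0.02), mu = 1e-8, kappa = 1.76, and
2.5e5 generations of relaxed selection by default. Substitutions are
K2P-like (single rate plus ts/tv bias — exactly the two parameters the
rate model uses); indels arrive at 7e-10 per site per generation with
geometric(0.5) lengths truncated at 10 bp, so ~6/7 of indels
frameshift and the frameshift-to-stop ratio lands near the observed
46/30; splice dinucleotides mutate at the point rate; read support is
Binomial(n, 1/2) at heterozygous sites with Poisson depth (mean 20x).

Every introduced LoF event is recorded and then verified against the
final sequence by *local* codon checks (is the stop still there, still
in frame given the net upstream indel offset, not interrupted by an
insertion) — never by re-running the detector, so the
generator-vs-detector round trip remains a genuine two-route test.
Events destroyed by later mutations are dropped: the truth table
describes the emitted data. Indel placement rejects positions that
would merge or split existing gap runs, keeping truth indels and
detected indel runs in 1:1 correspondence.

What the generator does *not* emulate: selection and demography (the
clock assumes strict neutrality, so neither is modelled), segregating
unfixed LoF alleles, context-dependent (CpG) mutation rates, assembly
truncation, orthology confusion, and alignment error. Passing tests
therefore show the inference chain is correct *given* its model; they do
not validate the neutrality assumption on real data.

## Numerical and design choices

* Poisson-binomial by direct convolution; brute-force 2^T enumeration is
  the test oracle for T <= 12.
* Golden-section tolerance 1e-8 on log g (comfortably below the 1e-6
  closed-form agreement requirement).
* CI grid: 161 log-spaced points over ±2.5 decades around the
  closed-form guess, 25 bisection steps per boundary; simulation default
  1000 replicates per evaluation.
* Genotype ties are heterozygous by construction; zero-depth records go
  to a no-call list rather than erroring the whole table.
* All interchange coordinates are 1-based inclusive; conversion is
  centralized in the I/O module.
* Test problem sizes: the parameter-recovery check runs 200 replicates
  per true depth at T = 88 equal 1-kb genes with 400-replicate,
  61-point CIs; the generator calibration check averages 60 replicates
  of the full 88-gene simulation. These sizes keep each check's Monte
  Carlo error well inside the asserted tolerances.

## Known limitations

* The clock models fixed LoF substitutions only; in young cave
  populations where LoF alleles still segregate it will underestimate
  colonization age.
* `p_FS` inherits whatever ascertainment bias the observed
  frameshift/stop counts carry.
* The Dollo mapper takes presence/absence at face value: genotyping
  uncertainty does not propagate into origin assignment.
* With `D = T` (every gene lost) the clock only bounds the age from
  below; the upper bound is open.
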