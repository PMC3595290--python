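# Methods

## The measurement model

A 3′-tag DGE library is a multiset of fixed-length sequence tags. Each
transcript contributes tags only from its 3′-most `CATG` site (oligo-dT
capture followed by NlaIII digestion retains the 3′-terminal fragment;
MmeI then cuts ~17 nt downstream of the anchor), so a tag is a 21-nt
window: the 4-nt `CATG` anchor plus 17 nt of downstream transcript. Tag
*counts*, not read coverage, carry the expression signal, and no gene-
length normalisation applies: tags-per-million (TPM here means *tags*
per million clean tags, not the modern length-normalised RNA-seq TPM).

The reference ("virtual") tag index deliberately covers **all**
sense-strand `CATG` windows of every transcript, not only the 3′-most
one: real libraries contain internal-site tags from incomplete
digestion, and the permissive index converts them into (excluded)
ambiguity rather than silent mis-assignment. Antisense windows are not
indexed — oligo-dT selection implies sense-strand tags. Windows
containing `N` are skipped at index build time because `N`-containing
query tags are already removed by QC.

Assignment gives strict priority to exact matches and consults the
Hamming-distance-1 neighbourhood only when no exact hit exists. The
priority rule is the less arbitrary of the two obvious conventions: it
can only reduce false ambiguity, never create it. One mismatch absorbs
both sequencing errors and homokaryon allele SNPs relative to the
reference assembly.

## QC and the accounting ledger

Cleaning removes, in order: (1) tags containing any `N`; (2) adaptor
tags; (3) tags whose **remaining** copy number is exactly 1. The order
matters for attribution (a copy-1 tag containing an `N` is an `N` tag)
and matches the conventional row order of DGE library characteristics
tables, whose identities the `QCAccounting.validate` method enforces:

    clean = raw − N-containing − adaptor − copy-1      (totals and distincts)

Adaptor matching defaults to exact full-tag equality; a prefix mode
(shared leading stretch ≥ 8 nt) is available since truncated adaptors
are common in practice but the exact convention used in published
ledgers is generally unstated. "Low quality" is interpreted as exactly
"contains N" — no base-quality model is used. Copy-number-threshold
rows use ≥ for the first threshold (2) and strict > for the rest,
matching the printed labels they reproduce.

## Quantification

A gene's raw intensity in one library is the summed copy count of clean
tags assigned uniquely to it; ambiguous and unmapped copies are tallied
but never attributed. TPM divides by **total clean tags** (not mapped
tags). Genes with zero unambiguous tags are reported at the floor TPM
0.01 so that fold changes remain finite; the floor is applied at
reporting time only — raw zeros stay zeros and a `detected` flag marks
floored values. Whether the original convention floored before or after
normalisation is not decidable from published tables; this package
floors the reported TPM and exposes the floor as a parameter.

## The exact two-library test

For counts *x*, *y* in libraries of depth *N₁*, *N₂*, the
Audic–Claverie conditional mass p(y|x) (a negative binomial with size
*x*+1 and success probability *N₁*/(*N₁*+*N₂*)) is evaluated in
log-space via log-gamma. Tails are accumulated stably: the lower tail
as a single log-sum-exp over k ≤ y, the upper tail summed upward in
chunks of 512 until a chunk contributes less than e⁻³⁷ of the running
total *and* the summation has passed the conditional mode (terms only
decay geometrically beyond the mode, so stopping earlier would be
unsafe).

Two-sidedness doubles the smaller inclusive tail and caps at 1 — the
conservative standard for discrete exact tests. Because the conditional
mass is not exchangeable in its two libraries, the raw doubled-tail
p-value depends on which library is conditioned on (differences up to
~2× at small counts). The implementation therefore canonicalises the
orientation — it always conditions on the library with the smaller
(count, depth) pair — making `p(x,y,N₁,N₂) ≡ p(y,x,N₂,N₁)` exact by
construction while remaining the same family of doubled-tail exact
p-values. The empirical type-I error stays below the nominal level
(discrete-test conservativeness), which the suite verifies on a seeded
Poisson null of 10⁴ genes at depth 10⁶.

Significance calling: genes with raw count ≤ 40 in **both** libraries
are filtered off before testing (they get no p-value and cannot be
significant); BH step-up adjustment (via statsmodels) runs over the
tested set only; defaults are p < 0.005, FDR ≤ 0.001, |log₂FC| > 2.
The |log₂FC| > 2 default follows the stated significance rule of the
protocol this package reproduces; descriptive ≥3-fold comparisons use
`fold_classify`, which exposes the fold as a parameter.

## Strain-triad comparison

"Expressed" defaults to ≥ 1 unambiguous clean tag — the weakest
count-based rule, consistent with the 0.01-TPM floor for undetected
genes. The Venn partition is permutation-equivariant in strain order,
and the headline percentage is (total − detected-nowhere)/total × 100
rounded to 2 decimals.

Complementation categories, with TPM thresholds as parameters:

* **A** — zero unambiguous tags in parent 1 and TPM ≥ `high_tpm` (50)
  in parent 2; **B** mirrored;
* **C** — both parents ≤ `low_tpm` (20), heterokaryon ≥ `high_tpm` and
  ≥ `min_fold` (3) × both parents.

The numeric cutoffs behind "high" and "extreme low" are nowhere defined
in the protocol's source material; these defaults are declared
calibrations chosen so the published exemplar gene panels classify into
their stated categories, and they are configuration values, not facts.
Categories are mutually exclusive by construction (A/B require a
high-expressed parent, C forbids one).

## CAZyme profiling

Class totals (GH/GT/PL/CE) are sums over family columns resolved by
name prefix or an explicit map; unknown families raise with the
offending rows listed. Lineage averages round half away from zero
(the convention only matters at .5 and reproduces the published
rounded means). Genome rank is descending by grand total with ties
taking the minimum rank; per-class maxima report full tie sets.

Double clustering runs scipy agglomerative clustering independently on
rows and columns; defaults are Euclidean distance on **raw counts**
with average linkage. The published figure this mirrors names no metric
or linkage and shows a colour scale clipped at >20, which motivates raw
counts; exact dendrogram reproduction is explicitly not a contract —
leaf orders being permutations of the labels and monotone merge heights
are. Constant matrices cluster at all-zero heights and are flagged
`degenerate`; a single-row (or single-column) matrix returns that axis
as a single leaf with no linkage.

## The synthetic-data generator

The generator emulates the profiled study design: two homokaryons (P1,
P2) with SNP-diverged alleles and a heterokaryon (H) carrying both,
single-replicate libraries of millions of tags. Defaults are the
study's scale: 11,534 genes, 5.9 × 10⁶ tags per library, and an allele
divergence of 10⁻³ per base (≈ 35,000 SNPs over a ~37 Mb genome).
Where the protocol's source states no value — instrument error and
contamination rates — defaults are chosen once at realistic Illumina
magnitudes: per-base error 0.005, N-tag rate 0.003, adaptor rate
5 × 10⁻⁵, 30,000 junk singletons; silent-gene fractions 0.08 per
parent, boost fraction 0.01 with a 30× heterokaryon boost. Baseline
expression is log-normal (median 30 TPM, σ = 1.5 in log-space) with an
extra σ = 0.6 log-normal strain divergence, normalised to the TPM
scale per strain.

Emission draws per-gene counts (Poisson, or negative binomial with
variance μ + αμ² when `dispersion` α > 0 — a knob, not a fitted
quantity, since single-replicate libraries cannot identify it) from the
3′-most window of the emitting allele; the heterokaryon splits each
gene's count binomially between the two alleles. Each emitted copy may
be replaced by an N-containing or adaptor tag, or acquire per-base
substitution errors (copies drawn as erroneous are guaranteed ≥ 1
error, a negligible distortion that only shifts mass onto exactly-one-
error tags); junk singletons come from a dedicated random substream so
that noise settings never perturb the biological draws. Copy totals are
conserved exactly: gene emissions plus planted singletons equal the
library total.

Truth labels derive from the planted rates by the same definitions the
classifiers use but through entirely separate code: A requires a rate
of exactly 0 in P1 and ≥ 50 TPM in P2 (so every labelled gene is in
principle recoverable); C genes get parental rates uniform on [2, 15]
TPM, guaranteeing the boosted heterokaryon rate clears both the level
and fold conditions.

What the generator does **not** emulate: positional/sequence-dependent
error profiles, quality scores, incomplete NlaIII digestion
(internal-site tag emission), library-prep amplification bias, and
inter-replicate biological variance. Passing tests therefore show the
pipeline's logic is correct under idealised sampling noise, not that
the thresholds are optimal for any real instrument.

## Validation problem sizes

The test suite exercises the full study-scale triad (11,534 genes,
3 × 5.9 M tags) once as a shared fixture; module tests use 400–2,000
gene triads with 10⁵–10⁶-tag libraries. The Poisson null for type-I
error uses 10⁴ genes at depth 10⁶; the exact-rational oracle covers
counts ≤ 60 over 100+ random depth pairs; sampling-convergence checks
use a noise-free 2,000-gene, 4 × 10⁶-tag library, where ≥ 95% of genes
with rate ≥ 100 TPM must be recovered within 10% relative error.

## Known limitations

* The exact test assumes Poisson sampling within a library; with
  overdispersed synthetic data (`dispersion` > 0) it is anticonservative
  by design, as any single-replicate exact test must be.
* One-mismatch assignment cannot distinguish a sequencing error from an
  allele SNP; parent-diagnostic tags with ≥ 2 SNPs in the window go
  unmapped against a single-parent reference index.
* The complementation thresholds are calibrations; sensitivity near the
  50-TPM boundary is limited by sampling noise at realistic depths.
* Biclustering defaults (Euclidean/average on raw counts) are one
  defensible convention among several; conclusions that depend on exact
  dendrogram topology should not be drawn from it.
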