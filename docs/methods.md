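# Methods

This note documents the statistical conventions, the synthetic-data model,
the numerical choices, and the known limitations of `codonuse`.

## Codon universe and counting

All statistics operate on the 59-codon universe: the 61 sense codons of the
standard genetic code minus the two non-degenerate codons AUG (Met) and UGG
(Trp). Stop codons are never counted; a terminal stop on an input CDS is
stripped and recorded, an internal stop rejects the record. Codons carrying
ambiguity codes are dropped individually by default (`drop-codon`), because
rejecting a whole otherwise-clean GenBank record would discard analyzable
data; `reject-sequence` is available where stricter curation is wanted.
Sequences are stored on the DNA alphabet; published-style tables print RNA
codons.

Composition follows the CodonW convention: overall A/C/G/U% are computed
over the full CDS nucleotides, while every positional statistic (A3s–U3s,
GC1s/GC2s/GC3s, and the GC3s used by ENC and the expected curve) is
computed over synonymous codons only, so the two families excluded from
bias statistics cannot distort the positional signal. GC12s is exactly
(GC1s + GC2s)/2. Group SDs default to the population form (n divisor);
`ddof=1` is a parameter.

GRAVY uses the standard Kyte–Doolittle per-residue scale, which spans
−4.5 to +4.5. Typical proteins fall within roughly ±2, which is sometimes
reported as the index's range; no clamping is applied. Aromaticity is the
F+Y+W residue fraction.

## RSCU

RSCU_ij = g_ij · n_i / Σ_family g. Families with zero observations are
*undefined* (NaN), never zero, and are excluded from group means — imputing
zeros would bias per-codon summaries downward in short genes. Group RSCU is
the mean of per-sequence RSCU vectors (matching how published tables are
typically assembled, sequence by sequence); pooled-count RSCU is offered as
an alternative and differs whenever sequences contribute unequal family
totals. The most-used codon per family is marked per group; ties break
lexicographically and carry an explicit flag. Classification thresholds are
\>1.6 (overrepresented) and <0.6 (underrepresented), both exposed as
pipeline parameters.

## ENC

Per family, S = Σ(n_i/n)² and F = (nS − 1)/(n − 1), defined for n ≥ 2.
Families with F ≤ 0 (possible when nS = 1 at tiny n) are excluded from the
class mean with a diagnostic, following CodonW. Class means F̄_k over
k ∈ {2, 3, 4, 6} assemble ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆. When the
single 3-fold family (Ile) is absent, F̄₃ is imputed as (F̄₂ + F̄₄)/2
(Wright's correction) and the result is flagged. No analogous
interpolation exists for the 6-fold class, so a gene with no usable 2-, 4-
or 6-fold family raises "sequence too short for ENC" — real protein-coding
genes always contain Leu/Ser/Arg, so this only affects pathological
fragments. Sampling noise can push ENC slightly above 61; such values are
clamped to 61 with a flag. ENC ≤ 35 is reported as "significant bias", the
conventional cut-off.

The expected curve is ENC*(s) = 2 + s + 29/(s² + (1−s)²) with s the
synonymous GC3s fraction — the same subset as the composition module, so
plot coordinates are internally consistent.

## PR2 and neutrality

PR2 uses the five strictly fourfold families (Ala, Gly, Pro, Thr, Val) by
default; the fourfold codon boxes of Leu/Ser/Arg can be included by option,
since "four-codon families" is ambiguous for the sixfold amino acids. A
zero denominator marks that coordinate undefined rather than failing.

The neutrality fit is ordinary least squares of GC12 on GC3 with a
two-sided t-test on the slope. The mutational share is slope×100 and the
selection share is defined as its complement to 100 (published splits
occasionally do not sum to 100 because both are quoted from separate
regressions; here the complement is enforced by construction). Per-host
fits are the same operation on host-filtered subsets.

Spearman correlations use mid-rank ties; p-values come from the t
approximation (adequate for n > 10), with an exact permutation p available
for n ≤ 10 (full enumeration of rank permutations). Stars follow the usual
convention: ** for p < 0.01, * for p < 0.05, ns otherwise.

## Host tables and adaptation indices

Host tables are accepted in Kazusa style ("GCU 17.6 ( 12345)", any layout;
counts preferred over the printed per-thousand values) or as a plain
codon/count TSV. Tables are normalized to per-thousand *first*, which makes
every derived quantity exactly invariant to the overall scale of the input;
only if the normalized table contains zero-frequency codons is a 0.5
per-thousand pseudocount added to every codon. This "lazy" smoothing keeps
the two analytic identities exact on zero-free tables — RCDI = 1 for a
host-matched query and CAI = 1 for a host-preferred-only gene — while still
preventing −∞ logarithms against sparse references.

* CAI = exp(Σ g_c ln w_c / Σ g_c) with w_c = f_c / max(f) within the
  family; Met/Trp are excluded (their w ≡ 1 contributes nothing).
* RCDI = Σ_c (q_c / h_c) · g_c / N with q and h the query and host
  within-family relative frequencies; by the Cauchy–Schwarz inequality
  RCDI ≥ 1 with equality iff q = h family-wise.
* SiD: R(A,B) is the cosine of the two 59-dimensional RSCU vectors
  (undefined entries dropped pairwise) and D = (1 − R)/2, the dominant
  convention in the codon-usage literature; the printed equation in some
  sources is typographically ambiguous between this and 1 − R/2, so the
  latter is available behind `convention="one-minus-half"`.

Three mock host tables (GC-rich, AT-rich, balanced third-position
preferences; synthetic, not real organisms) ship as fixtures; real host
tables are user input.

## PCA

Centered, unscaled PCA (full SVD) of the n×59 RSCU matrix. Undefined
entries are imputed with the column mean, making them inert once centered;
a column undefined everywhere becomes constant and simply carries no
variance. Inertia fractions are reported for all positive-variance axes
(the effective rank depends on n and degeneracies; no fixed axis count is
forced). Axis signs follow a deterministic convention — the largest-|loading|
codon on each axis is made positive — so score tables are bit-for-bit
reproducible regardless of input order or BLAS.

## The synthetic-data generator

Each codon position is an independent draw from a two-component mixture:
with probability `w_sel` the position is *selected* (amino acid from the
composition profile, codon = the host table's preferred codon), otherwise
it is *mutational*. The mutational component has two regimes:

* **fixed-profile** (`aa_profile` given): the amino acid comes from the
  profile and the synonym is chosen by drawing the third position from the
  mutational nucleotide distribution π (restricted to the thirds the family
  offers), then uniformly among codons sharing that third. First/second
  positions are therefore controlled only indirectly, through the sixfold
  families' codon boxes. This regime holds protein composition fixed and is
  the one used for ENC/CAI/RCDI selection-response studies and for the
  GC-rich (coat-protein-like, mean GC ≈ 53%, mild host selection) and
  AU-rich (NABP-like, mean AU ≈ 54%) fixture sets.
* **neutral** (`aa_profile=None`): whole codons are drawn from π applied at
  all three positions, conditioned on not being a stop. Here GC at every
  position tracks the mutational GC parameter, which is what the neutrality
  plot presumes; this regime generates the GC-gradient sets used to check
  that the GC12-on-GC3 slope recovers ≈ 1 under pure mutation.

Two structural facts about the neutral regime are worth recording. First,
the genetic code itself (stop-codon exclusion and the uneven GC content of
first/second positions across families) makes the asymptotic GC12-vs-GC3
slope ≈ 0.97 rather than exactly 1. Second, finite gene length adds
binomial noise to the GC3 regressor and attenuates the slope further; at
900 codons and a mutational GC grid spanning 0.2–0.8 the recovered slope is
≈ 0.96–0.98. The parameter-recovery suite therefore uses 200 genes of 900
codons, a size at which both effects together stay well inside a ±0.05
band around 1.

Selection responses are U-shaped, not monotone, for RCDI against a *diffuse*
host table: the generator's selected component emits only the preferred
codon, so pushing `w_sel` toward 1 overshoots a host that spreads its usage
across synonyms. Monotonicity of CAI/RCDI in `w_sel` is therefore tested
against the matching reference — a table concentrated on the preferred
codons (its smoothed zeros supply the off-codon mass). This is a property
of the mixture model, not of the indices. Optional synonymous noise
(`noise_rate`) resamples a codon uniformly within its family, never
changing the protein.

All randomness flows through an explicit integer seed
(`numpy.random.default_rng`); there is no global state, and fixture
generation is byte-reproducible.

What the generator does **not** emulate: phylogenetic correlation between
sequences (real isolates are related by descent, inflating effective
sample-size assumptions in regressions and correlations), indels and
recombination, dinucleotide-level constraints (e.g. CpG avoidance), and
amino-acid composition that co-varies with host. Passing tests on this
generator therefore validate the *estimators*, not any claim about real
virus data.

## Pipeline conventions

Tables print floats at 4 decimals; the headline statistics (neutrality
slope/p, correlation rho/p, PCA inertia) additionally carry full-precision
`*_raw` columns. The manifest and log echo input files by basename only, so
identical runs in different directories are byte-identical. A stage failure
writes the partial manifest with the failing stage recorded, then re-raises
(the CLI exits non-zero).

## Problem sizes used in the validation suite

Oracle-equivalence checks run 200 randomized cases per statistic against
independent brute-force reimplementations at 1e−9. Parameter recovery uses
200 genes × 900 codons (neutrality) and 5 selection levels × 100 replicates
× 300 codons (monotonicity); these sizes give comfortable statistical
resolution while keeping the whole suite in the tens of seconds.

## Known limitations

* ENC is undefined for fragments lacking whole degeneracy classes (see
  above); no ENC′ (background-corrected) variant is provided.
* CAI comparisons across host tables are only meaningful between tables of
  comparable bias strength; a near-uniform reference inflates CAI for any
  query (visible in `examples/03_host_adaptation.py`).
* The per-sequence SiD against a single host is reported; the index is
  often quoted on group-mean RSCU vectors, which can be obtained by passing
  `mean_rscu(...)` output instead.
* Real-organism host tables are deliberately not bundled; results depend on
  the provenance and version of whatever table the user supplies.
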