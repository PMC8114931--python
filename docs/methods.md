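# Methods

`admixkit` infers interspecific gene flow from genome-wide variant data.
This note documents the models it implements, the conventions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Allele-frequency panels

All site-based statistics consume a matrix of per-lineage derived-allele
frequencies built from a multi-sample VCF and a sample-to-lineage map.
Only biallelic SNVs enter the panel; a lineage's frequency at a site is
the fraction of its called allele copies carrying the derived allele, and
is missing when nothing was called (statistics then skip that site for
the affected quartet only — pairwise deletion, matching the behaviour of
the standard f-statistic tools). Polarization uses the outgroup: sites
where the outgroup lineage is missing or polymorphic are dropped, and
site alleles are flipped where the outgroup is fixed for the VCF ALT
allele. Polarization is optional because Patterson's D is invariant to
joint allele relabelling, but fd requires derived polarity; the default
is on.

Coordinates are 1-based inside the panel (VCF convention) and 0-based
half-open in all window/BED output (BED convention).

Jackknife blocks are contiguous runs of equal site counts, never spanning
a chromosome boundary, with per-chromosome allocation by largest
remainders. Equal-count blocks equalise the information each block
contributes; fixed-physical-length blocking is available as an
alternative (`assign_blocks_by_length`). The default of 100 blocks is a
conventional choice balancing SE stability against the independence of
blocks; it is configurable everywhere.

Fixed windows tile each chromosome; a window is retained when the
fraction of its sites with any missing lineage is below 1% (the
`max_missing=0.01` default).

## D statistics and the block jackknife

For an ordered quartet (P1, P2, P3, O) with derived frequencies
p1..p4, the per-site site-pattern terms are

    ABBA = (1 - p1) p2 p3 (1 - p4),   BABA = p1 (1 - p2) p3 (1 - p4)

and D = Σ(ABBA − BABA) / Σ(ABBA + BABA) over informative sites. On
fixed alleles this reduces exactly to the integer site-pattern count
ratio. Significance comes from a weighted delete-one block jackknife
(Busing-type weighting with block weights equal to informative-site
counts; an unweighted mode reduces to the plain delete-one formula when
blocks are equal). Z = D/SE is compared both against the fixed |Z| > 3.3
rule and, in the triplet sweep, against a Bonferroni-adjusted two-sided
normal p at family level 0.05 — the two conventions answer different
questions and are reported side by side rather than reconciled.

The triplet sweep orients each unordered ingroup triplet
deterministically (P3 = alphabetically smallest member, then P1 < P2), so
the sign of D is reproducible across runs; with 34 ingroup lineages it
produces C(34,3) = 5984 rows.

f4(A,B;C,D) = mean of (pA − pB)(pC − pD), with f2(A,B) = f4(A,B;A,B).
The f4-ratio of two quartets that share the non-admixed side estimates an
admixture proportion α; its SE is a delete-one jackknife of the ratio.
Ratios whose denominator falls below 1e-9 are flagged unstable.

## Admixture graphs

A graph is a rooted DAG with drift lengths d_e ≥ 0 (f2 units) on edges
and a mixing proportion α on each two-parent node. With deterministic
admixture mixing, a leaf's frequency is linear in the per-edge drift
increments, weighted by the probability w_i(e) that a lineage sampled at
leaf i traverses edge e; hence

    E[f4(A,B;C,D)] = Σ_e d_e (w_A(e) − w_B(e)) (w_C(e) − w_D(e)).

Scenario fitting minimises the Mahalanobis cost
(F − f)ᵀ S⁻¹ (F − f) where f is the observed D or f4 vector and S its
block-jackknife covariance. Because F is linear in the drifts for fixed
α, the optimal nonnegative drift vector is obtained by whitened
non-negative least squares, and Nelder–Mead searches only over the α
vector (logit-transformed), multi-restarted from jittered starts and
polished until the improvement stalls. This "linear algebra plus
Nelder–Mead" split makes the optimisation fast and reliable; the default
budget (50 restarts, 20 000 function evaluations, simplex tolerances
1e-10/1e-12) is far more than the 1–3-dimensional α search needs.

Numerical and identifiability choices:

- S is regularised with a 1e-8 ridge and inverted by pseudo-inverse.
  Observed f4 entries satisfy exact linear identities (they live in the
  f-statistic subspace), so S is often rank-deficient by construction;
  the pseudo-inverse confines the cost to the informative subspace.
- The two edges directly below the root contribute identical
  coefficients to every f4 and are fused: one parameter carries their
  drift sum, reported as such.
- Edges entering an admixture node carry zero drift by default (the
  usual graph convention); freeing them is an option.
- When the observed vector holds D statistics, the drift estimates
  absorb one overall positive scale (D's quartet-specific denominator is
  not predicted by the drift algebra), so only products scale × d_e are
  interpretable; α is unaffected. A pure-f4/f2 mode has no such scale.
- Fitting benefits from including f2-style entries (repeated-leaf
  quartets) in the observed vector: distinct-leaf f4s alone leave pendant
  drifts — and with few quartets even α — underdetermined.

`compare_scenarios` fits every scenario with the same data and restart
budget and ranks by minimal error; errors tied within a relative
tolerance are ordered by parsimony (fewer admixture edges first).

## Window scans: Dxy, fd, π and permutation nulls

- Dxy(A,B) per window = mean over sites of pA(1 − pB) + pB(1 − pA)
  (variant-only denominator by default; a per-bp mode divides the sum by
  window length instead — real-data Dxy scales depend on which callable
  sites are counted, so both are provided).
- fd per window = Σ(ABBA − BABA) / Σ(ABBA_D − BABA_D) where the
  denominator substitutes the donor proxy PD = max(p2, p3) per site for
  both P2 and P3. fd is undefined (reported missing, not zero) when the
  numerator is ≤ 0, following the statistic's published definition;
  at sites with p2 = p3 the proxy choice is forced, removing tie
  nondeterminism.
- π per site = 2k(n − k)/(n(n − 1)) for k derived of n called copies;
  window π is the variant-only mean.

Permutation tests compare a window against the genome background by
recomputing its statistic on randomly drawn site sets of the same size
(window-label resampling is available as an alternative). p-values use
the add-one convention (1 + #as-or-more-extreme)/(1 + draws), so the
floor at 1000 permutations is 1/1001. Dxy is tested one-sided low and fd
one-sided high, the directions that support introgression.

Candidate introgressed blocks are maximal runs of ≥ `min_run` retained
windows with Dxy below a genome-wide quantile and fd above a threshold,
merged across single-window gaps and ranked by run length.

## Local trees

Trees are compared as unrooted topologies (the safest common denominator
for mixed rooted/unrooted inputs); the outgroup is used only to orient
triplet classification. RF distance is the symmetric difference of
nontrivial bipartition sets (normalised by 2(n − 3) on request);
leaf-set mismatches raise instead of silently pruning. Topology counting
prunes each window's tree to the focal taxa, tallies resolved topologies
(polytomic prunings count as unresolved, and windows missing a focal
taxon are flagged out of the denominator). Concordant-window selection
retains windows whose pruned topology has RF 0 to the consensus,
ignoring branch lengths.

## Branch-length mixture test (introgression vs ILS)

For one triplet topology's internal branch lengths across local trees,
the contrast is

    model 1: x ~ Exp(λ)
    model 2: x ~ π1 Exp(λ) + π2 (C + Exp(λ)),  C ≥ 0

fitted by maximum likelihood. Model 1's MLE is λ = 1/mean. Model 2 runs
EM over (π2, λ) with the shift C profiled on a 50-point grid spanning
(0, 3·mean] and refined on a finer local grid around the best point.
The model-1 solution (π2 = 0, C = 0) is always included among model-2
candidates, so the mixture log-likelihood can never fall below the
single-exponential one (nesting), and each EM pass is monotone by
construction. Models are compared by BIC with k = 1 vs k = 3; BIC ties
within 1e-6 prefer the 1-parameter model. Zero-variance samples are
flagged degenerate and returned as model 1 with λ = 1/c.

## Counting dN/dS and the fg/bg contrast

Pairwise dN/dS uses the Nei–Gojobori (1986) counting method: per-codon
synonymous site fractions enumerate all nine single-base changes under
the standard code, averaged over the two sequences; changes to stop
codons count as nonsynonymous, the only convention that keeps the exact
conservation S + N = 3 × codons. Multi-difference codons average their
observed differences over all minimal mutational paths that avoid stop
codons (falling back to all paths in the rare case every path crosses a
stop). Proportions are Jukes–Cantor corrected, d = −(3/4)ln(1 − 4p/3);
ω is undefined when dS = 0 or a correction is out of range (p ≥ 3/4).
Codons containing gaps or ambiguity codes in either sequence are dropped
pairwise. A counting estimator was chosen over ML codon models so the
estimates are exactly reproducible by hand; externally computed ω tables
can be fed directly into the comparison below.

The foreground/background test compares mean ω between genes from
introgressed regions and genes concordant with the consensus phylogeny
by permuting gene class labels (default 1000 permutations, add-one
convention). The default alternative is one-sided fg > bg, the direction
of the adaptive-introgression hypothesis; two-sided and median-based
modes are provided.

## Synthetic data

The generator produces every input with known truth:

- **Frequencies** drift down an admixture graph under a Balding–Nichols
  Beta model: child mean = parent frequency, variance = d·p(1 − p);
  admixture nodes mix deterministically. Root frequencies default to
  Uniform(0.05, 0.95). Because mixing is deterministic and increments
  independent, the exact leaf covariance — hence every expected
  f-statistic — follows from a moment recursion
  (`expected_leaf_covariance`), which the tests use as the analytic
  oracle. Note that along a chain of edges the realised f2 is slightly
  below the sum of the d_e (heterozygosity shrinks multiplicatively by
  Π(1 − d_e)); ratios of f-statistics, and therefore α estimates, are
  unaffected. Sites monomorphic across all leaves are dropped post hoc,
  as a real SNV panel would; this rescales all f-statistics by a common
  factor and cancels from every ratio and graph fit.
- **Scan panels** plant an introgressed block by copying donor
  frequencies into the recipient (plus drift 0.002) inside a stated
  interval. The scan benchmark uses a deep-drift tree (edge drifts
  0.1–0.3) so lineage frequencies sit near fixation: between-species
  Dxy then reflects near-fixed differences and the planted block shows
  the low-Dxy / high-fd signature. With shallow drift the
  shared-polymorphism term 2p(1 − p) dominates Dxy and the contrast is
  physically weak — a property of the statistic, not the detector.
- **Triplet branch lengths** are draws from the exponential /
  shifted-exponential mixture.
- **Codon pairs** evolve by proposal–acceptance: Poisson(3·L·t) random
  single-base proposals, stops rejected, synonymous changes accepted at
  rate 1 and nonsynonymous at relative rate ω.

Every generator is a pure function of (config, seed) and emits a truth
sidecar sufficient to recompute expected statistics without rerunning.

What the generator does **not** emulate: linkage and recombination (sites
are independent, so jackknife SEs on synthetic data are if anything
conservative relative to real linked genomes), coalescent genealogies
(expected f-statistics are exact by construction rather than
coalescent-averaged), sequencing error, genotype uncertainty, and
ascertainment from a discovery panel. Passing the benchmarks therefore
validates the estimators and their calibration under the stated model,
not robustness to those real-data complications.

## Benchmark study conditions

The acceptance studies (in `admixkit.studies`, reported by
`scripts/acceptance.py`) use: 500 replicate triplets of 20k sites and
100 blocks for null calibration; 50k-site panels, 20 seeds, and
α ∈ {0.1, 0.3, 0.5} for proportion recovery; three nested scenarios
(tree, one, two reticulations) on 50k-site panels for ranking; 5 Mb
chromosomes of 100 × 50 kb windows with a 10-window planted block for
scan detection; 500 windows × 200 permutations for null uniformity; and
50 seeds of n = 2000 branch lengths (π2 = 0.5, C = 2, λ = 1) for the
mixture test. These sizes were chosen so each study gives stable counts
at desk scale while the full benchmark completes in a few minutes.

## Limitations

- Admixture graphs support at most two parents per node and no automated
  topology search; scenarios are user-specified and compared.
- The D-mode graph fit identifies α and products scale × d_e only.
- The panel carries lineage-level frequencies; individual-level
  statistics (heterozygosity per sample, phasing-aware methods) are out
  of scope.
- The NG86 estimator saturates for deeply diverged pairs (Jukes–Cantor
  correction undefined at p ≥ 3/4) and ignores transition/transversion
  and codon-frequency biases.
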