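# admixkit

Genome-wide introgression inference for phylogenomic datasets: Patterson's
D / f4-statistics with block-jackknife significance, admixture-graph
scenario fitting, windowed Dxy/fd introgression scans with permutation
nulls, local-tree concordance and topology summaries, an
exponential-mixture branch-length test separating introgression from
incomplete lineage sorting (ILS), and foreground-vs-background dN/dS
permutation comparisons.

The package is aimed at researchers analysing multi-species whole-genome
variant data — for example a radiation of diverged lineages with one or
more individuals each plus an outgroup — who want to (1) detect gene flow
between lineages, (2) quantify admixture proportions and compare explicit
reticulation scenarios, (3) localise introgressed haplotype blocks along
chromosomes, and (4) ask whether genes in those blocks evolve under
different selective constraint. Every analysis can be exercised end to
end on synthetic data generated under a known admixture graph, so all
estimators ship with generative ground-truth benchmarks.

## The statistics

For a lineage quartet (P1, P2, P3, O) with derived-allele frequencies
p1..p4, the site-pattern terms are ABBA = (1−p1)p2·p3(1−p4) and
BABA = p1(1−p2)p3(1−p4), and

    D = Σ(ABBA − BABA) / Σ(ABBA + BABA)

with a weighted block-jackknife SE over contiguous genomic blocks and
Z = D/SE. f4(A,B;C,D) = mean (pA−pB)(pC−pD); ratios of suitable f4s
estimate admixture proportions α. An admixture graph (rooted DAG with
drift lengths d_e and mixing proportions α) predicts every f-statistic
through edge-overlap path algebra, and competing reticulation scenarios
are fitted to the observed statistic vector f by minimising

    (F − f)ᵀ S⁻¹ (F − f)

(S = block-jackknife covariance) with non-negative least squares over
drifts nested inside a Nelder–Mead search over α — then ranked by
minimal error. Along chromosomes, fixed windows carry Dxy (absolute
divergence), the bounded admixture-fraction estimator fd, and nucleotide
diversity π, tested against the genome background by permutation; runs of
low-Dxy/high-fd windows are emitted as candidate introgressed blocks.
Gene-tree discordance is summarised by Robinson–Foulds distances and
topology counts, with a QuIBL-style Exp(λ) versus
π1·Exp(λ) + π2·(C + Exp(λ)) BIC contrast on triplet internal branch
lengths. Pairwise dN/dS uses the Nei–Gojobori counting method with
Jukes–Cantor correction. See `docs/methods.md` for conventions and
assumptions.

## Worked example

Simulate 50 000 sites under a 5-leaf graph in which lineage X derives 30%
of its ancestry from the B branch and 70% from the C branch, then detect
and quantify the admixture:

```python
import itertools
import admixkit as ak
from admixkit.studies import reference_admixed_graph

g = reference_admixed_graph(alpha=0.3)
cfg = ak.SimulationConfig(graph=g, n_sites=50_000, seed=42, outgroup="O")
panel, truth = ak.simulate_frequencies(cfg)
panel = ak.assign_blocks(panel, 100)

res = ak.d_statistic(panel, ("A", "X", "C", "O"))
print(f"D(A,X;C,O) = {res.D:.4f}  SE = {res.se:.4f}  Z = {res.Z:.1f}")

ratio, se, _ = ak.f4_ratio(panel, ("A","O","X","C"), ("A","O","B","C"))
print(f"f4-ratio alpha = {ratio:.3f} +/- {se:.3f}")

leaves = panel.lineage_ids
qs = [tuple(q) for q in itertools.combinations(leaves, 4)]
qs += [(a, b, a, b) for a, b in itertools.combinations(leaves, 2)]
obs = ak.f4_vector(panel, qs, statistic="f4")
fit = ak.ScenarioModel(g, obs, scenario_id="one-reticulation").fit(
    restarts=5, seed=1)
print(fit.summary())
```

Output:

```
D(A,X;C,O) = 0.0186  SE = 0.0014  Z = 13.4
f4-ratio alpha = 0.293 +/- 0.012
Admixture-graph scenario fit: one-reticulation
  statistic fitted : f4
  minimal error    : 0.151922
  restarts         : 5   converged: True
  admixture edges  : 1
  alpha[X0]     : 0.2925
  root-pair drift  : 0.0129327 (edges ('R', 'I') + ('R', 'O'), fused)
  ...
```

The strongly positive Z (13.4 ≫ 3.3) rejects the no-gene-flow null for
the (A, X; C) triplet: X shares a significant excess of derived alleles
with C. Both the f4-ratio (0.293 ± 0.012) and the graph fit (α̂ = 0.2925)
recover the generating proportion α = 0.3. The minimal error is the
Mahalanobis cost of the fitted scenario — near zero here because the
fitted topology is the generating one; fitting a tree-only scenario to
the same data yields an error orders of magnitude larger, which is how
competing reticulation scenarios are ranked. Fitted drifts are in
effective units (drift × heterozygosity), so their ratios, not absolute
values, mirror the generating lengths; α is unit-free.

A shell interface wraps the same functions:

```bash
admixkit dstat --vcf calls.vcf --popmap popmap.tsv --outgroup OUT \
    --blocks 100 --out triplets.tsv
admixkit scan --vcf calls.vcf --popmap popmap.tsv \
    --quartet P1,P2,P3,OUT --window 50000 --perms 1000 --seed 1 \
    --out scan.tsv
admixkit fitgraph --vcf calls.vcf --popmap popmap.tsv --outgroup OUT \
    --graphs m1.dag --graphs m2.dag --restarts 50 --seed 1 --out fits.tsv
admixkit dnds --genes gene1.fasta --genes gene2.fasta \
    --classes classes.tsv --perms 1000 --seed 1 --out omega.tsv
admixkit simulate --preset graph --graph-file true.dag --sites 50000 \
    --seed 1 --out-prefix sim
```

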