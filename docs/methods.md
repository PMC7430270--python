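# Methods

## The model

`spfa` scores directed signaling pathways for association with a
two-condition (normal vs disease) expression contrast by combining two
independent probabilities per pathway.

**Effector genes and signal variation.** An effector gene is a pathway
node that receives signals but emits none: in-degree ≥ 1 and out-degree 0
in the directed pathway graph, with self-edges ignored for both degrees (a
self-loop is not a signal to another gene). Disease phenotypes are assumed
to manifest as changes in the signals effectors receive. For an upstream
gene g_s with a directed path to effector g_e, the signal variation is

    e_se = |cor_disease(g_s, g_e) − cor_normal(g_s, g_e)| / d_se,

where the correlations are Pearson coefficients computed separately within
each condition's samples and d_se is the *network distance* — the shortest
directed-path length from g_s to g_e in edges — acting as an attenuation
penalty for indirectly transmitted signals. Per effector,
ASV(g_i) = Σ_j e_ij over its s upstream genes; per pathway,
ASV = Σ_i ASV(g_i) over its k effectors. Scoring uses topology only; edge
signs and interaction types parsed from KGML are stored for reporting but
never enter the score.

**Permutation probability P_sd.** The observed ASV is referred to a
gene-identity permutation null: holding the topology fixed, the pathway's
node labels are replaced by a uniform draw without replacement from all
measured genes (each relabeled node carrying that gene's real expression
rows), and ASV is recomputed per draw (default 2000 draws). Only gene
identities are permuted; sample labels never are. The estimator is the
smoothed

    P_sd = (1 + #{ASV_per ≥ ASV_obs}) / (1 + n_perm),

a valid permutation p-value that cannot return 0 — a raw proportion of 0
would make the downstream combination ln(0)-undefined. The raw-proportion
estimator is available (`estimator="literal"`) with a floor at 1/n_perm.

**Over-representation probability P_de.** Differentially expressed genes
are selected by a cascade (below) and referred to a hypergeometric model:
with m measured genes of which n are DEGs, a pathway covering t measured
genes and containing r DEGs scores P_de = P(X ≥ r), the standard ORA upper
tail. The universe is the set of measured genes, not the genome —
unmeasured genes can neither be drawn nor be DEGs, and only measured
pathway nodes count toward t. A variant returning one minus the point mass
P(X = r) is available as `mode="literal_eq5"`; it is not a tail
probability and is off by default.

**Combination, FDR, ranking.** The two probabilities use disjoint aspects
of the data (pair correlations vs DEG counts) and are combined as two
independent uniform p-values via the closed form

    c = P_de · P_sd,   P = c − c·ln(c),

which is P(U₁U₂ ≤ c) for independent uniforms; P is strictly increasing in
c and equals 1 exactly at c = 1. Combined P values are Benjamini–Hochberg
adjusted across all pathways of the run, ranked by ascending adjusted P
(ties by raw P, then pathway ID), and called significant at P_adj ≤ 0.05
by default. The squared Pearson correlation between the P_de and P_sd
vectors across pathways (`SPFAResults.independence_r2`) is reported as an
independence diagnostic; on null data it sits near zero.

**Differential expression and the DEG cascade.** Per-gene statistics come
from a Welch two-sample t-test with BH adjustment; `log_fc` is the mean
difference (disease − normal), so the matrix is assumed log-scale. A
precomputed table (gene_id, p_value, p_adj, log_fc) may be supplied
instead. Selection cascades: (1) if more than 200 genes have adjusted
p < 0.05, take them; (2) else if more than 200 genes have raw p < 0.05 and
|log_fc| > 1.5, take them; (3) else take the top 1% of genes by smallest
p-value (ties by larger |log_fc|, then gene ID). "More than 200" is
strict. All five thresholds are configurable.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_perm` | 2000 | permutation draws per pathway for P_sd |
| `seed` | 0 | run seed; per-pathway child seeds are derived from (seed, CRC32(pathway_id)), so results are independent of processing order |
| `alpha` | 0.05 | significance threshold on adjusted combined P |
| `estimator` | smoothed | P_sd estimator (smoothed or literal with 1/n_perm floor) |
| `ora_mode` | upper_tail | hypergeometric tail vs the one-minus-point-mass variant |
| DEG cascade | 200 / 0.05 / 0.05 / 1.5 / 0.01 | min_count, fdr_thresh, p_thresh, lfc_thresh, top_frac |

## Degenerate inputs and numerical choices

* A gene unmeasured, or constant within a condition, has undefined
  correlations; its pairs contribute e = 0 and are flagged degenerate
  rather than propagating NaN. A constant gene transmits no detectable
  signal change.
* Pathway genes absent from the expression matrix stay in the graph for
  distance computation (removing them would silently shorten distances for
  measured pairs) but contribute 0.
* Pathways with no effectors cannot be permutation-tested; they are
  reported with P = P_de, flagged `ora_only`, kept in the table and the BH
  family, and excluded from the independence diagnostic.
* Duplicate gene rows are collapsed by maximum variance at load; missing
  values are a hard error (no imputation rule is defined).
* P_de is clamped to (1e-300, 1]; P_sd is positive by construction.
* Correlations are computed from per-condition standardized (centered,
  unit-norm) expression rows held in memory, so any pair correlation is a
  dot product and the permutation null evaluates vectorized in blocks of
  256 draws.
* Both conditions need ≥ 2 samples (hard error); fewer than 3 warns.
* Nodes inside directed cycles upstream of an effector enter the upstream
  set once, at their shortest-path distance — one term per upstream gene,
  not per path.

## The synthetic-data generator

The generator (`spfa.simulate`) emulates exactly the statistical structure
the score detects, with known ground truth:

* **Pathways** are random DAGs (default 20 pathways of 8–15 nodes) over a
  gene universe (default 2,000 genes). Nodes are topologically ordered; a
  designated sink layer (≈ a fifth of nodes, ≥ 1) receives but never emits
  edges and every non-sink node is forced to emit at least one edge, so
  the sinks are exactly the effectors. Cycles are accepted by the scoring
  modules but never generated, keeping ground-truth distances
  unambiguous. Background pathways draw genes disjoint from the target
  pathway so the perturbed set is unambiguous.
* **Expression**: background genes are i.i.d. Gaussian in both conditions
  (default 20 samples per condition, unit SD). Target-pathway genes share
  one latent factor per condition: x_g = s_g·√|ρ|·z + √(1−|ρ|)·ε_g, with
  the loading sign s_g flipped on effector genes when ρ < 0. Because
  effectors are never upstream of other effectors, every scored
  (upstream, effector) pair then has correlation ρ — exactly ρ_normal
  (default +0.8) in normal and ρ_disease (default −0.8) in disease, at any
  network distance. A per-edge factor construction was rejected: with unit
  variances the loading product caps pairwise |ρ| at 1/degree for
  multi-edge genes, which cannot reach 0.8.
* **Differential expression**: half of the target pathway's genes
  (`deg_frac_target=0.5`) and 1% of background genes
  (`deg_frac_background=0.01`) get a 2-SD mean shift in disease. These
  defaults were fixed by an a-priori power argument: at 20+20 samples a
  2-SD shift is detected near-certainly by the Welch test, ~26 true DEGs
  fall below the 200-gene cascade cutoffs so the top-1% rule fires with
  ~20 selections dominated by true shifts, giving the target pathway a
  strongly non-null r while background pathways rarely catch a DEG. They
  represent a strong, clean microarray contrast — one clearly perturbed
  pathway against a quiet genome.
* `SimulationConfig.null()` gives a globally null dataset: equal
  co-expression in both conditions (ρ = 0.5 on the target pathway in both)
  and no mean shifts, under which P_sd is uniform and P_de carries no
  pathway signal.

What the generator does **not** emulate: probe-level noise, GC or batch
effects, heavy-tailed expression, correlated background modules,
overlapping pathway memberships, or pathways whose perturbation is partial
or sign-mixed. Passing the recovery benchmark therefore demonstrates that
the pipeline detects the structure it models, not that it attains any
particular sensitivity on real microarray data.

## Benchmarks the package runs on itself

`scripts/acceptance.py` (problem sizes chosen to keep a desk-scale run
under a minute):

* **Recovery**: 20 replicates at the default study conditions, 500
  permutations — fraction of replicates with the target pathway at rank 1
  and adjusted P ≤ 0.05, the median target rank, and the mean
  significant-pathway ratio.
* **Null calibration**: 5 globally null runs of 60 pathways over 1,500
  genes — the KS statistic of P_sd against U(0,1) and the mean squared
  correlation between P_de and P_sd (expected near zero).
* **Effector census**: the fraction of generated pathways containing at
  least one effector (1.0 by construction; real KEGG collections contain a
  minority of pathways with none, which the pipeline reports `ora_only`).

## Known limitations

* Correlation differences also arise between randomly paired genes, so the
  permutation null has genuine spread; P_sd is calibrated but not
  especially powerful for weak co-expression changes.
* Pearson correlation is linear and scale-dependent under monotone
  transforms; run the method on the same (log) scale throughout.
* The hypergeometric term treats genes as exchangeable and ignores
  inter-gene correlation within pathways.
* KGML expansion of multi-gene entries and group nodes (every listed gene
  becomes a node sharing the entry's edges) is a documented choice; other
  expansions would change distances.
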