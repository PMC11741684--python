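# Methods

## Model

`signet` scores configurations **a** that assign exactly one active gene
per locus. Under a naïve-Bayes factorization the log-likelihood of the
data given **a** is a sum of independent feature scores; constants shared
by all genes of a locus (the inactive-gene distance term, the categorical
baseline `S0 = H ln α + W ln(1−α)`) cancel in within-locus comparisons
and are dropped. The per-gene score is

    S_i = S_Dist + S_Mendelian + S_Exome + S_Coloc + S_PPI + S_GRI.

**Distance.** The signed SNP-to-TSS distance x of the active gene follows
a two-sided exponential with scale γ: `S_Dist = −ln 2γ − |x|/γ`. The sign
convention is negative when the SNP lies 5′ of the TSS on the gene's
sense strand. The maximum-likelihood update is γ = mean |x| over active
genes at GWAS loci; singleton Mendelian genes (x = 0 by definition) are
excluded from the update so they cannot shrink γ. γ is floored at 1 bp
to guard degenerate inputs in which every active distance is 0.

**Categorical evidence.** Each of the three features (Mendelian, exome,
colocalization) contributes a log-odds
`S_f = ln[(n11+c)/(n10+c)] − ln[(n01+c)/(n00+c)]` (pseudocount c = 1)
when the active gene carries the feature, else 0. The counts are tallied
over all genes in GWAS loci (n10 + n11 = L, n00 + n01 = G − L); singleton
Mendelian loci are excluded entirely, since they would otherwise inflate
the Mendelian feature with genes that are active by construction.
Fractional counts are legal (used by the 80 %-subset shrinkage
illustration).

**Network enrichment.** For each network the observed edge count E among
the active genes is compared with a degree-corrected expectation built
from normalized degrees on the network restricted to the locus genes:
δ_i = d_i/2E_tot (undirected), δ′_in = d′_in/E′_tot and
δ′_out = d′_out/E′_tot (directed), with

    E0  = ½(Σδ)² − ½Σδ²                      (undirected, factorized)
    E0′ = (Σδ′_in)(Σδ′_out) − Σδ′_in δ′_out  (directed, factorized)

which equal the pairwise double sums exactly (tested against an O(n²)
oracle at relative tolerance 1e−12). The log-likelihood ratio is the
Poisson form `Λ(E) = lnΓ(E+1) − E ln E0 + E0 − ln(T+1)` with the
convention 0·ln 0 = 0; Λ at the (generally non-integer) baseline E0 uses
the continuous lnΓ extension. The score used by the sampler reflects Λ
about its baseline, `S = Λ(E0) + sgn(E−E0)·|Λ(E) − Λ(E0)|`, so it is
non-decreasing in E: edge depletion is never rewarded, which prevents
convergence into edge-depleted local optima. E0 = 0 with E > 0 is
impossible (an observed edge implies positive endpoint degrees, hence
positive δ) and is treated as a contract violation. The pair totals are
T = (L+M)(L+M−1)/2 for the undirected network (pairs of active genes)
and T′ = (G+M)(G+M−1) for the directed one (ordered pairs over all
genes); the asymmetry is retained as specified — both are constants
within a run and only shift scores uniformly.

Note that with δ = d/2E_tot the expected count satisfies E0 ≤ ½ for any
active set, so E0 is a degree-*ranking* correction rather than a
calibrated edge count (for the full gene set E = E_tot while E0 < 1).
One consequence, relevant to interpreting controls, is that each edge
among active genes is worth several nats, so network evidence dominates
distance and categorical terms wherever edges are present.

## Optimization

Runs start from a best-guess configuration (priority Mendelian > exome >
colocalized > nearest TSS; ties uniform at random) or from a uniform
random one. Each pass visits the non-singleton loci in a fresh random
permutation; at each locus the candidate genes are scored with all other
loci frozen and the argmax installed (score ties broken uniformly at
random). Softmax weights w_i = exp(S_i)/Σ exp(S_j) (max-subtracted) are
recorded at each visit. After every pass γ and the S_f are refit by
maximum likelihood from the current active genes. A run converges when a
full pass changes no active gene — the parameter refit is then also
stationary — or stops at the pass cap (default 100; synthetic studies
typically converge in 2–6 passes). After convergence one scoring-only
sweep computes final weights for every gene as a pure function of the
converged state. Greedy argmax was chosen over Gibbs sampling: the
concern is trapping near one high-scoring configuration, which is
assessed instead by independent restarts (run seeds = base seed + run
index, one generator per run). Selection frequency (fraction of restarts
a gene ends active) and mean final weight are deliberately distinct
summaries — a gene with weight just above 0.5 is always selected.

Network scores are memoized per network with the set of active
nonzero-degree genes as the key; zero-degree genes cannot change E or
E0. The incremental per-locus edge-count bookkeeping is not implemented;
caching plus the factorized E0 is sufficient at the scales targeted.

## Synthetic studies

The generator emulates the structure the model assumes: one significant
SNP per locus (each locus on its own chromosome; merging of overlapping
windows is exercised by hand-built multi-SNP fixtures), a planted causal
gene at a signed distance drawn from the untruncated two-sided
exponential with scale `gamma_true`, decoy genes uniform in ±flank,
evidence flags drawn at per-category rates on planted genes (background
rate on decoys, default 0), PPI edges at `planted_edge_prob` among
planted genes (plus the always-active singleton Mendelian genes) and
`background_edge_prob` for every other pair, and regulatory edges as
random planted→planted ordered pairs plus background. Defaults mirror a
cardiac-electrophysiology-sized analysis: 226 loci, 5 genes per locus,
250 kb flank, γ_true = 150 kb, evidence rates 0.05/0.05/0.15, 19
singleton Mendelian genes. The same seed reproduces a byte-identical
bundle.

Two intentional consequences of this design matter when reading tests:

* **Window censoring.** Distances are drawn untruncated, so a planted
  gene lands outside its 250 kb window with probability e^(−D/γ) (≈ 19 %
  at the defaults). Such genes are absent from their locus (a
  Mendelian-flagged one becomes a singleton locus); recovery metrics are
  computed over loci whose planted gene is a member. The censored MLE of
  γ converges to the truncated-exponential mean (≈ 92 kb at the
  defaults), a property of the truncation rather than an estimator
  defect; the γ-recovery test therefore uses a 1 Mb flank with γ_true =
  150 kb, where censoring is < 0.2 % and γ̂ must land within 15 %.
* **What the generator does not emulate:** linkage disequilibrium,
  genotype-level noise, the asymmetric excess of gene-body SNPs seen in
  real signed-distance distributions, multi-SNP loci, tissue-specific
  networks. Passing recovery tests therefore demonstrates correctness of
  the inference machinery under the model's own assumptions, not
  performance on real GWAS data.

## Experimental conditions of the behavioral tests

* **Enriched recovery** (network signal only): 40 loci × 5 genes,
  γ_true = 60 kb, planted edge probability 0.15 vs background 0.002, no
  evidence flags, 10 replicate studies, 3 restarts each. Assertion:
  SigNet recovery exceeds nearest-gene recovery in the mean and in every
  paired replicate.
* **Null recovery:** identical but planted edge probability equal to
  background and no planted regulatory edges; SigNet and nearest-gene
  recovery agree within 0.1.
* **Shuffled-network control:** the degree-preserving (stub-matching)
  shuffle preserves each gene's degree, and in this generative family
  planted enrichment necessarily shows up as planted excess degree; a
  shuffle of an *enriched* network therefore retains part of the planted
  signal by construction — this is a property of the method and the
  generator, not a defect. The clean negative control is the shuffle of
  the *null* network, asserted indistinguishable from the no-network run
  (margin 0.1); on enriched studies the shuffled network is asserted to
  never outperform the true one.
* **No-network ≡ best-guess:** with both networks empty the run returns
  the initialization exactly. This identity is structural at
  information-poor loci (distance-only greedy selection is the nearest
  gene) and holds at evidence-bearing loci whenever the feature
  log-odds exceeds the flagged gene's within-locus distance penalty
  Δ|x|/γ — the regime of the real studies this emulates (S_f ≈ 2.7–4.0
  nats vs at most ≈ 1.6). It is tested on evidence-free generated
  studies and on an evidence-dominant fixture whose margin is asserted
  as an explicit precondition. Outside that regime the sampler may
  legitimately trade a far flagged gene for a near unflagged one; that
  behavior is correct and not asserted against.
* **Small-scale global optimality:** on random 5-locus instances with
  2–3 genes each, the best of 100 random restarts matches the exhaustive
  profile-likelihood maximum (parameters set to their MLE per
  configuration) on at least 7 of 8 instances — the restart strategy is
  stochastic, and a ≥ 99 % per-instance success rate is the target
  property, not certainty.

Problem sizes throughout (tens of loci, a few replicates, 2–3 restarts)
were chosen as the smallest scales at which the asserted effects are
unambiguous; the full pipeline at 245 loci × 100 restarts runs in well
under a minute thanks to score caching.

## Numerical choices and edge cases

* Softmax weights are computed with max subtraction; shifted scores give
  identical weights.
* Ties: minimum-|x| gene ties break lexicographically (deterministic
  MinDist); score ties in the sweep and priority ties in best-guess
  initialization break uniformly with the run's generator; a tie for the
  most-selected gene (possible with an even restart count) breaks
  lexicographically and is flagged in the run summary.
* The configuration-model shuffle drops self-loops and collapses
  multi-edges after stub matching (standard practice; the degree
  sequence is exact before the collapse, slightly reduced after).
* Empty restricted networks yield E_tot = 0, all δ = 0, and network
  scores that reduce to the constant −ln(T+1), contributing nothing to
  within-locus comparisons.
* Loci never merge across chromosomes; the window boundary |tss − pos| ≤
  D is inclusive; if a SNP's window is empty the single nearest-TSS gene
  on the chromosome is used.
* Readers map columns by case-insensitive header name with common
  synonyms; duplicate (rsid, trait) rows keep the smallest p-value;
  duplicate annotation symbols collapse to the widest bounds with the
  TSS at the maximal boundary (start on +, end on −).

## Evaluation utilities

Pairwise evidence overlap uses the one-sided (enrichment) Fisher exact
test, i.e. the hypergeometric tail P(X ≥ k); sidedness is a design
choice, as enrichment is the direction of interest. The three-way
overlap test is a binomial tail with success probability equal to the
product of the three marginal rates — the most natural reading of a
"binomial test" for a triple intersection. Gene-set enrichment is a
hypergeometric test per GMT set against an explicit universe (default:
all locus genes, matching the method-vs-method comparison purpose) with
Benjamini–Hochberg adjustment. The hidden-evidence experiment clears the
flags of each single-evidence gene in turn on a copy of the locus set
and reports per-category recovery; subset robustness reruns the sampler
on random locus subsets and reports parameter dispersion; rank
concordance compares two per-gene score tables after subtracting each
method's within-locus maximum, on the genes present in both.

## Known limitations

One active gene per locus (loci with several true causal genes are
summarized only through SigNet+); no LD-aware locus construction or
TAD-based windows; unweighted, tissue-agnostic networks; the directed
and undirected pair totals follow the specified asymmetric definitions;
E0 is not a calibrated expected edge count (see above), so absolute
network scores should not be interpreted as likelihoods, only
within-locus differences.
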