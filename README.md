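# signet

Bayesian prioritization of causal genes at GWAS loci by integrating
within-locus evidence with cross-locus network enrichment.

## The problem

A genome-wide association study points to loci, not genes: each
significant SNP sits in a window that typically contains several
candidate genes, and the gene nearest the SNP is the true causal gene
only about half the time. `signet` selects one *active* (putatively
causal) gene per locus by combining, in a naïve-Bayes log-likelihood:

* **distance** — an exponential density over the signed distance *x*
  from the gene's transcription start site to the nearest locus SNP,
  `S_Dist(x) = ln[ exp(−|x|/γ) / 2γ ]`, with scale γ refit by maximum
  likelihood (γ = mean |x| of the active genes);
* **categorical evidence** — Mendelian-disease, exome-variant and
  eQTL-colocalization flags, each contributing a learned log-odds
  `S_f = ln[(n₁₁+1)/(n₁₀+1)] − ln[(n₀₁+1)/(n₀₀+1)]` when the active
  gene carries the feature (counts from the active/inactive ×
  with/without 2×2 table, pseudocount 1);
* **network enrichment** — the observed number of protein–protein
  (undirected) and regulatory TF→target (directed) edges *E* among the
  active genes, compared with a degree-corrected expectation
  `E₀ = Σ_{i<j} δᵢδⱼ` (δᵢ = dᵢ/2E_tot) through a Poisson
  log-likelihood ratio `Λ(E) = lnΓ(E+1) − E ln E₀ + E₀ − ln(T+1)`,
  reflected about Λ(E₀) so that only edge *enrichment* is rewarded.

The total gene score is `S = S_Dist + S_Mendelian + S_Exome +
S_Coloc + S_PPI + S_GRI`. A greedy coordinate-ascent sampler visits
loci in random order, reassigns each locus to its argmax-score gene with
the rest frozen, refits γ and the S_f after every pass, and stops at a
fixed point. Independent restarts yield per-gene selection frequencies
and softmax weights; per locus the package reports the **SigNet** gene
(most often selected), **SigNet+** (SigNet plus all flagged genes), and
**MinDist** (nearest-TSS baseline).

It is intended for statistical geneticists who have GWAS summary
associations, a gene annotation, evidence gene lists, and network edge
lists, and want a reproducible, auditable gene ranking per locus.

## Worked example

Simulate a 30-locus study with planted causal genes whose PPI edges are
enriched (edge probability 0.2 among planted genes vs 0.005 background),
then run the sampler:

```bash
signet simulate --config sim.yaml --out study
# wrote synthetic study (30 loci, 3 singleton Mendelian genes) to study
signet run --gwas study/gwas.tsv --genes study/genes.tsv \
  --ppi study/ppi.tsv --gri study/gri.tsv \
  --mendelian study/mendelian.txt --exome study/exome.txt \
  --coloc study/coloc.txt --runs 10 --seed 1 --out results
# 30 GWAS loci + 4 singleton Mendelian loci, 143 genes; results in results
```

`results/summary.tsv` holds one row per gene. At the first locus the
planted gene `L0001G00` sits 168 kb from the SNP — four other genes are
closer — yet its network edges to genes selected at other loci give it
selection frequency 1.0:

```
locus_id  gene      distance_bp  ... selection_frequency  signet  mindist
L0001     L0001G04  -8188            0.0                  0       1
L0001     L0001G02  -112346          0.0                  0       0
L0001     L0001G03  158368           0.0                  0       0
L0001     L0001G00  168361           1.0                  1       0
L0001     L0001G01  224164           0.0                  0       0
```

Against the generator's ground truth, SigNet recovers 24 of the 30
planted genes in this study; the nearest-gene baseline recovers 10.
`results/parameters.tsv` logs each run's convergence (here 3 passes)
and final parameters (γ ≈ 86.9 kb, S_coloc ≈ 3.80), and
`results/metadata.json` records the seed and configuration.

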