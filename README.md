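# cernanet

Discovery and clinical validation of competing endogenous RNA (ceRNA)
regulation from tumor transcriptomics.

Under the ceRNA hypothesis, a long noncoding RNA (lncRNA) sponges a shared
microRNA and thereby de-represses that miRNA's mRNA targets. In
tumor/normal expression cohorts this leaves a recognizable signature: the
miRNA is differentially expressed opposite to both partners, miRNA–lncRNA
and miRNA–mRNA expression correlate negatively across tumors, and
lncRNA–mRNA correlate positively. `cernanet` implements the full discovery
pipeline around that signature for researchers analyzing multi-cohort
tumor/normal expression studies (microarray or RNA-seq style, on the log2
scale):

1. **Differential screens** — a random-variance-model (RVM) moderated
   t-test per cohort. Per-feature pooled variances $s^2$ on $d$ degrees of
   freedom are modelled with an inverse-gamma prior so that
   $s^2 a b \sim F(d, 2a)$; after fitting $(a, b)$ by maximum likelihood,
   each variance is shrunk, $\tilde s^2 = (d s^2 + 2/b)/(d + 2a)$, and the
   t statistic gains $2a$ degrees of freedom. Genes/lncRNAs pass at
   $|\mathrm{FC}| > 2$ and $p < 0.05$; miRNAs at $|\mathrm{FC}| > 1.5$,
   $p < 0.05$, FDR (Benjamini–Hochberg) $< 0.05$. Fold changes use the
   signed convention (a 4-fold repression prints as −4.0). Screens are
   intersected across cohorts requiring a consistent direction.
2. **Gene-set over-representation** — two-sided Fisher exact (or χ²) on the
   2×2 table, with the enrichment ratio
   $R_e = (n_f/n)/(N_f/N)$
   ($n_f$ flagged genes in the set, $n$ set size, $N_f$ flagged on the
   array, $N$ array size), and the intersection of genes appearing in both
   a significant GO term and a significant pathway.
3. **Signal-net centrality** — on the relation-table subgraph induced by
   the intersected genes: connectivity $K_i = \sum_{u \ne i} a_{ui}$
   (plus directed in/outdegree) and Freeman relative betweenness
   $C'_B(v) = \frac{2}{(n-1)(n-2)} \sum_{s \ne v \ne t} \sigma_{st}(v)/\sigma_{st} \in [0, 1]$
   for hub ranking.
4. **Seed-match target prediction** — a deterministic in-house predictor on
   the canonical site taxonomy (8mer, 7mer-m8, 7mer-A1, 6mer; reverse
   complements of miRNA nt 2–8/2–7 with an A1 anchor), with an
   intersection combiner over two thresholds emulating consensus calling
   across prediction tools.
5. **ceRNA assembly** — an miRNA-centered edge survives only if the pair is
   sequence-predicted, the members are DE in opposite directions, and their
   tumor-sample Pearson $r$ is negative with $p < 0.05$ (from
   $t = r\sqrt{(n-2)/(1-r^2)}$); triplets form through shared miRNAs and
   split into two direction-stratified sub-networks.
6. **Clinical validation** — median-split Kaplan–Meier with the log-rank
   test, univariate/multivariate Cox proportional hazards (Efron ties;
   multivariate entry for univariate-significant terms), and ROC AUC via
   the Mann–Whitney rank statistic with a Hanley–McNeil confidence
   interval.

A first-class synthetic-data generator plants recoverable ground truth —
DE mean shifts, sponge-driven triplet correlations via a latent per-tumor
miRNA activity, embedded 8mer seed sites (decoys scrubbed of canonical
sites), enriched gene sets, a network hub, and expression-linked
exponential survival — so every stage is testable without downloads.

## Worked example

```bash
python examples/05_cerna_assembly.py
```

prints (simulated study, 100 tumor samples, 10 planted triplets):

```
ceRNA network: 10 lncRNAs / 10 miRNAs / 10 mRNAs, 20 edges, 10 triplets
lncRNA_id miRNA_id mRNA_id  r_lnc_mi  r_mi_m  r_lnc_m
    L0122  mir0006   G0483     -0.58   -0.65     0.71
    L0139  mir0014   G0242     -0.54   -0.59     0.77
    L0197  mir0032   G0073     -0.69   -0.69     0.83

recovery of the 10 planted triplets: precision 1.00, recall 1.00
```

Each row is one lncRNA–miRNA–mRNA triplet with its three pairwise Pearson
correlations: both miRNA-centered correlations are negative and the
lncRNA–mRNA correlation positive — the ceRNA signature — and the assembly
recovered all ten planted triplets with no false positives. Likewise,

```bash
python examples/06_clinical_validation.py
```

```
feature L0013 (planted log-hazard 0.7)
log-rank p = 9.62e-07 between high and low expression groups
Cox HR = 1.42 per log2 unit (95% CI 1.29-1.57)
AUC = 0.83 (95% CI 0.75-0.90)
```

shows the survival stage flagging a planted harmful lncRNA: patients above
its median expression die sooner (HR > 1), and expression discriminates
events from survivors (AUC 0.83).

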