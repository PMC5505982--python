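# pstfst

Tools for asking a classic question in evolutionary ecology: **when
populations respond differently to an environmental stressor, is that
divergence shaped by selection or just by genetic drift?**

The package implements the P_ST–F_ST comparison for common-garden
experiments, motivated by thermotolerance assays on the Mediterranean red
gorgonian *Paramuricea clavata*: colonies from several populations are held
at a stressful temperature in shared aquaria, tissue necrosis (% of the
colony with dead tissue or denuded axis, 0–100) is scored daily, and the
same colonies are genotyped at microsatellite loci. Phenotypic divergence
among populations is then compared with neutral genetic divergence:

* **F_ST** — neutral divergence from genotypes, estimated with the
  Weir–Cockerham (1984) moment estimator θ (variance components *a*, *b*,
  *c* summed over alleles and loci, θ = Σa / Σ(a+b+c)), with percentile
  bootstrap CIs over loci; plus population-specific F_ST from a hierarchical
  Bayesian model in which pool allele frequencies are Dirichlet-distributed
  around an ancestral frequency with concentration (1 − F_i)/F_i.
* **P_ST** — the phenotypic analog of Q_ST computed from total variance
  components,

  P_ST = c·σ²GB / (c·σ²GB + 2·h²·σ²GW),

  where σ²GW = MS_W and σ²GB = max(0, (MS_B − MS_W)/n0) are extracted from a
  one-way PERMANOVA on Euclidean distances between colony necrosis
  trajectories (days 10/20/30), n0 = (1/(a−1))(Σnᵢ − Σnᵢ²/Σnᵢ), and c/h² = 1
  under the null assumption of constant genetic architecture. Point
  estimates and 95% CIs come from 1000 stratified bootstrap replicates
  (median, and the 25th/975th sorted values).
* **The comparison** — a Mantel test between the pairwise P_ST and F_ST
  matrices, per-pair and global 95% CI overlap (P_ST significantly above
  F_ST would signal divergent selection), and a Spearman correlation between
  population-specific F_ST and final-day necrosis (drift-susceptible
  populations being hit harder is the drift signature).

Supporting modules cover Genepop I/O, Monte-Carlo exact tests of genotypic
differentiation with transitive-closure pool merging, null-allele EM
estimation, one-way/two-way PERMANOVA with permutation p-values and
post-hocs, necrosis response summaries, and thermal-regime statistics for
hourly temperature series (daily climatology, July–October warm-period and
90th-percentile-tail statistics, Kruskal–Wallis with Dunn–Šidák post-hocs).
A synthetic-data module generates all three input types under a
Balding–Nichols drift model with known ground truth.

## Worked example

Simulate a six-pool study (30 colonies per pool, six microsatellite loci,
drift intensities F_i = 0.04–0.16, a drift-linked necrosis phenotype) and
run the whole analysis:

```yaml
# config.yaml
sim: {}            # simulate the default six-pool common-garden dataset
seed: 1
n_perm: 999
n_boot: 1000
n_mc: 4999
mcmc_iter: 20000
mcmc_burn_in: 5000
outdir: out
```

```bash
$ pstfst run-all --config config.yaml
{
  "config_hash": "8c5c86f8777c9b66",
  "global_theta": 0.08613197240538056,
  "global_pst": 0.3644832082563315,
  "mantel_r": 0.9198408705989727,
  "mantel_p": 0.006993006993006993,
  "spearman_rho": 0.7714285714285715,
  "status": "ok"
}
```

Reading the output: global θ ≈ 0.086 recovers the simulated mean drift
intensity (0.078); pairwise P_ST correlates strongly and significantly with
pairwise F_ST (Mantel r = 0.92, p = 0.007), and population-specific F_ST
tracks final-day necrosis (Spearman ρ = 0.77) — the pattern expected when
drift, not local adaptation, shapes the differential response. `out/`
contains the pairwise divergence table (P_ST and F_ST with 95% CIs per pool
pair), PERMANOVA term tables, the comparison report, phenotype summaries and
thermal statistics, plus `run_manifest.json` recording the config hash and a
content hash per output file.

The same stages are available piecewise (`pstfst simulate | popgen |
permanova | pst | compare | phenotype | thermal`) and as library functions:

```python
from pstfst.datasets import gorgonian_divergence
from pstfst.divergence import mantel_test, ci_overlap_compare

pst, fst = gorgonian_divergence()          # bundled six-pool example tables
r, p = mantel_test(pst, fst, n_perm=999, seed=0)   # r = 0.574, p = 0.008
ci_overlap_compare(pst, fst)["overlap"].all()      # True: all 15 pairs
```

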