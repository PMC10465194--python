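# comigrate

Temporal co-occurrence networks and **co-migration fidelity** from
standardized bird-ringing count series at migration stopover sites.

Migratory landbirds adjust their spring timing under climate change, and
they do not travel alone: species with similar schedules pass a stopover
site together. Given daily capture counts of many species over many years,
this package asks three questions:

1. **Who migrates with whom, each year?** Build one species network per
   season from lag-1 Spearman rank correlations of daily abundances
   (species *b* leading *a* by one day), keep links with *r* > 0.5 at
   Holm-adjusted *p* < 0.05, after removing species below the 25th
   percentile of season totals.
2. **Is the group structure strengthening?** Partition each yearly network
   with the Louvain algorithm, measure modularity
   *Q* = Σ_c [L_c/m − (d_c/2m)²], smooth the yearly series with an
   AIC-selected simple moving average, and test for a monotone trend with
   the Mann–Kendall statistic and Theil–Sen slope.
3. **How faithful are co-migrating pairs?** Stack the yearly module labels
   into a species × year affiliation matrix and score each species pair by
   the normalized mutual information, nmi = 2·I(a;b)/(H(a)+H(b)) ∈ [0, 1],
   of their affiliation histories. Cluster species by complete linkage on
   1 − nmi (dendrogram cut 0.5) and partition the fidelity distances among
   species traits — wintering area, foraging niche — with a
   permutational multivariate ANOVA (PERMANOVA).

A seeded synthetic-data generator plants known co-migration groups in
realistic multi-year count series (Gaussian passage waves, phenological
drift, log-normal abundance variation, Poisson or negative-binomial
counts), so the whole chain is testable without any field data. The trait
table for the 31 focal species of the Ponza (Tyrrhenian Sea) spring
stopover scheme ships with the package.

## Worked example

Simulate the default study-scale scenario (31 species, 15 seasons of 92
days, three planted timing groups aligned with the wintering areas) and run
the full analysis:

```bash
comigrate run-all --outdir demo_run --seed 1 --simulate --n-perm 999
# report written to demo_run/report.json
# mean Q = 0.599; MK z = 0.893 (p = 0.3719); 3 fidelity clusters
```

From `demo_run/report.json` (seed 1):

* Every yearly network is strongly modular: mean *Q* = 0.599 ± 0.033
  (range 0.511–0.633), all 15 years above the *Q* > 0.3 convention — the
  planted timing guilds produce dense within-group co-occurrence.
* No modularity trend is planted, and none is detected: Mann–Kendall
  *z* = 0.893 (*p* = 0.37), Sen slope 0.002 /yr.
* 23 species keep at least 8 analysable years after the abundance filter;
  clustering their fidelity matrix at cut 0.5 yields 3 clusters that match
  the planted groups exactly (NMI vs ground truth = 1.0). Mean within-group
  fidelity is 1.0 in each wintering area, against an overall pairwise mean
  of 0.595.
* PERMANOVA: wintering area explains the fidelity distances (R² = 1.0,
  *p* = 0.002 with 999 permutations; the pseudo-F is infinite because the
  planted groups leave no residual), and all three pairwise area contrasts
  are significant after Holm adjustment (adjusted *p* = 0.027–0.029).
  Foraging niche, unrelated to the planted timing, explains nothing.

Every stage can also be run separately (`comigrate simulate | infer |
modularity | trend | fidelity | permanova`) against the same run
directory; stages communicate through plain CSV/GraphML/JSON artifacts,
and a given `--seed` makes the whole chain bit-for-bit reproducible. Real
data enter through `--counts` / `--traits` CSVs (long or wide count
layout; see `comigrate infer --help`).

The same API is available from Python:

```python
import comigrate as cm

seasons, truth = cm.simulate(cm.default_scenario(seed=1))
net = cm.build_network(seasons[0])            # one year's network
part = cm.louvain(net, seed=1)                # modules + Q
print(part.Q, part.n_modules)                 # 0.5564803804994054 3
```

## Caveat on the fidelity statistic

NMI compares affiliation histories up to relabelling: species pairs that
never share a module can still score high if their module memberships move
in lock-step, and with year-to-year-static partitions the between-group
values reduce to label coincidences near the 0.5 clustering cut. The
statistic is informative when module composition genuinely varies between
years — as in real stopover data. `docs/methods.md` discusses this and all
other modelling choices in detail.
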