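# ch4rumen

Methane phenotyping of dairy cows from laser-methane-detector (LMD)
traces, and analysis of how rumen 16S bacterial communities differ
between low and high methane-emitting animals.

Enteric methane leaves a cow's rumen mostly by eructation, so a handheld
LMD pointed at the nostrils records a trace whose *peaks* — not its
baseline — carry the emission signal. `ch4rumen` implements the full
computational chain used in large LMD screening campaigns:

1. **Phenotyping.** Per 3-minute session (~180 readings, ppm × m):
   range-filter to [200, 8000], set a threshold at mean + 1 SD and
   average the readings strictly above it. Per cow: mean of ≥ 2 session
   phenotypes, then population QC at mean ± 3 SD.
2. **Extreme-group selection.** Among cows passing eligibility filters
   (milk yield 30–40 kg, parity 1–2), assign LME (low-emitting) below
   mean − 0.65 SD and HME above mean + 0.65 SD of the phenotype
   distribution.
3. **Community analysis** of each group's rumen ASV table: low-count
   filtering, shared/unique ASV (Venn) partition, α diversity (Observed,
   bias-corrected Chao1, Shannon, Gini–Simpson 1 − Σp², Pielou H/ln S),
   analytic rarefaction, Bray–Curtis or unweighted UniFrac β diversity,
   PCoA and nonmetric MDS, and PERMANOVA (ADONIS) with
   p = (1 + #{F* ≥ F}) / (1 + n_perm).
4. **Differential abundance**: a clean-room two-class LEfSe-style screen —
   Kruskal–Wallis per feature, Benjamini–Hochberg FDR within each
   taxonomic rank, and an LDA effect size on per-million-normalized
   abundances, passing at FDR < 0.05 and log10(LDA) > 3 — plus Spearman
   correlation networks of the top-10 taxa per group.
5. **Predicted-function profiling**: PICRUSt2-style KO tables normalized
   to RPKM (count × 10⁹ / (length_bp × library)), aggregated to KEGG
   level-2/level-3 pathways, and screened with the same machinery at
   log10(LDA) > 1 (or > 2).

Because raw LMD/16S datasets of this kind are rarely deposited, the
`simulate` module generates every input with known ground truth
(boxcar-eructation traces, Dirichlet-multinomial ASV tables with spiked
taxa, gamma-Poisson KO tables with pathway effects), which is what the
test suite and the reproduction script run on.

## Worked example

```python
from ch4rumen import phenotyping as ph
from ch4rumen.simulate import TraceSimSpec, simulate_lmd_sessions

sessions, latent = simulate_lmd_sessions(TraceSimSpec(seed=1))
cows = ph.phenotype_cows(sessions)          # filter -> peaks -> QC
# ... attach milk_yield/parity, then:
selected = ph.select_groups(cows[cows["qc_pass"]])
```

Running `python examples/01_phenotyping.py` prints:

```
180 sessions of 180 readings each
LME: n=12 mean=877.7 sd=91.9 CV=10.47% ppm x m
HME: n=15 mean=1341.8 sd=91.4 CV=6.81% ppm x m
Welch t-test LME vs HME: t=-13.07, df=23.7, p=2.59e-12
```

i.e. from 60 simulated cows, 12 low and 15 high emitters are selected;
the groups sit ~460 ppm × m apart with within-group CVs of 7–10%, and a
Welch test confirms the separation the selection was designed to create.
The other scripts in `examples/` walk through diversity/ordination
(`02`), the differential-taxa screen (`03`), function profiling (`04`)
and the one-call pipeline (`05`).

A thin CLI wraps the same functions for shell use:

```bash
ch4 run --out demo --seed 11          # full chain + manifest.json
ch4 phenotype --traces traces.csv --out phen.tsv
ch4 diversity --table asv.tsv --tax tax.tsv --groups groups.tsv --out div/
```

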