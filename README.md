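# rhythmrank

Prioritize the **core transcriptional regulators** of periodic biological
programs — cell cycles, circadian clocks — directly from time-series gene
expression data.

Large periodic transcriptional programs are driven by small gene regulatory
networks whose core nodes (mostly transcription factors, TFs) interact in a
strongly connected loop of activation and repression; the rest of the
rhythmic transcriptome consists of output genes that receive the periodic
signal but do not feed back, plus an aperiodic majority. Core transcripts
tend to oscillate precisely at the process period with large amplitude,
while the signal degrades as it propagates outward. `rhythmrank` turns that
observation into a gene-prioritization pipeline: it quantifies **periodicity
at a specified period T** and **regulation strength** (variability about the
mean, an amplitude proxy) for every gene, combines the statistics into
ranking metrics, and evaluates how strongly a ranking enriches its top with
known core genes.

## Metrics

For a profile $G = (x_1,\dots,x_n)$ sampled at times $t_1,\dots,t_n$, with
$\tilde{x}_i = x_i - \bar{x}$:

| metric | definition | direction |
|---|---|---|
| Per score | $\sqrt{\left(\sum_i \tilde x_i \cos\frac{2\pi t_i}{T}\right)^2 + \left(\sum_i \tilde x_i \sin\frac{2\pi t_i}{T}\right)^2}$ | larger |
| Reg score | population SD of $G$ about $\bar x$ | larger |
| $p_{per}, p_{reg}$ | add-one empirical tail probabilities of the scores against an ensemble of profiles resampled from the data | smaller |
| $p_{jtk}$ | JTK-style rhythmicity p-value: exact one-sided permutation null of the Kendall S statistic against phase-shifted cosine templates, Bonferroni-corrected over phases | smaller |
| PerReg | $\mathrm{Per}(G)\cdot\mathrm{Reg}(G)$ (no resampling needed) | larger |
| DL | $p_{per}\cdot p_{reg}$ | smaller |
| DL×JTK | $p_{jtk}\cdot p_{reg}$ | smaller |

Rankings are evaluated with tie-aware precision–recall curves, average
precision (AP), the $C/N$ random baseline ($C$ positives among $N$
candidates), and recall among the top $k$ (default 25) for three tasks:
core-vs-rest among TFs, core-vs-rest among all genes, and the TF-vs-all
negative control.

A synthetic-transcriptome generator (`rhythmrank.synthetic_data`) produces
labeled benchmark datasets — precise large-amplitude core oscillators,
distance-degraded output genes, white-noise background, optional RNA-seq
style abundances with sub-threshold and duplicate-probe rows — so the whole
pipeline is testable without any external download.

## Worked example

```bash
rhythmrank simulate --n-genes 2000 --n-core 15 --n-output 200 \
    --n-tf-extra 150 --seed 11 -o sim/
rhythmrank score --expression sim/expression.tsv \
    --period 94 --interval 16 --duration 254 \
    --n-null 10000 --seed 12 -o scored/
rhythmrank evaluate --scores scored/scores.tsv \
    --core sim/core_genes.txt --tf sim/tf_genes.txt -o eval/
```

The evaluation summary (trimmed to two tasks and three metrics) prints:

```
       task    metric       ap  baseline  recall_at_25
core_in_tfs   per_reg 0.992157  0.090909      1.000000
core_in_tfs  dl_x_jtk 0.879871  0.090909      1.000000
core_in_all   per_reg 0.895175  0.007500      0.933333
core_in_all  dl_x_jtk 0.702936  0.007500      0.800000
  tf_in_all   per_reg 0.186595  0.082500      0.090909
```

Reading: among the 165 TFs, ranking by PerReg places essentially every one
of the 15 core genes above the non-core TFs (AP 0.99 against a random
baseline of 0.09), and all 15 appear in the top 25. The same ranking still
finds the core among all 2,000 genes (AP 0.90 vs baseline 0.0075). The
TF-vs-all control sits near its baseline once the core genes themselves are
discounted: TF membership per se carries no dynamic signal.

The same steps run from a single YAML config via `rhythmrank all`.
Library users can call `simulate_dataset`, `score_dataset`, and
`evaluate_scores` directly; every CLI output (scores, rankings, PR curves,
JSON summary, preprocessing report) has a function-level equivalent.

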