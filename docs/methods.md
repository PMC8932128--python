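# Methods

## The model and its assumptions

`rhythmrank` assumes a periodic transcriptional program driven by a small
core of mutually regulating transcription factors. The observable
consequences taken as the working hypothesis are: (1) core transcripts
oscillate at the specified process period T with high fidelity; (2) their
oscillation amplitude — equivalently, the variability of their abundance
about its mean ("regulation strength") — is large; (3) both properties
degrade with network distance from the core; (4) neither property is
characteristic of transcription factors in general. The pipeline does not
model the network itself: it quantifies per-gene dynamic features and asks
whether a ranking by those features enriches its top with core genes.

The period T is an input (from the experimental design or an external
period-estimation step), never inferred; exactly one period is scored per
dataset.

## Periodicity and regulation scores

The regulation score is the population standard deviation of the profile
about its mean (`ddof=0`; a `ddof=1` switch exists). The periodicity score
is the magnitude of the single-frequency Fourier component of the
mean-centered profile at period T, evaluated at the *actual* sample times.
Using true times matters because supported designs include non-integer
samples-per-cycle ratios (e.g. a 94 min period sampled every 16 min: 5.875
samples per cycle), where forcing an integer grid would alias the phase
drift the score is supposed to capture. Both scores are invariant to adding
a constant and scale linearly under positive rescaling, so the PerReg
product scales quadratically.

Significance is assessed against an empirical null: `n_null` synthetic
profiles are resampled from the observed data, scored by both statistics,
and each gene receives add-one tail probabilities
`p = (1 + #{null >= obs}) / (1 + n_null)`. One shared profile ensemble
serves both statistics, so the two p-values refer to the same null
universe. Three resampling modes are provided because the choice materially
affects the regulation p-value: `pooled` (default — every entry drawn from
the pooled multiset of all observed values), `per_timepoint`
(column-respecting), and `within_gene_permutation` (gene-respecting).
`n_null` defaults to 10,000; a seed is mandatory. The add-one estimator
keeps p-values strictly positive, so products of p-values never collapse to
zero. Empirical p-values are discrete — at most `n_null + 1` distinct
values — which produces tie blocks in p-value rankings; enlarging the
ensemble refines (disambiguates) the attainable set at linear cost.

## The JTK rhythmicity p-value

A profile is correlated, via Kendall's tau, with cosine templates
`cos(2π(t − φ)/T)` at phase offsets φ = 0, step, 2·step, … < T (step
defaults to the sampling interval, so the number of phase groups roughly
equals the samples per cycle). Templates are converted to mid-ranks;
offsets yielding identical rank patterns are deduplicated. Cosine values
are rounded to 9 decimals before ranking so that analytically tied template
values (e.g. symmetric samples about a peak) tie exactly in floating point.

For each template the one-sided permutation probability P(S ≥ S_obs) of the
Kendall S statistic is computed; the minimum over templates is multiplied
by the number of distinct templates (Bonferroni) and capped at 1. Waveform
asymmetry scanning and multi-period scanning are deliberately excluded: the
templates are plain sinusoids at the one specified period.

**Exact null.** Measured abundances are effectively continuous (tie-free),
while templates are tied. Ordering the template's tie groups by template
value with sizes n_1,…,n_g, the S statistic of a tie-free profile satisfies
S = 2J − P, where P is the number of between-group pairs and J the
Jonckheere–Terpstra statistic. The exact permutation null of J is the
coefficient sequence of the Gaussian (q-)multinomial coefficient
[N; n_1,…,n_g]_q, computed by integer polynomial convolution via the
q-Pascal recurrence — exact rational arithmetic, no enumeration, cached per
tie-group signature. The exact path is used up to `n_exact = 25`
timepoints; beyond that (and for the measure-zero case of profiles that
themselves contain ties) a tie-corrected normal approximation with
continuity correction is used (correction 1.0 on the tie-free lattice of
spacing 2, else 0.5). At n = 20 the two routes agree to < 0.005 absolute.
All-tied profiles carry no evidence and receive p = 1 by definition.

## Ranking and combination

Direction conventions are explicit per metric: p-value products ascend
(smaller is better), naive scores descend. The combined metrics are plain
products: DL = p_per·p_reg, DL×JTK = p_jtk·p_reg, PerReg = Per·Reg. Because
AP is invariant under strictly monotone transforms of the scores, any
monotone re-expression of these products (e.g. log) would leave all
reported evaluation unchanged. Sorting is stable, but the within-block
order of equal scores is an implementation convenience only; tie blocks are
exported and treated as exchangeable downstream.

## Evaluation

AP is non-interpolated: the mean of precision at each positive's rank.
Discrete p-values make tie handling a first-order concern, so every
statistic takes a tie policy. The `expected` default uses the closed-form
expectation over uniform orderings within each block: for a block of b
items with c positives starting after m items (k of them positive), the
block's AP contribution is

    Σ_{r=1..b} [ (k+1)·c/b + (r−1)·c(c−1)/(b(b−1)) ] / (m + r),

which matches explicit within-block shuffle simulations to Monte-Carlo
error. `pessimistic` and `optimistic` place the block's positives last and
first, bracketing every possible resolution; the three are reported side by
side. PR curves under the expected policy spread a block's positives evenly
(the j-th at depth j·b/c), which reproduces the flat precision C/N for a
fully tied ranking. Recall@k resolves a block straddling position k by its
hypergeometric mean share.

**Random baseline.** The conventional random-classifier baseline is C/N.
The exact expectation of non-interpolated AP for a uniformly random ranking
is, however,

    E[AP] = H_N/N + (C−1)(N−H_N)/(N(N−1)),

strictly above C/N (the first positives are evaluated at small
denominators), converging to C/N as C grows at fixed prevalence. At C = 17,
N = 307 the exact value is 0.0718 versus C/N = 0.0554. The package exposes
`evaluation.expected_random_ap` and the test suite calibrates
random-classifier behaviour against the exact expectation; C/N is still
reported as the baseline field because it is the convention users expect,
and it is exact in the regime (large C) where the approximation is usually
invoked. Identically, the expected-policy AP of a single all-spanning tie
block equals the exact formula, not C/N.

## Preprocessing

RNA-seq profiles are dropped when below 1 FPKM at strictly more than half
of the timepoints ("more than half" is a strict inequality: a profile low
at exactly half the timepoints is kept). After filtering, RNA-seq
abundances default to log2(FPKM+1) — variance-based scores on raw FPKM are
dominated by the most abundant genes — with `transform: none` available;
microarray log-ratios are used as provided. Leading timepoints confounded
by synchronization recovery can be dropped (k = 2 for elutriation-
synchronized cell-cycle arrays). Multi-probe genes are collapsed to the
profile with the highest mean abundance; mean ties keep the first profile
in file order (deterministic). Matrices with missing or non-numeric cells
are rejected at ingestion rather than imputed — the scoring statistics have
no principled missing-data treatment. Gene IDs are matched to label lists
by exact string equality after upper-casing; unmatched label IDs are
reported, never silently dropped. The FPKM floor applies to raw FPKM before
any log transform.

## The synthetic-data generator

The generator emulates the qualitative structure the metrics are designed
to detect, not any particular organism. Core genes: x(t) = A·cos(2π(t−φ)/T)
with A log-normal (default median 2, log-scale 0.25 on the log-ratio
scale), φ uniform on [0, T), period exactly T. Output genes at network
distance d ∈ {1,…,D} (d uniform, D = 3; no explicit graph topology):
amplitude A·γ^d (γ = 0.6 by default), period T·(1+δ) with δ ~ N(0, 0.05),
damping envelope e^(−λt) (λ = 0.002 per time unit). Background genes: white
noise with SD 0.5. Measurement noise (SD 0.25) is added to every gene.
The default design is 16 samples at 16 min spacing with T = 94 min, so the
non-integer samples-per-cycle path is the default path. The RNA-seq mode
maps the signal through 10·2^x onto a non-negative abundance scale and
plants sub-threshold profiles (uniform on [0, 0.5) FPKM) and
lower-abundance duplicate probes in configured fractions; the planted sets
are disjoint so each preprocessing step's removal count is exactly its
planted count. TF labels are the core plus a uniform random draw of
non-core genes.

What passing tests on these data do *not* show: robustness to non-sinusoidal
waveforms, missing samples, batch structure, heteroskedastic measurement
noise, multi-tissue mixture dilution, or shared external forcing beyond the
additive diurnal analogue — real transcriptomes contain all of these.

Default problem sizes in the test and acceptance harnesses (2,000–5,000
genes, 10,000-profile null ensembles, 20 replicate seeds per condition)
were chosen so each statistical check has enough resolution for its stated
tolerance while the full suite remains interactive-fast; all are plain
parameters.

## Numerical choices and degenerate inputs

Exact JTK nulls use Python integer arithmetic (coefficients overflow
doubles well below n = 25) and convert to float only in the final survival
function. Constant profiles: Per = Reg = 0, p_jtk = 1, tau undefined
(flagged, not NaN-propagated). Kendall denominators with tied data use the
tau-b correction. AP with zero positives raises rather than returning 0.
Rankings reject non-finite scores by gene name. The fully-vectorized JTK
matrix path computes one exact survival function per template tie-group
signature and reuses it across all genes.

## Known limitations

Single fixed period per run (no period scanning or estimation); sinusoidal
templates only; empirical p-values are exchangeable-null only (no
autocorrelation-preserving null); no multiple-dataset meta-ranking; the
synthetic generator's independence assumptions understate the correlation
structure of real co-regulated transcriptomes.
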