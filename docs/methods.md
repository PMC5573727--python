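# Methods

This note documents the models, conventions and numerical choices behind
`elmseq`, module by module, including what the simulator does and does not
emulate about real screen data.

## Measurement model

Each reporter construct carries four GATC sites upstream of a randomized
promoter (N25 + fixed TATAAT Pribnow box + N7, screen coordinates −37..+1
with no position 0, +1 the theoretical transcription start) or a
randomized 5′-UTR (25 nt at −25..−1 before the +1 = A of the dam ATG, with
a fixed transcript first base at −26: T for the strong promoter, A for the
weak one). Dam expression methylates the adenine of GATC; MboI cuts
unmethylated sites and DpnI cuts methylated ones, so the uncut survivors
of each digestion report the construct's methylation state. A
hemimethylated site (one strand marked) resists both enzymes.

## Read processing (`readproc`, `templates`)

Raw reads are reverse complements of the construct sense strand; they are
flipped and matched against the constant anchors **exactly** at fixed
template offsets (a floating-search mode exists for robustness, default
off, and is the only mode that can detect an indel-shortened variant as
`length_mismatch`). Reads with any `N` inside the randomized region are
rejected as `ambiguous_base`. Counts are exact multiset counts of
accepted reads per digestion pool; pool totals count accepted reads only,
with rejected reads tallied by reason. Quality scores are ignored; FASTA
and FASTQ (plain or gzipped) are both accepted.

Only 33 nt of the dam reading frame are pinned down by the filtering
anchors; the longer coding context used for folding windows extends this
with a synthetic in-frame continuation (see `templates.py`). It is
arbitrary but fixed, which matters only for the folding provider's inputs,
never for counting.

## DAMRatio (`damratio`)

`CPM = (X + 1)/(N + 1) × 1e6` with the pseudocount guaranteeing positive
values at any depth, `DAMRatio = CPM_mbo / CPM_dpn`, log base 10
throughout. The support filter keeps variants with **strictly more than**
100 reads (default) in the DpnI or MboI pool; the uncut pool is reserved
for DNA-dosage normalization of RNA abundances. CPMs always use the
unfiltered pool totals.

Replicates are combined by ordinary least squares of replicate B's log10
DAMRatio on replicate A's over their shared variants (≥ 50 required),
mapping B back through the fitted line onto A's scale, then averaging the
available values per variant; variants seen in one replicate keep their
single (mapped) value. Whether the original analysis averaged raw or
regression-adjusted values is not determinable from its description; the
mapping used here is recorded in the fit metadata
(`ols_b_on_a_inverse_then_mean`).

## Mixture standardization and classification (`mixture`)

Log10 DAMRatios are fitted with a 1-D Gaussian mixture (EM, tolerance
1e-6 on the log-likelihood, ≤ 500 iterations, 20 seeded k-means++
restarts; deterministic given the seed). `k="auto"` selects the component
count by BIC over {1, 2, 3}: the screens' distributions are bimodal (weak
promoter screens can need a third, middle component), and K = 1 is
included so a genuinely unimodal input standardizes to its single peak
rather than to the left half of an artificially split Gaussian.
Components with sd < 1e-4 are pruned by refitting with one fewer.

Standardization subtracts the left-most component mean (the
low-productive peak) so screens share a zero point. Classification
compares each value's posterior under the right-most ("high") vs
left-most ("low") component only; any middle component's responsibility
is reported but not used for the call, and exact ties go to "low".

## Positional and motif statistics (`posstats`)

Per (position, base) cell the log2 odds ratio of high vs low class uses
the Haldane–Anscombe pseudocount α = 0.5 so zero cells stay defined;
Fisher exact p-values are Bonferroni-corrected over all 4 × L cells. The
odds ratio cancels library-composition bias common to both classes.
Motif-subgroup comparisons (e.g. extended −10 TGN variants, alternative
Pribnow boxes TATAAT/TAAAAT/TACAAT/TAGAAT) use two-tailed equal-variance
t-tests by default (Welch by flag), Bonferroni over all pairwise
comparisons; groups smaller than 2 are skipped.

Shine–Dalgarno detection is deliberately simple and declared as such: the
longest contiguous run of the UTR window (−20..−1 by default) matching the
SD consensus (equivalently, pairing contiguously and antiparallel with the
16S anti-SD, the consensus' reverse complement), with `has_sd` at runs ≥ 4.
The consensus is a configurable parameter, not a claim about the assay
species. Folding-energy-controlled SD comparisons stratify on ΔG bins of
1 kcal/mol.

## Epistasis (`epistasis`)

Pairwise epistasis is the plug-in mutual information (bits) of the bases
at two positions among **high-productive** sequences, divided by the mean
MI of repeated random draws from the **full library** ("same number of
sequences": draw size defaults to the observed-set size, draws without
replacement, configurable to the alternative readings by flags). Ratios
≈ 1 mean no dependence beyond library structure and estimator bias.

A calibration caveat worth knowing: for truly independent positions the
plug-in MI is approximately χ²₉/(2N ln 2)-distributed, so its *relative*
fluctuation (~47%) does not shrink with N. Consequently only an observed
set that coincides with (or nearly exhausts) the resampling pool yields
ratios pinned near 1; a strict random subset of the pool scatters well
outside ±25% no matter the depth. Planted couplings, in contrast, sit
orders of magnitude above the null and are reliably the matrix argmax —
that is the regime the statistic is designed for.

## Folding (`folding`)

Folding energies come from a provider contract with two backends. The
default is a deterministic maximum-base-pairing model (Watson–Crick + GU
wobble, minimum hairpin loop 3, −1.0 kcal/mol per pair, dynamic
programming vectorized over variant batches, dot-bracket structures by
traceback). It is a combinatorial model with the right monotonicity —
more pairing, lower energy — not nearest-neighbor thermodynamics, and
every analysis records which provider produced its numbers. An RNAfold
subprocess backend is available when the binary is installed. DNA input
is transcribed (T→U) before folding.

The window scan computes, for every (start, end) coordinate pair in the
configured ranges (defaults −26..−1 × −10..100, minimum window 8 nt),
the Pearson correlation across variants between the window's ΔG and log10
DAMRatio, reporting NaN for windows leaving the available sequence. The
count of admissible windows depends on these explicit length constraints
and is reported rather than assumed. Exposure analysis marks a position
hidden iff paired in the dot-bracket structure; high/low exposure
comparisons stratify on ΔG bins (width 1 kcal/mol) to control overall
stability, combining bins into a size-weighted log2 enrichment with
pseudocount 0.5, Fisher exact p per position on pooled counts.

## Predictors (`predict`)

Sequences are one-hot encoded, A=(1,0,0,0) … T=(0,0,0,1), concatenated
per position. The classifier is Bernoulli naive Bayes with Laplace
smoothing 1 (the smoothing makes posteriors only asymptotically invariant
under training-set duplication). The regressor is ε-insensitive SVR on
log10 DAMRatio with RBF kernel, ε = 0.2, C = 1.0 and bandwidth
γ = 1/n_features by default — ε is fixed by the assay's design; C and γ
are library defaults exposed as flags. ΔG features are appended for
exactly the windows whose training-split scan correlation is positive;
the scan must come from the training split only (leakage guard), and the
selected windows are frozen into the model metadata. AUC is the rank-sum
form with ties counting ½, cross-checked against an independent
implementation in the tests.

## TSS calling (`tss`)

RNA-seq reads are kept iff they contain the dam 5′ anchor exactly. After
trimming the ligation barcode (6 nt by default), the portion before the
anchor is matched as an exact suffix of a library variant's 26-nt UTR —
reads are 5′-truncated transcripts of known constructs, so suffix lookup
is complete and alignment unnecessary. Lengths < 15 are discarded
(mapping ambiguity floor); a 26-nt match implies the correct promoter +1
base because that base is part of the stored UTR; suffixes matching more
than one variant are discarded rather than fractionally assigned (policy
recorded in the mapping tally). TPM = N_il/N_tot × 1e6 without
pseudocount, N_tot the anchor-filtered read count. The called TSS is the
read-count argmax over lengths, ties resolved toward the longer UTR (the
theoretical +1, label N7) and flagged; length 26 → N7, 25 → N8, etc. RNA
abundance (ΣTPM per variant) is optionally divided by log10 of the uncut
DNA count, left unnormalized with a flag when that count is ≤ 1.

## Simulator (`simulate`)

Ground truth: log expression = Σ positional weights + Σ pairwise
epistasis bonuses + Gaussian noise; methylation probability
m = E/(E + K_half) (saturating link, K_half defaulting to the library
median so the screen straddles its dynamic range); per-site
hemimethylation fraction h. Per GATC site, survival of the MboI digestion
is h + (1−h)m and of DpnI h + (1−h)(1−m); the four sites are independent,
so fragments survive with the fourth power — with h = 0 this is m⁴ and
(1−m)⁴. Pools are multinomial draws over variants weighted by abundance ×
survival (the uncut pool by abundance alone), optionally expanded into
raw reverse-complement reads with a uniform substitution error rate.
RNA-seq reads carry a random barcode, a planted-length UTR suffix and the
dam anchor, with counts ∝ expression × planted length distribution (by
default purine first bases shift the dominant start one base downstream,
mirroring the N7→N8 shift these screens observe).

Default study conditions: the stock promoter configuration plants graded
effects at −17..−13 (A favorable, C unfavorable, ~±1.2 natural-log units
per position), a purine bonus at +1 and one interacting pair, with noise
sd 0.3 — log10 expression then spans roughly three decades, comparable to
the dynamic range such screens report. Pipeline-recovery analyses use
1,000 variants at 10^6 reads per pool; predictor analyses use 12,000
variants so that two disjoint 5,000-sequence training sets and a
2,000-sequence test set exist, matching the scale at which the assay's
published stability checks are meaningful while keeping desk-scale run
times.

What the simulator does **not** emulate: PCR duplicates and amplification
bias, per-site methylation correlation along a molecule (a processivity
parameter exists but defaults off), library synthesis composition bias
(available as an option, off by default), sequencing quality scores, and
any model of the hemimethylation *mechanism* beyond the minimal
both-enzymes-resistant site state — the last is a reconstruction, since
the original simulation's details are not available. Passing tests
therefore demonstrate correctness of the pipeline's inference under a
clean generative model, not robustness to every artifact of real runs.

## Growth curves (`growthqc` → `growth`)

Pairwise slopes between measurements a fixed gap apart (3 for the early
slope, 4 for the late), summarized as the maximum over sliding windows
(30 slopes, step 1) of the within-window median. The early slope is
restricted to the 10–30 h interval before windowing; when a restricted
series is shorter than one full window the whole series forms a single
window (hourly sampling gives 18 pairwise slopes in that interval), and
trailing incomplete windows are otherwise dropped.

## Determinism and problem sizes

Every stochastic step (simulation, mixture restarts, resampling nulls,
train/test splits) takes an explicit seed and is bit-reproducible given
it. Tests and the acceptance script run on simulated libraries of
120–12,000 variants and up to 10^6 reads per pool — sizes chosen so the
full suite completes in about a minute while leaving every statistical
margin wide; the acceptance script reports the problem size next to each
measured quantity.
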