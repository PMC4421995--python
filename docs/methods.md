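# Methods

`decaydet` analyzes what determines mRNA lifetime in a bacterium growing at
different rates. Its inputs are per-gene half-lives and mRNA concentrations
measured at four steady-state growth rates (mu = 0.10, 0.20, 0.40,
0.63 h^-1), transcript sequences (ORF and experimentally mapped 5'UTR) and
gene-level annotations (operon membership and position, COG functional
categories, essentiality, cell location of the product, signal-peptide
flag). This note records the models, conventions, numerical choices and
limitations; everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Linear covariance models of ln(half-life)

One ordinary-least-squares model is fitted per growth rate on a single
shared gene set:

    ln(t_half) = alpha + sum_q beta_q * x_q + sum_l lambda_l * 1[level l] + eps

* **Response.** ln(half-life in minutes), never standardized. Coefficients
  are therefore "semi-standardized": beta_q is the change in ln(t_half) per
  SD of the (ln-transformed) covariate.
* **Quantitative covariates** — mRNA concentration, CAI, ORF length, 5'UTR
  length, 5'UTR+ORF length, %GC of ORF / 5'UTR / 5'UTR+ORF, folding Z
  score. All are ln-transformed to symmetrize their distributions, except
  the Z score, which is already on a normal scale; all are then centered
  and reduced (population SD) so coefficient magnitudes are comparable.
  In the protein models, GRAVY and the amino-acid percentages are likewise
  not ln-transformed (they can be zero or negative).
* **Qualitative covariates** — essentiality, signal peptide and
  second-nucleotide (purine vs pyrimidine) as single 0/1 indicators;
  operon size as a categorical term with monocistronic baseline; cell
  location as categorical with the most frequent label as baseline; COG as
  one indicator per category with *no* baseline, because genes may belong
  to several categories. `DesignSpec(standardize_indicators=True)`
  additionally centers/reduces the indicator columns, putting qualitative
  coefficients on the same scale as quantitative ones; parameter-recovery
  experiments use this option so generated and refitted coefficients are
  directly comparable.
* **Complete cases.** A gene enters the analysis only if every covariate is
  present and the response and mRNA concentration are measured at **all
  four** growth rates, so the four models describe one population.
  Covariates that are ln-transformed must additionally be strictly
  positive; in practice this only excludes 5'UTRs containing no G or C
  (zero %GC), about 1% of genes under the default generator.

**Term selection** minimizes `n*ln(RSS/n) + 2N` (n observations, N
estimated coefficients — the least-squares form of the Akaike criterion)
by bidirectional stepwise search starting from the full model. A
qualitative term enters or leaves with all of its columns; N counts
columns. Moves are accepted only if they strictly lower the criterion
(tolerance 1e-10); ties prefer the smaller model, then the
lexicographically first term. On small scopes the search matches
exhaustive best-subset enumeration in >= 95% of random instances (it is a
heuristic; rare divergences are expected and tolerated). Reported p-values
are OLS t-tests on the final selected model; because they are computed
after selection they are descriptive, not strictly valid tests — the same
caveat applies to any stepwise-selected model.

The protein-level models use ln(protein concentration) as response,
exclude mRNA concentration (strongly collinear with half-life by
construction of the decay process) and add ln(half-life), GRAVY and the 20
amino-acid percentage covariates. The amino-acid percentages sum to 100,
so the full design is rank-deficient by one; the stepwise RSS evaluation
uses a least-squares solver that tolerates this, and the final fit rejects
rank-deficient selections explicitly.

## Sequence features

* **CAI** — geometric mean of relative adaptedness `w` over informative
  codons. `w(codon) = count / max count among synonyms` in a reference set
  of highly expressed (ribosomal-like) genes. Met, Trp and stop codons are
  excluded (their families are uninformative); reference codons with zero
  count receive `w = 0.5 / max_count` so the log is defined. Both choices
  follow common CAI practice and are configurable — the original CAI
  definition leaves them open.
* **5'UTR conventions** — when several TSS are annotated, the furthest
  from the start codon defines the UTR (minimizing sequence loss). The
  transcript's second nucleotide is position 2 counting the TSS as 1;
  purines are {A, G}. Sequences are stored as DNA throughout; U/T
  normalization happens at I/O boundaries.
* **GRAVY** — mean Kyte–Doolittle hydropathy per residue; the hydropathy
  table ships as a data file. Translation uses the bacterial code.

## Folding Z score

For the region from 30 nt upstream to 24 nt downstream of the start codon
(positions -30..-1, +1..+24; no position 0):

    Z = (MFE_native - mean MFE_shuffled) / SD MFE_shuffled

over 100 dinucleotide-preserving shuffles (sample SD). Shuffling uses the
Euler-path construction: the last-exit edge of every vertex is redrawn
until the exits form an arborescence into the final base, remaining edges
are permuted, and the walk is replayed. This preserves the exact
dinucleotide multiset and the two end bases and gives every valid shuffle
positive probability.

5'UTRs shorter than 30 nt contribute what they have and the result is
flagged truncated; dropping them instead would discard the covariate for a
large minority of genes. Genes with no mapped 5'UTR get a missing Z score
by default. Homopolymeric regions (shuffle SD below 1e-9) yield a missing
Z score. Shuffle RNGs are spawned per gene from one master seed.

The bundled folding engine is a nested-structure dynamic program over
{GC: -3, AU: -2, GU: -1} kcal/mol pair energies, a -1 kcal/mol bonus per
directly stacked pair and a minimum hairpin loop of 3 nt. These constants
are deliberately simple: Z scores only compare the native sequence with
its own shuffles under the same engine, so the Z score is invariant to any
affine rescaling of the energy table. An adapter for the external
`RNAfold` nearest-neighbor folder is provided for users who want physical
energies; no analysis here requires it.

## 5'UTR motif exceptionality

All 1024 5-nt words are scored in a sequence set (each 5'UTR truncated to
its last 100 nt before the start codon) against a first-order Markov (M1)
null fitted to the set's pooled dinucleotide counts:

    E(w) = sum_seq (L_seq - 4) * mu(w1) * prod p(w_i | w_{i-1})

The score is the probit of the p-value from the Gaussian approximation to
`N(w) - E_hat(w)`. The variance accounts for (i) word self-overlap and
(ii) plug-in estimation of the M1 parameters from the scored sequences:
the statistic is linearized in the word, dinucleotide and interior-letter
counts, and the asymptotic covariances of word counts in a stationary
Markov chain (overlap terms plus a fundamental-matrix tail) give
`Var = n c' Sigma c`. Monte-Carlo tests confirm the first two moments to
within a few percent, and null scores are ~N(0,1). An optional empirical
null — dinucleotide-shuffling every sequence B times, which samples the
exact conditional distribution given dinucleotide composition — can
override the analytic p-value and acts as the in-repo oracle for the
approximation. (The original motif analysis used a compound-Poisson
approximation; for the abundant words of interest the approximations
agree, while rare-word tails may differ.)

Quartile comparison: genes with a nonempty truncated 5'UTR and a half-life
at the growth rate of interest are ranked by half-life (ties broken by
gene id); the top and bottom `ceil(0.25 n)` form the stable and unstable
sets (1937 eligible genes give sets of 485). Words with stable-set score
>= 3 and stable-minus-unstable score difference >= 3 are reported as
candidate stabilizing motifs. Both thresholds are explicit configuration:
with ~N(0,1) null scores and 1024 words, about one word per run clears
them by chance, so single-run calls need replication — exactly why the
planted-motif experiments use repeated seeds. Motif-to-start-codon
distance counts the nucleotides between the word's 3' end and the first
base of the start codon (a word ending immediately before the ATG is at
distance 0).

## Operon and kinetics analyses

Operons are analyzed only when every member cistron has a half-life at all
four growth rates and positions run consecutively from 1. Within-operon
stability gradients are summarized as log2 ratios of the half-life at
position k versus position 1. The "last cistron stabilized" fraction uses
the half-life ratio last/first >= 1.5; the ratio is averaged across growth
rates before thresholding by default (a per-rate variant is available) —
the alternative reading, a mean ratio >= 1.5, is also reported.
Degradation rate constants are `k = ln(2)/t_half` per minute; kinetics
summaries bin genes by integer-aligned unit-width bins of log2 mRNA
concentration. Boxplot summaries use linear-interpolation quantiles and
the McGill notch `median +/- 1.58*IQR/sqrt(n)`; disjoint notches indicate
medians that differ at roughly 95% confidence.

## Synthetic data generator

The generator emulates the compiled dataset's structure so the whole
pipeline runs with no external data:

* operon sizes 1–16 (default mix: 55% monocistronic, tail to 16);
* ORF lengths lognormal around 280 codons (sigma 0.45, minimum 30);
  ORFs start ATG, end with a stop, length divisible by 3;
* codon choice mixes a GC-tilted distribution (tilt solved numerically so
  the expected ORF GC hits `gc_target`, default 0.51) with each amino
  acid's preferred codon, at a per-gene bias drawn from (0.05, 0.95) —
  the bias drives CAI; the CAI reference set is 55 "ribosomal-like" genes
  generated at 95% preferred-codon usage;
* 5'UTRs of 1–100 nt, i.i.d. bases at the target GC, occasionally with a
  second annotated TSS; COG / essentiality / location labels drawn from
  E. coli-like frequencies.

Expression follows the same linear structure the model module fits.
ln(mRNA) is drawn per rate (means rising with growth rate, SD 1 on the ln
scale) and enters the predictor through its coefficient — with the default
beta_mrna = -0.85 this makes (ln mRNA, ln t_half) jointly Gaussian with a
strong negative correlation, as in the measured data. All truth
coefficients, qualitative ones included, are defined on the standardized
scale (the generator centers/reduces each column exactly as the model
module does, sharing the feature code path), so refitting recovers them
directly; with sigma = 0 recovery is exact to numerical precision.
Default truth: beta_mrna = -0.85, beta_CAI = +0.2, beta_ORFlen = -0.15,
lambda_essential = +0.1, sigma = 0.72 (R^2 ~ 0.6, the quality of fit of
the mid-range growth-rate models). Half-lives are centered on the
geometric midpoint of the 1–53 min range; hard clipping to that range is
available but off by default, because truncating the tails attenuates the
very coefficients recovery experiments measure. Protein levels are driven
by standardized ln(half-life) (-0.14) and ln(CAI) (+0.5) with noise set
for R^2 ~ 0.5. Optionally a 5-nt word is planted at a uniform position
into a fraction of the 5'UTRs of one stability quartile, and a
per-position ln(half-life) increment emulates the 5'-to-3' within-operon
stability gradient.

For genome-scale runs the Z-score covariate can be drawn from its own
null, N(0,1), instead of being computed by folding ("simulated" mode, the
default in `generate_dataset`): folding 100 shuffles for every gene costs
minutes per replicate, carries no planted signal, and the folding-based
mode remains available (`zscore_source="fold"`) and is what the Z-score
module's own tests exercise. Because simulated Z scores are not derivable
from the sequences, refits must reuse the generator's feature vectors —
`generate_dataset` returns them.

**What passing tests do and do not show.** The generator's covariates are
cleaner than real data: measurement error in half-lives is a single
lognormal noise term, mRNA concentration is exogenous rather than the
outcome of coupled synthesis/decay, codon usage has a single preferred
codon per amino acid, UTR lengths are uniform rather than skewed, and no
gene-specific regulation (sRNAs, riboswitches, RNase-site idiosyncrasies)
exists. Recovery results therefore validate the *statistical machinery*
(transformation, coding, selection, scoring), not the biological claims;
on real data, selection among collinear covariates (the three length
terms, the three GC terms) is genuinely ambiguous, which is why
parameter-recovery experiments exclude the composite 5'UTR+ORF length
from the candidate scope — at realistic length scales it is a
deterministic near-copy of ORF length.

## Numerical choices

* Standardization uses the population SD (ddof = 0); two points {a, b}
  map to {-1, +1}.
* Natural logs everywhere in modelling; log2 only for ratio displays.
* Stepwise acceptance tolerance 1e-10; zero RSS maps to a -inf criterion
  with a warning; zero-variance design columns raise an error naming the
  term; dummy columns that become constant after complete-case filtering
  are dropped silently with their term.
* Shuffle-degenerate Z scores (SD < 1e-9) and words whose expected count
  is zero (unseen dinucleotide) are flagged missing/unscorable rather
  than forced to a number; a word whose count is deterministic under the
  null (variance 0, observed = expected) scores exactly 0.
* Quantile convention: numpy linear interpolation.
* Problem sizes in the default test and acceptance runs: 1500-gene genomes
  for recovery (10–20 replicates), 2000-gene genomes for motif experiments
  (quartile sets of 500, matching the real analysis's 485), 800 genes for
  protein models. These sizes reproduce the study-scale statistics while
  keeping a full run in minutes on one CPU.

## Known limitations

* The bundled folding engine is not a nearest-neighbor thermodynamic
  model; absolute MFEs are not comparable to RNAfold's, only Z scores are
  meaningful.
* Analytic motif variances are asymptotic (O(1/L) boundary terms ignored)
  and the Gaussian tail underestimates the skew of rare-word counts; use
  the empirical null for words with small expected counts.
* Post-selection p-values are not honest tests (see above).
* The operon analysis assumes the annotation's positions reflect the
  transcript's 5'-to-3' order and treats each operon's genes as one
  transcription unit; suboperonic structure is not modelled.
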