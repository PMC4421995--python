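# decaydet

Genome-wide analysis of what determines mRNA lifetime in a bacterium
growing at different rates.

Bacterial transcripts are degraded within minutes, and their half-lives
span more than an order of magnitude (roughly 1–53 min in *E. coli*).
`decaydet` asks which general, gene-level properties explain that
variability, and whether the answer changes with growth rate. It takes
per-gene mRNA half-lives and concentrations measured at four steady-state
growth rates (mu = 0.10, 0.20, 0.40, 0.63 h^-1), transcript sequences
(ORF + experimentally mapped 5'UTR) and annotations (operon
membership/position, COG category, essentiality, cell location,
signal-peptide flag), and provides:

* **Covariance models** — per growth rate, an OLS model

  `ln(t_half) = alpha + sum_q beta_q x_q + sum_l lambda_l 1[level] + eps`

  over standardized quantitative covariates (mRNA concentration, CAI,
  lengths, GC%, folding Z score) and qualitative indicators, with
  bidirectional stepwise term selection minimizing `n ln(RSS/n) + 2N`
  (the least-squares Akaike criterion). Analogous models explain protein
  concentrations (adding ln half-life, GRAVY, amino-acid composition).
* **Sequence features** — codon adaptation index against a highly
  expressed reference set; GC contents and lengths per region; the
  thermodynamic Z score of the -30/+24 start-codon region over
  dinucleotide-preserving shuffles, with a bundled folding engine and an
  `RNAfold` adapter.
* **5'UTR motif exceptionality** — all 1024 pentamers scored against a
  first-order Markov null (expected counts, overlap- and
  estimation-corrected variances, probit scores) in the most- and
  least-stable half-life quartiles, plus motif position profiles and
  notched-boxplot half-life comparisons.
* **Decay structure** — degradation rate constants `k = ln 2 / t_half`,
  kinetics vs concentration summaries, and cistron-position analysis of
  polycistronic transcripts (log2 half-life ratios vs the first cistron).
* **A synthetic-data generator** with known ground truth (operon
  structures, codon bias driving CAI, planted 5'UTR motifs, planted
  within-operon stability gradients), so every stage is testable without
  any external dataset.

See `docs/methods.md` for model conventions, numerical choices and
limitations.

## Worked example

```python
import decaydet as d

# a 1500-gene synthetic genome with known truth:
# beta_mrna = -0.85, beta_CAI = +0.2, beta_ORFlen = -0.15,
# lambda_essential = +0.1, residual sigma = 0.72 (R^2 ~ 0.6)
recs, truth, feats, ref = d.generate_dataset(seed=7)

results = d.run_models(recs, feats)
for mu, res in results.items():
    f = res.final_fit
    print(f"mu={mu}: n={f.n} adjR2={f.adj_r2:.2f} "
          f"mrna={f.coef.get('mrna', float('nan')):+.2f} "
          f"cai={f.coef.get('cai', float('nan')):+.2f} "
          f"selected={len(res.selected_terms)} terms")

res = d.compare_quartiles(recs, "0.10")
print("eligible quartile size:", res["split"].set_size,
      "| differential words:", res["differential"] or "none")
```

prints

```
mu=0.10: n=1490 adjR2=0.61 mrna=-0.84 cai=+0.21 selected=4 terms
mu=0.20: n=1490 adjR2=0.62 mrna=-0.84 cai=+0.20 selected=8 terms
mu=0.40: n=1490 adjR2=0.58 mrna=-0.85 cai=+0.16 selected=6 terms
mu=0.63: n=1490 adjR2=0.62 mrna=-0.87 cai=+0.21 selected=6 terms
eligible quartile size: 375 | differential words: none
```

Each growth-rate model recovers the planted determinants: mRNA
concentration dominates with a negative coefficient near -0.85 (more
abundant transcripts decay faster), CAI is positive near +0.2 (optimal
codon usage stabilizes), and the adjusted R^2 sits near the generated 0.6.
A handful of additional weak terms enter by chance, as expected from an
AIC-type criterion. With no motif planted, no pentamer is called
differential between the stable and unstable quartiles; planting AGGAG
into half the stable quartile (`SyntheticTruth(motif_plant=...)`) makes it
the top differential word.

The same pipeline runs from the shell:

```sh
decaydet simulate --seed 7 --out data/
decaydet features --dataset data/ --out out/
decaydet fit --dataset data/ --features-table out/features.tsv --out out/
decaydet motifs --dataset data/ --growth-rate 0.10 --out out/
decaydet operons --dataset data/ --out out/
decaydet kinetics --dataset data/ --growth-rate 0.10 --out out/
```

To analyze a real compiled dataset, lay it out in the same three files
(`genes.tsv` with the documented columns, `orf.fasta`, `utr5.fasta`; see
`decaydet.io_core`) plus a CAI reference FASTA.

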