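"""Synthetic genomes and expression data with known ground truth.

The generator emulates the structure of the real compiled dataset so every
downstream stage runs without any external download: operon structures of
1-16 genes, ORFs with tunable codon bias (driving CAI) and GC content,
experimentally-mapped-style 5'UTRs of 1-100 nt with optional multiple TSS,
COG / essentiality / cell-location labels, and measurements at the four
growth rates mu = 0.10, 0.20, 0.40 and 0.63 h^-1.

Expression is generated from the same linear structure the model module
fits: ln(half-life) is a linear combination of the *standardized*
covariates (computed by the shared feature code path, so truth
coefficients live on the same scale as fitted ones) plus Gaussian noise.
mRNA concentration is drawn on the log scale and enters the linear
predictor through its (negative, by default) coefficient, which makes
(ln mRNA, ln half-life) jointly Gaussian with a configurable correlation.
Protein levels are driven by half-life and CAI.  Optionally a 5-nt motif
is planted into a fraction of the 5'UTRs of one stability quartile.

Half-life calibration: unless an intercept is given explicitly, the
intercept is set to the midpoint of the configured range (default 1-53
min) on the ln scale.  Hard clipping of the tails to the range is off by
default because it would attenuate the very coefficients the recovery
tests measure; enable ``truth.clip`` to enforce bounded support.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .features import (CODON_TO_AA, ReferenceUsage, SENSE_CODONS, SYNONYMOUS,
                       compute_features, effective_utr5)
from .folding import zscores_for_records
from .io_core import (DEFAULT_GROWTH_RATES, GeneRecord, write_fasta,
                      write_gene_table)

#: stylized highly-expressed-gene codon preferences (one major codon per
#: amino acid); the reference set is built from these, so CAI ~ codon bias.
PREFERRED_CODON: dict[str, str] = {
    "A": "GCG", "R": "CGT", "N": "AAC", "D": "GAC", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGT", "H": "CAC", "I": "ATC",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTC", "P": "CCG",
    "S": "TCT", "T": "ACC", "W": "TGG", "Y": "TAC", "V": "GTT",
}
STOPS = ("TAA", "TGA", "TAG")

_GC = {c: sum(b in "GC" for b in c) for c in SENSE_CODONS}
_PREF_OF = {c: PREFERRED_CODON[CODON_TO_AA[c]] for c in SENSE_CODONS}


@dataclass
class GenomeConfig:
    """Sequence- and annotation-level knobs of the synthetic genome."""

    n_genes: int = 1500
    gc_target: float = 0.51
    operon_size_dist: dict[int, float] = field(default_factory=lambda: {
        1: 0.55, 2: 0.15, 3: 0.10, 4: 0.08, 5: 0.05,
        6: 0.03, 8: 0.02, 12: 0.015, 16: 0.005})
    utr_len_range: tuple[int, int] = (1, 100)
    orf_mean_codons: int = 280
    orf_sigma: float = 0.45
    orf_min_codons: int = 30
    codon_bias_range: tuple[float, float] = (0.05, 0.95)
    cog_probs: dict[str, float] = field(default_factory=lambda: {
        "C": 0.06, "D": 0.01, "E": 0.09, "F": 0.02, "G": 0.08,
        "H": 0.04, "I": 0.03, "J": 0.05, "K": 0.07, "L": 0.05,
        "M": 0.05, "N": 0.02, "O": 0.03, "P": 0.05, "Q": 0.02,
        "R": 0.12, "S": 0.10, "T": 0.04, "U": 0.01, "V": 0.02})
    n_cogs_probs: tuple[float, float, float] = (0.15, 0.75, 0.10)
    essential_prob: float = 0.10
    location_probs: dict[str, float] = field(default_factory=lambda: {
        "Cytoplasmic": 0.70, "Inner membrane": 0.15, "Periplasmic": 0.06,
        "Outer membrane": 0.04, "Unknown": 0.05})
    signal_peptide_prob: float = 0.08
    multi_tss_prob: float = 0.25

    def validate(self) -> None:
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError(f"gc_target {self.gc_target} outside (0, 1)")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.utr_len_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid utr_len_range {self.utr_len_range}")
        if not all(1 <= s <= 16 for s in self.operon_size_dist):
            raise ValueError("operon sizes must lie in [1, 16]")
        blo, bhi = self.codon_bias_range
        if not (0.0 <= blo <= bhi <= 1.0):
            raise ValueError(f"invalid codon_bias_range {self.codon_bias_range}")


@dataclass
class SyntheticTruth:
    """Ground-truth generative parameters of a simulated dataset.

    ``beta`` maps quantitative covariate names (model-module naming) to
    coefficients on the standardized scale; ``lam`` maps qualitative
    indicator labels (e.g. ``essential``, ``cog[J]``, ``operon_size[4]``)
    to coefficients on the same standardized scale (the generator centers
    and reduces the indicator column before applying the coefficient, so
    beta and lam are directly comparable and equally recoverable).
    ``sigma`` is the residual SD of ln(half-life).
    """

    beta: dict[str, float] = field(default_factory=lambda: {
        "mrna": -0.85, "cai": 0.2, "orf_length": -0.15})
    lam: dict[str, float] = field(default_factory=lambda: {"essential": 0.1})
    sigma: float = 0.72
    alpha: float | None = None
    halflife_range: tuple[float, float] = (1.0, 53.0)
    clip: bool = False
    mrna_log_mean: dict[str, float] = field(default_factory=lambda: {
        "0.10": 2.0, "0.20": 2.3, "0.40": 2.7, "0.63": 3.0})
    mrna_log_sd: float = 1.0
    #: ln(half-life) added per cistron position beyond the first (0 = none;
    #: positive values emulate the 5'-to-3' within-operon stability gradient)
    position_effect: float = 0.0
    motif_plant: dict | None = None       # {word, target_quartile, plant_fraction}
    # sigma_p gives protein-model R^2 ~ 0.5 at the default coefficients
    protein_truth: dict | None = field(default_factory=lambda: {
        "coef_halflife": -0.14, "coef_cai": 0.5, "sigma_p": 0.52,
        "alpha_p": 5.0})
    seed: int = 0

    def validate(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        for name, coef in {**self.beta, **self.lam}.items():
            if not math.isfinite(coef):
                raise ValueError(f"non-finite coefficient for {name!r}")
        if self.motif_plant is not None:
            frac = self.motif_plant.get("plant_fraction", 0.0)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"plant_fraction {frac} outside [0, 1]")

    @property
    def effective_alpha(self) -> float:
        if self.alpha is not None:
            return self.alpha
        lo, hi = self.halflife_range
        return 0.5 * (math.log(lo) + math.log(hi))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        raw["halflife_range"] = tuple(raw["halflife_range"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# genome generation


def _solve_gc_tilt(gc_target: float, mean_bias: float) -> float:
    """Exponential-tilt parameter making the expected codon GC hit the target.

    Codons are drawn from ``pi_theta(c) proportional to exp(theta * gc(c))``,
    then swapped for the amino acid's preferred codon with probability equal
    to the gene's bias; the tilt is solved so the mixture's expected GC
    fraction equals ``gc_target`` at the mean bias.
    """
    gcs = np.array([_GC[c] for c in SENSE_CODONS], dtype=float)
    pref_gcs = np.array([_GC[_PREF_OF[c]] for c in SENSE_CODONS], dtype=float)

    def expected_gc(theta: float) -> float:
        w = np.exp(theta * gcs)
        w /= w.sum()
        mixture = (1 - mean_bias) * gcs + mean_bias * pref_gcs
        return float(w @ mixture) / 3.0

    return brentq(lambda t: expected_gc(t) - gc_target, -8.0, 8.0)


def _codon_probs(theta: float) -> np.ndarray:
    w = np.exp(theta * np.array([_GC[c] for c in SENSE_CODONS], dtype=float))
    return w / w.sum()


def generate_genome(config: GenomeConfig | None = None,
                    seed: int = 0) -> list[GeneRecord]:
    """Sequences and annotations for a synthetic genome (no expression yet).

    ORFs start with ATG, end with a stop and have length divisible by 3;
    genes of an operon share an operon id and consecutive positions;
    per-gene codon bias drawn from ``codon_bias_range`` controls the CAI.
    Byte-identical output for identical (config, seed).
    """
    config = config or GenomeConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    sizes = sorted(config.operon_size_dist)
    size_p = np.array([config.operon_size_dist[s] for s in sizes], dtype=float)
    size_p /= size_p.sum()

    theta = _solve_gc_tilt(config.gc_target,
                           float(np.mean(config.codon_bias_range)))
    base_probs = _codon_probs(theta)
    pref_idx = np.array([SENSE_CODONS.index(_PREF_OF[c]) for c in SENSE_CODONS])
    # i.i.d. base distribution with the same GC for UTRs
    gc = config.gc_target
    utr_base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    records: list[GeneRecord] = []
    cog_cats = sorted(config.cog_probs)
    cog_p = np.array([config.cog_probs[c] for c in cog_cats], dtype=float)
    cog_p /= cog_p.sum()
    loc_labels = sorted(config.location_probs)
    loc_p = np.array([config.location_probs[l] for l in loc_labels], dtype=float)
    loc_p /= loc_p.sum()
    blo, bhi = config.codon_bias_range
    ulo, uhi = config.utr_len_range

    op_counter = 0
    while len(records) < config.n_genes:
        size = int(rng.choice(sizes, p=size_p))
        size = min(size, config.n_genes - len(records))
        op_counter += 1
        operon_id = f"op{op_counter:05d}" if size > 1 else None
        for pos in range(1, size + 1):
            gid = f"g{len(records) + 1:05d}"
            ncod = int(round(config.orf_mean_codons
                             * math.exp(rng.normal(0.0, config.orf_sigma))))
            ncod = max(config.orf_min_codons, ncod)
            bias = rng.uniform(blo, bhi)
            idx = rng.choice(len(SENSE_CODONS), size=ncod, p=base_probs)
            swap = rng.random(ncod) < bias
            idx[swap] = pref_idx[idx[swap]]
            orf = "ATG" + "".join(SENSE_CODONS[i] for i in idx) \
                + STOPS[rng.integers(len(STOPS))]
            utr_len = int(rng.integers(ulo, uhi + 1))
            utr = "".join(np.array(list("ACGT"))[
                rng.choice(4, size=utr_len, p=utr_base_p)])
            tss = [utr_len]
            if utr_len > 1 and rng.random() < config.multi_tss_prob:
                tss = [int(rng.integers(1, utr_len)), utr_len]
            n_cogs = int(rng.choice(3, p=np.array(config.n_cogs_probs)))
            cogs = frozenset(
                rng.choice(cog_cats, size=n_cogs, replace=False, p=cog_p))
            records.append(GeneRecord(
                gene_id=gid,
                orf_seq=orf,
                utr5_seq=utr,
                tss_offsets=tss,
                operon_id=operon_id,
                operon_size=size,
                operon_position=pos,
                cog=cogs,
                essential=bool(rng.random() < config.essential_prob),
                cell_location=str(rng.choice(loc_labels, p=loc_p)),
                signal_peptide=bool(rng.random() < config.signal_peptide_prob),
            ))
    return records


def generate_reference_set(seed: int = 0, n_genes: int = 55,
                           n_codons: int = 250) -> list[str]:
    """Ribosomal-like reference ORFs: strongly biased toward preferred codons."""
    rng = np.random.default_rng(seed)
    aas = sorted(SYNONYMOUS)
    seqs = []
    for _ in range(n_genes):
        codons = []
        for _ in range(n_codons):
            aa = aas[rng.integers(len(aas))]
            fam = SYNONYMOUS[aa]
            if rng.random() < 0.95:
                codons.append(PREFERRED_CODON[aa])
            else:
                codons.append(fam[rng.integers(len(fam))])
        seqs.append("ATG" + "".join(codons) + "TAA")
    return seqs


# ---------------------------------------------------------------------------
# expression simulation


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def _indicator(label: str, rec: GeneRecord, feat) -> float:
    if label == "essential":
        return float(rec.essential)
    if label == "signal_peptide":
        return float(rec.signal_peptide)
    if label == "second_nt[purine]":
        return float(feat.second_nt == "purine")
    if label.startswith("operon_size[") and label.endswith("]"):
        return float(rec.operon_size == int(label[12:-1]))
    if label.startswith("cog[") and label.endswith("]"):
        return float(label[4:-1] in rec.cog)
    if label.startswith("cell_location[") and label.endswith("]"):
        return float(rec.cell_location == label[14:-1])
    raise ValueError(f"unknown qualitative truth label {label!r}")


def simulate_expression(
    records: Sequence[GeneRecord],
    truth: SyntheticTruth,
    growth_rates: Sequence[str] = DEFAULT_GROWTH_RATES,
    ref_usage: ReferenceUsage | None = None,
    zscore_source: str = "simulated",
    n_shuffles: int = 100,
) -> tuple[list[GeneRecord], dict]:
    """Fill half-life, mRNA and protein measurements from the ground truth.

    Covariates are computed with the shared feature code path and
    standardized exactly as the model module does, so the truth
    coefficients are recoverable by refitting.  ``zscore_source`` is
    ``"fold"`` (folding-based, the measurement the Z-score covariate
    represents) or ``"simulated"`` (a standard-normal draw per gene --
    the Z score's own null distribution -- for genome-scale runs where
    the covariate carries no planted signal).

    Returns the records (mutated in place) and the feature vectors used,
    which downstream refits should reuse so that stochastic covariates
    (simulated Z scores) are identical.
    """
    truth.validate()
    records = list(records)
    rng = np.random.default_rng(truth.seed)
    if ref_usage is None:
        ref_usage = ReferenceUsage.from_sequences(
            generate_reference_set(seed=truth.seed))

    if zscore_source == "fold":
        zs = zscores_for_records(records, n_shuffles=n_shuffles,
                                 seed=truth.seed)
    elif zscore_source == "simulated":
        zs = {rec.gene_id: float(z)
              for rec, z in zip(records, rng.normal(size=len(records)))}
    else:
        raise ValueError(f"unknown zscore_source {zscore_source!r}")
    features = compute_features(records, ref_usage, zscores=zs)

    n = len(records)
    cov_std: dict[str, np.ndarray] = {}
    for term in truth.beta:
        if term == "mrna":
            continue
        vals = np.array([getattr(features[r.gene_id], term) for r in records],
                        dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"covariate {term} missing for some genes")
        if term != "zscore":
            vals = np.log(vals)
        cov_std[term] = _standardize(vals)

    qual = np.zeros(n)
    for label, coef in truth.lam.items():
        ind = np.array([_indicator(label, rec, features[rec.gene_id])
                        for rec in records])
        if ind.std(ddof=0) < 1e-12:
            raise ValueError(f"qualitative truth label {label!r} is constant "
                             "in this genome")
        # lambda lives on the standardized scale, like beta
        qual = qual + coef * _standardize(ind)

    if truth.position_effect:
        qual = qual + truth.position_effect * np.array(
            [rec.operon_position - 1 for rec in records], dtype=float)

    lo, hi = truth.halflife_range
    alpha = truth.effective_alpha
    halflife_by_rate: dict[str, np.ndarray] = {}
    for mu in growth_rates:
        ln_mrna = rng.normal(truth.mrna_log_mean.get(mu, 2.5),
                             truth.mrna_log_sd, size=n)
        pred = np.full(n, alpha) + qual
        for term, coef in truth.beta.items():
            x = _standardize(ln_mrna) if term == "mrna" else cov_std[term]
            pred = pred + coef * x
        pred = pred + rng.normal(0.0, truth.sigma, size=n)
        t_half = np.exp(pred)
        if truth.clip:
            t_half = np.clip(t_half, lo, hi)
        halflife_by_rate[mu] = t_half
        for rec, t, m in zip(records, t_half, np.exp(ln_mrna)):
            rec.half_life[mu] = float(t)
            rec.mrna_conc[mu] = float(m)

    if truth.protein_truth is not None:
        pt = truth.protein_truth
        ln_cai_std = _standardize(np.log(np.array(
            [features[r.gene_id].cai for r in records], dtype=float)))
        for mu in growth_rates:
            ln_t_std = _standardize(np.log(halflife_by_rate[mu]))
            ln_p = (pt.get("alpha_p", 5.0)
                    + pt["coef_halflife"] * ln_t_std
                    + pt["coef_cai"] * ln_cai_std
                    + rng.normal(0.0, pt["sigma_p"], size=n))
            for rec, p in zip(records, np.exp(ln_p)):
                rec.protein_conc[mu] = float(p)

    if truth.motif_plant is not None:
        _plant_motif(records, truth.motif_plant, growth_rates[0], rng)
    return records, features


def _plant_motif(records: Sequence[GeneRecord], plant: Mapping,
                 growth_rate: str, rng: np.random.Generator) -> None:
    """Insert the word into a fraction of one stability quartile's 5'UTRs."""
    word = str(plant["word"]).upper().replace("U", "T")
    frac = float(plant.get("plant_fraction", 0.5))
    target = plant.get("target_quartile", "stable")
    eligible = [r for r in records
                if len(effective_utr5(r)) >= len(word)
                and growth_rate in r.half_life]
    ranked = sorted(eligible, key=lambda r: (-r.half_life[growth_rate],
                                             r.gene_id))
    size = math.ceil(0.25 * len(eligible))
    quartile = ranked[:size] if target == "stable" else ranked[-size:]
    chosen = rng.choice(len(quartile), size=int(round(frac * size)),
                        replace=False)
    for i in chosen:
        rec = quartile[int(i)]
        utr = rec.utr5_seq
        pos = int(rng.integers(0, len(utr) - len(word) + 1))
        rec.utr5_seq = utr[:pos] + word + utr[pos + len(word):]


def generate_dataset(
    config: GenomeConfig | None = None,
    truth: SyntheticTruth | None = None,
    seed: int = 0,
    zscore_source: str = "simulated",
    n_shuffles: int = 100,
) -> tuple[list[GeneRecord], SyntheticTruth, dict, ReferenceUsage]:
    """Genome + expression in one call; returns records, truth, features, ref."""
    truth = truth if truth is not None else SyntheticTruth(seed=seed)
    records = generate_genome(config, seed=seed)
    ref = ReferenceUsage.from_sequences(generate_reference_set(seed=seed))
    records, features = simulate_expression(
        records, truth, ref_usage=ref, zscore_source=zscore_source,
        n_shuffles=n_shuffles)
    return records, truth, features, ref


# ---------------------------------------------------------------------------
# dataset writing


def write_dataset(
    records: Sequence[GeneRecord],
    truth: SyntheticTruth,
    out_dir: str | Path,
    reference: Sequence[str] | None = None,
    growth_rates: Sequence[str] = DEFAULT_GROWTH_RATES,
    force: bool = False,
) -> dict[str, Path]:
    """Write gene table, FASTA files and truth JSON to a directory.

    Refuses to overwrite existing files unless ``force`` is set.
    :func:`decaydet.io_core.load_gene_table` on the output reproduces the
    records.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.tsv",
        "orf": out / "orf.fasta",
        "utr5": out / "utr5.fasta",
        "truth": out / "truth.json",
    }
    if reference is not None:
        paths["reference"] = out / "reference.fasta"
    existing = [p for p in paths.values() if p.exists()]
    if existing and not force:
        raise FileExistsError(
            f"refusing to overwrite {existing[0]} (pass force=True)")
    write_gene_table(records, paths["genes"], growth_rates=growth_rates)
    write_fasta(records, paths["orf"], "orf")
    write_fasta(records, paths["utr5"], "utr5")
    truth.to_json(paths["truth"])
    if reference is not None:
        with open(paths["reference"], "w") as fh:
            for i, seq in enumerate(reference, 1):
                fh.write(f">ref{i:03d}\n{seq}\n")
    return paths
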