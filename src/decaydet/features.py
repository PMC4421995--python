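"""Sequence- and annotation-derived covariates.

Computes the per-gene quantitative covariates used by the half-life and
protein models: codon adaptation index (CAI) against a highly expressed
reference gene set, region lengths and GC contents, the nature of the
transcript's second nucleotide, and protein-level descriptors (Kyte-
Doolittle GRAVY and amino-acid composition).  The folding Z score is
computed by :mod:`decaydet.folding` and attached here.

Conventions
-----------
* Transcripts are stored in the DNA alphabet throughout (U<->T normalized
  at I/O boundaries).
* When several transcription start sites are annotated, the 5'UTR is taken
  from the TSS furthest upstream of the start codon, minimizing loss of
  sequence information.
* Purines are {A, G}; pyrimidines are {C, T}.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils import gc_fraction

from .io_core import GeneRecord

_BACTERIAL_TABLE = CodonTable.unambiguous_dna_by_id[11]
#: codon -> amino acid for the 61 sense codons (bacterial/standard code).
CODON_TO_AA: dict[str, str] = dict(_BACTERIAL_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_BACTERIAL_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> synonymous codon family
SYNONYMOUS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMOUS.setdefault(_aa, ())
    SYNONYMOUS[_aa] += (_codon,)

#: amino acids excluded from CAI (single-codon families, w identically 1)
_CAI_EXCLUDED_AA = frozenset(aa for aa, fam in SYNONYMOUS.items() if len(fam) == 1)

AMINO_ACIDS = tuple(sorted(SYNONYMOUS))

with resources.files("decaydet.data").joinpath("hydropathy_kd.json").open() as _fh:
    #: Kyte-Doolittle hydropathy values, one per standard residue.
    HYDROPATHY: dict[str, float] = json.load(_fh)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


@dataclass
class FeatureVector:
    """Derived covariates for one gene; ``None`` marks a missing value."""

    gene_id: str
    cai: float | None = None
    orf_length: int | None = None
    utr5_length: int | None = None
    utr5_orf_length: int | None = None
    gc_orf: float | None = None
    gc_utr5: float | None = None
    gc_utr5_orf: float | None = None
    zscore: float | None = None
    second_nt: str | None = None          # "purine" / "pyrimidine"
    gravy: float | None = None
    aa_percent: dict[str, float] = field(default_factory=dict)


class ReferenceUsage:
    """Relative synonymous-codon adaptedness from a reference gene set.

    ``w[codon] = count(codon) / max count among its synonyms`` over the
    reference ORFs (classically a set of ribosomal-protein genes).  Codons
    never observed in the reference receive ``w = smoothing / max_count`` so
    the geometric mean stays defined; amino acids entirely absent from the
    reference are uninformative and get ``w = 1`` for all their codons.
    """

    def __init__(self, counts: Mapping[str, int], smoothing: float = 0.5):
        self.counts = {c: int(counts.get(c, 0)) for c in SENSE_CODONS}
        self.smoothing = float(smoothing)
        self.w: dict[str, float] = {}
        for aa, family in SYNONYMOUS.items():
            m = max(self.counts[c] for c in family)
            for c in family:
                if m == 0:
                    self.w[c] = 1.0
                elif self.counts[c] == 0:
                    self.w[c] = self.smoothing / m
                else:
                    self.w[c] = self.counts[c] / m

    @classmethod
    def from_sequences(cls, orfs: Iterable[str], smoothing: float = 0.5
                       ) -> "ReferenceUsage":
        counts: dict[str, int] = {}
        for orf in orfs:
            seq = str(orf).upper().replace("U", "T")
            for i in range(0, len(seq) - len(seq) % 3, 3):
                codon = seq[i:i + 3]
                if codon in CODON_TO_AA:
                    counts[codon] = counts.get(codon, 0) + 1
        return cls(counts, smoothing=smoothing)

    @classmethod
    def from_fasta(cls, path, smoothing: float = 0.5) -> "ReferenceUsage":
        return cls.from_sequences(
            (str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")),
            smoothing=smoothing,
        )


def compute_cai(orf: str, ref: ReferenceUsage) -> float:
    """Geometric mean of relative adaptedness over informative codons.

    Codons for Met and Trp (single-codon families) and stop codons carry no
    usage information and are excluded, following common CAI practice.
    """
    seq = str(orf).upper().replace("U", "T")
    if len(seq) % 3:
        raise ValueError(f"ORF length {len(seq)} is not a multiple of 3")
    log_sum, n = 0.0, 0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if codon in STOP_CODONS:
            continue
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            raise ValueError(f"invalid codon {codon!r} at position {i}")
        if aa in _CAI_EXCLUDED_AA:
            continue
        log_sum += math.log(ref.w[codon])
        n += 1
    if n == 0:
        raise ValueError("ORF contains no informative codons for CAI")
    return math.exp(log_sum / n)


def effective_utr5(record: GeneRecord) -> str:
    """5'UTR from the furthest annotated TSS (or the full stored sequence)."""
    if record.tss_offsets:
        length = max(record.tss_offsets)
        return record.utr5_seq[-length:] if length < len(record.utr5_seq) \
            else record.utr5_seq
    return record.utr5_seq


def compute_composition(record: GeneRecord) -> FeatureVector:
    """Lengths, GC percentages and second-nucleotide class for one gene.

    The transcript starts at the TSS: position 1 is the first 5'UTR base,
    so the second nucleotide is the second transcript base.  Genes with no
    mapped 5'UTR get missing UTR-dependent features (never zeros).
    """
    fv = FeatureVector(gene_id=record.gene_id)
    orf = record.orf_seq
    utr = effective_utr5(record)
    if orf:
        fv.orf_length = len(orf)
        fv.gc_orf = 100.0 * gc_fraction(orf)
    if utr:
        fv.utr5_length = len(utr)
        fv.gc_utr5 = 100.0 * gc_fraction(utr)
        transcript = utr + orf
        if len(transcript) >= 2:
            fv.second_nt = "purine" if transcript[1] in PURINES else "pyrimidine"
    if orf and utr:
        fv.utr5_orf_length = len(utr) + len(orf)
        fv.gc_utr5_orf = 100.0 * gc_fraction(utr + orf)
    return fv


def translate_orf(orf: str) -> str:
    """Translate an ORF (bacterial code), dropping the trailing stop."""
    seq = str(orf).upper().replace("U", "T")
    protein = str(Seq(seq).translate(table=11))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError("internal stop codon in ORF")
    return protein


def compute_protein_features(protein: str) -> dict:
    """GRAVY and amino-acid percentages for a polypeptide.

    GRAVY is the sum of Kyte-Doolittle hydropathy values over all residues
    divided by the number of residues.
    """
    protein = str(protein).upper()
    if not protein:
        raise ValueError("empty protein sequence")
    total = 0.0
    counts = {aa: 0 for aa in AMINO_ACIDS}
    for pos, aa in enumerate(protein, start=1):
        if aa not in HYDROPATHY:
            raise ValueError(f"unknown residue {aa!r} at position {pos}")
        total += HYDROPATHY[aa]
        counts[aa] += 1
    n = len(protein)
    return {
        "gravy": total / n,
        "aa_percent": {aa: 100.0 * c / n for aa, c in counts.items()},
    }


def compute_features(
    records: Sequence[GeneRecord],
    ref: ReferenceUsage,
    zscores: Mapping[str, float | None] | None = None,
    protein: bool = True,
) -> dict[str, FeatureVector]:
    """Full feature vectors for a record set (Z scores attached if given)."""
    out: dict[str, FeatureVector] = {}
    for rec in records:
        fv = compute_composition(rec)
        if rec.orf_seq:
            fv.cai = compute_cai(rec.orf_seq, ref)
            if protein:
                try:
                    prot = translate_orf(rec.orf_seq)
                    pf = compute_protein_features(prot)
                    fv.gravy = pf["gravy"]
                    fv.aa_percent = pf["aa_percent"]
                except ValueError:
                    pass
        if zscores is not None:
            fv.zscore = zscores.get(rec.gene_id)
        out[rec.gene_id] = fv
    return out
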