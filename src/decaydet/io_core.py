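"""Tabular and sequence I/O for the mRNA-lifetime pipeline.

The pipeline operates on per-gene records combining transcript sequences
(ORF and experimentally mapped 5'UTR), operon/COG/essentiality annotations
and per-growth-rate expression measurements (mRNA half-life, mRNA
concentration and optionally protein concentration).

On disk a dataset is

* a UTF-8 TSV gene table, one row per gene (schema in ``TABLE_COLUMNS``;
  list-valued fields semicolon-delimited; missing values written as ``NA``
  or left empty -- never as 0);
* two FASTA files (ORF and 5'UTR) whose record ids are gene ids.

The same layout is produced by :mod:`decaydet.synthetic_data` and can host a
re-formatted copy of a real compiled genome table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Growth rates (h^-1, as string labels) of the four steady-state cultures.
DEFAULT_GROWTH_RATES: tuple[str, ...] = ("0.10", "0.20", "0.40", "0.63")

DNA_ALPHABET = frozenset("ACGT")

#: Fixed (non-measurement) columns of the gene table, in writing order.
TABLE_COLUMNS: tuple[str, ...] = (
    "gene_id",
    "tss_offsets",
    "operon_id",
    "operon_size",
    "operon_position",
    "cog",
    "essential",
    "cell_location",
    "signal_peptide",
)

_MISSING = {"", "NA", "NaN", "nan", "None"}


class DuplicateGeneError(ValueError):
    """Raised when the gene table contains a repeated gene id."""


class ParseError(ValueError):
    """Raised for malformed fields, naming the offending row and column."""


@dataclass
class GeneRecord:
    """One gene: sequences, annotations and per-condition measurements.

    ``half_life`` (minutes), ``mrna_conc`` and ``protein_conc`` (arbitrary
    units) map growth-rate labels to strictly positive values; a missing
    measurement is simply absent from the map.  ``tss_offsets`` lists mapped
    transcription start sites as nt upstream of the start codon; the 5'UTR
    used in the analysis is the one from the furthest TSS.
    """

    gene_id: str
    orf_seq: str = ""
    utr5_seq: str = ""
    tss_offsets: list[int] = field(default_factory=list)
    operon_id: str | None = None
    operon_size: int = 1
    operon_position: int = 1
    cog: frozenset[str] = frozenset()
    essential: bool = False
    cell_location: str = "Unknown"
    signal_peptide: bool = False
    half_life: dict[str, float] = field(default_factory=dict)
    mrna_conc: dict[str, float] = field(default_factory=dict)
    protein_conc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.orf_seq = _norm_seq(self.orf_seq, self.gene_id, "orf_seq")
        self.utr5_seq = _norm_seq(self.utr5_seq, self.gene_id, "utr5_seq")
        self.cog = frozenset(self.cog)
        if self.operon_position > self.operon_size:
            raise ValueError(
                f"{self.gene_id}: operon_position {self.operon_position} "
                f"exceeds operon_size {self.operon_size}"
            )
        if self.operon_size < 1 or self.operon_position < 1:
            raise ValueError(f"{self.gene_id}: operon size/position must be >= 1")
        if any(o <= 0 for o in self.tss_offsets):
            raise ValueError(f"{self.gene_id}: TSS offsets must be positive")
        for name, mapping in (
            ("half_life", self.half_life),
            ("mrna_conc", self.mrna_conc),
            ("protein_conc", self.protein_conc),
        ):
            for mu, val in mapping.items():
                if not (val > 0) or not math.isfinite(val):
                    raise ValueError(
                        f"{self.gene_id}: {name}[{mu}] = {val!r} must be "
                        "strictly positive and finite"
                    )

    def copy(self, **changes) -> "GeneRecord":
        return replace(self, **changes)


def _norm_seq(seq: str, gene_id: str, which: str) -> str:
    """Uppercase, normalize U->T and validate the DNA alphabet."""
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{gene_id}: {which} contains non-ACGT symbols {sorted(bad)}")
    return s


@dataclass
class AnalysisMatrix:
    """Complete-case table for one growth rate.

    ``response`` is ln(half-life in minutes) (or ln(protein concentration)
    for protein models), never standardized.  ``table`` holds the raw
    covariates, one row per gene: quantitative columns on their natural
    scale, qualitative columns as labels.  Transformation, standardization
    and dummy coding happen in :func:`decaydet.model.build_design_matrix`.
    """

    gene_ids: list[str]
    response: np.ndarray
    table: pd.DataFrame
    growth_rate: str
    response_kind: str = "halflife"

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    def __post_init__(self) -> None:
        if not (len(self.gene_ids) == len(self.response) == len(self.table)):
            raise ValueError("gene_ids, response and table must have equal length")
        if self.table.isna().any().any():
            raise ValueError("AnalysisMatrix must not contain missing values")


# ---------------------------------------------------------------------------
# gene table reading / writing


def _parse_float(value: str, gene_id: str, column: str) -> float | None:
    if value in _MISSING:
        return None
    try:
        out = float(value)
    except ValueError as exc:
        raise ParseError(f"row {gene_id!r}, column {column!r}: "
                         f"cannot parse {value!r} as a number") from exc
    return out


def _parse_bool(value: str, gene_id: str, column: str) -> bool:
    v = value.strip().lower()
    if v in {"1", "true", "yes"}:
        return True
    if v in {"0", "false", "no", ""}:
        return False
    raise ParseError(f"row {gene_id!r}, column {column!r}: "
                     f"cannot parse {value!r} as a flag")


def load_gene_table(
    path: str | Path,
    orf_fasta: str | Path | None = None,
    utr5_fasta: str | Path | None = None,
) -> list[GeneRecord]:
    """Read a gene table TSV plus ORF / 5'UTR FASTA files.

    One :class:`GeneRecord` is created per table row.  Genes cited in the
    table but absent from a FASTA get an empty sequence and a logged
    warning; FASTA entries absent from the table are reported the same way.
    Duplicate gene ids raise :class:`DuplicateGeneError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: gene table lacks a 'gene_id' column")
    ids = df["gene_id"].tolist()
    dupes = {g for g in ids if ids.count(g) > 1}
    if dupes:
        raise DuplicateGeneError(f"{path}: duplicate gene_id(s) {sorted(dupes)}")

    orfs = _read_fasta(orf_fasta)
    utrs = _read_fasta(utr5_fasta)
    for label, seqs in (("ORF", orfs), ("5'UTR", utrs)):
        extra = set(seqs) - set(ids)
        if extra:
            logger.warning("%d %s FASTA entries not present in the gene table: %s",
                           len(extra), label, sorted(extra)[:5])

    rate_cols = {c: c.split("_")[-1] for c in df.columns
                 if c.startswith(("half_life_", "mrna_", "protein_"))}

    records = []
    for _, row in df.iterrows():
        gid = row["gene_id"]
        if orf_fasta is not None and gid not in orfs:
            logger.warning("gene %s has no ORF sequence in FASTA", gid)
        half, mrna, prot = {}, {}, {}
        for col, mu in rate_cols.items():
            val = _parse_float(row[col], gid, col)
            if val is None:
                continue
            if col.startswith("half_life_"):
                half[mu] = val
            elif col.startswith("mrna_"):
                mrna[mu] = val
            else:
                prot[mu] = val
        tss = [int(_parse_float(x, gid, "tss_offsets"))
               for x in row.get("tss_offsets", "").split(";") if x not in _MISSING]
        size = _parse_float(row.get("operon_size", "1"), gid, "operon_size")
        pos = _parse_float(row.get("operon_position", "1"), gid, "operon_position")
        records.append(GeneRecord(
            gene_id=gid,
            orf_seq=orfs.get(gid, ""),
            utr5_seq=utrs.get(gid, ""),
            tss_offsets=tss,
            operon_id=row.get("operon_id") or None,
            operon_size=int(size if size is not None else 1),
            operon_position=int(pos if pos is not None else 1),
            cog=frozenset(c for c in row.get("cog", "").split(";") if c),
            essential=_parse_bool(row.get("essential", ""), gid, "essential"),
            cell_location=row.get("cell_location") or "Unknown",
            signal_peptide=_parse_bool(row.get("signal_peptide", ""), gid,
                                       "signal_peptide"),
            half_life=half,
            mrna_conc=mrna,
            protein_conc=prot,
        ))
    return records


def _read_fasta(path: str | Path | None) -> dict[str, str]:
    if path is None:
        return {}
    return {rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(str(path), "fasta")}


def write_gene_table(records: Sequence[GeneRecord], path: str | Path,
                     growth_rates: Sequence[str] = DEFAULT_GROWTH_RATES) -> None:
    """Write the gene table TSV (sequences go to FASTA, not here)."""
    rows = []
    has_protein = any(r.protein_conc for r in records)
    for r in records:
        row = {
            "gene_id": r.gene_id,
            "tss_offsets": ";".join(str(o) for o in r.tss_offsets),
            "operon_id": r.operon_id or "",
            "operon_size": r.operon_size,
            "operon_position": r.operon_position,
            "cog": ";".join(sorted(r.cog)),
            "essential": int(r.essential),
            "cell_location": r.cell_location,
            "signal_peptide": int(r.signal_peptide),
        }
        for mu in growth_rates:
            row[f"half_life_{mu}"] = r.half_life.get(mu, "NA")
            row[f"mrna_{mu}"] = r.mrna_conc.get(mu, "NA")
            if has_protein:
                row[f"protein_{mu}"] = r.protein_conc.get(mu, "NA")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fasta(records: Sequence[GeneRecord], path: str | Path,
                which: str = "orf") -> None:
    """Write ORF or 5'UTR sequences; genes with empty sequence are skipped."""
    attr = {"orf": "orf_seq", "utr5": "utr5_seq"}[which]
    seqs = [SeqRecord(Seq(getattr(r, attr)), id=r.gene_id, description="")
            for r in records if getattr(r, attr)]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# complete-case assembly

#: Quantitative covariates drawn from the feature vectors (natural scale).
QUANTITATIVE_FEATURES = (
    "cai", "orf_length", "utr5_length", "utr5_orf_length",
    "gc_orf", "gc_utr5", "gc_utr5_orf", "zscore",
)
QUALITATIVE_FEATURES = (
    "operon_size", "essential", "cog", "cell_location",
    "signal_peptide", "second_nt",
)


def assemble_complete_matrix(
    records: Sequence[GeneRecord],
    features: Mapping[str, "decaydet.features.FeatureVector"],  # noqa: F821
    growth_rate: str,
    growth_rates: Sequence[str] = DEFAULT_GROWTH_RATES,
    response: str = "halflife",
) -> tuple[AnalysisMatrix, dict[str, str]]:
    """Build the complete-case analysis matrix for one growth rate.

    A gene is retained only if every covariate is present *and* the response
    (and mRNA concentration) is measured at **all** growth rates, so that the
    four per-rate models share a single gene set.  Returns the matrix and a
    ``gene_id -> reason`` report for the dropped genes.
    """
    if growth_rate not in growth_rates:
        raise ValueError(f"growth rate {growth_rate!r} not among {growth_rates}")
    dropped: dict[str, str] = {}
    rows, resp, gene_ids = [], [], []
    for rec in records:
        feat = features.get(rec.gene_id)
        reason = _incomplete_reason(rec, feat, growth_rates, response)
        if reason:
            dropped[rec.gene_id] = reason
            continue
        if response == "halflife":
            resp.append(math.log(rec.half_life[growth_rate]))
        else:
            resp.append(math.log(rec.protein_conc[growth_rate]))
        row = {name: getattr(feat, name) for name in QUANTITATIVE_FEATURES}
        row["mrna"] = rec.mrna_conc[growth_rate]
        row.update(
            operon_size=rec.operon_size,
            essential=rec.essential,
            cog=";".join(sorted(rec.cog)),
            cell_location=rec.cell_location,
            signal_peptide=rec.signal_peptide,
            second_nt=feat.second_nt,
        )
        if response == "protein":
            row["half_life"] = rec.half_life[growth_rate]
            row["gravy"] = feat.gravy
            for aa, pct in feat.aa_percent.items():
                row[f"aa_{aa}"] = pct
        rows.append(row)
        gene_ids.append(rec.gene_id)
    if not rows:
        raise ValueError("no gene survives complete-case filtering")
    matrix = AnalysisMatrix(
        gene_ids=gene_ids,
        response=np.asarray(resp, dtype=float),
        table=pd.DataFrame(rows, index=gene_ids),
        growth_rate=growth_rate,
        response_kind=response,
    )
    return matrix, dropped


def _incomplete_reason(rec, feat, growth_rates, response) -> str | None:
    if feat is None:
        return "no feature vector"
    for mu in growth_rates:
        if mu not in rec.half_life:
            return f"half-life missing at mu={mu}"
        if mu not in rec.mrna_conc:
            return f"mRNA concentration missing at mu={mu}"
        if response == "protein" and mu not in rec.protein_conc:
            return f"protein concentration missing at mu={mu}"
    for name in QUANTITATIVE_FEATURES:
        val = getattr(feat, name)
        if val is None or (isinstance(val, float) and math.isnan(val)):
            return f"feature {name} missing"
        # ln-transformed covariates must be strictly positive (Z score exempt)
        if name != "zscore" and val <= 0:
            return f"feature {name} not ln-transformable (value {val})"
    if feat.second_nt is None:
        return "second nucleotide unknown (no 5'UTR)"
    if response == "protein" and feat.gravy is None:
        return "protein features missing"
    return None
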