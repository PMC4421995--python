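"""Linear covariance models of ln(half-life) and ln(protein level).

One ordinary-least-squares model is fitted per growth rate.  The response,
ln(half-life in minutes) (or ln(protein concentration)), is *not*
standardized; quantitative covariates are ln-transformed (except the
folding Z score, which is already on a normal scale, and the protein-model
GRAVY / amino-acid percentages, which can be zero or negative), then
centered and reduced so their coefficients are directly comparable.
Qualitative covariates enter as indicator columns: essentiality,
signal-peptide and second-nucleotide as single indicators; operon size
(baseline: monocistronic) and cell location (baseline: most frequent
label) as categorical sets; COG as one indicator per category with no
baseline, since a gene may belong to several categories.

Term selection minimizes the criterion

    n * ln(RSS / n) + 2 * N

(n observations, N estimated coefficients) by bidirectional stepwise
search starting from the full model; a qualitative term enters or leaves
with all of its indicator columns at once.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_core import AnalysisMatrix, DEFAULT_GROWTH_RATES, assemble_complete_matrix

logger = logging.getLogger(__name__)

#: quantitative terms of the half-life model, in reporting order
HALFLIFE_QUANTITATIVE = (
    "mrna", "cai", "orf_length", "utr5_length", "utr5_orf_length",
    "gc_orf", "gc_utr5", "gc_utr5_orf", "zscore",
)
QUALITATIVE_TERMS = (
    "operon_size", "essential", "cog", "cell_location",
    "signal_peptide", "second_nt",
)
#: quantitative terms never ln-transformed before standardization
NO_LOG_TERMS = frozenset({"zscore", "gravy"})


@dataclass
class DesignSpec:
    """Which terms enter a model and how they are transformed."""

    response: str                       # "halflife" | "protein"
    quantitative: tuple[str, ...]
    qualitative: tuple[str, ...]
    growth_rate: str
    #: also center/reduce indicator columns, putting qualitative coefficients
    #: on the same scale as quantitative ones (used by recovery experiments;
    #: the default 0/1 coding matches classical factor coding)
    standardize_indicators: bool = False

    @classmethod
    def halflife(cls, growth_rate: str, **kw) -> "DesignSpec":
        return cls("halflife", HALFLIFE_QUANTITATIVE, QUALITATIVE_TERMS,
                   growth_rate, **kw)

    @classmethod
    def protein(cls, growth_rate: str,
                aa_terms: Sequence[str] = (), **kw) -> "DesignSpec":
        quant = tuple(t for t in HALFLIFE_QUANTITATIVE if t != "mrna")
        quant += ("half_life", "gravy") + tuple(aa_terms)
        return cls("protein", quant, QUALITATIVE_TERMS, growth_rate, **kw)


@dataclass
class Design:
    """Numeric design matrix plus the term -> column map."""

    y: np.ndarray
    X: pd.DataFrame                     # includes the "intercept" column
    term_columns: dict[str, list[str]]  # excludes the intercept
    growth_rate: str
    response_kind: str

    @property
    def terms(self) -> list[str]:
        return list(self.term_columns)

    def columns_for(self, terms: Sequence[str]) -> list[str]:
        cols = ["intercept"]
        for t in terms:
            cols.extend(self.term_columns[t])
        return cols


@dataclass
class ModelFit:
    """OLS estimates for one model."""

    terms: list[str]
    coef: pd.Series
    se: pd.Series
    pvalue: pd.Series
    rss: float
    n: int
    N: int
    adj_r2: float


@dataclass
class SelectionResult:
    """Outcome of the stepwise search."""

    selected_terms: list[str]
    criterion_trace: list[tuple[int, str, str, float]]
    final_fit: ModelFit


class CollinearityError(ValueError):
    """Raised when the design matrix is rank deficient."""


def _standardize(values: np.ndarray, term: str) -> np.ndarray:
    sd = values.std(ddof=0)
    if sd < 1e-12:
        raise ValueError(f"covariate {term!r} has zero variance")
    return (values - values.mean()) / sd


def build_design_matrix(matrix: AnalysisMatrix, spec: DesignSpec) -> Design:
    """Expand an analysis matrix into a numeric design.

    Quantitative columns are ln-transformed (unless listed in
    ``NO_LOG_TERMS`` or starting with ``aa_``), centered and reduced with
    the population SD.  Qualitative columns are dummy coded as documented
    in the module docstring.
    """
    tbl = matrix.table
    cols: dict[str, np.ndarray] = {}
    term_columns: dict[str, list[str]] = {}

    for term in spec.quantitative:
        raw = tbl[term].to_numpy(dtype=float)
        if term in NO_LOG_TERMS or term.startswith("aa_"):
            vals = raw
        else:
            if (raw <= 0).any():
                raise ValueError(f"covariate {term!r} must be positive for ln")
            vals = np.log(raw)
        cols[term] = _standardize(vals, term)
        term_columns[term] = [term]

    for term in spec.qualitative:
        if term not in tbl.columns:
            continue
        if term in ("essential", "signal_peptide"):
            cols[term] = tbl[term].astype(bool).to_numpy().astype(float)
            term_columns[term] = [term]
        elif term == "second_nt":
            col = f"second_nt[purine]"
            cols[col] = (tbl[term] == "purine").to_numpy().astype(float)
            term_columns[term] = [col]
        elif term == "operon_size":
            levels = sorted(set(tbl[term].astype(int)))
            names = []
            for lev in levels:
                if lev == 1:            # baseline: monocistronic
                    continue
                col = f"operon_size[{lev}]"
                cols[col] = (tbl[term].astype(int) == lev).to_numpy().astype(float)
                names.append(col)
            if names:
                term_columns[term] = names
        elif term == "cell_location":
            counts = tbl[term].value_counts()
            baseline = counts.index[0]
            names = []
            for lev in sorted(set(tbl[term])):
                if lev == baseline:
                    continue
                col = f"cell_location[{lev}]"
                cols[col] = (tbl[term] == lev).to_numpy().astype(float)
                names.append(col)
            if names:
                term_columns[term] = names
        elif term == "cog":
            cats = sorted({c for row in tbl[term] for c in str(row).split(";") if c})
            names = []
            for cat in cats:
                col = f"cog[{cat}]"
                cols[col] = tbl[term].map(
                    lambda s, c=cat: float(c in str(s).split(";"))).to_numpy()
                names.append(col)
            if names:
                term_columns[term] = names
        else:
            raise ValueError(f"unknown qualitative term {term!r}")

    X = pd.DataFrame(cols, index=matrix.gene_ids)
    X.insert(0, "intercept", 1.0)
    for term, names in list(term_columns.items()):
        kept = [c for c in names if X[c].std(ddof=0) > 1e-12]
        if not kept:
            del term_columns[term]
            X = X.drop(columns=names)
        elif len(kept) < len(names):
            X = X.drop(columns=[c for c in names if c not in kept])
            term_columns[term] = kept
    if spec.standardize_indicators:
        for term in spec.qualitative:
            for col in term_columns.get(term, []):
                X[col] = _standardize(X[col].to_numpy(), col)
    return Design(y=matrix.response, X=X, term_columns=term_columns,
                  growth_rate=spec.growth_rate, response_kind=spec.response)


def fit_ols(design: Design, terms: Sequence[str] | None = None) -> ModelFit:
    """OLS fit of the model containing ``terms`` (default: all).

    Coefficients minimize the residual sum of squares; per-coefficient
    two-sided t-test p-values and the adjusted R^2,
    ``1 - (RSS/(n-N)) / (TSS/(n-1))``, are reported.
    """
    terms = list(design.terms if terms is None else terms)
    X = design.X[design.columns_for(terms)]
    n, N = X.shape
    if n <= N:
        raise ValueError(f"n = {n} observations cannot identify N = {N} coefficients")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < N:
        raise CollinearityError(
            f"design is rank deficient (rank {rank} < {N} columns); "
            f"suspect columns: {_collinear_columns(X)}")
    res = sm.OLS(design.y, X).fit()
    return ModelFit(
        terms=terms,
        coef=res.params,
        se=res.bse,
        pvalue=res.pvalues,
        rss=float(res.ssr),
        n=n,
        N=N,
        adj_r2=float(res.rsquared_adj),
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    _, R = np.linalg.qr(X.to_numpy())
    diag = np.abs(np.diag(R))
    tol = diag.max() * 1e-10
    return [c for c, d in zip(X.columns, diag) if d < tol]


def selection_criterion(fit: ModelFit) -> float:
    """``n * ln(RSS/n) + 2N`` (natural log); -inf sentinel for RSS = 0."""
    if fit.rss <= 0:
        warnings.warn("RSS is zero; selection criterion is -inf")
        return -math.inf
    return fit.n * math.log(fit.rss / fit.n) + 2 * fit.N


def _rss(design: Design, terms: Sequence[str]) -> tuple[float, int]:
    X = design.X[design.columns_for(terms)].to_numpy()
    coef, res, rank, _ = np.linalg.lstsq(X, design.y, rcond=None)
    if res.size:
        rss = float(res[0])
    else:
        rss = float(np.sum((design.y - X @ coef) ** 2))
    return rss, X.shape[1]


def _criterion(design: Design, terms: Sequence[str]) -> float:
    rss, N = _rss(design, terms)
    n = len(design.y)
    if rss <= 0:
        return -math.inf
    return n * math.log(rss / n) + 2 * N


def stepwise_select(design: Design,
                    scope: Sequence[str] | None = None) -> SelectionResult:
    """Bidirectional stepwise term selection from the full model.

    At each step all single-term drops and adds within ``scope`` are
    evaluated; the move lowering the criterion most is taken, with ties
    broken in favor of the smaller model and then by term name.  The trace
    of accepted moves is strictly decreasing in the criterion.
    """
    scope = list(design.terms if scope is None else scope)
    unknown = set(scope) - set(design.terms)
    if unknown:
        raise ValueError(f"scope terms not in design: {sorted(unknown)}")
    current = list(scope)
    crit = _criterion(design, current)
    trace: list[tuple[int, str, str, float]] = [(0, "start", "", crit)]
    step = 0
    while True:
        step += 1
        candidates: list[tuple[float, int, str, str, list[str]]] = []
        for term in current:
            reduced = [t for t in current if t != term]
            candidates.append((_criterion(design, reduced), 0, term, "drop", reduced))
        for term in scope:
            if term in current:
                continue
            extended = sorted(current + [term])
            candidates.append((_criterion(design, extended), 1, term, "add", extended))
        if not candidates:
            break
        # ties: prefer drops (smaller model), then lexicographic term name
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        best_crit, _, best_term, action, best_terms = candidates[0]
        if best_crit < crit - 1e-10:
            current, crit = best_terms, best_crit
            trace.append((step, action, best_term, crit))
        else:
            break
    final = fit_ols(design, current)
    return SelectionResult(selected_terms=sorted(current),
                           criterion_trace=trace, final_fit=final)


def run_models(
    records,
    features: Mapping,
    growth_rates: Sequence[str] = DEFAULT_GROWTH_RATES,
    response: str = "halflife",
) -> dict[str, SelectionResult]:
    """Fit and select one model per growth rate on the shared gene set.

    For half-life models the candidate scope is the full covariate list
    including mRNA concentration.  For protein models the response is
    ln(protein), mRNA concentration is excluded (it is strongly collinear
    with half-life) and ln(half-life), GRAVY and the amino-acid
    percentages are added to the scope.
    """
    if response == "protein" and not any(
            getattr(r, "protein_conc", None) for r in records):
        raise ValueError("no protein concentrations available; "
                         "protein models cannot be fitted")
    results: dict[str, SelectionResult] = {}
    for mu in growth_rates:
        matrix, dropped = assemble_complete_matrix(
            records, features, mu, growth_rates=growth_rates, response=response)
        if response == "halflife":
            spec = DesignSpec.halflife(mu)
        else:
            aa_terms = sorted(c for c in matrix.table.columns if c.startswith("aa_"))
            spec = DesignSpec.protein(mu, aa_terms)
        design = build_design_matrix(matrix, spec)
        results[mu] = stepwise_select(design)
        logger.info("mu=%s: n=%d, dropped=%d, selected %s",
                    mu, matrix.n, len(dropped), results[mu].selected_terms)
    return results


def report_table(results: Mapping[str, SelectionResult]) -> pd.DataFrame:
    """Coefficients and p-values per growth rate, one row per parameter.

    Parameters not selected at a growth rate are shown as ``N.S``.
    """
    all_cols: list[str] = []
    for res in results.values():
        for c in res.final_fit.coef.index:
            if c not in all_cols:
                all_cols.append(c)
    rows = []
    for col in all_cols:
        row: dict[str, object] = {"parameter": col}
        for mu, res in results.items():
            if col in res.final_fit.coef.index:
                row[f"coef_{mu}"] = round(float(res.final_fit.coef[col]), 4)
                row[f"pvalue_{mu}"] = float(res.final_fit.pvalue[col])
            else:
                row[f"coef_{mu}"] = "N.S"
                row[f"pvalue_{mu}"] = "N.S"
        rows.append(row)
    rows.append({"parameter": "adjusted_R2",
                 **{f"coef_{mu}": round(res.final_fit.adj_r2, 4)
                    for mu, res in results.items()}})
    return pd.DataFrame(rows)
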