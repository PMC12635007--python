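"""Gene expression-based Age Monitoring Clock (GamC).

The clock estimates a per-subject aging rate (AR) from the residuals of
per-gene linear regressions of relative expression on chronological age
(CA).  For each clock gene G an ordinary-least-squares fit

    expression_G = intercept_G + a_G * CA + residual

yields a slope ``a_G`` and per-subject residuals ``sigma_{G,i}``.  The
gene-specific age deviation of subject i is ``Delta_{G,i} = sigma_{G,i} /
a_G`` (years), the aging rate is the average over the N clock genes,

    AR_i = Delta_i = (1/N) * sum_G sigma_{G,i} / a_G ,

and the clock readout is ``GamC_i = CA_i + Delta_i``.  Because OLS
residuals sum to zero and are uncorrelated with the regressor, the AR has
zero mean and zero sample correlation with CA by construction, and the
regression of GamC on CA has unit slope and zero intercept.

Relative expression from qPCR is computed as ``2**(-dCt)`` with ``dCt =
Ct_gene - mean(Ct of the reference genes)``; normalized transcriptomic
matrices go through the identical clock math (``Delta = sigma/a`` is
invariant to the scale of the expression column).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DEFAULT_REFERENCE_GENES",
    "ExpressionMatrix",
    "GeneFit",
    "ClockResult",
    "MissingReferenceGeneError",
    "DegenerateGeneError",
    "delta_ct_expression",
    "select_age_genes",
    "fit_clock",
    "apply_clock",
]

#: Reference genes used for dCt normalization unless the caller overrides.
DEFAULT_REFERENCE_GENES = ("UBE2D2", "GUSB2")

#: Relative slope threshold below which Delta = sigma/a is numerically
#: unstable: a gene is rejected when |a_G| < MIN_SLOPE_FACTOR * SD(expr)/SD(CA).
MIN_SLOPE_FACTOR = 1e-3


class MissingReferenceGeneError(ValueError):
    """A subject lacks a Ct value for one of the reference genes."""


class DegenerateGeneError(ValueError):
    """A clock gene is unusable (zero variance or near-zero age slope)."""


@dataclass
class ExpressionMatrix:
    """Subjects-by-genes relative expression with aligned chronological ages.

    ``values`` rows are subjects, columns genes; ``ca`` is indexed like the
    rows.  ``source_kind`` records whether values are qPCR ``2**-dCt`` (which
    must be positive) or normalized transcriptomic units (any real scale).
    """

    values: pd.DataFrame
    ca: pd.Series
    source_kind: str = "qpcr"

    def __post_init__(self) -> None:
        self.ca = self.ca.reindex(self.values.index)
        if self.ca.isna().any():
            missing = list(self.ca.index[self.ca.isna()])
            raise ValueError(f"no chronological age for subjects {missing}")
        if (self.ca <= 0).any():
            raise ValueError("chronological ages must be positive")
        if self.source_kind not in ("qpcr", "transcriptomic"):
            raise ValueError(f"unknown source_kind {self.source_kind!r}")
        if self.source_kind == "qpcr" and (self.values <= 0).any().any():
            raise ValueError("qPCR relative expression must be positive")

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns


@dataclass
class GeneFit:
    """OLS fit of one gene's expression against chronological age."""

    gene_name: str
    slope: float            # a_G, expression units per year
    intercept: float        # expression units
    r: float                # Pearson R of expression vs CA
    p: float                # two-sided P-value
    n: int                  # subjects used in the fit
    sigma: pd.Series = field(repr=False)  # residual per subject, expr units

    def residual(self, expression: float, ca: float) -> float:
        """Residual of a (possibly new) observation against the stored line."""
        return expression - (self.intercept + self.slope * ca)


@dataclass
class ClockResult:
    """Per-subject aging rate and GamC plus the per-gene fits behind them."""

    ar: pd.Series           # Delta_i, years
    gamc: pd.Series         # CA_i + Delta_i, years
    ca: pd.Series
    gene_fits: list[GeneFit]
    n_genes_used: pd.Series  # genes contributing per subject (missing reduce N)

    @property
    def n_genes(self) -> int:
        return len(self.gene_fits)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ca": self.ca, "ar": self.ar, "gamc": self.gamc,
             "n_genes": self.n_genes_used}
        ).rename_axis("subject_id")

    def model_to_json(self) -> str:
        """Serializable per-gene model (slopes/intercepts/R/P), no residuals."""
        return json.dumps(
            {
                "genes": [
                    {"gene": f.gene_name, "slope": f.slope,
                     "intercept": f.intercept, "r": f.r, "p": f.p, "n": f.n}
                    for f in self.gene_fits
                ]
            },
            indent=2,
        )


def delta_ct_expression(
    ct: pd.DataFrame,
    ca: pd.Series | None = None,
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCE_GENES,
) -> ExpressionMatrix | pd.DataFrame:
    """Relative expression ``2**-dCt`` from a long-format Ct table.

    Parameters
    ----------
    ct
        Long table with columns ``subject_id``, ``gene``, ``ct`` (cycles).
    ca
        Chronological age per subject.  If omitted, the bare expression
        DataFrame is returned instead of an :class:`ExpressionMatrix`.
    reference_genes
        Genes whose mean Ct forms the dCt baseline; every subject must carry
        all of them.

    dCt for a target gene is its Ct minus the arithmetic mean of the
    reference-gene Cts (equivalently, the geometric mean of their linear-scale
    expression).  Missing target Cts produce missing matrix entries; a missing
    reference Ct rejects the subject.
    """
    required = {"subject_id", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    if (ct["ct"].dropna() <= 0).any():
        raise ValueError("Ct values must be positive cycle counts")

    wide = ct.pivot_table(index="subject_id", columns="gene", values="ct",
                          aggfunc="mean")
    for ref in reference_genes:
        if ref not in wide.columns:
            raise MissingReferenceGeneError(f"reference gene {ref!r} absent")
    ref_ct = wide[list(reference_genes)]
    bad = ref_ct.isna().any(axis=1)
    if bad.any():
        raise MissingReferenceGeneError(
            f"subjects missing a reference Ct: {list(wide.index[bad])}"
        )
    targets = [g for g in wide.columns if g not in reference_genes]
    dct = wide[targets].sub(ref_ct.mean(axis=1), axis=0)
    expr = 2.0 ** (-dct)
    if ca is None:
        return expr
    return ExpressionMatrix(values=expr, ca=ca, source_kind="qpcr")


def select_age_genes(
    expr: ExpressionMatrix,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Select genes whose expression correlates with chronological age.

    Pearson correlation on the linear expression scale, two-sided P; a gene
    is selected when P <= ``alpha``.  Returns the selected gene names and a
    report with R and P for every testable gene.  Zero-variance genes are
    excluded (recorded with NaN statistics); genes need at least 3
    non-missing subjects.
    """
    rows = []
    for gene in expr.genes:
        v = expr.values[gene]
        ok = v.notna() & expr.ca.notna()
        n = int(ok.sum())
        if n < 3:
            raise ValueError(f"gene {gene!r} has fewer than 3 observations")
        x, y = expr.ca[ok].to_numpy(float), v[ok].to_numpy(float)
        if np.std(y) == 0 or np.std(x) == 0:
            rows.append({"gene": gene, "r": np.nan, "p": np.nan, "n": n,
                         "selected": False})
            continue
        r, p = sps.pearsonr(x, y)
        rows.append({"gene": gene, "r": float(r), "p": float(p), "n": n,
                     "selected": bool(p <= alpha)})
    report = pd.DataFrame(rows).set_index("gene")
    return list(report.index[report["selected"]]), report


def _fit_gene(expr: ExpressionMatrix, gene: str,
              min_slope_factor: float) -> GeneFit:
    v = expr.values[gene]
    ok = v.notna()
    if int(ok.sum()) < 3:
        raise DegenerateGeneError(f"gene {gene!r}: fewer than 3 observations")
    x = expr.ca[ok].to_numpy(float)
    y = v[ok].to_numpy(float)
    sy, sx = np.std(y), np.std(x)
    if sy == 0:
        raise DegenerateGeneError(f"gene {gene!r}: zero expression variance")
    fit = sps.linregress(x, y)
    guard = min_slope_factor * sy / sx
    if abs(fit.slope) < guard:
        raise DegenerateGeneError(
            f"gene {gene!r}: |slope| {abs(fit.slope):.3g} below guard "
            f"{guard:.3g}; Delta = sigma/a would be unstable"
        )
    sigma = pd.Series(y - (fit.intercept + fit.slope * x), index=v.index[ok])
    return GeneFit(gene_name=gene, slope=float(fit.slope),
                   intercept=float(fit.intercept), r=float(fit.rvalue),
                   p=float(fit.pvalue), n=len(x),
                   sigma=sigma.reindex(expr.subjects))


def fit_clock(
    expr: ExpressionMatrix,
    genes: list[str] | None = None,
    min_slope_factor: float = MIN_SLOPE_FACTOR,
) -> ClockResult:
    """Fit the clock: per-gene OLS vs CA, then AR and GamC per subject.

    ``genes`` defaults to every column of the matrix.  Genes failing the
    minimum-slope guard raise :class:`DegenerateGeneError`.  A subject
    missing some selected genes gets its AR from the remaining ones with N
    reduced (tracked in ``n_genes_used``).
    """
    if genes is None:
        genes = list(expr.genes)
    if len(genes) == 0:
        raise ValueError("empty gene list")
    missing = [g for g in genes if g not in expr.genes]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")

    fits = [_fit_gene(expr, g, min_slope_factor) for g in genes]
    return _score(fits, expr)


def apply_clock(gene_fits: list[GeneFit],
                expr_new: ExpressionMatrix) -> ClockResult:
    """Score new subjects with stored per-gene regression lines.

    Residuals are taken against the stored line (intercept + slope*CA), so
    the zero-mean/zero-correlation AR guarantees of :func:`fit_clock` hold
    only in-sample; out-of-sample AR is an honest deviation estimate.
    """
    missing = [f.gene_name for f in gene_fits
               if f.gene_name not in expr_new.genes]
    if missing:
        raise KeyError(f"model genes not in matrix: {missing}")
    scored = []
    for f in gene_fits:
        v = expr_new.values[f.gene_name]
        sigma = v - (f.intercept + f.slope * expr_new.ca)
        scored.append(GeneFit(gene_name=f.gene_name, slope=f.slope,
                              intercept=f.intercept, r=f.r, p=f.p, n=f.n,
                              sigma=sigma))
    return _score(scored, expr_new)


def _score(fits: list[GeneFit], expr: ExpressionMatrix) -> ClockResult:
    # Delta_{G,i} = sigma_{G,i} / a_G; AR_i = mean over genes with data.
    per_gene = pd.DataFrame(
        {f.gene_name: f.sigma / f.slope for f in fits}, index=expr.subjects
    )
    ar = per_gene.mean(axis=1, skipna=True)
    n_used = per_gene.notna().sum(axis=1)
    if (n_used == 0).any():
        bad = list(expr.subjects[n_used == 0])
        raise ValueError(f"subjects with no usable clock gene: {bad}")
    gamc = expr.ca + ar
    return ClockResult(ar=ar, gamc=gamc, ca=expr.ca.copy(), gene_fits=fits,
                       n_genes_used=n_used)


def load_model_json(text: str) -> list[GeneFit]:
    """Rebuild gene fits (without residuals) from :meth:`ClockResult.model_to_json`."""
    obj = json.loads(text)
    return [
        GeneFit(gene_name=g["gene"], slope=g["slope"], intercept=g["intercept"],
                r=g["r"], p=g["p"], n=g["n"], sigma=pd.Series(dtype=float))
        for g in obj["genes"]
    ]
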