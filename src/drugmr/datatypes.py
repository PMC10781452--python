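"""Core domain containers.

GWAS summary statistics are carried as :class:`pandas.DataFrame` objects in a
canonical column layout (one row per SNP-trait association); small structured
results use dataclasses.  Coordinates are 1-based inclusive GRCh37 throughout;
BED input is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import CoordinateError, MatrixError, SchemaError

#: Canonical summary-statistics columns.  ``eaf``, ``n`` and ``n_cases`` may
#: be missing/NaN; operations that need them say so in their docstrings.
SUMMARY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
    "n_cases",
]

MANDATORY_SUMMARY_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pvalue",
]

#: Columns of a harmonized instrument table (exposure and outcome effects
#: aligned to the same effect allele per SNP).
HARMONIZED_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "beta_exp",
    "se_exp",
    "pvalue_exp",
    "n_exp",
    "eaf_exp",
    "beta_out",
    "se_out",
    "n_out",
    "flipped",
    "palindromic_resolution",
]

#: Drug-target genes and the lipid trait used to proxy their modulation.
#: LDL-cholesterol-lowering targets versus triglyceride-lowering targets.
GENE_EXPOSURE_TRAIT = {
    "LDLR": "LDL_C",
    "HMGCR": "LDL_C",
    "PCSK9": "LDL_C",
    "NPC1L1": "LDL_C",
    "APOB": "LDL_C",
    "CETP": "LDL_C",
    "LPL": "TG",
    "ANGPTL3": "TG",
    "APOC3": "TG",
}

VALID_EXPOSURE_TRAITS = ("LDL_C", "TG")


@dataclass
class GeneRegion:
    """A drug-target gene interval (1-based inclusive, GRCh37).

    ``flank_bp`` is stored, not baked into ``start``/``end``; the cis-window
    used for instrument selection is ``[start - flank_bp, end + flank_bp]``.
    """

    gene: str
    chrom: str
    start: int
    end: int
    exposure_trait: str = "LDL_C"
    flank_bp: int = 100_000

    def __post_init__(self):
        if self.start > self.end:
            raise CoordinateError(
                f"{self.gene}: start ({self.start}) > end ({self.end})"
            )
        if self.start < 1:
            raise CoordinateError(f"{self.gene}: start must be >= 1")
        if self.flank_bp < 0:
            raise CoordinateError(f"{self.gene}: flank_bp must be >= 0")
        if self.exposure_trait not in VALID_EXPOSURE_TRAITS:
            raise SchemaError(
                f"{self.gene}: unknown exposure_trait {self.exposure_trait!r}; "
                f"expected one of {VALID_EXPOSURE_TRAITS}"
            )
        self.chrom = str(self.chrom)

    @property
    def window(self) -> tuple[int, int]:
        """Cis-window (1-based inclusive) after applying the flank."""
        return (max(1, self.start - self.flank_bp), self.end + self.flank_bp)


@dataclass
class LDMatrix:
    """Pairwise LD r-squared between a set of variants."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.variant_ids)
        if self.r2.shape != (m, m):
            raise MatrixError(
                f"LD matrix shape {self.r2.shape} does not match "
                f"{m} variant ids"
            )
        if np.nanmax(np.abs(self.r2 - self.r2.T)) > 1e-9:
            raise MatrixError("LD matrix is not symmetric")
        if np.nanmin(self.r2) < -1e-9 or np.nanmax(self.r2) > 1 + 1e-9:
            raise MatrixError("LD r2 values must lie in [0, 1]")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != m:
            raise MatrixError("duplicate variant ids in LD matrix")

    def get(self, a: str, b: str) -> Optional[float]:
        """r2 between two variants, or None if either is absent."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


@dataclass
class HarmonizedInstrumentSet:
    """Aligned exposure/outcome effects for one gene-outcome analysis.

    ``table`` follows :data:`HARMONIZED_COLUMNS`; every row's ``beta_exp``
    and ``beta_out`` refer to the same effect allele.  ``exclusions``
    records variants dropped during harmonization with the reason.
    """

    gene: str
    outcome: str
    table: pd.DataFrame
    exclusions: Optional[pd.DataFrame] = None

    def __post_init__(self):
        missing = [
            c
            for c in ("variant_id", "beta_exp", "se_exp", "beta_out", "se_out")
            if c not in self.table.columns
        ]
        if missing:
            raise SchemaError(f"harmonized table missing columns: {missing}")
        if len(self.table) < 1:
            raise SchemaError("harmonized instrument set is empty")
        if (self.table["se_exp"] <= 0).any() or (self.table["se_out"] <= 0).any():
            raise SchemaError("standard errors must be strictly positive")

    @property
    def k(self) -> int:
        return len(self.table)

    def subset(self, mask) -> "HarmonizedInstrumentSet":
        return HarmonizedInstrumentSet(
            gene=self.gene,
            outcome=self.outcome,
            table=self.table.loc[mask].reset_index(drop=True),
            exclusions=self.exclusions,
        )


@dataclass
class MREstimate:
    """One estimator's causal effect for one gene-outcome pair.

    ``beta`` is on the scale of the harmonized inputs (per 1-unit *increase*
    in exposure unless the pipeline's lipid-lowering sign convention has been
    applied); ``scale`` is ``"beta"`` for continuous outcomes and ``"log_or"``
    for binary ones.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    nsnp: int
    scale: str = "beta"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.se <= 0:
            raise SchemaError(f"{self.method}: se must be > 0, got {self.se}")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise SchemaError(
                f"{self.method}: CI [{self.ci_low}, {self.ci_high}] does not "
                f"bracket beta={self.beta}"
            )

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))


@dataclass
class FStatReport:
    """Instrument-strength summary: per-SNP and overall F statistics."""

    per_snp: pd.DataFrame  # variant_id, r2_explained, f_stat
    k: int
    n: int
    overall_r2: float
    overall_f: float
    weak_flag: bool


@dataclass
class MetaResult:
    """Pooled effect across several estimates (fixed or DerSimonian-Laird)."""

    model: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    tau2: float
    q: float
    q_p: float
    n_studies: int


@dataclass
class DiagnosticsReport:
    """Bundle of heterogeneity/pleiotropy diagnostics for one instrument set."""

    q: float
    q_df: int
    q_p: float
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_p: Optional[float] = None
    loo: Optional[pd.DataFrame] = None
    steiger: Optional[pd.DataFrame] = None
    fstat: Optional[FStatReport] = None


def empty_summary_frame() -> pd.DataFrame:
    """An empty DataFrame with the canonical summary-statistics columns."""
    return pd.DataFrame({c: pd.Series(dtype=object) for c in SUMMARY_COLUMNS})
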