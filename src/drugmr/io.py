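"""Reading and writing of GWAS summary statistics, gene regions, LD matrices
and result tables.

Interchange formats are deliberately plain: header-mapped TSV/CSV for summary
statistics (consortium headers vary, so a ``column_map`` or a named preset
translates them), BED for gene regions (0-based half-open on disk, converted
to 1-based inclusive in memory), square TSV for LD, and a fixed-column TSV for
results that round-trips losslessly at 12 significant digits.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .datatypes import (
    GENE_EXPOSURE_TRAIT,
    LDMatrix,
    GeneRegion,
    MANDATORY_SUMMARY_COLUMNS,
    SUMMARY_COLUMNS,
    VALID_EXPOSURE_TRAITS,
)
from .errors import (
    CoordinateError,
    DuplicateVariantError,
    EmptyInputError,
    MatrixError,
    SchemaError,
)

logger = logging.getLogger(__name__)

#: Built-in header dialects.  Keys are file headers (lower-cased), values are
#: canonical field names.
COLUMN_PRESETS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in SUMMARY_COLUMNS},
    # IEU OpenGWAS-style flat files
    "ieu": {
        "snp": "variant_id",
        "chr": "chrom",
        "bp": "pos",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "eaf": "eaf",
        "beta": "beta",
        "se": "se",
        "pval": "pvalue",
        "samplesize": "n",
        "ncase": "n_cases",
    },
    # GLGC 2013-style lipid files
    "glgc": {
        "rsid": "variant_id",
        "markername": "variant_id",
        "chromosome": "chrom",
        "position": "pos",
        "a1": "effect_allele",
        "a2": "other_allele",
        "freq.a1.1000g.eur": "eaf",
        "beta": "beta",
        "se": "se",
        "p-value": "pvalue",
        "n": "n",
    },
}

#: Fixed column order of the main results TSV.
RESULT_COLUMNS = [
    "target_gene",
    "outcome",
    "method",
    "nsnp",
    "beta",
    "se",
    "ci_low",
    "ci_high",
    "or_value",
    "or_ci_low",
    "or_ci_high",
    "pvalue",
    "qvalue",
    "Q",
    "Q_p",
    "egger_intercept",
    "egger_intercept_p",
    "mean_F",
    "power",
]

_ALLELE_RE = r"^[ACGT]+$"


def _resolve_column_map(
    column_map: Optional[Mapping[str, str] | str],
) -> dict[str, str]:
    if column_map is None:
        return dict(COLUMN_PRESETS["canonical"])
    if isinstance(column_map, str):
        try:
            return dict(COLUMN_PRESETS[column_map])
        except KeyError:
            raise SchemaError(
                f"unknown column preset {column_map!r}; "
                f"available: {sorted(COLUMN_PRESETS)}"
            ) from None
    return {str(k): str(v) for k, v in column_map.items()}


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def read_summary_stats(
    path: str,
    column_map: Optional[Mapping[str, str] | str] = None,
    *,
    sep: Optional[str] = None,
    duplicate_policy: str = "error",
) -> pd.DataFrame:
    """Read a GWAS summary-statistics table into the canonical layout.

    Parameters
    ----------
    path
        Tab- or comma-separated file with a header row.
    column_map
        Mapping from file headers to canonical field names, or the name of a
        built-in preset (``"canonical"``, ``"ieu"``, ``"glgc"``).  Headers are
        matched case-insensitively.
    duplicate_policy
        ``"error"`` (default) raises on repeated variant ids;
        ``"keep_lowest_p"`` keeps the most significant row per variant.

    Returns
    -------
    DataFrame with :data:`~drugmr.datatypes.SUMMARY_COLUMNS`.  Rows violating
    basic invariants (non-positive se, p outside (0,1], identical alleles,
    eaf outside (0,1), pos < 1) are dropped; the drop count is logged and
    recorded in ``df.attrs["n_dropped"]`` (with ``df.attrs["n_input"]``).
    Row order of kept rows is preserved.
    """
    cmap = _resolve_column_map(column_map)
    cmap_lower = {k.lower(): v for k, v in cmap.items()}
    if sep is None:
        sep = _sniff_sep(path)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    if raw.empty and len(raw.columns) == 0:
        raise EmptyInputError(f"{path}: no data")

    rename = {}
    for col in raw.columns:
        canon = cmap_lower.get(col.lower())
        if canon is not None and canon not in rename.values():
            rename[col] = canon
    df = raw.rename(columns=rename)

    missing = [c for c in MANDATORY_SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: mandatory column(s) {missing} not resolvable via column_map"
        )
    if df.empty:
        raise EmptyInputError(f"{path}: header only, no rows")

    for c in SUMMARY_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df = df[SUMMARY_COLUMNS].copy()

    df["variant_id"] = df["variant_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str).str.replace(r"\.0$", "", regex=True)
    for c in ("effect_allele", "other_allele"):
        df[c] = df[c].astype(str).str.upper().str.strip()
    for c in ("pos", "n", "n_cases"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in ("eaf", "beta", "se", "pvalue"):
        df[c] = pd.to_numeric(df[c], errors="coerce")

    n_input = len(df)
    ok = (
        df["effect_allele"].str.match(_ALLELE_RE)
        & df["other_allele"].str.match(_ALLELE_RE)
        & (df["effect_allele"] != df["other_allele"])
        & df["beta"].notna()
        & (df["se"] > 0)
        & (df["pvalue"] > 0)
        & (df["pvalue"] <= 1)
    )
    # optional fields only constrain when present
    ok &= df["pos"].isna() | (df["pos"] >= 1)
    ok &= df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))
    ok &= df["n"].isna() | (df["n"] > 0)

    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d/%d rows failing summary-statistic invariants",
            path,
            n_dropped,
            n_input,
        )
    df = df.loc[ok].reset_index(drop=True)
    if df.empty:
        raise EmptyInputError(f"{path}: all {n_input} rows failed validation")

    dup = df["variant_id"].duplicated(keep=False)
    if dup.any():
        if duplicate_policy == "error":
            ids = df.loc[dup, "variant_id"].unique()[:5]
            raise DuplicateVariantError(
                f"{path}: duplicate variant ids (e.g. {list(ids)}); "
                "pass duplicate_policy='keep_lowest_p' to resolve"
            )
        elif duplicate_policy == "keep_lowest_p":
            df = (
                df.sort_values("pvalue", kind="stable")
                .drop_duplicates("variant_id", keep="first")
                .sort_index()
                .reset_index(drop=True)
            )
        else:
            raise SchemaError(f"unknown duplicate_policy {duplicate_policy!r}")

    df["pos"] = df["pos"].astype("Int64")
    df.attrs["n_input"] = n_input
    df.attrs["n_dropped"] = n_dropped
    return df


def read_gene_regions(path: str) -> list[GeneRegion]:
    """Read a BED-like gene-region table.

    Columns: chrom, start, end, gene[, exposure_trait].  BED coordinates are
    0-based half-open on disk and converted to 1-based inclusive.  When the
    trait column is absent, the built-in drug-target assignment
    (:data:`~drugmr.datatypes.GENE_EXPOSURE_TRAIT`) is used; unknown genes
    without a trait column raise a schema error.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.empty:
        raise EmptyInputError(f"{path}: no regions")
    if df.shape[1] < 4:
        raise SchemaError(f"{path}: need >= 4 columns (chrom start end gene)")

    regions: list[GeneRegion] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        chrom = str(row[0]).replace("chr", "")
        start0, end0 = int(row[1]), int(row[2])
        gene = str(row[3])
        if end0 < start0:
            raise CoordinateError(f"{gene}: BED end {end0} < start {start0}")
        if gene in seen:
            raise SchemaError(f"{path}: duplicate gene {gene!r}")
        seen.add(gene)
        if df.shape[1] >= 5 and pd.notna(row[4]):
            trait = str(row[4])
            if trait not in VALID_EXPOSURE_TRAITS:
                raise SchemaError(
                    f"{gene}: unknown exposure_trait token {trait!r}"
                )
        else:
            trait = GENE_EXPOSURE_TRAIT.get(gene)
            if trait is None:
                raise SchemaError(
                    f"{gene}: not a known drug-target gene and no "
                    "exposure_trait column given"
                )
        # BED [s, e) half-open, 0-based  ->  1-based inclusive [s+1, e].
        # A BED row with start == end denotes a single-base feature here.
        regions.append(
            GeneRegion(
                gene=gene,
                chrom=chrom,
                start=start0 + 1,
                end=max(end0, start0 + 1),
                exposure_trait=trait,
            )
        )
    return regions


def write_gene_regions(regions: Iterable[GeneRegion], path: str) -> None:
    """Write regions back to 0-based half-open BED (inverse of the reader)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene}\t{r.exposure_trait}\n"
            )


def read_ld_matrix(path: str) -> LDMatrix:
    """Read a square LD r-squared matrix (TSV with id header row and column).

    Asymmetry up to 1e-6 is repaired by averaging with the transpose; larger
    asymmetry is an error.  The diagonal is forced to 1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise EmptyInputError(f"{path}: empty LD matrix")
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise MatrixError(f"{path}: row and column variant ids differ")
    m = df.to_numpy(dtype=float)
    asym = np.nanmax(np.abs(m - m.T)) if m.size else 0.0
    if asym > 1e-6:
        raise MatrixError(f"{path}: asymmetry {asym:.3g} exceeds 1e-6")
    m = (m + m.T) / 2.0
    if np.nanmin(m) < -1e-9 or np.nanmax(m) > 1 + 1e-9:
        raise MatrixError(f"{path}: r2 value outside [0, 1]")
    np.clip(m, 0.0, 1.0, out=m)
    np.fill_diagonal(m, 1.0)
    return LDMatrix(variant_ids=ids, r2=m)


def write_ld_matrix(ld: LDMatrix, path: str) -> None:
    pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def write_summary_stats(df: pd.DataFrame, path: str) -> None:
    """Write canonical summary statistics as TSV (12 significant digits)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_results(results: pd.DataFrame, path: str) -> None:
    """Write the main results table with the fixed column order.

    Columns absent from ``results`` are emitted empty; extra columns are
    appended after the fixed block.  Numeric values round-trip to 12
    significant digits.
    """
    if results is None or len(results) == 0:
        raise EmptyInputError("write_results: empty results table")
    out = results.copy()
    for c in RESULT_COLUMNS:
        if c not in out.columns:
            out[c] = np.nan
    extra = [c for c in out.columns if c not in RESULT_COLUMNS]
    out = out[RESULT_COLUMNS + extra]
    # %.17g is lossless for doubles, comfortably inside the 1e-12 contract
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path: str) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise EmptyInputError(f"{path}: empty results table")
    return df
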