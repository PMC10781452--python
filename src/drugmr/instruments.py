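"""Cis-instrument selection, allele harmonization, Steiger directionality
filtering and instrument-strength statistics.

The selection stage keeps genome-wide-significant SNPs inside the gene's
cis-window and prunes them by greedy p-value-ranked LD clumping (keep the most
significant SNP, discard everything correlated with it within the clumping
window, repeat).  Harmonization aligns outcome effects to the exposure's
effect allele, resolving strand flips and excluding allele-inconsistent and
(by default) palindromic variants.  Steiger filtering removes variants that
explain more variance in the outcome than in the exposure — the signature of
reverse causation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    FStatReport,
    GeneRegion,
    HarmonizedInstrumentSet,
    LDMatrix,
)
from .errors import (
    ConfigError,
    DomainError,
    InsufficientInstrumentsError,
    NoOverlapError,
    SampleSizeError,
    SchemaError,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def _is_palindromic(ea: str, oa: str) -> bool:
    """A/T or G/C style variants: allele labels cannot resolve the strand."""
    return _complement(ea) == oa


@dataclass
class InstrumentSelectionConfig:
    """Thresholds governing instrument selection and filtering.

    Defaults follow the drug-target convention for lipid traits:
    genome-wide significance p <= 5e-8 inside the gene region with a
    +/-100 kb flank, LD clumping at r2 < 0.3 within a 100 kb window, a
    minimum of 3 surviving instruments per gene, and Steiger filtering that
    removes any variant whose outcome variance explained is not strictly
    smaller than its exposure variance explained.
    """

    pvalue_threshold: float = 5e-8
    clump_r2: float = 0.3
    clump_window_bp: int = 100_000
    flank_bp: int = 100_000
    min_snps: int = 3
    steiger_enabled: bool = True
    steiger_alpha: float = 0.05
    steiger_mode: str = "direction_only"  # or "significant"
    missing_ld_r2: float = 1.0  # conservative: unknown LD forces discard
    palindrome_policy: str = "drop"  # or "infer_by_eaf"
    eaf_tolerance: float = 0.42
    scale_factor: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.pvalue_threshold < 1.0):
            raise ConfigError("pvalue_threshold must lie in (0, 1)")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ConfigError("clump_r2 must lie in [0, 1]")
        if self.clump_window_bp < 0 or self.flank_bp < 0:
            raise ConfigError("window/flank sizes must be >= 0")
        if self.min_snps < 1:
            raise ConfigError("min_snps must be >= 1")
        if self.steiger_mode not in ("direction_only", "significant"):
            raise ConfigError(f"unknown steiger_mode {self.steiger_mode!r}")
        if self.palindrome_policy not in ("drop", "infer_by_eaf"):
            raise ConfigError(
                f"unknown palindrome_policy {self.palindrome_policy!r}"
            )


def select_cis_instruments(
    exposure_stats: pd.DataFrame,
    region: GeneRegion,
    ld: LDMatrix,
    config: InstrumentSelectionConfig | None = None,
) -> pd.DataFrame:
    """Select clumped genome-wide-significant cis-SNPs for one gene.

    Candidates are SNPs on ``region.chrom`` with position inside
    ``[start - flank, end + flank]`` and ``pvalue <= pvalue_threshold``.
    Greedy clumping then repeatedly keeps the lowest-p remaining SNP and
    discards every remaining SNP with r2 >= ``clump_r2`` to it *and*
    position within ``clump_window_bp`` of it.  Ties in p-value break by
    (pos, variant_id).  Missing LD pairs are treated as
    ``config.missing_ld_r2`` (default 1: discard) with a logged warning.

    Returns the kept SNPs in ascending p-value order; raises
    :class:`InsufficientInstrumentsError` if fewer than ``min_snps`` survive.
    """
    cfg = config or InstrumentSelectionConfig()
    flank = cfg.flank_bp if cfg.flank_bp is not None else region.flank_bp
    lo, hi = max(1, region.start - flank), region.end + flank

    df = exposure_stats
    if df["pos"].isna().any() or (df["chrom"] == "nan").any():
        raise SchemaError("cis-selection requires chrom and pos for every SNP")
    cand = df[
        (df["chrom"].astype(str) == str(region.chrom))
        & (df["pos"] >= lo)
        & (df["pos"] <= hi)
        & (df["pvalue"] <= cfg.pvalue_threshold)
    ].copy()

    cand = cand.sort_values(
        ["pvalue", "pos", "variant_id"], kind="stable"
    ).reset_index(drop=True)

    kept_idx: list[int] = []
    discarded = np.zeros(len(cand), dtype=bool)
    warned_missing = False
    ids = cand["variant_id"].to_numpy()
    pos = cand["pos"].to_numpy(dtype=float)
    for i in range(len(cand)):
        if discarded[i]:
            continue
        kept_idx.append(i)
        for j in range(i + 1, len(cand)):
            if discarded[j]:
                continue
            if abs(pos[j] - pos[i]) > cfg.clump_window_bp:
                continue
            r2 = ld.get(ids[i], ids[j])
            if r2 is None:
                if not warned_missing:
                    logger.warning(
                        "%s: missing LD for some candidate pairs; using r2=%g",
                        region.gene,
                        cfg.missing_ld_r2,
                    )
                    warned_missing = True
                r2 = cfg.missing_ld_r2
            if r2 >= cfg.clump_r2:
                discarded[j] = True

    kept = cand.iloc[kept_idx].reset_index(drop=True)
    if len(kept) < cfg.min_snps:
        raise InsufficientInstrumentsError(
            f"{region.gene}: only {len(kept)} instrument(s) survived "
            f"selection (min_snps={cfg.min_snps})",
            n_selected=len(kept),
        )
    return kept


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    policy: str = "drop",
    eaf_tolerance: float = 0.42,
    gene: str = "",
    outcome_name: str = "",
) -> HarmonizedInstrumentSet:
    """Align outcome effects to the exposure's effect allele per shared SNP.

    Rules, per variant shared between the two tables:

    * identical alleles — copy the outcome effect;
    * swapped alleles (EA<->OA) — negate ``beta_out`` and flip ``eaf``;
    * alleles matching only after strand complement — complement, then
      apply the identical/swapped rule;
    * anything else — exclude as allele-inconsistent (e.g. A/G vs A/C);
    * palindromic variants (A/T, G/C) — excluded under ``policy="drop"``;
      under ``policy="infer_by_eaf"`` they are oriented so that minor/major
      status agrees between studies, but excluded as ambiguous when either
      allele frequency lies in ``[eaf_tolerance, 1 - eaf_tolerance]``.

    Raises :class:`NoOverlapError` when no variants are shared.
    """
    if policy not in ("drop", "infer_by_eaf"):
        raise ConfigError(f"unknown palindrome policy {policy!r}")
    out_by_id = outcome.set_index("variant_id", drop=False)
    if out_by_id.index.has_duplicates:
        raise SchemaError("outcome table has duplicate variant ids")
    shared = [v for v in exposure["variant_id"] if v in out_by_id.index]
    if not shared:
        raise NoOverlapError("no shared variants between exposure and outcome")

    rows = []
    excluded = []
    for v in shared:
        ex = exposure.loc[exposure["variant_id"] == v].iloc[0]
        oy = out_by_id.loc[v]
        ea_x, oa_x = ex["effect_allele"], ex["other_allele"]
        ea_y, oa_y = oy["effect_allele"], oy["other_allele"]
        beta_y = float(oy["beta"])
        eaf_y = float(oy["eaf"]) if pd.notna(oy["eaf"]) else np.nan
        flipped = False
        resolution = "not_palindromic"

        if _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                excluded.append((v, "inconsistent_alleles"))
                continue
            if policy == "drop":
                excluded.append((v, "palindromic_dropped"))
                continue
            eaf_x = float(ex["eaf"]) if pd.notna(ex["eaf"]) else np.nan
            # align labels first, then orient by allele-frequency agreement
            if ea_y != ea_x:
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y if not math.isnan(eaf_y) else eaf_y
                flipped = not flipped
            if math.isnan(eaf_x) or math.isnan(eaf_y):
                excluded.append((v, "palindromic_no_eaf"))
                continue
            lo, hi = eaf_tolerance, 1.0 - eaf_tolerance
            if lo <= eaf_x <= hi or lo <= eaf_y <= hi:
                excluded.append((v, "palindromic_ambiguous"))
                continue
            if (eaf_x < 0.5) != (eaf_y < 0.5):
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y
                flipped = not flipped
            resolution = "inferred_flipped" if flipped else "inferred_forward"
        else:
            if {ea_y, oa_y} == {ea_x, oa_x}:
                pass
            elif {_complement(ea_y), _complement(oa_y)} == {ea_x, oa_x}:
                ea_y, oa_y = _complement(ea_y), _complement(oa_y)
                resolution = "strand_flip"
            else:
                excluded.append((v, "inconsistent_alleles"))
                continue
            if ea_y != ea_x:
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y if not math.isnan(eaf_y) else eaf_y
                flipped = True

        rows.append(
            {
                "variant_id": v,
                "effect_allele": ea_x,
                "other_allele": oa_x,
                "beta_exp": float(ex["beta"]),
                "se_exp": float(ex["se"]),
                "pvalue_exp": float(ex["pvalue"]),
                "n_exp": float(ex["n"]) if pd.notna(ex["n"]) else np.nan,
                "eaf_exp": float(ex["eaf"]) if pd.notna(ex["eaf"]) else np.nan,
                "beta_out": beta_y,
                "se_out": float(oy["se"]),
                "n_out": float(oy["n"]) if pd.notna(oy["n"]) else np.nan,
                "flipped": flipped,
                "palindromic_resolution": resolution,
            }
        )

    exclusions = pd.DataFrame(excluded, columns=["variant_id", "reason"])
    if not rows:
        raise NoOverlapError(
            "all shared variants were excluded during harmonization "
            f"({exclusions['reason'].value_counts().to_dict()})"
        )
    return HarmonizedInstrumentSet(
        gene=gene,
        outcome=outcome_name,
        table=pd.DataFrame(rows),
        exclusions=exclusions,
    )


def _r2_from_t(beta: np.ndarray, se: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Variance explained from the t statistic: r2 = t^2 / (t^2 + n - 2)."""
    t2 = (beta / se) ** 2
    return t2 / (t2 + n - 2.0)


def steiger_filter(
    hset: HarmonizedInstrumentSet,
    config: InstrumentSelectionConfig | None = None,
) -> tuple[HarmonizedInstrumentSet, pd.DataFrame]:
    """Remove variants whose outcome r2 is not smaller than their exposure r2.

    Per SNP, variance explained on each side is computed from the t
    statistic, r2 = t^2/(t^2 + n - 2); the direction is "forward" iff
    r2_exp > r2_out (strictly).  The Steiger z statistic compares the two
    correlations on the Fisher-z scale:

        z = (atanh|r_exp| - atanh|r_out|) / sqrt(1/(n_exp-3) + 1/(n_out-3))

    with a two-sided normal p-value.  In ``direction_only`` mode (default)
    every non-forward SNP is removed; in ``significant`` mode only
    non-forward SNPs with steiger p < ``steiger_alpha`` are removed.

    Returns the filtered set and a per-SNP results table.  Requires per-SNP
    sample sizes > 3 on both sides.
    """
    cfg = config or InstrumentSelectionConfig()
    t = hset.table
    n_exp = t["n_exp"].to_numpy(dtype=float)
    n_out = t["n_out"].to_numpy(dtype=float)
    if np.isnan(n_exp).any() or np.isnan(n_out).any():
        raise SampleSizeError("steiger filtering requires n_exp and n_out per SNP")
    if (n_exp <= 3).any() or (n_out <= 3).any():
        bad = t.loc[(n_exp <= 3) | (n_out <= 3), "variant_id"].tolist()
        raise SampleSizeError(f"sample size <= 3 for SNP(s) {bad}")

    r2_exp = _r2_from_t(
        t["beta_exp"].to_numpy(), t["se_exp"].to_numpy(), n_exp
    )
    r2_out = _r2_from_t(
        t["beta_out"].to_numpy(), t["se_out"].to_numpy(), n_out
    )
    r_exp = np.sqrt(r2_exp)
    r_out = np.sqrt(r2_out)
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(
        1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0)
    )
    pval = 2.0 * sps.norm.sf(np.abs(z))
    forward = r2_exp > r2_out

    if cfg.steiger_mode == "direction_only":
        remove = ~forward
    else:
        remove = (~forward) & (pval < cfg.steiger_alpha)

    report = pd.DataFrame(
        {
            "variant_id": t["variant_id"],
            "r2_exp": r2_exp,
            "r2_out": r2_out,
            "direction_forward": forward,
            "steiger_z": z,
            "steiger_p": pval,
            "removed": remove,
        }
    )
    if remove.all():
        raise InsufficientInstrumentsError(
            f"{hset.gene}/{hset.outcome}: steiger filtering removed all "
            f"{hset.k} SNPs",
            n_selected=0,
        )
    return hset.subset(~remove), report


def compute_f_statistics(
    hset: HarmonizedInstrumentSet, use_eaf: bool = False
) -> FStatReport:
    """Instrument-strength F statistics, per SNP and for the whole set.

    F = R2 (n - 1 - k) / ((1 - R2) k), with R2 the variance in the exposure
    explained by the instruments, n the exposure sample size and k the number
    of SNPs.  Per-SNP r2 defaults to the t-statistic form
    t^2/(t^2 + n - 2); with ``use_eaf=True`` the standardized-trait form
    2 beta^2 eaf (1 - eaf) is used instead (requires eaf).  The set-level R2
    sums per-SNP r2 (clipped below 1) and the set-level F uses the minimum
    exposure sample size.  Weak-instrument flag: overall F <= 10.
    """
    t = hset.table
    k = hset.k
    n_arr = t["n_exp"].to_numpy(dtype=float)
    if np.isnan(n_arr).any():
        raise SampleSizeError("F statistics require n_exp per SNP")
    n = float(np.min(n_arr))
    if k >= n - 1:
        raise DomainError(f"degenerate design: k={k} >= n-1={n - 1}")

    if use_eaf:
        eaf = t["eaf_exp"].to_numpy(dtype=float)
        if np.isnan(eaf).any():
            raise DomainError("use_eaf=True requires eaf for every SNP")
        r2 = 2.0 * t["beta_exp"].to_numpy() ** 2 * eaf * (1.0 - eaf)
    else:
        r2 = _r2_from_t(
            t["beta_exp"].to_numpy(), t["se_exp"].to_numpy(), n_arr
        )
    f_snp = r2 * (n_arr - 2.0) / np.clip(1.0 - r2, 1e-300, None)

    overall_r2 = float(min(np.sum(r2), 1.0 - 1e-12))
    overall_f = overall_r2 * (n - 1.0 - k) / ((1.0 - overall_r2) * k)
    return FStatReport(
        per_snp=pd.DataFrame(
            {"variant_id": t["variant_id"], "r2_explained": r2, "f_stat": f_snp}
        ),
        k=k,
        n=int(n),
        overall_r2=overall_r2,
        overall_f=float(overall_f),
        weak_flag=bool(overall_f <= 10.0),
    )


def f_statistic(r2: float, n: float, k: int) -> float:
    """Closed-form instrument F statistic, F = R2 (n-1-k) / ((1-R2) k)."""
    if not (0.0 <= r2 < 1.0):
        raise DomainError("r2 must lie in [0, 1)")
    if k < 1 or n <= k + 1:
        raise DomainError("need k >= 1 and n > k + 1")
    return r2 * (n - 1.0 - k) / ((1.0 - r2) * k)
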