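"""Config-driven orchestration of the drug-target MR analysis grid.

For each (target gene, outcome) cell the stages run in fixed order:
cis-instrument selection -> allele harmonization -> Steiger filtering ->
instrument-strength F statistics -> the five causal-effect estimators ->
heterogeneity/pleiotropy diagnostics and leave-one-out -> statistical power;
then Benjamini-Hochberg FDR is applied over the IVW p-values (per outcome
category by default) and plot-ready tables are derived.

Reporting convention: effects are expressed per 1 unit *lower* exposure
(the lipid-lowering direction), i.e. the per-1-unit-increase regression
estimate is negated; a per-trait ``scale_factor`` supports rescaling
(e.g. SD to mmol/L) before negation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .datatypes import HarmonizedInstrumentSet, MREstimate
from .diagnostics import (
    bh_fdr,
    cochran_q,
    egger_intercept_test,
    leave_one_out,
    mr_power,
)
from .errors import (
    ConfigError,
    DrugMRError,
    EmptyInputError,
    InsufficientInstrumentsError,
    NoOverlapError,
)
from .estimators import egger, ivw, max_likelihood, weighted_median, weighted_mode
from .instruments import (
    InstrumentSelectionConfig,
    compute_f_statistics,
    harmonize,
    select_cis_instruments,
    steiger_filter,
)

logger = logging.getLogger(__name__)

OUTCOME_CATEGORIES = (
    "longevity",
    "cardiometabolic",
    "cancer",
    "positive_control",
)


@dataclass
class OutcomeSpec:
    """One outcome GWAS: file, label, type and multiplicity grouping."""

    label: str
    path: str
    outcome_type: str = "binary"  # continuous | binary
    category: str = "cardiometabolic"
    n: Optional[float] = None
    n_cases: Optional[float] = None
    column_map: Optional[str] = None

    def __post_init__(self):
        if self.outcome_type not in ("continuous", "binary"):
            raise ConfigError(f"{self.label}: bad outcome_type")
        if self.category not in OUTCOME_CATEGORIES:
            raise ConfigError(
                f"{self.label}: category must be one of {OUTCOME_CATEGORIES}"
            )

    @property
    def case_fraction(self) -> Optional[float]:
        if self.n_cases is None or self.n is None or self.n == 0:
            return None
        return self.n_cases / self.n


@dataclass
class AnalysisConfig:
    """Everything :func:`run_analysis` needs, loadable from YAML."""

    exposure_paths: dict  # trait -> summary-stats path
    outcomes: list
    regions_path: str
    ld_path: str
    selection: InstrumentSelectionConfig = dc_field(
        default_factory=InstrumentSelectionConfig
    )
    effects_model: str = "auto"
    n_boot: int = 1000
    seed: int = 0
    phi: float = 1.0
    fdr_scope: str = "per_category"  # per_category | global
    lower_exposure_convention: bool = True
    scale_factor: dict = dc_field(default_factory=dict)  # trait -> factor
    exposure_column_map: Optional[str] = None

    def __post_init__(self):
        labels = [o.label for o in self.outcomes]
        if len(set(labels)) != len(labels):
            raise ConfigError("outcome labels must be unique")
        if self.fdr_scope not in ("per_category", "global"):
            raise ConfigError(f"unknown fdr_scope {self.fdr_scope!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sel = InstrumentSelectionConfig(**raw.get("selection", {}))
        outcomes = [OutcomeSpec(**o) for o in raw["outcomes"]]
        kwargs = {
            k: raw[k]
            for k in (
                "effects_model",
                "n_boot",
                "seed",
                "phi",
                "fdr_scope",
                "lower_exposure_convention",
                "scale_factor",
                "exposure_column_map",
            )
            if k in raw
        }
        return cls(
            exposure_paths=raw["exposures"],
            outcomes=outcomes,
            regions_path=raw["regions"],
            ld_path=raw["ld"],
            selection=sel,
            **kwargs,
        )


@dataclass
class PipelineResult:
    results: pd.DataFrame
    diagnostics: pd.DataFrame
    loo: pd.DataFrame
    skipped: pd.DataFrame
    log: list


def _report_estimate(
    est: MREstimate, scale_factor: float, lower_convention: bool
) -> dict:
    """Map an estimate onto the reporting convention and OR scale."""
    sf = scale_factor if scale_factor else 1.0
    beta = est.beta * sf
    se = est.se * sf
    lo, hi = est.ci_low * sf, est.ci_high * sf
    if lower_convention:
        beta, lo, hi = -beta, -hi, -lo
    row = {
        "method": est.method,
        "nsnp": est.nsnp,
        "beta": beta,
        "se": se,
        "ci_low": lo,
        "ci_high": hi,
        "pvalue": est.pvalue,
    }
    if est.scale == "log_or":
        row["or_value"] = float(np.exp(beta))
        row["or_ci_low"] = float(np.exp(lo))
        row["or_ci_high"] = float(np.exp(hi))
    else:
        row["or_value"] = np.nan
        row["or_ci_low"] = np.nan
        row["or_ci_high"] = np.nan
    return row


def analyze_cell(
    hset: HarmonizedInstrumentSet,
    outcome_type: str = "continuous",
    case_fraction: Optional[float] = None,
    n_outcome: Optional[float] = None,
    effects_model: str = "auto",
    n_boot: int = 1000,
    seed: int = 0,
    phi: float = 1.0,
) -> tuple[list[MREstimate], dict]:
    """All estimators plus diagnostics for one harmonized set.

    Returns the raw (per 1-unit-increase) estimates and a diagnostics dict
    with Q, the Egger intercept triple, mean F and power.
    """
    scale = "log_or" if outcome_type == "binary" else "beta"
    k = hset.k
    estimates = [ivw(hset, effects_model=effects_model, scale=scale)]
    if k >= 3:
        estimates.append(egger(hset, scale=scale))
        estimates.append(
            weighted_median(hset, n_boot=n_boot, seed=seed, scale=scale)
        )
        estimates.append(
            weighted_mode(hset, phi=phi, n_boot=n_boot, seed=seed + 1, scale=scale)
        )
    if k >= 2:
        estimates.append(max_likelihood(hset, scale=scale))

    diag: dict = {"Q": np.nan, "Q_p": np.nan, "egger_intercept": np.nan,
                  "egger_intercept_p": np.nan, "mean_F": np.nan, "power": np.nan}
    if k >= 2:
        q, _, q_p = cochran_q(hset)
        diag["Q"], diag["Q_p"] = q, q_p
    if k >= 3:
        a, _, a_p = egger_intercept_test(hset)
        diag["egger_intercept"], diag["egger_intercept_p"] = a, a_p
    fstat = compute_f_statistics(hset)
    diag["mean_F"] = float(fstat.per_snp["f_stat"].mean())
    diag["overall_F"] = fstat.overall_f
    diag["overall_R2"] = fstat.overall_r2
    diag["weak_flag"] = fstat.weak_flag
    if n_outcome:
        ivw_beta = estimates[0].beta
        diag["power"] = mr_power(
            n_outcome=n_outcome,
            r2_exposure=fstat.overall_r2,
            beta_true=ivw_beta,
            outcome_type=outcome_type,
            case_fraction=case_fraction,
        )
    return estimates, diag


def run_analysis(config: AnalysisConfig) -> PipelineResult:
    """Execute the full target-by-outcome grid defined by ``config``.

    Genes yielding fewer than ``min_snps`` instruments are reported in the
    skip table (not an error); a global failure is raised only when *no*
    gene yields instruments.
    """
    log: list[str] = []
    regions = gio.read_gene_regions(config.regions_path)
    ld = gio.read_ld_matrix(config.ld_path)
    exposures = {
        trait: gio.read_summary_stats(path, config.exposure_column_map)
        for trait, path in config.exposure_paths.items()
    }
    outcome_tables = {
        o.label: gio.read_summary_stats(o.path, o.column_map)
        for o in config.outcomes
    }
    log.append(f"seed={config.seed} n_boot={config.n_boot} phi={config.phi}")

    result_rows = []
    diag_rows = []
    loo_rows = []
    skip_rows = []
    for gi, region in enumerate(regions):
        if region.exposure_trait not in exposures:
            raise ConfigError(
                f"{region.gene}: no exposure file for trait "
                f"{region.exposure_trait}"
            )
        expo = exposures[region.exposure_trait]
        try:
            selected = select_cis_instruments(expo, region, ld, config.selection)
        except InsufficientInstrumentsError as exc:
            skip_rows.append(
                {
                    "target_gene": region.gene,
                    "outcome": "*",
                    "stage": "selection",
                    "n_snps": exc.n_selected,
                    "reason": str(exc),
                }
            )
            continue
        log.append(f"{region.gene}: {len(selected)} instruments selected")

        for oi, ospec in enumerate(config.outcomes):
            try:
                hset = harmonize(
                    selected,
                    outcome_tables[ospec.label],
                    policy=config.selection.palindrome_policy,
                    eaf_tolerance=config.selection.eaf_tolerance,
                    gene=region.gene,
                    outcome_name=ospec.label,
                )
                n_harmonized = hset.k
                if config.selection.steiger_enabled:
                    hset, steiger_tbl = steiger_filter(hset, config.selection)
                if hset.k < config.selection.min_snps:
                    raise InsufficientInstrumentsError(
                        f"{region.gene}/{ospec.label}: {hset.k} SNPs after "
                        "filtering",
                        n_selected=hset.k,
                    )
            except (InsufficientInstrumentsError, NoOverlapError) as exc:
                skip_rows.append(
                    {
                        "target_gene": region.gene,
                        "outcome": ospec.label,
                        "stage": "harmonization/steiger",
                        "n_snps": getattr(exc, "n_selected", 0),
                        "reason": str(exc),
                    }
                )
                continue

            sf = config.scale_factor.get(region.exposure_trait, 1.0)
            cell_seed = (config.seed * 99991 + gi * 1009 + oi * 13 + 7) % (2**31)
            estimates, diag = analyze_cell(
                hset,
                outcome_type=ospec.outcome_type,
                case_fraction=ospec.case_fraction,
                n_outcome=ospec.n,
                effects_model=config.effects_model,
                n_boot=config.n_boot,
                seed=cell_seed,
                phi=config.phi,
            )
            log.append(
                f"{region.gene}/{ospec.label}: k={hset.k} "
                f"(harmonized {n_harmonized}), cell_seed={cell_seed}"
            )
            for est in estimates:
                row = {
                    "target_gene": region.gene,
                    "outcome": ospec.label,
                    "outcome_category": ospec.category,
                }
                row.update(
                    _report_estimate(est, sf, config.lower_exposure_convention)
                )
                row.update(
                    {
                        "Q": diag["Q"],
                        "Q_p": diag["Q_p"],
                        "egger_intercept": diag["egger_intercept"],
                        "egger_intercept_p": diag["egger_intercept_p"],
                        "mean_F": diag["mean_F"],
                        "power": diag["power"],
                        "qvalue": np.nan,
                    }
                )
                result_rows.append(row)
            diag_rows.append(
                {
                    "target_gene": region.gene,
                    "outcome": ospec.label,
                    "nsnp": hset.k,
                    **{k: diag[k] for k in (
                        "Q", "Q_p", "egger_intercept", "egger_intercept_p",
                        "mean_F", "overall_F", "overall_R2", "weak_flag",
                        "power",
                    )},
                }
            )
            if hset.k >= 2:
                loo = leave_one_out(hset, effects_model=config.effects_model)
                loo.insert(0, "outcome", ospec.label)
                loo.insert(0, "target_gene", region.gene)
                loo_rows.append(loo)

    if not result_rows:
        reasons = "; ".join(r["reason"] for r in skip_rows) or "no regions"
        raise DrugMRError(f"no gene yielded instruments: {reasons}")

    results = pd.DataFrame(result_rows)
    results = _attach_qvalues(results, config.fdr_scope)
    diagnostics = pd.DataFrame(diag_rows)
    loo_df = (
        pd.concat(loo_rows, ignore_index=True)
        if loo_rows
        else pd.DataFrame(
            columns=["target_gene", "outcome", "variant_id", "beta", "se",
                     "pvalue", "influential"]
        )
    )
    skipped = pd.DataFrame(
        skip_rows,
        columns=["target_gene", "outcome", "stage", "n_snps", "reason"],
    )
    return PipelineResult(
        results=results,
        diagnostics=diagnostics,
        loo=loo_df,
        skipped=skipped,
        log=log,
    )


def _attach_qvalues(results: pd.DataFrame, fdr_scope: str) -> pd.DataFrame:
    """BH-adjust the primary (IVW) p-values and attach q-values to every
    row of the corresponding cell."""
    results = results.copy()
    primary = results["method"].isin(("ivw_fixed", "ivw_random", "wald_ratio"))
    prim = results.loc[primary]
    if fdr_scope == "global":
        groups = [prim]
    else:
        groups = [g for _, g in prim.groupby("outcome_category", sort=False)]
    qmap: dict[tuple[str, str], float] = {}
    for g in groups:
        q = bh_fdr(g["pvalue"].to_numpy())
        for (tg, oc), qv in zip(
            zip(g["target_gene"], g["outcome"]), q, strict=True
        ):
            qmap[(tg, oc)] = float(qv)
    results["qvalue"] = [
        qmap.get((tg, oc), np.nan)
        for tg, oc in zip(results["target_gene"], results["outcome"])
    ]
    return results


def make_plot_tables(
    results: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Derive plot-ready tables from the results grid.

    Returns ``(forest, heatmap, heatmap_mask)``: the forest table has one
    row per (gene, outcome, method) with effect, CI, p and q; the heatmap is
    a genes-by-outcomes matrix of the primary (IVW) estimate — OR for binary
    outcomes, beta for continuous — with a parallel boolean mask of q < 0.05.
    """
    if results is None or len(results) == 0:
        raise EmptyInputError("make_plot_tables: empty results")
    forest_cols = [
        "target_gene", "outcome", "method", "nsnp", "beta", "se",
        "ci_low", "ci_high", "or_value", "or_ci_low", "or_ci_high",
        "pvalue", "qvalue",
    ]
    forest = results[[c for c in forest_cols if c in results.columns]].copy()

    primary = results[
        results["method"].isin(("ivw_fixed", "ivw_random", "wald_ratio"))
    ].copy()
    primary["display"] = np.where(
        primary["or_value"].notna(), primary["or_value"], primary["beta"]
    )
    heatmap = primary.pivot(
        index="target_gene", columns="outcome", values="display"
    )
    mask = (
        primary.assign(sig=primary["qvalue"] < 0.05)
        .pivot(index="target_gene", columns="outcome", values="sig")
        .fillna(False)
    )
    return forest, heatmap, mask
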