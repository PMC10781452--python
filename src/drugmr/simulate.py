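"""Synthetic paired GWAS summary statistics with known ground truth.

The generator realises the standard two-sample MR data model: per-SNP true
exposure effects ``gamma_j``, a causal effect ``beta_true`` carrying them to
the outcome, and independent sampling noise in the exposure and outcome
panels (two separate cohorts).  The instrumental-variable assumptions can be
violated on demand: horizontal pleiotropy (balanced or directional direct
outcome effects ``alpha_j`` on a fraction of SNPs, breaking the exclusion
restriction) and reverse causation (SNPs whose primary effect is on the
outcome, breaking directionality and detectable by Steiger filtering).

Defaults mirror a lipid drug-target analysis: ~20 cis-SNPs, an exposure GWAS
of 170,000 (lipid consortium scale) and an outcome GWAS of 300,000, effects
in SD units with a true causal effect of 0.1 per SD, and per-SNP exposure
z-statistics of at least 6 so every instrument clears genome-wide
significance (p <= 5e-8) in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import GeneRegion, HarmonizedInstrumentSet, LDMatrix
from .errors import ConfigError

#: exposure z threshold guaranteeing p <= 5e-8 discoverability (z for
#: p = 5e-8 is ~5.45; 6 leaves headroom for sampling noise)
_Z_DISCOVERY = 6.0


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic gene-outcome dataset.

    ``pleiotropy_mean`` defaults to 0 under balanced pleiotropy and 0.05
    under directional pleiotropy when left as None.  ``prop_invalid`` only
    applies when ``pleiotropy_mode != "none"``.
    """

    seed: int = 0
    n_snps: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.02
    gamma_min: float = 0.005
    beta_true: float = 0.1
    n_exp: int = 170_000
    n_out: int = 300_000
    ld_rho: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.01
    pleiotropy_mean: Optional[float] = None
    prop_invalid: float = 0.3
    n_reverse: int = 0
    beta_reverse: float = 0.05
    outcome_type: str = "continuous"  # continuous | binary
    case_fraction: float = 0.1

    def __post_init__(self):
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must be within (0, 0.5]")
        if not (0.0 <= self.prop_invalid <= 1.0):
            raise ConfigError("prop_invalid must lie in [0, 1]")
        if not (0.0 <= self.ld_rho <= 0.99):
            raise ConfigError("ld_rho must lie in [0, 0.99]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.outcome_type not in ("continuous", "binary"):
            raise ConfigError(f"unknown outcome_type {self.outcome_type!r}")
        if self.outcome_type == "binary" and not (0 < self.case_fraction < 1):
            raise ConfigError("case_fraction must lie in (0, 1)")
        n_invalid = self.n_invalid
        if n_invalid + self.n_reverse > self.n_snps:
            raise ConfigError(
                f"{n_invalid} pleiotropic + {self.n_reverse} reverse-causal "
                f"SNPs exceed n_snps={self.n_snps}"
            )

    @property
    def n_invalid(self) -> int:
        if self.pleiotropy_mode == "none":
            return 0
        return math.ceil(self.prop_invalid * self.n_snps)

    @property
    def resolved_pleiotropy_mean(self) -> float:
        if self.pleiotropy_mean is not None:
            return self.pleiotropy_mean
        return 0.05 if self.pleiotropy_mode == "directional" else 0.0


@dataclass
class SimulationTruth:
    """Ground-truth ledger: everything needed to score recovery."""

    config: SimulationConfig
    variant_ids: list[str]
    maf: np.ndarray
    gamma: np.ndarray  # true exposure effects (0 for reverse-causal SNPs)
    alpha: np.ndarray  # direct (pleiotropic) outcome effects
    delta: np.ndarray  # direct outcome effects of reverse-causal SNPs
    reverse_flag: np.ndarray
    b_x: np.ndarray
    se_x: np.ndarray
    b_y: np.ndarray
    se_y: np.ndarray
    n_exp: np.ndarray = field(default=None)
    n_out: np.ndarray = field(default=None)

    @property
    def beta_true(self) -> float:
        return self.config.beta_true

    def to_harmonized(self, gene: str = "SYNTH", outcome: str = "SIM") -> HarmonizedInstrumentSet:
        """Package the realized effects directly as a harmonized set
        (alleles are already aligned by construction)."""
        k = len(self.gamma)
        tbl = pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "effect_allele": ["A"] * k,
                "other_allele": ["G"] * k,
                "beta_exp": self.b_x,
                "se_exp": self.se_x,
                "pvalue_exp": 2.0 * sps.norm.sf(np.abs(self.b_x / self.se_x)),
                "n_exp": self.n_exp,
                "eaf_exp": self.maf,
                "beta_out": self.b_y,
                "se_out": self.se_y,
                "n_out": self.n_out,
                "flipped": False,
                "palindromic_resolution": "not_palindromic",
            }
        )
        return HarmonizedInstrumentSet(gene=gene, outcome=outcome, table=tbl)


@dataclass
class SimulatedDataset:
    """Output bundle of :func:`simulate` (field order mirrors the pipeline
    inputs: exposure stats, outcome stats, LD, region, plus the truth)."""

    exposure: pd.DataFrame
    outcome: pd.DataFrame
    ld: LDMatrix
    region: GeneRegion
    truth: SimulationTruth


def _truncated_normal(rng, n, sd, lower_abs):
    """Normal(0, sd^2) with |value| >= lower_abs via rejection (seeded)."""
    out = rng.normal(0.0, sd, size=n)
    bad = np.abs(out) < lower_abs
    while bad.any():
        out[bad] = rng.normal(0.0, sd, size=int(bad.sum()))
        bad = np.abs(out) < lower_abs
    return out


def simulate(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate one synthetic exposure/outcome summary-statistics pair.

    Mechanism (deterministic given ``config.seed``):

    * MAF_j ~ Uniform(maf_range); standard errors follow the
      standardized-trait approximation se = 1/sqrt(2 n MAF(1-MAF)) (binary
      outcomes additionally divide by sqrt(K(1-K)), log-odds scale);
    * gamma_j ~ Normal(0, gamma_sd^2) truncated away from zero at
      |gamma| >= gamma_min, then rescaled by a single common factor so the
      expected exposure z-statistic |gamma_j|/se_Xj is at least 6 for every
      SNP (p <= 5e-8 discoverable);
    * b_Xj ~ Normal(gamma_j, se_Xj^2); for valid forward SNPs
      b_Yj ~ Normal(beta_true * gamma_j + alpha_j, se_Yj^2), where the
      pleiotropic alpha_j ~ Normal(mean, sd^2) on the lowest-index
      ceil(prop_invalid * k) SNPs (zero elsewhere);
    * the last ``n_reverse`` SNPs are reverse-causal: a large direct outcome
      effect delta_j (drawn like gamma, floored at 6 outcome SEs) with
      b_Yj ~ Normal(delta_j, se_Yj^2) and
      b_Xj ~ Normal(beta_reverse * delta_j, se_Xj^2);
    * exposure and outcome noise streams are independent (two-sample design);
    * the LD matrix is AR(1) in position order, r2(i,j) = ld_rho^(2|i-j|);
      positions are 1 kb apart inside a synthetic LDL_C gene region.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_snps

    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=k)
    se_x = 1.0 / np.sqrt(2.0 * cfg.n_exp * maf * (1.0 - maf))
    if cfg.outcome_type == "binary":
        kk = cfg.case_fraction * (1.0 - cfg.case_fraction)
        se_y = 1.0 / np.sqrt(2.0 * cfg.n_out * kk * maf * (1.0 - maf))
    else:
        se_y = 1.0 / np.sqrt(2.0 * cfg.n_out * maf * (1.0 - maf))

    gamma = _truncated_normal(rng, k, cfg.gamma_sd, cfg.gamma_min)
    # inflate the whole effect vector by one common factor so even the
    # weakest instrument is discoverable (expected z >= 6); a global rescale
    # preserves the shape of the effect-size distribution
    scale_up = float(np.max(_Z_DISCOVERY * se_x / np.abs(gamma)))
    if scale_up > 1.0:
        gamma = gamma * scale_up

    alpha = np.zeros(k)
    n_invalid = cfg.n_invalid
    if n_invalid:
        alpha[:n_invalid] = rng.normal(
            cfg.resolved_pleiotropy_mean, cfg.pleiotropy_sd, size=n_invalid
        )
        if cfg.pleiotropy_mode == "directional":
            # directional means directional in the instrument's orientation:
            # applied with sign(gamma) so every invalid SNP pushes the ratio
            # (and hence the causal estimate) the same way; otherwise signed
            # instruments would self-balance a constant-mean alpha
            alpha[:n_invalid] *= np.sign(gamma[:n_invalid])

    reverse = np.zeros(k, dtype=bool)
    delta = np.zeros(k)
    if cfg.n_reverse:
        reverse[k - cfg.n_reverse :] = True
        d = _truncated_normal(rng, cfg.n_reverse, cfg.gamma_sd, cfg.gamma_min)
        floor_y = _Z_DISCOVERY * se_y[reverse]
        small = np.abs(d) < floor_y
        d[small] = np.sign(d[small]) * floor_y[small]
        delta[reverse] = d
        gamma[reverse] = 0.0
        alpha[reverse] = 0.0

    mean_x = np.where(reverse, cfg.beta_reverse * delta, gamma)
    mean_y = np.where(reverse, delta, cfg.beta_true * gamma + alpha)
    b_x = mean_x + se_x * rng.standard_normal(k)
    b_y = mean_y + se_y * rng.standard_normal(k)

    variant_ids = [f"snp_{i + 1:04d}" for i in range(k)]
    start = 1_000_000
    pos = start + 1000 * np.arange(k)
    region = GeneRegion(
        gene="SYNTH",
        chrom="1",
        start=start,
        end=int(pos[-1]),
        exposure_trait="LDL_C",
        flank_bp=0,
    )

    idx = np.arange(k)
    r2 = cfg.ld_rho ** (2.0 * np.abs(idx[:, None] - idx[None, :]))
    ld = LDMatrix(variant_ids=variant_ids, r2=r2)

    def _panel(b, se, n, n_cases=None):
        return pd.DataFrame(
            {
                "variant_id": variant_ids,
                "chrom": region.chrom,
                "pos": pos,
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": maf,
                "beta": b,
                "se": se,
                "pvalue": np.clip(
                    2.0 * sps.norm.sf(np.abs(b / se)), 1e-300, 1.0
                ),
                "n": float(n),
                "n_cases": (
                    float(n_cases) if n_cases is not None else np.nan
                ),
            }
        )

    exposure = _panel(b_x, se_x, cfg.n_exp)
    outcome = _panel(
        b_y,
        se_y,
        cfg.n_out,
        n_cases=(
            round(cfg.case_fraction * cfg.n_out)
            if cfg.outcome_type == "binary"
            else None
        ),
    )

    truth = SimulationTruth(
        config=cfg,
        variant_ids=variant_ids,
        maf=maf,
        gamma=gamma,
        alpha=alpha,
        delta=delta,
        reverse_flag=reverse,
        b_x=b_x,
        se_x=se_x,
        b_y=b_y,
        se_y=se_y,
        n_exp=np.full(k, float(cfg.n_exp)),
        n_out=np.full(k, float(cfg.n_out)),
    )
    return SimulatedDataset(
        exposure=exposure, outcome=outcome, ld=ld, region=region, truth=truth
    )


def cell_seed(master_seed: int, target_index: int, outcome_index: int) -> int:
    """Deterministic per-cell seed: mixes the master seed with the grid
    indices by fixed odd multipliers, reduced mod 2^31."""
    return (master_seed * 1_000_003 + target_index * 10_007 + outcome_index * 101 + 1) % (
        2**31
    )


def simulate_grid(
    base: SimulationConfig,
    targets: list[str],
    outcomes: list[str],
    seed: int,
) -> tuple[dict[tuple[str, str], SimulatedDataset], pd.DataFrame]:
    """Simulate a full target-by-outcome grid with derived per-cell seeds.

    Returns the keyed collection and a manifest (target, outcome, seed).
    Duplicate target or outcome names are a configuration error.
    """
    if not targets or not outcomes:
        raise ConfigError("targets and outcomes must be non-empty")
    if len(set(targets)) != len(targets) or len(set(outcomes)) != len(outcomes):
        raise ConfigError("duplicate keys in targets/outcomes")
    cells: dict[tuple[str, str], SimulatedDataset] = {}
    manifest_rows = []
    for ti, t in enumerate(targets):
        for oi, o in enumerate(outcomes):
            s = cell_seed(seed, ti, oi)
            cells[(t, o)] = simulate(replace(base, seed=s))
            manifest_rows.append({"target": t, "outcome": o, "seed": s})
    return cells, pd.DataFrame(manifest_rows)
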