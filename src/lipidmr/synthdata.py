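"""Synthetic mother-data generator with known causal architecture.

Generates merged lipid/CAD summary tables that structurally mimic the
consortium meta-analysis data the pipeline was designed for, with the
causal truth recorded so selection, harmonization, partitioning, the MR
estimators and the null simulation are all testable end to end.

Model, per SNP j:

* a membership set over {LDL, HDL, TG} (possibly empty) fixes which
  exposures the SNP truly affects; counts of unique, pairwise-shared and
  triple-shared SNPs default to the observed architecture of a real
  338-SNP instrument set (heavy HDL-TG sharing, almost no LDL-HDL
  sharing);
* true per-SD effects ``gamma_jx`` for member exposures are
  ``sign(z) * (gamma_min + |z| * gamma_scale)`` with ``z`` multivariate
  normal (truncated at 4 SD) under a lipid-like cross-trait correlation,
  so every true effect clears the genome-wide threshold by construction;
* observed exposure betas add estimation noise with SE ``1/sqrt(n)``
  (per-SD trait scale), so sample size governs instrument precision;
* the outcome log odds is ``sum_x theta_x * gamma_jx`` plus optional
  direct (horizontal) effects plus estimation noise with SE
  ``cad_se_factor/sqrt(n_cad)``;
* p-values are two-sided Wald tests of beta/SE, so they round-trip
  through the SE-from-p derivation;
* per-trait sample sizes concentrate just below their maximum
  (exponential deficit), giving the P_c/P_d proportion filters real
  bite;
* allele pairs are random ordered pairs from {A,C,G,T}; each trait
  presents the pair in a random orientation with the beta sign adjusted,
  so harmonization is exercised nontrivially.

The generator does not model LD, allele-frequency spectra or population
structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .gwas_io import EXPOSURES, merged_columns
from .harmonize import build_beta_table
from .mr import mvmr
from .selection import Thresholds, apply_thresholds

_PAIR_KEYS = (("ldl", "hdl"), ("ldl", "tg"), ("hdl", "tg"))
_NUCLEOTIDES = ("A", "C", "G", "T")


@dataclass
class SynthConfig:
    """Generator configuration; defaults emulate a 338-SNP instrument study.

    ``n_unique``/``n_pairs``/``n_triple`` fix the true association
    architecture (and hence the pleiotropy fraction); ``theta`` holds the
    planted causal effects on the CAD log-odds scale per 1 SD of each
    lipid; ``n_range`` gives per-trait sample-size bounds with mass piled
    near the upper bound; ``gamma_min``/``gamma_scale`` set the true
    effect magnitudes; ``effect_corr`` is the cross-trait correlation of
    effect draws for SNPs shared between exposures; ``direct_effect_sd``
    adds horizontal SNP-to-outcome effects (0 = none).
    """

    m: int = 20_000
    n_unique: Mapping[str, int] = field(
        default_factory=lambda: {"ldl": 76, "hdl": 96, "tg": 83}
    )
    n_pairs: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("ldl", "hdl"): 1,
            ("ldl", "tg"): 18,
            ("hdl", "tg"): 47,
        }
    )
    n_triple: int = 17
    theta: Mapping[str, float] = field(
        default_factory=lambda: {"ldl": 0.4, "hdl": -0.3, "tg": 0.0}
    )
    gamma_min: float = 0.025
    gamma_scale: float = 0.02
    effect_corr: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("ldl", "hdl"): -0.1,
            ("ldl", "tg"): 0.3,
            ("hdl", "tg"): -0.6,
        }
    )
    n_range: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "ldl": (85_000, 95_000),
            "hdl": (85_000, 95_000),
            "tg": (85_000, 95_000),
            "cad": (170_000, 185_000),
        }
    )
    n_deficit_frac: float = 0.02
    cad_se_factor: float = 2.0
    direct_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.total_associated
        if total > self.m:
            raise ConfigError(f"{total} associated SNPs exceed M={self.m}")
        if any(v < 0 for v in self.n_unique.values()) or self.n_triple < 0:
            raise ConfigError("association counts must be non-negative")

    @property
    def total_associated(self) -> int:
        return sum(self.n_unique.values()) + sum(self.n_pairs.values()) + self.n_triple

    @property
    def pleiotropy_fraction(self) -> float:
        total = self.total_associated
        if total == 0:
            return 0.0
        return (sum(self.n_pairs.values()) + self.n_triple) / total

    def scaled(self, factor: float) -> "SynthConfig":
        """Scale the association architecture (not M) by ``factor``."""
        return replace(
            self,
            n_unique={k: max(0, round(v * factor)) for k, v in self.n_unique.items()},
            n_pairs={k: max(0, round(v * factor)) for k, v in self.n_pairs.items()},
            n_triple=max(0, round(self.n_triple * factor)),
        )


@dataclass
class Truth:
    """Ground truth of a generated table."""

    membership: pd.DataFrame  # snp_id + boolean column per exposure
    gamma: pd.DataFrame  # true per-SD exposure effects
    theta: dict
    config: SynthConfig


def _corr_matrix(config: SynthConfig, members: tuple[str, ...]) -> np.ndarray:
    k = len(members)
    corr = np.eye(k)
    for i, j in itertools.combinations(range(k), 2):
        key = tuple(sorted((members[i], members[j])))
        rho = config.effect_corr.get(key, config.effect_corr.get(key[::-1], 0.0))
        corr[i, j] = corr[j, i] = rho
    return corr


def _draw_sample_sizes(config: SynthConfig, trait: str, m: int, rng) -> np.ndarray:
    lo, hi = config.n_range[trait]
    deficit = rng.exponential(scale=config.n_deficit_frac * hi, size=m)
    return np.clip(np.rint(hi - deficit), lo, hi)


def generate_mother_data(config: SynthConfig, seed: int | None = None) -> tuple[pd.DataFrame, Truth]:
    """Generate one synthetic merged table plus its ground truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    m = config.m

    # --- membership architecture ---------------------------------------
    groups: list[tuple[str, ...]] = []
    groups += [(x,) for x in EXPOSURES for _ in range(config.n_unique.get(x, 0))]
    for pair in _PAIR_KEYS:
        groups += [pair] * config.n_pairs.get(pair, 0)
    groups += [tuple(EXPOSURES)] * config.n_triple

    member = {x: np.zeros(m, dtype=bool) for x in EXPOSURES}
    assoc_rows = rng.choice(m, size=len(groups), replace=False)
    gamma = {x: np.zeros(m) for x in EXPOSURES}
    for row, members in zip(assoc_rows, groups):
        corr = _corr_matrix(config, members)
        z = np.clip(rng.multivariate_normal(np.zeros(len(members)), corr), -4.0, 4.0)
        for x, z_x in zip(members, z):
            member[x][row] = True
            gamma[x][row] = np.sign(z_x) * (config.gamma_min + abs(z_x) * config.gamma_scale)

    # --- observed summary statistics ------------------------------------
    table = pd.DataFrame({"snp_id": [f"snp_{i:06d}" for i in range(m)]})
    table["chrom"] = rng.integers(1, 23, size=m).astype(str)
    table["pos"] = rng.integers(1, 250_000_001, size=m).astype(float)

    pair_idx = rng.integers(0, 4, size=m)
    other_off = rng.integers(1, 4, size=m)
    base_a1 = np.array(_NUCLEOTIDES)[pair_idx]
    base_a2 = np.array(_NUCLEOTIDES)[(pair_idx + other_off) % 4]

    theta = {x: float(config.theta.get(x, 0.0)) for x in EXPOSURES}
    beta_cad_true = sum(theta[x] * gamma[x] for x in EXPOSURES)
    if config.direct_effect_sd > 0:
        beta_cad_true = beta_cad_true + rng.normal(0.0, config.direct_effect_sd, size=m)

    for trait in (*EXPOSURES, "cad"):
        n = _draw_sample_sizes(config, trait, m, rng)
        if trait == "cad":
            se = config.cad_se_factor / np.sqrt(n)
            beta = beta_cad_true + rng.normal(0.0, se)
        else:
            se = 1.0 / np.sqrt(n)
            beta = gamma[trait] + rng.normal(0.0, se)
        # Random presentation orientation; beta sign follows the labels.
        flip = rng.random(m) < 0.5
        table[f"beta_{trait}"] = np.where(flip, -beta, beta)
        table[f"se_{trait}"] = se
        table[f"p_{trait}"] = 2.0 * stats.norm.sf(np.abs(beta) / se)
        table[f"n_{trait}"] = n
        table[f"a1_{trait}"] = np.where(flip, base_a2, base_a1)
        table[f"a2_{trait}"] = np.where(flip, base_a1, base_a2)

    table = table[merged_columns()]
    truth = Truth(
        membership=pd.DataFrame({"snp_id": table["snp_id"], **member}),
        gamma=pd.DataFrame({"snp_id": table["snp_id"], **gamma}),
        theta=theta,
        config=config,
    )
    return table, truth


@dataclass
class RecoveryReport:
    """Parameter-recovery harness output.

    ``estimates`` holds one row per (replicate, exposure); ``summary`` one
    row per exposure with the planted effect, mean estimate, bias,
    empirical (Monte-Carlo) SE of the mean, and 95%-CI coverage.
    """

    estimates: pd.DataFrame
    summary: pd.DataFrame


def recovery_experiment(
    config: SynthConfig,
    replicates: int = 20,
    seed: int = 0,
    thresholds: Thresholds | None = None,
) -> RecoveryReport:
    """Generate -> select -> harmonize -> MVMR, repeated; report recovery of theta.

    ``thresholds`` defaults to stage-1 only at genome-wide significance so
    every truly associated SNP is eligible.
    """
    if replicates < 2:
        raise ConfigError("recovery_experiment needs >= 2 replicates")
    thresholds = thresholds or Thresholds(p_v=5e-08)
    seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)

    rows = []
    for rep, rep_seed in enumerate(seeds):
        table, truth = generate_mother_data(config, seed=int(rep_seed))
        selected = apply_thresholds(table, thresholds, reference=table)
        result = mvmr(build_beta_table(selected))
        for est in result.estimates:
            rows.append(
                {
                    "rep": rep,
                    "exposure": est.exposure,
                    "beta": est.beta,
                    "se": est.se,
                    "p": est.p,
                    "theta": truth.theta[est.exposure],
                    "covered": (est.beta - 1.959964 * est.se)
                    <= truth.theta[est.exposure]
                    <= (est.beta + 1.959964 * est.se),
                    "n_snps": est.n_snps,
                }
            )
    estimates = pd.DataFrame(rows)
    grouped = estimates.groupby("exposure", sort=False)
    summary = grouped.agg(
        theta=("theta", "first"),
        mean_beta=("beta", "mean"),
        sd_beta=("beta", lambda s: s.std(ddof=1)),
        coverage=("covered", "mean"),
        mean_n_snps=("n_snps", "mean"),
    ).reset_index()
    summary["bias"] = summary["mean_beta"] - summary["theta"]
    summary["mc_se"] = summary["sd_beta"] / np.sqrt(replicates)
    return RecoveryReport(estimates=estimates, summary=summary)


def tg_confounding_experiment(
    config: SynthConfig | None = None,
    replicates: int = 20,
    seed: int = 0,
    p_threshold: float = 5e-08,
) -> pd.DataFrame:
    """Contrast full-set single-variable MR with unique-set MVMR for TG.

    Under :func:`tg_confounding_config` TG has no causal effect and no
    unique instruments; its apparent instruments are SNPs shared with HDL
    and LDL.  Per replicate this runs (a) IVW for TG on the full selected
    set (instruments: SNPs associated with TG) and (b) MVMR on the
    unique-SNP subset, and records both TG p-values plus the IVW slope.
    The expected pattern: (a) significant (spurious), (b) not.
    """
    from .mr import ivw
    from .pleiotropy import partition_table

    config = config or tg_confounding_config()
    seeds = np.random.SeedSequence(seed).generate_state(replicates) % (2**31)
    rows = []
    for rep, rep_seed in enumerate(seeds):
        table, _ = generate_mother_data(config, seed=int(rep_seed))
        selected = apply_thresholds(table, Thresholds(p_v=p_threshold), reference=table)
        beta_table = build_beta_table(selected)
        tg_set = beta_table[beta_table["p_tg"] <= p_threshold]
        full = ivw(
            tg_set["beta_tg"].to_numpy(),
            tg_set["beta_cad"].to_numpy(),
            tg_set["se_cad"].to_numpy(),
            exposure="tg",
        )
        part = partition_table(beta_table, p_threshold)
        unique = beta_table[beta_table["snp_id"].isin(part.unique)]
        est = mvmr(unique).get("mvmr", "tg")
        rows.append(
            {
                "rep": rep,
                "ivw_full_beta": full.beta,
                "ivw_full_p": full.p,
                "mvmr_unique_beta": est.beta,
                "mvmr_unique_p": est.p,
                "n_tg_instruments": full.n_snps,
                "n_unique": len(unique),
            }
        )
    return pd.DataFrame(rows)


def tg_confounding_config(base: SynthConfig | None = None) -> SynthConfig:
    """Scenario reproducing the TG-confounding mechanism.

    TG has no causal effect (theta_tg = 0) and no unique instruments; it
    is associated only through SNPs shared with HDL and LDL, whose effects
    are cross-correlated.  Single-variable MR of TG on the full set then
    reports a spurious positive effect, while multivariable MR on the
    unique-SNP subset correctly finds nothing.
    """
    base = base or SynthConfig()
    n_unique = dict(base.n_unique)
    n_unique["tg"] = 0
    theta = dict(base.theta)
    theta["tg"] = 0.0
    return replace(base, n_unique=n_unique, theta=theta)
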