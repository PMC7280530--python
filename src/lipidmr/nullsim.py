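"""Null-GWAS embedding simulation with FDR evaluation.

The simulation asks whether the three-stage instrument selection pulls
SNPs out of a genome-wide background by signal or by chance, and what the
surviving pleiotropy-free instruments say about the lipid-CAD effects.

Construction, per replicate:

1. **Null background** — from a *mother* merged table (real or synthetic),
   build M null SNPs: per trait, null betas are drawn from a normal with
   the mother data's beta mean and variance, null p-values uniformly on
   ``[p_low, 1]`` (linear scale), null sample sizes from a normal with the
   mother's moments (rounded, floored at 1), and allele pairs are a
   permutation of the mother's pairs so the allele multiset per trait is
   preserved.  Null SNPs are scattered uniformly over 22 chromosomes.
2. **Embedding** — each SNP of a *test set* (a previously selected
   instrument set) is written into randomly chosen null rows, once per
   exposure it is associated with, each placement replacing that row's
   exposure fields *and* CAD fields.  Placements are independent across
   exposures, so a SNP associated with two or three lipids is duplicated
   or triplicated to separate genomic locations — its exposure-CAD effect
   pairs survive intact, but any cross-exposure (pleiotropic) linkage is
   broken by construction.  Truth labels record which simulated rows carry
   test content.
3. **Selection + MVMR** — the standard selection stages run on the
   simulated table for every (P_c, P_d) grid cell at the chosen P_v; the
   false discovery rate is the fraction of selected SNPs that are *not*
   labelled test rows.  Multivariable MR runs on each cell's harmonized
   selection, and everything is averaged over replicates.

When ``p_low`` exceeds ``P_v`` no null row can pass stage 1, so the FDR is
exactly zero — the analytic calibration point.  A ``p_low`` below ``P_v``
(e.g. 1e-12) admits null SNPs and produces strictly positive FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import CapacityError, EmptyResultError, ValidationError
from .gwas_io import EXPOSURES, TRAITS, derive_se_from_p
from .harmonize import build_beta_table
from .mr import mvmr
from .pleiotropy import classify_associations
from .selection import select_stage1, select_stage2
from .exceptions import CollinearityError, InsufficientInstrumentsError

logger = logging.getLogger(__name__)

#: Fraction m/M above which embedded test SNPs are no longer guaranteed to
#: be effectively free of chance co-association between exposures.
M_OVER_M_LIMIT = 0.005


@dataclass
class NullSimConfig:
    """Configuration of the embedding simulation.

    ``m_null`` is the null background size M (defaults to the mother-table
    size); ``p_low`` the lower bound of the uniform null p-value range;
    ``pc_grid`` x ``pd_grid`` the selection grid; ``p_v`` the stage-1
    cutoff; ``replicates`` the number of independent simulations averaged
    per cell.
    """

    m_null: int | None = None
    p_low: float = 1e-07
    p_v: float = 5e-08
    pc_grid: Sequence[float] = (0.9, 0.95, 0.97, 0.98, 0.99)
    pd_grid: Sequence[float] = (0.97, 0.98, 0.99)
    replicates: int = 10
    seed: int = 0
    proportions: str = "stage1"

    def __post_init__(self) -> None:
        if not (0.0 < self.p_low < 1.0):
            raise ValidationError(f"p_low must be in (0, 1), got {self.p_low}")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if not self.pc_grid or not self.pd_grid:
            raise ValidationError("P_c / P_d grids must be non-empty")
        if self.proportions not in ("stage1", "full"):
            raise ValidationError("proportions must be 'stage1' or 'full'")


@dataclass
class SimSummary:
    """Replicate-averaged simulation results.

    ``summary`` holds one row per (P_c, P_d) cell with averaged selected /
    false SNP counts, FDR, per-exposure association counts and MVMR betas
    and p-values; ``replicates`` retains the per-replicate rows for
    dispersion reporting.
    """

    summary: pd.DataFrame
    replicates: pd.DataFrame
    config: NullSimConfig = field(default=None)  # type: ignore[assignment]


def _permuted_pairs(a1: np.ndarray, a2: np.ndarray, m: int, rng) -> tuple[np.ndarray, np.ndarray]:
    n = len(a1)
    if m <= n:
        idx = rng.permutation(n)[:m]
    else:
        idx = np.concatenate([rng.permutation(n) for _ in range(-(-m // n))])[:m]
    return a1[idx], a2[idx]


def build_null_profiles(mother: pd.DataFrame, config: NullSimConfig, rng=None) -> pd.DataFrame:
    """Simulate a null merged table from the mother data's moments.

    Null standard errors are derived from the simulated (beta, p) pairs so
    the table satisfies the same contracts as a real merged table.
    """
    if mother is None or len(mother) == 0:
        raise EmptyResultError("mother table must be non-empty")
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    m = config.m_null if config.m_null is not None else len(mother)

    out = pd.DataFrame({"snp_id": [f"null_{i:07d}" for i in range(m)]})
    out["chrom"] = rng.integers(1, 23, size=m).astype(str)
    out["pos"] = rng.integers(1, 250_000_001, size=m).astype(float)

    for trait in TRAITS:
        beta = mother[f"beta_{trait}"].to_numpy(dtype=float)
        n = mother[f"n_{trait}"].to_numpy(dtype=float)
        b = rng.normal(np.mean(beta), np.std(beta, ddof=1), size=m)
        p = rng.uniform(config.p_low, 1.0, size=m)
        nn = np.maximum(1, np.rint(rng.normal(np.mean(n), np.std(n, ddof=1), size=m)))
        a1, a2 = _permuted_pairs(
            mother[f"a1_{trait}"].to_numpy(), mother[f"a2_{trait}"].to_numpy(), m, rng
        )
        out[f"beta_{trait}"] = b
        out[f"se_{trait}"] = derive_se_from_p(b, p)
        out[f"p_{trait}"] = p
        out[f"n_{trait}"] = nn
        out[f"a1_{trait}"] = a1
        out[f"a2_{trait}"] = a2
    return out


def embed_test_set(
    null_table: pd.DataFrame,
    test_set: pd.DataFrame,
    p_v: float = 5e-08,
    rng=None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Embed a test SNP set into the null background, breaking pleiotropy.

    Returns the simulated merged table and a label Series (aligned to its
    rows) holding the source test ``snp_id`` for rows that carry test
    content and ``NA`` elsewhere.  The (exposure beta, CAD beta, alleles,
    sample sizes) tuple of every placement is copied verbatim from the
    test row, so exposure-outcome relationships are preserved exactly.

    Raises
    ------
    CapacityError
        If the placements do not fit into the null table.
    """
    rng = np.random.default_rng(rng)
    sim = null_table.copy()
    m_total = len(sim)

    membership = classify_associations(test_set, p_v)
    placements: list[tuple[int, str]] = []  # (test-row position, exposure)
    for pos_j in range(len(test_set)):
        for x in EXPOSURES:
            if bool(membership[x].iloc[pos_j]):
                placements.append((pos_j, x))

    if len(placements) > m_total:
        raise CapacityError(
            f"{len(placements)} placements exceed null capacity M={m_total}"
        )
    if len(test_set) / m_total >= M_OVER_M_LIMIT:
        warnings.warn(
            f"m/M = {len(test_set) / m_total:.4f} >= {M_OVER_M_LIMIT}; embedded SNPs "
            "may co-associate by chance",
            stacklevel=2,
        )

    targets = rng.choice(m_total, size=len(placements), replace=False)
    labels = pd.Series(pd.NA, index=sim.index, dtype="object")
    cad_fields = [f"{f}_cad" for f in ("beta", "se", "p", "n", "a1", "a2")]
    for (pos_j, x), target in zip(placements, targets):
        row = test_set.iloc[pos_j]
        cols = [f"{f}_{x}" for f in ("beta", "se", "p", "n", "a1", "a2")] + cad_fields
        sim.iloc[target, [sim.columns.get_loc(c) for c in cols]] = row[cols].to_numpy()
        labels.iloc[target] = row["snp_id"]
    return sim, labels


def compute_fdr(selected: pd.DataFrame, labels: pd.Series) -> float:
    """Fraction of selected SNPs not originating from the test set.

    An empty selection has FDR defined as 0 (with a warning) so grid cells
    that select nothing do not poison averages.
    """
    n_sel = len(selected)
    if n_sel == 0:
        warnings.warn("empty selection: FDR defined as 0", stacklevel=2)
        return 0.0
    n_false = int(labels.reindex(selected.index).isna().sum())
    return n_false / n_sel


def run_simulation_grid(
    mother: pd.DataFrame,
    test_set: pd.DataFrame,
    config: NullSimConfig,
) -> SimSummary:
    """Full simulation: build nulls, embed, select per grid cell, MVMR, average.

    One master seed spawns independent per-replicate substreams, so the
    result is a pure function of (mother, test_set, config).
    """
    seed_seq = np.random.SeedSequence(config.seed)
    rows = []
    for rep, child in enumerate(seed_seq.spawn(config.replicates)):
        rng = np.random.default_rng(child)
        null_table = build_null_profiles(mother, config, rng=rng)
        sim, labels = embed_test_set(null_table, test_set, p_v=config.p_v, rng=rng)
        stage1 = select_stage1(sim, config.p_v)
        # Sample-size proportions are taken over the stage-1 survivors by
        # default: computing them on the full simulated table lets the
        # unbounded normal null sample-size draws set the maxima, which no
        # embedded (real-valued) row can reach at high cutoffs.
        reference = stage1 if config.proportions == "stage1" else sim
        for p_c in config.pc_grid:
            for p_d in config.pd_grid:
                if len(stage1) == 0:
                    selected = stage1
                else:
                    selected = select_stage2(stage1, p_c, p_d, reference=reference)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fdr = compute_fdr(selected, labels)
                n_false = int(labels.reindex(selected.index).isna().sum())
                row = {
                    "rep": rep,
                    "p_c": p_c,
                    "p_d": p_d,
                    "n_selected": len(selected),
                    "n_false": n_false,
                    "fdr": fdr,
                    "flag": "",
                }
                for x in EXPOSURES:
                    row[f"n_{x}"] = int((selected[f"p_{x}"] <= config.p_v).sum())
                    row[f"beta_{x}"] = np.nan
                    row[f"p_{x}"] = np.nan
                if len(selected) >= 4:
                    try:
                        result = mvmr(build_beta_table(selected, on_irreconcilable="letter"))
                        for est in result.estimates:
                            row[f"beta_{est.exposure}"] = est.beta
                            row[f"p_{est.exposure}"] = est.p
                    except (CollinearityError, InsufficientInstrumentsError) as exc:
                        row["flag"] = f"mvmr failed: {type(exc).__name__}"
                else:
                    row["flag"] = "insufficient instruments"
                rows.append(row)
    replicate_frame = pd.DataFrame(rows)
    return summarize_replicates(replicate_frame, config)


def summarize_replicates(replicate_frame: pd.DataFrame, config: NullSimConfig | None = None) -> SimSummary:
    """Average per-replicate grid results into one row per (P_c, P_d) cell."""
    if replicate_frame.empty:
        raise EmptyResultError("no replicate results to summarize")
    value_cols = [
        c for c in replicate_frame.columns if c not in ("rep", "p_c", "p_d", "flag")
    ]
    grouped = replicate_frame.groupby(["p_c", "p_d"], sort=True)
    summary = grouped[value_cols].mean().reset_index()
    summary["n_reps"] = grouped.size().to_numpy()
    summary["n_reps_ok"] = (
        grouped["flag"].apply(lambda s: int((s == "").sum())).to_numpy()
    )
    return SimSummary(summary=summary, replicates=replicate_frame, config=config)
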