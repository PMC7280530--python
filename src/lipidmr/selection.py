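"""Three-stage instrument selection and the threshold-grid convergence scan.

A SNP enters the instrument set through three successive filters applied to
the merged lipid/CAD table:

1. **Association** — keep SNPs whose smallest exposure p-value ``P_vj``
   satisfies ``P_vj <= P_v`` (inclusive), i.e. SNPs associated with at
   least one lipid component.
2. **Sample-size proportion** — keep SNPs with ``P_cj > P_c`` and
   ``P_dj > P_d`` (both strict), where ``P_cj`` is the SNP's summed
   exposure sample size relative to the per-table maximum of that sum and
   ``P_dj`` the analogous outcome-sample-size proportion.  This retains
   SNPs genotyped in (nearly) the full meta-analysis samples.
3. **Distance pruning** — within each chromosome, retained SNPs must be at
   least ``AIL`` base pairs apart (adjacent interval length); when two
   candidates are closer, the one with the smaller ``P_vj`` (stronger
   association) wins, ties going to the smaller position.

The mixed inequality conventions (inclusive stage 1, strict stage 2) are
deliberate and load-bearing for boundary cases.

:func:`scan_grid` reruns the full pipeline (selection, harmonization,
multivariable MR) over a grid of threshold settings and reports how the
three causal-effect estimates move with the number of SNPs selected.  It
flags the most stable grid point as advisory output only; choosing the
operating point remains the analyst's decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import CoordinateError, DegenerateTableError, ValidationError
from .gwas_io import EXPOSURES


@dataclass(frozen=True)
class Thresholds:
    """The selection tuple (P_v, P_c, P_d, AIL).

    ``p_v`` is the stage-1 association cutoff (genome-wide significance by
    default), ``p_c``/``p_d`` the stage-2 sample-size-proportion cutoffs in
    [0, 1], and ``ail`` the stage-3 minimum adjacent interval length in
    base pairs (0 disables pruning).
    """

    p_v: float = 5e-08
    p_c: float = 0.0
    p_d: float = 0.0
    ail: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_v <= 1.0):
            raise ValidationError(f"p_v must be in (0, 1], got {self.p_v}")
        for name in ("p_c", "p_d"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.ail < 0:
            raise ValidationError(f"ail must be >= 0, got {self.ail}")


def compute_pvj(table: pd.DataFrame) -> pd.Series:
    """Per-SNP ``P_vj``: the smallest p-value among the three lipid exposures."""
    return table[[f"p_{x}" for x in EXPOSURES]].min(axis=1)


def compute_pcj_pdj(table: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-SNP sample-size proportions (``P_cj``, ``P_dj``).

    ``P_cj`` divides each SNP's summed exposure sample size by the largest
    such sum in the table; ``P_dj`` does the same with the outcome sample
    size.  Both therefore lie in (0, 1] with at least one SNP at 1.

    Raises
    ------
    DegenerateTableError
        If either maximum is zero or not finite.
    """
    n_sum = sum(table[f"n_{x}"] for x in EXPOSURES)
    n_cad = table["n_cad"]
    max_sum = n_sum.max()
    max_cad = n_cad.max()
    if not np.isfinite(max_sum) or max_sum <= 0 or not np.isfinite(max_cad) or max_cad <= 0:
        raise DegenerateTableError("maximum sample size is zero or undefined")
    return n_sum / max_sum, n_cad / max_cad


def select_stage1(table: pd.DataFrame, p_v: float) -> pd.DataFrame:
    """Keep SNPs associated with at least one exposure: ``P_vj <= P_v``."""
    return table.loc[compute_pvj(table) <= p_v].copy()


def select_stage2(
    table: pd.DataFrame,
    p_c: float,
    p_d: float,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Keep SNPs with ``P_cj > P_c`` and ``P_dj > P_d`` (strict).

    Proportions are computed on ``reference`` when given (normally the full
    merged table, so the denominators are not shrunk by stage 1) and on
    ``table`` itself otherwise.
    """
    base = table if reference is None else reference
    pcj, pdj = compute_pcj_pdj(base)
    if reference is not None:
        pcj = pcj.reindex(table.index)
        pdj = pdj.reindex(table.index)
    return table.loc[(pcj > p_c) & (pdj > p_d)].copy()


def select_ail(table: pd.DataFrame, ail: int) -> pd.DataFrame:
    """Greedy per-chromosome distance pruning at minimum spacing ``ail`` bp.

    Scanning each chromosome in position order, a candidate closer than
    ``ail`` to the most recently kept SNP competes with it: the SNP with
    the smaller ``P_vj`` survives (tie: the smaller position, i.e. the
    incumbent).  Displacing an incumbent re-opens the comparison with the
    SNP kept before it, so retained SNPs are pairwise at least ``ail``
    apart.  ``ail == 0`` returns the input unchanged.

    Raises
    ------
    CoordinateError
        If any row lacks chrom/pos (the message lists offending SNP ids).
    """
    if ail == 0:
        return table.copy()
    missing = table["chrom"].isna() | table["pos"].isna()
    if missing.any():
        ids = table.loc[missing, "snp_id"].tolist()
        raise CoordinateError(f"missing coordinates for SNP(s): {ids[:10]}")

    pvj = compute_pvj(table)
    keep_labels: list = []
    work = pd.DataFrame(
        {"pos": table["pos"].astype(float), "pvj": pvj, "chrom": table["chrom"]},
        index=table.index,
    )
    for _, sub in work.groupby("chrom", sort=False):
        sub = sub.sort_values(["pos", "pvj"], kind="stable")
        kept: list[tuple[float, float, object]] = []  # (pos, pvj, label)
        for label, row in sub.iterrows():
            placed = True
            while kept and row["pos"] - kept[-1][0] < ail:
                if row["pvj"] < kept[-1][1]:
                    kept.pop()
                else:
                    placed = False
                    break
            if placed:
                kept.append((row["pos"], row["pvj"], label))
        keep_labels.extend(label for _, _, label in kept)

    return table.loc[table.index.intersection(keep_labels, sort=False)].copy()


def apply_thresholds(
    table: pd.DataFrame,
    thresholds: Thresholds,
    reference: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run stages 1 -> 2 -> 3 with one :class:`Thresholds` setting."""
    stage1 = select_stage1(table, thresholds.p_v)
    base = reference if reference is not None else table
    stage2 = select_stage2(stage1, thresholds.p_c, thresholds.p_d, reference=base)
    return select_ail(stage2, thresholds.ail)


#: AIL ladder used by both named schemes (base pairs).
_AIL_LADDER = (25_000, 20_000, 15_000, 10_000, 5_000, 1_000)


def scheme_grid(scheme: str, p_v: float = 5e-08) -> list[Thresholds]:
    """Named threshold grids for the convergence scan.

    Scheme ``"A"`` walks five (P_c, P_d) settings from (0.95, 0.972) up to
    (0.99, 0.99) at AIL = 0, then the AIL ladder 25..1 kbp at
    P_c = P_d = 0.99.  Scheme ``"B"`` uses (0.972, 0.972) and
    (0.979, 0.979) at AIL = 0, then the AIL ladder at P_c = P_d = 0.979.
    """
    scheme = scheme.upper()
    if scheme == "A":
        pairs = [(0.95, 0.972), (0.972, 0.972), (0.979, 0.979), (0.98, 0.98), (0.99, 0.99)]
        ail_at = (0.99, 0.99)
    elif scheme == "B":
        pairs = [(0.972, 0.972), (0.979, 0.979)]
        ail_at = (0.979, 0.979)
    else:
        raise ValidationError(f"unknown scheme {scheme!r}; expected 'A' or 'B'")
    grid = [Thresholds(p_v=p_v, p_c=pc, p_d=pd_, ail=0) for pc, pd_ in pairs]
    grid.extend(
        Thresholds(p_v=p_v, p_c=ail_at[0], p_d=ail_at[1], ail=ail) for ail in _AIL_LADDER
    )
    return grid


@dataclass
class ConvergenceCurve:
    """Result of a threshold-grid scan.

    ``frame`` has one row per grid point with the thresholds, the number of
    SNPs selected, the three multivariable-MR effect estimates and a
    ``stability`` score (the maximum absolute change of any estimate to a
    neighbouring grid point; smaller is more stable).
    ``suggested_index`` flags the most stable usable grid point — advisory
    only, never applied automatically.
    """

    frame: pd.DataFrame
    suggested_index: int | None = None
    grid: Sequence[Thresholds] = field(default_factory=tuple)


def scan_grid(table: pd.DataFrame, grid: Iterable[Thresholds]) -> ConvergenceCurve:
    """Run select -> harmonize -> MVMR for every grid point.

    Grid points yielding fewer than four instruments (or a rank-deficient
    design) are flagged rather than fatal.
    """
    from .harmonize import build_beta_table
    from .mr import mvmr
    from .exceptions import CollinearityError

    grid = list(grid)
    if not grid:
        raise ValidationError("grid must be non-empty")

    rows = []
    for th in grid:
        selected = apply_thresholds(table, th, reference=table)
        row = {
            "p_v": th.p_v,
            "p_c": th.p_c,
            "p_d": th.p_d,
            "ail": th.ail,
            "n_snps": len(selected),
            "beta_ldl": np.nan,
            "beta_hdl": np.nan,
            "beta_tg": np.nan,
            "flag": "",
        }
        if len(selected) < 4:
            row["flag"] = "insufficient instruments"
        else:
            try:
                beta_table = build_beta_table(selected)
                result = mvmr(beta_table)
                for est in result.estimates:
                    row[f"beta_{est.exposure}"] = est.beta
            except CollinearityError:
                row["flag"] = "collinear design"
        rows.append(row)

    frame = pd.DataFrame(rows)
    betas = frame[["beta_ldl", "beta_hdl", "beta_tg"]].to_numpy()
    stability = np.full(len(frame), np.nan)
    for i in range(len(frame)):
        if frame.loc[i, "flag"]:
            continue
        diffs = []
        for j in (i - 1, i + 1):
            if 0 <= j < len(frame) and not frame.loc[j, "flag"]:
                diffs.append(np.nanmax(np.abs(betas[i] - betas[j])))
        if diffs:
            stability[i] = max(diffs)
    frame["stability"] = stability
    suggested = None
    if np.isfinite(stability).any():
        suggested = int(np.nanargmin(stability))
    return ConvergenceCurve(frame=frame, suggested_index=suggested, grid=tuple(grid))
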