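"""Reading, validating, merging and writing GWAS summary-statistic tables.

The analysis consumes one summary table per trait: three lipid exposures
(LDL-c, HDL-c, TG; per-SD effect estimates) and one binary outcome (CAD;
log odds ratios).  Tables are tab-separated text with a header.  Two named
column dialects are shipped: ``"lipid"`` for consortium lipid meta-analysis
tables and ``"cad"`` for the CAD meta-analysis table (case/control sample
sizes reported separately).  Any other layout is supplied as an explicit
column mapping.

The central container is the *merged table*: a :class:`pandas.DataFrame`
with one row per SNP present in all four traits and, for each trait ``t``,
columns ``beta_t, se_t, p_t, n_t, a1_t, a2_t`` plus shared ``snp_id``,
``chrom`` and ``pos``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    EmptyResultError,
    FormatError,
    UndefinedStatisticError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Trait labels in canonical order: the three exposures, then the outcome.
TRAITS = ("ldl", "hdl", "tg", "cad")
#: The lipid exposures only.
EXPOSURES = ("ldl", "hdl", "tg")

#: Per-trait fields carried through the merged table, in canonical order.
TRAIT_FIELDS = ("beta", "se", "p", "n", "a1", "a2")

#: Named column dialects.  ``n_case``/``n_control`` are summed into ``n``.
DIALECTS: dict[str, dict[str, str]] = {
    "lipid": {
        "snp_id": "SNPID",
        "a1": "A1",
        "a2": "A2",
        "beta": "beta",
        "se": "se",
        "n": "N",
        "p": "P-value",
    },
    "cad": {
        "snp_id": "markername",
        "a1": "allele1",
        "a2": "allele2",
        "beta": "log_odds",
        "se": "log_odds_se",
        "p": "p_value",
        "n_case": "N_case",
        "n_control": "N_control",
    },
}

_MANDATORY = ("snp_id", "a1", "a2", "beta", "p")

_CHRPOS_RE = re.compile(r"^(?:chr)?([0-9xym]{1,2}):([0-9]+)$")


def merged_columns() -> list[str]:
    """Canonical column order of a merged table."""
    cols = ["snp_id", "chrom", "pos"]
    for trait in TRAITS:
        cols.extend(f"{field}_{trait}" for field in TRAIT_FIELDS)
    return cols


@dataclass
class TraitTable:
    """Validated summary statistics for a single trait.

    ``df`` columns: ``snp_id, chrom, pos, a1, a2, beta, se, p, n,
    se_from_p``; ``snp_id`` is unique and lower-case.
    """

    trait: str
    df: pd.DataFrame

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.df)


def derive_se_from_p(beta, p):
    """Standard error implied by an effect estimate and its two-sided p-value.

    Inverts the Wald test: ``se = |beta| / z`` with ``z`` the upper
    ``1 - p/2`` standard-normal quantile, so recomputing
    ``p = 2 * Phi(-|beta|/se)`` returns the input.  Accepts scalars or
    arrays.

    Raises
    ------
    UndefinedStatisticError
        If any ``p >= 1``, ``p <= 0`` or ``beta == 0`` (no finite SE exists).
    """
    beta_arr = np.asarray(beta, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr >= 1.0) or np.any(p_arr <= 0.0):
        raise UndefinedStatisticError("SE from p requires 0 < p < 1")
    if np.any(beta_arr == 0.0):
        raise UndefinedStatisticError("SE from p requires beta != 0")
    z = stats.norm.isf(p_arr / 2.0)
    out = np.abs(beta_arr) / z
    if out.ndim == 0:
        return float(out)
    return out


def _resolve_mapping(dialect) -> dict[str, str]:
    if isinstance(dialect, str):
        try:
            return dict(DIALECTS[dialect])
        except KeyError:
            raise FormatError(
                f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)} "
                "or pass an explicit column mapping"
            ) from None
    return dict(dialect)


def _parse_chrom_pos(snp_id: pd.Series) -> tuple[pd.Series, pd.Series]:
    extracted = snp_id.str.extract(_CHRPOS_RE)
    chrom = extracted[0]
    pos = pd.to_numeric(extracted[1], errors="coerce")
    return chrom, pos


def read_trait_table(path, trait: str, dialect="lipid") -> TraitTable:
    """Read and validate one trait's summary table.

    Rows violating record invariants (``p`` outside (0, 1], ``n < 1``,
    identical alleles, non-finite beta) are dropped with a logged count.
    Rows lacking an SE get one derived from (beta, p) where possible and
    are flagged in the ``se_from_p`` column.

    Raises
    ------
    FormatError
        If a mapped mandatory column is absent (the message names it).
    ValidationError
        On duplicate ``snp_id`` (the message names the first offender).
    """
    mapping = _resolve_mapping(dialect)
    raw = pd.read_csv(path, sep="\t", comment="#", dtype={mapping["snp_id"]: str})

    for field in _MANDATORY:
        col = mapping.get(field)
        if col is None or col not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {col or field!r}")
    has_n = "n" in mapping and mapping["n"] in raw.columns
    has_cc = all(
        key in mapping and mapping[key] in raw.columns
        for key in ("n_case", "n_control")
    )
    if not has_n and not has_cc:
        raise FormatError(
            f"{path}: missing sample-size column "
            f"({mapping.get('n', 'N')!r} or case/control counts)"
        )

    df = pd.DataFrame()
    df["snp_id"] = raw[mapping["snp_id"]].astype(str).str.strip().str.lower()
    df["a1"] = raw[mapping["a1"]].astype(str).str.strip().str.upper()
    df["a2"] = raw[mapping["a2"]].astype(str).str.strip().str.upper()
    for field in ("beta", "p"):
        df[field] = pd.to_numeric(raw[mapping[field]], errors="coerce")
    if has_n:
        df["n"] = pd.to_numeric(raw[mapping["n"]], errors="coerce")
    else:
        # One scalar per SNP is needed downstream; cases + controls.
        df["n"] = pd.to_numeric(raw[mapping["n_case"]], errors="coerce") + pd.to_numeric(
            raw[mapping["n_control"]], errors="coerce"
        )
    if "se" in mapping and mapping["se"] in raw.columns:
        df["se"] = pd.to_numeric(raw[mapping["se"]], errors="coerce")
    else:
        df["se"] = np.nan

    if "chrom" in mapping and mapping["chrom"] in raw.columns:
        df["chrom"] = raw[mapping["chrom"]].astype(str).str.strip()
        df["pos"] = pd.to_numeric(raw.get(mapping.get("pos")), errors="coerce")
    else:
        df["chrom"], df["pos"] = _parse_chrom_pos(df["snp_id"])

    dupes = df["snp_id"][df["snp_id"].duplicated()]
    if not dupes.empty:
        raise ValidationError(
            f"{path}: duplicate snp_id (first offender: {dupes.iloc[0]!r})"
        )

    ok = (
        df["beta"].notna()
        & df["p"].notna()
        & (df["p"] > 0.0)
        & (df["p"] <= 1.0)
        & df["n"].notna()
        & (df["n"] >= 1)
        & (df["a1"] != df["a2"])
        & (df["se"].isna() | (df["se"] > 0.0))
    )
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning(
            "%s (%s): rejected %d row(s) violating record invariants",
            path,
            trait,
            n_rejected,
        )
    df = df.loc[ok].reset_index(drop=True)

    derivable = df["se"].isna() & (df["beta"] != 0.0) & (df["p"] < 1.0)
    df["se_from_p"] = derivable
    if derivable.any():
        df.loc[derivable, "se"] = derive_se_from_p(
            df.loc[derivable, "beta"].to_numpy(), df.loc[derivable, "p"].to_numpy()
        )
        logger.info(
            "%s (%s): derived SE from (beta, p) for %d row(s)",
            path,
            trait,
            int(derivable.sum()),
        )

    order = ["snp_id", "chrom", "pos", "a1", "a2", "beta", "se", "p", "n", "se_from_p"]
    return TraitTable(trait=trait.lower(), df=df[order])


def merge_by_snpid(tables: Iterable[TraitTable]) -> pd.DataFrame:
    """Inner-join four trait tables on ``snp_id`` into a merged table.

    The result holds the intersection of the four SNP id sets with every
    per-trait field preserved unchanged; rows are sorted by ``snp_id`` so
    the merge is invariant to table order.

    Raises
    ------
    ValidationError
        If the four canonical traits are not each supplied exactly once.
    EmptyResultError
        If the id intersection is empty.
    """
    by_trait: dict[str, pd.DataFrame] = {}
    for table in tables:
        trait = table.trait.lower()
        if trait in by_trait:
            raise ValidationError(f"trait {trait!r} supplied more than once")
        by_trait[trait] = table.df
    missing = [t for t in TRAITS if t not in by_trait]
    if missing:
        raise ValidationError(f"missing trait table(s): {missing}")

    merged: pd.DataFrame | None = None
    for trait in TRAITS:
        df = by_trait[trait]
        renamed = df.rename(
            columns={f: f"{f}_{trait}" for f in TRAIT_FIELDS}
        )[["snp_id", "chrom", "pos"] + [f"{f}_{trait}" for f in TRAIT_FIELDS]]
        renamed = renamed.rename(columns={"chrom": f"chrom_{trait}", "pos": f"pos_{trait}"})
        merged = renamed if merged is None else merged.merge(renamed, on="snp_id", how="inner")

    assert merged is not None
    if merged.empty:
        raise EmptyResultError("no SNP is present in all four trait tables")

    chrom = pd.Series(pd.NA, index=merged.index, dtype="object")
    pos = pd.Series(np.nan, index=merged.index, dtype=float)
    for trait in TRAITS:
        chrom = chrom.where(chrom.notna(), merged[f"chrom_{trait}"])
        pos = pos.where(pos.notna(), merged[f"pos_{trait}"])
    merged["chrom"] = chrom
    merged["pos"] = pos
    merged = merged.drop(
        columns=[f"chrom_{t}" for t in TRAITS] + [f"pos_{t}" for t in TRAITS]
    )
    merged = merged.sort_values("snp_id", kind="stable").reset_index(drop=True)
    return merged[merged_columns()]


def trait_table_from_merged(merged: pd.DataFrame, trait: str) -> TraitTable:
    """Project one trait's records back out of a merged table."""
    trait = trait.lower()
    df = pd.DataFrame({"snp_id": merged["snp_id"]})
    df["chrom"] = merged["chrom"]
    df["pos"] = merged["pos"]
    for field in TRAIT_FIELDS:
        df[field] = merged[f"{field}_{trait}"]
    df["se_from_p"] = False
    return TraitTable(trait=trait, df=df)


# Column precedence used to canonicalize written tables; covers merged
# tables and the harmonized beta table.
_CANONICAL_PRECEDENCE = (
    ["snp_id", "chrom", "pos"]
    + [f"{f}_{t}" for t in TRAITS for f in TRAIT_FIELDS]
    + [f"flipped_{t}" for t in EXPOSURES]
    + ["palindromic"]
)


def write_table(table: pd.DataFrame, path, provenance: Mapping | None = None) -> None:
    """Write a table as tab-separated text in canonical column order.

    Columns known to the package are emitted in a fixed documented order;
    any extra columns follow alphabetically, so output never depends on the
    in-memory ordering.  ``provenance`` entries become ``# key: value``
    header comments.

    Raises
    ------
    EmptyResultError
        If the table has no rows.
    """
    if table is None or len(table) == 0:
        raise EmptyResultError(f"refusing to write empty table to {path}")
    known = [c for c in _CANONICAL_PRECEDENCE if c in table.columns]
    extra = sorted(c for c in table.columns if c not in known)
    out = table[known + extra]
    with open(path, "w", encoding="utf-8") as handle:
        if provenance:
            for key, value in provenance.items():
                handle.write(f"# {key}: {value}\n")
        out.to_csv(handle, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "snp_id" in df.columns:
        df["snp_id"] = df["snp_id"].astype(str)
    if "chrom" in df.columns:
        df["chrom"] = df["chrom"].astype("object").where(df["chrom"].notna(), pd.NA)
        df["chrom"] = df["chrom"].map(lambda v: str(v) if not pd.isna(v) else pd.NA)
    return df
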