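"""Dissecting an instrument set into shared (pleiotropic) and unique SNPs.

A selected SNP is *associated* with an exposure when its p-value for that
exposure passes a threshold (genome-wide significance, 5e-08, by default,
inclusive).  SNPs associated with exactly one lipid component are *unique*
(also called restricted) instruments; SNPs associated with two or three
are *shared* and carry potential pleiotropic effects that can confound
single-exposure causal attribution.  The seven-region Venn breakdown of
the three association sets quantifies the overlap structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ClassificationError
from .gwas_io import EXPOSURES

#: Threshold presets: genome-wide significance plus the relaxed cutoffs
#: used when re-partitioning externally selected instrument sets.
THRESHOLD_PRESETS = {"genomewide": 5e-08, "relaxed3": 1e-03, "relaxed4": 1e-04}

#: The seven Venn regions over (LDL, HDL, TG), canonical order.
VENN_REGIONS = (
    "ldl_only",
    "hdl_only",
    "tg_only",
    "ldl_hdl",
    "ldl_tg",
    "hdl_tg",
    "all_three",
)


def classify_associations(
    table: pd.DataFrame, p_threshold: float = 5e-08
) -> pd.DataFrame:
    """Per-SNP exposure membership: ``p_xj <= p_threshold`` (inclusive).

    Returns a DataFrame indexed like ``table`` with ``snp_id`` and one
    boolean column per exposure.
    """
    out = pd.DataFrame({"snp_id": table["snp_id"]}, index=table.index)
    for x in EXPOSURES:
        out[x] = table[f"p_{x}"] <= p_threshold
    return out


@dataclass
class PartitionResult:
    """Shared/unique dissection of an instrument set.

    ``membership`` is the boolean per-SNP exposure matrix; the subset
    fields hold SNP ids; ``venn`` maps each of the seven regions to its
    count.  Unique and shared ids partition the input set.
    """

    p_threshold: float
    membership: pd.DataFrame
    unique_ldl: list = field(default_factory=list)
    unique_hdl: list = field(default_factory=list)
    unique_tg: list = field(default_factory=list)
    shared: list = field(default_factory=list)
    venn: dict = field(default_factory=dict)

    @property
    def unique(self) -> list:
        """All unique (single-exposure) SNP ids."""
        return self.unique_ldl + self.unique_hdl + self.unique_tg


def partition_shared_unique(
    membership: pd.DataFrame, p_threshold: float = 5e-08
) -> PartitionResult:
    """Partition SNPs into unique (one exposure) and shared (>= 2) subsets.

    Raises
    ------
    ClassificationError
        If any SNP carries no exposure membership — such a SNP could not
        have passed the association stage that produced the set, so the
        classification threshold and the selection threshold disagree.
    """
    counts = membership[list(EXPOSURES)].sum(axis=1)
    if (counts == 0).any():
        ids = membership.loc[counts == 0, "snp_id"].tolist()
        raise ClassificationError(
            f"SNP(s) with no exposure membership (selection/threshold mismatch): {ids[:10]}"
        )

    is_l = membership["ldl"]
    is_h = membership["hdl"]
    is_t = membership["tg"]
    venn = {
        "ldl_only": int((is_l & ~is_h & ~is_t).sum()),
        "hdl_only": int((~is_l & is_h & ~is_t).sum()),
        "tg_only": int((~is_l & ~is_h & is_t).sum()),
        "ldl_hdl": int((is_l & is_h & ~is_t).sum()),
        "ldl_tg": int((is_l & ~is_h & is_t).sum()),
        "hdl_tg": int((~is_l & is_h & is_t).sum()),
        "all_three": int((is_l & is_h & is_t).sum()),
    }

    ids = membership["snp_id"]
    return PartitionResult(
        p_threshold=p_threshold,
        membership=membership,
        unique_ldl=ids[is_l & (counts == 1)].tolist(),
        unique_hdl=ids[is_h & (counts == 1)].tolist(),
        unique_tg=ids[is_t & (counts == 1)].tolist(),
        shared=ids[counts >= 2].tolist(),
        venn=venn,
    )


def partition_table(
    table: pd.DataFrame, p_threshold: float = 5e-08
) -> PartitionResult:
    """Classify and partition in one step (convenience wrapper)."""
    return partition_shared_unique(
        classify_associations(table, p_threshold), p_threshold=p_threshold
    )


def venn_counts(a, b) -> tuple[int, int, int]:
    """Two-set overlap counts: ``(|a & b|, |a - b|, |b - a|)``."""
    sa, sb = set(a), set(b)
    return len(sa & sb), len(sa - sb), len(sb - sa)
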