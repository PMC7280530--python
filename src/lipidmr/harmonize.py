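"""Allele harmonization: building the beta table used by every MR estimator.

Two-sample MR regresses outcome effect sizes on exposure effect sizes
across SNPs, so every effect must be expressed for the same allele.  The
CAD table's reference (major) allele anchors the orientation: for each
exposure, a SNP whose exposure effect allele differs from the CAD
reference allele has its exposure beta sign-flipped.  The outcome beta is
never flipped.

Reconciliation rules, applied per exposure in priority order:

1. effect alleles equal                      -> keep beta;
2. exposure effect allele equals the CAD
   other allele                              -> flip beta, swap labels;
3. complement of the exposure effect allele
   equals the CAD reference allele           -> keep beta, complement labels;
4. complement equals the CAD other allele    -> flip beta, complement + swap;
5. anything else                             -> ``HarmonizationError``.

On data reported against a single strand (the usual consortium
convention) rules 3-4 never fire and this reduces to plain letter
comparison.  A/T and C/G (palindromic) SNPs are strand-ambiguous; they are
flagged, never silently resolved or removed, so the analyst can audit
them.  Standard errors, p-values and sample sizes pass through unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import HarmonizationError
from .gwas_io import EXPOSURES, TRAITS

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(lambda a: _COMPLEMENT.get(a, "?"))


def build_beta_table(merged: pd.DataFrame, on_irreconcilable: str = "error") -> pd.DataFrame:
    """Harmonize a merged (or selected) table against the CAD reference allele.

    Returns a beta table with the merged columns plus ``flipped_{ldl,hdl,tg}``
    orientation flags and a ``palindromic`` flag; row order matches the
    input.  Re-running on an already harmonized table changes nothing.

    ``on_irreconcilable`` controls rows whose exposure allele shares no
    letter (or complement) with the CAD pair: ``"error"`` raises;
    ``"letter"`` falls back to the bare letter rule (flip iff the effect
    alleles differ, labels untouched), which is what simulated tables with
    permuted allele profiles require.

    Raises
    ------
    HarmonizationError
        If any exposure allele is irreconcilable with the CAD allele pair
        (the message lists offending SNP ids) and ``on_irreconcilable`` is
        ``"error"``.
    """
    if on_irreconcilable not in ("error", "letter"):
        raise ValueError("on_irreconcilable must be 'error' or 'letter'")
    out = merged.copy()
    cad1 = out["a1_cad"]
    cad2 = out["a2_cad"]

    for x in EXPOSURES:
        a1 = out[f"a1_{x}"]
        a2 = out[f"a2_{x}"]
        comp1 = _complement(a1)
        comp2 = _complement(a2)

        direct_keep = a1 == cad1
        direct_flip = ~direct_keep & (a1 == cad2)
        comp_keep = ~direct_keep & ~direct_flip & (comp1 == cad1)
        comp_flip = ~direct_keep & ~direct_flip & ~comp_keep & (comp1 == cad2)
        bad = ~(direct_keep | direct_flip | comp_keep | comp_flip)
        if bad.any():
            if on_irreconcilable == "error":
                ids = out.loc[bad, "snp_id"].tolist()
                raise HarmonizationError(
                    f"irreconcilable alleles for exposure {x!r}: SNP(s) {ids[:10]}"
                )
            # Bare letter rule: flip on differing effect alleles.
            direct_flip = direct_flip | (bad & (a1 != cad1))
            direct_keep = direct_keep | (bad & (a1 == cad1))

        flipped = direct_flip | comp_flip
        out[f"beta_{x}"] = np.where(flipped, -out[f"beta_{x}"], out[f"beta_{x}"])
        new_a1 = a1.where(direct_keep, a2.where(direct_flip, comp1.where(comp_keep, comp2)))
        new_a2 = a2.where(direct_keep, a1.where(direct_flip, comp2.where(comp_keep, comp1)))
        out[f"a1_{x}"] = new_a1
        out[f"a2_{x}"] = new_a2
        # flags accumulate across rebuilds so re-harmonizing keeps provenance
        if f"flipped_{x}" in merged.columns:
            flipped = flipped | merged[f"flipped_{x}"].astype(bool)
        out[f"flipped_{x}"] = flipped

    return flag_palindromes(out)


def flag_palindromes(beta_table: pd.DataFrame) -> pd.DataFrame:
    """Flag strand-ambiguous SNPs (A/T or C/G outcome allele pairs).

    Nothing is removed; the flag makes the lack of strand handling in the
    harmonization auditable.
    """
    out = beta_table.copy()
    pair_ok = out["a1_cad"].map(_COMPLEMENT.get) == out["a2_cad"]
    out["palindromic"] = pair_ok.fillna(False).astype(bool)
    return out


def beta_table_columns() -> list[str]:
    """Canonical column order of a written beta table."""
    cols = ["snp_id", "chrom", "pos"]
    for trait in TRAITS:
        cols.extend(f"{f}_{trait}" for f in ("beta", "se", "p", "n", "a1", "a2"))
    cols.extend(f"flipped_{x}" for x in EXPOSURES)
    cols.append("palindromic")
    return cols
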