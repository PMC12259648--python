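"""Combined panel report: kinetics, thermostability and hydrodynamics.

Derived annotations are always recomputed from the input tables — KD from
the rate constants with an internal-consistency check, fold changes
relative to a designated parental variant, Tm shifts, and the residue-40
hydrodynamic-radius group comparison with an exact Mann-Whitney test.
Inputs may be fitted results or externally reported tables (e.g. published
values) in the same column layout, so both run through identical code.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from . import datasets
from .biophys import group_summary, mann_whitney_exact
from .kinetics import KineticFit, round_half_away, summarize_kinetics

__all__ = ["variant_has_substitution", "fold_with_rule", "build_report"]


def variant_has_substitution(variant: str, sub: str) -> bool:
    """Whether a panel variant (named by its substitution set) carries a
    given reversion.  The UCA carries all six lineage reversions."""
    if variant == "UCA":
        return sub in (
            datasets.HEAVY_LINEAGE_SUBSTITUTIONS + datasets.LIGHT_LINEAGE_SUBSTITUTIONS
        )
    return sub in variant.split(",")


def fold_with_rule(numerator: float, denominator: float) -> float:
    """Reported fold change: one decimal below 10, nearest integer above
    (both half-away-from-zero)."""
    raw = numerator / denominator
    return round_half_away(raw, 1) if raw < 10 else round_half_away(raw, 0)


def build_report(
    kinetics: dict[str, KineticFit] | pd.DataFrame | None = None,
    biophys: pd.DataFrame | None = None,
    parental: str = datasets.PARENTAL,
    reported_rh_p: float | None = datasets.REPORTED_RH_PVALUE,
) -> dict:
    """Assemble the combined variant-panel report.

    ``kinetics`` is either fitted :class:`KineticFit` objects per variant
    or a table with scaled columns (ka_1e5, kd_1e-4, KD_nM); ``biophys``
    carries Tm and Rh summary columns.  Defaults to the published panel
    tables.
    """
    if kinetics is None and biophys is None:
        kinetics = datasets.kinetics_table()
        biophys = datasets.biophys_table()
    elif kinetics is None:
        kinetics = datasets.kinetics_table()

    if isinstance(kinetics, pd.DataFrame):
        fits = {name: row.to_dict() for name, row in kinetics.iterrows()}
    else:
        fits = dict(kinetics)
    kin = summarize_kinetics(fits)
    if parental not in kin.index:
        raise ValueError(f"parental variant {parental!r} missing from kinetics input")

    kd_ref = float(kin.loc[parental, "KD_nM"])
    ka_ref = float(kin.loc[parental, "ka_1e5"])
    kdis_ref = float(kin.loc[parental, "kd_1e-4"])
    kin = kin.assign(
        KD_fold_vs_parental=[
            fold_with_rule(v, kd_ref) for v in kin["KD_nM"]
        ],
        ka_fold_vs_parental=[round_half_away(v / ka_ref, 1) for v in kin["ka_1e5"]],
        kd_fold_vs_parental=[
            fold_with_rule(v, kdis_ref) for v in kin["kd_1e-4"]
        ],
    )

    out: dict = {"kinetics": kin}

    if biophys is not None and len(biophys):
        bio = biophys.copy()
        if parental in bio.index:
            tm_ref = float(bio.loc[parental, "tm_mean_C"])
            bio["tm_delta_vs_parental_C"] = (bio["tm_mean_C"] - tm_ref).round(1)
        out["biophys"] = bio

        n40 = [
            v for v in bio.index if variant_has_substitution(v, "T40_H_N")
        ]
        t40 = [v for v in bio.index if v not in n40]
        rh25 = bio["rh25_mean_nm"].dropna()
        if len(n40) >= 2 and len(t40) >= 2:
            groups = group_summary(
                rh25.to_dict(), lambda v: variant_has_substitution(v, "T40_H_N")
            )
            u, p = mann_whitney_exact(
                [rh25[v] for v in t40 if v in rh25.index],
                [rh25[v] for v in n40 if v in rh25.index],
            )
            rh_cmp = {
                "n40_mean_sd_nm": groups[True],
                "t40_mean_sd_nm": groups[False],
                "mann_whitney_U": u,
                "exact_two_sided_p": p,
            }
            if reported_rh_p is not None:
                rh_cmp["reported_p"] = reported_rh_p
                rh_cmp["reported_p_discrepant"] = (
                    abs(p - reported_rh_p) > 0.0005
                )
            out["rh25_residue40_comparison"] = rh_cmp

        tm_shift_variants = [
            v
            for v in bio.index
            if v != parental and variant_has_substitution(v, "T40_H_N")
        ]
        if tm_shift_variants and "tm_delta_vs_parental_C" in bio:
            deltas = bio.loc[tm_shift_variants, "tm_delta_vs_parental_C"]
            out["tm_shift_T40N_variants_C"] = {
                "per_variant": deltas.to_dict(),
                "min": float(deltas.min()),
                "max": float(deltas.max()),
            }
    return out


def report_to_json(report: dict) -> dict:
    """JSON-serializable form of :func:`build_report` output."""
    def conv(obj):
        if isinstance(obj, pd.DataFrame):
            return obj.reset_index().to_dict(orient="records")
        if isinstance(obj, dict):
            return {str(k): conv(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [conv(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, float) and np.isnan(obj):
            return None
        return obj

    return conv(report)
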