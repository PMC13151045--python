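"""The fish plasma model (FPM): partitioning, TWC, and its Rf_u refinement.

The FPM predicts the steady-state fish blood-plasma concentration of a
pharmaceutical from its water concentration through a hydrophobicity-
driven blood:water partition coefficient,

    P_blood:water = 10^(0.73 * LogD_ow - 0.88),

and inverts that relation to a therapeutic water concentration (TWC):
the water concentration at which fish plasma would reach the human
therapeutic plasma concentration C_max,

    TWC = C_max / P_blood:water.                    (original FPM)

The refinement divides C_max by the relative unbound fraction
Rf_u = f_u(fish)/f_u(human) before partitioning, with LogD evaluated at
the fish species' plasma pH:

    TWC = (C_max / Rf_u) / P_blood:water.           (refined FPM)

A lower TWC means higher priority for in vivo testing.  Conservatism is
assessed against chronic fish early-life-stage effect concentrations:
a TWC at or below the LOEC is a conservative (protective) prediction.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .catalog import APIRecord, SpeciesContext
from .dialysis import FuSummary
from .rfu import rfu_max as _rfu_max, rfu_median as _rfu_median

__all__ = [
    "PARTITION_SLOPE",
    "PARTITION_INTERCEPT",
    "HUMAN_REFERENCE_PH",
    "TWCResult",
    "blood_water_partition",
    "predict_fss_pc",
    "twc_original",
    "twc_refined",
    "assess_conservatism",
    "derive_rfu",
    "screen",
    "write_twc_table",
]

#: Coefficients of the blood:water partition regression on LogD_ow.
PARTITION_SLOPE = 0.73
PARTITION_INTERCEPT = -0.88

#: LogD reference pH for the generic ("fish") original FPM.
HUMAN_REFERENCE_PH = 7.4


@dataclass
class TWCResult:
    """Original and refined therapeutic water concentrations for one API.

    All concentrations in mg/L.  Fields are ``None`` when an input
    needed to compute them (C_max, Rf_u, effect concentration) is
    absent or below quantification — never zero.
    """

    api_name: str
    species_id: str
    logd_used_original: float
    logd_used_refined: float
    p_bw_original: float
    p_bw_refined: float
    rfu: float | None = None
    twc_original: float | None = None
    twc_refined: float | None = None
    twc_ratio: float | None = None
    ratio_orig_to_loec: float | None = None
    ratio_refined_to_loec: float | None = None
    conservative_original: bool | None = None
    conservative_refined: bool | None = None


def blood_water_partition(logd: float,
                          slope: float = PARTITION_SLOPE,
                          intercept: float = PARTITION_INTERCEPT) -> float:
    """Blood:water partition coefficient 10^(slope*LogD + intercept)."""
    if not math.isfinite(logd):
        raise ValueError("LogD must be finite")
    return 10.0 ** (slope * logd + intercept)


def predict_fss_pc(water_conc: float, p_bw: float) -> float:
    """Steady-state fish plasma concentration: W * P_blood:water (mg/L)."""
    if water_conc < 0:
        raise ValueError("water concentration cannot be negative")
    return water_conc * p_bw


def twc_original(cmax: float | None, p_bw: float) -> float | None:
    """Original-FPM therapeutic water concentration C_max / P.

    Returns ``None`` (absent, not zero) when C_max is missing.
    """
    if cmax is None:
        return None
    if cmax <= 0 or p_bw <= 0:
        raise ValueError("cmax and p_bw must be positive")
    return cmax / p_bw


def twc_refined(cmax: float | None, rfu: float | None,
                p_bw_fish: float) -> float | None:
    """Refined-FPM TWC: (C_max / Rf_u) / P_fish.

    ``P_fish`` uses LogD at the fish plasma pH.  Absent when C_max is
    missing or Rf_u is missing/below quantification (printed 0).
    """
    if cmax is None or rfu is None or rfu <= 0:
        return None
    if cmax <= 0 or p_bw_fish <= 0:
        raise ValueError("cmax and p_bw_fish must be positive")
    return (cmax / rfu) / p_bw_fish


def assess_conservatism(result: TWCResult, noec: float | None,
                        loec: float | None) -> TWCResult:
    """Attach TWC/effect-concentration ratios and conservatism flags.

    Ratios are computed against the LOEC where available, otherwise the
    NOEC.  The conservative flag (TWC <= LOEC, inclusive) is only set
    when a LOEC is present.
    """
    effect = loec if loec is not None else noec
    if effect is None:
        return result
    if effect <= 0:
        raise ValueError(f"{result.api_name}: effect concentration must be positive")
    if result.twc_original is not None:
        result.ratio_orig_to_loec = result.twc_original / effect
        if loec is not None:
            result.conservative_original = result.twc_original <= loec
    if result.twc_refined is not None:
        result.ratio_refined_to_loec = result.twc_refined / effect
        if loec is not None:
            result.conservative_refined = result.twc_refined <= loec
    return result


def derive_rfu(fish: Mapping[str, FuSummary], human: Mapping[str, FuSummary],
               rule: str = "max") -> dict[str, float]:
    """Per-API Rf_u from f_u summaries under the median or max rule."""
    if rule not in ("max", "median"):
        raise ValueError("rfu rule must be 'max' or 'median'")
    out = {}
    for name, fsum in fish.items():
        hsum = human.get(name)
        if hsum is None:
            continue
        out[name] = (_rfu_max(fsum, hsum) if rule == "max"
                     else _rfu_median(fsum, hsum))
    return out


def screen(apis: Sequence[APIRecord], species: SpeciesContext,
           rfu_by_api: Mapping[str, float] | None = None,
           human_reference_ph: float = HUMAN_REFERENCE_PH,
           ) -> tuple[list[TWCResult], list[str]]:
    """Run the full original + refined FPM screen over an API table.

    ``rfu_by_api`` maps API name to the Rf_u to apply (e.g. derived from
    f_u summaries via :func:`derive_rfu`, or taken from a published
    table).  APIs lacking C_max or Rf_u yield rows with absent TWC
    fields.  Rows missing a required LogD are reported in the returned
    error list and skipped; output preserves input order.
    """
    rfu_by_api = rfu_by_api or {}
    results: list[TWCResult] = []
    errors: list[str] = []
    for rec in apis:
        try:
            logd_h = rec.logd(human_reference_ph)
            logd_f = rec.logd(species.plasma_ph)
        except KeyError as exc:
            errors.append(str(exc))
            continue
        p_h = blood_water_partition(logd_h)
        p_f = blood_water_partition(logd_f)
        rfu = rfu_by_api.get(rec.name)
        res = TWCResult(
            api_name=rec.name,
            species_id=species.species_id,
            logd_used_original=logd_h,
            logd_used_refined=logd_f,
            p_bw_original=p_h,
            p_bw_refined=p_f,
            rfu=rfu,
            twc_original=twc_original(rec.cmax, p_h),
            twc_refined=twc_refined(rec.cmax, rfu, p_f),
        )
        if res.twc_original is not None and res.twc_refined is not None:
            res.twc_ratio = res.twc_original / res.twc_refined
        assess_conservatism(res, rec.noec, rec.loec)
        results.append(res)
    return results, errors


_TWC_COLUMNS = [
    "api", "species", "logd_original", "p_bw_original",
    "logd_refined", "p_bw_refined", "rfu",
    "twc_original_mg_per_L", "twc_refined_mg_per_L", "twc_ratio",
    "ratio_original_to_loec", "ratio_refined_to_loec",
    "conservative_original", "conservative_refined",
]


def write_twc_table(results: Iterable[TWCResult], path: str | Path) -> None:
    """Write screening results as CSV (column order mirrors the report table)."""

    def fmt(v):
        return "" if v is None else (v if isinstance(v, bool) else repr(v))

    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TWC_COLUMNS)
        for r in results:
            writer.writerow([
                r.api_name, r.species_id,
                repr(r.logd_used_original), repr(r.p_bw_original),
                repr(r.logd_used_refined), repr(r.p_bw_refined),
                fmt(r.rfu), fmt(r.twc_original), fmt(r.twc_refined),
                fmt(r.twc_ratio), fmt(r.ratio_orig_to_loec),
                fmt(r.ratio_refined_to_loec), fmt(r.conservative_original),
                fmt(r.conservative_refined),
            ])
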