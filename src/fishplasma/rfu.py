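"""Fish:human relative unbound fractions (Rf_u) and prioritization flags.

Rf_u = f_u(fish) / f_u(human).  Two aggregate variants are used for
screening: the ratio of medians, and the worst case
f_u,max(fish) / f_u,min(human).  Compounds with median Rf_u >= 3 or
maximum Rf_u >= 10 are flagged as candidates where the generic fish
plasma model under-predicts internal exposure; both thresholds are
inclusive and configurable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .catalog import SPECIATION_MAPPINGS, charge_class_of
from .dialysis import FuSummary

__all__ = [
    "RfuResult",
    "UndefinedRatioError",
    "rfu_point",
    "rfu_median",
    "rfu_max",
    "compare_fu",
    "classify_rfu",
    "speciation_summary",
    "twc_reduction_count",
    "write_rfu_table",
]

MEDIAN_THRESHOLD = 3.0
MAX_THRESHOLD = 10.0


class UndefinedRatioError(ZeroDivisionError):
    """Human f_u denominator is zero; the ratio is undefined."""


@dataclass
class RfuResult:
    """Relative unbound fraction for one API in one fish species."""

    api_name: str
    species_id: str
    rfu_median: float
    rfu_max: float
    rfu_point: float | None = None
    flag_median_ge3: bool = False
    flag_max_ge10: bool = False

    def __post_init__(self):
        if self.rfu_median < 0 or self.rfu_max < 0:
            raise ValueError(f"{self.api_name}: Rf_u cannot be negative")


def rfu_point(fu_fish: float, fu_human: float) -> float:
    """Point ratio f_u(fish) / f_u(human)."""
    if fu_human <= 0:
        raise UndefinedRatioError("human f_u must be positive")
    if fu_fish < 0:
        raise ValueError("fish f_u cannot be negative")
    return fu_fish / fu_human


def rfu_median(fish: FuSummary, human: FuSummary) -> float:
    """Ratio of median unbound fractions."""
    if human.fu_median <= 0:
        raise UndefinedRatioError(
            f"{fish.api_name}: human median f_u must be positive"
        )
    return fish.fu_median / human.fu_median


def rfu_max(fish: FuSummary, human: FuSummary) -> float:
    """Worst-case ratio: fish maximum over human minimum."""
    if human.fu_min <= 0:
        raise UndefinedRatioError(
            f"{fish.api_name}: human minimum f_u must be positive"
        )
    return fish.fu_max / human.fu_min


def compare_fu(fish: FuSummary, human: FuSummary) -> RfuResult:
    """Build an :class:`RfuResult` (median and worst-case, with flags)."""
    if fish.api_name != human.api_name:
        raise ValueError(
            f"API mismatch: {fish.api_name} vs {human.api_name}"
        )
    result = RfuResult(
        api_name=fish.api_name,
        species_id=fish.species_id,
        rfu_median=rfu_median(fish, human),
        rfu_max=rfu_max(fish, human),
    )
    return classify_rfu(result)


def classify_rfu(result: RfuResult,
                 median_threshold: float = MEDIAN_THRESHOLD,
                 max_threshold: float = MAX_THRESHOLD) -> RfuResult:
    """Set inclusive prioritization flags on a ratio result (in place)."""
    result.flag_median_ge3 = result.rfu_median >= median_threshold
    result.flag_max_ge10 = result.rfu_max >= max_threshold
    return result


def speciation_summary(
    results: Iterable[RfuResult],
    speciation_by_api: Mapping[str, str],
    grouping: str = "ionization_group",
    rule: str = "max",
    denominator: str = "measured",
) -> dict[str, dict[str, int]]:
    """Per-charge-group counts of flagged APIs: {group: {n_flagged, n_total}}.

    ``grouping`` names one of the speciation collapses
    (:data:`SPECIATION_MAPPINGS`); ``rule`` selects which flag counts
    ('max' for worst-case Rf_u >= 10, 'median' for median Rf_u >= 3).
    ``denominator`` sets the group totals: 'measured' counts rows with a
    positive Rf_u under the chosen rule (below-quantification ratios
    are excluded), 'all' counts every classified row.
    """
    if grouping not in SPECIATION_MAPPINGS:
        raise KeyError(f"unknown grouping {grouping!r}")
    if rule not in ("max", "median"):
        raise ValueError("rule must be 'max' or 'median'")
    if denominator not in ("measured", "all"):
        raise ValueError("denominator must be 'measured' or 'all'")

    groups = sorted(set(SPECIATION_MAPPINGS[grouping].values()))
    counts = {g: {"n_flagged": 0, "n_total": 0} for g in groups}
    for r in results:
        code = speciation_by_api.get(r.api_name)
        if code is None:
            raise KeyError(f"no speciation code for {r.api_name!r}")
        group = charge_class_of(code, grouping)
        ratio = r.rfu_max if rule == "max" else r.rfu_median
        if denominator == "measured" and ratio <= 0:
            continue
        counts[group]["n_total"] += 1
        flagged = r.flag_max_ge10 if rule == "max" else r.flag_median_ge3
        if flagged:
            counts[group]["n_flagged"] += 1
    return counts


def twc_reduction_count(ratios: Sequence[float | None],
                        low: float = 10.0, high: float = 100.0) -> int:
    """Count ratios (original/refined TWC) falling in [low, high].

    ``None`` entries (undefined ratios) are skipped.
    """
    return sum(1 for r in ratios
               if r is not None and r == r and low <= r <= high)


def write_rfu_table(results: Iterable[RfuResult], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["api", "species", "rfu_median", "rfu_max",
                         "flag_median_ge3", "flag_max_ge10"])
        for r in results:
            writer.writerow([r.api_name, r.species_id,
                             repr(r.rfu_median), repr(r.rfu_max),
                             r.flag_median_ge3, r.flag_max_ge10])
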