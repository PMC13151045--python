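"""Unbound fractions from rapid equilibrium dialysis (RED).

In a RED assay, plasma spiked with drug (10 uM nominal in the reference
protocol) equilibrates across a size-cutoff membrane with protein-free
buffer; only unbound drug crosses.  The unbound fraction in 100% plasma
is simply f_u = C_buffer / C_plasma.  When the assay is run on diluted
plasma (e.g. 10% plasma for small-bodied fish), the measured fraction
f_u,D must be corrected back to undiluted plasma:

    f_u = f_u,D / (D - (D - 1) * f_u,D)

which at dilution factor D = 10 is the familiar f_u10 / (10 - 9 f_u10).
The correction assumes linear (non-saturated) binding, under which
diluting the protein D-fold scales the bound:free ratio D-fold.

Replicates within a laboratory are averaged; minimum, median and maximum
f_u are then taken across laboratory means, so a single-lab compound has
identical min/median/max.  Total mass recovery (plasma + buffer versus
the nominal spike) is the QC gate for non-specific binding losses.
"""

from __future__ import annotations

import csv
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DialysisMeasurement",
    "FuSummary",
    "MeasurementError",
    "compute_fu",
    "correct_dilution",
    "dilute_fu",
    "compute_recovery",
    "classify_recovery",
    "aggregate_fu",
    "read_assay_table",
    "write_fu_table",
]

#: Recovery QC bands (percent): >=70 pass, [50, 70) caution, <50 fail.
RECOVERY_PASS = 70.0
RECOVERY_CAUTION = 50.0


class MeasurementError(ValueError):
    """A dialysis measurement that cannot yield a defined f_u."""


@dataclass(frozen=True)
class DialysisMeasurement:
    """One replicate's equilibrium concentrations (uM)."""

    api_name: str
    species_id: str
    lab_id: str
    replicate: int
    plasma_conc: float
    buffer_conc: float
    nominal_spike: float = 10.0
    dilution_factor: float = 1.0

    def __post_init__(self):
        if self.plasma_conc < 0 or self.buffer_conc < 0:
            raise MeasurementError(
                f"{self.api_name}: negative concentration"
            )
        if self.dilution_factor < 1:
            raise MeasurementError(
                f"{self.api_name}: dilution_factor must be >= 1"
            )
        if self.replicate < 1:
            raise MeasurementError(f"{self.api_name}: replicate must be >= 1")


@dataclass
class FuSummary:
    """Aggregated unbound fraction for one (API, species).

    Values above 1 (buffer exceeding plasma under measurement noise) are
    retained and flagged ``fu_above_one`` rather than clamped.
    """

    api_name: str
    species_id: str
    fu_min: float
    fu_median: float
    fu_max: float
    n_replicates: int
    n_labs: int
    qc_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.fu_min <= self.fu_median <= self.fu_max:
            raise ValueError(
                f"{self.api_name}: order statistics out of order "
                f"({self.fu_min}, {self.fu_median}, {self.fu_max})"
            )


def compute_fu(plasma_conc: float, buffer_conc: float) -> float:
    """Unbound fraction from equilibrium concentrations: buffer / plasma.

    No clamping is applied; ratios above 1 are returned as-is so QC can
    flag them.
    """
    if plasma_conc <= 0:
        raise MeasurementError(
            "plasma concentration must be positive for a defined f_u"
        )
    if buffer_conc < 0:
        raise MeasurementError("buffer concentration must be non-negative")
    return buffer_conc / plasma_conc


def correct_dilution(fu_diluted: float, dilution_factor: float) -> float:
    """Undiluted-plasma f_u from the value measured in D-fold diluted plasma.

    f_u = f_u,D / (D - (D - 1) * f_u,D); identity at D = 1, and equal to
    f_u10 / (10 - 9 f_u10) at D = 10.
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if fu_diluted < 0:
        raise MeasurementError("f_u cannot be negative")
    if fu_diluted > 1:
        raise MeasurementError(
            f"diluted f_u {fu_diluted} exceeds 1; flag fu_above_one upstream"
        )
    d = dilution_factor
    return fu_diluted / (d - (d - 1.0) * fu_diluted)


def dilute_fu(fu: float, dilution_factor: float) -> float:
    """Algebraic inverse of :func:`correct_dilution`.

    The f_u that would be measured in D-fold diluted plasma for a
    compound whose undiluted f_u is ``fu`` (linear binding).
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    d = dilution_factor
    return d * fu / (1.0 + (d - 1.0) * fu)


def compute_recovery(plasma_conc: float, buffer_conc: float,
                     nominal_spike: float,
                     plasma_volume: float = 1.0,
                     buffer_volume: float = 1.0) -> float:
    """Total mass recovery (%) across both dialysis chambers.

    100 * (plasma mass + buffer mass) / nominal spiked mass, with the
    spike nominally all in the plasma chamber.  Chamber volumes default
    to equal.
    """
    if plasma_volume <= 0 or buffer_volume <= 0:
        raise ValueError("chamber volumes must be positive")
    if nominal_spike <= 0:
        raise ValueError("nominal spike must be positive")
    recovered = plasma_conc * plasma_volume + buffer_conc * buffer_volume
    nominal = nominal_spike * plasma_volume
    return 100.0 * recovered / nominal


def classify_recovery(recovery_pct: float,
                      pass_threshold: float = RECOVERY_PASS,
                      caution_threshold: float = RECOVERY_CAUTION) -> str:
    """QC class for a recovery percentage: 'pass', 'caution' or 'fail'."""
    if recovery_pct >= pass_threshold:
        return "pass"
    if recovery_pct >= caution_threshold:
        return "caution"
    return "fail"


def _median(values: Sequence[float]) -> float:
    # midpoint convention for even counts
    return statistics.median(values)


def aggregate_fu(measurements: Iterable[DialysisMeasurement],
                 apply_dilution_correction: bool = True) -> FuSummary:
    """Aggregate replicate measurements of one (API, species) pair.

    Per replicate: f_u = buffer/plasma, corrected to undiluted plasma.
    Within each lab replicates are averaged (arithmetic mean); min,
    median and max are then taken across lab means.  With a single lab
    the three statistics coincide.

    Raises if measurements span several (API, species) pairs, or if
    dilution factors are mixed while correction is disabled.
    """
    ms = list(measurements)
    if not ms:
        raise ValueError("no measurements to aggregate")
    keys = {(m.api_name, m.species_id) for m in ms}
    if len(keys) > 1:
        raise ValueError(f"measurements span several (api, species): {keys}")
    dilutions = {m.dilution_factor for m in ms}
    if not apply_dilution_correction and len(dilutions) > 1:
        raise ValueError(
            "mixed dilution factors require dilution correction"
        )

    flags: set[str] = set()
    by_lab: dict[str, list[float]] = {}
    for m in ms:
        fu_raw = compute_fu(m.plasma_conc, m.buffer_conc)
        if fu_raw > 1.0:
            flags.add("fu_above_one")
            # above-unity values cannot pass through the dilution
            # correction (denominator may vanish); carry them unscaled
            fu = fu_raw
        elif apply_dilution_correction:
            fu = correct_dilution(fu_raw, m.dilution_factor)
        else:
            fu = fu_raw
        recovery = compute_recovery(m.plasma_conc, m.buffer_conc,
                                    m.nominal_spike)
        if classify_recovery(recovery) != "pass":
            flags.add("low_recovery")
        by_lab.setdefault(m.lab_id, []).append(fu)

    lab_means = [statistics.fmean(v) for v in by_lab.values()]
    api, species = next(iter(keys))
    return FuSummary(
        api_name=api,
        species_id=species,
        fu_min=min(lab_means),
        fu_median=_median(lab_means),
        fu_max=max(lab_means),
        n_replicates=len(ms),
        n_labs=len(by_lab),
        qc_flags=frozenset(flags),
    )


def aggregate_all(measurements: Iterable[DialysisMeasurement],
                  apply_dilution_correction: bool = True) -> list[FuSummary]:
    """Group measurements by (API, species) and aggregate each group.

    Output order follows first appearance in the input.
    """
    groups: dict[tuple[str, str], list[DialysisMeasurement]] = {}
    for m in measurements:
        groups.setdefault((m.api_name, m.species_id), []).append(m)
    return [aggregate_fu(v, apply_dilution_correction)
            for v in groups.values()]


ASSAY_HEADER = ["api", "species", "lab", "replicate", "plasma_conc_uM",
                "buffer_conc_uM", "nominal_uM", "dilution_factor"]


def read_assay_table(path: str | Path) -> list[DialysisMeasurement]:
    """Read a dialysis assay CSV (one row per replicate chamber pair)."""
    out: list[DialysisMeasurement] = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty assay file")
        missing = [c for c in ASSAY_HEADER if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing assay columns {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                out.append(DialysisMeasurement(
                    api_name=row["api"].strip(),
                    species_id=row["species"].strip(),
                    lab_id=row["lab"].strip(),
                    replicate=int(row["replicate"]),
                    plasma_conc=float(row["plasma_conc_uM"]),
                    buffer_conc=float(row["buffer_conc_uM"]),
                    nominal_spike=float(row["nominal_uM"]),
                    dilution_factor=float(row["dilution_factor"]),
                ))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: row {i}: {exc}") from exc
    if not out:
        raise ValueError(f"{path}: no measurements")
    return out


def write_fu_table(summaries: Iterable[FuSummary], path: str | Path) -> None:
    """Write f_u summaries as CSV."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["api", "species", "fu_min", "fu_median", "fu_max",
                         "n_replicates", "n_labs", "qc_flags"])
        for s in summaries:
            writer.writerow([
                s.api_name, s.species_id,
                repr(s.fu_min), repr(s.fu_median), repr(s.fu_max),
                s.n_replicates, s.n_labs, ";".join(sorted(s.qc_flags)),
            ])
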