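"""Organelle environment covariates: local pH and membrane charge.

Each compartment carries intra-organelle pH observations from two literature
surveys (2009 and 2015 compilations) and a membrane charge, defined as the
summed relative content (%) of the charged phospholipids phosphatidylserine
(PS) and phosphatidylinositol (PI) in the organelle's membrane.  The two pH
observations are averaged into a single regression covariate; an observation
reported as an interval is first collapsed to its midpoint.

The plasma membrane has no intra-organelle pH (it is a boundary, not a
lumen); it is excluded by default from any computation that requires pH.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ParameterError, ValidationError
from .sequence_io import LOCALIZATIONS

#: tokens treated as a missing value in environment tables
_MISSING_TOKENS = {"", "-", "–", "—", "na", "nan", "none"}

PHValue = float | tuple[float, float] | None


@dataclass(frozen=True)
class CompartmentEnvironment:
    """One organelle's pH observations, averaged pH, and membrane charge."""

    compartment: str
    ph_2009: PHValue
    ph_2015: PHValue
    charge_pct: float
    ph_avg: float | None = None

    def __post_init__(self) -> None:
        if self.compartment not in LOCALIZATIONS:
            raise ValidationError(f"unknown compartment {self.compartment!r}")
        for value in (
            *_interval_bounds(self.ph_2009),
            *_interval_bounds(self.ph_2015),
            self.ph_avg,
        ):
            if value is not None and not 0.0 < value < 14.0:
                raise ValidationError(
                    f"{self.compartment}: pH value {value} outside (0, 14)"
                )
        if not 0.0 <= self.charge_pct <= 100.0:
            raise ValidationError(
                f"{self.compartment}: charge_pct {self.charge_pct} outside [0, 100]"
            )
        if (self.ph_avg is None) != (self.ph_2009 is None and self.ph_2015 is None):
            raise ValidationError(
                f"{self.compartment}: ph_avg must be missing iff both sources are"
            )


def _interval_bounds(value: PHValue) -> tuple[float, ...]:
    if value is None:
        return ()
    if isinstance(value, tuple):
        return value
    return (value,)


def average_ph(ph_2009: float | None, ph_2015: PHValue) -> float | None:
    """Average the available pH sources; an interval collapses to its midpoint.

    Symmetric in its arguments (an interval is equally legal in either slot);
    returns ``None`` when both sources are missing.
    """
    collapsed = [
        0.5 * (v[0] + v[1]) if isinstance(v, tuple) else v
        for v in (ph_2009, ph_2015)
        if v is not None
    ]
    if not collapsed:
        return None
    return sum(collapsed) / len(collapsed)


def membrane_charge_from_lipids(ps_pct: float, pi_pct: float) -> float:
    """Membrane charge (%) as the summed PS and PI relative contents."""
    for name, v in (("ps_pct", ps_pct), ("pi_pct", pi_pct)):
        if not 0.0 <= v <= 100.0:
            raise ParameterError(f"{name} must lie in [0, 100], got {v}")
    if ps_pct + pi_pct > 100.0:
        raise ParameterError(
            f"PS + PI content exceeds 100%: {ps_pct} + {pi_pct}"
        )
    return ps_pct + pi_pct


def _parse_ph(token: str, compartment: str, column: str) -> PHValue:
    token = token.strip()
    if token.lower() in _MISSING_TOKENS:
        return None
    if "-" in token[1:]:  # interval "a-b" (leading "-" would be a sign)
        lo_s, _, hi_s = token.partition("-")
        try:
            lo, hi = float(lo_s), float(hi_s)
        except ValueError as exc:
            raise ValidationError(
                f"{compartment}: malformed pH interval {token!r} in {column}"
            ) from exc
        if hi < lo:
            raise ValidationError(
                f"{compartment}: decreasing pH interval {token!r} in {column}"
            )
        return (lo, hi)
    try:
        return float(token)
    except ValueError as exc:
        raise ValidationError(
            f"{compartment}: malformed pH value {token!r} in {column}"
        ) from exc


def load_environment_table(
    path: str | Path | None = None,
) -> list[CompartmentEnvironment]:
    """Load an environment table; with no path, the built-in 8-compartment table.

    Expected TSV columns: ``compartment``, ``ph_2009``, ``ph_2015``,
    ``charge_pct``; ``ph_avg`` is populated via :func:`average_ph`.
    """
    if path is None:
        text = (
            resources.files("piscape.data")
            .joinpath("organelle_environment.tsv")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    header = lines[0].split("\t")
    required = ["compartment", "ph_2009", "ph_2015", "charge_pct"]
    if header[: len(required)] != required:
        raise ValidationError(
            f"environment table: expected columns {required}, got {header}"
        )
    rows: list[CompartmentEnvironment] = []
    for ln in lines[1:]:
        parts = [p.strip() for p in ln.split("\t")]
        if len(parts) < 4:
            raise ValidationError(f"environment table: malformed row {ln!r}")
        compartment = parts[0]
        ph09 = _parse_ph(parts[1], compartment, "ph_2009")
        ph15 = _parse_ph(parts[2], compartment, "ph_2015")
        try:
            charge = float(parts[3])
        except ValueError as exc:
            raise ValidationError(
                f"{compartment}: malformed charge_pct {parts[3]!r}"
            ) from exc
        rows.append(
            CompartmentEnvironment(
                compartment=compartment,
                ph_2009=ph09,
                ph_2015=ph15,
                charge_pct=charge,
                ph_avg=average_ph(ph09, ph15),
            )
        )
    return rows


def write_environment_table(
    rows: list[CompartmentEnvironment], path: str | Path
) -> None:
    """Write rows in the same TSV dialect the loader reads (lossless round-trip)."""

    def fmt(value: PHValue) -> str:
        if value is None:
            return "-"
        if isinstance(value, tuple):
            return f"{value[0]:g}-{value[1]:g}"
        return f"{value:g}"

    with Path(path).open("w") as handle:
        handle.write("compartment\tph_2009\tph_2015\tcharge_pct\n")
        for row in rows:
            handle.write(
                f"{row.compartment}\t{fmt(row.ph_2009)}\t{fmt(row.ph_2015)}\t"
                f"{row.charge_pct:g}\n"
            )
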