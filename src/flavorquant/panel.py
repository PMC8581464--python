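"""Analyte panel and chromatographic identification rules.

The panel couples each flavoring chemical to its GC retention time,
accurate-mass quantitation and qualifier ions, assigned isotope-labeled
internal standard, and working quantitation range.  A default panel of
20 flavoring chemicals and 5 internal standards ships with the package
(``data/panel_default.csv``); d- and l-limonene are modeled as a single
quantifiable species (identical retention and spectra on this column).

Identification rules implemented here:

* accurate-mass ion matching inside a ppm window (default +/-10 ppm),
* qualifier-ion relative-abundance checks against the expected spectrum,
* relative retention time (RRT) against the assigned internal standard,
  with the EPA-suggested 0.80-1.20 comfort band,
* chromatographic peak resolution from FWHM-based peak widths,
  Rs = (RT2 - RT1) / (0.5 * (W1 + W2)).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Sequence

from .errors import ArgumentError, PanelLoadError

#: Names required of a complete default-style panel (strict loading).
EXPECTED_ANALYTES: tuple[str, ...] = (
    "Acetoin",
    "Butanoic Acid",
    "Benzaldehyde",
    "2,3,5-Trimethylpyrazine",
    "dl-Limonene",
    "Eucalyptol",
    "Benzyl Alcohol",
    "Furaneol",
    "Maltol",
    "L-Menthol",
    "Methyl Salicylate",
    "Ethyl Maltol",
    "(+)Pulegone",
    "Ethyl Salicylate",
    "trans-Cinnamaldehyde",
    "Triacetin",
    "Eugenol",
    "Vanillin",
    "Ethyl Vanillin",
    "Isovanillin",
)

EXPECTED_INTERNAL_STANDARDS: tuple[str, ...] = (
    "Benzene-d6",
    "Pyridine-d5",
    "Chlorobenzene-d5",
    "Naphthalene-d8",
    "Acenaphthene-d10",
)

#: EPA-suggested relative-retention-time comfort band.
RRT_RANGE = (0.80, 1.20)


@dataclass(frozen=True)
class QualifierIon:
    """A secondary (qualifier) ion and its expected relative abundance (%)."""

    mz: float
    relative_abundance: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ArgumentError(f"qualifier m/z must be positive, got {self.mz}")
        if not (0 < self.relative_abundance <= 100):
            raise ArgumentError(
                f"qualifier relative abundance must be in (0, 100], got {self.relative_abundance}"
            )


@dataclass(frozen=True)
class InternalStandard:
    """An isotope-labeled internal standard added at fixed concentration."""

    name: str
    cas: str
    formula: str
    mw: float
    rt: float
    quant_mz: float
    qual_ions: tuple[QualifierIon, ...] = ()
    final_conc: float = 1.0  # mg/ml in the working IS solution

    def __post_init__(self):
        if self.rt <= 0:
            raise ArgumentError(f"{self.name}: retention time must be positive")
        if self.final_conc <= 0:
            raise ArgumentError(f"{self.name}: IS concentration must be positive")


@dataclass(frozen=True)
class Analyte:
    """One target flavoring chemical with its identification metadata."""

    name: str
    cas: str
    formula: str
    mw: float
    rt: float
    quant_mz: float
    qual_ions: tuple[QualifierIon, ...]
    is_name: str
    working_lloq: float
    working_uloq: float

    def __post_init__(self):
        if self.rt <= 0 or self.quant_mz <= 0:
            raise ArgumentError(f"{self.name}: RT and quant m/z must be positive")
        if not (self.working_lloq < self.working_uloq):
            raise ArgumentError(f"{self.name}: working LLOQ must be below ULOQ")
        if not (0.02 <= self.working_lloq <= 10.0 and 0.02 <= self.working_uloq <= 10.0):
            raise ArgumentError(
                f"{self.name}: working range must sit within [0.02, 10.00] mg/ml"
            )


@dataclass(frozen=True)
class PeakObservation:
    """A measured chromatographic peak for one species in one injection."""

    sample_id: str
    analyte_name: str
    area: float
    rt: float
    fwhm: float | None = None
    observed_mz: float | None = None

    def __post_init__(self):
        if self.area < 0:
            raise ArgumentError("peak area must be nonnegative")
        if self.fwhm is not None and self.fwhm <= 0:
            raise ArgumentError("FWHM must be positive when present")


@dataclass
class Panel:
    """The loaded panel: analytes plus internal standards, name-indexed."""

    analytes: dict[str, Analyte] = field(default_factory=dict)
    internal_standards: dict[str, InternalStandard] = field(default_factory=dict)

    def analyte(self, name: str) -> Analyte:
        try:
            return self.analytes[name]
        except KeyError:
            lowered = {k.lower(): v for k, v in self.analytes.items()}
            # lenient lookup: "l-menthol" and "L-Menthol" are the same species
            if name.lower() in lowered:
                return lowered[name.lower()]
            raise PanelLoadError(f"unknown analyte {name!r}") from None

    def internal_standard_for(self, analyte: str | Analyte) -> InternalStandard:
        a = analyte if isinstance(analyte, Analyte) else self.analyte(analyte)
        return self.internal_standards[a.is_name]

    @property
    def species_names(self) -> list[str]:
        return list(self.analytes) + list(self.internal_standards)


def _parse_qual_ions(text: str) -> tuple[QualifierIon, ...]:
    if not text:
        return ()
    ions = []
    for chunk in text.split("|"):
        mz, ab = chunk.split(":")
        ions.append(QualifierIon(float(mz), float(ab)))
    return tuple(ions)


def default_panel_path() -> Path:
    return Path(resources.files("flavorquant").joinpath("data/panel_default.csv"))


def load_panel(path: str | Path | None = None, strict: bool = True) -> Panel:
    """Load a panel-definition file (the packaged default when *path* is None).

    With ``strict=True`` the file must contain exactly the 20 analytes and
    5 internal standards of the default panel; missing or duplicate species
    and dangling internal-standard references raise :class:`PanelLoadError`
    naming the offending species.
    """
    p = Path(path) if path is not None else default_panel_path()
    if not p.exists():
        raise PanelLoadError(f"panel file not found: {p}")
    panel = Panel()
    with open(p, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"kind", "name", "cas", "formula", "mw", "rt", "quant_mz", "qual_ions"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise PanelLoadError(f"panel file {p} lacks required columns {sorted(required)}")
        for row in reader:
            name = row["name"].strip()
            kind = row["kind"].strip()
            try:
                if kind == "analyte":
                    if name in panel.analytes:
                        raise PanelLoadError(f"duplicate analyte {name!r}")
                    panel.analytes[name] = Analyte(
                        name=name,
                        cas=row["cas"].strip(),
                        formula=row["formula"].strip(),
                        mw=float(row["mw"]),
                        rt=float(row["rt"]),
                        quant_mz=float(row["quant_mz"]),
                        qual_ions=_parse_qual_ions(row["qual_ions"].strip()),
                        is_name=row["is_name"].strip(),
                        working_lloq=float(row["working_lloq"]),
                        working_uloq=float(row["working_uloq"]),
                    )
                elif kind == "internal_standard":
                    if name in panel.internal_standards:
                        raise PanelLoadError(f"duplicate internal standard {name!r}")
                    panel.internal_standards[name] = InternalStandard(
                        name=name,
                        cas=row["cas"].strip(),
                        formula=row["formula"].strip(),
                        mw=float(row["mw"]),
                        rt=float(row["rt"]),
                        quant_mz=float(row["quant_mz"]),
                        qual_ions=_parse_qual_ions(row["qual_ions"].strip()),
                        final_conc=float(row["final_conc"] or 1.0),
                    )
                else:
                    raise PanelLoadError(f"unknown species kind {kind!r} for {name!r}")
            except (ValueError, ArgumentError) as exc:
                raise PanelLoadError(f"bad panel row for {name!r}: {exc}") from exc

    for a in panel.analytes.values():
        if a.is_name not in panel.internal_standards:
            raise PanelLoadError(
                f"analyte {a.name!r} references unknown internal standard {a.is_name!r}"
            )
    if strict:
        missing = [n for n in EXPECTED_ANALYTES if n not in panel.analytes]
        missing += [n for n in EXPECTED_INTERNAL_STANDARDS if n not in panel.internal_standards]
        if missing:
            raise PanelLoadError(f"panel is missing required species: {', '.join(missing)}")
        extra = set(panel.analytes) - set(EXPECTED_ANALYTES)
        if extra:
            raise PanelLoadError(f"unexpected analytes in strict panel: {sorted(extra)}")
    return panel


def match_ion(observed_mz: float, reference_mz: float, window_ppm: float = 10.0) -> bool:
    """True iff the observed accurate mass is within *window_ppm* of reference."""
    if observed_mz <= 0 or reference_mz <= 0:
        raise ArgumentError("m/z values must be positive")
    if window_ppm <= 0:
        raise ArgumentError("ppm window must be positive")
    return abs(observed_mz - reference_mz) / reference_mz * 1e6 <= window_ppm


def qualifier_ok(
    analyte: Analyte | InternalStandard,
    observed_abundances: Sequence[float],
    rel_tol: float = 0.30,
) -> bool:
    """Check observed qualifier relative abundances against the expected spectrum.

    Each expected qualifier must be observed within ``rel_tol`` (relative,
    default +/-30%) of its reference abundance.  The observed list must be
    given in the panel's qualifier order.
    """
    expected = analyte.qual_ions
    if len(observed_abundances) != len(expected):
        raise ArgumentError(
            f"{analyte.name}: expected {len(expected)} qualifier abundances, "
            f"got {len(observed_abundances)}"
        )
    for obs, ion in zip(observed_abundances, expected):
        if not (0 <= obs <= 100):
            raise ArgumentError("observed abundances must be in [0, 100]")
        if abs(obs - ion.relative_abundance) > rel_tol * ion.relative_abundance:
            return False
    return True


class RelativeRetention(NamedTuple):
    value: float
    in_range: bool


def relative_retention_time(analyte_rt: float, is_rt: float) -> RelativeRetention:
    """Analyte RT over internal-standard RT, flagged against the 0.80-1.20 band."""
    if analyte_rt <= 0 or is_rt <= 0:
        raise ArgumentError("retention times must be positive")
    rrt = analyte_rt / is_rt
    return RelativeRetention(rrt, RRT_RANGE[0] <= rrt <= RRT_RANGE[1])


def peak_resolution(rt1: float, rt2: float, w1: float, w2: float) -> float:
    """Chromatographic resolution Rs = (RT2 - RT1) / (0.5 * (W1 + W2)).

    Widths are FWHM values; the caller orders the peaks (rt2 >= rt1).
    """
    if w1 <= 0 or w2 <= 0:
        raise ArgumentError("peak widths must be positive")
    if rt2 < rt1:
        raise ArgumentError("rt2 must not precede rt1; order the peaks first")
    return (rt2 - rt1) / (0.5 * (w1 + w2))
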