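"""Physicochemical quality indices for edible oils.

Free acidity and the acid index come from alkali titration of the oil;
polyphenol, chlorophyll and carotenoid contents come from absorbance
readings at protocol-specific wavelengths.  Each formula is homogeneous of
degree one in its driving reading, which makes exact inversion fixtures
possible (see :mod:`arganet.synthetic`).

Quality grades (extra virgin / virgin / refined / lampante) are assigned
from free acidity by configurable bands.  The default bands are
deliberately non-monotone: a very low acidity (< 0.2 %) indicates a
refined rather than a virgin oil, because refining strips free fatty
acids below what fresh cold-pressed oil exhibits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .exceptions import ConfigurationError, InvalidInputError, UndefinedRatioError

logger = logging.getLogger(__name__)

#: molar mass of oleic acid, g/mol — free acidity is expressed as % oleic acid
OLEIC_MOLAR_MASS = 282.46
#: molar mass of KOH, g/mol
KOH_MOLAR_MASS = 56.1
#: Folin-Ciocalteu calibration multiplier for the 10 g oil protocol (ppm per AU)
POLYPHENOL_CALIBRATION = 403.68
#: specific-absorbance divisor of the Wolff chlorophyll method (AU per ppm per cm)
CHLOROPHYLL_COEFF = 0.1086
#: carotenoid protocol constants: A470 * 25 * 10000 / (2000 * 7.5) ppm
CAROTENOID_FACTOR = 25.0 * 10000.0 / (2000.0 * 7.5)


@dataclass(frozen=True)
class TitrationRecord:
    """Alkali titration readings for acidity determination.

    V: titrant volume (ml); C: NaOH concentration (mol/L); N: KOH normality
    (eq/L); m: oil mass (g); M: oleic-acid molar mass (g/mol).
    """

    V: float = 0.0
    C: float = 0.0
    N: float = 0.0
    m: float = 1.0
    M: float = OLEIC_MOLAR_MASS


@dataclass(frozen=True)
class AbsorbanceRecord:
    """Spectrophotometer readings (absorbance units) and cell path length (cm)."""

    A630: float = 0.0
    A670: float = 0.0
    A710: float = 0.0
    A470: float = 0.0
    A725: float = 0.0
    L: float = 1.0


@dataclass
class QualityIndices:
    """Physicochemical quality summary of one oil."""

    free_acidity: Optional[float] = None  # % oleic acid
    acid_index: Optional[float] = None  # mg KOH / g oil
    polyphenol: Optional[float] = None  # ppm
    chlorophyll: Optional[float] = None  # ppm
    carotenoid: Optional[float] = None  # ppm
    grade: Optional[str] = None


def free_acidity(t: TitrationRecord) -> float:
    """Free acidity as percent oleic acid: V*C*M / (10*m)."""
    if t.m <= 0:
        raise UndefinedRatioError("oil mass must be positive for free acidity")
    return t.V * t.C * t.M / (10.0 * t.m)


def acid_index(t: TitrationRecord) -> float:
    """Acid index, mg KOH per g oil: V*56.1*N / m."""
    if t.m <= 0:
        raise UndefinedRatioError("oil mass must be positive for the acid index")
    return t.V * KOH_MOLAR_MASS * t.N / t.m


def total_polyphenols(a: AbsorbanceRecord) -> float:
    """Total polyphenols (ppm gallic-acid equivalents): 403.68 * A725."""
    if a.A725 < 0:
        raise InvalidInputError(f"negative absorbance A725 = {a.A725}")
    return POLYPHENOL_CALIBRATION * a.A725


def chlorophyll(a: AbsorbanceRecord) -> float:
    """Chlorophyll content (ppm) by the three-wavelength baseline method.

    [A670 - (A630 + A710)/2] / (0.1086 * L).  A noisy baseline can push the
    numerator negative; the result is then floored at 0 with a warning,
    since a pigment content cannot be negative.
    """
    if a.L <= 0:
        raise UndefinedRatioError("cell path length must be positive")
    value = (a.A670 - (a.A630 + a.A710) / 2.0) / (CHLOROPHYLL_COEFF * a.L)
    if value < 0:
        logger.warning(
            "chlorophyll computed negative (%.4g ppm) from baseline noise; floored to 0",
            value,
        )
        return 0.0
    return value


def carotenoid(a: AbsorbanceRecord) -> float:
    """Carotenoid content (ppm): A470 * 25 * 10000 / (2000 * 7.5)."""
    if a.A470 < 0:
        raise InvalidInputError(f"negative absorbance A470 = {a.A470}")
    return a.A470 * CAROTENOID_FACTOR


@dataclass(frozen=True)
class GradeBand:
    """One acidity band: (lower, upper] or [lower, upper) and its label."""

    lower: float
    upper: float
    label: str
    #: whether the upper bound belongs to this band (the lower bound's
    #: membership follows from the previous band's upper_inclusive)
    upper_inclusive: bool = True


#: Default bands: [0, 0.2) refined, [0.2, 1.0] extra virgin,
#: (1.0, 2.0] virgin, (2.0, inf) lampante.
DEFAULT_GRADE_BANDS: tuple[GradeBand, ...] = (
    GradeBand(0.0, 0.2, "refined", upper_inclusive=False),
    GradeBand(0.2, 1.0, "extra virgin", upper_inclusive=True),
    GradeBand(1.0, 2.0, "virgin", upper_inclusive=True),
    GradeBand(2.0, math.inf, "lampante", upper_inclusive=True),
)


def _check_bands(rules: Sequence[GradeBand]) -> None:
    if not rules:
        raise ConfigurationError("no grade bands configured")
    if rules[0].lower != 0.0:
        raise ConfigurationError("grade bands must start at 0")
    for prev, cur in zip(rules, rules[1:]):
        if cur.lower != prev.upper:
            raise ConfigurationError(
                f"grade bands have a gap or overlap between {prev.label!r} "
                f"(upper {prev.upper}) and {cur.label!r} (lower {cur.lower})"
            )
        if cur.upper <= cur.lower:
            raise ConfigurationError(f"empty grade band {cur.label!r}")
    if not math.isinf(rules[-1].upper):
        raise ConfigurationError("grade bands must cover [0, inf)")


def classify_grade(
    acidity: float, rules: Sequence[GradeBand] = DEFAULT_GRADE_BANDS
) -> str:
    """Assign a quality-grade label from free acidity (% oleic acid)."""
    if acidity < 0:
        raise InvalidInputError(f"negative free acidity {acidity}")
    _check_bands(rules)
    for i, band in enumerate(rules):
        # a band owns its lower bound iff the previous band excluded it
        if i == 0 or not rules[i - 1].upper_inclusive:
            lower_ok = acidity >= band.lower
        else:
            lower_ok = acidity > band.lower
        upper_ok = acidity <= band.upper if band.upper_inclusive else acidity < band.upper
        if lower_ok and upper_ok:
            return band.label
    raise ConfigurationError("grade bands do not cover the given acidity")


def quality_from_readings(
    acidity_titration: Optional[TitrationRecord] = None,
    index_titration: Optional[TitrationRecord] = None,
    absorbance: Optional[AbsorbanceRecord] = None,
    grade_bands: Sequence[GradeBand] = DEFAULT_GRADE_BANDS,
) -> QualityIndices:
    """Assemble a :class:`QualityIndices` from whichever raw readings exist."""
    q = QualityIndices()
    if acidity_titration is not None:
        q.free_acidity = free_acidity(acidity_titration)
        q.grade = classify_grade(q.free_acidity, grade_bands)
    if index_titration is not None:
        q.acid_index = acid_index(index_titration)
    if absorbance is not None:
        q.polyphenol = total_polyphenols(absorbance)
        q.chlorophyll = chlorophyll(absorbance)
        q.carotenoid = carotenoid(absorbance)
    return q
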