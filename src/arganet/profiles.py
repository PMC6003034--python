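"""Fatty-acid profiles and derived nutritional indices.

An oil's fatty-acid composition is reported as percent of total FAME
(fatty-acid methyl ester) peak area from gas chromatography.  Four acids
dominate argan oil — palmitic (C16:0) and stearic (C18:0) among the
saturated acids, oleic (C18:1) and linoleic (C18:2) among the unsaturated
ones — and the standard nutritional indices are derived from them:

* total SFA  = palmitic + stearic (plus any declared minor saturated acids)
* total UFA  = oleic + linoleic (plus declared minor unsaturated acids)
* P/S index  = linoleic / total SFA   (polyunsaturated over saturated)
* UFA/SFA    = total UFA / total SFA

Percentages are compositional: a valid profile closes to 100 within a
tolerance.  All arithmetic keeps full floating precision; rounding to the
two decimals conventional in composition tables is left to presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .exceptions import InvalidInputError, UndefinedRatioError, ValidationError

#: acids counted as saturated / unsaturated by default (Table-style four-acid profiles)
DEFAULT_SFA_NAMES: tuple[str, ...] = ("palmitic", "stearic")
DEFAULT_UFA_NAMES: tuple[str, ...] = ("oleic", "linoleic")

#: default closure tolerance, percent of total composition
DEFAULT_CLOSURE_TOL = 1.0


@dataclass(frozen=True)
class FattyAcidProfile:
    """Fatty-acid composition in percent of total FAME peak area."""

    palmitic: float
    stearic: float
    oleic: float
    linoleic: float
    #: additional acids (name -> percent), e.g. arachidic or linolenic traces
    minor: Mapping[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        d = {
            "palmitic": self.palmitic,
            "stearic": self.stearic,
            "oleic": self.oleic,
            "linoleic": self.linoleic,
        }
        d.update(self.minor)
        return d

    def get(self, name: str) -> float:
        d = self.as_dict()
        if name not in d:
            raise KeyError(f"fatty acid {name!r} not present in profile")
        return d[name]

    @property
    def total(self) -> float:
        return sum(self.as_dict().values())

    @property
    def closure_deviation(self) -> float:
        """Signed deviation of the composition sum from 100 percent."""
        return self.total - 100.0


@dataclass(frozen=True)
class DerivedIndices:
    """Nutritional indices derived from a fatty-acid profile (percent / ratios)."""

    total_sfa: float
    total_ufa: float
    ps_index: float
    ufa_sfa_ratio: float


@dataclass(frozen=True)
class YieldRecord:
    """Stage-to-stage extraction yields, percent mass ratios."""

    nut_per_fruit: Optional[float] = None
    kernel_per_nut: Optional[float] = None
    kernel_per_fruit: Optional[float] = None
    oil_per_kernel: Optional[float] = None


@dataclass
class OilSample:
    """One oil sample: metadata, composition and (optionally) quality indices."""

    sample_id: str
    region: str
    extraction: str
    profile: FattyAcidProfile
    quality: Optional["QualityIndices"] = None  # noqa: F821 - see arganet.quality


def normalize_peak_areas(areas: Mapping[str, float]) -> FattyAcidProfile:
    """Convert raw GC peak areas into a percent composition.

    Each percentage is ``100 * area / sum(areas)``, the peak-area rule used
    to quantify FAME chromatograms.  Acids other than the four majors are
    stored in ``minor``.

    Raises
    ------
    InvalidInputError
        if no areas are given, any area is negative, or all areas are zero.
    """
    if not areas:
        raise InvalidInputError("no peak areas given")
    for name, a in areas.items():
        if a < 0:
            raise InvalidInputError(f"negative peak area for {name!r}: {a}")
    total = sum(areas.values())
    if total <= 0:
        raise InvalidInputError("all peak areas are zero")
    percents = {name: 100.0 * a / total for name, a in areas.items()}
    majors = {k: percents.pop(k, 0.0) for k in ("palmitic", "stearic", "oleic", "linoleic")}
    return FattyAcidProfile(minor=percents, **majors)


def validate_profile(
    profile: FattyAcidProfile, tol: float = DEFAULT_CLOSURE_TOL
) -> FattyAcidProfile:
    """Check range and closure constraints; return the profile unchanged.

    Every percentage must lie in [0, 100] and the composition must sum to
    100 +/- ``tol``.  The signed closure deviation is available afterwards as
    ``profile.closure_deviation``.

    Raises
    ------
    ValidationError
        naming the offending acid for a range violation, or reporting the
        sum for a closure violation.
    """
    for name, value in profile.as_dict().items():
        if not (0.0 <= value <= 100.0):
            raise ValidationError(f"fatty acid {name!r} out of range [0, 100]: {value}")
    if abs(profile.closure_deviation) > tol:
        raise ValidationError(
            f"composition sums to {profile.total:.2f}, outside 100 +/- {tol}"
        )
    return profile


def derive_indices(
    profile: FattyAcidProfile,
    sfa_names: Sequence[str] = DEFAULT_SFA_NAMES,
    ufa_names: Sequence[str] = DEFAULT_UFA_NAMES,
) -> DerivedIndices:
    """Compute total SFA/UFA, the P/S index and the UFA/SFA ratio.

    The P/S numerator is the polyunsaturated fraction, here linoleic acid
    (the only polyunsaturated acid in the four-acid profile).

    Raises
    ------
    UndefinedRatioError
        if the total SFA is zero (both ratios undefined).
    """
    total_sfa = sum(profile.get(n) for n in sfa_names)
    total_ufa = sum(profile.get(n) for n in ufa_names)
    if total_sfa == 0:
        raise UndefinedRatioError("total SFA is zero; P/S and UFA/SFA undefined")
    ps_index = profile.get("linoleic") / total_sfa
    return DerivedIndices(
        total_sfa=total_sfa,
        total_ufa=total_ufa,
        ps_index=ps_index,
        ufa_sfa_ratio=total_ufa / total_sfa,
    )


def yield_ratios(masses: Mapping[str, float]) -> YieldRecord:
    """Stage-to-stage extraction yields from masses of fruit, nut, kernel, oil.

    Each available ratio is ``100 * child / parent`` along the chain
    fruit -> nut -> kernel -> oil; ``kernel_per_fruit`` is also the product
    of the two upstream yields over 100 when both are available.

    Raises
    ------
    InvalidInputError for negative masses; UndefinedRatioError when a needed
    denominator is zero.
    """
    for stage, m in masses.items():
        if m < 0:
            raise InvalidInputError(f"negative mass for stage {stage!r}: {m}")

    def ratio(child: str, parent: str) -> Optional[float]:
        if child not in masses or parent not in masses:
            return None
        if masses[parent] == 0:
            raise UndefinedRatioError(f"zero {parent!r} mass; {child}/{parent} undefined")
        return 100.0 * masses[child] / masses[parent]

    rec = YieldRecord(
        nut_per_fruit=ratio("nut", "fruit"),
        kernel_per_nut=ratio("kernel", "nut"),
        kernel_per_fruit=ratio("kernel", "fruit"),
        oil_per_kernel=ratio("oil", "kernel"),
    )
    if (
        rec.kernel_per_fruit is None
        and rec.nut_per_fruit is not None
        and rec.kernel_per_nut is not None
    ):
        rec = replace(rec, kernel_per_fruit=rec.nut_per_fruit * rec.kernel_per_nut / 100.0)
    return rec
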