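"""The published argan-oil study tables, embedded as plain data.

Seven oils spanning Tunisia, Morocco and two Algerian provenances, each
obtained by a named extraction procedure.  ``FATTY_ACIDS`` carries the four
major fatty-acid percentages plus the derived rows *as printed* (two
decimals); the printed derived rows are retained separately because
downstream correlation tables in the source study were computed on the
printed two-decimal values, and one printed cell (P/S for the
Algeria-Tindouf solvent oil, 1.48) differs in the last place from the
value recomputed from the printed acid percentages (1.4851 -> 1.49).

All values are percent of total FAME area (fatty acids), percent oleic
acid (free acidity), or ppm (contents).
"""

from __future__ import annotations

import pandas as pd

from .profiles import FattyAcidProfile, OilSample, validate_profile
from .quality import QualityIndices

#: sample_id, region, extraction, palmitic, stearic, oleic, linoleic,
#: then the printed derived rows: total_sfa, total_ufa, ps_index, ufa_sfa_ratio
FATTY_ACIDS: tuple[tuple, ...] = (
    ("TUN-SOL", "Tunisia", "solvent", 16.13, 7.10, 52.53, 24.24, 23.23, 76.77, 1.04, 3.30),
    ("MAR-CPC", "Morocco", "cold pressing", 14.43, 6.17, 47.17, 32.22, 20.60, 79.39, 1.56, 3.85),
    ("MAR-SOL", "Morocco", "solvent", 12.79, 5.35, 45.53, 34.64, 18.14, 80.17, 1.91, 4.42),
    ("MAR-CPE", "Morocco", "cold pressing", 13.50, 5.50, 47.00, 33.00, 19.00, 80.00, 1.74, 4.21),
    ("ALG-TIN-SOL", "Algeria-Tindouf", "solvent", 13.84, 5.68, 50.30, 28.99, 19.52, 79.29, 1.48, 4.06),
    ("ALG-TIN-CP", "Algeria-Tindouf", "cold pressing", 13.00, 5.20, 44.30, 35.80, 18.20, 80.10, 1.97, 4.40),
    ("ALG-MOS-SOL", "Algeria-Mostaganem", "solvent", 12.28, 4.72, 45.02, 36.80, 17.00, 81.82, 2.16, 4.81),
)

_FA_COLUMNS = (
    "sample_id", "region", "extraction",
    "palmitic", "stearic", "oleic", "linoleic",
    "total_sfa", "total_ufa", "ps_index", "ufa_sfa_ratio",
)

#: physicochemical properties per oil: free acidity (% oleic) and grade;
#: density and refractive index stored as metadata only
PHYSICOCHEMICAL: tuple[tuple, ...] = (
    ("Tunisia", "solvent", 0.841, 1.470, 0.90, "extra virgin"),
    ("Morocco", "cold pressing", 0.890, 1.473, 1.05, "virgin"),
    ("Morocco", "solvent", 0.906, 1.468, 1.30, "virgin"),
    ("Algeria-Tindouf", "solvent", 0.912, 1.465, 0.12, "refined"),
    ("Algeria-Tindouf", "cold pressing", 0.914, None, 0.80, "extra virgin"),
    ("Algeria-Mostaganem", "solvent", 0.918, 1.469, 0.11, "refined"),
)

_PC_COLUMNS = ("region", "extraction", "density", "refractive_index", "free_acidity", "grade")

#: minor-component contents in ppm
CONTENTS: tuple[tuple, ...] = (
    ("Tunisia", "solvent", 55.0, 0.009, 1.8),
    ("Morocco", "mechanical pressing", 10.0, 1.8, 0.86),
    ("Algeria", "cold pressing", 120.0, 1.3, 0.74),
)

_CT_COLUMNS = ("region", "extraction", "polyphenol", "chlorophyll", "carotenoid")

#: stage yields in percent (None where not reported; the mechanically
#: pressed Moroccan oil/kernel yield was published as a 30-50 range)
YIELDS: tuple[tuple, ...] = (
    ("Tunisia", "solvent", 25.0, 10.0, 2.5, 61.3),
    ("Morocco", "solvent", None, None, None, 58.0),
    ("Morocco", "mechanical pressing", 27.0, 10.8, 3.0, None),
    ("Morocco", "hand pressing", None, None, 2.7, 20.0),
    ("Algeria-Tindouf", "solvent", None, None, None, 55.9),
    ("Algeria-Mostaganem", "solvent", None, None, None, 66.5),
)

_YD_COLUMNS = (
    "region", "extraction", "nut_per_fruit", "kernel_per_nut",
    "kernel_per_fruit", "oil_per_kernel",
)

#: Tunisian quality indices beyond acidity: acid index (mg KOH/g)
TUNISIA_ACID_INDEX = 1.85

#: closure tolerance for the published table — three columns sum to
#: 98.30-98.82 because minor acids were left untabulated
STUDY_CLOSURE_TOL = 2.0


def load_fatty_acids() -> pd.DataFrame:
    """The composition table (acids plus printed derived rows) as a DataFrame."""
    return pd.DataFrame(list(FATTY_ACIDS), columns=_FA_COLUMNS)


def load_physicochemical() -> pd.DataFrame:
    return pd.DataFrame(list(PHYSICOCHEMICAL), columns=_PC_COLUMNS)


def load_contents() -> pd.DataFrame:
    return pd.DataFrame(list(CONTENTS), columns=_CT_COLUMNS)


def load_yields() -> pd.DataFrame:
    return pd.DataFrame(list(YIELDS), columns=_YD_COLUMNS)


def study_samples() -> list[OilSample]:
    """The seven study oils as validated :class:`OilSample` objects."""
    samples = []
    grade_by_key = {(r, e): g for r, e, *_rest, g in PHYSICOCHEMICAL}
    fa_by_key = {(r, e): fa for r, e, _d, _ri, fa, _g in PHYSICOCHEMICAL}
    for row in FATTY_ACIDS:
        sid, region, extraction = row[0], row[1], row[2]
        profile = validate_profile(
            FattyAcidProfile(*row[3:7]), tol=STUDY_CLOSURE_TOL
        )
        quality = None
        key = (region, extraction)
        if key in grade_by_key:
            quality = QualityIndices(
                free_acidity=fa_by_key[key], grade=grade_by_key[key]
            )
        samples.append(OilSample(sid, region, extraction, profile, quality))
    return samples
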