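"""Synthetic data with the statistical structure the analysis assumes.

Three generators cover the pipeline's input surface:

* :func:`simulate_sem` — linear-Gaussian structural equation models over a
  known DAG, the ground truth for skeleton-recovery and orientation tests;
* :func:`simulate_oil_table` — cohorts of oil samples grouped by region and
  extraction procedure, with Gaussian trait noise re-closed to 100 %
  (compositions are compositional, so noise is followed by renormalization);
* :func:`absorbance_fixtures` — exact inversions of the quality formulas,
  producing titration/absorbance readings that reproduce target contents.

Every generator takes an explicit integer seed; identical spec + seed gives
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .correlation import DataMatrix
from .exceptions import ConfigurationError, InvalidInputError
from .profiles import FattyAcidProfile, OilSample
from .quality import (
    CAROTENOID_FACTOR,
    CHLOROPHYLL_COEFF,
    KOH_MOLAR_MASS,
    OLEIC_MOLAR_MASS,
    POLYPHENOL_CALIBRATION,
    AbsorbanceRecord,
    TitrationRecord,
)


# ---------------------------------------------------------------------------
# linear-Gaussian SEM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SemSpec:
    """A linear-Gaussian structural equation model over a DAG.

    ``parents`` maps each node to its parent tuple; ``coefficients`` maps
    (parent, child) to the linear weight.  Each node is its parents'
    weighted sum plus N(0, noise_sd) noise, generated in topological order.
    """

    nodes: tuple[str, ...]
    parents: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    coefficients: Mapping[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 1.0
    n: int = 100
    seed: int = 0

    def topological_order(self) -> list[str]:
        order: list[str] = []
        placed: set[str] = set()
        remaining = list(self.nodes)
        while remaining:
            progress = False
            for node in list(remaining):
                if all(p in placed for p in self.parents.get(node, ())):
                    order.append(node)
                    placed.add(node)
                    remaining.remove(node)
                    progress = True
            if not progress:
                raise ConfigurationError(f"parent map contains a cycle among {remaining}")
        return order

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.n < 1:
            raise ConfigurationError("n must be at least 1")
        for child, ps in self.parents.items():
            if child not in self.nodes:
                raise ConfigurationError(f"unknown node {child!r} in parent map")
            for p in ps:
                if p not in self.nodes:
                    raise ConfigurationError(f"unknown parent {p!r} of {child!r}")
        self.topological_order()


def chain_spec(p: int, beta: float, n: int, seed: int, noise_sd: float = 1.0) -> SemSpec:
    """Causal chain x0 -> x1 -> ... -> x{p-1} with a common weight."""
    nodes = tuple(f"x{i}" for i in range(p))
    parents = {nodes[i]: (nodes[i - 1],) for i in range(1, p)}
    coefs = {(nodes[i - 1], nodes[i]): beta for i in range(1, p)}
    return SemSpec(nodes, parents, coefs, noise_sd=noise_sd, n=n, seed=seed)


def fork_spec(k: int, beta: float, n: int, seed: int, noise_sd: float = 1.0) -> SemSpec:
    """Common cause x0 -> x1, ..., x0 -> xk."""
    nodes = tuple(f"x{i}" for i in range(k + 1))
    parents = {nodes[i]: (nodes[0],) for i in range(1, k + 1)}
    coefs = {(nodes[0], nodes[i]): beta for i in range(1, k + 1)}
    return SemSpec(nodes, parents, coefs, noise_sd=noise_sd, n=n, seed=seed)


def simulate_sem(spec: SemSpec) -> DataMatrix:
    """Draw n samples from the SEM, nodes generated in topological order."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    order = spec.topological_order()
    data = {name: None for name in spec.nodes}
    for node in order:
        x = rng.normal(0.0, spec.noise_sd, size=spec.n)
        for parent in spec.parents.get(node, ()):
            x = x + spec.coefficients.get((parent, node), 0.0) * data[parent]
        data[node] = x
    values = np.column_stack([data[name] for name in spec.nodes])
    return DataMatrix(values, spec.nodes)


def sem_implied_covariance(spec: SemSpec) -> np.ndarray:
    """Population covariance (I - B)^{-T} D (I - B)^{-1} implied by the SEM."""
    spec.validate()
    p = len(spec.nodes)
    idx = {name: i for i, name in enumerate(spec.nodes)}
    B = np.zeros((p, p))  # B[i, j] = weight of parent i on child j
    for child, ps in spec.parents.items():
        for parent in ps:
            B[idx[parent], idx[child]] = spec.coefficients.get((parent, child), 0.0)
    A = np.linalg.inv(np.eye(p) - B.T)  # maps noise to observations
    return spec.noise_sd**2 * (A @ A.T)


# ---------------------------------------------------------------------------
# oil cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OilCohortSpec:
    """Group-structured oil cohort: (region, extraction, mean profile) groups."""

    groups: tuple[tuple[str, str, FattyAcidProfile], ...]
    n_per_group: int = 5
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be at least 1")
        for region, extraction, mean in self.groups:
            if abs(mean.total - 100.0) > 1.0:
                raise ConfigurationError(
                    f"group mean for ({region}, {extraction}) does not close to 100"
                )


_MAX_RESAMPLE = 100


def simulate_oil_table(spec: OilCohortSpec) -> list[OilSample]:
    """Per-sample profile = group mean + Gaussian noise, re-closed to 100 %.

    Draws producing a negative percentage are resampled (bounded retries).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    acid_names = ("palmitic", "stearic", "oleic", "linoleic")
    samples: list[OilSample] = []
    for gi, (region, extraction, mean) in enumerate(spec.groups):
        mu = np.array([mean.get(a) for a in acid_names])
        for k in range(spec.n_per_group):
            for attempt in range(_MAX_RESAMPLE):
                vals = mu + rng.normal(0.0, spec.noise_sd, size=len(acid_names))
                if (vals >= 0).all():
                    break
            else:
                raise InvalidInputError(
                    "could not draw a non-negative composition; lower noise_sd"
                )
            vals = 100.0 * vals / vals.sum()
            profile = FattyAcidProfile(**dict(zip(acid_names, vals)))
            samples.append(
                OilSample(
                    sample_id=f"G{gi}-{k:02d}",
                    region=region,
                    extraction=extraction,
                    profile=profile,
                )
            )
    return samples


def default_cohort_spec(seed: int = 0, noise_sd: float = 1.0) -> OilCohortSpec:
    """Test cohort: 3 regions x 2 extraction procedures x 5 replicates (n=30).

    Group means bracket the composition range reported for argan oils
    (palmitic 12-16 %, stearic 5-7 %, oleic 44-53 %, linoleic 24-37 %),
    with region shifting the oleic/linoleic balance and extraction giving a
    small systematic offset.  n=30 > p keeps the unshrunk covariance
    nonsingular for lambda=0 test paths.
    """
    bases = {
        "Tunisia": (16.0, 7.0, 52.5, 24.5),
        "Morocco": (14.0, 6.0, 47.0, 33.0),
        "Algeria": (12.5, 5.0, 45.5, 37.0),
    }
    groups = []
    for region, (pa, st, ol, li) in bases.items():
        for extraction, shift in (("solvent", 0.0), ("cold pressing", 0.8)):
            mean = FattyAcidProfile(
                palmitic=pa - shift / 2,
                stearic=st,
                oleic=ol + shift,
                linoleic=li - shift / 2,
            )
            total = mean.total
            mean = FattyAcidProfile(
                palmitic=100 * mean.palmitic / total,
                stearic=100 * mean.stearic / total,
                oleic=100 * mean.oleic / total,
                linoleic=100 * mean.linoleic / total,
            )
            groups.append((region, extraction, mean))
    return OilCohortSpec(tuple(groups), n_per_group=5, noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# quality-formula inversion fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QualityFixture:
    """Raw readings that reproduce the requested quality targets exactly."""

    absorbance: AbsorbanceRecord
    acidity_titration: TitrationRecord
    index_titration: TitrationRecord


def absorbance_fixtures(
    free_acidity: float = 0.0,
    acid_index: float = 0.0,
    polyphenol: float = 0.0,
    chlorophyll: float = 0.0,
    carotenoid: float = 0.0,
    seed: int = 0,
    C_naoh: float = 0.177,
    m_acidity: float = 5.0,
    N_koh: float = 0.1,
    m_index: float = 1.0,
    L: float = 1.0,
) -> QualityFixture:
    """Invert the quality formulas to obtain generating readings.

    The chlorophyll inversion draws a random (seeded) baseline at 630 and
    710 nm and places A670 so the baseline-corrected difference gives the
    target; all other channels invert deterministically.
    """
    for name, v in (
        ("free_acidity", free_acidity),
        ("acid_index", acid_index),
        ("polyphenol", polyphenol),
        ("chlorophyll", chlorophyll),
        ("carotenoid", carotenoid),
    ):
        if v < 0:
            raise InvalidInputError(f"target {name} must be non-negative, got {v}")
    rng = np.random.default_rng(seed)
    a630, a710 = rng.uniform(0.0, 0.05, size=2)
    a670 = chlorophyll * CHLOROPHYLL_COEFF * L + (a630 + a710) / 2.0
    absorbance = AbsorbanceRecord(
        A630=a630,
        A670=a670,
        A710=a710,
        A470=carotenoid / CAROTENOID_FACTOR,
        A725=polyphenol / POLYPHENOL_CALIBRATION,
        L=L,
    )
    acidity_titration = TitrationRecord(
        V=free_acidity * 10.0 * m_acidity / (C_naoh * OLEIC_MOLAR_MASS),
        C=C_naoh,
        m=m_acidity,
        M=OLEIC_MOLAR_MASS,
    )
    index_titration = TitrationRecord(
        V=acid_index * m_index / (KOH_MOLAR_MASS * N_koh), N=N_koh, m=m_index
    )
    return QualityFixture(absorbance, acidity_titration, index_titration)
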