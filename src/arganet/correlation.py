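"""Variable encoding and Pearson correlation screening.

The study design correlates ten variables per oil: two encoded categorical
descriptors (cultivation region, extraction procedure), the four major
fatty-acid percentages, and the four derived indices.  Categorical labels
enter the correlation as integer codes, so any correlation involving them
depends on the chosen coding — results carry the encoding that produced
them.

Significance uses the exact small-sample t transform
``t = r * sqrt((n-2) / (1-r^2))`` with n-2 degrees of freedom, two-sided,
without multiple-testing correction by default (a Benjamini-Hochberg
adjustment is available but off by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import profiles
from .exceptions import EncodingError, InsufficientDataError
from .profiles import OilSample

#: canonical order of the ten analysis variables
DEFAULT_VARIABLES: tuple[str, ...] = (
    "region",
    "extraction",
    "palmitic",
    "stearic",
    "oleic",
    "linoleic",
    "total_sfa",
    "total_ufa",
    "ps_index",
    "ufa_sfa_ratio",
)

DEFAULT_REGION_CODES: dict[str, int] = {
    "Tunisia": 1,
    "Morocco": 2,
    "Algeria": 3,
    "Algeria-Tindouf": 3,
    "Algeria-Mostaganem": 3,
}

DEFAULT_EXTRACTION_CODES: dict[str, int] = {
    "solvent": 1,
    "mechanical pressing": 2,
    "cold pressing": 3,
    "hand pressing": 3,
}


@dataclass(frozen=True)
class VariableEncoding:
    """Ordered variable list plus label -> code maps for the categoricals."""

    variables: tuple[str, ...] = DEFAULT_VARIABLES
    region_codes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_REGION_CODES))
    extraction_codes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_EXTRACTION_CODES)
    )

    def code(self, kind: str, label: str) -> float:
        table = self.region_codes if kind == "region" else self.extraction_codes
        if label not in table:
            raise EncodingError(f"no {kind} code declared for label {label!r}")
        return float(table[label])


@dataclass(frozen=True)
class DataMatrix:
    """Samples-by-variables numeric matrix with named columns."""

    values: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] != len(self.columns):
            raise ValueError("values must be 2-D with one column per variable name")
        if np.isnan(v).any():
            raise ValueError("DataMatrix must not contain missing values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DataMatrix":
        return cls(df.to_numpy(dtype=float), tuple(map(str, df.columns)))


@dataclass
class CorrelationResult:
    """Pearson r and two-sided p matrices with significance flags."""

    r: pd.DataFrame
    pval: pd.DataFrame
    n: int
    #: alpha -> boolean DataFrame of significant pairs
    sig: dict[float, pd.DataFrame]
    encoding: Optional[VariableEncoding] = None
    dropped: tuple[str, ...] = ()

    def tidy(self) -> pd.DataFrame:
        """Flat (var1, var2, r, p, sig_*) table over the upper triangle."""
        cols = list(self.r.columns)
        rows = []
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                row = {"var1": a, "var2": b, "r": self.r.loc[a, b], "p": self.pval.loc[a, b]}
                for alpha, flags in self.sig.items():
                    row[f"sig_{alpha}"] = bool(flags.loc[a, b])
                rows.append(row)
        return pd.DataFrame(rows)

    def to_table(self) -> pd.DataFrame:
        """Lower-triangular presentation with r and p interleaved row-wise."""
        cols = list(self.r.columns)
        out = {}
        for i, a in enumerate(cols):
            r_row, p_row = [], []
            for j, b in enumerate(cols):
                if j < i:
                    r_row.append(round(float(self.r.loc[a, b]), 3))
                    p_row.append(round(float(self.pval.loc[a, b]), 3))
                elif j == i:
                    r_row.append(1.0)
                    p_row.append(np.nan)
                else:
                    r_row.append(np.nan)
                    p_row.append(np.nan)
            out[f"{a} r"] = r_row
            out[f"{a} p"] = p_row
        return pd.DataFrame(out, index=cols).T


def encode_dataset(
    samples: Sequence[OilSample],
    enc: VariableEncoding | None = None,
    indices: Optional[Sequence[profiles.DerivedIndices]] = None,
) -> DataMatrix:
    """Build the samples-by-variables matrix from oil samples.

    Derived indices are computed from each sample's profile when not
    supplied.  Categorical labels are mapped through the encoding's coding
    maps; an unseen label raises :class:`EncodingError`.
    """
    if not samples:
        raise InsufficientDataError("no samples to encode")
    enc = enc or VariableEncoding()
    if indices is None:
        indices = [profiles.derive_indices(s.profile) for s in samples]
    rows = []
    for s, idx in zip(samples, indices):
        vals = {
            "region": enc.code("region", s.region),
            "extraction": enc.code("extraction", s.extraction),
            "palmitic": s.profile.palmitic,
            "stearic": s.profile.stearic,
            "oleic": s.profile.oleic,
            "linoleic": s.profile.linoleic,
            "total_sfa": idx.total_sfa,
            "total_ufa": idx.total_ufa,
            "ps_index": idx.ps_index,
            "ufa_sfa_ratio": idx.ufa_sfa_ratio,
        }
        rows.append([vals[v] for v in enc.variables])
    return DataMatrix(np.array(rows, dtype=float), tuple(enc.variables))


def pearson_r_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p from the t transform with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 observations, got {n}")
    xd = x - x.mean()
    yd = y - y.mean()
    r = float(xd @ yd / np.sqrt((xd @ xd) * (yd @ yd)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def pearson_with_pvalues(
    X: DataMatrix,
    alpha_levels: Iterable[float] = (0.05, 0.01),
    adjust: Optional[str] = None,
) -> CorrelationResult:
    """All-pairs Pearson correlation with two-sided p-values.

    Zero-variance columns are excluded with a warning (their correlation is
    undefined).  ``adjust="bh"`` applies a Benjamini-Hochberg correction to
    the upper-triangle p-values before flagging significance.
    """
    if X.n < 3:
        raise InsufficientDataError(f"need at least 3 samples, got {X.n}")
    keep, dropped = [], []
    for name in X.columns:
        col = X.column(name)
        if np.std(col) <= 1e-12 * max(1.0, abs(col.mean())):
            dropped.append(name)
        else:
            keep.append(name)
    if dropped:
        warnings.warn(
            f"zero-variance column(s) excluded from correlation: {dropped}",
            stacklevel=2,
        )
    cols = keep
    k = len(cols)
    r = np.eye(k)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            rij, pij = pearson_r_pvalue(X.column(cols[i]), X.column(cols[j]))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    if adjust == "bh":
        iu = np.triu_indices(k, 1)
        adj = stats.false_discovery_control(p[iu], method="bh")
        p[iu] = adj
        p[(iu[1], iu[0])] = adj
    elif adjust is not None:
        raise ValueError(f"unknown p-value adjustment {adjust!r}")
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    sig = {float(a): (pdf < a) for a in alpha_levels}
    return CorrelationResult(r=rdf, pval=pdf, n=X.n, sig=sig, dropped=tuple(dropped))
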