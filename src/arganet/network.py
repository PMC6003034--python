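"""Partial-correlation network construction with a variance-ordering
orientation heuristic.

The model treats the encoded sample table as draws from a multivariate
Gaussian.  Because the study regime has fewer samples than variables
(n = 7 oils, p = 10 variables), the sample correlation matrix is singular;
the covariance is therefore shrunk toward the identity on the standardized
scale,

    Sigma(lambda) = (1 - lambda) * S + lambda * I,

with the shrinkage intensity chosen analytically from the estimated
variances of the off-diagonal correlations (Schafer-Strimmer form)

    lambda* = sum_{i<j} Var-hat(r_ij) / sum_{i<j} r_ij^2,   clipped to [0, 1].

The precision matrix Omega = Sigma(lambda)^{-1} then always exists, and

* partial correlations  rho_ij = -omega_ij / sqrt(omega_ii * omega_jj)
  define the undirected skeleton: pairs with |rho_ij| >= tau are joined;
* each node's standardized partial variance g_k = sigma_kk / omega_kk
  (on the standardized scale sigma_kk = 1, so g_k = 1 / omega_kk, the
  unexplained share of the node's variance given all others) defines the
  orientation score.  For an edge (i, j) the ratio

      B_ij = g_i / g_j = omega_jj * sigma_ii / (omega_ii * sigma_jj)

  orients the edge i -> j when B_ij > 1, j -> i when B_ij < 1, and leaves
  it undirected when B_ij = 1 (within a tie tolerance).  A node high in
  this ordering is "exogenous": little of its variance is explained by
  the rest of the system, so arcs flow from it toward better-explained
  nodes.  Because orientation follows a single total preorder over nodes,
  the directed subgraph can never contain a cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import DataMatrix, VariableEncoding, encode_dataset
from .exceptions import ConfigurationError, InsufficientDataError, ValidationError

DEFAULT_TAU = 0.3
DEFAULT_TIE_EPS = 1e-9


# ---------------------------------------------------------------------------
# stage functions
# ---------------------------------------------------------------------------

def standardize(X: DataMatrix) -> DataMatrix:
    """Center each column to mean 0 and scale to unit sd (denominator n-1)."""
    V = X.values
    mu = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    for name, m, s in zip(X.columns, mu, sd):
        # relative threshold: a column of identical values has sd ~ eps*|mean|
        if not np.isfinite(s) or s <= 1e-12 * max(1.0, abs(m)):
            raise ValidationError(f"column {name!r} has zero variance; cannot standardize")
    return DataMatrix((V - mu) / sd, X.columns)


@dataclass(frozen=True)
class PrecisionEstimate:
    """Shrunk covariance and its inverse on the standardized scale."""

    sigma: np.ndarray  #: sample correlation matrix S (before shrinkage)
    sigma_shrunk: np.ndarray  #: (1-lambda) S + lambda I
    omega: np.ndarray  #: inverse of sigma_shrunk
    sigma_diag: np.ndarray  #: per-variable variances on the working scale
    shrinkage: float  #: lambda in [0, 1]
    n: int
    p: int
    columns: tuple[str, ...] = ()


def shrinkage_intensity(Z: DataMatrix) -> float:
    """Analytic shrinkage intensity toward the identity correlation target.

    lambda* = sum_{i != j} Var-hat(r_ij) / sum_{i != j} r_ij^2 where the
    variance of each empirical correlation is estimated from the spread of
    its per-sample products w_kij = z_ki * z_kj:

        Var-hat(r_ij) = n / (n-1)^3 * sum_k (w_kij - mean_k w_kij)^2
    """
    V = Z.values
    n, p = V.shape
    if n < 3:
        raise InsufficientDataError(f"need at least 3 samples, got {n}")
    W = V[:, :, None] * V[:, None, :]  # n x p x p per-sample products
    wbar = W.mean(axis=0)
    r = n / (n - 1.0) * wbar
    var_r = n / (n - 1.0) ** 3 * ((W - wbar) ** 2).sum(axis=0)
    off = ~np.eye(p, dtype=bool)
    denom = (r[off] ** 2).sum()
    if denom == 0:
        return 1.0
    lam = var_r[off].sum() / denom
    return float(min(1.0, max(0.0, lam)))


def estimate_precision(
    Z: DataMatrix, shrinkage: Optional[float] = None
) -> PrecisionEstimate:
    """Invert the shrunk covariance of standardized data.

    With ``shrinkage=None`` the analytic intensity is used; an explicit
    value must lie in [0, 1] (0 = raw sample covariance, valid only when
    it is nonsingular; 1 = identity).
    """
    n, p = Z.n, Z.p
    if n < 3:
        raise InsufficientDataError(f"need at least 3 samples, got {n}")
    if shrinkage is None:
        lam = shrinkage_intensity(Z)
    else:
        lam = float(shrinkage)
        if not (0.0 <= lam <= 1.0):
            raise ConfigurationError(f"shrinkage must be in [0, 1], got {lam}")
    S = Z.values.T @ Z.values / (n - 1)
    sigma_shrunk = (1.0 - lam) * S + lam * np.eye(p)
    omega = np.linalg.inv(sigma_shrunk)
    omega = (omega + omega.T) / 2.0  # symmetrize against round-off
    return PrecisionEstimate(
        sigma=S,
        sigma_shrunk=sigma_shrunk,
        omega=omega,
        sigma_diag=np.diag(sigma_shrunk).copy(),
        shrinkage=lam,
        n=n,
        p=p,
        columns=Z.columns,
    )


def partial_correlation_matrix(pe: PrecisionEstimate) -> np.ndarray:
    """rho_ij = -omega_ij / sqrt(omega_ii * omega_jj), unit diagonal."""
    d = np.diag(pe.omega)
    if np.any(d <= 0):
        raise np.linalg.LinAlgError("precision matrix is not positive definite")
    scale = np.sqrt(np.outer(d, d))
    rho = -pe.omega / scale
    np.fill_diagonal(rho, 1.0)
    return rho


def select_edges(
    pcorr: np.ndarray, tau: float = DEFAULT_TAU
) -> list[tuple[int, int, float]]:
    """Undirected skeleton: pairs (i < j) with |rho_ij| >= tau."""
    if not (0.0 <= tau <= 1.0):
        raise ConfigurationError(f"tau must be in [0, 1], got {tau}")
    p = pcorr.shape[0]
    return [
        (i, j, float(pcorr[i, j]))
        for i in range(p)
        for j in range(i + 1, p)
        if abs(pcorr[i, j]) >= tau
    ]


def node_order_scores(pe: PrecisionEstimate) -> np.ndarray:
    """Orientation scores g_k = sigma_kk / omega_kk.

    On the standardized scale sigma_kk = 1 so g_k is the standardized
    partial variance 1 / omega_kk: the fraction of node k's variance left
    unexplained by all other nodes.  B_ij = g_i / g_j.
    """
    return pe.sigma_diag / np.diag(pe.omega)


def b_matrix(g: np.ndarray) -> np.ndarray:
    """Pairwise orientation ratios B_ij = g_i / g_j (so B_ij * B_ji = 1)."""
    g = np.asarray(g, dtype=float)
    return np.outer(g, 1.0 / g)


@dataclass
class Network:
    """Oriented partial-correlation network.

    Every skeleton edge appears exactly once: as a directed arc (u, v)
    when B_uv > 1 beyond the tie tolerance, otherwise as an undirected
    edge.  The directed subgraph is acyclic by construction (orientation
    follows the total preorder of the node scores).
    """

    nodes: tuple[str, ...]
    #: (u, v, rho) pairs left undirected (orientation tie)
    undirected_edges: list[tuple[str, str, float]] = field(default_factory=list)
    #: (u, v, rho, B_uv) arcs oriented u -> v
    directed_arcs: list[tuple[str, str, float, float]] = field(default_factory=list)
    #: node -> standardized partial variance g
    node_scores: dict[str, float] = field(default_factory=dict)
    tau: float = DEFAULT_TAU
    tie_eps: float = DEFAULT_TIE_EPS

    def to_digraph(self) -> nx.DiGraph:
        """Directed arcs only, for acyclicity checks and DAG algorithms."""
        G = nx.DiGraph()
        G.add_nodes_from(self.nodes)
        for u, v, rho, b in self.directed_arcs:
            G.add_edge(u, v, rho=rho, B=b)
        return G

    def to_networkx(self) -> nx.DiGraph:
        """Full network; undirected ties carry ``directed=False``."""
        G = self.to_digraph()
        for u, v, _, _ in self.directed_arcs:
            G[u][v]["directed"] = True
        for u, v, rho in self.undirected_edges:
            G.add_edge(u, v, rho=rho, directed=False)
        return G

    @property
    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_digraph())


def orient_edges(
    edges: Sequence[tuple[int, int, float]],
    g: np.ndarray,
    nodes: Sequence[str],
    tau: float = DEFAULT_TAU,
    tie_eps: float = DEFAULT_TIE_EPS,
) -> Network:
    """Orient each skeleton edge by the score ratio B_ij = g_i / g_j."""
    net = Network(nodes=tuple(nodes), tau=tau, tie_eps=tie_eps,
                  node_scores={nodes[k]: float(g[k]) for k in range(len(nodes))})
    for i, j, rho in edges:
        b = float(g[i] / g[j])
        if abs(b - 1.0) <= tie_eps:
            net.undirected_edges.append((nodes[i], nodes[j], rho))
        elif b > 1.0:
            net.directed_arcs.append((nodes[i], nodes[j], rho, b))
        else:
            net.directed_arcs.append((nodes[j], nodes[i], rho, 1.0 / b))
    assert net.is_acyclic, "orientation by a total preorder produced a cycle"
    return net


def build_network(
    X: DataMatrix,
    shrinkage: Optional[float] = None,
    tau: float = DEFAULT_TAU,
    tie_eps: float = DEFAULT_TIE_EPS,
) -> "NetworkResults":
    """Run the full pipeline standardize -> precision -> pcorr -> skeleton
    -> orientation and return the results object with all intermediates."""
    return PartialCorrelationNetwork(X).fit(shrinkage=shrinkage, tau=tau, tie_eps=tie_eps)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class PartialCorrelationNetwork:
    """Gaussian partial-correlation network model for a sample table.

    Parameters
    ----------
    data : DataMatrix, pandas.DataFrame or (n, p) array
        Numeric samples-by-variables observations.
    columns : sequence of str, optional
        Variable names when ``data`` is a bare array.

    Examples
    --------
    >>> model = PartialCorrelationNetwork(df)
    >>> res = model.fit(tau=0.3)
    >>> print(res.summary())
    """

    def __init__(self, data, columns: Optional[Sequence[str]] = None):
        if isinstance(data, DataMatrix):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = DataMatrix.from_dataframe(data)
        else:
            arr = np.asarray(data, dtype=float)
            names = tuple(columns) if columns else tuple(f"x{i}" for i in range(arr.shape[1]))
            self.data = DataMatrix(arr, names)

    @classmethod
    def from_samples(cls, samples, encoding: Optional[VariableEncoding] = None):
        """Build the model from a list of :class:`~arganet.profiles.OilSample`."""
        return cls(encode_dataset(samples, enc=encoding))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, columns: Optional[Sequence[str]] = None):
        if columns is not None:
            df = df[list(columns)]
        return cls(df)

    def fit(
        self,
        shrinkage: Optional[float] = None,
        tau: float = DEFAULT_TAU,
        tie_eps: float = DEFAULT_TIE_EPS,
        standardize_data: bool = True,
    ) -> "NetworkResults":
        """Estimate the shrunk precision matrix and assemble the network.

        ``standardize_data=False`` applies the orientation test in its
        literal raw-scale form B_ij = omega_jj sigma_ii / (omega_ii
        sigma_jj) on the unstandardized covariance; the default
        standardizes first, which makes the two readings of the test
        coincide.
        """
        X = self.data
        if standardize_data:
            Z = standardize(X)
            pe = estimate_precision(Z, shrinkage=shrinkage)
        else:
            n, p = X.n, X.p
            V = X.values - X.values.mean(axis=0)
            S = V.T @ V / (n - 1)
            lam = shrinkage_intensity(standardize(X)) if shrinkage is None else float(shrinkage)
            if not (0.0 <= lam <= 1.0):
                raise ConfigurationError(f"shrinkage must be in [0, 1], got {lam}")
            target = np.diag(np.diag(S))
            sigma_shrunk = (1.0 - lam) * S + lam * target
            omega = np.linalg.inv(sigma_shrunk)
            omega = (omega + omega.T) / 2.0
            pe = PrecisionEstimate(
                sigma=S, sigma_shrunk=sigma_shrunk, omega=omega,
                sigma_diag=np.diag(sigma_shrunk).copy(), shrinkage=lam,
                n=n, p=p, columns=X.columns,
            )
        pcorr = partial_correlation_matrix(pe)
        edges = select_edges(pcorr, tau=tau)
        g = node_order_scores(pe)
        net = orient_edges(edges, g, X.columns, tau=tau, tie_eps=tie_eps)
        return NetworkResults(model=self, precision=pe, pcorr=pcorr, network=net)


class NetworkResults:
    """Fitted partial-correlation network with all intermediate estimates.

    Attributes
    ----------
    precision : PrecisionEstimate
    pcorr : (p, p) ndarray of partial correlations
    network : Network
    """

    def __init__(self, model, precision: PrecisionEstimate, pcorr: np.ndarray, network: Network):
        self.model = model
        self.precision = precision
        self.pcorr = pcorr
        self.network = network

    @property
    def columns(self) -> tuple[str, ...]:
        return self.model.data.columns

    @property
    def shrinkage(self) -> float:
        return self.precision.shrinkage

    @property
    def node_scores(self) -> dict[str, float]:
        return self.network.node_scores

    @property
    def arcs(self) -> list[tuple[str, str, float, float]]:
        return self.network.directed_arcs

    @property
    def undirected(self) -> list[tuple[str, str, float]]:
        return self.network.undirected_edges

    def pcorr_frame(self) -> pd.DataFrame:
        cols = list(self.columns)
        return pd.DataFrame(self.pcorr, index=cols, columns=cols)

    def b_matrix(self) -> pd.DataFrame:
        g = np.array([self.node_scores[c] for c in self.columns])
        cols = list(self.columns)
        return pd.DataFrame(b_matrix(g), index=cols, columns=cols)

    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        net = self.network
        lines = [
            "Partial-correlation network",
            "=" * 64,
            f"Observations:        {self.precision.n}",
            f"Variables:           {self.precision.p}",
            f"Shrinkage lambda:    {self.shrinkage:.4f}",
            f"Edge threshold tau:  {net.tau}",
            f"Arcs / undirected:   {len(net.directed_arcs)} / {len(net.undirected_edges)}",
            f"Acyclic:             {net.is_acyclic}",
            "-" * 64,
            f"{'arc':<38}{'rho':>10}{'B':>12}",
        ]
        for u, v, rho, b in sorted(net.directed_arcs, key=lambda e: -abs(e[2])):
            lines.append(f"{u + ' -> ' + v:<38}{rho:>10.3f}{b:>12.3f}")
        for u, v, rho in net.undirected_edges:
            lines.append(f"{u + ' -- ' + v:<38}{rho:>10.3f}{'tie':>12}")
        lines.append("-" * 64)
        lines.append("node scores g (standardized partial variance):")
        for name in sorted(self.node_scores, key=self.node_scores.get, reverse=True):
            lines.append(f"  {name:<24}{self.node_scores[name]:>10.4f}")
        return "\n".join(lines)
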