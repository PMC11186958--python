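"""Graph representation, ERGM summary statistics and network metrics.

Graphs are undirected, binary, on a fixed labelled node set (0-based).
Statistics are defined by a :class:`StatisticSpec`, an ordered list of
terms that fixes the coordinate order of the ERGM parameter vector.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "Graph",
    "StatisticSpec",
    "Term",
    "MetricDistributions",
    "count_edges",
    "count_nodematch",
    "count_homotopy",
    "esp_counts",
    "gwesp",
    "summary_stats",
    "change_stats",
    "metric_distributions",
]

# term kinds understood by the statistic machinery
EDGES = "edges"
NODEMATCH = "nodematch"
NODEMATCH_HOMOTOPY = "nodematch_homotopy"
GWESP = "gwesp"


@dataclass(frozen=True)
class Term:
    """A single summary-statistic descriptor.

    kind is one of ``edges``, ``nodematch``, ``nodematch_homotopy``,
    ``gwesp``; ``attribute`` names the node attribute for nodematch
    terms, ``tau`` is the (fixed) decay of a gwesp term.
    """

    kind: str
    attribute: str | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (EDGES, NODEMATCH, NODEMATCH_HOMOTOPY, GWESP):
            raise ValueError(f"unknown statistic term kind: {self.kind!r}")
        if self.kind == NODEMATCH and not self.attribute:
            raise ValueError("nodematch term requires an attribute name")
        if self.kind == GWESP:
            if self.tau is None or not self.tau > 0:
                raise ValueError("gwesp term requires decay tau > 0")

    def label(self) -> str:
        if self.kind == NODEMATCH:
            return f"nodematch.{self.attribute}"
        if self.kind == GWESP:
            return f"gwesp.fixed.{self.tau:g}"
        if self.kind == NODEMATCH_HOMOTOPY:
            return "nodematch.homotopy"
        return "edges"


_TERM_RE = re.compile(r"^(\w+)(?:\(([^)]*)\))?$")


@dataclass(frozen=True)
class StatisticSpec:
    """Ordered collection of summary-statistic terms.

    The order of ``terms`` defines the coordinate order of every
    parameter vector theta used with this spec; it must not change over
    the lifetime of a model. The natural-parameter map is the identity
    (models linear in theta only).
    """

    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        if len(self.terms) < 1:
            raise ValueError("a StatisticSpec needs at least one term")

    @property
    def p(self) -> int:
        return len(self.terms)

    @property
    def labels(self) -> list[str]:
        return [t.label() for t in self.terms]

    @classmethod
    def from_strings(cls, items: list[str] | tuple[str, ...]) -> "StatisticSpec":
        """Parse terms like ``edges``, ``nodematch(hemisphere)``,
        ``nodematch_homotopy``, ``gwesp(0.9)``."""
        terms = []
        for item in items:
            m = _TERM_RE.match(item.strip())
            if m is None:
                raise ValueError(f"cannot parse statistic term {item!r}")
            kind, arg = m.group(1), m.group(2)
            if kind == EDGES:
                terms.append(Term(EDGES))
            elif kind == NODEMATCH:
                terms.append(Term(NODEMATCH, attribute=arg or "hemisphere"))
            elif kind == NODEMATCH_HOMOTOPY:
                terms.append(Term(NODEMATCH_HOMOTOPY))
            elif kind == GWESP:
                terms.append(Term(GWESP, tau=float(arg)))
            else:
                raise ValueError(f"unknown statistic term {item!r}")
        return cls(tuple(terms))

    def to_strings(self) -> list[str]:
        out = []
        for t in self.terms:
            if t.kind == NODEMATCH:
                out.append(f"nodematch({t.attribute})")
            elif t.kind == GWESP:
                out.append(f"gwesp({t.tau:g})")
            else:
                out.append(t.kind)
        return out


class Graph:
    """Undirected binary graph on N labelled nodes with node attributes.

    Parameters
    ----------
    adjacency
        Symmetric N x N 0/1 matrix with zero diagonal.
    hemisphere
        Optional per-node categorical labels (length N).
    homotopy_partner
        Optional per-node index of the mirrored node; must be a
        fixed-point-free involution (partner[partner[i]] == i,
        partner[i] != i). Use -1 for "no partner" entries only if the
        whole array is absent semantics are not needed.
    """

    __slots__ = ("adjacency", "hemisphere", "homotopy_partner")

    def __init__(
        self,
        adjacency: np.ndarray,
        hemisphere: np.ndarray | list | None = None,
        homotopy_partner: np.ndarray | list | None = None,
        *,
        validate: bool = True,
    ):
        A = np.asarray(adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        A = A.astype(np.int8, copy=True)
        if validate:
            if not np.array_equal(A, A.T):
                raise ValueError("adjacency must be symmetric")
            if np.any(np.diag(A) != 0):
                raise ValueError("adjacency diagonal must be zero")
            if not np.isin(A, (0, 1)).all():
                raise ValueError("adjacency entries must be 0 or 1")
        self.adjacency = A
        n = A.shape[0]
        if hemisphere is not None:
            hemisphere = np.asarray(hemisphere)
            if hemisphere.shape != (n,):
                raise ValueError("hemisphere must have one label per node")
        self.hemisphere = hemisphere
        if homotopy_partner is not None:
            partner = np.asarray(homotopy_partner, dtype=np.int64)
            if partner.shape != (n,):
                raise ValueError("homotopy_partner must have one entry per node")
            if validate:
                idx = np.arange(n)
                if np.any(partner == idx):
                    raise ValueError("homotopy_partner must be fixed-point free")
                if np.any((partner < 0) | (partner >= n)):
                    raise ValueError("homotopy_partner indices out of range")
                if np.any(partner[partner] != idx):
                    raise ValueError("homotopy_partner must be an involution")
            homotopy_partner = partner
        self.homotopy_partner = homotopy_partner

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        return count_edges(self) / (n * (n - 1) / 2)

    def copy(self) -> "Graph":
        return Graph(
            self.adjacency.copy(),
            None if self.hemisphere is None else self.hemisphere.copy(),
            None if self.homotopy_partner is None else self.homotopy_partner.copy(),
            validate=False,
        )

    def with_adjacency(self, adjacency: np.ndarray, *, validate: bool = False) -> "Graph":
        """A graph sharing this one's node attributes but new edges."""
        return Graph(adjacency, self.hemisphere, self.homotopy_partner, validate=validate)

    @classmethod
    def empty(
        cls,
        n_nodes: int,
        hemisphere: np.ndarray | list | None = None,
        homotopy_partner: np.ndarray | list | None = None,
    ) -> "Graph":
        return cls(np.zeros((n_nodes, n_nodes), dtype=np.int8), hemisphere, homotopy_partner)

    @classmethod
    def complete(cls, n_nodes: int, **kw) -> "Graph":
        A = np.ones((n_nodes, n_nodes), dtype=np.int8)
        np.fill_diagonal(A, 0)
        return cls(A, **kw)

    @classmethod
    def from_edges(
        cls,
        n_nodes: int,
        edges: list[tuple[int, int]],
        hemisphere=None,
        homotopy_partner=None,
    ) -> "Graph":
        A = np.zeros((n_nodes, n_nodes), dtype=np.int8)
        for i, j in edges:
            if i == j:
                raise ValueError("self-loops are not allowed")
            A[i, j] = A[j, i] = 1
        return cls(A, hemisphere, homotopy_partner)

    def edge_list(self) -> list[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(iu.tolist(), ju.tolist()))

    def __eq__(self, other) -> bool:  # attribute-blind edge equality
        return isinstance(other, Graph) and np.array_equal(self.adjacency, other.adjacency)

    def __repr__(self) -> str:
        return f"Graph(n_nodes={self.n_nodes}, n_edges={count_edges(self)})"


@dataclass
class MetricDistributions:
    """Degree / geodesic / edgewise-shared-partner count distributions.

    ``degree[d]`` counts nodes of degree d (d = 0..N-1); ``geodesic[l]``
    counts node pairs at shortest-path distance l (l = 1..N-1) with
    unreachable pairs in ``geodesic_inf``; ``esp[w]`` counts edges whose
    endpoints share exactly w partners (w = 0..N-2).
    """

    degree: np.ndarray
    geodesic: np.ndarray
    geodesic_inf: int
    esp: np.ndarray


def _require_attribute(g: Graph, attribute: str) -> np.ndarray:
    if attribute != "hemisphere":
        raise ValueError(f"unknown node attribute {attribute!r}")
    if g.hemisphere is None:
        raise ValueError("graph has no hemisphere labels")
    return g.hemisphere


def count_edges(g: Graph) -> int:
    """Number of unordered connected dyads."""
    return int(g.adjacency.sum()) // 2


def count_nodematch(g: Graph, attribute: str = "hemisphere") -> int:
    """Number of edges whose endpoints share the given attribute value."""
    labels = _require_attribute(g, attribute)
    same = labels[:, None] == labels[None, :]
    return int((g.adjacency * same).sum()) // 2


def count_homotopy(g: Graph) -> int:
    """Number of edges joining homotopic (mirror-partner) node pairs."""
    if g.homotopy_partner is None:
        raise ValueError("graph has no homotopy partner map")
    idx = np.arange(g.n_nodes)
    return int(g.adjacency[idx, g.homotopy_partner].sum()) // 2


def esp_counts(g: Graph) -> np.ndarray:
    """Edgewise shared-partner counts EP_w for w = 0..N-2.

    EP_w is the number of connected node pairs with exactly w common
    neighbours; the counts sum to the number of edges.
    """
    A = g.adjacency.astype(np.int64)
    n = g.n_nodes
    counts = np.zeros(max(n - 1, 1), dtype=np.int64)
    if n < 2:
        return counts
    common = A @ A
    iu, ju = np.nonzero(np.triu(A, k=1))
    w = common[iu, ju]
    np.add.at(counts, w, 1)
    return counts


def gwesp(g: Graph, tau: float) -> float:
    """Geometrically weighted edgewise shared-partner statistic.

    e^tau * sum_{w>=1} {1 - (1 - e^-tau)^w} EP_w ; the w-sum is
    truncated at w = N-2, the maximum attainable shared-partner count.
    """
    if not tau > 0:
        raise ValueError("gwesp decay tau must be > 0")
    ep = esp_counts(g)
    # e^tau (1 - b^w) with b = 1 - e^-tau equals sum_{j<w} b^j, which is
    # exact at w = 1 (weight 1.0) where the direct form loses an ulp
    b = 1.0 - np.exp(-tau)
    weights = np.concatenate([[0.0], np.cumsum(b ** np.arange(len(ep) - 1))])
    return float(weights @ ep)


def _term_value(g: Graph, term: Term) -> float:
    if term.kind == EDGES:
        return float(count_edges(g))
    if term.kind == NODEMATCH:
        return float(count_nodematch(g, term.attribute))
    if term.kind == NODEMATCH_HOMOTOPY:
        return float(count_homotopy(g))
    return gwesp(g, term.tau)


def summary_stats(g: Graph, spec: StatisticSpec) -> np.ndarray:
    """The p-vector s(y) in the spec's term order."""
    return np.array([_term_value(g, t) for t in spec.terms], dtype=np.float64)


def change_stats(g: Graph, dyad: tuple[int, int], spec: StatisticSpec) -> np.ndarray:
    """Change statistics for toggling a dyad.

    Returns s(y with dyad present) - s(y with dyad absent), independent
    of the dyad's current state in ``g``.
    """
    i, j = dyad
    if i == j:
        raise ValueError("change statistics are undefined for self-pairs")
    A = g.adjacency
    out = np.empty(spec.p, dtype=np.float64)
    # shared-partner structure is evaluated with the dyad absent
    had_edge = A[i, j] == 1
    if had_edge:
        A[i, j] = A[j, i] = 0
    try:
        for m, term in enumerate(spec.terms):
            if term.kind == EDGES:
                out[m] = 1.0
            elif term.kind == NODEMATCH:
                labels = _require_attribute(g, term.attribute)
                out[m] = 1.0 if labels[i] == labels[j] else 0.0
            elif term.kind == NODEMATCH_HOMOTOPY:
                if g.homotopy_partner is None:
                    raise ValueError("graph has no homotopy partner map")
                out[m] = 1.0 if g.homotopy_partner[i] == j else 0.0
            else:
                b = 1.0 - np.exp(-term.tau)
                common = np.nonzero((A[i] == 1) & (A[j] == 1))[0]
                delta = np.exp(term.tau) * (1.0 - b ** len(common))
                for k in common:
                    sp_ik = int(((A[i] == 1) & (A[k] == 1)).sum())
                    sp_jk = int(((A[j] == 1) & (A[k] == 1)).sum())
                    # f(w+1) - f(w) with f(w) = e^tau (1 - b^w) simplifies to b^w
                    delta += b ** sp_ik + b ** sp_jk
                out[m] = delta
    finally:
        if had_edge:
            A[i, j] = A[j, i] = 1
    return out


def metric_distributions(g: Graph) -> MetricDistributions:
    """Degree, geodesic-distance and shared-partner distributions."""
    n = g.n_nodes
    deg = np.zeros(n, dtype=np.int64)
    np.add.at(deg, g.degrees(), 1)

    dist = shortest_path(g.adjacency, method="D", unweighted=True, directed=False)
    iu = np.triu_indices(n, k=1)
    pair_d = dist[iu]
    finite = np.isfinite(pair_d)
    geo = np.zeros(max(n, 1), dtype=np.int64)  # index by distance 0..N-1; 0 unused
    np.add.at(geo, pair_d[finite].astype(np.int64), 1)
    geo = geo[1:] if n >= 1 else geo
    inf_count = int((~finite).sum())

    return MetricDistributions(
        degree=deg, geodesic=geo, geodesic_inf=inf_count, esp=esp_counts(g)
    )
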