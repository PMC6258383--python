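"""Spatial populations, radius-based connectivity and synapse groups.

The model network overlays a stimulus population (D), an excitatory
population (E) and an inhibitory population (I) on one shared 2D plane of
grid units.  Neurons are connected to every neuron (of any population)
within a fixed Euclidean radius, except that nothing projects back onto the
stimulus population.  There are no periodic boundaries and no autapses.

Weights are non-negative conductance weights in µS·ms; the sign of a
synapse enters only through the reversal potential of its *presynaptic*
population (excitatory populations drive toward ``V_E``, inhibitory toward
``V_I``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ConfigurationError",
    "PopulationSpec",
    "SimConfig",
    "SynapseGroup",
    "NetworkTopology",
    "Network",
    "build_topology",
]


class ConfigurationError(ValueError):
    """Raised when a population, synapse or simulation parameter is invalid."""


EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"


@dataclass(frozen=True)
class PopulationSpec:
    """A rectangular lattice of neurons on the shared plane.

    Parameters
    ----------
    name:
        Population label; the standard network uses ``"D"`` (stimulus),
        ``"E"`` (excitatory) and ``"I"`` (inhibitory).
    rows, cols:
        Lattice dimensions; the population size is ``rows * cols``.
    spacing:
        Grid units per lattice step.  All populations must tile the same
        plane, i.e. ``cols * spacing`` equals the plane extent.
    synapse_sign:
        ``"excitatory"`` or ``"inhibitory"`` — the sign of this
        population's *outgoing* synapses.
    reversal_potential:
        Reversal potential (mV) of this population's outgoing synapses.
    p_noise:
        Probability in [0, 1] that a spike emitted by this population is
        hidden from the plasticity machinery (learning noise).
    """

    name: str
    rows: int
    cols: int
    spacing: float
    synapse_sign: str
    reversal_potential: float
    p_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ConfigurationError(
                f"population {self.name!r}: grid dimensions must be positive "
                f"(got {self.rows}x{self.cols})"
            )
        if self.spacing <= 0:
            raise ConfigurationError(
                f"population {self.name!r}: spacing must be positive"
            )
        if self.synapse_sign not in (EXCITATORY, INHIBITORY):
            raise ConfigurationError(
                f"population {self.name!r}: unknown synapse_sign "
                f"{self.synapse_sign!r}"
            )
        if not 0.0 <= self.p_noise <= 1.0:
            raise ConfigurationError(
                f"population {self.name!r}: p_noise must lie in [0, 1]"
            )

    @property
    def size(self) -> int:
        return self.rows * self.cols

    @property
    def is_excitatory(self) -> bool:
        return self.synapse_sign == EXCITATORY

    def coordinates(self) -> np.ndarray:
        """(size, 2) array of real-valued plane coordinates, row-major.

        Lattices share the plane's origin: neuron ``(r, c)`` sits at
        ``(c * spacing, r * spacing)``.
        """
        r, c = np.divmod(np.arange(self.size), self.cols)
        return np.column_stack((c * self.spacing, r * self.spacing)).astype(float)


@dataclass(frozen=True)
class SimConfig:
    """Scalar simulation parameters (units: nF, µS, mV, ms)."""

    C: float = 1.0            # membrane capacitance, nF
    g_L: float = 0.05         # leak conductance, µS
    V_L: float = -70.0        # leak reversal, mV
    V_E: float = 0.0          # excitatory reversal, mV
    V_I: float = -80.0        # inhibitory reversal, mV
    V_th: float = -55.0       # spike threshold, mV
    V_rt: float = -70.0       # reset potential, mV
    tau_ref: float = 5.0      # refractory period, ms
    tau_r_E: float = 0.5      # excitatory synaptic rise, ms
    tau_d_E: float = 2.0      # excitatory synaptic decay, ms
    tau_r_I: float = 0.5      # inhibitory synaptic rise, ms
    tau_d_I: float = 7.0      # inhibitory synaptic decay, ms
    dt: float = 0.1           # integration step, ms
    tau_A: float = 140.0      # postsynaptic activity window, ms
    tau_m: float = 20.0       # membrane decay constant used by plasticity, ms
    duration: float = 1000.0  # default run duration, ms
    seed: int = 0             # master seed

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.tau_A <= 0:
            raise ConfigurationError("tau_A must be positive")
        if self.tau_m <= 0:
            raise ConfigurationError("tau_m must be positive")
        if not (self.V_I <= self.V_L <= self.V_th < self.V_E):
            raise ConfigurationError(
                "reversal/threshold ordering V_I <= V_L <= V_th < V_E violated"
            )
        for key in ("tau_ref", "tau_r_E", "tau_d_E", "tau_r_I", "tau_d_I"):
            if getattr(self, key) <= 0:
                raise ConfigurationError(f"{key} must be positive")

    @property
    def window_steps(self) -> int:
        """Length of the activity window tau_A in integration steps."""
        return int(round(self.tau_A / self.dt))

    @property
    def V_s(self) -> float:
        """Reset-to-threshold voltage V_th - V_rt (mV); one spike's worth."""
        return self.V_th - self.V_rt


class SynapseGroup:
    """Weights and plasticity constants for one ordered population pair.

    Edges are stored in two aligned sparse layouts so that both the
    outgoing neighbours of a presynaptic neuron and the incoming
    neighbours of a postsynaptic neuron are retrievable in amortised
    constant time per neighbour:

    * pre-indexed (CSR): ``indptr``/``post``/``w`` — ``w`` is the single
      authoritative weight array;
    * post-indexed (CSC): ``pindptr``/``pre``/``pos`` where ``pos`` maps
      each incoming edge back to its slot in ``w``.
    """

    def __init__(
        self,
        pre_pop: str,
        post_pop: str,
        indptr: np.ndarray,
        post: np.ndarray,
        *,
        n_post: int,
        epsilon: float,
        gamma: float,
        w_init: float,
        pre_sign: str,
        reversal: float,
    ) -> None:
        if gamma <= 0:
            raise ConfigurationError(
                f"synapse group {pre_pop}->{post_pop}: gamma must be positive"
            )
        if epsilon < 0 or w_init < 0:
            raise ConfigurationError(
                f"synapse group {pre_pop}->{post_pop}: epsilon and w_init "
                "must be non-negative"
            )
        self.pre_pop = pre_pop
        self.post_pop = post_pop
        self.indptr = indptr
        self.post = post
        self.w = np.full(post.shape[0], float(w_init))
        self.epsilon = float(epsilon)
        self.gamma = float(gamma)
        self.w_init = float(w_init)
        self.pre_sign = pre_sign
        self.reversal = float(reversal)
        # post-indexed view
        n_edges = post.shape[0]
        order = np.argsort(post, kind="stable")
        counts = np.bincount(post, minlength=n_post)
        self.pindptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        self.pos = order.astype(np.int64)
        # presynaptic index of every edge, then gather per post neuron
        pre_of_edge = np.repeat(
            np.arange(indptr.shape[0] - 1), np.diff(indptr)
        ).astype(np.int64)
        self.pre = pre_of_edge[order]
        self.n_pre = indptr.shape[0] - 1
        self.n_post = n_post
        self.n_edges = n_edges

    @property
    def name(self) -> str:
        return f"{self.pre_pop}{self.post_pop}"

    def out_edges(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """(post indices, weight slots) of presynaptic neuron ``j``."""
        sl = slice(self.indptr[j], self.indptr[j + 1])
        return self.post[sl], np.arange(sl.start, sl.stop)

    def in_edges(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(pre indices, weight slots) of postsynaptic neuron ``i``."""
        sl = slice(self.pindptr[i], self.pindptr[i + 1])
        return self.pre[sl], self.pos[sl]

    def weight_matrix(self) -> np.ndarray:
        """Dense (n_pre, n_post) weight matrix (small networks only)."""
        m = np.zeros((self.n_pre, self.n_post))
        pre = np.repeat(np.arange(self.n_pre), np.diff(self.indptr))
        m[pre, self.post] = self.w
        return m


@dataclass
class NetworkTopology:
    """Populations with coordinates plus lazily-built radius connectivity."""

    populations: list[PopulationSpec]
    connection_radius: float
    _coords: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _edges: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )
    _trees: dict[str, cKDTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.populations:
            raise ConfigurationError("at least one population is required")
        if self.connection_radius <= 0:
            raise ConfigurationError("connection_radius must be positive")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate population names")
        for p in self.populations:
            self._coords[p.name] = p.coordinates()
        extents = {p.name: p.cols * p.spacing for p in self.populations}
        ref = max(extents.values())
        for name, ext in extents.items():
            if abs(ext - ref) > max(p.spacing for p in self.populations):
                raise ConfigurationError(
                    f"population {name!r} does not tile the shared plane "
                    f"(extent {ext} vs {ref})"
                )

    def spec(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise ConfigurationError(f"unknown population {name!r}")

    def coords(self, name: str) -> np.ndarray:
        if name not in self._coords:
            raise ConfigurationError(f"unknown population {name!r}")
        return self._coords[name]

    def size(self, name: str) -> int:
        return self.spec(name).size

    def _tree(self, name: str) -> cKDTree:
        if name not in self._trees:
            self._trees[name] = cKDTree(self.coords(name))
        return self._trees[name]

    def edges(self, pre: str, post: str) -> tuple[np.ndarray, np.ndarray]:
        """CSR edge arrays ``(indptr, post_idx)`` for an ordered pair.

        An edge (j, i) exists iff the Euclidean distance between the two
        neurons is <= ``connection_radius`` (ties included) and it is not a
        distance-zero self connection within one population.
        """
        key = (pre, post)
        if key in self._edges:
            return self._edges[key]
        cpre = self.coords(pre)
        tree = self._tree(post)
        neigh = tree.query_ball_point(cpre, self.connection_radius)
        counts = np.fromiter((len(x) for x in neigh), dtype=np.int64,
                             count=len(neigh))
        flat = np.concatenate([np.sort(x) for x in neigh]) if counts.sum() else \
            np.empty(0, dtype=np.int64)
        flat = flat.astype(np.int64)
        indptr = np.concatenate(([0], np.cumsum(counts)))
        if pre == post:
            # drop autapses: same index within one population
            pre_of_edge = np.repeat(np.arange(len(neigh)), counts)
            keep = flat != pre_of_edge
            flat = flat[keep]
            counts = np.bincount(pre_of_edge[keep], minlength=len(neigh))
            indptr = np.concatenate(([0], np.cumsum(counts)))
        self._edges[key] = (indptr.astype(np.int64), flat)
        return self._edges[key]

    def in_degree(self, pre: str, post: str) -> np.ndarray:
        """Per-postsynaptic-neuron in-degree for an ordered pair."""
        _, flat = self.edges(pre, post)
        return np.bincount(flat, minlength=self.size(post))


def build_topology(
    specs: list[PopulationSpec], radius: float
) -> NetworkTopology:
    """Lay out populations on the shared plane with radius connectivity.

    Edge sets are built lazily per ordered pair, so constructing the
    full-scale topology (90 000 excitatory neurons) is cheap until a
    specific pair's edges are requested.
    """
    return NetworkTopology(populations=list(specs), connection_radius=radius)


class Network:
    """A topology plus the synapse groups that actually exist.

    Only ordered pairs present in ``pair_params`` get a ``SynapseGroup``;
    the standard network has all pairs except those into the stimulus
    population.
    """

    def __init__(
        self,
        topology: NetworkTopology,
        cfg: SimConfig,
        pair_params: dict[tuple[str, str], dict[str, float]],
    ) -> None:
        self.topology = topology
        self.cfg = cfg
        self.groups: dict[tuple[str, str], SynapseGroup] = {}
        for (pre, post), params in pair_params.items():
            if post == "D":
                raise ConfigurationError(
                    "the stimulus population cannot be postsynaptic"
                )
            pre_spec = topology.spec(pre)
            indptr, flat = topology.edges(pre, post)
            self.groups[(pre, post)] = SynapseGroup(
                pre,
                post,
                indptr,
                flat,
                n_post=topology.size(post),
                epsilon=params["epsilon"],
                gamma=params["gamma"],
                w_init=params["w_init"],
                pre_sign=pre_spec.synapse_sign,
                reversal=pre_spec.reversal_potential,
            )

        self.groups_by_name: dict[str, SynapseGroup] = {
            g.name: g for g in self.groups.values()
        }

    @property
    def sim_pops(self) -> list[str]:
        """Populations integrated by the dynamics (everything but D)."""
        return [p.name for p in self.topology.populations if p.name != "D"]

    def group(self, pre: str, post: str) -> SynapseGroup:
        return self.groups[(pre, post)]

    def incoming(self, post: str) -> list[SynapseGroup]:
        return [g for (pr, po), g in self.groups.items() if po == post]

    def outgoing(self, pre: str) -> list[SynapseGroup]:
        return [g for (pr, po), g in self.groups.items() if pr == pre]
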