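"""Discrete Bayesian networks with exact inference.

A clinical decision model is represented as a directed acyclic graph over
categorical variables, with one conditional probability table (CPT) per
variable.  Therapy-eligibility nodes are ``target`` variables; posterior
inference given evidence on the remaining variables yields a MAP prediction
per target.

Two inference routes are provided: :func:`enumerate_posterior`, a brute-force
sum over all completions of the evidence (the reference oracle, feasible only
for small networks), and :func:`infer_posterior`, exact variable elimination
with a greedy min-degree ordering.  Both are exact; they must agree to within
``PROB_TOL`` on any network where enumeration is feasible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

#: tolerance for CPT row normalisation and posterior sums
PROB_TOL = 1e-9
#: rows off by at most this much are silently renormalised at model load
LOAD_RENORM_TOL = 1e-6

VALID_ROLES = ("diagnostic", "intermediate", "target")
BOOLEAN_STATES = ("true", "false")

#: refuse brute-force enumeration beyond this many joint completions
_MAX_ENUMERATION = 2_000_000


class ModelError(ValueError):
    """Invalid model structure, parameters or query."""


class CycleError(ModelError):
    """An edge insertion would create a directed cycle."""

    def __init__(self, parent: str, child: str, path: Sequence[str]):
        self.path = tuple(path)
        super().__init__(
            f"adding edge {parent}->{child} creates a cycle through "
            + " -> ".join(self.path)
        )


class ImpossibleEvidenceError(ModelError):
    """The supplied evidence has probability zero under the model."""


@dataclass(frozen=True)
class DiscreteVariable:
    """A named clinical concept with an ordered list of categorical states.

    State order is semantically meaningful: MAP ties are broken in favour of
    the first declared state, and for therapy nodes the first state is the
    "eligible"/positive one used for ROC scoring.
    """

    name: str
    states: tuple[str, ...]
    role: str = "diagnostic"

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelError("variable name must be non-empty")
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise ModelError(f"variable {self.name!r} needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise ModelError(f"variable {self.name!r} has duplicate states")
        if self.role not in VALID_ROLES:
            raise ModelError(
                f"variable {self.name!r}: role {self.role!r} not in {VALID_ROLES}"
            )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def is_boolean(self) -> bool:
        return self.states == BOOLEAN_STATES

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ModelError(
                f"{state!r} is not a state of variable {self.name!r} "
                f"(states: {list(self.states)})"
            ) from None


@dataclass
class CPT:
    """Conditional distribution of ``child`` given its ``parents``.

    ``table`` has one row per full parent-state configuration and one column
    per child state.  Rows are ordered row-major over the parent state lists
    in declared parent order (last parent varies fastest), matching the
    flattening convention of the XDSL export.
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.table = np.asarray(self.table, dtype=float)
        if self.table.ndim != 2:
            raise ModelError(f"CPT for {self.child!r}: table must be 2-D")

    def validate(self, cardinality: Mapping[str, int]) -> None:
        n_rows = int(np.prod([cardinality[p] for p in self.parents], dtype=np.int64))
        if self.table.shape[0] != n_rows:
            raise ModelError(
                f"CPT for {self.child!r}: {self.table.shape[0]} rows, "
                f"expected {n_rows} (product of parent cardinalities)"
            )
        if self.table.shape[1] != cardinality[self.child]:
            raise ModelError(
                f"CPT for {self.child!r}: {self.table.shape[1]} columns, "
                f"expected {cardinality[self.child]} child states"
            )
        if np.any(self.table < -PROB_TOL) or np.any(self.table > 1 + PROB_TOL):
            raise ModelError(f"CPT for {self.child!r}: entries outside [0, 1]")
        bad = np.abs(self.table.sum(axis=1) - 1.0) > PROB_TOL
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ModelError(
                f"CPT for {self.child!r}: row {row} sums to "
                f"{self.table[row].sum()!r}, not 1"
            )

    def copy(self) -> "CPT":
        return CPT(self.child, self.parents, self.table.copy())


def _uniform_cpt(child: DiscreteVariable, parents: Sequence[DiscreteVariable]) -> CPT:
    n_rows = int(np.prod([p.n_states for p in parents], dtype=np.int64))
    table = np.full((n_rows, child.n_states), 1.0 / child.n_states)
    return CPT(child.name, tuple(p.name for p in parents), table)


def parent_config_index(
    parent_states: Sequence[str],
    parents: Sequence[DiscreteVariable],
) -> int:
    """Row index of a parent-state configuration (last parent fastest)."""
    idx = 0
    for var, state in zip(parents, parent_states):
        idx = idx * var.n_states + var.state_index(state)
    return idx


def parent_configurations(
    parents: Sequence[DiscreteVariable],
) -> Iterable[tuple[str, ...]]:
    """All parent-state configurations in CPT row order."""
    return itertools.product(*(p.states for p in parents))


class BayesianNetwork:
    """DAG over :class:`DiscreteVariable` plus one :class:`CPT` per variable.

    Construct either from ``(variables, edges)`` — CPTs initialised uniform,
    pending learning — or from ``(variables, cpts=...)`` with explicit tables.
    Instances are treated as immutable; structural operations return new
    networks.
    """

    def __init__(
        self,
        variables: Iterable[DiscreteVariable],
        edges: Iterable[tuple[str, str]] = (),
        cpts: Mapping[str, CPT] | None = None,
        metadata: Mapping[str, str] | None = None,
    ):
        self._variables: dict[str, DiscreteVariable] = {}
        for var in variables:
            if var.name in self._variables:
                raise ModelError(f"duplicate variable {var.name!r}")
            self._variables[var.name] = var
        self.metadata: dict[str, str] = dict(metadata or {})

        if cpts is None:
            parent_lists: dict[str, list[str]] = {n: [] for n in self._variables}
            for parent, child in edges:
                self._require(parent)
                self._require(child)
                if parent in parent_lists[child]:
                    raise ModelError(f"duplicate edge {parent}->{child}")
                parent_lists[child].append(parent)
            self._cpts = {
                name: _uniform_cpt(
                    self._variables[name],
                    [self._variables[p] for p in parent_lists[name]],
                )
                for name in self._variables
            }
        else:
            self._cpts = {name: cpt.copy() for name, cpt in cpts.items()}
            given_edges = list(edges)
            if given_edges and sorted(given_edges) != sorted(self.edges):
                raise ModelError("explicit edge list does not match CPT parents")
        self.validate()

    # -- basic accessors ---------------------------------------------------

    def _require(self, name: str) -> DiscreteVariable:
        try:
            return self._variables[name]
        except KeyError:
            raise ModelError(f"unknown variable {name!r}") from None

    @property
    def variables(self) -> tuple[DiscreteVariable, ...]:
        return tuple(self._variables.values())

    @property
    def variable_names(self) -> tuple[str, ...]:
        return tuple(self._variables)

    def variable(self, name: str) -> DiscreteVariable:
        return self._require(name)

    def __contains__(self, name: str) -> bool:
        return name in self._variables

    @property
    def cpts(self) -> dict[str, CPT]:
        return dict(self._cpts)

    def cpt(self, name: str) -> CPT:
        self._require(name)
        return self._cpts[name]

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        out = []
        for name, cpt in self._cpts.items():
            out.extend((p, name) for p in cpt.parents)
        return tuple(out)

    def parents(self, name: str) -> tuple[str, ...]:
        self._require(name)
        return self._cpts[name].parents

    def children(self, name: str) -> tuple[str, ...]:
        self._require(name)
        return tuple(c for c, cpt in self._cpts.items() if name in cpt.parents)

    def targets(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables if v.role == "target")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._variables)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self) -> list[str]:
        order = list(nx.topological_sort(self.graph()))
        # stable tie-break: keep declaration order among independent nodes
        rank = {n: i for i, n in enumerate(self._variables)}
        return sorted(order, key=lambda n: (self._topo_depth()[n], rank[n]))

    def _topo_depth(self) -> dict[str, int]:
        depth: dict[str, int] = {}
        for name in nx.topological_sort(self.graph()):
            ps = self._cpts[name].parents
            depth[name] = 1 + max((depth[p] for p in ps), default=-1)
        return depth

    def validate(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = [e[0] for e in cycle] + [cycle[-1][1]]
            raise CycleError(path[0], path[1], path)
        cardinality = {n: v.n_states for n, v in self._variables.items()}
        if set(self._cpts) != set(self._variables):
            missing = set(self._variables) - set(self._cpts)
            extra = set(self._cpts) - set(self._variables)
            raise ModelError(f"CPT/variable mismatch: missing={missing}, extra={extra}")
        for name, cpt in self._cpts.items():
            if cpt.child != name:
                raise ModelError(f"CPT keyed {name!r} declares child {cpt.child!r}")
            for p in cpt.parents:
                self._require(p)
            cpt.validate(cardinality)

    # -- functional updates ------------------------------------------------

    def with_cpts(self, cpts: Mapping[str, CPT]) -> "BayesianNetwork":
        """New network with some CPTs replaced (parent lists may change)."""
        merged = dict(self._cpts)
        merged.update({n: c for n, c in cpts.items()})
        return BayesianNetwork(self.variables, cpts=merged, metadata=self.metadata)

    def with_parents(self, child: str, parents: Sequence[str]) -> "BayesianNetwork":
        """New network where ``child`` has the given parent list and a uniform
        CPT pending learning."""
        child_var = self._require(child)
        parent_vars = [self._require(p) for p in parents]
        return self.with_cpts({child: _uniform_cpt(child_var, parent_vars)})

    def structure_signature(self):
        """Hashable summary of (variables, states, roles, edges) for
        structural-equality checks, ignoring CPT values."""
        return (
            tuple((v.name, v.states, v.role) for v in self.variables),
            tuple(sorted(self.edges)),
        )

    def copy(self) -> "BayesianNetwork":
        return BayesianNetwork(self.variables, cpts=self._cpts, metadata=self.metadata)


# ---------------------------------------------------------------------------
# structural operations
# ---------------------------------------------------------------------------


def add_edge(network: BayesianNetwork, parent: str, child: str) -> BayesianNetwork:
    """Add a directed edge; the child's CPT is re-expanded to uniform.

    Raises :class:`CycleError` (reporting the offending path) if the edge
    would close a directed cycle.
    """
    network.variable(parent)
    network.variable(child)
    if parent in network.parents(child):
        raise ModelError(f"edge {parent}->{child} already present")
    g = network.graph()
    if nx.has_path(g, child, parent):
        path = nx.shortest_path(g, child, parent) + [child]
        raise CycleError(parent, child, path)
    return network.with_parents(child, network.parents(child) + (parent,))


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def check_evidence(network: BayesianNetwork, evidence: Mapping[str, str]) -> None:
    """Validate an evidence map: known variables, legal states."""
    for name, state in evidence.items():
        network.variable(name).state_index(state)


def joint_probability(
    network: BayesianNetwork, assignment: Mapping[str, str]
) -> float:
    """Chain-rule probability of a full assignment over every variable."""
    missing = [n for n in network.variable_names if n not in assignment]
    if missing:
        raise ModelError(f"assignment misses variables: {missing}")
    check_evidence(network, assignment)
    prob = 1.0
    for var in network.variables:
        cpt = network.cpt(var.name)
        row = parent_config_index(
            [assignment[p] for p in cpt.parents],
            [network.variable(p) for p in cpt.parents],
        )
        prob *= cpt.table[row, var.state_index(assignment[var.name])]
        if prob == 0.0:
            return 0.0
    return prob


def enumerate_posterior(
    network: BayesianNetwork,
    evidence: Mapping[str, str],
    query: str,
) -> dict[str, float]:
    """Exact posterior of ``query`` by brute-force enumeration.

    Sums :func:`joint_probability` over every completion of the evidence and
    renormalises.  Reference oracle; use :func:`infer_posterior` in anger.
    """
    check_evidence(network, evidence)
    qvar = network.variable(query)
    if query in evidence:
        raise ModelError(f"query {query!r} is already fixed by evidence")
    hidden = [
        v for v in network.variables if v.name not in evidence and v.name != query
    ]
    n_comb = qvar.n_states * int(
        np.prod([v.n_states for v in hidden], dtype=np.int64)
    )
    if n_comb > _MAX_ENUMERATION:
        raise ModelError(
            f"enumeration over {n_comb} completions refused; use infer_posterior"
        )
    totals = np.zeros(qvar.n_states)
    for combo in itertools.product(*(v.states for v in hidden)):
        partial = dict(evidence)
        partial.update(zip((v.name for v in hidden), combo))
        for i, qstate in enumerate(qvar.states):
            partial[query] = qstate
            totals[i] += joint_probability(network, partial)
    z = totals.sum()
    if z <= 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {dict(evidence)!r} has probability 0"
        )
    return dict(zip(qvar.states, (totals / z).tolist()))


@dataclass
class _Factor:
    axes: tuple[str, ...]
    array: np.ndarray

    def restrict(self, evidence_idx: Mapping[str, int]) -> "_Factor":
        axes, array = list(self.axes), self.array
        for name in [a for a in self.axes if a in evidence_idx]:
            ax = axes.index(name)
            array = np.take(array, evidence_idx[name], axis=ax)
            axes.pop(ax)
        return _Factor(tuple(axes), array)

    def multiply(self, other: "_Factor") -> "_Factor":
        axes = list(self.axes) + [a for a in other.axes if a not in self.axes]
        a = self.array.reshape(
            self.array.shape + (1,) * (len(axes) - len(self.axes))
        )
        b = other.array.reshape(
            other.array.shape + (1,) * (len(axes) - len(other.axes))
        )
        b = np.moveaxis(
            b, range(len(other.axes)), [axes.index(x) for x in other.axes]
        )
        return _Factor(tuple(axes), a * b)

    def marginalize(self, name: str) -> "_Factor":
        ax = self.axes.index(name)
        return _Factor(
            self.axes[:ax] + self.axes[ax + 1 :], self.array.sum(axis=ax)
        )


def _elimination_order(hidden: list[str], factors: list[_Factor]) -> list[str]:
    """Greedy min-degree ordering on the factor interaction graph."""
    adj: dict[str, set[str]] = {h: set() for h in hidden}
    for f in factors:
        for a in f.axes:
            if a in adj:
                adj[a].update(x for x in f.axes if x != a and x in adj)
    order = []
    remaining = set(hidden)
    while remaining:
        pick = min(remaining, key=lambda v: (len(adj[v] & remaining), v))
        order.append(pick)
        neigh = adj[pick] & remaining
        for u in neigh:  # connect neighbours (fill-in)
            adj[u].update(neigh - {u})
        remaining.discard(pick)
    return order


def infer_posterior(
    network: BayesianNetwork,
    evidence: Mapping[str, str],
    query: str,
) -> dict[str, float]:
    """Exact posterior of ``query`` given evidence, by variable elimination.

    Agrees with :func:`enumerate_posterior` to within ``PROB_TOL`` wherever
    enumeration is feasible; raises :class:`ImpossibleEvidenceError` when the
    evidence has probability zero.
    """
    check_evidence(network, evidence)
    qvar = network.variable(query)
    if query in evidence:
        raise ModelError(f"query {query!r} is already fixed by evidence")
    evidence_idx = {
        n: network.variable(n).state_index(s) for n, s in evidence.items()
    }
    factors = []
    for var in network.variables:
        cpt = network.cpt(var.name)
        axes = cpt.parents + (var.name,)
        shape = tuple(network.variable(a).n_states for a in axes)
        f = _Factor(axes, cpt.table.reshape(shape)).restrict(evidence_idx)
        if f.axes:
            factors.append(f)
        else:  # fully observed family: scalar weight
            factors.append(_Factor((), f.array))
    hidden = [
        n for n in network.variable_names if n not in evidence and n != query
    ]
    for h in _elimination_order(hidden, [f for f in factors if f.axes]):
        related = [f for f in factors if h in f.axes]
        rest = [f for f in factors if h not in f.axes]
        prod = related[0]
        for f in related[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(h)]
    result = _Factor((), np.array(1.0))
    for f in factors:
        result = result.multiply(f) if f.axes else _Factor(
            result.axes, result.array * float(np.asarray(f.array))
        )
    if result.axes != (query,):
        # query may be absent if all factors were scalars (cannot happen:
        # the query's own CPT always carries its axis)
        raise ModelError(f"elimination left unexpected axes {result.axes}")
    z = result.array.sum()
    if z <= 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {dict(evidence)!r} has probability 0"
        )
    return dict(zip(qvar.states, (result.array / z).tolist()))


def predict_map(
    network: BayesianNetwork,
    evidence: Mapping[str, str],
    target: str,
) -> str:
    """MAP state of ``target``; ties broken by declared state order."""
    posterior = infer_posterior(network, evidence, target)
    states = network.variable(target).states
    values = np.array([posterior[s] for s in states])
    return states[int(np.argmax(values))]  # argmax is first-wins


# ---------------------------------------------------------------------------
# complexity
# ---------------------------------------------------------------------------


def free_parameter_breakdown(network: BayesianNetwork) -> dict[str, int]:
    """Per-variable free parameters: (|states|-1) * prod(parent cardinalities)."""
    out = {}
    for var in network.variables:
        cpt = network.cpt(var.name)
        rows = int(
            np.prod(
                [network.variable(p).n_states for p in cpt.parents], dtype=np.int64
            )
        )
        out[var.name] = (var.n_states - 1) * rows
    return out


def free_parameter_count(network: BayesianNetwork) -> int:
    """Total free parameters of the network's CPTs."""
    return sum(free_parameter_breakdown(network).values())


def total_state_count(network: BayesianNetwork) -> int:
    """Sum of state counts over all variables."""
    return sum(v.n_states for v in network.variables)
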