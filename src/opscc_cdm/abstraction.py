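"""Model-abstraction operators: state merging, variable condensation,
transitivity resolution, binarization and leaky noisy-OR compilation.

Each operator transforms a (network, dataset) pair coherently — the dataset
is remapped through the same state/variable mapping the model undergoes — and
returns an :class:`AbstractionStep` recording what was done and how the free
parameter count changed.  A list of step specifications (a *recipe*) replays
a whole multi-stage simplification, so a detailed first-draft model can be
reduced to its clinically condensed successors reproducibly.

By default every operator re-learns the affected CPTs from the remapped
dataset (the training data are "adapted accordingly" and the model refit);
``merge_states`` additionally offers an analytic aggregation path for use
without data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .model import (
    BOOLEAN_STATES,
    CPT,
    BayesianNetwork,
    DiscreteVariable,
    ModelError,
    free_parameter_breakdown,
    free_parameter_count,
    parent_configurations,
    total_state_count,
)
from .learning import DataError, LearningConfig, PatientDataset, learn_cpts

SHRINKING_KINDS = ("merge", "condense", "binarize", "resolve_transitivity")
STEP_KINDS = SHRINKING_KINDS + ("noisy_or",)


@dataclass
class AbstractionStep:
    """Provenance record of one abstraction transform."""

    kind: str
    description: str
    before_parameters: int
    after_parameters: int
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in STEP_KINDS:
            raise ModelError(f"unknown abstraction kind {self.kind!r}")
        if self.kind in SHRINKING_KINDS and (
            self.after_parameters > self.before_parameters
        ):
            raise ModelError(
                f"{self.kind} step increased free parameters "
                f"({self.before_parameters} -> {self.after_parameters})"
            )


@dataclass(frozen=True)
class StatePartition:
    """Disjoint grouping of a variable's states into new labelled groups."""

    variable: str
    groups: tuple[tuple[str, ...], ...]
    new_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "groups", tuple(tuple(g) for g in self.groups)
        )
        object.__setattr__(self, "new_labels", tuple(self.new_labels))
        if len(self.groups) != len(self.new_labels):
            raise ModelError("one new label per group required")
        if len(set(self.new_labels)) != len(self.new_labels):
            raise ModelError("new labels must be unique")
        if len(self.groups) < 1:
            raise ModelError("at least one group required")

    def validate_for(self, var: DiscreteVariable) -> None:
        flat = [s for g in self.groups for s in g]
        if len(flat) != len(set(flat)):
            dupes = {s for s in flat if flat.count(s) > 1}
            raise ModelError(f"overlapping groups for {var.name!r}: {sorted(dupes)}")
        if set(flat) != set(var.states):
            missing = set(var.states) - set(flat)
            extra = set(flat) - set(var.states)
            raise ModelError(
                f"groups must partition states of {var.name!r} "
                f"(missing {sorted(missing)}, unknown {sorted(extra)})"
            )

    def state_map(self) -> dict[str, str]:
        return {
            s: label for g, label in zip(self.groups, self.new_labels) for s in g
        }


@dataclass(frozen=True)
class CondensationRule:
    """Replace several source variables by one derived summary variable.

    ``mapping`` must be total over the cross-product of source states.  The
    derived variable takes the explicit ``parents`` (default: none — a
    directly observed summary); children of any source are rewired to depend
    on the derived variable instead, so downstream conditionals survive the
    condensation and are re-learned from the remapped data.
    """

    sources: tuple[str, ...]
    derived: DiscreteVariable
    mapping: Mapping[tuple[str, ...], str]
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(
            self,
            "mapping",
            {tuple(k): v for k, v in dict(self.mapping).items()},
        )
        if not self.sources:
            raise ModelError("condensation needs >=1 source variable")

    def validate_for(self, network: BayesianNetwork) -> None:
        for s in self.sources:
            network.variable(s)
        if self.derived.name in network:
            raise ModelError(
                f"derived variable name {self.derived.name!r} already in use"
            )
        for p in self.parents:
            if p in self.sources:
                raise ModelError(f"derived parent {p!r} is a source variable")
            network.variable(p)
        state_lists = [network.variable(s).states for s in self.sources]
        derived_states = set(self.derived.states)
        for combo in itertools.product(*state_lists):
            if combo not in self.mapping:
                raise ModelError(
                    f"condensation mapping misses source tuple {combo!r}"
                )
            if self.mapping[combo] not in derived_states:
                raise ModelError(
                    f"mapping value {self.mapping[combo]!r} is not a state of "
                    f"{self.derived.name!r}"
                )


@dataclass(frozen=True)
class NoisyOrSpec:
    """Leaky noisy-OR gate: Boolean effect, Boolean causes, one link
    probability per cause plus a background leak."""

    effect: str
    causes: tuple[str, ...]
    link_probabilities: tuple[float, ...]
    leak: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "causes", tuple(self.causes))
        object.__setattr__(
            self, "link_probabilities", tuple(float(p) for p in self.link_probabilities)
        )
        if len(self.causes) != len(self.link_probabilities):
            raise ModelError("one link probability per cause required")
        for p in (*self.link_probabilities, self.leak):
            if not 0.0 <= p <= 1.0:
                raise ModelError(f"probability {p!r} outside [0, 1]")


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------


def _relearn(
    network: BayesianNetwork,
    dataset: PatientDataset | None,
    config: LearningConfig | None,
) -> BayesianNetwork:
    if dataset is None:
        return network
    return learn_cpts(network, dataset, config or LearningConfig())


def merge_states(
    network: BayesianNetwork,
    dataset: PatientDataset | None,
    partition: StatePartition,
    config: LearningConfig | None = None,
    relearn: bool = True,
) -> tuple[BayesianNetwork, PatientDataset | None, AbstractionStep]:
    """Cluster a variable's states into groups; remap model and data.

    With a dataset and ``relearn=True`` (default) every CPT touching the
    variable is re-estimated from the remapped records.  Without a dataset
    (or ``relearn=False``) the tables are aggregated analytically: child-state
    columns are summed within each group, and for CPTs where the merged
    variable is a parent, the rows of each group are averaged (uniform
    pooling over the merged configurations — exact only when those
    configurations were equiprobable, hence re-learning is the default).
    """
    var = network.variable(partition.variable)
    partition.validate_for(var)
    state_map = partition.state_map()
    new_var = DiscreteVariable(var.name, partition.new_labels, var.role)
    group_idx = [
        [var.state_index(s) for s in g] for g in partition.groups
    ]

    variables = [new_var if v.name == var.name else v for v in network.variables]
    new_cpts: dict[str, CPT] = {}
    for v in network.variables:
        cpt = network.cpt(v.name)
        if v.name == var.name:
            table = np.stack(
                [cpt.table[:, idx].sum(axis=1) for idx in group_idx], axis=1
            )
            new_cpts[v.name] = CPT(v.name, cpt.parents, table)
        elif var.name in cpt.parents:
            ax = cpt.parents.index(var.name)
            cards = [network.variable(p).n_states for p in cpt.parents]
            shaped = cpt.table.reshape(tuple(cards) + (v.n_states,))
            pooled = np.stack(
                [shaped.take(idx, axis=ax).mean(axis=ax) for idx in group_idx],
                axis=ax,
            )
            new_cpts[v.name] = CPT(
                v.name, cpt.parents, pooled.reshape(-1, v.n_states)
            )
        else:
            new_cpts[v.name] = cpt.copy()
    merged_net = BayesianNetwork(variables, cpts=new_cpts, metadata=network.metadata)

    new_dataset = None
    if dataset is not None:
        new_df = dataset.df.copy()
        new_df[var.name] = new_df[var.name].map(state_map)
        new_dataset = PatientDataset(new_df, dataset.provenance)
        if relearn:
            merged_net = _relearn(merged_net, new_dataset, config)

    step = AbstractionStep(
        "merge",
        f"merged {var.n_states} states of {var.name!r} into "
        f"{len(partition.groups)} ({', '.join(partition.new_labels)})",
        free_parameter_count(network),
        free_parameter_count(merged_net),
        {"variable": var.name, "state_map": state_map},
    )
    return merged_net, new_dataset, step


def condense_variables(
    network: BayesianNetwork,
    dataset: PatientDataset | None,
    rule: CondensationRule,
    config: LearningConfig | None = None,
) -> tuple[BayesianNetwork, PatientDataset | None, AbstractionStep]:
    """Replace the source variables by one derived summary variable.

    Every dataset row gains the derived column via the (total) mapping and
    loses the source columns; children of the sources are rewired to the
    derived variable and re-learned.
    """
    rule.validate_for(network)
    sources = set(rule.sources)
    rewired = sorted(
        {c for s in rule.sources for c in network.children(s)} - sources
    )

    variables = [v for v in network.variables if v.name not in sources]
    variables.append(rule.derived)
    edges: list[tuple[str, str]] = []
    for v in network.variables:
        if v.name in sources:
            continue
        replaced = False
        for p in network.parents(v.name):
            if p in sources:
                if not replaced:
                    edges.append((rule.derived.name, v.name))
                    replaced = True
            else:
                edges.append((p, v.name))
    edges.extend((p, rule.derived.name) for p in rule.parents)
    condensed_net = BayesianNetwork(variables, edges=edges, metadata=network.metadata)
    # keep untouched CPTs; rewired children and the derived node stay uniform
    keep = {
        v.name: network.cpt(v.name)
        for v in network.variables
        if v.name not in sources and v.name not in rewired
    }
    condensed_net = condensed_net.with_cpts(keep)

    new_dataset = None
    if dataset is not None:
        for s in rule.sources:
            if s not in dataset.columns:
                raise DataError(f"source column {s!r} not in dataset")
        new_df = dataset.df.copy()
        tuples = list(zip(*(new_df[s] for s in rule.sources)))
        new_df[rule.derived.name] = [rule.mapping[t] for t in tuples]
        new_df = new_df.drop(columns=list(rule.sources))
        new_dataset = PatientDataset(new_df, dataset.provenance)
        condensed_net = _relearn(condensed_net, new_dataset, config)

    step = AbstractionStep(
        "condense",
        f"condensed {', '.join(rule.sources)} into {rule.derived.name!r}",
        free_parameter_count(network),
        free_parameter_count(condensed_net),
        {
            "sources": list(rule.sources),
            "derived": rule.derived.name,
            "rewired_children": rewired,
        },
    )
    return condensed_net, new_dataset, step


def binarize_target(
    network: BayesianNetwork,
    dataset: PatientDataset | None,
    variable: str,
    true_states: Sequence[str],
    config: LearningConfig | None = None,
    relearn: bool = True,
) -> tuple[BayesianNetwork, PatientDataset | None, AbstractionStep]:
    """Discretize a variable into the Boolean pair [true, false].

    ``true_states`` (a proper, non-empty subset of the variable's states)
    maps to ``true``; equivalent to :func:`merge_states` with the two-group
    partition, so model and data stay coherent.
    """
    var = network.variable(variable)
    true_set = tuple(dict.fromkeys(true_states))
    for s in true_set:
        var.state_index(s)
    if not true_set or len(true_set) >= var.n_states:
        raise ModelError(
            f"true_states must be a proper non-empty subset of "
            f"{variable!r} states, got {list(true_states)!r}"
        )
    false_set = tuple(s for s in var.states if s not in true_set)
    partition = StatePartition(variable, (true_set, false_set), BOOLEAN_STATES)
    net, ds, step = merge_states(network, dataset, partition, config, relearn)
    step = AbstractionStep(
        "binarize",
        f"binarized {variable!r}: true <- {list(true_set)}",
        step.before_parameters,
        step.after_parameters,
        step.details,
    )
    return net, ds, step


def resolve_transitivity(
    network: BayesianNetwork,
    targets: Sequence[str],
) -> tuple[BayesianNetwork, AbstractionStep]:
    """Enforce independence of causal influence between target families.

    For every pair of distinct targets X != Y, edges running from a parent of
    X to a parent of Y are removed, so no links remain between the parent
    sets of different inferred nodes.  Children losing parents get uniform
    CPTs pending re-learning.  Idempotent; never adds edges.
    """
    parent_sets = {t: set(network.parents(t)) for t in targets}
    removed: list[tuple[str, str]] = []
    for x, y in itertools.permutations(targets, 2):
        for u in parent_sets[x]:
            for v in parent_sets[y]:
                if u != v and u in network.parents(v):
                    removed.append((u, v))
    removed = sorted(set(removed))
    net = network
    for u, v in removed:
        net = net.with_parents(v, tuple(p for p in net.parents(v) if p != u))
    step = AbstractionStep(
        "resolve_transitivity",
        f"removed {len(removed)} inter-family edge(s) between parents of "
        f"distinct targets",
        free_parameter_count(network),
        free_parameter_count(net),
        {"targets": list(targets), "removed_edges": removed},
    )
    return net, step


def compile_noisy_or(spec: NoisyOrSpec) -> CPT:
    """Compile a leaky noisy-OR gate into a full CPT.

    ``P(effect=true | x) = 1 - (1 - leak) * prod_{i: x_i = true} (1 - p_i)``;
    the table has ``2^n_causes`` rows in row-major cause order (true first).
    """
    n = len(spec.causes)
    rows = []
    for combo in itertools.product(BOOLEAN_STATES, repeat=n):
        fail = 1.0 - spec.leak
        for state, p in zip(combo, spec.link_probabilities):
            if state == "true":
                fail *= 1.0 - p
        rows.append([1.0 - fail, fail])
    return CPT(spec.effect, spec.causes, np.array(rows))


def apply_noisy_or(
    network: BayesianNetwork,
    spec: NoisyOrSpec,
) -> tuple[BayesianNetwork, AbstractionStep]:
    """Re-parameterize the effect node as a leaky noisy-OR of its causes.

    The effect's parent set becomes the cause list and its CPT the compiled
    gate; effect and causes must be Boolean variables already present."""
    effect = network.variable(spec.effect)
    if not effect.is_boolean:
        raise ModelError(f"noisy-OR effect {spec.effect!r} must be Boolean")
    for c in spec.causes:
        if not network.variable(c).is_boolean:
            raise ModelError(f"noisy-OR cause {c!r} must be Boolean")
    net = network.with_cpts({spec.effect: compile_noisy_or(spec)})
    step = AbstractionStep(
        "noisy_or",
        f"leaky noisy-OR for {spec.effect!r} over {list(spec.causes)} "
        f"(leak={spec.leak})",
        free_parameter_count(network),
        free_parameter_count(net),
        {
            "effect": spec.effect,
            "causes": list(spec.causes),
            "link_probabilities": list(spec.link_probabilities),
            "leak": spec.leak,
        },
    )
    return net, step


# ---------------------------------------------------------------------------
# complexity comparison
# ---------------------------------------------------------------------------


def complexity_report(
    before: BayesianNetwork, after: BayesianNetwork
) -> dict:
    """Free parameters, total states and edge counts for two model versions,
    with per-variable breakdowns and the deltas."""

    def side(net: BayesianNetwork) -> dict:
        return {
            "free_parameters": free_parameter_count(net),
            "total_states": total_state_count(net),
            "n_edges": len(net.edges),
            "n_variables": len(net.variables),
            "per_variable": free_parameter_breakdown(net),
        }

    b, a = side(before), side(after)
    delta = {
        k: b[k] - a[k]
        for k in ("free_parameters", "total_states", "n_edges", "n_variables")
    }
    return {"before": b, "after": a, "reduction": delta}


# ---------------------------------------------------------------------------
# recipes: serializable step lists
# ---------------------------------------------------------------------------


def _rule_from_spec(network: BayesianNetwork, spec: Mapping) -> CondensationRule:
    derived = DiscreteVariable(
        spec["name"], tuple(spec["states"]), spec.get("role", "diagnostic")
    )
    mapping = {tuple(row[:-1]): row[-1] for row in spec["mapping"]}
    return CondensationRule(
        tuple(spec["sources"]), derived, mapping, tuple(spec.get("parents", ()))
    )


def apply_recipe(
    network: BayesianNetwork,
    dataset: PatientDataset | None,
    steps: Sequence[Mapping],
    config: LearningConfig | None = None,
) -> tuple[BayesianNetwork, PatientDataset | None, list[AbstractionStep]]:
    """Replay a list of abstraction-step specifications.

    Each step is a mapping with an ``op`` key naming a supported operator
    (``merge``, ``condense``, ``binarize``, ``resolve_transitivity``,
    ``noisy_or``) plus that operator's parameters; see the packaged
    reference recipes for the schema.
    """
    records: list[AbstractionStep] = []
    net, ds = network, dataset
    for spec in steps:
        op = spec.get("op")
        if op == "merge":
            groups = tuple(tuple(g["states"]) for g in spec["groups"])
            labels = tuple(g["label"] for g in spec["groups"])
            partition = StatePartition(spec["variable"], groups, labels)
            net, ds, step = merge_states(net, ds, partition, config)
        elif op == "condense":
            net, ds, step = condense_variables(
                net, ds, _rule_from_spec(net, spec), config
            )
        elif op == "binarize":
            net, ds, step = binarize_target(
                net, ds, spec["variable"], spec["true_states"], config
            )
        elif op == "resolve_transitivity":
            net, step = resolve_transitivity(net, spec["targets"])
            if ds is not None:
                net = _relearn(net, ds, config)
        elif op == "noisy_or":
            causes = [c for c, _ in spec["causes"]]
            probs = [p for _, p in spec["causes"]]
            net, step = apply_noisy_or(
                net, NoisyOrSpec(spec["effect"], causes, probs, spec.get("leak", 0.0))
            )
        else:
            raise ModelError(f"unsupported recipe operator {op!r}")
        if "rationale" in spec:
            step.details["rationale"] = spec["rationale"]
        records.append(step)
    return net, ds, records
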