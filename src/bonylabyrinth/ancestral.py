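"""Ancestral-state reconstruction on the composite therian cladogram.

Discrete characters use unordered (uniform-cost) maximum parsimony,
implemented as a Sankoff dynamic program that handles multistate
characters, polymorphic or missing tips, and polytomies directly — no
resolution of multifurcations is ever performed.  For each internal node
the full set of states attainable in *some* most-parsimonious labeling is
reported; a set larger than one is an equivocal node.

Continuous traits use the Brownian-motion maximum-likelihood point
estimates, i.e. generalized least squares, computed by an exact two-pass
message-passing scheme (equivalently: weighted squared-change parsimony
with weights 1/branch length).  Each edge carries a Gaussian "message"
(conditional mean and effective variance-length); combining the messages
arriving at a node from all its neighbours gives that node's marginal ML
estimate.  No iteration is involved and multifurcations are handled
natively.  Branch lengths default to 1 everywhere (the source cladogram
publishes none), so continuous estimates are topology-only
approximations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

INF = math.inf


@dataclass
class AncestralReconstruction:
    """Reconstruction for one character over one tree."""

    character: str
    kind: str  # "discrete" | "continuous"
    node_states: dict = field(default_factory=dict)  # label -> frozenset | float
    tree_length: Optional[float] = None  # parsimony steps (discrete only)

    def is_equivocal(self, node_label: str) -> bool:
        s = self.node_states[node_label]
        return isinstance(s, frozenset) and len(s) > 1


def _node_key(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label if node.label is not None else f"@{id(node)}"


# ---------------------------------------------------------------------------
# discrete: uniform-cost Sankoff parsimony
# ---------------------------------------------------------------------------

def parsimony_asr(
    tree: dendropy.Tree,
    tip_states: Mapping[str, object],
    character: str = "character",
) -> AncestralReconstruction:
    """Unordered-parsimony ancestral states for one discrete character.

    ``tip_states`` maps tip label -> state, set of states (polymorphism), or
    ``None`` (missing; contributes every state at no cost).  Returns, per
    node, the frozenset of states attainable in at least one
    most-parsimonious labeling, plus the minimum number of changes.
    """
    states: set = set()
    for v in tip_states.values():
        if v is None:
            continue
        if isinstance(v, (set, frozenset)):
            states.update(v)
        else:
            states.add(v)
    if not states:
        raise ValueError("all tips missing; nothing to reconstruct")
    states_list = sorted(states)
    idx = {s: i for i, s in enumerate(states_list)}
    k = len(states_list)

    def unit_cost(i: int, j: int) -> int:
        return 0 if i == j else 1

    # upward pass: up[v][s] = min changes in the subtree of v given v = s
    up: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            obs = tip_states.get(node.taxon.label)
            cost = np.full(k, INF)
            if obs is None:
                cost[:] = 0.0
            elif isinstance(obs, (set, frozenset)):
                for s in obs:
                    cost[idx[s]] = 0.0
            else:
                cost[idx[obs]] = 0.0
        else:
            cost = np.zeros(k)
            for child in node.child_nodes():
                child_up = up[child]
                cost += np.array(
                    [min(child_up[j] + unit_cost(i, j) for j in range(k))
                     for i in range(k)]
                )
        up[node] = cost

    root = tree.seed_node
    tree_length = float(up[root].min())

    # downward pass: out[v][s] = min changes outside v's subtree given v = s
    out: dict[dendropy.Node, np.ndarray] = {root: np.zeros(k)}
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        if not children:
            continue
        child_min = {}
        for child in children:
            child_up = up[child]
            child_min[child] = np.array(
                [min(child_up[j] + unit_cost(i, j) for j in range(k))
                 for i in range(k)]
            )
        total_children = sum(child_min.values())
        for child in children:
            # parent-state cost excluding this child's subtree
            parent_excl = out[node] + total_children - child_min[child]
            out[child] = np.array(
                [min(parent_excl[i] + unit_cost(i, j) for i in range(k))
                 for j in range(k)]
            )

    node_states: dict[str, frozenset] = {}
    for node in tree.preorder_node_iter():
        total = up[node] + out[node]
        best = total.min()
        node_states[_node_key(node)] = frozenset(
            states_list[i] for i in range(k) if total[i] == best
        )
    return AncestralReconstruction(
        character=character, kind="discrete",
        node_states=node_states, tree_length=tree_length,
    )


# ---------------------------------------------------------------------------
# continuous: Brownian-motion GLS by message passing
# ---------------------------------------------------------------------------

def _combine(messages: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Precision-weighted combination of Gaussian messages (mean, length)."""
    wsum = sum(1.0 / l for _, l in messages)
    mean = sum(m / l for m, l in messages) / wsum
    return mean, 1.0 / wsum


def brownian_asr(
    tree: dendropy.Tree,
    tip_values: Mapping[str, float],
    character: str = "trait",
) -> AncestralReconstruction:
    """Brownian-motion ML (GLS) ancestral estimates for a continuous trait.

    Tips with missing values are pruned from the calculation; internal
    estimates are the marginal ML values.  On a star tree with equal branch
    lengths the root estimate is the arithmetic tip mean.  Zero or negative
    branch lengths are rejected.
    """
    have = {t: v for t, v in tip_values.items() if v is not None}
    if len(have) < 2:
        raise ValueError("need at least 2 tips with values")

    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is not None:
            if edge.length <= 0:
                raise ValueError("branch lengths must be positive")

    # upward messages: for node v (toward its parent), the distribution of
    # v's value given the tip data below it: (conditional mean, extra length)
    up_msg: dict[dendropy.Node, Optional[tuple[float, float]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            up_msg[node] = (have[label], 0.0) if label in have else None
        else:
            msgs = []
            for child in node.child_nodes():
                m = up_msg[child]
                if m is None:
                    continue
                msgs.append((m[0], m[1] + child.edge.length))
            up_msg[node] = _combine(msgs) if msgs else None
    if up_msg[tree.seed_node] is None:
        raise ValueError("no tip data anywhere in the tree")

    # downward messages: dist of v's value given data outside v's subtree
    down_msg: dict[dendropy.Node, Optional[tuple[float, float]]] = {
        tree.seed_node: None
    }
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        for child in children:
            msgs = []
            parent_down = down_msg[node]
            if parent_down is not None:
                msgs.append(parent_down)
            for sib in children:
                if sib is child or up_msg[sib] is None:
                    continue
                m = up_msg[sib]
                msgs.append((m[0], m[1] + sib.edge.length))
            if msgs:
                mean, length = _combine(msgs)
                down_msg[child] = (mean, length + child.edge.length)
            else:
                down_msg[child] = None

    node_states: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label in have:
                node_states[label] = float(have[label])
            continue
        msgs = []
        for child in node.child_nodes():
            m = up_msg[child]
            if m is not None:
                msgs.append((m[0], m[1] + child.edge.length))
        if down_msg[node] is not None:
            msgs.append(down_msg[node])
        if not msgs:
            continue
        node_states[_node_key(node)] = float(_combine(msgs)[0])
    return AncestralReconstruction(
        character=character, kind="continuous", node_states=node_states
    )


# ---------------------------------------------------------------------------
# whole-matrix reconstruction
# ---------------------------------------------------------------------------

DISCRETE_CHARACTERS = (
    "lsc_entry",
    "lsc_position",
    "largest_canal",
    "cochlea_shape",
    "coil_bin",
    "contribution_bin",
)


def reconstruct_all(
    tree: dendropy.Tree,
    discrete_matrix: Mapping[str, Mapping[str, object]],
    continuous_matrix: Mapping[str, Mapping[str, float]],
) -> dict:
    """Reconstruct every character; return one row per *labeled* internal
    node.

    ``discrete_matrix``: character name -> {tip label: state/set/None};
    ``continuous_matrix``: trait name -> {tip label: value/None}.
    Row cells hold the state (string) for unambiguous nodes, a
    '|'-joined sorted list for equivocal ones, and floats for continuous
    traits.  Deterministic.
    """
    recs = {
        name: parsimony_asr(tree, states, name)
        for name, states in discrete_matrix.items()
    }
    cont = {
        name: brownian_asr(tree, values, name)
        for name, values in continuous_matrix.items()
    }
    rows: dict[str, dict] = {}
    for node in tree.preorder_internal_node_iter():
        if node.label is None:
            continue
        row: dict = {}
        for name, rec in recs.items():
            s = rec.node_states[node.label]
            row[name] = "|".join(sorted(s))
        for name, rec in cont.items():
            row[name] = rec.node_states.get(node.label)
        rows[node.label] = row
    return {"nodes": rows, "discrete": recs, "continuous": cont}


def simulate_brownian(
    tree: dendropy.Tree, root_value: float, sigma: float, rng: np.random.Generator
) -> dict[str, float]:
    """Simulate one Brownian realization; returns tip label -> value.

    Used for estimator-calibration experiments (root recovery) and as an
    independent check of the GLS reconstruction.
    """
    values: dict[dendropy.Node, float] = {tree.seed_node: root_value}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[node.parent_node]
        values[node] = parent + rng.normal(0.0, sigma * math.sqrt(node.edge.length))
    return {
        leaf.taxon.label: values[leaf] for leaf in tree.leaf_node_iter()
    }
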