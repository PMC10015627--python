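"""Branch regime paintings: a discrete state on every branch of a tree.

State coding throughout the package: 0 = outcrosser (dioecious),
1 = selfer (androdioecious). A painting assigns each branch the state at
its child end, plus a root state, and remembers how it was produced
(observed tips / argmax of marginals / simulated) and where ties were
broken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .tree import Phylogeny

OUTCROSSER = 0
SELFER = 1

STATE_NAMES = {OUTCROSSER: "outcrosser", SELFER: "selfer"}
STATE_CODES = {v: k for k, v in STATE_NAMES.items()}


@dataclass
class RegimePainting:
    states: dict[int, int]  # child-node id -> state of the branch above it
    root_state: int
    provenance: str = "unspecified"
    ties: set[int] = field(default_factory=set)

    def branch_state(self, child_id: int) -> int | None:
        return self.states.get(child_id)

    def node_state(self, tree: Phylogeny, node_id: int) -> int:
        """State at a node: its branch state, or the root state at the root."""
        if node_id == tree.root:
            return self.root_state
        s = self.states.get(node_id)
        if s is None:
            raise KeyError(f"branch above node {node_id} is not painted")
        return s

    def validate(self, tree: Phylogeny, tip_states: dict[str, int] | None = None) -> None:
        for n in tree.nodes:
            if n.parent is not None and n.id not in self.states:
                raise ValueError(f"branch above node {n.id} unpainted")
        if tip_states is not None:
            for t in tree.tips():
                if t.label in tip_states and tip_states[t.label] is not None:
                    if self.states[t.id] != tip_states[t.label]:
                        raise ValueError(
                            f"tip branch {t.label} painted {self.states[t.id]} "
                            f"but observed {tip_states[t.label]}"
                        )

    def states_present(self) -> set[int]:
        return set(self.states.values()) | {self.root_state}


def uniform_painting(tree: Phylogeny, state: int, provenance: str = "uniform") -> RegimePainting:
    return RegimePainting(
        {n.id: state for n in tree.nodes if n.parent is not None}, state, provenance
    )
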