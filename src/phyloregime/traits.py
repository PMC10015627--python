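"""Tip trait tables (genome size in Mb, repeat content in % of genome, GC%)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .tree import Phylogeny


@dataclass
class TraitTable:
    """One continuous trait, one value per taxon.

    ``node_values`` optionally carries the simulated truth at internal
    nodes (keyed by node id) when the table came from the generator; it is
    never read by estimators.
    """

    name: str
    values: dict[str, float]
    units: str = ""
    node_values: dict[int, float] | None = field(default=None, repr=False)

    def validate(self, tree: Phylogeny) -> None:
        tips = set(tree.tip_labels())
        unknown = set(self.values) - tips
        if unknown:
            raise ValueError(f"trait taxa not in tree: {sorted(unknown)}")
        for k, v in self.values.items():
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"non-finite trait value for {k}")

    def vector(self, labels: list[str]) -> list[float]:
        return [self.values[l] for l in labels]


def read_traits_tsv(path: str | Path) -> dict[str, TraitTable]:
    """Read a taxon-by-trait TSV (first column taxon) into one table per column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {
        str(col): TraitTable(str(col), {str(k): float(v) for k, v in df[col].dropna().items()})
        for col in df.columns
    }


def write_traits_tsv(tables: dict[str, TraitTable], path: str | Path) -> None:
    df = pd.DataFrame({name: pd.Series(t.values) for name, t in tables.items()})
    df.index.name = "taxon"
    df.sort_index().to_csv(path, sep="\t")


def read_states_tsv(path: str | Path) -> dict[str, int]:
    """Read taxon -> reproductive mode (selfer/outcrosser or 1/0)."""
    from .painting import STATE_CODES

    df = pd.read_csv(path, sep="\t", header=None, names=["taxon", "state"], comment="#")
    out: dict[str, int] = {}
    for _, row in df.iterrows():
        raw = str(row["state"]).strip().lower()
        if raw in STATE_CODES:
            out[str(row["taxon"])] = STATE_CODES[raw]
        elif raw in {"0", "1"}:
            out[str(row["taxon"])] = int(raw)
        else:
            raise ValueError(f"unrecognized state {row['state']!r} for {row['taxon']}")
    return out


def write_states_tsv(states: dict[str, int], path: str | Path) -> None:
    from .painting import STATE_NAMES

    with open(path, "w") as fh:
        for taxon in sorted(states):
            fh.write(f"{taxon}\t{STATE_NAMES[states[taxon]]}\n")
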