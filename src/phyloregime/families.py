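"""Gene-family (orthogroup) count matrices in CAFE-like layout."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .tree import Phylogeny


@dataclass
class GeneFamilyMatrix:
    """family x taxon non-negative integer counts.

    ``counts`` is indexed by family id with one column per taxon.
    High-confidence families are those present (count >= 1) in at least
    half of the taxa — the filter applied before turnover fitting.
    """

    counts: pd.DataFrame
    descriptions: dict[str, str] = field(default_factory=dict)
    extinct_flags: dict[str, bool] = field(default_factory=dict)
    # simulated truth at internal nodes (family x node id), set by the
    # generator on request; never read by estimators
    node_counts: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative gene-family counts")
        self.counts = self.counts.astype(int)

    @property
    def families(self) -> list[str]:
        return [str(f) for f in self.counts.index]

    @property
    def taxa(self) -> list[str]:
        return [str(t) for t in self.counts.columns]

    def validate(self, tree: Phylogeny) -> None:
        missing = set(tree.tip_labels()) - set(self.taxa)
        if missing:
            raise ValueError(f"tree tips without counts: {sorted(missing)}")

    def high_confidence(self) -> "GeneFamilyMatrix":
        present = (self.counts >= 1).sum(axis=1)
        keep = present >= len(self.taxa) / 2
        sub = self.counts.loc[keep]
        return GeneFamilyMatrix(
            sub,
            {f: d for f, d in self.descriptions.items() if f in sub.index},
            {f: e for f, e in self.extinct_flags.items() if f in sub.index},
        )

    def drop(self, exclude: set[str]) -> "GeneFamilyMatrix":
        keep = [f for f in self.counts.index if f not in exclude]
        return GeneFamilyMatrix(
            self.counts.loc[keep],
            {f: d for f, d in self.descriptions.items() if f in keep},
            {f: e for f, e in self.extinct_flags.items() if f in keep},
        )


def read_families_tsv(path: str | Path) -> GeneFamilyMatrix:
    """Read the CAFE-like layout: Desc TAB FamilyID TAB one column per taxon."""
    df = pd.read_csv(path, sep="\t")
    desc_col, id_col = df.columns[0], df.columns[1]
    counts = df.set_index(id_col).drop(columns=[desc_col])
    counts.index = counts.index.astype(str)
    desc = {str(f): str(d) for f, d in zip(df[id_col], df[desc_col])}
    return GeneFamilyMatrix(counts, desc)


def write_families_tsv(matrix: GeneFamilyMatrix, path: str | Path) -> None:
    df = matrix.counts.copy()
    df.insert(0, "FamilyID", df.index)
    df.insert(0, "Desc", [matrix.descriptions.get(f, "na") for f in df.index])
    df.to_csv(path, sep="\t", index=False)
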