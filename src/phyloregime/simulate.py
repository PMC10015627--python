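"""Synthetic data with the statistical structure the analysis assumes.

Every stage of the pipeline is testable without genome-derived inputs:
this module generates regime histories on a tree (two-state Markov
switching), continuous traits under Brownian motion or regime-dependent
Ornstein--Uhlenbeck dynamics (exact transition densities, no Euler
discretization), and gene-family count matrices under a critical linear
birth--death process with per-gene duplication and loss at equal rate
lambda.

``make_study_fixture`` builds the default study design: an 11-tip,
height-1 ultrametric binary tree shaped like the Elegans group of
*Caenorhabditis* — four self-fertile tips (C. elegans, C. briggsae, two
C. tropicalis strains) arising from three independent selfing origins
among seven outcrossing relatives — with a genome-size-like trait, a
percent-scale transposable-element trait under a two-optimum OU process,
and a gene-family matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .families import GeneFamilyMatrix, write_families_tsv
from .painting import OUTCROSSER, SELFER, RegimePainting
from .traits import TraitTable, write_states_tsv, write_traits_tsv
from .tree import Phylogeny, read_newick, write_newick

__all__ = [
    "SimulationSpec",
    "simulate_regime_history",
    "simulate_trait",
    "simulate_gene_families",
    "shifted_geometric_prior",
    "make_study_fixture",
    "elegans_like_tree",
    "FixtureBundle",
]


@dataclass
class SimulationSpec:
    """Parameters of the generative model.

    Rates are per unit branch length; trait units follow the trait being
    simulated (Mb for genome size, % of genome for repeat classes).
    """

    seed: int
    trait_model: str = "OU"  # {"BM", "OU"}
    y0: float = 0.0
    alpha: float = math.log(2) / 0.05  # rate of adaptation; default t1/2 = 5% of height
    sigma2: float = 2 * (math.log(2) / 0.05) * 1.35  # default stationary variance 1.35
    theta: dict[int, float] = field(default_factory=lambda: {OUTCROSSER: 6.19, SELFER: 2.97})
    q01: float = 0.1
    q10: float = 0.1
    lam: float = 0.43
    error_eps: float = 0.0
    n_families: int = 1000
    root_count_mean: float = 5.0

    def __post_init__(self) -> None:
        if self.trait_model not in {"BM", "OU"}:
            raise ValueError(f"unknown trait model {self.trait_model!r}")
        if self.trait_model == "OU" and not self.alpha > 0:
            raise ValueError("OU requires alpha > 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not (0 <= self.error_eps < 0.5):
            raise ValueError("error probability must lie in [0, 0.5)")
        for r in (self.q01, self.q10, self.lam):
            if r < 0 or not math.isfinite(r):
                raise ValueError("rates must be finite and non-negative")

    @property
    def stationary_variance(self) -> float:
        return self.sigma2 / (2 * self.alpha)


# -- regime histories ---------------------------------------------------


def simulate_regime_history(
    tree: Phylogeny, q01: float, q10: float, root_state: int, seed: int
) -> RegimePainting:
    """Evolve a two-state Markov chain along the tree.

    Switch events are placed by exponential waiting times; each branch is
    assigned the state at its child end.
    """
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    rates = {0: q01, 1: q10}
    states: dict[int, int] = {}
    node_state = {tree.root: root_state}
    for n in tree.preorder():
        if n.parent is None:
            continue
        s, remaining = node_state[n.parent], n.length
        while True:
            rate = rates[s]
            if rate == 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait >= remaining:
                break
            remaining -= wait
            s = 1 - s
        states[n.id] = s
        node_state[n.id] = s
    return RegimePainting(states, root_state, provenance="simulated")


# -- continuous traits --------------------------------------------------


def simulate_trait(
    tree: Phylogeny,
    painting: RegimePainting | None,
    spec: SimulationSpec,
    seed: int | None = None,
    name: str = "trait",
    units: str = "",
) -> TraitTable:
    """Simulate a continuous trait down the tree.

    BM: child ~ Normal(parent, sigma2 * t). OU within a constant-regime
    branch: child ~ Normal(parent * e^{-a t} + theta (1 - e^{-a t}),
    v (1 - e^{-2 a t})) with v = sigma2 / (2 alpha) — the exact transition
    density. A zero-length branch copies the parent value exactly.

    Returns tip values; the simulated truth at every node is kept on
    ``TraitTable.node_values`` for calibration experiments.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    if spec.trait_model == "OU":
        if painting is None:
            raise ValueError("OU simulation requires a regime painting")
        missing = {s for s in painting.states_present() if s not in spec.theta}
        if missing:
            raise ValueError(f"no optimum defined for regime state(s) {sorted(missing)}")
    node_values: dict[int, float] = {tree.root: spec.y0}
    for n in tree.preorder():
        if n.parent is None:
            continue
        parent, t = node_values[n.parent], n.length
        if spec.trait_model == "BM":
            val = parent if t == 0 else rng.normal(parent, math.sqrt(spec.sigma2 * t))
        else:
            a, v = spec.alpha, spec.stationary_variance
            th = spec.theta[painting.node_state(tree, n.id)]
            if t == 0:
                val = parent
            else:
                decay = math.exp(-a * t)
                mean = parent * decay + th * (1 - decay)
                sd = math.sqrt(v * (1 - decay * decay))
                val = rng.normal(mean, sd)
        node_values[n.id] = val
    tips = {n.label: node_values[n.id] for n in tree.tips()}
    return TraitTable(name, tips, units, node_values=node_values)


# -- gene families ------------------------------------------------------


def shifted_geometric_prior(mean: float = 5.0):
    """Root-count prior on {1, 2, ...} with the given mean (default 5)."""
    if mean <= 1:
        raise ValueError("mean must exceed 1")
    p = 1.0 / mean

    def draw(rng: np.random.Generator) -> int:
        return int(rng.geometric(p))

    return draw


def _evolve_bd(n: int, t: float, lam: float, rng: np.random.Generator) -> int:
    """Critical linear birth--death: per-gene birth and death each at rate lam."""
    if lam == 0 or t == 0:
        return n
    remaining = t
    while n > 0:
        wait = rng.exponential(1.0 / (2 * lam * n))
        if wait >= remaining:
            break
        remaining -= wait
        n += 1 if rng.random() < 0.5 else -1
    return n


def simulate_gene_families(
    tree: Phylogeny,
    lam_map,
    root_prior=None,
    n_families: int = 1000,
    eps: float = 0.0,
    seed: int = 0,
    selfer_loss_survival: float | None = None,
    painting: RegimePainting | None = None,
    record_node_counts: bool = False,
) -> GeneFamilyMatrix:
    """Simulate gene-family counts under the per-gene birth--death model.

    ``lam_map`` is either a scalar rate or a dict mapping child-node ids to
    branch-specific rates. Tip counts are perturbed by the symmetric +/-1
    miscount model with probability ``eps`` (counts of 0 are never
    perturbed: an absent family yields no gene calls to miscount).
    Families extinct at every tip are retained and flagged.

    ``selfer_loss_survival`` plants directed losses for classifier
    calibration: on branches painted selfer, each surviving gene is
    additionally retained with this probability (binomial thinning). It is
    not part of the null model.
    """
    if not (0 <= eps < 0.5):
        raise ValueError("eps must lie in [0, 0.5)")
    if not tree.is_binary() or not tree.is_ultrametric(1e-6):
        raise ValueError("gene-family simulation expects an ultrametric binary tree")
    rng = np.random.default_rng(seed)
    if root_prior is None:
        root_prior = shifted_geometric_prior()
    get_lam = (lambda nid: lam_map[nid]) if isinstance(lam_map, dict) else (lambda nid: lam_map)

    order = [n for n in tree.preorder()]
    tip_labels = [n.label for n in tree.tips()]
    rows = np.zeros((n_families, len(tip_labels)), dtype=int)
    node_rows: list[dict[int, int]] = []
    extinct: dict[str, bool] = {}
    for i in range(n_families):
        counts = {tree.root: root_prior(rng)}
        for n in order:
            if n.parent is None:
                continue
            c = _evolve_bd(counts[n.parent], n.length, get_lam(n.id), rng)
            if (
                selfer_loss_survival is not None
                and painting is not None
                and painting.branch_state(n.id) == SELFER
                and c > 0
            ):
                c = int(rng.binomial(c, selfer_loss_survival))
            counts[n.id] = c
        if record_node_counts:
            node_rows.append(dict(counts))
        tip_counts = [counts[tree.tip_id(l)] for l in tip_labels]
        if eps > 0:
            for j, c in enumerate(tip_counts):
                if c >= 1:
                    u = rng.random()
                    if u < eps / 2:
                        tip_counts[j] = c - 1
                    elif u < eps:
                        tip_counts[j] = c + 1
        rows[i] = tip_counts
        extinct[f"F{i:05d}"] = all(c == 0 for c in tip_counts)
    index = [f"F{i:05d}" for i in range(n_families)]
    counts_df = pd.DataFrame(rows, index=index, columns=tip_labels)
    out = GeneFamilyMatrix(counts_df, {}, extinct)
    if record_node_counts:
        out.node_counts = pd.DataFrame(node_rows, index=index)  # simulated truth
    return out


def random_binary_tree(
    n_tips: int, seed: int, ultrametric: bool = False, height: float = 1.0
) -> Phylogeny:
    """A random binary tree by successive random joins.

    Branch lengths are Exponential(mean 0.5); with ``ultrametric`` the tree
    is built as a coalescent-style ladder of uniform join depths and
    rescaled to the requested height.
    """
    rng = np.random.default_rng(seed)
    from .tree import Node, Phylogeny as _P

    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not ultrametric:
        nodes = [Node(i, f"t{i + 1}", None, float(rng.exponential(0.5))) for i in range(n_tips)]
        active = list(range(n_tips))
        while len(active) > 1:
            i, j = rng.choice(len(active), 2, replace=False)
            a, b = active[max(i, j)], active[min(i, j)]
            nid = len(nodes)
            length = float(rng.exponential(0.5)) if len(active) > 2 else 0.0
            nodes.append(Node(nid, None, None, length, [a, b]))
            nodes[a].parent = nid
            nodes[b].parent = nid
            active = [x for x in active if x not in (a, b)] + [nid]
        root = active[0]
        nodes[root].length = 0.0
        return _P(nodes, root)
    # ultrametric: draw increasing join depths, hang tips at height
    depths = np.sort(rng.uniform(0, 1, n_tips - 1))
    nodes = [Node(i, f"t{i + 1}", None, 0.0) for i in range(n_tips)]
    node_depth = {i: 1.0 for i in range(n_tips)}
    active = list(range(n_tips))
    for d in depths[::-1]:
        i, j = rng.choice(len(active), 2, replace=False)
        a, b = active[max(i, j)], active[min(i, j)]
        nid = len(nodes)
        nodes.append(Node(nid, None, None, 0.0, [a, b]))
        for child in (a, b):
            nodes[child].parent = nid
            nodes[child].length = (node_depth[child] - d) * height
        node_depth[nid] = float(d)
        active = [x for x in active if x not in (a, b)] + [nid]
    root = active[0]
    nodes[root].length = 0.0
    tree = _P(nodes, root)
    # shift so the root sits at depth 0
    root_depth = node_depth[root] * height
    for c in tree.nodes[root].children:
        tree.nodes[c].length += root_depth
    return _P(tree.nodes, root)


# -- the study fixture --------------------------------------------------

_ELEGANS_NEWICK = (
    "(C_sinica:1.0,((C_elegans:0.55,C_inopinata:0.55):0.30,"
    "((C_briggsae:0.5,C_nigoni:0.5):0.25,"
    "((C_tropicalis_JU1373:0.1,C_tropicalis_NIC58:0.1):0.55,"
    "(C_latens:0.45,(C_remanei_PX506:0.2,"
    "(C_remanei_PX356:0.08,C_remanei_PX439:0.08):0.12):0.25):0.20):0.10):0.10):0.15);"
)

SELFER_TIPS = {"C_elegans", "C_briggsae", "C_tropicalis_JU1373", "C_tropicalis_NIC58"}


def elegans_like_tree() -> Phylogeny:
    """The 11-tip, height-1.0, ultrametric binary fixture tree."""
    return read_newick(_ELEGANS_NEWICK)


def elegans_like_painting(tree: Phylogeny) -> RegimePainting:
    """Three independent selfing origins: the C. elegans and C. briggsae
    terminal branches and the C. tropicalis two-strain clade (stem plus
    both strain branches). Everything else, including the root, outcrosses.
    """
    states: dict[int, int] = {}
    trop = {tree.tip_id("C_tropicalis_JU1373"), tree.tip_id("C_tropicalis_NIC58")}
    trop_stem = tree.mrca(*trop)
    selfer_branches = {tree.tip_id("C_elegans"), tree.tip_id("C_briggsae"), trop_stem} | trop
    for n in tree.nodes:
        if n.parent is not None:
            states[n.id] = SELFER if n.id in selfer_branches else OUTCROSSER
    return RegimePainting(states, OUTCROSSER, provenance="fixture")


@dataclass
class FixtureBundle:
    tree: Phylogeny
    painting: RegimePainting
    genome_size: TraitTable
    te_percent: TraitTable
    families: GeneFamilyMatrix
    seed: int

    def tip_states(self) -> dict[str, int]:
        return {t.label: self.painting.states[t.id] for t in self.tree.tips()}


def make_study_fixture(
    seed: int,
    n_families: int = 1000,
    lam: float = 0.43,
    truncate_te_at_zero: bool = False,
) -> FixtureBundle:
    """Generate the full study fixture from one seed.

    The TE-like percent trait evolves under a two-optimum OU process with
    theta_selfer = 2.97, theta_outcrosser = 6.19 (percent of genome),
    phylogenetic half-life 5% of tree height and stationary variance 1.35;
    the genome-size-like trait under BM from 150 Mb with sigma^2 = 2500.
    Gene families evolve with lambda = 0.43 per gene per unit length from a
    shifted-geometric(mean 5) root prior. Percent traits are simulated
    untruncated (the inference model is Gaussian); pass
    ``truncate_te_at_zero`` for a display-only non-negative view.
    """
    tree = elegans_like_tree()
    painting = elegans_like_painting(tree)
    ss = np.random.SeedSequence(seed)
    s_gs, s_te, s_fam = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))

    gs_spec = SimulationSpec(seed=s_gs, trait_model="BM", y0=150.0, sigma2=2500.0)
    genome_size = simulate_trait(tree, None, gs_spec, name="genome_size_mb", units="Mb")

    te_spec = SimulationSpec(seed=s_te, trait_model="OU", y0=6.19)
    te = simulate_trait(tree, painting, te_spec, name="te_percent", units="% of genome")
    if truncate_te_at_zero:
        te = TraitTable(te.name, {k: max(0.0, v) for k, v in te.values.items()}, te.units)

    families = simulate_gene_families(tree, lam, n_families=n_families, seed=s_fam)
    return FixtureBundle(tree, painting, genome_size, te, families, seed)


def write_fixture(bundle: FixtureBundle, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(write_newick(bundle.tree) + "\n")
    write_states_tsv(bundle.tip_states(), out / "regimes.tsv")
    write_traits_tsv(
        {t.name: t for t in (bundle.genome_size, bundle.te_percent)}, out / "traits.tsv"
    )
    write_families_tsv(bundle.families, out / "families.tsv")
    manifest = {
        "seed": bundle.seed,
        "n_tips": bundle.tree.n_tips,
        "height": bundle.tree.height(),
        "selfer_tips": sorted(SELFER_TIPS),
        "n_families": len(bundle.families.families),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
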