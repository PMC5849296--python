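"""Synthetic fossil datasets with the statistical structure the pipeline
assumes, so every stage runs and is testable without any external data.

One configuration drives three coupled products:

* an occurrence table — first appearances uniform over the configured time
  span, range durations exponential with the configured extinction
  intensity (mean duration = 1 / intensity), time-bin labels from the
  range midpoint;
* a tree consistent with the occurrences (older taxa attach deeper:
  stepwise random attachment in order of decreasing first appearance),
  time-calibrated with the package's own rule;
* trait matrices on that tree — continuous functional characters by
  Brownian motion (variance proportional to path length), discrete ones by
  a continuous-time Markov chain (jump times Poisson along each branch),
  plus a discrete+continuous phylogenetic character matrix in the same
  TNT-flavoured dialect the reader accepts, and a uniform missingness mask.

The functional characters carry the exact schema of the study inputs —
habitat (continental / brackish / marine), wingspan, jaw curvature,
cervical elongation, hindlimb elongation, ulna:humerus and
metacarpal IV:humerus — so the pipeline's readers are exercised verbatim.
All randomness flows from one mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chronogram import calibrate_tree
from .io_formats import (CharacterMatrix, CharacterSpec, FunctionalMatrix,
                         Node, OccurrenceTable, TreeDocument)

__all__ = ["SimulationConfig", "simulate_occurrences",
           "simulate_tree_and_traits", "FUNCTIONAL_SCHEMA"]

#: The seven functional characters of the study design.
FUNCTIONAL_SCHEMA: dict[str, dict] = {
    "habitat": {"kind": "categorical",
                "states": ["continental", "brackish", "marine"]},
    "wingspan": {"kind": "continuous", "unit": "m"},
    "jaw_curvature": {"kind": "categorical", "states": ["0", "1", "2"]},
    "cervical_elongation": {"kind": "categorical", "states": ["0", "1", "2"]},
    "hindlimb_elongation": {"kind": "categorical", "states": ["0", "1", "2"]},
    "ulna_humerus": {"kind": "continuous", "unit": "ratio"},
    "metacarpal4_humerus": {"kind": "continuous", "unit": "ratio"},
}

#: Default study bins: Santonian-Campanian vs Maastrichtian (GTS2012).
DEFAULT_BINS = (("Santonian-Campanian", 86.3, 72.1),
                ("Maastrichtian", 72.1, 66.0))


@dataclass
class SimulationConfig:
    """Knobs of the generator; rates per Ma, ages in Ma, seed mandatory."""

    n_taxa: int = 30
    span: tuple[float, float] = (86.3, 66.0)  # (oldest, youngest)
    bins: tuple = DEFAULT_BINS
    extinction_rate: float = 0.5       # 1/mean range duration
    brownian_sigma2: float = 0.02      # per-Ma variance of continuous traits
    transition_rate: float = 0.05      # CTMC jumps per Ma, discrete traits
    n_discrete_states: int = 3
    n_phylo_discrete: int = 40         # phylogenetic matrix columns
    n_phylo_continuous: int = 4
    missing_fraction: float = 0.1
    min_branch: float = 1.0            # calibration offset for trait branches
    seed: int = field(default=None)  # type: ignore[assignment]
    #: optional separate stream for trait evolution: two configs sharing
    #: ``seed`` but differing here give the same occurrences and topology
    #: with independent trait draws (paired simulation designs)
    trait_seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must be in [0, 1)")
        for rate in (self.extinction_rate, self.brownian_sigma2,
                     self.transition_rate):
            if rate < 0:
                raise ValueError("rates must be non-negative")
        if self.span[0] <= self.span[1]:
            raise ValueError("degenerate time span")


def _bin_label(cfg: SimulationConfig, midpoint: float) -> str:
    for label, old, young in cfg.bins:
        if old >= midpoint > young:
            return label
    return "other"


def simulate_occurrences(cfg: SimulationConfig) -> OccurrenceTable:
    """Per-taxon [fad, lad]: fad uniform over the span, duration
    exponential with mean 1/extinction_rate, lad floored at 0."""
    rng = np.random.default_rng(cfg.seed)
    old, young = cfg.span
    fads = rng.uniform(young, old, cfg.n_taxa)
    if cfg.extinction_rate > 0:
        durations = rng.exponential(1.0 / cfg.extinction_rate, cfg.n_taxa)
    else:
        durations = np.zeros(cfg.n_taxa)
    lads = np.maximum(fads - durations, 0.0)
    taxa = [f"t{i + 1:03d}" for i in range(cfg.n_taxa)]
    mid = (fads + lads) / 2
    df = pd.DataFrame({
        "fad": fads, "lad": lads, "override_fad": np.nan,
        "bin": [_bin_label(cfg, m) for m in mid],
    }, index=pd.Index(taxa, name="taxon"))
    return OccurrenceTable(df)


def _random_topology(taxa_oldest_first: list[str],
                     rng: np.random.Generator) -> TreeDocument:
    """Stepwise random attachment, oldest taxa first, so older taxa sit
    deeper in the tree on average."""
    root = Node(children=[Node(name=taxa_oldest_first[0]),
                          Node(name=taxa_oldest_first[1])])
    for name in taxa_oldest_first[2:]:
        edges = []
        for node in root.preorder():
            for child in node.children:
                edges.append((node, child))
        parent, child = edges[rng.integers(len(edges))]
        mid = Node(children=[child, Node(name=name)])
        parent.children[parent.children.index(child)] = mid
    return TreeDocument(root)


def _branch_durations(tree: TreeDocument) -> dict[int, float]:
    """id(node) -> length of the edge above it, from calibrated ages."""
    out = {}
    parents = tree.parents()
    for node in tree.root.preorder():
        p = parents.get(id(node))
        out[id(node)] = 0.0 if p is None else max(p.age - node.age, 0.0)
    return out


def _brownian_column(tree: TreeDocument, durations, sigma2: float,
                     root_value: float, rng) -> dict[str, float]:
    values = {id(tree.root): root_value}
    parents = tree.parents()
    for node in tree.root.preorder():
        if id(node) not in values:
            t = durations[id(node)]
            values[id(node)] = values[id(parents[id(node)])] + \
                rng.normal(0.0, np.sqrt(max(sigma2 * t, 0.0)))
    return {n.name: values[id(n)] for n in tree.leaves()}


def _ctmc_column(tree: TreeDocument, durations, rate: float, k: int,
                 rng) -> dict[str, int]:
    states = {id(tree.root): int(rng.integers(k))}
    parents = tree.parents()
    for node in tree.root.preorder():
        if id(node) not in states:
            s = states[id(parents[id(node)])]
            n_jumps = rng.poisson(rate * durations[id(node)])
            for _ in range(n_jumps):
                s = (s + 1 + int(rng.integers(k - 1))) % k
            states[id(node)] = s
    return {n.name: states[id(n)] for n in tree.leaves()}


def _apply_missing_mask(df: pd.DataFrame, fraction: float, rng) -> pd.DataFrame:
    """Uniform Bernoulli mask, then guarantee every row and column keeps at
    least one observation (re-reveal the first masked cell if needed)."""
    out = df.copy()
    mask = rng.random(out.shape) < fraction
    out = out.mask(pd.DataFrame(mask, index=out.index, columns=out.columns))
    for i in range(out.shape[0]):
        if out.iloc[i].isna().all():
            out.iloc[i, 0] = df.iloc[i, 0]
    for j in range(out.shape[1]):
        if out.iloc[:, j].isna().all():
            out.iloc[0, j] = df.iloc[0, j]
    return out


def simulate_tree_and_traits(cfg: SimulationConfig, occ: OccurrenceTable
                             ) -> tuple[TreeDocument, FunctionalMatrix,
                                        CharacterMatrix]:
    """Tree + functional matrix + phylogenetic character matrix on the
    occurrences.  Topology, trait evolution and occurrence generation each
    use a separate stream derived from the seed; ``trait_seed`` (when set)
    re-seeds only the trait stream."""
    rng_topo = np.random.default_rng(cfg.seed + 1)
    order = sorted(occ.taxa, key=occ.fad, reverse=True)
    tree = _random_topology(order, rng_topo)
    rng = np.random.default_rng(
        (cfg.seed if cfg.trait_seed is None else cfg.trait_seed) + 2)
    tt = calibrate_tree(tree, occ, min_branch=cfg.min_branch)
    durations = _branch_durations(tt.tree)

    # functional matrix in the exact study schema
    cols: dict[str, list] = {}
    s2 = cfg.brownian_sigma2
    wingspan = _brownian_column(tt.tree, durations, s2, np.log(3.0), rng)
    ulna = _brownian_column(tt.tree, durations, s2, np.log(1.8), rng)
    mc4 = _brownian_column(tt.tree, durations, s2, np.log(2.2), rng)
    taxa = occ.taxa
    cols["wingspan"] = [float(np.exp(wingspan[t])) for t in taxa]
    cols["ulna_humerus"] = [float(np.exp(ulna[t])) for t in taxa]
    cols["metacarpal4_humerus"] = [float(np.exp(mc4[t])) for t in taxa]
    for name in ("habitat", "jaw_curvature", "cervical_elongation",
                 "hindlimb_elongation"):
        states = FUNCTIONAL_SCHEMA[name]["states"]
        col = _ctmc_column(tt.tree, durations, cfg.transition_rate,
                           len(states), rng)
        cols[name] = [states[col[t]] for t in taxa]
    fdata = pd.DataFrame(cols, index=pd.Index(taxa, name="taxon"))
    fdata = fdata[list(FUNCTIONAL_SCHEMA)]
    fdata = _apply_missing_mask(fdata, cfg.missing_fraction, rng)
    fm = FunctionalMatrix(fdata, dict(FUNCTIONAL_SCHEMA),
                          bins=occ.table["bin"].copy())

    # phylogenetic character matrix (discrete CTMC + continuous BM columns)
    specs: list[CharacterSpec] = []
    raw_cols: list[dict[str, object]] = []
    for _ in range(cfg.n_phylo_discrete):
        specs.append(CharacterSpec("unordered"))
        col = _ctmc_column(tt.tree, durations, cfg.transition_rate * 4,
                           cfg.n_discrete_states, rng)
        raw_cols.append({t: frozenset({col[t]}) for t in taxa})
    for _ in range(cfg.n_phylo_continuous):
        specs.append(CharacterSpec("continuous"))
        col = _brownian_column(tt.tree, durations, s2, 0.0, rng)
        raw_cols.append({t: float(col[t]) for t in taxa})
    cells = [[raw_cols[j][t] for j in range(len(raw_cols))] for t in taxa]
    for i in range(len(taxa)):
        for j in range(len(raw_cols)):
            if rng.random() < cfg.missing_fraction and i > 0:
                cells[i][j] = None
    cm = CharacterMatrix(list(taxa), specs, cells)
    return tree, fm, cm
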