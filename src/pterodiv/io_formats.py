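"""Readers and writers for the formats the pipeline touches.

Trees travel as newick (parsed with dendropy, held in a light rooted-node
structure that can carry ages), stratigraphic occurrences and functional
trait tables as CSV with a YAML schema sidecar, and phylogenetic
character-taxon matrices in a documented TNT-flavoured block dialect that
mixes discrete and continuous partitions.

Conventions that hold everywhere downstream:

* ages are in Ma before present — larger numbers are older;
* missing values in CSV are empty cells or ``NA``;
* in character matrices ``?`` is missing and ``-`` inapplicable; both are
  scored as missing but the distinction is preserved for reporting.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Node",
    "TreeDocument",
    "OccurrenceTable",
    "CharacterSpec",
    "CharacterMatrix",
    "FunctionalMatrix",
    "read_newick",
    "write_newick",
    "read_character_matrix",
    "write_character_matrix",
    "read_occurrences",
    "read_functional_matrix",
    "read_schema",
]

MISSING = "?"
INAPPLICABLE = "-"


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass(eq=False)  # identity semantics: tree surgery indexes nodes by `is`
class Node:
    """A node of a rooted tree; ``length`` is the edge above, ``age`` in Ma."""

    name: str | None = None
    length: float | None = None
    age: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def copy(self) -> "Node":
        return Node(self.name, self.length, self.age,
                    [c.copy() for c in self.children])


@dataclass
class TreeDocument:
    """A rooted tree of named leaves, optionally with branch lengths or ages."""

    root: Node

    def leaves(self) -> list[Node]:
        return [n for n in self.root.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def postorder(self):
        return self.root.postorder()

    def preorder(self):
        return self.root.preorder()

    def parents(self) -> dict[int, Node]:
        """Map id(child) -> parent node."""
        out: dict[int, Node] = {}
        for node in self.root.preorder():
            for child in node.children:
                out[id(child)] = node
        return out

    def copy(self) -> "TreeDocument":
        return TreeDocument(self.root.copy())

    def validate(self) -> None:
        names = self.leaf_names()
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names: {dupes}")
        for node in self.root.preorder():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length on {node.name!r}")
            if node.age is not None:
                for child in node.children:
                    if child.age is not None and child.age > node.age + 1e-9:
                        raise ValueError(
                            f"child age {child.age} exceeds parent age {node.age}")


def read_newick(text: str) -> TreeDocument:
    """Parse a newick string into a :class:`TreeDocument`.

    Branch lengths are optional and polytomies are allowed.  Raises
    :class:`ValueError` (with the parser's position information) on
    malformed input.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False)
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        return Node(name=label, length=dnode.edge.length,
                    children=[convert(c) for c in dnode.child_nodes()])

    doc = TreeDocument(convert(dtree.seed_node))
    doc.validate()
    return doc


def _newick_label(name: str | None) -> str:
    if name is None:
        return ""
    if re.search(r"[\s(),:;\[\]']", name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: TreeDocument, lengths_from_ages: bool = False) -> str:
    """Serialise a tree to newick.

    A single leaf is written as ``A;``.  When ``lengths_from_ages`` is set
    (or the tree carries ages but no lengths) each branch length is emitted
    as ``parent_age - child_age``.
    """
    has_ages = all(n.age is not None for n in tree.postorder())
    has_lengths = any(n.length is not None for n in tree.postorder())
    use_ages = lengths_from_ages or (has_ages and not has_lengths)

    def fmt_len(x: float) -> str:
        return format(x, ".12g")

    def render(node: Node, parent: Node | None) -> str:
        if node.is_leaf:
            out = _newick_label(node.name)
        else:
            out = "(" + ",".join(render(c, node) for c in node.children) + ")"
            out += _newick_label(node.name)
        if use_ages and parent is not None:
            out += ":" + fmt_len(parent.age - node.age)
        elif not use_ages and node.length is not None and parent is not None:
            out += ":" + fmt_len(node.length)
        return out

    return render(tree.root, None) + ";"


# ---------------------------------------------------------------------------
# occurrences
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceTable:
    """Per-taxon stratigraphic ranges in Ma: first (fad) and last (lad)
    appearance, with an optional curatorial first-appearance override that
    replaces the fad before any computation (used for taxa whose own record
    is unconstrained and which borrow a relative's earliest occurrence).
    """

    table: pd.DataFrame  # index: taxon; columns fad, lad, override_fad, bin

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError(
                f"duplicate taxa: {sorted(t.index[t.index.duplicated()])}")
        bad = t[t["fad"] < t["lad"]]
        if len(bad):
            raise ValueError(
                "reversed ranges (fad < lad) for: " + ", ".join(bad.index))
        if (t["lad"] < 0).any():
            raise ValueError("negative ages")

    @property
    def taxa(self) -> list[str]:
        return list(self.table.index)

    def fad(self, taxon: str) -> float:
        """Effective first appearance (override applied when present)."""
        row = self.table.loc[taxon]
        ov = row.get("override_fad")
        if ov is not None and not pd.isna(ov):
            return float(ov)
        return float(row["fad"])

    def lad(self, taxon: str) -> float:
        return float(self.table.loc[taxon, "lad"])

    def ranges(self) -> pd.DataFrame:
        """Effective [fad, lad] per taxon as a DataFrame."""
        fads = [self.fad(t) for t in self.taxa]
        lads = [self.lad(t) for t in self.taxa]
        return pd.DataFrame({"fad": fads, "lad": lads}, index=self.taxa)

    def subset(self, taxa) -> "OccurrenceTable":
        return OccurrenceTable(self.table.loc[list(taxa)].copy())


def read_occurrences(source) -> OccurrenceTable:
    """Read a CSV of ``taxon,fad,lad[,override_fad][,bin]`` into an
    :class:`OccurrenceTable`.  Ages in Ma; ``fad >= lad`` is enforced.
    """
    df = pd.read_csv(source, na_values=["NA", ""], keep_default_na=False)
    required = {"taxon", "fad", "lad"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"occurrence table missing columns: {sorted(missing_cols)}")
    df = df.set_index("taxon")
    for col in ("fad", "lad", "override_fad"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    if "override_fad" not in df.columns:
        df["override_fad"] = np.nan
    return OccurrenceTable(df)


# ---------------------------------------------------------------------------
# phylogenetic character matrices (TNT-flavoured dialect)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CharacterSpec:
    """Type and weight of one phylogenetic character."""

    kind: str  # "unordered" | "ordered" | "continuous"
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in ("unordered", "ordered", "continuous"):
            raise ValueError(f"unknown character kind {self.kind!r}")
        if self.weight <= 0:
            raise ValueError("weights must be positive")


@dataclass
class CharacterMatrix:
    """Discrete + continuous phylogenetic characters.

    ``cells[i][j]`` is, for discrete characters, a frozenset of integer
    states (singleton for a plain coding, larger for polymorphism) or
    ``None`` for missing; for continuous characters a float or ``None``.
    ``inapplicable`` records which ``None`` cells were coded ``-`` rather
    than ``?`` — both score as missing, the distinction is for reporting.
    """

    taxa: list[str]
    characters: list[CharacterSpec]
    cells: list[list]
    inapplicable: set[tuple[int, int]] = field(default_factory=set)
    continuous_rescaled: bool = False

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in character matrix")
        n, k = len(self.taxa), len(self.characters)
        if len(self.cells) != n or any(len(r) != k for r in self.cells):
            raise ValueError("cell block does not match declared dimensions")
        for i, row in enumerate(self.cells):
            for j, cell in enumerate(row):
                if cell is None:
                    continue
                if self.characters[j].kind == "continuous":
                    if not math.isfinite(cell):
                        raise ValueError(f"non-finite continuous cell at ({i},{j})")
                elif not cell:
                    raise ValueError(f"empty state set at ({i},{j})")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def column(self, j: int) -> list:
        return [row[j] for row in self.cells]

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(list(self.taxa), list(self.characters),
                               [list(r) for r in self.cells],
                               set(self.inapplicable), self.continuous_rescaled)


_CELL_RE = re.compile(r"\[([0-9]+)\]|([0-9?\-])")


def _parse_discrete_row(text: str, where: str) -> list:
    cells: list = []
    pos = 0
    while pos < len(text):
        m = _CELL_RE.match(text, pos)
        if not m:
            raise ValueError(f"unknown symbol {text[pos]!r} in {where}")
        if m.group(1) is not None:
            cells.append(frozenset(int(c) for c in m.group(1)))
        else:
            sym = m.group(2)
            if sym == MISSING:
                cells.append(None)
            elif sym == INAPPLICABLE:
                cells.append(("-", None))  # tagged, resolved by caller
            else:
                cells.append(frozenset({int(sym)}))
        pos = m.end()
    return cells


def read_character_matrix(text: str, ordered=()) -> CharacterMatrix:
    """Parse a TNT/NEXUS-style character block.

    The dialect (a documented superset of what TNT emits for mixed
    partitions)::

        xread
        <nchar> <ntax>
        &[continuous]
        TaxonA  1.23 ? 0.5
        ...
        &[discrete]
        TaxonA  010?[01]-
        ...
        ;

    Partition headers may repeat and appear in any order; characters are
    numbered in order of appearance.  Discrete symbols are ``0``–``9``,
    ``?`` (missing), ``-`` (inapplicable) and ``[..]`` polymorphism.
    ``ordered`` lists the (global, 0-based) indices of discrete characters
    to score as ordered; all other discrete characters are unordered.
    """
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("'")]
    if not lines or lines[0].lower() != "xread":
        raise ValueError("character block must start with 'xread'")
    try:
        nchar, ntax = (int(tok) for tok in lines[1].split())
    except (IndexError, ValueError) as exc:
        raise ValueError("expected '<nchar> <ntax>' after xread") from exc

    taxa: list[str] = []
    rows: dict[str, list] = {}
    kinds: list[str] = []
    mode = "discrete"
    block_cols: int | None = None
    block_start = 0
    seen_in_block: set[str] = set()

    def open_block(new_mode: str) -> None:
        nonlocal mode, block_cols, block_start, seen_in_block
        mode = new_mode
        block_start = len(kinds)
        block_cols = None
        seen_in_block = set()

    for ln in lines[2:]:
        if ln == ";":
            break
        low = ln.lower()
        if low.startswith("&"):
            if "continuous" in low:
                open_block("continuous")
            elif "discrete" in low or "num" in low:
                open_block("discrete")
            else:
                raise ValueError(f"unknown partition header {ln!r}")
            continue
        parts = ln.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"malformed matrix row {ln!r}")
        taxon, body = parts
        if taxon in seen_in_block:
            raise ValueError(f"duplicate row for {taxon!r} in one partition")
        seen_in_block.add(taxon)
        if mode == "continuous":
            cells: list = []
            for tok in body.split():
                if tok == MISSING:
                    cells.append(None)
                elif tok == INAPPLICABLE:
                    cells.append(("-", None))
                else:
                    cells.append(float(tok))
        else:
            cells = _parse_discrete_row(body.replace(" ", ""), f"row {taxon!r}")
        if block_cols is None:
            block_cols = len(cells)
            kinds.extend([mode] * block_cols)
        elif len(cells) != block_cols:
            raise ValueError(
                f"row {taxon!r} has {len(cells)} cells, expected {block_cols}")
        if taxon not in rows:
            taxa.append(taxon)
            rows[taxon] = []
        if len(rows[taxon]) != block_start:
            raise ValueError(f"taxon {taxon!r} missing from an earlier partition")
        rows[taxon].extend(cells)

    if len(taxa) != ntax:
        raise ValueError(f"declared {ntax} taxa, found {len(taxa)}")
    if len(kinds) != nchar:
        raise ValueError(f"declared {nchar} characters, found {len(kinds)}")

    ordered = set(ordered)
    specs = []
    for j, kind in enumerate(kinds):
        if kind == "continuous":
            specs.append(CharacterSpec("continuous"))
        else:
            specs.append(CharacterSpec("ordered" if j in ordered else "unordered"))

    inapplicable: set[tuple[int, int]] = set()
    cell_rows: list[list] = []
    for i, taxon in enumerate(taxa):
        row = rows[taxon]
        if len(row) != nchar:
            raise ValueError(f"taxon {taxon!r} has {len(row)} cells, expected {nchar}")
        clean = []
        for j, cell in enumerate(row):
            if isinstance(cell, tuple):  # tagged inapplicable
                inapplicable.add((i, j))
                clean.append(None)
            else:
                clean.append(cell)
        cell_rows.append(clean)

    return CharacterMatrix(taxa, specs, cell_rows, inapplicable)


def write_character_matrix(matrix: CharacterMatrix) -> str:
    """Serialise to the dialect accepted by :func:`read_character_matrix`.

    Continuous characters are written first, then discrete, so the reader's
    global character numbering may permute relative to ``matrix`` only when
    the input interleaves kinds; matrices produced by this package never do.
    """
    cont = [j for j, c in enumerate(matrix.characters) if c.kind == "continuous"]
    disc = [j for j, c in enumerate(matrix.characters) if c.kind != "continuous"]
    out = ["xread", f"{matrix.n_characters} {matrix.n_taxa}"]

    def cell_text(i: int, j: int) -> str:
        cell = matrix.cells[i][j]
        if cell is None:
            return INAPPLICABLE if (i, j) in matrix.inapplicable else MISSING
        if matrix.characters[j].kind == "continuous":
            return format(cell, ".12g")
        if len(cell) == 1:
            return str(next(iter(cell)))
        return "[" + "".join(str(s) for s in sorted(cell)) + "]"

    if cont:
        out.append("&[continuous]")
        for i, taxon in enumerate(matrix.taxa):
            out.append(taxon + "  " + " ".join(cell_text(i, j) for j in cont))
    if disc:
        out.append("&[discrete]")
        for i, taxon in enumerate(matrix.taxa):
            out.append(taxon + "  " + "".join(cell_text(i, j) for j in disc))
    out.append(";")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# functional trait matrices
# ---------------------------------------------------------------------------

VALID_KINDS = ("categorical", "ordered", "continuous")


@dataclass
class FunctionalMatrix:
    """Taxa x typed functional characters with missing values allowed.

    ``schema`` maps character name to ``{"kind": ..., "states": [...]}``;
    ``states`` gives the rank order for ordered characters and the legal
    state list for categorical ones.  ``bins`` assigns each taxon to a time
    bin label (e.g. Santonian-Campanian vs Maastrichtian) when present.
    """

    data: pd.DataFrame  # index: taxon, columns: characters, NaN = missing
    schema: dict[str, dict]
    bins: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate taxa in functional matrix")
        unknown = set(self.data.columns) - set(self.schema)
        if unknown:
            raise ValueError(f"characters missing from schema: {sorted(unknown)}")
        for name in self.data.columns:
            kind = self.schema[name].get("kind")
            if kind not in VALID_KINDS:
                raise ValueError(f"unknown character kind {kind!r} for {name!r}")
        if self.data.notna().sum(axis=1).eq(0).any():
            empty = self.data.index[self.data.notna().sum(axis=1) == 0]
            raise ValueError(f"taxa with no observed values: {list(empty)}")
        if self.data.notna().sum(axis=0).eq(0).any():
            empty = self.data.columns[self.data.notna().sum(axis=0) == 0]
            warnings.warn(f"characters with no observed values: {list(empty)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def characters(self) -> list[str]:
        return list(self.data.columns)

    def kind(self, name: str) -> str:
        return self.schema[name]["kind"]

    def group(self, label: str) -> list[str]:
        if self.bins is None:
            raise ValueError("functional matrix carries no bin assignment")
        return list(self.bins.index[self.bins == label])


def read_schema(source) -> dict[str, dict]:
    """Load a YAML character schema: ``name -> {kind, states?}``."""
    import os

    if hasattr(source, "read"):
        schema = yaml.safe_load(source)
    elif "\n" not in str(source) and os.path.exists(str(source)):
        with open(str(source)) as fh:
            schema = yaml.safe_load(fh)
    else:
        schema = yaml.safe_load(str(source))
    if not isinstance(schema, dict):
        raise ValueError("schema must be a mapping of character -> spec")
    for name, spec in schema.items():
        if not isinstance(spec, dict) or "kind" not in spec:
            raise ValueError(f"schema entry {name!r} lacks a 'kind'")
    return schema


def read_functional_matrix(source, schema) -> FunctionalMatrix:
    """Read a functional trait CSV (``taxon`` column + one column per
    character, optional ``bin`` column) typed by a schema mapping/YAML."""
    if not isinstance(schema, dict):
        schema = read_schema(schema)
    # read everything as text so discrete states keep their spelling
    df = pd.read_csv(source, na_values=["NA", ""], keep_default_na=False,
                     dtype=str)
    if "taxon" not in df.columns:
        raise ValueError("functional matrix needs a 'taxon' column")
    df = df.set_index("taxon")
    bins = None
    if "bin" in df.columns:
        bins = df.pop("bin")
    for name in df.columns:
        if name not in schema:
            raise ValueError(f"character {name!r} not in schema")
        kind = schema[name]["kind"]
        if kind == "continuous":
            df[name] = pd.to_numeric(df[name])
        else:
            states = schema[name].get("states")
            if states is not None:
                bad = set(df[name].dropna()) - set(states)
                if bad:
                    raise ValueError(
                        f"character {name!r} has undeclared states {sorted(bad)}")
    return FunctionalMatrix(df, schema, bins)
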