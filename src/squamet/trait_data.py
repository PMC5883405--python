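"""Species trait tables, phylogenies, and their alignment.

The analysis input is a species-level table of standard metabolic rate
(SMR, ml O2/h), body mass (g) and measurement temperature (degC), with two
binary classifications per species: body plan (lizard vs snake) and
reproductive mode (oviparous vs viviparous).  Trees are rooted newick with
non-negative branch lengths; length-free newick defaults every branch to 1,
matching the equal-branch-length convention used throughout the analysis.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import dendropy
import pandas as pd

logger = logging.getLogger("squamet")

CLADES = ("lizard", "snake")
REPRODUCTIVE_MODES = ("oviparous", "viviparous")

#: canonical column order of the on-disk trait table
TRAIT_COLUMNS = (
    "species",
    "clade",
    "reproductive_mode",
    "body_mass_g",
    "temperature_C",
    "smr_ml_o2_per_h",
)


class TraitTableError(ValueError):
    """Malformed trait table (missing columns, duplicates, empty)."""


class TraitRecordError(ValueError):
    """A single record violates its invariants; the message names the species."""


def _canon_species(name: str) -> str:
    """Exact matching after trimming and space->underscore (newick convention)."""
    return str(name).strip().replace(" ", "_")


@dataclass(frozen=True)
class TraitRecord:
    """One species' traits.

    Invariants: positive mass and SMR, temperature in (0, 50) degC (the
    source data span 20-40 degC), clade and reproductive mode from their
    two-level sets.
    """

    species: str
    clade: str
    reproductive_mode: str
    body_mass_g: float
    temperature_C: float
    smr: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", _canon_species(self.species))
        object.__setattr__(self, "clade", str(self.clade).strip().lower())
        object.__setattr__(
            self, "reproductive_mode", str(self.reproductive_mode).strip().lower()
        )
        if self.clade not in CLADES:
            raise TraitRecordError(
                f"{self.species}: clade must be one of {CLADES}, got {self.clade!r}"
            )
        if self.reproductive_mode not in REPRODUCTIVE_MODES:
            raise TraitRecordError(
                f"{self.species}: reproductive_mode must be one of "
                f"{REPRODUCTIVE_MODES}, got {self.reproductive_mode!r}"
            )
        for name in ("body_mass_g", "temperature_C", "smr"):
            v = getattr(self, name)
            try:
                object.__setattr__(self, name, float(v))
            except (TypeError, ValueError):
                raise TraitRecordError(f"{self.species}: {name} is not numeric: {v!r}")
        if not self.body_mass_g > 0:
            raise TraitRecordError(f"{self.species}: body_mass_g must be > 0")
        if not self.smr > 0:
            raise TraitRecordError(f"{self.species}: smr must be > 0")
        if not (0 < self.temperature_C < 50):
            raise TraitRecordError(
                f"{self.species}: temperature_C must lie in (0, 50) degC"
            )


@dataclass
class TraitTable:
    """Ordered, non-empty collection of :class:`TraitRecord` with unique species."""

    records: list[TraitRecord]
    load_log: list[str] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise TraitTableError("trait table is empty")
        seen: set[str] = set()
        for r in self.records:
            if r.species in seen:
                raise TraitTableError(f"duplicate species: {r.species}")
            seen.add(r.species)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def subset(self, keep: list[str]) -> "TraitTable":
        """Records for ``keep``, in the order of ``keep``."""
        by_name = {r.species: r for r in self.records}
        missing = [s for s in keep if s not in by_name]
        if missing:
            raise TraitTableError(f"species not in table: {missing}")
        return TraitTable([by_name[s] for s in keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [r.species for r in self.records],
                "clade": [r.clade for r in self.records],
                "reproductive_mode": [r.reproductive_mode for r in self.records],
                "body_mass_g": [r.body_mass_g for r in self.records],
                "temperature_C": [r.temperature_C for r in self.records],
                "smr_ml_o2_per_h": [r.smr for r in self.records],
            }
        )


def read_trait_table(source) -> TraitTable:
    """Read a delimited trait table (comma or tab, auto-detected).

    ``source`` is a path or file-like object.  The header must name the six
    required columns (any order).  Categorical values are case-normalized;
    repairs are recorded in the returned table's ``load_log``.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    header = text.splitlines()[0] if text else ""
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableError(f"missing required column(s): {missing}")
    if len(df) == 0:
        raise TraitTableError("trait table has a header but no data rows")
    log: list[str] = []
    records = []
    for _, row in df.iterrows():
        raw_clade = str(row["clade"])
        raw_mode = str(row["reproductive_mode"])
        rec = TraitRecord(
            species=row["species"],
            clade=raw_clade,
            reproductive_mode=raw_mode,
            body_mass_g=row["body_mass_g"],
            temperature_C=row["temperature_C"],
            smr=row["smr_ml_o2_per_h"],
        )
        if raw_clade != rec.clade or raw_mode != rec.reproductive_mode:
            log.append(f"{rec.species}: normalized categorical value(s)")
        records.append(rec)
    table = TraitTable(records)
    table.load_log = log
    return table


def write_trait_table(table: TraitTable, destination) -> None:
    """Write CSV with the canonical header; numeric fields keep >= 10
    significant digits so read-write round-trips are exact to float precision."""
    df = table.to_frame()
    kwargs = dict(index=False, float_format="%.12g")
    if hasattr(destination, "write"):
        df.to_csv(destination, **kwargs)
    else:
        df.to_csv(str(destination), **kwargs)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class PhylogenyError(ValueError):
    pass


@dataclass
class Phylogeny:
    """Rooted tree with uniquely labeled tips and non-negative branch lengths.

    Thin wrapper over a :class:`dendropy.Tree`; tip label order is the
    tree's own leaf iteration order and defines the species order of any
    covariance matrix built from it.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise PhylogenyError(f"duplicate tip labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is not None and edge.length < 0:
                raise PhylogenyError("negative branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))

    def to_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        )
        return s.strip() + ("\n" if not s.endswith("\n") else "")


def read_newick(text: str) -> Phylogeny:
    """Parse one newick tree; branch lengths absent in the text default to 1."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise PhylogenyError(f"invalid newick: {exc}") from exc
    for taxon in tree.taxon_namespace:
        taxon.label = _canon_species(taxon.label)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            node.edge.length = 0.0 if node.edge.length is None else node.edge.length
        elif node.edge.length is None:
            node.edge.length = 1.0
    return Phylogeny(tree)


def set_branch_lengths_equal(phylo: Phylogeny, value: float = 1.0) -> Phylogeny:
    """Return a copy with every (non-root) branch length set to ``value``."""
    if not value > 0:
        raise ValueError("branch length value must be > 0")
    out = phylo.copy()
    for node in out.tree.preorder_node_iter():
        if node is out.tree.seed_node:
            node.edge.length = 0.0
        else:
            node.edge.length = float(value)
    return out


def align(
    table: TraitTable, phylo: Phylogeny, policy: str = "prune"
) -> tuple[TraitTable, Phylogeny]:
    """Match a trait table and a tree to the same species, in tree-tip order.

    ``strict`` errors on any mismatch; ``prune`` drops species missing from
    either side, logging a warning listing them.
    """
    if policy not in ("strict", "prune"):
        raise ValueError(f"policy must be 'strict' or 'prune', got {policy!r}")
    table_sp = set(table.species)
    tree_sp = set(phylo.tip_labels)
    common = table_sp & tree_sp
    if not common:
        raise ValueError("no species shared between table and tree")
    dropped = sorted((table_sp | tree_sp) - common)
    if dropped:
        if policy == "strict":
            raise ValueError(f"species mismatch under strict policy: {dropped}")
        logger.warning("align: dropping %d unmatched species: %s", len(dropped), dropped)
    out_tree = phylo
    if tree_sp - common:
        t = phylo.tree.clone(depth=1)
        keep = [tx for tx in t.taxon_namespace if tx.label in common]
        t.retain_taxa(keep)
        out_tree = Phylogeny(t)
    order = [s for s in out_tree.tip_labels]
    return table.subset(order), out_tree
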