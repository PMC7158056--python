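"""Presence/absence of the ole cluster on a species tree.

Leaves are annotated present/absent/unknown from a presence table,
genus-level ubiquity is the share of genera that are all-or-none, and
"presence clusters" are maximal runs of present leaves in a canonical
ladderized leaf order (children sorted by subtree size, ties by smallest
leaf name) — the deterministic analogue of counting positive arcs on a
circular tree by eye.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd

PRESENT, ABSENT, UNKNOWN = "present", "absent", "unknown"


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; leaf names must be unique."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises schema-specific error classes
        raise ValueError(f"malformed Newick in {path}: {exc}") from exc
    names = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf names in tree")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def read_presence_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"present": bool})
    required = {"species_id", "genus", "present"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"presence table missing columns {sorted(missing)}")
    if table["species_id"].duplicated().any():
        raise ValueError("duplicate species_id in presence table")
    return table


def annotate_presence(tree: dendropy.Tree, table: pd.DataFrame) -> tuple[dendropy.Tree, list[str]]:
    """Attach a status annotation to every leaf.

    Species in the table but not in the tree are returned as unmatched
    (reported, not fatal); leaves not in the table become 'unknown'.
    """
    status = dict(zip(table["species_id"], table["present"]))
    seen = set()
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        if name in status:
            leaf.status = PRESENT if status[name] else ABSENT
            seen.add(name)
        else:
            leaf.status = UNKNOWN
    unmatched = sorted(set(status) - seen)
    return tree, unmatched


def genus_ubiquity(table: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Per-genus fraction of species with the cluster, plus a summary.

    ubiquity_rate is the share of genera whose fraction is exactly 0 or 1
    — the tree-of-life observation that a genus either has the cluster in
    all members or in none.
    """
    frac = table.groupby("genus")["present"].mean()
    all_or_none = ((frac == 0.0) | (frac == 1.0)).sum()
    summary = {
        "n_genera": int(frac.size),
        "n_all_or_none": int(all_or_none),
        "ubiquity_rate": float(all_or_none / frac.size) if frac.size else float("nan"),
    }
    return frac, summary


def _ordered_leaves(node) -> list:
    if node.is_leaf():
        return [node]
    kids = sorted(
        node.child_nodes(),
        key=lambda c: (len(c.leaf_nodes()), min(l.taxon.label for l in c.leaf_nodes())),
    )
    out = []
    for kid in kids:
        out.extend(_ordered_leaves(kid))
    return out


def canonical_leaf_order(tree: dendropy.Tree) -> list[str]:
    """Ladderized leaf order: children by subtree size, ties by leaf name."""
    return [leaf.taxon.label for leaf in _ordered_leaves(tree.seed_node)]


def count_presence_clusters(tree: dendropy.Tree, gap_tolerance: int = 0) -> int:
    """Number of maximal runs of present leaves in the canonical order.

    Runs separated by <= gap_tolerance non-present leaves merge; leaves
    with unknown status separate runs the same way absent ones do.
    """
    statuses = [leaf.status for leaf in _ordered_leaves(tree.seed_node)]
    clusters = 0
    gap = None  # None until the first present leaf
    for s in statuses:
        if s == PRESENT:
            if gap is None or gap > gap_tolerance:
                clusters += 1
            gap = 0
        elif gap is not None:
            gap += 1
    return clusters


def leaf_status_table(tree: dendropy.Tree) -> pd.DataFrame:
    rows = [
        {"species_id": leaf.taxon.label, "status": leaf.status}
        for leaf in _ordered_leaves(tree.seed_node)
    ]
    return pd.DataFrame(rows)
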