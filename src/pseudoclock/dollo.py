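"""Dollo mapping of LoF mutations and pseudogenes onto a species tree.

A complex loss (a specific LoF allele, or the pseudogenization of a gene)
is assumed to arise once and never revert. Under that model the origin of
a character shared by a set of carrier tips is the branch subtending their
most recent common ancestor; a single carrier maps to its terminal branch.
Characters whose carriers are not a clade, or the same gene lost through
different alleles in different lineages, violate single origin and are
flagged as independent losses by the homoplasy screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import pandas as pd

PRESENT, ABSENT, MISSING = "present", "absent", "missing"


@dataclass
class CharacterMatrix:
    """Presence/absence of mutations (rows) across tips (columns).

    Entries are 'present', 'absent' or 'missing'. Missing entries default
    to absent for origin mapping; when a missing tip borders the carrier
    clade this is noted, since resolving it to present could move the
    origin rootward.
    """

    rows: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for mutation_id, entries in self.rows.items():
            states = set(entries.values())
            bad = states - {PRESENT, ABSENT, MISSING}
            if bad:
                raise ValueError(f"{mutation_id}: invalid states {sorted(bad)}")
            if states <= {MISSING}:
                raise ValueError(f"{mutation_id}: all entries missing")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CharacterMatrix":
        """Build from a 0/1/NA table (rows = mutations, columns = tips)."""
        rows = {}
        for mutation_id, row in df.iterrows():
            entries = {}
            for tip, value in row.items():
                if pd.isna(value):
                    entries[tip] = MISSING
                else:
                    entries[tip] = PRESENT if int(value) == 1 else ABSENT
            rows[str(mutation_id)] = entries
        return cls(rows=rows)

    def carriers(self, mutation_id: str) -> set[str]:
        return {
            tip
            for tip, state in self.rows[mutation_id].items()
            if state == PRESENT
        }


@dataclass
class BranchAssignment:
    """Origin branch per mutation plus per-branch tallies.

    ``origins`` maps mutation id to the label of the origin node (tip
    label for terminal branches, internal node key otherwise); every
    mapped mutation is assigned exactly once, so branch counts sum to the
    number of mapped mutations.
    """

    origins: dict[str, str]
    branch_counts: dict[str, int]
    tip_private_counts: dict[str, int] = field(default_factory=dict)
    root_spanning: tuple[str, ...] = ()

    @property
    def total_mapped(self) -> int:
        return len(self.origins)


def _node_key(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    tips = sorted(leaf.taxon.label for leaf in node.leaf_iter())
    return "mrca(" + ",".join(tips) + ")"


def map_origin(tree: dendropy.Tree, carriers: set[str]) -> dendropy.Node:
    """Origin branch of a character: the MRCA of its carriers.

    Raises on unknown tips or an empty carrier set. If the MRCA is the
    root, the character spans the whole tree and the caller should flag it.
    """
    if not carriers:
        raise ValueError("carrier set is empty")
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = set(carriers) - labels
    if unknown:
        raise ValueError(f"carriers not in tree: {sorted(unknown)}")
    if len(carriers) == 1:
        (tip,) = carriers
        return tree.find_node_with_taxon_label(tip)
    return tree.mrca(taxon_labels=sorted(carriers))


def branch_counts(matrix: CharacterMatrix, tree: dendropy.Tree) -> BranchAssignment:
    """Map every mutation to its Dollo origin and tally per branch.

    Missing entries are treated as absent; mutations with no carriers are
    left unmapped. Mutations whose MRCA is the tree root are still counted
    there but listed in ``root_spanning``.
    """
    origins: dict[str, str] = {}
    counts: dict[str, int] = {}
    tip_private: dict[str, int] = {}
    root_spanning: list[str] = []
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for mutation_id in matrix.rows:
        extra = set(matrix.rows[mutation_id]) - labels
        if extra:
            raise ValueError(
                f"{mutation_id}: matrix columns not in tree: {sorted(extra)}"
            )
        carriers = matrix.carriers(mutation_id)
        if not carriers:
            continue
        bordering = {
            tip
            for tip, state in matrix.rows[mutation_id].items()
            if state == MISSING
        }
        if bordering:
            warnings.warn(
                f"{mutation_id}: missing entries for {sorted(bordering)} "
                "treated as absent; resolving them as present could move "
                "the origin rootward",
                stacklevel=2,
            )
        node = map_origin(tree, carriers)
        key = _node_key(node)
        origins[mutation_id] = key
        counts[key] = counts.get(key, 0) + 1
        if node.is_leaf():
            tip_private[key] = tip_private.get(key, 0) + 1
        if node is tree.seed_node:
            root_spanning.append(mutation_id)
    return BranchAssignment(
        origins=origins,
        branch_counts=counts,
        tip_private_counts=tip_private,
        root_spanning=tuple(root_spanning),
    )


def _is_clade(tree: dendropy.Tree, carriers: set[str]) -> bool:
    node = map_origin(tree, carriers)
    clade = {leaf.taxon.label for leaf in node.leaf_iter()}
    return clade == set(carriers)


def homoplasy_screen(
    matrix: CharacterMatrix,
    tree: dendropy.Tree,
    allele_identity: Mapping[str, Mapping[str, str]] | None = None,
) -> pd.DataFrame:
    """Flag characters violating single origin.

    A mutation is flagged when its carriers are non-monophyletic on the
    tree (the same descriptor in distant tips with intervening absences),
    or when ``allele_identity`` shows different exact alleles among
    carriers of the same gene-level character (independent losses).

    Returns a table (mutation_id, reason) of flagged characters.
    """
    flagged = []
    for mutation_id in matrix.rows:
        carriers = matrix.carriers(mutation_id)
        if not carriers:
            continue
        if len(carriers) > 1 and not _is_clade(tree, carriers):
            flagged.append(
                {
                    "mutation_id": mutation_id,
                    "reason": "carriers non-monophyletic (Dollo violation)",
                }
            )
        if allele_identity and mutation_id in allele_identity:
            alleles = {
                allele_identity[mutation_id][tip]
                for tip in carriers
                if tip in allele_identity[mutation_id]
            }
            if len(alleles) > 1:
                flagged.append(
                    {
                        "mutation_id": mutation_id,
                        "reason": (
                            "different LoF alleles among carriers "
                            "(independent losses)"
                        ),
                    }
                )
    return pd.DataFrame(flagged, columns=["mutation_id", "reason"])


def annotate_tree_with_counts(
    tree: dendropy.Tree, assignment: BranchAssignment
) -> str:
    """Newick string with per-branch origin counts as node labels.

    The input tree is left untouched.
    """

    def write(node: dendropy.Node) -> str:
        count = assignment.branch_counts.get(_node_key(node), 0)
        if node.is_leaf():
            return f"{node.taxon.label}[{count}]"
        inner = ",".join(write(c) for c in node.child_nodes())
        return f"({inner}){count}"

    return write(tree.seed_node) + ";"


def counts_table(assignment: BranchAssignment) -> pd.DataFrame:
    rows = [
        {"branch": branch, "n_events": count}
        for branch, count in sorted(assignment.branch_counts.items())
    ]
    return pd.DataFrame(rows, columns=["branch", "n_events"])
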