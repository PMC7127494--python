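"""Tree-based species assignment and cross-marker congruence.

Trees are inferred elsewhere (maximum likelihood, Bayesian inference, ...)
and consumed here as Newick.  Assignment places each unlabelled (query) leaf
in the smallest clade that contains reference sequences of exactly one
species; per-species monophyly of the references is required, otherwise the
affected queries stay unassigned.  Outgroup leaves are used for rooting and
pruned before any ingroup monophyly test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


class TreeError(ValueError):
    pass


@dataclass
class LabelledTree:
    """A rooted/rootable tree over specimen ids with optional node supports."""

    tree: dendropy.Tree
    outgroup: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate leaf labels")
        missing = self.outgroup - set(labels)
        if missing:
            raise TreeError(f"outgroup leaves not in tree: {sorted(missing)}")

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def ingroup(self) -> "LabelledTree":
        """Root at the outgroup and prune it, keeping supports."""
        t = self.tree.clone(depth=1)
        t.is_rooted = True
        if not self.outgroup:
            return LabelledTree(tree=t, outgroup=frozenset())
        og_taxa = [tx for tx in t.taxon_namespace if tx.label in self.outgroup]
        mrca = t.mrca(taxa=og_taxa)
        if mrca is not t.seed_node:
            t.reroot_at_edge(mrca.edge, update_bipartitions=False)
        t.prune_taxa(og_taxa)
        return LabelledTree(tree=t, outgroup=frozenset())


def _node_support(node: dendropy.Node) -> float | None:
    label = node.label
    if label is None:
        return None
    try:
        return float(label)
    except ValueError:
        return None


def read_newick(path, outgroup: set[str] | None = None) -> LabelledTree:
    """Parse Newick (with optional branch lengths and internal support labels)."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"Newick parse error in {path}: {exc}") from exc
    return LabelledTree(tree=tree, outgroup=frozenset(outgroup or ()))


def parse_newick(text: str, outgroup: set[str] | None = None) -> LabelledTree:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True, preserve_underscores=True
        )
    except Exception as exc:
        raise TreeError(f"Newick parse error: {exc}") from exc
    return LabelledTree(tree=tree, outgroup=frozenset(outgroup or ()))


def write_newick(t: LabelledTree, path) -> None:
    t.tree.write(path=str(path), schema="newick", suppress_rooting=True)


def is_monophyletic(t: LabelledTree, members: set[str]) -> tuple[bool, float | None]:
    """Whether the smallest clade containing ``members`` contains nothing else.

    The tree is rooted via the outgroup (then pruned) first.  Returns the
    verdict plus the support value at the members' MRCA, when present.
    """
    ingroup = t.ingroup()
    leaves = set(ingroup.leaf_labels())
    unknown = set(members) - leaves
    if unknown:
        raise TreeError(f"unknown leaf names: {sorted(unknown)}")
    if not members:
        raise TreeError("empty member set")
    taxa = [tx for tx in ingroup.tree.taxon_namespace if tx.label in members]
    mrca = ingroup.tree.mrca(taxa=taxa)
    clade = {lf.taxon.label for lf in mrca.leaf_iter()}
    return clade == set(members), _node_support(mrca)


@dataclass(frozen=True)
class SpeciesAssignment:
    """Per-specimen species assignment derived from one marker's tree."""

    marker: str
    assigned: dict[str, tuple[str, float | None]]  # id -> (species, clade support)
    unassigned: frozenset[str] = field(default_factory=frozenset)

    def species(self, specimen_id: str) -> str | None:
        entry = self.assigned.get(specimen_id)
        return entry[0] if entry else None


def assign_by_clade(
    t: LabelledTree, references: dict[str, str], marker: str = ""
) -> SpeciesAssignment:
    """Assign each query leaf the species of the smallest species-pure
    reference clade containing it.

    References of a species must be monophyletic with respect to the other
    references; queries that would depend on a polyphyletic species stay
    unassigned.  Outgroup leaves are never assigned.
    """
    ingroup = t.ingroup()
    leaves = set(ingroup.leaf_labels())
    refs = {sid: sp for sid, sp in references.items() if sid in leaves}
    if not refs:
        raise TreeError("no reference leaves present in the tree")

    # species whose references are mutually monophyletic (ignoring queries)
    ref_mono: dict[str, bool] = {}
    for sp in set(refs.values()):
        members = [tx for tx in ingroup.tree.taxon_namespace if refs.get(tx.label) == sp]
        mrca = ingroup.tree.mrca(taxa=members)
        clade_refs = {refs[lf.taxon.label] for lf in mrca.leaf_iter() if lf.taxon.label in refs}
        ref_mono[sp] = clade_refs == {sp}

    assigned: dict[str, tuple[str, float | None]] = {}
    unassigned: set[str] = set()
    for leaf in ingroup.tree.leaf_node_iter():
        sid = leaf.taxon.label
        if sid in refs:
            continue
        node = leaf.parent_node
        hit = None
        while node is not None:
            clade_ref_species = {
                refs[lf.taxon.label] for lf in node.leaf_iter() if lf.taxon.label in refs
            }
            if clade_ref_species:
                hit = (clade_ref_species, _node_support(node))
                break
            node = node.parent_node
        if hit is None:
            unassigned.add(sid)
            continue
        species_set, support = hit
        if len(species_set) == 1:
            (sp,) = species_set
            if ref_mono[sp]:
                assigned[sid] = (sp, support)
            else:
                unassigned.add(sid)
        else:
            unassigned.add(sid)
    return SpeciesAssignment(marker=marker, assigned=assigned, unassigned=frozenset(unassigned))


def congruence(a: SpeciesAssignment, b: SpeciesAssignment) -> list[str]:
    """Specimens assigned different species by the two markers (sorted ids).

    Specimens unassigned under either marker are excluded.
    """
    shared = set(a.assigned) & set(b.assigned)
    return sorted(sid for sid in shared if a.assigned[sid][0] != b.assigned[sid][0])


def write_assignments(assignments: list[SpeciesAssignment], incongruent: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("specimen_id\tmarker\tspecies\tclade_support\n")
        for asg in assignments:
            for sid, (sp, support) in sorted(asg.assigned.items()):
                s = "" if support is None else f"{support:g}"
                fh.write(f"{sid}\t{asg.marker}\t{sp}\t{s}\n")
            for sid in sorted(asg.unassigned):
                fh.write(f"{sid}\t{asg.marker}\tUNASSIGNED\t\n")
        fh.write("\n# cross-marker incongruent specimens\n")
        for sid in incongruent:
            fh.write(f"{sid}\n")
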