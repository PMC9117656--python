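"""p-distances, neighbor joining, newick I/O and monophyly tests.

The distance-based tree is a deliberately light stand-in for full ML/Bayesian
inference: the statements it supports are monophyly claims about labeled
clades on a tree rooted at a named outgroup, which whole-plastome data resolve
with strong signal.  NJ follows the Saitou-Nei Q-criterion with a
deterministic lowest-index tie-break; negative branch lengths are clamped to
zero.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .plastome_io import Msa

_BASES = (b"A", b"C", b"G", b"T")


def p_distance_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise fraction of differing bases among columns where both rows have
    bases (gaps and N excluded pairwise, not listwise)."""
    n = mat.shape[0]
    ok = np.zeros(mat.shape, dtype=bool)
    for b in _BASES:
        ok |= mat == b
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ok[i] & ok[j]
            total = int(comparable.sum())
            if total == 0:
                raise ValueError(f"rows {i} and {j} share no comparable columns")
            diff = int((mat[i] != mat[j])[comparable].sum())
            dm[i, j] = dm[j, i] = diff / total
    return dm


def p_distance(msa: Msa) -> tuple[list[str], np.ndarray]:
    if len(msa.rows) < 2:
        raise ValueError("need at least two rows")
    return list(msa.sample_ids), p_distance_matrix(msa.matrix())


def neighbor_joining(ids: list[str], dm: np.ndarray) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree.

    Tie-break: among minimal Q entries the pair with the lowest (i, j) index
    in the current working matrix is joined, which makes the output
    deterministic for any input.
    """
    n = len(ids)
    if n < 3:
        raise ValueError("need at least three taxa")
    if dm.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    d = dm.astype(float).copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)                     # first minimum = lowest (i, j)
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        ni, nj = nodes[active[i]], nodes[active[j]]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = max(0.0, float(li))
        nj.edge.length = max(0.0, float(lj))
        # distances from the new node to all remaining nodes
        new_row = 0.5 * (sub[i, :] + sub[j, :] - dij)
        gi, gj = active[i], active[j]
        d = np.pad(d, ((0, 1), (0, 1)))
        new_idx = d.shape[0] - 1
        for pos, a in enumerate(active):
            d[new_idx, a] = d[a, new_idx] = new_row[pos]
        nodes.append(parent)
        active = [a for a in active if a not in (gi, gj)] + [new_idx]
    # join the last two nodes at the (unrooted) seed
    a, b = active
    root = dendropy.Node()
    root.add_child(nodes[a])
    root.add_child(nodes[b])
    nodes[a].edge.length = max(0.0, float(d[a, b]) / 2)
    nodes[b].edge.length = max(0.0, float(d[a, b]) / 2)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def nj_tree(msa: Msa) -> dendropy.Tree:
    ids, dm = p_distance(msa)
    return neighbor_joining(ids, dm)


def is_monophyletic(
    tree: dendropy.Tree,
    leaf_labels,
    outgroup: str | None = None,
) -> bool:
    """True when ``leaf_labels`` form a complete clade.

    When ``outgroup`` is given the (cloned) tree is first rooted on that
    leaf's edge, which is how an unrooted NJ tree acquires the direction the
    monophyly statement needs.
    """
    labels = set(leaf_labels)
    tree_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if not labels <= tree_labels:
        raise ValueError(f"labels not in tree: {sorted(labels - tree_labels)}")
    if labels == tree_labels:
        return True
    work = tree.clone(depth=1)
    if outgroup is not None:
        node = None
        for lf in work.leaf_node_iter():
            if lf.taxon.label == outgroup:
                node = lf
                break
        if node is None:
            raise ValueError(f"outgroup {outgroup!r} not in tree")
        work.reroot_at_edge(node.edge, update_bipartitions=False)
    mrca = work.mrca(taxon_labels=sorted(labels))
    if mrca is None:
        return False
    under = {lf.taxon.label for lf in mrca.leaf_iter()}
    return under == labels


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def tree_from_newick_string(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick",
                             preserve_underscores=True)
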