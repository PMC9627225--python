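"""Phylogeny handling: congeneric imputation and the Brownian covariance.

The occurrence model's phylogenetic random effect needs a covariance matrix
``Sigma_spp`` over the analyzed species, derived from a rooted tree with
branch lengths under a Brownian-motion model: the covariance of two species
is the branch length shared from the root to their most recent common
ancestor.  Species in the occurrence data but absent from the tree are
grafted next to a randomly chosen congener (uniform attachment point along
the congener's terminal branch), which keeps the tree bifurcating and — for
ultrametric trees — keeps all tips contemporaneous.  The matrix is scaled by
its maximum diagonal entry, so an ultrametric tree yields a unit diagonal;
the absolute scale is absorbed by the phylogenetic variance parameter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import dendropy

__all__ = ["impute_congeners", "brownian_vcv"]


def impute_congeners(
    tree: dendropy.Tree,
    species_list: list[str],
    genus_map: dict[str, str],
    seed: int,
) -> dendropy.Tree:
    """Graft species missing from the tree beside random congeners.

    Each missing species (processed in sorted order for determinism) picks a
    congener tip uniformly at random — previously grafted tips included — and
    is attached at a uniform point along that tip's terminal branch.  The new
    tip's branch length equals the attachment height, so its root-to-tip
    distance matches the congener's.

    Raises ``ValueError`` when a missing species has no congener tip.
    """
    tree = tree.clone(depth=1)
    rng = np.random.default_rng(seed)
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = sorted(set(species_list) - set(tips))
    for sp in missing:
        genus = genus_map.get(sp)
        congeners = sorted(
            t for t in tips if genus_map.get(t, t.split("_")[0]) == genus
        )
        if not congeners:
            raise ValueError(f"no congener tip for missing species {sp!r}")
        host = tips[congeners[rng.integers(len(congeners))]]
        L = host.edge.length or 0.0
        h = float(rng.uniform(0.0, L)) if L > 0 else 0.0
        parent = host.parent_node
        knee = dendropy.Node()
        knee.edge.length = L - h
        parent.remove_child(host)
        parent.add_child(knee)
        host.edge.length = h
        knee.add_child(host)
        new_tip = dendropy.Node()
        new_tip.edge.length = h
        knee.add_child(new_tip)
        taxon = dendropy.Taxon(label=sp)
        tree.taxon_namespace.add_taxon(taxon)
        new_tip.taxon = taxon
        tips[sp] = new_tip
    return tree


def brownian_vcv(
    tree: dendropy.Tree,
    species: list[str] | None = None,
    scale: bool = True,
) -> pd.DataFrame:
    """Brownian-motion variance-covariance matrix of the tips.

    Entry (i, j) is the root-to-MRCA shared branch length; the diagonal holds
    root-to-tip distances.  With ``scale=True`` the matrix is divided by its
    maximum diagonal entry (tree height), giving unit diagonal for
    ultrametric trees.  ``species`` restricts and orders the rows/columns.
    """
    labels = []
    depth: dict[int, float] = {}
    tip_sets: dict[int, list[int]] = {}
    root = tree.seed_node
    depth[id(root)] = root.edge.length or 0.0
    n_guess = sum(1 for _ in tree.leaf_node_iter())
    V = np.zeros((n_guess, n_guess))
    for node in tree.preorder_node_iter():
        if node is not root:
            bl = node.edge.length
            if bl is not None and bl < 0:
                raise ValueError("negative branch length")
            depth[id(node)] = depth[id(node.parent_node)] + (bl or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = len(labels)
            labels.append(node.taxon.label)
            tip_sets[id(node)] = [i]
            V[i, i] = depth[id(node)]
        else:
            children = node.child_nodes()
            sets = [tip_sets.pop(id(c)) for c in children]
            d = depth[id(node)]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for i in sets[a]:
                        V[i, sets[b]] = d
                        V[np.ix_(sets[b], [i])] = d
            tip_sets[id(node)] = [i for s in sets for i in s]
    vcv = pd.DataFrame(V, index=labels, columns=labels)
    if species is not None:
        missing = sorted(set(species) - set(labels))
        if missing:
            raise ValueError(f"species not in tree: {missing}")
        vcv = vcv.loc[species, species]
    if scale:
        vcv = vcv / vcv.to_numpy().diagonal().max()
    return vcv
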