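"""Independent reference implementations used to cross-check the package.

Everything here deliberately avoids the library's own code paths: naive
loops for the threshold scan, and the covariance-matrix GLS route for
Brownian-motion ancestral states.
"""

import numpy as np

import phyloemg as pe


def brute_force_scan(env, n_thresholds=50, n_permutations=10, seed=0):
    """Naive per-threshold randomization scan (independent of the vectorized path)."""
    env = np.asarray(env, dtype=float)
    lo, hi = env.min(), env.max()
    thresholds = [lo + k * (hi - lo) / n_thresholds for k in range(1, n_thresholds + 1)]

    def runs(series, thr):
        count, prev = 0, False
        for v in series:
            above = v > thr
            if above and not prev:
                count += 1
            prev = above
        return count

    runs_orig = [runs(env, th) for th in thresholds]
    rng = np.random.default_rng(seed)
    runs_perm = np.zeros(n_thresholds)
    for _ in range(n_permutations):
        p = rng.permutation(env)
        runs_perm += [runs(p, th) for th in thresholds]
    runs_perm /= n_permutations
    diff = runs_perm - np.array(runs_orig)
    return thresholds[int(np.argmax(diff))]


def random_tree(n_tips, seed):
    import random

    import dendropy

    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        taxon_namespace=taxa,
        rng=random.Random(seed),
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = max(edge.length, 1e-3) * rng.uniform(0.5, 2.0)
    return pe.PhyloTree(tree=tree)


def gls_ancestral_oracle(tree, tip_values):
    """Conditional-expectation GLS route for BM ancestral states.

    Root: mu = (1' C^-1 y) / (1' C^-1 1) with C the tip covariance (shared
    root-to-MRCA path lengths); node v: mu + c_v' C^-1 (y - mu) with c_v the
    node-tip shared path lengths.
    """
    t = tree.tree
    tips = list(t.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in tips]
    depth = {}
    leafset = {}
    for node in t.preorder_node_iter():
        parent = node.parent_node
        base = depth[id(parent)] if parent is not None else 0.0
        depth[id(node)] = base + (node.edge.length or 0.0)
    for node in t.postorder_node_iter():
        leafset[id(node)] = frozenset(id(x) for x in node.leaf_iter())

    def shared_depth(u, tip):
        # depth of the deepest ancestor-or-self of u whose clade contains tip
        anc = u
        while id(tip) not in leafset[id(anc)]:
            anc = anc.parent_node
        return depth[id(anc)]

    n = len(tips)
    C = np.array([[shared_depth(a, b) for b in tips] for a in tips])
    y = np.array([tip_values[l] for l in labels])
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    mu = float(ones @ Cinv @ y / (ones @ Cinv @ ones))
    out = {}
    for node in t.preorder_node_iter():
        if node.is_leaf():
            continue
        c_v = np.array([shared_depth(node, tip) for tip in tips])
        out[node.label] = float(mu + c_v @ Cinv @ (y - mu))
    return out
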