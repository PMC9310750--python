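import numpy as np
import pytest

from umbelevo import mk, synth, tree

PSEUDO_STATES = ("floral", "absent", "hyperfloral")


@pytest.fixture(scope="session")
def three_tip_tree():
    return tree.parse_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture(scope="session")
def four_tip_tree():
    return tree.parse_newick("((A:1,B:2):1,(C:1.5,D:0.5):2):0;")


@pytest.fixture(scope="session")
def yule50():
    return synth.simulate_bd_tree(1.0, 0.0, n_tips=50, seed=1234)


def random_tree(rng, n_tips):
    """Random non-ultrametric rooted binary tree (for I/O round trips)."""
    parent = [-1]
    blen = [0.0]
    labels = [None]
    leaves = [0]
    while len(leaves) < n_tips:
        v = leaves.pop(rng.integers(len(leaves)))
        for _ in range(2):
            parent.append(v)
            blen.append(float(rng.uniform(0.05, 3.0)))
            labels.append(None)
            leaves.append(len(parent) - 1)
    for i, v in enumerate(sorted(leaves)):
        labels[v] = f"t{i + 1}"
    return tree.Phylogeny(np.array(parent), np.array(blen), labels)


def enumeration_loglik(t, tips, Q, states, prior=None):
    """Brute-force Mk likelihood: sum over all internal-node assignments."""
    from itertools import product

    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    P = mk.transition_matrices(Q, t.blen)
    internals = [v for v in range(t.n_nodes) if t.children[v]]
    if prior is None:
        prior = np.full(k, 1.0 / k)
    tot = 0.0
    tip_sets = {v: {sidx[s] for s in tips[t.labels[v]]} for v in t.tips}
    for assign in product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        for tipsets in product(*[sorted(tip_sets[v]) for v in t.tips]):
            amap2 = dict(amap)
            amap2.update(dict(zip([int(v) for v in t.tips], tipsets)))
            p = prior[amap2[t.root]] if t.children[t.root] else prior[amap2[t.root]]
            for v in range(t.n_nodes):
                if t.parent[v] >= 0:
                    p *= P[v][amap2[int(t.parent[v])], amap2[v]]
            tot += p
    return np.log(tot)


def enumeration_marginals(t, tips, Q, states, prior=None):
    """Clamp-and-renormalize marginal probabilities by enumeration."""
    k = len(states)
    out = {}
    for v in range(t.n_nodes):
        if not t.children[v]:
            continue
        liks = []
        for s in range(k):
            clamped = _clamped_loglik(t, tips, Q, states, v, s, prior)
            liks.append(np.exp(clamped))
        liks = np.array(liks)
        out[v] = liks / liks.sum()
    return out


def _clamped_loglik(t, tips, Q, states, node, state, prior):
    from itertools import product

    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    P = mk.transition_matrices(Q, t.blen)
    internals = [v for v in range(t.n_nodes) if t.children[v]]
    if prior is None:
        prior = np.full(k, 1.0 / k)
    tot = 0.0
    tip_sets = {v: sorted(sidx[s] for s in tips[t.labels[v]]) for v in t.tips}
    for assign in product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        if amap[node] != state:
            continue
        for tipassign in product(*[tip_sets[v] for v in t.tips]):
            amap2 = dict(amap)
            amap2.update(dict(zip([int(v) for v in t.tips], tipassign)))
            p = prior[amap2[t.root]]
            for v in range(t.n_nodes):
                if t.parent[v] >= 0:
                    p *= P[v][amap2[int(t.parent[v])], amap2[v]]
            tot += p
    return np.log(tot) if tot > 0 else -np.inf
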