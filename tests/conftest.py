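"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from transat import MultipleAlignment, load_default_models, tree_from_newick_string

CANONICAL = {"AU", "UA", "GC", "CG", "GU", "UG"}


@pytest.fixture(scope="session")
def models():
    return load_default_models()


@pytest.fixture(scope="session")
def unpaired_model(models):
    return models[0]


@pytest.fixture(scope="session")
def paired_model(models):
    return models[1]


@pytest.fixture
def two_leaf_tree():
    return tree_from_newick_string("(A:0.3,B:0.7);")


@pytest.fixture
def toy_alignment():
    return MultipleAlignment(["A", "B"], ["GGGGAAAACCCC", "GGGGAAAACCCC"])


# ---------------------------------------------------------------------------
# Brute-force helix enumeration oracle: scan all (p, q, run) triples.
# ---------------------------------------------------------------------------

def brute_force_helices(seq: str, min_len: int = 4, min_loop: int = 3):
    """All maximal helices by exhaustive search over (p, q, run) triples."""
    n = len(seq)

    def pair_ok(p, q):
        return seq[p] + seq[q] in CANONICAL

    def valid(p, q, run):
        if run < min_len or p < 0 or q >= n:
            return False
        inner_p, inner_q = p + run - 1, q - run + 1
        if inner_q - inner_p < min_loop + 1:
            return False
        return all(pair_ok(p + k, q - k) for k in range(run))

    found = set()
    for p in range(n):
        for q in range(p + 1, n):
            for run in range(min_len, n):
                if not valid(p, q, run):
                    continue
                # maximal: no valid extension outward or inward
                if valid(p - 1, q + 1, run + 1):
                    continue
                if valid(p, q, run + 1):
                    continue
                found.add(tuple((p + k, q - k) for k in range(run)))
    return found


# ---------------------------------------------------------------------------
# Exhaustive pruning oracle: sum over all internal-node state assignments.
# ---------------------------------------------------------------------------

def exhaustive_likelihood(tree, model, leaf_weights):
    """Tree likelihood by explicit summation over internal-node states.

    ``leaf_weights`` maps leaf label -> observation weight vector.  Leaf
    states are summed analytically (a dot product per leaf); every
    assignment of states to the root and internal nodes is enumerated.
    """
    k = model.n_states
    internals = [n for n in range(tree.n_nodes) if tree.children[n] is not None]
    if not internals:  # single-leaf tree
        (leaf,) = tree.leaf_indices()
        return float(model.freqs @ leaf_weights[tree.labels[leaf]])
    total = 0.0
    for states in itertools.product(range(k), repeat=len(internals)):
        state_of = dict(zip(internals, states))
        term = model.freqs[state_of[tree.root]]
        for node in internals:
            for kid in tree.children[node]:
                p = model.transition_matrix(tree.branch_lengths[kid])
                if tree.children[kid] is None:
                    term *= p[state_of[node]] @ leaf_weights[tree.labels[kid]]
                else:
                    term *= p[state_of[node], state_of[kid]]
        total += term
    return float(total)


# ---------------------------------------------------------------------------
# Random rooted binary trees and rerooting (for invariance checks).
# ---------------------------------------------------------------------------

def random_newick(n_leaves: int, rng: np.random.Generator) -> str:
    labels = [f"L{i}" for i in range(n_leaves)]

    def grow(names):
        if len(names) == 1:
            return names[0]
        split = int(rng.integers(1, len(names)))
        left, right = grow(names[:split]), grow(names[split:])
        return f"({left}:{rng.uniform(0.05, 1.0):.6f},{right}:{rng.uniform(0.05, 1.0):.6f})"

    return grow(labels) + ";"


def reroot_newick(newick: str, rng: np.random.Generator) -> str:
    """Reroot along a random edge; unrooted shape and lengths unchanged."""
    import dendropy

    t = dendropy.Tree.get(data=newick, schema="newick",
                          suppress_internal_node_taxa=True)
    edges = [
        e
        for e in t.preorder_edge_iter()
        if e.head_node is not t.seed_node and e.length
    ]
    edge = edges[int(rng.integers(len(edges)))]
    frac = float(rng.uniform(0.2, 0.8))
    t.reroot_at_edge(
        edge,
        length1=edge.length * frac,
        length2=edge.length * (1 - frac),
        update_bipartitions=False,
    )
    t.suppress_unifurcations()
    return t.as_string(schema="newick", suppress_rooting=True)
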