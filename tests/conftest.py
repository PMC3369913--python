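"""Shared fixtures: random aligned sets, random additive trees, and
synthetic Scr/Antp-style reference panels.

All fixture data is generated programmatically from fixed seeds; nothing
is read from disk except the package's own small TSV tables.
"""

from __future__ import annotations

import numpy as np
import pytest

from hoxdiv.distance import DistanceMatrix
from hoxdiv.rates import load_reference_rate_table, rate_table_from_precomputed
from hoxdiv.seqio import AlignedSequenceSet, SequenceRecord

BASES = "ACGT"
AMINO = "ACDEFGHIKLMNPQRSTVWY"


def random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def random_aa(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture(scope="session")
def reference_table():
    """Packaged transcription of the published rate table (60 rows)."""
    return load_reference_rate_table()


@pytest.fixture(scope="session")
def reference_rates(reference_table):
    """RateTable recomputed from the packaged p%% and age columns."""
    return rate_table_from_precomputed(reference_table)


def random_aligned_set(rng: np.random.Generator, n: int = 5,
                       length: int = 75,
                       alphabet: str = "nt") -> AlignedSequenceSet:
    make = random_nt if alphabet == "nt" else random_aa
    recs = tuple(
        SequenceRecord(id=f"tx{i}", sequence=make(rng, length),
                       alphabet=alphabet)
        for i in range(n)
    )
    return AlignedSequenceSet(recs, alphabet=alphabet)


class RandomTree:
    """A random binary unrooted tree with known leaf-to-leaf distances.

    Built by repeatedly joining two random active clades with positive
    edge lengths; exposes the additive distance matrix it generates and
    the set of non-trivial bipartitions (as frozensets of leaf labels)
    for topology comparison.
    """

    def __init__(self, rng: np.random.Generator, n_leaves: int,
                 min_len: float = 0.05, max_len: float = 1.0):
        labels = [f"L{i:02d}" for i in range(n_leaves)]
        # dist[a][b]: distance from clade root a to each leaf b under it
        clades = {i: {labels[i]: 0.0} for i in range(n_leaves)}
        self.n = n_leaves
        self.labels = labels
        dist = np.zeros((n_leaves, n_leaves))
        roots = list(range(n_leaves))
        splits: list[frozenset[str]] = []
        next_id = n_leaves
        while len(roots) > 1:
            i, j = rng.choice(len(roots), size=2, replace=False)
            a, b = roots[int(i)], roots[int(j)]
            la = float(rng.uniform(min_len, max_len))
            lb = float(rng.uniform(min_len, max_len))
            for leaf_a, da in clades[a].items():
                for leaf_b, db in clades[b].items():
                    d = da + la + db + lb
                    ia, ib = labels.index(leaf_a), labels.index(leaf_b)
                    dist[ia, ib] = dist[ib, ia] = d
            merged = {leaf: d + la for leaf, d in clades[a].items()}
            merged.update({leaf: d + lb for leaf, d in clades[b].items()})
            if 1 < len(merged) < n_leaves - 1:
                splits.append(frozenset(merged))
            for leaf_set, root in ((clades[a], a), (clades[b], b)):
                if 1 < len(leaf_set) < n_leaves - 1:
                    splits.append(frozenset(leaf_set))
            clades[next_id] = merged
            del clades[a], clades[b]
            roots = [r for r in roots if r not in (a, b)] + [next_id]
            next_id += 1
        self.matrix = DistanceMatrix(tuple(labels), dist)
        full = frozenset(labels)
        norm = set()
        for s in splits:
            comp = full - s
            norm.add(min(s, comp, key=sorted))
        self.bipartitions = norm


def tree_bipartitions(tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of a dendropy tree, normalised to the
    lexicographically smaller side."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(clade) < len(leaves) - 1:
            comp = leaves - clade
            out.add(min(clade, comp, key=sorted))
    return out


def make_panel_pair(length: int = 60,
                    diff_positions: tuple[int, ...] = (1, 4, 6, 7, 60),
                    members_per_panel: int = 2):
    """Two synthetic homeodomain panels (frame 1..length) identical
    everywhere except at ``diff_positions`` (1-based), where their
    residue sets are disjoint. Mimics the Scr/Antp situation: identical
    over the central window, discriminable only at a handful of
    terminal positions."""
    from hoxdiv.classify import HoxReferencePanel
    from hoxdiv.seqio import build_aligned_set

    rng = np.random.default_rng(2024)
    backbone = random_aa(rng, length)
    seq_a = list(backbone)
    seq_b = list(backbone)
    for pos in diff_positions:
        i = pos - 1
        seq_a[i] = "K"
        seq_b[i] = "Q"
    recs_a = [SequenceRecord(id=f"ScrRef{m}", sequence="".join(seq_a),
                             alphabet="aa") for m in range(members_per_panel)]
    recs_b = [SequenceRecord(id=f"AntpRef{m}", sequence="".join(seq_b),
                             alphabet="aa") for m in range(members_per_panel)]
    return (
        HoxReferencePanel("Scr", build_aligned_set(recs_a)),
        HoxReferencePanel("Antp", build_aligned_set(recs_b)),
    )


@pytest.fixture
def scr_antp_panels():
    return make_panel_pair()
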