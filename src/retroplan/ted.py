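"""Ordered-tree edit distance (Zhang & Shasha).

Generic implementation over any rooted ordered tree: callers supply a
children accessor and per-node insertion/deletion/substitution costs.  The
algorithm is the classic keyroot decomposition with O(n^2) memory on the
forest-distance table; route trees here are tens of nodes, so quadratic cost
is negligible.
"""

from __future__ import annotations

from typing import Callable, Sequence, TypeVar

import numpy as np

T = TypeVar("T")


def _postorder(root: T, children: Callable[[T], Sequence[T]]) -> tuple[list[T], list[int]]:
    """Post-order node list and, per node, the index of its leftmost leaf."""
    nodes: list[T] = []
    lmld: list[int] = []

    def visit(node: T) -> int:
        kids = children(node)
        first_leaf = None
        for kid in kids:
            leaf = visit(kid)
            if first_leaf is None:
                first_leaf = leaf
        nodes.append(node)
        index = len(nodes) - 1
        lmld.append(first_leaf if first_leaf is not None else index)
        return lmld[index]

    visit(root)
    return nodes, lmld


def _keyroots(lmld: list[int]) -> list[int]:
    seen: dict[int, int] = {}
    for i, leaf in enumerate(lmld):
        seen[leaf] = i  # last (highest) node sharing this leftmost leaf
    return sorted(seen.values())


def tree_edit_distance(
    root_a: T,
    root_b: T,
    children: Callable[[T], Sequence[T]],
    substitute_cost: Callable[[T, T], float],
    delete_cost: Callable[[T], float] = lambda _n: 1.0,
    insert_cost: Callable[[T], float] = lambda _n: 1.0,
) -> float:
    """Minimum-cost sequence of node edits transforming tree A into tree B."""
    nodes_a, lmld_a = _postorder(root_a, children)
    nodes_b, lmld_b = _postorder(root_b, children)
    n, m = len(nodes_a), len(nodes_b)
    dist = np.zeros((n, m))
    del_costs = np.array([delete_cost(x) for x in nodes_a])
    ins_costs = np.array([insert_cost(x) for x in nodes_b])

    for i in _keyroots(lmld_a):
        for j in _keyroots(lmld_b):
            li, lj = lmld_a[i], lmld_b[j]
            rows, cols = i - li + 2, j - lj + 2
            forest = np.zeros((rows, cols))
            forest[1:, 0] = np.cumsum(del_costs[li : i + 1])
            forest[0, 1:] = np.cumsum(ins_costs[lj : j + 1])
            for di in range(1, rows):
                ai = li + di - 1
                for dj in range(1, cols):
                    bj = lj + dj - 1
                    if lmld_a[ai] == li and lmld_b[bj] == lj:
                        forest[di, dj] = min(
                            forest[di - 1, dj] + del_costs[ai],
                            forest[di, dj - 1] + ins_costs[bj],
                            forest[di - 1, dj - 1]
                            + substitute_cost(nodes_a[ai], nodes_b[bj]),
                        )
                        dist[ai, bj] = forest[di, dj]
                    else:
                        forest[di, dj] = min(
                            forest[di - 1, dj] + del_costs[ai],
                            forest[di, dj - 1] + ins_costs[bj],
                            forest[lmld_a[ai] - li, lmld_b[bj] - lj] + dist[ai, bj],
                        )
    return float(dist[n - 1, m - 1])
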