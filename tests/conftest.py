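"""Shared fixtures and the brute-force level-set oracle.

The oracle classifies every grid vertex by counting connected components of
superlevel and sublevel sets at each threshold of the (value, index) total
order, using the same dual connectivity pair as the contour tree (superlevel
at 6, sublevel at 26, or swapped).  It is deliberately independent of the
sweep/union-find implementation it checks.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import topolight as tl

DUAL = {6: 26, 26: 6}


def oracle_critical_sets(values: np.ndarray, connectivity: int = 6):
    """(maxima, minima, join saddles, split saddles) as vertex-index sets."""
    values = np.asarray(values, float)
    while values.ndim < 3:
        values = values[..., np.newaxis]
    s_up = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    s_dn = ndimage.generate_binary_structure(3, 1 if DUAL[connectivity] == 6 else 3)
    flat = values.ravel(order="F")
    n = flat.size
    order = np.lexsort((np.arange(n), flat))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(n)
    R = rank.reshape(values.shape, order="F")
    maxima, minima, jsad, ssad = set(), set(), set(), set()
    for v in range(n):
        rv = rank[v]
        _, n_after = ndimage.label(R >= rv, structure=s_up)
        _, n_before = ndimage.label(R > rv, structure=s_up)
        if n_after == n_before + 1:
            maxima.add(v)
        elif n_after < n_before:
            jsad.add(v)
        _, m_after = ndimage.label(R <= rv, structure=s_dn)
        _, m_before = ndimage.label(R < rv, structure=s_dn)
        if m_after == m_before + 1:
            minima.add(v)
        elif m_after < m_before:
            ssad.add(v)
    return maxima, minima, jsad, ssad


def tree_critical_sets(ct: tl.ContourTree):
    """The same four sets read off a contour tree's node degrees."""
    return (
        {nd.vertex_index for nd in ct.nodes if ct.up_degree[nd.id] == 0},
        {nd.vertex_index for nd in ct.nodes if ct.down_degree[nd.id] == 0},
        {nd.vertex_index for nd in ct.nodes if ct.up_degree[nd.id] >= 2},
        {nd.vertex_index for nd in ct.nodes if ct.down_degree[nd.id] >= 2},
    )


# 5x5 two-blob field: maxima 9 and 8 joined through a saddle at 5, on a
# serpentine monotone background with a single minimum at 2.4.
_TWO_BLOB_ROWS = np.array([
    [4.0, 4.1, 4.2, 4.3, 4.4],
    [3.9, 9.0, 5.0, 8.0, 4.5],
    [3.8, 3.7, 3.6, 3.5, 3.4],
    [2.9, 3.0, 3.1, 3.2, 3.3],
    [2.8, 2.7, 2.6, 2.5, 2.4],
])


@pytest.fixture(scope="session")
def two_blob_5x5() -> tl.ScalarField:
    return tl.ScalarField(_TWO_BLOB_ROWS.T.copy())  # index order (x, y)


@pytest.fixture(scope="session")
def two_blob_tree(two_blob_5x5):
    return tl.build_contour_tree(two_blob_5x5)


@pytest.fixture(scope="session")
def two_blob_decomposition(two_blob_tree):
    return tl.decompose_branches(two_blob_tree)


def three_blob_field() -> tl.ScalarField:
    """Three well-separated blobs along x: root (pers ~8.8, no siblings) and
    two depth-1 sibling children with lower persistence."""
    return tl.multi_blob_volume(
        (32, 20, 16),
        [((6.0, 10.0, 7.5), 9.0, 2.6),
         ((16.0, 10.0, 7.5), 8.0, 2.4),
         ((25.5, 10.0, 7.5), 6.5, 2.2)],
    )


@pytest.fixture(scope="session")
def three_blob_pipeline():
    """field, simplified decomposition, segmentation, attributes."""
    field = three_blob_field()
    ct = tl.build_contour_tree(field)
    bd = tl.simplify_tree(tl.decompose_branches(ct), "persistence", threshold=0.5)
    seg = tl.segment_field(field, bd)
    attrs = tl.annotate_structure(bd, field, seg)
    return field, bd, seg, attrs


@pytest.fixture(scope="session")
def nested_chain_pipeline():
    """Depth-{0,1,2} chain fixture with attributes."""
    field = tl.nested_blob_chain((25, 16, 16), levels=3)
    ct = tl.build_contour_tree(field)
    bd = tl.simplify_tree(tl.decompose_branches(ct), "persistence", threshold=0.5)
    seg = tl.segment_field(field, bd)
    attrs = tl.annotate_structure(bd, field, seg)
    return field, bd, seg, attrs
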