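"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linprog

from phewas_volcano import SimParams, rs1260326_fixture, simulate_phewas


@pytest.fixture
def gckr_records():
    """The two published rs1260326 associations (broad endocrine + mixed
    hyperlipidemia)."""
    return rs1260326_fixture()


@pytest.fixture
def small_table():
    """A modest synthetic PheWAS table with some true signals."""
    return simulate_phewas(SimParams(n_traits=400, frac_nonnull=0.1, seed=42))


# ---------------------------------------------------------------------------
# independent convex-hull oracles (never touch the monotone-chain code path)

def point_in_convex_combination(p, others) -> bool:
    """LP feasibility: is p a convex combination of ``others``?

    Solves  exists lambda >= 0, sum lambda = 1, others^T lambda = p.
    Boundary points (on an edge between others) count as inside, so a point
    passing this test is *not* a strict hull vertex.
    """
    others = np.asarray(others, dtype=float)
    if len(others) == 0:
        return False
    n = len(others)
    A_eq = np.vstack([others.T, np.ones(n)])
    b_eq = np.array([p[0], p[1], 1.0])
    res = linprog(np.zeros(n), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    return res.status == 0


def brute_force_hull_vertices(points) -> set[tuple[float, float]]:
    """O(n^3)-style oracle: keep a point iff it is not a convex combination
    of the remaining distinct points."""
    distinct = sorted(set(map(tuple, points)))
    out = set()
    for i, p in enumerate(distinct):
        others = distinct[:i] + distinct[i + 1:]
        if not point_in_convex_combination(p, others):
            out.add(p)
    return out


def edge_oracle_hull_vertices(points: np.ndarray) -> set[tuple[float, float]]:
    """Vectorized pairwise oracle for points in general position: (a, b) is a
    hull edge iff every other point lies strictly on one side; hull vertices
    are the endpoints of edges."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    verts: set[tuple[float, float]] = set()
    for i in range(n):
        d = pts - pts[i]
        for j in range(n):
            if i == j:
                continue
            cross = d[:, 0] * d[j, 1] - d[:, 1] * d[j, 0]
            mask = np.ones(n, bool)
            mask[[i, j]] = False
            if np.all(cross[mask] > 0) or np.all(cross[mask] < 0):
                verts.add(tuple(pts[i]))
                verts.add(tuple(pts[j]))
    return verts
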