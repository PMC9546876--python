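import numpy as np
import pytest

from notchisland import ModelParams, analytic_fields, force_free_fields, generate_lattice


@pytest.fixture(scope="session")
def lat7():
    return generate_lattice(7, seed=0)


@pytest.fixture(scope="session")
def lat20():
    return generate_lattice(20, seed=0)


@pytest.fixture(scope="session")
def lat400():
    """The default island size: 400 cells in the unit disk."""
    return generate_lattice(400, seed=1)


@pytest.fixture(scope="session")
def fields400(lat400):
    return analytic_fields(lat400)


@pytest.fixture
def params():
    return ModelParams()


def brute_force_shared_edges(polygons, eps=1e-9):
    """Independent adjacency oracle: collinear overlap of polygon segments.

    Two cells are neighbors iff some edge segment of one overlaps an edge
    segment of the other over positive length. Pure-numpy; does not reuse
    the package's geometry stack.
    """
    def segments(poly):
        return [(poly[k], poly[(k + 1) % len(poly)]) for k in range(len(poly))]

    def overlap_length(a0, a1, b0, b1):
        da = a1 - a0
        la = np.linalg.norm(da)
        if la < eps:
            return 0.0
        u = da / la
        # both b endpoints must lie on the line of a
        for pt in (b0, b1):
            off = pt - a0
            perp = abs(off[0] * u[1] - off[1] * u[0])
            if perp > 1e-7:
                return 0.0
        ta = sorted([0.0, la])
        tb = sorted([np.dot(b0 - a0, u), np.dot(b1 - a0, u)])
        lo, hi = max(ta[0], tb[0]), min(ta[1], tb[1])
        return max(0.0, hi - lo)

    n = len(polygons)
    adj = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            found = False
            for a0, a1 in segments(polygons[i]):
                for b0, b1 in segments(polygons[j]):
                    if overlap_length(np.asarray(a0), np.asarray(a1),
                                      np.asarray(b0), np.asarray(b1)) > eps:
                        found = True
                        break
                if found:
                    break
            if found:
                adj[i].add(j)
                adj[j].add(i)
    return [frozenset(s) for s in adj]
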