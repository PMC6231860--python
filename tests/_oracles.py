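"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the rank-test oracle
enumerates group labelings directly, and the point-in-polygon oracle is a
self-contained ray-casting implementation (the package uses shapely).
"""

from __future__ import annotations

from itertools import combinations


def exact_mann_whitney_p(a, b) -> tuple[float, float]:
    """(U of a, two-sided p) by exhaustive enumeration of labelings.

    Two-sided p = P(U <= lo) + P(U >= hi) where lo = min(u, n1*n2 - u) and
    hi = n1*n2 - lo, over all C(n1+n2, n1) assignments.
    """
    pooled = list(a) + list(b)
    n1, n2 = len(a), len(b)
    n = len(pooled)

    def u_of(idx):
        chosen = set(idx)
        return sum(
            (pooled[i] > pooled[j]) + 0.5 * (pooled[i] == pooled[j])
            for i in idx
            for j in range(n)
            if j not in chosen
        )

    u_obs = u_of(tuple(range(n1)))
    us = [u_of(c) for c in combinations(range(n), n1)]
    lo = min(u_obs, n1 * n2 - u_obs)
    hi = n1 * n2 - lo
    eps = 1e-9
    p = (sum(u <= lo + eps for u in us) + sum(u >= hi - eps for u in us)) / len(us)
    return u_obs, min(1.0, p)


def ray_cast_inside(lat: float, lon: float, ring) -> bool:
    """Even-odd ray casting for one closed ring of (lon, lat) pairs.

    A horizontal ray is shot toward +x; boundary points are treated as
    inside by an explicit on-segment check.
    """
    x, y = lon, lat
    inside = False
    m = len(ring)
    for i in range(m - 1):
        x1, y1 = ring[i]
        x2, y2 = ring[i + 1]
        # on-segment check (colinear + within bbox)
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x_int > x:
                inside = not inside
    return inside


def ray_cast_state(coords, features) -> str | None:
    """First feature (file order) whose outer ring contains (lat, lon)."""
    lat, lon = coords
    for name, ring in features:
        if ray_cast_inside(lat, lon, ring):
            return name
    return None
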