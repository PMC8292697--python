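"""Independent brute-force oracles, sharing no code with the implementation.

Each oracle re-states the documented convention with explicit Python loops:

* point membership on a plane: odd crossing-number parity over the plane's
  polygons, or lying on any polygon edge;
* the cumulative DVH as a direct per-voxel scan;
* edit distance as the classic dynamic-programming table;
* decision trees as a tiny recursive interpreter.
"""

import math


def point_in_polygon_strict(px, py, poly):
    """Crossing-number parity for one polygon (no boundary handling)."""
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i][0], poly[i][1]
        x2, y2 = poly[(i + 1) % n][0], poly[(i + 1) % n][1]
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def point_on_polygon_edge(px, py, poly, eps=1e-9):
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i][0], poly[i][1]
        x2, y2 = poly[(i + 1) % n][0], poly[(i + 1) % n][1]
        cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
        scale = max(abs(x2 - x1), abs(y2 - y1), 1.0)
        if abs(cross) <= eps * scale:
            if (min(x1, x2) - eps <= px <= max(x1, x2) + eps
                    and min(y1, y2) - eps <= py <= max(y1, y2) + eps):
                return True
    return False


def point_member(px, py, polygons):
    """Membership under the stated convention: parity over polygons is odd,
    or the point lies on any edge."""
    parity = False
    for poly in polygons:
        if point_in_polygon_strict(px, py, poly):
            parity = not parity
    if parity:
        return True
    return any(point_on_polygon_edge(px, py, poly) for poly in polygons)


def brute_force_mask(structure_contours, x_centers, y_centers, z_centers,
                     z_tol):
    """Binary voxel mask at voxel centers by explicit loops.

    ``structure_contours`` is a list of (points, z) pairs; each contour goes
    to the nearest z plane within z_tol.
    """
    nz, ny, nx = len(z_centers), len(y_centers), len(x_centers)
    by_plane = {}
    for pts, z in structure_contours:
        best_k, best_d = None, None
        for k, zc in enumerate(z_centers):
            d = abs(zc - z)
            if best_d is None or d < best_d:
                best_k, best_d = k, d
        if best_d > z_tol + 1e-9:
            raise ValueError("contour out of grid")
        by_plane.setdefault(best_k, []).append(pts)
    mask = [[[False] * nx for _ in range(ny)] for _ in range(nz)]
    for k, polys in by_plane.items():
        for j, py in enumerate(y_centers):
            for i, px in enumerate(x_centers):
                mask[k][j][i] = point_member(px, py, polys)
    return mask


def brute_force_dvh(mask, dose_values, voxel_volume, dose_points):
    """V(d) in percent at each dose point, by direct per-voxel scan."""
    total = 0.0
    doses = []
    nz = len(mask)
    for k in range(nz):
        for j in range(len(mask[k])):
            for i in range(len(mask[k][j])):
                if mask[k][j][i]:
                    total += voxel_volume
                    doses.append(dose_values[k][j][i])
    out = []
    for d in dose_points:
        v = sum(voxel_volume for x in doses if x >= d)
        out.append(100.0 * v / total)
    return out, total


def edit_distance(a, b):
    """Classic DP Levenshtein distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[n]


def eval_tree(nodes, root, features):
    """Recursive decision-tree interpreter over plain dicts.

    ``nodes[nid]`` is ``{"leaf": ...}`` or
    ``{"field", "op", "value", "true", "false"}``. Returns
    (result, missing_field_or_None).
    """
    node = nodes[root]
    if "leaf" in node:
        return node["leaf"], None
    f = node["field"]
    op = node["op"]
    if f not in features and op != "EXISTS":
        return "NOT_EVALUABLE", f
    actual = features.get(f)
    lit = node.get("value")
    if op == "EXISTS":
        outcome = f in features and features[f] is not None
    elif op == "EQ":
        outcome = actual == lit
    elif op == "NE":
        outcome = actual != lit
    elif op == "IN":
        outcome = actual in lit
    elif op == "LT":
        outcome = actual < lit
    elif op == "LE":
        outcome = actual <= lit
    elif op == "GT":
        outcome = actual > lit
    elif op == "GE":
        outcome = actual >= lit
    else:
        raise ValueError(op)
    return eval_tree(nodes, node["true"] if outcome else node["false"], features)


def shoelace_area(poly):
    n = len(poly)
    s = 0.0
    for i in range(n):
        x1, y1 = poly[i][0], poly[i][1]
        x2, y2 = poly[(i + 1) % n][0], poly[(i + 1) % n][1]
        s += x1 * y2 - x2 * y1
    return abs(s) / 2.0
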