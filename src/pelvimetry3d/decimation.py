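"""Quadric edge-collapse mesh decimation with an exact vertex budget.

Garland-Heckbert error quadrics with area-weighted plane quadrics, a lazy
binary heap, a link-condition test to keep the mesh 2-manifold, and a
triangle-flip guard.  The collapse loop stops exactly at the requested
vertex count, so a fixed mesh budget (e.g. 25,000 vertices per bone) is
reproducible across inputs.  Deterministic for a fixed input and target.
"""

from __future__ import annotations

import heapq

import numpy as np

__all__ = ["decimate_mesh"]


def _vertex_quadrics(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Sum of area-weighted plane quadrics of incident faces, per vertex."""
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    n = np.cross(b - a, c - a)
    area2 = np.linalg.norm(n, axis=1)  # twice the area
    nz = area2 > 0
    unit = np.zeros_like(n)
    unit[nz] = n[nz] / area2[nz, None]
    d = -np.einsum("ij,ij->i", unit, a)
    p = np.hstack([unit, d[:, None]])  # (m, 4) plane coefficients
    K = p[:, :, None] * p[:, None, :] * (0.5 * area2)[:, None, None]
    Q = np.zeros((len(vertices), 4, 4))
    for col in range(3):
        np.add.at(Q, faces[:, col], K)
    return Q


def _optimal_position(Q: np.ndarray, va: np.ndarray, vb: np.ndarray) -> tuple[np.ndarray, float]:
    """Collapse target minimizing vᵀQv; falls back to best of ends/midpoint.

    Scalar closed-form 3x3 solve (Cramer) — this runs once per candidate
    edge and dominates decimation time, so no small-array linalg here.
    """
    q00 = Q[0, 0]; q01 = Q[0, 1]; q02 = Q[0, 2]; q03 = Q[0, 3]
    q11 = Q[1, 1]; q12 = Q[1, 2]; q13 = Q[1, 3]
    q22 = Q[2, 2]; q23 = Q[2, 3]; q33 = Q[3, 3]

    det = (
        q00 * (q11 * q22 - q12 * q12)
        - q01 * (q01 * q22 - q12 * q02)
        + q02 * (q01 * q12 - q11 * q02)
    )
    trace = q00 + q11 + q22

    def cost_at(x: float, y: float, z: float) -> float:
        return (
            q00 * x * x + q11 * y * y + q22 * z * z
            + 2.0 * (q01 * x * y + q02 * x * z + q12 * y * z)
            + 2.0 * (q03 * x + q13 * y + q23 * z)
            + q33
        )

    ax, ay, az = va
    bx, by, bz = vb
    mx, my, mz = 0.5 * (ax + bx), 0.5 * (ay + by), 0.5 * (az + bz)
    cands = []
    # guard against near-singular quadrics (flat neighborhoods)
    if abs(det) > 1e-9 * max(trace * trace * trace / 27.0, 1e-30):
        inv = 1.0 / det
        x = -inv * (
            q03 * (q11 * q22 - q12 * q12)
            - q01 * (q13 * q22 - q12 * q23)
            + q02 * (q13 * q12 - q11 * q23)
        )
        y = -inv * (
            q00 * (q13 * q22 - q12 * q23)
            - q03 * (q01 * q22 - q12 * q02)
            + q02 * (q01 * q23 - q13 * q02)
        )
        z = -inv * (
            q00 * (q11 * q23 - q13 * q12)
            - q01 * (q01 * q23 - q13 * q02)
            + q03 * (q01 * q12 - q11 * q02)
        )
        # reject solutions far outside the edge neighborhood
        ex, ey, ez = ax - bx, ay - by, az - bz
        lim = 4.0 * (ex * ex + ey * ey + ez * ez) ** 0.5 + 1e-9
        dx, dy, dz = x - mx, y - my, z - mz
        if (dx * dx + dy * dy + dz * dz) ** 0.5 < lim:
            cands.append((x, y, z))
    cands += [(mx, my, mz), (ax, ay, az), (bx, by, bz)]
    best, best_cost = None, np.inf
    for cand in cands:
        cost = cost_at(*cand)
        if cost < best_cost:
            best, best_cost = cand, cost
    return np.array(best), max(best_cost, 0.0)


class _Decimator:
    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.V = np.array(vertices, dtype=float)
        self.F = np.array(faces, dtype=np.int64)
        nv = len(self.V)
        self.Q = _vertex_quadrics(self.V, self.F)
        self.alive_v = np.ones(nv, dtype=bool)
        self.alive_f = np.ones(len(self.F), dtype=bool)
        self.stamp = np.zeros(nv, dtype=np.int64)
        self.vneigh: list[set] = [set() for _ in range(nv)]
        self.vfaces: list[set] = [set() for _ in range(nv)]
        for fi, (i, j, k) in enumerate(self.F):
            self.vneigh[i].update((j, k))
            self.vneigh[j].update((i, k))
            self.vneigh[k].update((i, j))
            self.vfaces[i].add(fi)
            self.vfaces[j].add(fi)
            self.vfaces[k].add(fi)
        self.heap: list = []
        self.n_alive = nv

    def _push_edge(self, a: int, b: int) -> None:
        if a > b:
            a, b = b, a
        _, cost = _optimal_position(self.Q[a] + self.Q[b], self.V[a], self.V[b])
        heapq.heappush(self.heap, (cost, a, b, self.stamp[a], self.stamp[b]))

    def _seed_heap(self) -> None:
        self.heap = []
        edges = set()
        for fi in np.flatnonzero(self.alive_f):
            i, j, k = self.F[fi]
            edges.add((min(i, j), max(i, j)))
            edges.add((min(j, k), max(j, k)))
            edges.add((min(i, k), max(i, k)))
        if not edges:
            return
        ea = np.array(sorted(edges))
        Qe = self.Q[ea[:, 0]] + self.Q[ea[:, 1]]
        for (a, b), Q in zip(ea, Qe):
            _, cost = _optimal_position(Q, self.V[a], self.V[b])
            self.heap.append((cost, int(a), int(b), self.stamp[a], self.stamp[b]))
        heapq.heapify(self.heap)

    def _link_ok(self, a: int, b: int) -> bool:
        shared_faces = self.vfaces[a] & self.vfaces[b]
        if len(shared_faces) != 2:  # boundary or non-manifold edge
            return False
        opp = set()
        for fi in shared_faces:
            for v in self.F[fi]:
                if v != a and v != b:
                    opp.add(int(v))
        return (self.vneigh[a] & self.vneigh[b]) == opp

    def _flips(self, a: int, b: int, pos: np.ndarray, shared: set) -> bool:
        V, F = self.V, self.F
        for fi in (self.vfaces[a] | self.vfaces[b]) - shared:
            tri = F[fi]
            p = [V[v] for v in tri]
            n_old = np.cross(p[1] - p[0], p[2] - p[0])
            q = [pos if (v == a or v == b) else V[v] for v in tri]
            n_new = np.cross(q[1] - q[0], q[2] - q[0])
            nn = np.linalg.norm(n_new)
            if nn < 1e-14 or np.dot(n_old, n_new) <= 0:
                return True
        return False

    def _collapse(self, a: int, b: int, check_flips: bool = True) -> bool:
        shared = self.vfaces[a] & self.vfaces[b]
        pos, _ = _optimal_position(self.Q[a] + self.Q[b], self.V[a], self.V[b])
        if check_flips and self._flips(a, b, pos, shared):
            return False
        self.V[a] = pos
        self.Q[a] = self.Q[a] + self.Q[b]
        for fi in shared:
            self.alive_f[fi] = False
            for v in self.F[fi]:
                self.vfaces[int(v)].discard(fi)
        for fi in list(self.vfaces[b]):
            tri = self.F[fi]
            self.F[fi] = np.where(tri == b, a, tri)
            self.vfaces[b].discard(fi)
            self.vfaces[a].add(fi)
        # rewire adjacency
        for nb in self.vneigh[b]:
            if nb != a:
                self.vneigh[nb].discard(b)
                self.vneigh[nb].add(a)
                self.vneigh[a].add(nb)
            else:
                self.vneigh[nb].discard(b)
        self.vneigh[a].discard(a)
        self.vneigh[a].discard(b)
        self.vneigh[b] = set()
        self.alive_v[b] = False
        self.n_alive -= 1
        self.stamp[a] += 1
        self.stamp[b] += 1
        for nb in self.vneigh[a]:
            self.stamp[nb] += 1
            self._push_edge(a, nb)
        return True

    def run(self, target: int) -> tuple[np.ndarray, np.ndarray]:
        self._seed_heap()
        stale_rebuilds = 0
        check_flips = True
        while self.n_alive > target:
            if not self.heap:
                before = self.n_alive
                self._seed_heap()
                if not self.heap:
                    raise RuntimeError("decimation stalled: no collapsible edges left")
                stale_rebuilds = 0 if self.n_alive < before else stale_rebuilds + 1
                if stale_rebuilds == 1 and check_flips:
                    check_flips = False  # last resort: allow flips to hit the budget
                elif stale_rebuilds > 1:
                    raise RuntimeError("decimation stalled: no collapsible edges left")
            cost, a, b, sa, sb = heapq.heappop(self.heap)
            if (
                not self.alive_v[a]
                or not self.alive_v[b]
                or sa != self.stamp[a]
                or sb != self.stamp[b]
            ):
                continue
            if not self._link_ok(a, b):
                continue
            self._collapse(a, b, check_flips)
        keep = np.flatnonzero(self.alive_v)
        remap = np.full(len(self.V), -1, dtype=np.int64)
        remap[keep] = np.arange(len(keep))
        faces = remap[self.F[self.alive_f]]
        return self.V[keep], faces


def decimate_mesh(
    vertices: np.ndarray, faces: np.ndarray, target_vertices: int
) -> tuple[np.ndarray, np.ndarray]:
    """Decimate a closed manifold triangle mesh to exactly ``target_vertices``.

    Raises
    ------
    ValueError
        If the target exceeds the current vertex count ("cannot upsample")
        or is below 4 (no closed surface exists).
    """
    nv = len(vertices)
    if target_vertices > nv:
        raise ValueError(f"cannot upsample: target {target_vertices} > current {nv}")
    if target_vertices < 4:
        raise ValueError("target must be at least 4 for a closed surface")
    if target_vertices == nv:
        return np.array(vertices, dtype=float), np.array(faces, dtype=np.int64)
    return _Decimator(vertices, faces).run(target_vertices)
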