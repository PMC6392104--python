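"""2D Cellular Potts engine.

Cells are sets of nodes on a periodic L x L lattice; node index 0 is the
extracellular medium.  Dynamics proceed by Monte-Carlo steps (MCS): one
MCS performs N = 3 S index-copy attempts where a random source node tries
to copy its cell index onto a random first-order neighbour.  A copy is
accepted outright if it lowers the motility-biased energy, and with
Boltzmann probability exp(-increase / T) otherwise.

The energy combines a perimeter constraint, an area constraint and
heterotypic contact energies:

    Omega = lam_pm  sum_cells (p - P_type)^2
          + lam_area sum_cells (a - A_type)^2
          + sum_{neighbour node pairs} J[type, type'] (1 - delta_cell,cell')

Perimeters are measured as boundary node-edges x 4 um, which makes a
3 x 3 cell (the CD8 target shape) have exactly 48 um of perimeter.  A
per-cell motility term v (cos theta, sin theta) . (x_g - x_s) biases
copies along the cell's privileged direction.

The inner attempt loop is JIT-compiled; areas and perimeters are cached
incrementally and can be cross-checked against a full recomputation.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np
from numba import njit

from .params import MEDIUM, N_TYPES, PottsConfig, InvalidInputError

__all__ = [
    "Tissue",
    "boltzmann_acceptance",
    "delta_motility",
    "attempt_copy",
    "monte_carlo_step",
    "hamiltonian",
    "contact_pairs",
    "split_cell",
]


def boltzmann_acceptance(delta_e: float, temperature: float, u: float) -> bool:
    """Metropolis rule: accept if the (motility-biased) energy does not
    increase, else accept when the uniform draw u < exp(-delta_e / T)."""
    if delta_e <= 0.0:
        return True
    return u < math.exp(-delta_e / temperature)


def delta_motility(
    v: float, theta: float, x_s: Tuple[int, int], x_g: Tuple[int, int]
) -> float:
    """Motility energy bonus of copying from x_s onto its neighbour x_g:
    v (cos theta, sin theta) . (x_g - x_s); 0 for the medium (v = 0)."""
    # across the periodic seam the step is still a unit step
    dx = x_g[0] - x_s[0]
    dy = x_g[1] - x_s[1]
    if abs(dx) > 1:
        dx = -int(np.sign(dx))
    if abs(dy) > 1:
        dy = -int(np.sign(dy))
    return v * (math.cos(theta) * dx + math.sin(theta) * dy)


@njit(cache=True)
def _run_attempts(
    sigma,
    area,
    perim,
    ctype,
    J,
    lam_area_t,
    lam_pm_t,
    A_t,
    P_t,
    v_t,
    theta_x,
    theta_y,
    temperature,
    n_attempts,
    rng,
):
    L = sigma.shape[0]
    accepted = 0
    for _ in range(n_attempts):
        i = int(rng.random() * L)
        j = int(rng.random() * L)
        d = int(rng.random() * 4)
        if d == 0:
            ni = i + 1 if i + 1 < L else 0
            nj = j
            dx = 1.0
            dy = 0.0
        elif d == 1:
            ni = i - 1 if i > 0 else L - 1
            nj = j
            dx = -1.0
            dy = 0.0
        elif d == 2:
            ni = i
            nj = j + 1 if j + 1 < L else 0
            dx = 0.0
            dy = 1.0
        else:
            ni = i
            nj = j - 1 if j > 0 else L - 1
            dx = 0.0
            dy = -1.0
        s_src = sigma[i, j]
        s_tgt = sigma[ni, nj]
        if s_src == s_tgt:
            continue
        if s_tgt != MEDIUM and area[s_tgt] <= 1:
            continue  # a copy may not annihilate a cell's last node
        t_src = ctype[s_src]
        t_tgt = ctype[s_tgt]
        de = 0.0
        c_src = 0
        c_tgt = 0
        for k in range(4):
            if k == 0:
                mi = ni + 1 if ni + 1 < L else 0
                mj = nj
            elif k == 1:
                mi = ni - 1 if ni > 0 else L - 1
                mj = nj
            elif k == 2:
                mi = ni
                mj = nj + 1 if nj + 1 < L else 0
            else:
                mi = ni
                mj = nj - 1 if nj > 0 else L - 1
            sn = sigma[mi, mj]
            if sn == s_src:
                c_src += 1
            if sn == s_tgt:
                c_tgt += 1
            tn = ctype[sn]
            if sn != s_tgt:
                de -= J[t_tgt, tn]
            if sn != s_src:
                de += J[t_src, tn]
        if s_src != MEDIUM:
            a = float(area[s_src])
            tgt = A_t[t_src]
            de += lam_area_t[t_src] * ((a + 1.0 - tgt) ** 2 - (a - tgt) ** 2)
            w = lam_pm_t[t_src]
            if w > 0.0:
                p = 4.0 * perim[s_src]
                pn = p + 4.0 * (4.0 - 2.0 * c_src)
                P = P_t[t_src]
                de += w * ((pn - P) ** 2 - (p - P) ** 2)
        if s_tgt != MEDIUM:
            a = float(area[s_tgt])
            tgt = A_t[t_tgt]
            de += lam_area_t[t_tgt] * ((a - 1.0 - tgt) ** 2 - (a - tgt) ** 2)
            w = lam_pm_t[t_tgt]
            if w > 0.0:
                p = 4.0 * perim[s_tgt]
                pn = p + 4.0 * (2.0 * c_tgt - 4.0)
                P = P_t[t_tgt]
                de += w * ((pn - P) ** 2 - (p - P) ** 2)
        if s_src != MEDIUM:
            de -= v_t[t_src] * (theta_x[s_src] * dx + theta_y[s_src] * dy)
        ok = de <= 0.0
        if not ok:
            ok = rng.random() < math.exp(-de / temperature)
        if ok:
            sigma[ni, nj] = s_src
            area[s_src] += 1
            area[s_tgt] -= 1
            if s_src != MEDIUM:
                perim[s_src] += 4 - 2 * c_src
            if s_tgt != MEDIUM:
                perim[s_tgt] += 2 * c_tgt - 4
            accepted += 1
    return accepted


class Tissue:
    """Lattice plus per-cell geometric registry.

    Cell ids are never reused; dead cells keep their slot with
    ``alive = False`` and no lattice nodes.
    """

    def __init__(self, L: int, config: Optional[PottsConfig] = None, capacity: int = 256):
        if L < 4:
            raise InvalidInputError("lattice side must be at least 4")
        self.L = L
        self.config = config or PottsConfig()
        self.sigma = np.zeros((L, L), dtype=np.int64)
        self._cap = capacity
        self.area = np.zeros(capacity, dtype=np.int64)
        self.perim = np.zeros(capacity, dtype=np.int64)  # boundary edges
        self.ctype = np.zeros(capacity, dtype=np.int64)
        self.alive = np.zeros(capacity, dtype=bool)
        self.theta = np.zeros(capacity, dtype=np.float64)
        self.n_cells = 1  # index 0 = medium
        self.area[0] = L * L
        self.alive[0] = True
        c = self.config
        self._J = np.asarray(c.J, dtype=np.float64)
        self._A_t = np.asarray(c.target_area, dtype=np.float64)
        self._P_t = np.asarray(c.target_perimeter_um, dtype=np.float64)
        self._lam_area_t = np.where(
            np.arange(N_TYPES) == MEDIUM, 0.0, c.lam_area
        ).astype(np.float64)
        self._lam_pm_t = np.where(
            np.asarray(c.perimeter_constrained, dtype=bool), c.lam_pm, 0.0
        ).astype(np.float64)
        self._v_t = np.asarray(c.motility, dtype=np.float64)

    # -- registry ----------------------------------------------------------

    @property
    def S(self) -> int:
        return self.L * self.L

    def _grow(self, need: int) -> None:
        while self._cap < need:
            self._cap *= 2
        for name in ("area", "perim", "ctype", "theta"):
            arr = getattr(self, name)
            new = np.zeros(self._cap, dtype=arr.dtype)
            new[: len(arr)] = arr
            setattr(self, name, new)
        new_alive = np.zeros(self._cap, dtype=bool)
        new_alive[: len(self.alive)] = self.alive
        self.alive = new_alive

    def add_cell(self, nodes: Sequence[Tuple[int, int]], cell_type: int) -> int:
        if len(nodes) == 0:
            raise InvalidInputError("a cell needs at least one node")
        cid = self.n_cells
        self.n_cells += 1
        if self.n_cells > self._cap:
            self._grow(self.n_cells)
        for (i, j) in nodes:
            if self.sigma[i % self.L, j % self.L] != MEDIUM:
                raise InvalidInputError("cannot place a cell on occupied nodes")
            self.sigma[i % self.L, j % self.L] = cid
        self.ctype[cid] = cell_type
        self.alive[cid] = True
        self.area[cid] = len(nodes)
        self.area[0] -= len(nodes)
        self.perim[cid] = self._perimeter_of(cid)
        return cid

    def remove_cell(self, cid: int) -> None:
        """Apoptosis/removal: the cell's nodes revert to medium."""
        nodes = self.sigma == cid
        self.area[0] += int(nodes.sum())
        self.sigma[nodes] = MEDIUM
        self.area[cid] = 0
        self.perim[cid] = 0
        self.alive[cid] = False

    def set_type(self, cid: int, cell_type: int) -> None:
        self.ctype[cid] = cell_type

    def nodes_of(self, cid: int) -> np.ndarray:
        return np.argwhere(self.sigma == cid)

    def _perimeter_of(self, cid: int) -> int:
        mask = self.sigma == cid
        edges = 0
        for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
            edges += int((mask & (np.roll(self.sigma, sh, axis=ax) != cid)).sum())
        return edges

    def recompute_geometry(self) -> None:
        """Refresh cached areas and perimeters from the lattice."""
        counts = np.bincount(self.sigma.ravel(), minlength=self.n_cells)
        self.area[: self.n_cells] = counts[: self.n_cells]
        per = np.zeros(self.n_cells, dtype=np.int64)
        for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
            diff = self.sigma != np.roll(self.sigma, sh, axis=ax)
            per += np.bincount(self.sigma[diff].ravel(), minlength=self.n_cells)[
                : self.n_cells
            ]
        per[0] = 0
        self.perim[: self.n_cells] = per

    def refresh_theta(self, rng: np.random.Generator) -> None:
        """Resample every live cell's privileged direction uniformly."""
        live = np.flatnonzero(self.alive[: self.n_cells])
        live = live[live != 0]
        self.theta[live] = rng.uniform(0.0, 2.0 * np.pi, size=live.size)

    def fragmented_cells(self) -> List[int]:
        """Ids of live cells whose node set is not 4-connected."""
        out = []
        for cid in range(1, self.n_cells):
            if not self.alive[cid]:
                continue
            nodes = [tuple(x) for x in self.nodes_of(cid)]
            if nodes and not _connected(set(nodes), self.L):
                out.append(cid)
        return out


def _connected(nodes: Set[Tuple[int, int]], L: int) -> bool:
    start = next(iter(nodes))
    seen = {start}
    stack = [start]
    while stack:
        i, j = stack.pop()
        for ni, nj in (((i + 1) % L, j), ((i - 1) % L, j), (i, (j + 1) % L), (i, (j - 1) % L)):
            if (ni, nj) in nodes and (ni, nj) not in seen:
                seen.add((ni, nj))
                stack.append((ni, nj))
    return len(seen) == len(nodes)


# ---------------------------------------------------------------------------
# Energies


def hamiltonian(tissue: Tissue) -> float:
    """Full recomputation of the energy from the lattice (cache-free)."""
    t = tissue
    c = t.config
    n = t.n_cells
    counts = np.bincount(t.sigma.ravel(), minlength=n)[:n]
    per = np.zeros(n, dtype=np.int64)
    for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
        diff = t.sigma != np.roll(t.sigma, sh, axis=ax)
        per += np.bincount(t.sigma[diff].ravel(), minlength=n)[:n]
    types = t.ctype[:n]
    live = (np.arange(n) != MEDIUM) & (counts > 0)
    energy = float(
        np.sum(t._lam_area_t[types[live]] * (counts[live] - t._A_t[types[live]]) ** 2)
    )
    energy += float(
        np.sum(t._lam_pm_t[types[live]] * (4.0 * per[live] - t._P_t[types[live]]) ** 2)
    )
    # each unordered neighbour pair once: right and down edges
    for ax in (0, 1):
        s1 = t.sigma
        s2 = np.roll(t.sigma, -1, axis=ax)
        mask = s1 != s2
        energy += float(np.sum(t._J[types[s1[mask]], types[s2[mask]]]))
    return energy


def cached_hamiltonian(tissue: Tissue) -> float:
    """Energy from the incrementally maintained caches (areas/perimeters)
    plus a fresh contact sum; used to validate incremental bookkeeping."""
    t = tissue
    n = t.n_cells
    types = t.ctype[:n]
    counts = t.area[:n]
    live = (np.arange(n) != MEDIUM) & (counts > 0)
    energy = float(
        np.sum(t._lam_area_t[types[live]] * (counts[live] - t._A_t[types[live]]) ** 2)
    )
    energy += float(
        np.sum(
            t._lam_pm_t[types[live]] * (4.0 * t.perim[:n][live] - t._P_t[types[live]]) ** 2
        )
    )
    for ax in (0, 1):
        s1 = t.sigma
        s2 = np.roll(t.sigma, -1, axis=ax)
        mask = s1 != s2
        energy += float(np.sum(t._J[types[s1[mask]], types[s2[mask]]]))
    return energy


# ---------------------------------------------------------------------------
# Dynamics


def attempt_copy(tissue: Tissue, rng: np.random.Generator) -> bool:
    """One random copy attempt (Step 1-3 of the MCS algorithm)."""
    return _mcs(tissue, rng, 1) == 1


def monte_carlo_step(
    tissue: Tissue, rng: np.random.Generator, n_attempts: Optional[int] = None
) -> Tuple[int, int]:
    """One Monte-Carlo step: N = 3 S copy attempts (unless overridden).

    Returns (attempted, accepted).  Privileged-angle refreshes are the
    caller's responsibility (see Tissue.refresh_theta), so that the
    refresh cadence stays a simulation-level policy.
    """
    n = 3 * tissue.S if n_attempts is None else n_attempts
    return n, _mcs(tissue, rng, n)


def _mcs(tissue: Tissue, rng: np.random.Generator, n_attempts: int) -> int:
    t = tissue
    theta_x = np.cos(t.theta[: t.n_cells])
    theta_y = np.sin(t.theta[: t.n_cells])
    return int(
        _run_attempts(
            t.sigma,
            t.area,
            t.perim,
            t.ctype,
            t._J,
            t._lam_area_t,
            t._lam_pm_t,
            t._A_t,
            t._P_t,
            t._v_t,
            theta_x,
            theta_y,
            t.config.temperature,
            n_attempts,
            rng,
        )
    )


# ---------------------------------------------------------------------------
# Contacts and division geometry


def contact_pairs(sigma: np.ndarray) -> Set[Tuple[int, int]]:
    """Unordered pairs of distinct non-medium cells sharing at least one
    first-order neighbour edge."""
    pairs: Set[Tuple[int, int]] = set()
    for ax in (0, 1):
        s1 = sigma
        s2 = np.roll(sigma, -1, axis=ax)
        mask = (s1 != s2) & (s1 != MEDIUM) & (s2 != MEDIUM)
        a = s1[mask].ravel()
        b = s2[mask].ravel()
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


def contact_map(tissue: Tissue) -> "dict[int, set[int]]":
    """Adjacency of live cells: cid -> set of contacting cids."""
    adj: "dict[int, set[int]]" = {
        int(c): set() for c in np.flatnonzero(tissue.alive[: tissue.n_cells]) if c != 0
    }
    for a, b in contact_pairs(tissue.sigma):
        adj[a].add(b)
        adj[b].add(a)
    return adj


def _unwrap(nodes: np.ndarray, L: int) -> np.ndarray:
    """Map node coordinates to a connected patch around the first node,
    undoing periodic wrap (valid for cells smaller than half the box)."""
    ref = nodes[0]
    d = nodes - ref
    d = (d + L // 2) % L - L // 2
    return ref + d


def split_cell(
    tissue: Tissue, cid: int, rng: np.random.Generator
) -> Optional[Tuple[int, int]]:
    """Divide cell ``cid`` perpendicular to its principal axis.

    The node set is bisected into two connected halves of (as near as
    possible) equal size; one half keeps the mother's index, the other
    gets a fresh index.  Returns (mother_id, daughter_id), or None when
    the cell has a single node (division deferred).
    """
    nodes = tissue.nodes_of(cid)
    if len(nodes) < 2:
        return None
    un = _unwrap(nodes, tissue.L).astype(float)
    centred = un - un.mean(axis=0)
    cov = centred.T @ centred
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]  # principal direction; split perpendicular to it
    minor = v[:, 0]
    proj = centred @ axis
    perp = centred @ minor
    order = np.lexsort((perp, proj))
    half = len(nodes) // 2
    first = order[:half]
    second = order[half:]

    def ok(idx):
        sel = set(map(tuple, nodes[idx] % tissue.L))
        return _connected(sel, tissue.L)

    if not (ok(first) and ok(second)):
        # fall back to an axis-aligned cut along the larger extent
        ext = un.max(axis=0) - un.min(axis=0)
        ax = int(np.argmax(ext))
        order = np.lexsort((un[:, 1 - ax], un[:, ax]))
        first = order[:half]
        second = order[half:]
    new_nodes = [tuple(x) for x in (nodes[second] % tissue.L)]
    # daughter gets a fresh index; free the nodes first, then claim them
    for (i, j) in new_nodes:
        tissue.sigma[i, j] = MEDIUM
    tissue.area[0] += len(new_nodes)
    did = tissue.add_cell(new_nodes, int(tissue.ctype[cid]))
    tissue.area[cid] = len(first)
    tissue.perim[cid] = tissue._perimeter_of(cid)
    tissue.perim[did] = tissue._perimeter_of(did)
    tissue.theta[did] = rng.uniform(0.0, 2.0 * np.pi)
    return cid, did
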