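"""Weighted modularity maximisation by simulated annealing, with an
exact brute-force oracle and cartographic node roles.

The partition quality is Newman-Girvan weighted modularity

    Q = sum_m ( W_m / W  -  (S_m / 2W)^2 )

with W the total edge weight, W_m the within-module edge weight and S_m
the summed strength of module m's nodes. Association networks carry
signed weights; modularity and the role metrics use |w| throughout (the
sign is kept as an edge attribute upstream).

The optimiser follows the functional-cartography recipe: Metropolis
acceptance over single-node moves plus collective module merge/split
moves on a geometric cooling schedule, each connected component annealed
independently (a modularity-optimal module never spans components), and
a final greedy hill-climb from the best state visited. Node roles are
the within-module degree z-score z_i and the participation coefficient
P_i = 1 - sum_m (kappa_im / k_i)^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import DataError


@dataclass
class ModulePartition:
    """Node→module assignment with its modularity and optional node roles."""

    assignment: dict
    Q: float
    roles: pd.DataFrame | None = None
    seed: int | None = None
    schedule: dict = field(default_factory=dict)

    @property
    def M(self) -> float:  # modularity is conventionally reported as M
        return self.Q

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, module) -> list:
        return [v for v, m in self.assignment.items() if m == module]


def _abs_weight(d: dict) -> float:
    return abs(float(d.get("weight", 1.0)))


def modularity_score(network: nx.Graph, assignment: dict) -> float:
    """Weighted modularity Q of a node→module map (weights taken as |w|)."""
    missing = [v for v in network.nodes if v not in assignment]
    if missing:
        raise DataError(f"partition does not cover node(s): {missing[:5]}")
    W = sum(_abs_weight(d) for _, _, d in network.edges(data=True))
    if W == 0:
        return 0.0
    W_m: dict = {}
    S_m: dict = {}
    for u, v, d in network.edges(data=True):
        w = _abs_weight(d)
        if assignment[u] == assignment[v]:
            W_m[assignment[u]] = W_m.get(assignment[u], 0.0) + w
        S_m[assignment[u]] = S_m.get(assignment[u], 0.0) + w
        S_m[assignment[v]] = S_m.get(assignment[v], 0.0) + w
    return sum(W_m.get(m, 0.0) / W - (S_m.get(m, 0.0) / (2 * W)) ** 2 for m in
               set(assignment.values()) & (set(W_m) | set(S_m)))


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------


class _Anneal:
    """Annealing state for one connected component (global total weight W)."""

    def __init__(self, nodes, adj, strength, W, rng):
        self.nodes = nodes                      # list of node ids
        self.adj = adj                          # node -> list[(node, |w|)]
        self.s = strength                       # node -> strength
        self.W = W
        self.rng = rng
        self.assign = {v: i for i, v in enumerate(nodes)}  # singletons start
        self.Wm = dict.fromkeys(range(len(nodes)), 0.0)
        self.Sm = {i: self.s[v] for i, v in enumerate(nodes)}
        self.free: list[int] = []  # label pool for vacated modules (LIFO)
        self.size = dict.fromkeys(range(len(nodes)), 1)
        self.Q = self._full_Q()
        self.best_Q = self.Q
        self.best = dict(self.assign)

    def _full_Q(self) -> float:
        q = 0.0
        for m in self.Wm:
            q += self.Wm[m] / self.W - (self.Sm[m] / (2 * self.W)) ** 2
        return q

    def _k_to(self, v, module) -> float:
        a = self.assign
        return sum(w for u, w in self.adj[v] if a[u] == module)

    def _apply_single(self, v, b, k_va, k_vb) -> None:
        a = self.assign[v]
        if b not in self.Sm and self.free and self.free[-1] == b:
            self.free.pop()
        self.Wm[a] -= k_va
        self.Wm[b] = self.Wm.get(b, 0.0) + k_vb
        self.Sm[a] -= self.s[v]
        self.Sm[b] = self.Sm.get(b, 0.0) + self.s[v]
        self.assign[v] = b
        self.size[a] -= 1
        self.size[b] = self.size.get(b, 0) + 1
        if self.size[a] == 0:
            del self.Sm[a], self.Wm[a], self.size[a]
            self.free.append(a)

    def single_move(self, T) -> None:
        v = self.nodes[self.rng.integers(len(self.nodes))]
        a = self.assign[v]
        labels = [m for m in self.Sm if m != a]
        spare = self._spare_label()
        if spare is not None:
            labels.append(spare)
        if not labels:
            return
        b = labels[self.rng.integers(len(labels))]
        k_va = self._k_to(v, a)
        k_vb = self._k_to(v, b)
        Sa, Sb = self.Sm[a], self.Sm.get(b, 0.0)
        dQ = (k_vb - k_va) / self.W - self.s[v] * (Sb - Sa + self.s[v]) / (2 * self.W ** 2)
        if dQ >= 0 or self.rng.random() < math.exp(dQ / T):
            self._apply_single(v, b, k_va, k_vb)
            self.Q += dQ
            if self.Q > self.best_Q + 1e-13:
                self.best_Q = self.Q
                self.best = dict(self.assign)

    def _spare_label(self):
        return self.free[-1] if self.free else None

    def _between(self, a, b) -> float:
        asg = self.assign
        tot = 0.0
        for v in self.nodes:
            if asg[v] == a:
                tot += sum(w for u, w in self.adj[v] if asg[u] == b)
        return tot

    def merge_move(self, T) -> None:
        mods = list(self.Sm)
        if len(mods) < 2:
            return
        i, j = self.rng.choice(len(mods), size=2, replace=False)
        a, b = mods[i], mods[j]
        w_ab = self._between(a, b)
        dQ = w_ab / self.W - self.Sm[a] * self.Sm[b] / (2 * self.W ** 2)
        if dQ >= 0 or self.rng.random() < math.exp(dQ / T):
            for v in self.nodes:
                if self.assign[v] == b:
                    self.assign[v] = a
            self.Wm[a] = self.Wm[a] + self.Wm[b] + w_ab
            self.Sm[a] += self.Sm[b]
            self.size[a] += self.size[b]
            del self.Wm[b], self.Sm[b], self.size[b]
            self.free.append(b)
            self.Q += dQ
            if self.Q > self.best_Q + 1e-13:
                self.best_Q = self.Q
                self.best = dict(self.assign)

    def split_move(self, T) -> None:
        mods = [m for m in self.Sm if self.size[m] > 1]
        if not mods:
            return
        a = mods[self.rng.integers(len(mods))]
        members = [v for v in self.nodes if self.assign[v] == a]
        spare = self._spare_label()
        if spare is None:
            return
        old_Q = self.Q
        old_state = ({v: self.assign[v] for v in members}, dict(self.Wm),
                     dict(self.Sm), dict(self.size), list(self.free))
        # random bipartition then one greedy sweep between the two halves
        side = {v: bool(self.rng.integers(2)) for v in members}
        if all(side.values()) or not any(side.values()):
            side[members[0]] = not side[members[0]]
        for v in members:
            if side[v]:
                self._apply_single(v, spare, self._k_to(v, self.assign[v]),
                                   self._k_to(v, spare))
        for v in members:
            cur = self.assign[v]
            other = spare if cur == a else a
            if other not in self.Sm:
                continue
            k_cur = self._k_to(v, cur)
            k_oth = self._k_to(v, other)
            dQ = (k_oth - k_cur) / self.W - self.s[v] * (
                self.Sm.get(other, 0.0) - self.Sm[cur] + self.s[v]) / (2 * self.W ** 2)
            if dQ > 0:
                self._apply_single(v, other, k_cur, k_oth)
        self.Q = self._full_Q()
        dQ_total = self.Q - old_Q
        if dQ_total >= 0 or self.rng.random() < math.exp(dQ_total / T):
            if self.Q > self.best_Q + 1e-13:
                self.best_Q = self.Q
                self.best = dict(self.assign)
        else:  # revert
            asg, Wm, Sm, size, free = old_state
            self.assign.update(asg)
            self.Wm, self.Sm, self.size, self.free = Wm, Sm, size, free
            self.Q = old_Q

    def greedy_polish(self) -> None:
        """Hill-climb single moves from the best state until no improvement."""
        self.assign = dict(self.best)
        self._rebuild_stats()
        improved = True
        while improved:
            improved = False
            for v in self.nodes:
                a = self.assign[v]
                per_mod: dict = {}
                for u, w in self.adj[v]:
                    m = self.assign[u]
                    per_mod[m] = per_mod.get(m, 0.0) + w
                k_va = per_mod.get(a, 0.0)
                spare = self._spare_label()
                cands = [m for m in list(self.Sm) if m != a]
                if spare is not None:
                    cands.append(spare)
                best_dQ, best_b, best_kvb = 1e-12, None, 0.0
                for b in cands:
                    k_vb = per_mod.get(b, 0.0)
                    dQ = (k_vb - k_va) / self.W - self.s[v] * (
                        self.Sm.get(b, 0.0) - self.Sm[a] + self.s[v]) / (2 * self.W ** 2)
                    if dQ > best_dQ:
                        best_dQ, best_b, best_kvb = dQ, b, k_vb
                if best_b is not None:
                    self._apply_single(v, best_b, k_va, best_kvb)
                    self.Q += best_dQ
                    improved = True
        if self.Q > self.best_Q:
            self.best_Q = self.Q
            self.best = dict(self.assign)

    def _rebuild_stats(self) -> None:
        self.Wm, self.Sm, self.size = {}, {}, {}
        for v in self.nodes:
            m = self.assign[v]
            self.Sm[m] = self.Sm.get(m, 0.0) + self.s[v]
            self.size[m] = self.size.get(m, 0) + 1
            self.Wm.setdefault(m, 0.0)
            for u, w in self.adj[v]:
                if self.assign[u] == m and str(u) > str(v):
                    self.Wm[m] += w
        self.free = [i for i in reversed(range(len(self.nodes))) if i not in self.Sm]
        self.Q = self._full_Q()


def anneal_partition(network: nx.Graph, T0: float | None = None,
                     cooling_factor: float = 0.995, iters_per_T: int | None = None,
                     T_min_factor: float = 1e-3, seed: int | None = 0,
                     compute_roles: bool = True) -> ModulePartition:
    """Best-Q partition found by simulated annealing (deterministic per seed).

    T0 defaults to 1/(2 n_nodes); iters_per_T defaults to n^2 single-node
    moves plus n collective merge/split moves per temperature; cooling is
    geometric down to T0 * T_min_factor.
    """
    if network.number_of_nodes() == 0:
        raise DataError("cannot partition an empty network")
    W = sum(_abs_weight(d) for _, _, d in network.edges(data=True))
    if W == 0:
        assign = {v: i for i, v in enumerate(sorted(network.nodes, key=str))}
        part = ModulePartition(assign, 0.0, seed=seed)
        if compute_roles:
            part.roles = cartographic_roles(network, part)
        return part

    rng = np.random.default_rng(seed)
    n_total = network.number_of_nodes()
    T0 = T0 if T0 is not None else 1.0 / (2.0 * n_total)
    assign_out: dict = {}
    offset = 0
    accepted_trace: list[int] = []
    for comp in sorted(nx.connected_components(network), key=lambda c: sorted(map(str, c))):
        nodes = sorted(comp, key=str)
        adj = {v: [(u, _abs_weight(d)) for u, d in network[v].items()] for v in nodes}
        strength = {v: sum(w for _, w in adj[v]) for v in nodes}
        state = _Anneal(nodes, adj, strength, W, rng)
        n = len(nodes)
        if n > 1:
            singles = iters_per_T if iters_per_T is not None else n * n
            collective = max(1, n)
            T = T0
            T_min = T0 * T_min_factor
            while T > T_min:
                for _ in range(singles):
                    state.single_move(T)
                for c in range(collective):
                    if c % 2 == 0:
                        state.merge_move(T)
                    else:
                        state.split_move(T)
                T *= cooling_factor
        state.greedy_polish()
        relabel: dict = {}
        for v in nodes:
            m = state.best[v]
            if m not in relabel:
                relabel[m] = offset + len(relabel)
            assign_out[v] = relabel[m]
        offset += len(relabel)

    Q = modularity_score(network, assign_out)
    part = ModulePartition(assign_out, Q, seed=seed,
                           schedule={"T0": T0, "cooling_factor": cooling_factor,
                                     "iters_per_T": iters_per_T,
                                     "T_min_factor": T_min_factor})
    if compute_roles:
        part.roles = cartographic_roles(network, part)
    return part


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------


def _set_partitions(n: int):
    """All restricted-growth strings of length n (set partitions of 0..n-1)."""
    a = [0] * n
    b = [0] * n  # b[i] = max(a[:i+1])
    while True:
        yield tuple(a)
        i = n - 1
        while i > 0 and a[i] == b[i - 1] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        b[i] = max(b[i - 1], a[i])
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = b[j - 1]


def brute_force_partition(network: nx.Graph) -> ModulePartition:
    """Exact maximum-modularity partition by exhaustive enumeration (n <= 12)."""
    nodes = sorted(network.nodes, key=str)
    n = len(nodes)
    if n == 0:
        raise DataError("cannot partition an empty network")
    if n > 12:
        raise DataError(f"brute force limited to 12 nodes, got {n}")
    idx = {v: i for i, v in enumerate(nodes)}
    edges = [(idx[u], idx[v], _abs_weight(d)) for u, v, d in network.edges(data=True)]
    W = sum(w for _, _, w in edges)
    if W == 0:
        return ModulePartition({v: i for i, v in enumerate(nodes)}, 0.0)
    strength = [0.0] * n
    for i, j, w in edges:
        strength[i] += w
        strength[j] += w
    best_Q, best_a = -np.inf, None
    for a in _set_partitions(n):
        Wm: dict = {}
        Sm: dict = {}
        for i, j, w in edges:
            if a[i] == a[j]:
                Wm[a[i]] = Wm.get(a[i], 0.0) + w
        for i in range(n):
            Sm[a[i]] = Sm.get(a[i], 0.0) + strength[i]
        q = sum(Wm.get(m, 0.0) / W - (Sm[m] / (2 * W)) ** 2 for m in Sm)
        if q > best_Q + 1e-15:
            best_Q, best_a = q, a
    return ModulePartition({v: best_a[idx[v]] for v in nodes}, float(best_Q))


# ---------------------------------------------------------------------------
# Cartographic roles
# ---------------------------------------------------------------------------


def cartographic_roles(network: nx.Graph, partition: ModulePartition) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    kappa_i is node i's strength inside its own module; z_i standardises
    kappa over the module (sd 0 → z 0). P_i = 1 - sum_m (kappa_im/k_i)^2
    over all modules, with k_i the total strength (isolated nodes get
    z = P = 0).
    """
    assign = partition.assignment
    missing = [v for v in network.nodes if v not in assign]
    if missing:
        raise DataError(f"partition does not cover node(s): {missing[:5]}")
    nodes = sorted(network.nodes, key=str)
    kappa_in = {}
    k_tot = {}
    kappa_by_mod: dict = {}
    for v in nodes:
        per_mod: dict = {}
        for u, d in network[v].items():
            w = _abs_weight(d)
            per_mod[assign[u]] = per_mod.get(assign[u], 0.0) + w
        kappa_by_mod[v] = per_mod
        kappa_in[v] = per_mod.get(assign[v], 0.0)
        k_tot[v] = sum(per_mod.values())
    z = {}
    for m in set(assign.values()):
        members = [v for v in nodes if assign[v] == m]
        vals = np.array([kappa_in[v] for v in members])
        mu, sd = vals.mean(), vals.std()
        for v in members:
            z[v] = 0.0 if sd == 0 else (kappa_in[v] - mu) / sd
    P = {}
    for v in nodes:
        if k_tot[v] == 0:
            P[v] = 0.0
        else:
            P[v] = 1.0 - sum((k / k_tot[v]) ** 2 for k in kappa_by_mod[v].values())
    return pd.DataFrame({"module": [assign[v] for v in nodes],
                         "z": [z[v] for v in nodes],
                         "P": [P[v] for v in nodes]},
                        index=pd.Index(nodes, name="node"))
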