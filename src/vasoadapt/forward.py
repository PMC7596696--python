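"""Time-stepping biphasic blood-flow simulation.

At every global time step the pressure and flow field of the network is
obtained from a sparse linear solve (Poiseuille flow with an effective,
haematocrit-dependent transmissibility per vessel), after which the
discrete red blood cells are advected with the cell velocity of their
vessel.  RBCs reaching a divergent bifurcation are routed by sampling
the empirical phase-separation law; inflow boundaries inject cells to
maintain the prescribed inflow tube haematocrit and outflow boundaries
remove them.

Internal unit system: µm (length), ms (time), Pa (pressure), fL = µm³
(volume), hence flows in µm³/ms, transmissibilities in µm³/(Pa·ms) and
viscosities in Pa·ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

from .netgraph import VascularNetwork
from .rheology import (
    RheologyParams,
    discharge_from_tube,
    fahraeus_ratio,
    phase_separation_probability,
    relative_viscosity,
    tube_haematocrit,
)

__all__ = [
    "FlowState",
    "TimeAveragedField",
    "LinearNetworkSystem",
    "ForwardSimulator",
    "rbc_velocity",
    "run_forward",
]

#: haematocrit above which the empirical laws are evaluated at the cap
#: (the physical state is still tracked; a warning is emitted once)
HT_LAW_CAP = 0.95


@dataclass
class FlowState:
    """Instantaneous network flow field at one time step."""

    pressure: np.ndarray  # (Nn,) Pa
    flow: np.ndarray  # (Ne,) µm³/ms, signed along stored orientation
    transmissibility: np.ndarray  # (Ne,) µm³/(Pa·ms)
    mu_rel: np.ndarray  # (Ne,) relative apparent viscosity
    v_rbc: np.ndarray  # (Ne,) µm/ms, signed like the flow
    source: np.ndarray  # (Nn,) µm³/ms boundary source/sink terms
    h_t: np.ndarray  # (Ne,) tube haematocrit
    h_d: np.ndarray  # (Ne,) discharge haematocrit
    time_index: int = 0


@dataclass
class TimeAveragedField:
    """Arithmetic means of the flow field over a window of steps."""

    flow: np.ndarray  # ⟨q⟩ per edge
    pressure: np.ndarray  # ⟨p⟩ per node
    source: np.ndarray  # ⟨b⟩ per node
    transmissibility: np.ndarray  # window mean of instantaneous T per edge
    n_steps: int
    dt: float

    @property
    def boundary_inflow(self) -> float:
        """Total inflow over the boundaries, Σ max(⟨b⟩, 0)."""
        return float(np.sum(np.maximum(self.source, 0.0)))


class LinearNetworkSystem:
    """Sparse node-balance system with symmetric Dirichlet elimination.

    The flow balance at every node yields a weighted graph Laplacian in
    the nodal pressures.  Rows and columns of fixed-pressure nodes are
    eliminated symmetrically, so the reduced interior matrix stays
    symmetric positive definite and can serve both the forward solve
    and its own transpose in adjoint solves.
    """

    def __init__(self, network: VascularNetwork):
        self.network = network
        nn = network.n_nodes
        i = network.edge_nodes[:, 0]
        j = network.edge_nodes[:, 1]
        self.fixed = np.zeros(nn, dtype=bool)
        self.fixed[network.fixed_pressure_nodes] = True
        self.fixed_pressure = np.where(
            self.fixed, np.nan_to_num(network.pressure, nan=0.0), 0.0
        )
        interior = ~self.fixed
        self.interior = interior
        self.n_interior = int(interior.sum())
        perm = -np.ones(nn, dtype=np.int64)
        perm[interior] = np.arange(self.n_interior)
        self._perm = perm

        # Laplacian entries: (i,i,+T) (j,j,+T) (i,j,-T) (j,i,-T) per edge
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([i, j, j, i])
        self._sign = np.concatenate(
            [np.ones_like(i), np.ones_like(i), -np.ones_like(i), -np.ones_like(i)]
        ).astype(float)
        self._edge_of_entry = np.tile(np.arange(network.n_edges), 4)
        keep = interior[rows] & interior[cols]
        self._keep = keep
        self._rows_red = perm[rows[keep]]
        self._cols_red = perm[cols[keep]]
        # entries coupling an interior row to a fixed column move to the rhs
        to_rhs = interior[rows] & ~interior[cols]
        self._rhs_rows = perm[rows[to_rhs]]
        self._rhs_cols = cols[to_rhs]
        self._rhs_sign = self._sign[to_rhs]
        self._rhs_edge = self._edge_of_entry[to_rhs]

    def reduced_matrix(self, transmissibility: np.ndarray) -> csr_matrix:
        data = self._sign[self._keep] * transmissibility[self._edge_of_entry[self._keep]]
        return csr_matrix(
            (data, (self._rows_red, self._cols_red)),
            shape=(self.n_interior, self.n_interior),
        )

    def solve_pressure(self, transmissibility: np.ndarray) -> np.ndarray:
        """Nodal pressures satisfying flow balance at interior nodes."""
        nn = self.network.n_nodes
        p = self.fixed_pressure.copy()
        if self.n_interior == 0:
            return p
        rhs = np.zeros(self.n_interior)
        np.add.at(
            rhs,
            self._rhs_rows,
            -self._rhs_sign
            * transmissibility[self._rhs_edge]
            * self.fixed_pressure[self._rhs_cols],
        )
        a = self.reduced_matrix(transmissibility)
        try:
            x = spsolve(a.tocsc(), rhs)
        except Exception as err:  # singular system
            raise np.linalg.LinAlgError(
                "pressure system is singular; a component of the network has "
                "no fixed-pressure node"
            ) from err
        if not np.all(np.isfinite(x)):
            raise np.linalg.LinAlgError(
                "pressure system is singular; a component of the network has "
                "no fixed-pressure node"
            )
        p[self.interior] = x
        return p

    def solve_interior(self, transmissibility: np.ndarray, rhs: np.ndarray) -> np.ndarray:
        """Solve the reduced interior system A x = rhs (A is symmetric)."""
        if self.n_interior == 0:
            return np.zeros(0)
        a = self.reduced_matrix(transmissibility)
        x = spsolve(a.tocsc(), rhs)
        res = np.linalg.norm(a @ x - rhs)
        scale = np.linalg.norm(rhs)
        if scale > 0 and res > 1e-10 * scale:
            raise np.linalg.LinAlgError(
                f"interior solve residual {res / scale:.2e} exceeds 1e-10"
            )
        return x


def rbc_velocity(q, d, h_t, params: RheologyParams | None = None):
    """RBC velocity from the flow rate: ``v_rbc = q/A · H_d/H_t``.

    Signed like ``q``; for an empty vessel the dilute limit
    ``H_d/H_t → 1/r(d) ≥ 1`` applies.  RBCs always move at least as fast
    as the mean bulk velocity in the capillary range (Fåhraeus effect).
    """
    q = np.asarray(q, dtype=float)
    d = np.asarray(d, dtype=float)
    h_t = np.asarray(h_t, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    v_plasma = q / (0.25 * np.pi * d**2)
    h_d = np.asarray(discharge_from_tube(h_t, d))
    ratio = np.where(
        h_t > 0,
        np.divide(h_d, h_t, out=np.ones_like(h_d), where=h_t > 0),
        1.0 / np.asarray(fahraeus_ratio(d)),
    )
    out = v_plasma * ratio
    if out.ndim == 0:
        return float(out)
    return out


def _edge_source_accumulation(network: VascularNetwork, q: np.ndarray) -> np.ndarray:
    """Net flow leaving each node through its incident edges."""
    b = np.zeros(network.n_nodes)
    np.add.at(b, network.edge_nodes[:, 0], q)
    np.add.at(b, network.edge_nodes[:, 1], -q)
    return b


class ForwardSimulator:
    """Biphasic (plasma + discrete RBC) flow simulator on a vascular graph.

    Parameters
    ----------
    network
        The vascular graph with boundary conditions.
    params
        Haemorheological parameters.
    dt
        Global time step in ms.
    plasma_only
        If True no RBCs are tracked; the simulator is deterministic and
        linear in the boundary pressures.
    rng
        numpy random generator driving the stochastic bifurcation rule.
        All randomness of the simulator flows through it.

    The RBC population is stored as flat arrays of particle arc-length
    positions (µm along the stored edge orientation) and edge indices.
    Particles in one edge share the edge velocity, so their order is
    preserved by construction.
    """

    def __init__(
        self,
        network: VascularNetwork,
        params: RheologyParams | None = None,
        dt: float = 0.4,
        plasma_only: bool = False,
        rng: np.random.Generator | None = None,
    ):
        if dt <= 0:
            raise ValueError("time step must be positive")
        self.network = network
        self.params = params or RheologyParams()
        self.dt = dt
        self.plasma_only = plasma_only
        self.rng = rng or np.random.default_rng()
        self.system = LinearNetworkSystem(network)
        self.diameter = network.diameter.copy()  # current diameters α·d0
        self.rbc_pos = np.empty(0, dtype=float)
        self.rbc_edge = np.empty(0, dtype=np.int64)
        self.injected = 0
        self.exited = 0
        self.initial_total = 0
        self.time_index = 0
        self._area = None
        self._incident = network.incident_edges()
        self._inject_acc: dict[tuple[int, int], float] = {}
        self._ht_warned = False

    # -- state management ---------------------------------------------
    def set_alpha(self, alpha: np.ndarray) -> None:
        """Set current diameters to ``alpha * d0`` per edge."""
        alpha = np.asarray(alpha, dtype=float)
        if np.any(alpha <= 0):
            raise ValueError("relative diameters must be positive")
        self.diameter = alpha * self.network.diameter

    @property
    def n_rbc_per_edge(self) -> np.ndarray:
        return np.bincount(self.rbc_edge, minlength=self.network.n_edges)

    @property
    def n_rbc_total(self) -> int:
        return len(self.rbc_pos)

    def seed_haematocrit(self, h_t: float) -> None:
        """Populate every edge with equally spaced RBCs at tube haematocrit
        ``h_t`` (rounded to whole cells per edge)."""
        if self.plasma_only:
            raise ValueError("cannot seed RBCs in plasma-only mode")
        net = self.network
        pos_parts = []
        edge_parts = []
        for e in range(net.n_edges):
            vol = 0.25 * np.pi * self.diameter[e] ** 2 * net.length[e]
            n = int(round(h_t * vol / self.params.v_rbc))
            if n == 0:
                continue
            s = (np.arange(n) + 0.5) * net.length[e] / n
            pos_parts.append(s)
            edge_parts.append(np.full(n, e, dtype=np.int64))
        if pos_parts:
            self.rbc_pos = np.concatenate(pos_parts)
            self.rbc_edge = np.concatenate(edge_parts)
        self.initial_total = len(self.rbc_pos)

    # -- instantaneous solve ------------------------------------------
    def solve(self) -> FlowState:
        """Pressure/flow solve for the current RBC distribution."""
        net = self.network
        d = self.diameter
        if self.plasma_only:
            ht = np.zeros(net.n_edges)
            hd = np.zeros(net.n_edges)
            mu_rel = np.ones(net.n_edges)
        else:
            n_rbc = self.n_rbc_per_edge
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ht = np.asarray(
                    tube_haematocrit(n_rbc, self.params.v_rbc, d, net.length)
                )
            ht_law = ht
            if np.any(ht > HT_LAW_CAP):
                if not self._ht_warned:
                    warnings.warn(
                        f"tube haematocrit exceeded {HT_LAW_CAP}; empirical laws "
                        "evaluated at the cap",
                        stacklevel=2,
                    )
                    self._ht_warned = True
                ht_law = np.minimum(ht, HT_LAW_CAP)
            hd = np.asarray(discharge_from_tube(ht_law, d))
            h_for_mu = hd if self.params.use_discharge_viscosity else ht_law
            mu_rel = np.asarray(
                relative_viscosity(h_for_mu, d, self.params.viscosity_law)
            )
        t = np.pi * d**4 / (128.0 * net.length * self.params.mu_p * mu_rel)
        p = self.system.solve_pressure(t)
        q = t * (p[net.edge_nodes[:, 0]] - p[net.edge_nodes[:, 1]])
        # interior entries of b are the (tiny) flow-balance residuals
        b = _edge_source_accumulation(net, q)
        area = 0.25 * np.pi * d**2
        v_plasma = q / area
        if self.plasma_only:
            v_rbc = v_plasma
        else:
            ratio = np.where(
                ht > 0, np.divide(hd, ht, out=np.ones_like(hd), where=ht > 0),
                1.0 / np.asarray(fahraeus_ratio(d)),
            )
            v_rbc = v_plasma * ratio
        return FlowState(
            pressure=p,
            flow=q,
            transmissibility=t,
            mu_rel=mu_rel,
            v_rbc=v_rbc,
            source=b,
            h_t=ht,
            h_d=hd,
            time_index=self.time_index,
        )

    # -- RBC advection -------------------------------------------------
    def _outflow_edges(self, node: int, q: np.ndarray) -> list[int]:
        out = []
        for e in self._incident[node]:
            i, j = self.network.edge_nodes[e]
            if (i == node and q[e] > 0) or (j == node and q[e] < 0):
                out.append(int(e))
        return out

    def _choose_daughter(
        self, candidates: list[int], q: np.ndarray, flow: FlowState, parent: int
    ) -> int:
        """Sample the downstream edge among ``candidates`` (flow-ordered
        pairwise application of the two-daughter phase-separation law)."""
        cands = sorted(candidates)
        while len(cands) > 1:
            a = cands[0]
            rest = cands[1:]
            q_a = abs(q[a])
            q_rest = sum(abs(q[e]) for e in rest)
            d_rest = max(self.diameter[e] for e in rest)
            total = q_a + q_rest
            if total <= 0:
                return cands[0]
            p_a = phase_separation_probability(
                q_a / total,
                min(flow.h_d[parent], 0.99),
                self.diameter[parent],
                self.diameter[a],
                d_rest,
                self.params.phase_separation,
            )
            if self.rng.random() < p_a:
                return a
            cands = rest
        return cands[0]

    def advance(self, flow: FlowState) -> None:
        """Move all RBCs for one time step based on the current velocities."""
        if self.plasma_only:
            self.time_index += 1
            return
        net = self.network
        q = flow.flow
        v = flow.v_rbc
        l = net.length
        if len(self.rbc_pos):
            vel = v[self.rbc_edge]
            self.rbc_pos = self.rbc_pos + vel * self.dt
            over_hi = self.rbc_pos > l[self.rbc_edge]
            over_lo = self.rbc_pos < 0.0
            crossing = np.flatnonzero(over_hi | over_lo)
            if len(crossing):
                self._handle_crossings(crossing, over_hi, flow)
        self._inject(flow)
        self.time_index += 1

    def _handle_crossings(
        self, crossing: np.ndarray, over_hi: np.ndarray, flow: FlowState
    ) -> None:
        net = self.network
        q = flow.flow
        v = flow.v_rbc
        l = net.length
        # arrival order: particles that reached their node earliest first
        overshoot = np.where(
            over_hi[crossing],
            self.rbc_pos[crossing] - l[self.rbc_edge[crossing]],
            -self.rbc_pos[crossing],
        )
        speed = np.abs(v[self.rbc_edge[crossing]])
        order = np.argsort(-overshoot / np.maximum(speed, 1e-300), kind="stable")
        remove = []
        for k in crossing[order]:
            e = int(self.rbc_edge[k])
            i, j = net.edge_nodes[e]
            node = int(j) if over_hi[k] else int(i)
            shoot = (
                self.rbc_pos[k] - l[e] if over_hi[k] else -self.rbc_pos[k]
            )
            if self.system.fixed[node]:
                remove.append(k)
                self.exited += 1
                continue
            out = self._outflow_edges(node, q)
            if not out:
                # stagnation point: hold the particle at the junction
                self.rbc_pos[k] = l[e] if over_hi[k] else 0.0
                continue
            if len(out) == 1:
                new_e = out[0]
            else:
                new_e = self._choose_daughter(out, q, flow, parent=e)
            v_old = abs(v[e])
            v_new = abs(v[new_e])
            residual = shoot * (v_new / v_old) if v_old > 0 else 0.0
            residual = min(residual, 0.999 * l[new_e])  # at most one junction hop
            ni, nj = net.edge_nodes[new_e]
            self.rbc_edge[k] = new_e
            self.rbc_pos[k] = residual if ni == node else l[new_e] - residual
        if remove:
            keep = np.ones(len(self.rbc_pos), dtype=bool)
            keep[remove] = False
            self.rbc_pos = self.rbc_pos[keep]
            self.rbc_edge = self.rbc_edge[keep]

    def _inject(self, flow: FlowState) -> None:
        """Maintain the prescribed inflow tube haematocrit.

        Each inflow edge carries a fractional accumulator incremented by
        the RBC linear density matching the target haematocrit times the
        distance travelled this step; whole cells are injected at the
        upstream end whenever the accumulator exceeds one.
        """
        net = self.network
        q = flow.flow
        new_pos = []
        new_edge = []
        for node in net.inflow_ht_nodes:
            target_ht = net.ht_in[node]
            for e in self._outflow_edges(int(node), q):
                lam = target_ht * 0.25 * np.pi * self.diameter[e] ** 2 / self.params.v_rbc
                key = (int(node), e)
                acc = self._inject_acc.get(key, 0.0)
                acc += abs(flow.v_rbc[e]) * self.dt * lam
                while acc >= 1.0:
                    acc -= 1.0
                    i, _ = net.edge_nodes[e]
                    new_pos.append(0.0 if i == node else net.length[e])
                    new_edge.append(e)
                    self.injected += 1
                self._inject_acc[key] = acc
        if new_pos:
            self.rbc_pos = np.concatenate([self.rbc_pos, np.asarray(new_pos)])
            self.rbc_edge = np.concatenate(
                [self.rbc_edge, np.asarray(new_edge, dtype=np.int64)]
            )

    # -- stepping ------------------------------------------------------
    def step(self) -> FlowState:
        """One global time step: solve the flow field, then move the RBCs."""
        flow = self.solve()
        self.advance(flow)
        return flow

    def run_window(self, n_steps: int) -> TimeAveragedField:
        """Run ``n_steps`` steps and return the arithmetic window means."""
        if n_steps < 1:
            raise ValueError("averaging window must contain at least one step")
        net = self.network
        sum_q = np.zeros(net.n_edges)
        sum_p = np.zeros(net.n_nodes)
        sum_b = np.zeros(net.n_nodes)
        sum_t = np.zeros(net.n_edges)
        for _ in range(n_steps):
            fs = self.step()
            sum_q += fs.flow
            sum_p += fs.pressure
            sum_b += fs.source
            sum_t += fs.transmissibility
        inv = 1.0 / n_steps
        return TimeAveragedField(
            flow=sum_q * inv,
            pressure=sum_p * inv,
            source=sum_b * inv,
            transmissibility=sum_t * inv,
            n_steps=n_steps,
            dt=self.dt,
        )


def run_forward(
    network: VascularNetwork,
    params: RheologyParams | None = None,
    dt: float = 0.4,
    n_steps: int = 500,
    n_warmup: int = 0,
    seed_ht: float | None = None,
    plasma_only: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[TimeAveragedField, ForwardSimulator]:
    """Convenience driver: build a simulator, warm it up and average a window.

    Returns the window means and the simulator (whose particle state is
    the end-of-window state).
    """
    sim = ForwardSimulator(network, params, dt=dt, plasma_only=plasma_only, rng=rng)
    if not plasma_only:
        if seed_ht is None:
            inflow = network.inflow_ht_nodes
            seed_ht = float(np.mean(network.ht_in[inflow])) if len(inflow) else 0.0
        if seed_ht > 0:
            sim.seed_haematocrit(seed_ht)
    for _ in range(n_warmup):
        sim.step()
    avg = sim.run_window(n_steps)
    return avg, sim
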