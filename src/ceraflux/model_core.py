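"""GMA model of the yeast ceramide subsystem.

The network covers biosynthesis and utilization of dihydroceramides (DHC)
and phytoceramides (PHC) of five fatty-acyl chain classes, together with
the fatty-acyl-CoA elongation/desaturation column that supplies the
ceramide-synthase co-substrates.  It has 15 dependent metabolite pools and
53 fluxes.  Every flux follows a Generalized Mass Action (power-law) form

    v_j(t) = a_j(t) * prod(internal substrates, order 1) * prod(boundary drivers)

where ``a_j`` is the product of a rate constant and the enzyme activity
(a Vmax-like quantity); substrates enter with kinetic order 1 and the
activity enters linearly.

Pools X1..X5 are DHC, X6..X10 PHC and X11..X15 fatty acyl CoA, each block
spanning the chain classes C14/C16, C18, C18:1, C24/C24:1, C26/C26:1 in
order.  The sphingoid bases DHS/PHS, the lumped complex sphingolipid pool
(IPC/MIPC/M(IP)2C) and the fatty-acid source are boundary drivers: time
dependent inputs, not state variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: Fixed ordering of the five fatty-acyl chain classes.
CHAIN_CLASSES = ("C14/C16", "C18", "C18:1", "C24/C24:1", "C26/C26:1")

POOL_ROLES = ("DHC", "PHC", "FattyAcylCoA")

ENZYME_CLASSES = (
    "ceramide_synthase",
    "dihydroceramidase",
    "phytoceramidase",
    "IPC_synthase",
    "IPCase",
    "DHC_hydroxylase",
    "remodelase",
    "elongase",
    "desaturase",
)

#: Number of reactions each enzyme class catalyzes in the default network.
EXPECTED_CLASS_COUNTS = {
    "ceramide_synthase": 10,
    "dihydroceramidase": 5,
    "phytoceramidase": 5,
    "IPC_synthase": 10,
    "IPCase": 10,
    "DHC_hydroxylase": 5,
    "remodelase": 1,
    "elongase": 6,
    "desaturase": 1,
}

N_POOLS = 15
N_FLUXES = 53


class TopologyError(ValueError):
    """Raised when a network configuration violates structural invariants."""


@dataclass(frozen=True)
class MetabolitePool:
    id: int
    role: str
    chain: str


@dataclass(frozen=True)
class FluxSpec:
    """One reaction of the network.

    ``consumes``/``produces`` hold internal pool ids (at most one each for
    the ceramide network); internal substrates carry kinetic order 1.
    ``boundary_inputs`` are names of external drivers that multiply the
    rate.  A flux is a boundary flux if it exchanges material with the
    outside (missing consumer or producer, or a boundary driver).
    """

    id: int
    enzyme_class: str
    consumes: tuple[int, ...] = ()
    produces: tuple[int, ...] = ()
    boundary_inputs: tuple[str, ...] = ()

    @property
    def substrates(self) -> tuple[tuple[int, int], ...]:
        return tuple((pid, 1) for pid in self.consumes)

    @property
    def is_boundary(self) -> bool:
        return bool(self.boundary_inputs) or not self.consumes or not self.produces


DriverFn = Callable[[float], float]


@dataclass
class StoichiometricModel:
    pools: list[MetabolitePool]
    fluxes: list[FluxSpec]
    S: np.ndarray
    boundary_drivers: dict[str, DriverFn]
    groups: dict[str, list[int]] = field(default_factory=dict)
    unconstrained_fluxes: list[int] = field(default_factory=list)

    # fast-path index arrays built on first use
    _sub_idx: np.ndarray | None = field(default=None, repr=False)
    _drv_names: list[str] | None = field(default=None, repr=False)
    _drv_idx: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def n_fluxes(self) -> int:
        return len(self.fluxes)

    def enzyme_class_of(self, flux_id: int) -> str:
        return self.fluxes[flux_id - 1].enzyme_class

    def chain_class_of(self, flux_id: int) -> str | None:
        """Chain class of a flux, from the pool it touches (None for pure
        boundary plumbing such as the remodelase)."""
        fx = self.fluxes[flux_id - 1]
        for pid in fx.produces + fx.consumes:
            return self.pools[pid - 1].chain
        return None

    def class_members(self, enzyme_class: str) -> list[int]:
        return [f.id for f in self.fluxes if f.enzyme_class == enzyme_class]

    def group_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Indicator matrix G (n_groups x n_fluxes) and group names."""
        names = list(self.groups)
        G = np.zeros((len(names), self.n_fluxes))
        for i, name in enumerate(names):
            for fid in self.groups[name]:
                G[i, fid - 1] = 1.0
        return G, names

    def _build_index(self) -> None:
        if self._sub_idx is not None:
            return
        nsub = max((len(f.consumes) for f in self.fluxes), default=0)
        ndrv = max((len(f.boundary_inputs) for f in self.fluxes), default=0)
        if nsub > 1 or ndrv > 1:  # generic networks fall back to a loop
            self._sub_idx = np.empty(0)
            return
        # virtual index n_pools holds the constant 1.0
        sub = np.full(self.n_fluxes, self.n_pools, dtype=np.intp)
        names = sorted({n for f in self.fluxes for n in f.boundary_inputs})
        drv = np.full(self.n_fluxes, len(names), dtype=np.intp)
        for j, f in enumerate(self.fluxes):
            if f.consumes:
                sub[j] = f.consumes[0] - 1
            if f.boundary_inputs:
                drv[j] = names.index(f.boundary_inputs[0])
        self._sub_idx, self._drv_names, self._drv_idx = sub, names, drv

    def driver_values(self, t: float) -> dict[str, float]:
        return {name: fn(t) for name, fn in self.boundary_drivers.items()}


# ---------------------------------------------------------------------------
# default topology (encodes the ceramide pathway diagram)
# ---------------------------------------------------------------------------

def default_topology() -> dict:
    """Default network description of the ceramide subsystem.

    Per chain class k (pools: DHC=k+1, PHC=k+6, CoA=k+11) the DHC column
    holds ceramide synthase (DHS + CoA -> DHC), IPCase (IPC -> DHC),
    dihydroceramidase (DHC -> DHS, exits), DHC hydroxylase (DHC -> PHC) and
    IPC synthase (DHC -> IPC, exits); the PHC column mirrors it without the
    hydroxylase.  The center column elongates/desaturates acyl CoAs.
    """
    fluxes: list[dict] = []

    def add(fid, ec, consumes=(), produces=(), drivers=()):
        fluxes.append(
            dict(id=fid, enzyme_class=ec, consumes=list(consumes),
                 produces=list(produces), boundary_inputs=list(drivers))
        )

    for k in range(5):
        dhc, phc, coa = k + 1, k + 6, k + 11
        b = 5 * k
        add(b + 1, "ceramide_synthase", [coa], [dhc], ["DHS"])
        add(b + 2, "IPCase", [], [dhc], ["IPC"])
        add(b + 3, "dihydroceramidase", [dhc], [])
        add(b + 4, "DHC_hydroxylase", [dhc], [phc])
        add(b + 5, "IPC_synthase", [dhc], [])
    for k in range(5):
        dhc, phc, coa = k + 1, k + 6, k + 11
        b = 26 + 4 * k
        add(b + 0, "ceramide_synthase", [coa], [phc], ["PHS"])
        add(b + 1, "IPCase", [], [phc], ["IPC"])
        add(b + 2, "phytoceramidase", [phc], [])
        add(b + 3, "IPC_synthase", [phc], [])
    add(46, "remodelase", [], [11], ["FA"])
    add(47, "elongase", [11], [12])
    add(48, "elongase", [12], [14])
    add(49, "desaturase", [12], [13])
    add(50, "elongase", [14], [15])
    add(51, "elongase", [13], [14])
    add(52, "elongase", [14], [])
    add(53, "elongase", [15], [])

    pools = (
        [dict(id=i + 1, role="DHC", chain=CHAIN_CLASSES[i]) for i in range(5)]
        + [dict(id=i + 6, role="PHC", chain=CHAIN_CLASSES[i]) for i in range(5)]
        + [dict(id=i + 11, role="FattyAcylCoA", chain=CHAIN_CLASSES[i]) for i in range(5)]
    )

    groups = {
        "synthase_dhc": [1, 6, 11, 16, 21],
        "synthase_phc": [26, 30, 34, 38, 42],
        "ipcase_dhc": [2, 7, 12, 17, 22],
        "ipcase_phc": [27, 31, 35, 39, 43],
        "dihydroceramidase": [3, 8, 13, 18, 23],
        "phytoceramidase": [28, 32, 36, 40, 44],
        "hydroxylase": [4, 9, 14, 19, 24],
        "ipc_synthase_dhc": [5, 10, 15, 20, 25],
        "ipc_synthase_phc": [29, 33, 37, 41, 45],
        "coa_supply": [46],
        "elongation": [47, 48, 50, 51],
        "coa_drain": [52, 53],
    }

    return dict(
        pools=pools,
        fluxes=fluxes,
        drivers={"DHS": 1.0, "PHS": 1.0, "IPC": 1.0, "FA": 1.0},
        groups=groups,
        unconstrained_fluxes=[49],
    )


def load_topology(path) -> dict:
    """Load a topology config from a YAML (or JSON-compatible) file."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_topology(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def _make_driver(value) -> DriverFn:
    if np.isscalar(value):
        v = float(value)
        return lambda t: v
    tab = np.asarray(value, dtype=float)
    tt, vv = tab[:, 0], tab[:, 1]

    def fn(t, tt=tt, vv=vv):
        if np.any(np.asarray(t) < tt[0]) or np.any(np.asarray(t) > tt[-1]):
            raise ValueError(f"driver evaluated at t={t} outside [{tt[0]}, {tt[-1]}]")
        return np.interp(t, tt, vv)

    return fn


def build_ceramide_network(topology_config: dict | None = None) -> StoichiometricModel:
    """Build and validate a :class:`StoichiometricModel` from a config dict.

    With no argument the bundled default ceramide topology is used.
    Validation failures name the offending flux ids.
    """
    cfg = topology_config if topology_config is not None else default_topology()

    pools = [MetabolitePool(p["id"], p["role"], p["chain"]) for p in cfg["pools"]]
    n_pools = len(pools)
    fluxes = [
        FluxSpec(
            id=f["id"],
            enzyme_class=f["enzyme_class"],
            consumes=tuple(f.get("consumes", ())),
            produces=tuple(f.get("produces", ())),
            boundary_inputs=tuple(f.get("boundary_inputs", ())),
        )
        for f in cfg["fluxes"]
    ]

    errors = []
    seen = set()
    for f in fluxes:
        if f.id in seen:
            errors.append(f"duplicate flux id V{f.id}")
        seen.add(f.id)
        for pid in f.consumes + f.produces:
            if not 1 <= pid <= n_pools:
                errors.append(f"flux V{f.id}: pool id {pid} outside 1..{n_pools}")
        if f.enzyme_class not in ENZYME_CLASSES:
            errors.append(f"flux V{f.id}: unknown enzyme class {f.enzyme_class!r}")
    if errors:
        raise TopologyError("invalid topology: " + "; ".join(errors))

    fluxes.sort(key=lambda f: f.id)
    S = np.zeros((n_pools, len(fluxes)))
    for j, f in enumerate(fluxes):
        for pid in f.consumes:
            S[pid - 1, j] -= 1.0
        for pid in f.produces:
            S[pid - 1, j] += 1.0

    for j, f in enumerate(fluxes):
        if not f.is_boundary and abs(S[:, j].sum()) > 0:
            errors.append(f"flux V{f.id}: internal column not mass-balanced")
    if errors:
        raise TopologyError("invalid topology: " + "; ".join(errors))

    drivers = {name: _make_driver(v) for name, v in cfg.get("drivers", {}).items()}
    groups = {k: list(v) for k, v in cfg.get("groups", {}).items()}
    counts = np.zeros(len(fluxes), int)
    for members in groups.values():
        for fid in members:
            counts[fid - 1] += 1
    multi = [f"V{i + 1}" for i in np.nonzero(counts > 1)[0]]
    if multi:
        raise TopologyError(f"fluxes in more than one boundary group: {', '.join(multi)}")

    return StoichiometricModel(
        pools=pools,
        fluxes=fluxes,
        S=S,
        boundary_drivers=drivers,
        groups=groups,
        unconstrained_fluxes=list(cfg.get("unconstrained_fluxes", ())),
    )


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def evaluate_fluxes(
    model: StoichiometricModel,
    state: Sequence[float],
    activities: Sequence[float],
    t: float = 0.0,
) -> np.ndarray:
    """GMA rates v_j = a_j * prod(substrate pools) * prod(boundary drivers).

    Homogeneous of degree 1 in the activity vector; first order in each
    internal substrate.
    """
    x = np.asarray(state, dtype=float)
    a = np.asarray(activities, dtype=float)
    if x.shape != (model.n_pools,):
        raise ValueError(f"state must have length {model.n_pools}")
    if a.shape != (model.n_fluxes,):
        raise ValueError(f"activities must have length {model.n_fluxes}")
    if np.any(x < 0):
        bad = np.nonzero(x < 0)[0] + 1
        raise ValueError(f"negative state entries for pools {bad.tolist()}")

    model._build_index()
    if model._sub_idx is not None and model._sub_idx.size == model.n_fluxes:
        x_ext = np.append(x, 1.0)
        d_ext = np.append(
            np.array([model.boundary_drivers[n](t) for n in model._drv_names]),
            1.0,
        )
        return a * x_ext[model._sub_idx] * d_ext[model._drv_idx]

    drv = model.driver_values(t)
    rates = a.copy()
    for j, f in enumerate(model.fluxes):
        for pid in f.consumes:
            rates[j] *= x[pid - 1]
        for name in f.boundary_inputs:
            rates[j] *= drv[name]
    return rates


def rhs(model, state, activities, t: float = 0.0) -> np.ndarray:
    """Time derivative of the pool vector: S . v(state, activities, t)."""
    return model.S @ evaluate_fluxes(model, state, activities, t)


def simulate(
    model: StoichiometricModel,
    activities_fn: Callable[[float], np.ndarray],
    x0: Sequence[float],
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
):
    """Integrate the GMA ODEs and return the trajectory on ``t_grid``.

    ``activities_fn`` maps time (minutes) to the 53-activity vector.
    Concentrations are clipped at 0 (with a logged warning) if the solver
    undershoots by less than the solver tolerance.
    """
    from scipy.integrate import solve_ivp

    x0 = np.asarray(x0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("x0 must be nonnegative")

    def f(t, x):
        return model.S @ evaluate_fluxes(model, np.maximum(x, 0.0), activities_fn(t), t)

    sol = solve_ivp(
        f, (t_grid[0], t_grid[-1]), x0, t_eval=t_grid,
        method=method, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed near t={sol.t[-1] if sol.t.size else t_grid[0]}: {sol.message}")
    traj = sol.y.T
    undershoot = -traj.min(initial=0.0)
    if undershoot > 0:
        if undershoot > 100 * max(atol, rtol):
            raise RuntimeError(f"trajectory went negative by {undershoot:.3g}")
        logger.warning("clipping negative concentrations (max undershoot %.3g)", undershoot)
        traj = np.maximum(traj, 0.0)
    return traj


class InfeasibleSteadyStateError(RuntimeError):
    pass


def solve_baseline_steady_state(
    model: StoichiometricModel,
    x0: Sequence[float],
    boundary_values: Mapping[str, float] | None = None,
    v_prior: float | np.ndarray = 1.0,
    tol: float = 1e-8,
) -> np.ndarray:
    """Activities that hold ``x0`` at steady state (S.v = 0) at t = 0.

    ``boundary_values`` optionally pins the summed flux of each boundary
    group to a known baseline value.  The system is underdetermined, so the
    flux vector closest to ``v_prior`` (default: unit fluxes, the natural
    reference in fold-of-baseline units; 0 gives the minimum-norm solution)
    is selected; activities are recovered by dividing out the mass-action
    substrate/driver products.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("x0 must be strictly positive")
    m = evaluate_fluxes(model, x0, np.ones(model.n_fluxes), 0.0)

    rows = [model.S]
    tgt = [np.zeros(model.n_pools)]
    if boundary_values:
        G, names = model.group_matrix()
        sel = [i for i, n in enumerate(names) if n in boundary_values]
        rows.append(G[sel])
        tgt.append(np.array([boundary_values[names[i]] for i in sel]))
    C = np.vstack(rows)
    d = np.concatenate(tgt)
    p = np.broadcast_to(np.asarray(v_prior, dtype=float), (model.n_fluxes,)).copy()

    from ._qp import closest_nonneg_lsq

    v = closest_nonneg_lsq(C, d, p)
    resid = np.abs(C @ v - d).max()
    if resid > tol:
        raise InfeasibleSteadyStateError(
            f"no nonnegative activity vector balances the network (residual {resid:.3g})"
        )
    return v / m
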