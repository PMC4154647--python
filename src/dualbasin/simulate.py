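"""Langevin dynamics (BAOAB), temperature replica exchange and kinetic
ensembles from dissociated starts.

DNA beads are frozen: zero velocity, zero force, positions bitwise constant
over any run.  All randomness flows from explicit integer seeds through
``numpy.random.SeedSequence``; per-run child seeds are spawned from the
master sequence, so ensembles are reproducible run by run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

from dualbasin.energy import EnergyBreakdown
from dualbasin.geometry import random_rotation
from dualbasin.topology import TwoBasinTopology

__all__ = [
    "LangevinParams",
    "SimState",
    "REMDConfig",
    "Trajectory",
    "FirstPassageRecord",
    "init_state",
    "langevin_step",
    "run_md",
    "remd_exchange",
    "run_remd",
    "run_kinetic_ensemble",
    "run_batch_md",
    "state_from_positions",
]

_BLOWUP_DISPLACEMENT = 10.0  # A per step


@dataclass
class LangevinParams:
    dt: float = 5e-4          # tau
    friction: float = 0.25    # 1/tau
    temperature: float = 1.0  # eps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


@dataclass
class SimState:
    positions: np.ndarray
    velocities: np.ndarray
    step_count: int
    rng: np.random.Generator
    frozen_mask: np.ndarray
    forces: np.ndarray | None = None  # cache of forces at ``positions``

    def copy(self) -> "SimState":
        import copy as _copy

        return SimState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            step_count=self.step_count,
            rng=_copy.deepcopy(self.rng),
            frozen_mask=self.frozen_mask.copy(),
            forces=None if self.forces is None else self.forces.copy(),
        )


@dataclass
class REMDConfig:
    temperature_ladder: tuple[float, ...]
    exchange_interval: int = 5000
    total_steps: int = 50000
    stride: int = 100
    seed: int = 0
    dt: float = 5e-4
    friction: float = 0.25

    def __post_init__(self) -> None:
        ladder = tuple(float(t) for t in self.temperature_ladder)
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("temperature ladder must be strictly ascending")
        if self.exchange_interval <= 0:
            raise ValueError("exchange_interval must be positive")
        self.temperature_ladder = ladder


@dataclass
class Trajectory:
    """Frames recorded at a fixed stride, with per-frame energy breakdowns."""

    positions: np.ndarray          # (n_frames, n_beads, 3)
    step_numbers: np.ndarray       # (n_frames,)
    stride: int
    dt: float
    temperature: float
    seed: int
    energies: list[EnergyBreakdown] = field(default_factory=list)
    params_hash: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def times(self) -> np.ndarray:
        return self.step_numbers * self.dt

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("positions", data=self.positions)
            fh.create_dataset("step_numbers", data=self.step_numbers)
            if self.energies:
                comp = np.array(
                    [
                        [e.bonded, e.native_LJ, e.nonnative_excl,
                         e.native_elect, e.nonnative_elect]
                        for e in self.energies
                    ]
                )
                fh.create_dataset("energy_components", data=comp)
            fh.attrs["stride"] = self.stride
            fh.attrs["dt"] = self.dt
            fh.attrs["temperature"] = self.temperature
            fh.attrs["seed"] = self.seed
            fh.attrs["params_hash"] = self.params_hash

    @classmethod
    def from_hdf5(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as fh:
            energies = []
            if "energy_components" in fh:
                for row in fh["energy_components"][...]:
                    energies.append(EnergyBreakdown(*row))
            return cls(
                positions=fh["positions"][...],
                step_numbers=fh["step_numbers"][...],
                stride=int(fh.attrs["stride"]),
                dt=float(fh.attrs["dt"]),
                temperature=float(fh.attrs["temperature"]),
                seed=int(fh.attrs["seed"]),
                energies=energies,
                params_hash=str(fh.attrs["params_hash"]),
            )

    def to_multi_model_pdb(self, topology: TwoBasinTopology, path) -> None:
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        from dualbasin.topology import _KIND_ATOM

        n = topology.n_beads
        stack = struc.AtomArrayStack(self.n_frames, n)
        stack.coord = np.asarray(self.positions, float)
        stack.chain_id = np.array([b.chain_id[:4] for b in topology.beads])
        stack.res_id = np.array([b.residue_index for b in topology.beads])
        stack.res_name = np.array([b.residue_name[:5] for b in topology.beads])
        stack.atom_name = np.array([_KIND_ATOM[b.bead_kind] for b in topology.beads])
        stack.element = np.array(["C"] * n)
        stack.hetero = np.zeros(n, dtype=bool)
        f = pdb.PDBFile()
        f.set_structure(stack)
        f.write(str(path))


@dataclass(frozen=True)
class FirstPassageRecord:
    seed: int
    steps: int | None      # None if the run never reached the target
    time: float | None     # steps * dt, None if censored
    censored: bool
    max_steps: int
    dt: float

    @property
    def observation_time(self) -> float:
        """Passage time, or the observation horizon for censored runs."""
        return self.time if not self.censored else self.max_steps * self.dt


def params_hash(*objs) -> str:
    payload = json.dumps([getattr(o, "to_dict", lambda: repr(o))() for o in objs],
                         sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------


def maxwell_velocities(rng, n, temperature, masses=None):
    v = rng.standard_normal((n, 3))
    scale = np.sqrt(temperature / (np.ones(n) if masses is None else masses))
    return v * scale[:, None]


def init_state(
    topology: TwoBasinTopology,
    start_basin: str = "A",
    temperature: float = 1.0,
    seed: int = 0,
    dissociate: bool = False,
    d_start: float | None = None,
    clearance: float = 4.0,
    max_retries: int = 100,
) -> SimState:
    """Protein in the requested basin's reference conformation; DNA native
    and frozen.

    With ``dissociate=True`` the protein is rigidly rotated (uniform random
    orientation) and translated to a centre-of-mass separation of
    ``d_start`` from the DNA (default: native separation + 30 A), rejecting
    poses with any protein-DNA bead pair closer than ``clearance``.
    """
    rng = np.random.default_rng(seed)
    x = topology.ref_positions(start_basin)
    frozen = topology.dna_mask
    mobile = ~frozen

    if dissociate:
        if not np.any(frozen):
            raise ValueError("cannot build a dissociated start without DNA beads")
        dna_com = x[frozen].mean(axis=0)
        native_sep = np.linalg.norm(x[mobile].mean(axis=0) - dna_com)
        target = native_sep + 30.0 if d_start is None else d_start
        placed = False
        for _ in range(max_retries):
            rot = random_rotation(rng)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            prot = x[mobile] - x[mobile].mean(axis=0)
            prot = prot @ rot.T + dna_com + target * direction
            dmin = np.min(
                np.linalg.norm(prot[:, None, :] - x[frozen][None, :, :], axis=-1)
            )
            if dmin >= clearance:
                x = x.copy()
                x[mobile] = prot
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place a dissociated start with clearance {clearance} A "
                f"in {max_retries} attempts"
            )

    v = maxwell_velocities(rng, topology.n_beads, temperature)
    v[frozen] = 0.0
    return SimState(
        positions=x,
        velocities=v,
        step_count=0,
        rng=rng,
        frozen_mask=frozen.copy(),
    )


def state_from_positions(positions, temperature, seed, frozen_mask=None) -> SimState:
    """Seeded state for an arbitrary system (used by 1D fixtures)."""
    positions = np.asarray(positions, float)
    rng = np.random.default_rng(seed)
    n = len(positions)
    frozen = np.zeros(n, bool) if frozen_mask is None else np.asarray(frozen_mask, bool)
    v = maxwell_velocities(rng, n, temperature)
    v[frozen] = 0.0
    return SimState(positions.copy(), v, 0, rng, frozen.copy())


# ---------------------------------------------------------------------------
# BAOAB integrator
# ---------------------------------------------------------------------------


def _ou_coefficients(lp: LangevinParams):
    c1 = np.exp(-lp.friction * lp.dt)
    c2 = np.sqrt(lp.temperature * (1.0 - c1 * c1))
    return c1, c2


def langevin_step(state: SimState, lp: LangevinParams, system) -> SimState:
    """One BAOAB update of the mobile beads, in place; frozen beads untouched."""
    x, v = state.positions, state.velocities
    mobile = ~state.frozen_mask
    m = system.masses[:, None]
    if state.forces is None:
        state.forces = system.forces(x)
    f = state.forces
    half = 0.5 * lp.dt
    c1, c2 = _ou_coefficients(lp)

    v[mobile] += half * (f / m)[mobile]
    x_before = x[mobile].copy()
    x[mobile] += half * v[mobile]
    noise = state.rng.standard_normal(x.shape)
    v[mobile] = c1 * v[mobile] + c2 * (noise / np.sqrt(m))[mobile]
    x[mobile] += half * v[mobile]
    disp = np.max(np.linalg.norm(x[mobile] - x_before, axis=-1)) if np.any(mobile) else 0.0
    if disp > _BLOWUP_DISPLACEMENT:
        raise RuntimeError(
            f"bead displacement {disp:.1f} A in one step at step "
            f"{state.step_count}; reduce dt"
        )
    f = system.forces(x)
    v[mobile] += half * (f / m)[mobile]
    state.forces = f
    state.step_count += 1
    return state


def run_md(
    state: SimState,
    lp: LangevinParams,
    system,
    nsteps: int,
    stride: int = 100,
    topology_energies: bool = True,
) -> Trajectory:
    """Propagate and record frames every ``stride`` steps (plus the start)."""
    frames = [state.positions.copy()]
    steps = [state.step_count]
    energies = []

    def snapshot_energy():
        if topology_energies and hasattr(system, "energy_breakdown"):
            energies.append(system.energy_breakdown(state.positions))

    snapshot_energy()
    for k in range(1, nsteps + 1):
        langevin_step(state, lp, system)
        if k % stride == 0:
            frames.append(state.positions.copy())
            steps.append(state.step_count)
            snapshot_energy()
        if k % 10_000 == 0:
            logger.info(
                "step %d: potential %.3f eps, kinetic %.3f eps",
                state.step_count,
                system.energy(state.positions),
                0.5 * float(np.sum(state.velocities**2)),
            )
    return Trajectory(
        positions=np.array(frames),
        step_numbers=np.array(steps),
        stride=stride,
        dt=lp.dt,
        temperature=lp.temperature,
        seed=lp.seed,
        energies=energies,
        params_hash=params_hash(lp),
    )


# ---------------------------------------------------------------------------
# replica exchange
# ---------------------------------------------------------------------------


def remd_exchange(e_i: float, e_j: float, t_i: float, t_j: float, rng) -> bool:
    """Metropolis swap decision for neighbouring temperature replicas."""
    delta = (1.0 / t_i - 1.0 / t_j) * (e_i - e_j)
    return delta >= 0.0 or rng.random() < np.exp(delta)


@dataclass
class REMDResult:
    trajectories: list[Trajectory]            # one per ladder temperature
    acceptance_ratios: list[float]            # one per neighbour pair
    attempt_counts: list[int]
    energy_samples: list[np.ndarray]          # potential energies per temperature


def run_remd(config: REMDConfig, system, topology: TwoBasinTopology | None = None,
             initial_states: list[SimState] | None = None) -> REMDResult:
    """Neighbour-pair temperature replica exchange.

    Swap attempts happen every ``exchange_interval`` steps, alternating
    even/odd neighbour pairs; accepted swaps exchange configurations and
    rescale velocities by sqrt(T_new/T_old).
    """
    ladder = config.temperature_ladder
    n_rep = len(ladder)
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(n_rep + 1)
    swap_rng = np.random.default_rng(child[-1])

    if initial_states is None:
        if topology is None:
            raise ValueError("run_remd needs a topology or explicit initial states")
        states = [
            init_state(topology, "A", ladder[r],
                       seed=int(child[r].generate_state(1)[0] % (2**31)))
            for r in range(n_rep)
        ]
    else:
        states = [s.copy() for s in initial_states]

    lps = [
        LangevinParams(dt=config.dt, friction=config.friction,
                       temperature=ladder[r], seed=config.seed)
        for r in range(n_rep)
    ]

    frames: list[list[np.ndarray]] = [[] for _ in range(n_rep)]
    steps_rec: list[list[int]] = [[] for _ in range(n_rep)]
    energies: list[list[float]] = [[] for _ in range(n_rep)]
    attempts = [0] * max(n_rep - 1, 1)
    accepts = [0] * max(n_rep - 1, 1)

    def record(step):
        for r in range(n_rep):
            frames[r].append(states[r].positions.copy())
            steps_rec[r].append(step)
            energies[r].append(system.energy(states[r].positions))

    record(0)
    step = 0
    parity = 0
    while step < config.total_steps:
        block = min(config.exchange_interval, config.total_steps - step)
        for _ in range(block):
            step += 1
            for r in range(n_rep):
                langevin_step(states[r], lps[r], system)
            if step % config.stride == 0:
                record(step)
        if step >= config.total_steps:
            break
        for r in range(parity, n_rep - 1, 2):
            e_lo = system.energy(states[r].positions)
            e_hi = system.energy(states[r + 1].positions)
            attempts[r] += 1
            if remd_exchange(e_lo, e_hi, ladder[r], ladder[r + 1], swap_rng):
                accepts[r] += 1
                states[r], states[r + 1] = states[r + 1], states[r]
                scale_up = np.sqrt(ladder[r + 1] / ladder[r])
                states[r].velocities /= scale_up
                states[r + 1].velocities *= scale_up
                states[r].forces = None
                states[r + 1].forces = None
        parity = 1 - parity

    trajectories = [
        Trajectory(
            positions=np.array(frames[r]),
            step_numbers=np.array(steps_rec[r]),
            stride=config.stride,
            dt=config.dt,
            temperature=ladder[r],
            seed=config.seed,
            params_hash=params_hash(config),
        )
        for r in range(n_rep)
    ]
    ratios = [
        (accepts[k] / attempts[k]) if attempts[k] else float("nan")
        for k in range(n_rep - 1)
    ]
    return REMDResult(
        trajectories=trajectories,
        acceptance_ratios=ratios,
        attempt_counts=attempts[: n_rep - 1],
        energy_samples=[np.array(e) for e in energies],
    )


# ---------------------------------------------------------------------------
# kinetic ensembles
# ---------------------------------------------------------------------------


def run_kinetic_ensemble(
    system,
    n_runs: int,
    lp: LangevinParams,
    stop_predicate,
    max_steps: int,
    seed: int | None = None,
    seeds: list[int] | None = None,
    initial_positions=None,
    init_state_factory=None,
    check_interval: int = 1,
) -> list[FirstPassageRecord]:
    """First-passage ensemble with distinct per-run child seeds.

    ``stop_predicate`` maps positions to reached/not-reached; for systems
    with ``supports_batch`` it must accept a (runs, beads, 3) array and
    return a boolean vector, and all runs are propagated in lockstep.
    Runs that never reach the target within ``max_steps`` are flagged
    censored.
    """
    if seeds is None:
        if seed is None:
            raise ValueError("provide either seed or seeds")
        ss = np.random.SeedSequence(seed)
        seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n_runs)]
    if len(seeds) != n_runs:
        raise ValueError("len(seeds) must equal n_runs")
    if len(set(seeds)) != n_runs:
        raise ValueError("per-run seeds must be distinct")

    if getattr(system, "supports_batch", False) and initial_positions is not None:
        return _batched_ensemble(
            system, n_runs, lp, stop_predicate, max_steps, seeds, initial_positions
        )

    records = []
    for run_seed in seeds:
        if init_state_factory is not None:
            state = init_state_factory(run_seed)
        elif initial_positions is not None:
            state = state_from_positions(
                initial_positions, lp.temperature, run_seed,
                frozen_mask=system.frozen_mask,
            )
        else:
            raise ValueError("provide initial_positions or init_state_factory")
        steps_done = None
        if stop_predicate(state.positions):
            steps_done = 0
        else:
            for k in range(1, max_steps + 1):
                langevin_step(state, lp, system)
                if k % check_interval == 0 and stop_predicate(state.positions):
                    steps_done = k
                    break
        records.append(
            FirstPassageRecord(
                seed=run_seed,
                steps=steps_done,
                time=None if steps_done is None else steps_done * lp.dt,
                censored=steps_done is None,
                max_steps=max_steps,
                dt=lp.dt,
            )
        )
    return records


def run_batch_md(
    system,
    n_walkers: int,
    lp: LangevinParams,
    nsteps: int,
    seed: int,
    initial_positions,
    stride: int = 10,
    chunk: int = 2000,
):
    """Independent-walker ensemble propagated in lockstep (batch systems).

    Returns positions of shape (n_frames, n_walkers, n_beads, 3) recorded
    every ``stride`` steps including the start.  Each walker's noise stream
    is a pure function of its child seed.
    """
    if not getattr(system, "supports_batch", False):
        raise ValueError("run_batch_md requires a system with batched forces")
    n = system.n_beads
    ss = np.random.SeedSequence(seed)
    gens = [np.random.default_rng(c) for c in ss.spawn(n_walkers)]
    x = np.broadcast_to(np.asarray(initial_positions, float), (n_walkers, n, 3)).copy()
    m = system.masses[None, :, None]
    v = np.stack([g.standard_normal((n, 3)) for g in gens]) * np.sqrt(lp.temperature / m)
    half = 0.5 * lp.dt
    c1, c2 = _ou_coefficients(lp)
    f = system.forces(x)
    frames = [x.copy()]
    step = 0
    while step < nsteps:
        todo = min(chunk, nsteps - step)
        noise = np.stack([g.standard_normal((todo, n, 3)) for g in gens])
        for k in range(todo):
            step += 1
            v += half * f / m
            x += half * v
            v = c1 * v + c2 * noise[:, k] / np.sqrt(m)
            x += half * v
            f = system.forces(x)
            v += half * f / m
            if step % stride == 0:
                frames.append(x.copy())
    return np.array(frames)


def _batched_ensemble(system, n_runs, lp, stop_predicate, max_steps, seeds,
                      initial_positions, chunk: int = 2000):
    """Lockstep propagation of all runs; per-run generators keep each run's
    noise stream a pure function of its own seed."""
    n = system.n_beads
    gens = [np.random.default_rng(s) for s in seeds]
    x = np.broadcast_to(
        np.asarray(initial_positions, float), (n_runs, n, 3)
    ).copy()
    m = system.masses[None, :, None]
    v = np.stack([g.standard_normal((n, 3)) for g in gens]) * np.sqrt(lp.temperature / m)

    half = 0.5 * lp.dt
    c1, c2 = _ou_coefficients(lp)
    passage = np.full(n_runs, -1, dtype=np.int64)
    done = stop_predicate(x)
    passage[done] = 0
    f = system.forces(x)

    step = 0
    while step < max_steps and not np.all(done):
        todo = min(chunk, max_steps - step)
        noise = np.stack([g.standard_normal((todo, n, 3)) for g in gens])
        for k in range(todo):
            step += 1
            v += half * f / m
            x += half * v
            v = c1 * v + c2 * noise[:, k] / np.sqrt(m)
            x += half * v
            f = system.forces(x)
            v += half * f / m
            newly = (~done) & stop_predicate(x)
            passage[newly] = step
            done |= newly
            if np.all(done):
                break

    records = []
    for r in range(n_runs):
        reached = passage[r] >= 0
        records.append(
            FirstPassageRecord(
                seed=seeds[r],
                steps=int(passage[r]) if reached else None,
                time=float(passage[r] * lp.dt) if reached else None,
                censored=not reached,
                max_steps=max_steps,
                dt=lp.dt,
            )
        )
    return records
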