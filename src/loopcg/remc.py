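"""Replica-exchange Monte Carlo sampling of the lattice model.

Protocol: the scaffold is projected onto the lattice, the missing loop is
grown in at random, and the starting structure is copied to ``n_replicas``
identical replicas spanning an equally spaced temperature ladder.  Within
each macro-cycle every replica performs Metropolis sweeps with periodic
swap attempts between adjacent temperatures; after each macro-cycle all
temperatures are scaled down by a common factor (simulated annealing that
preserves the constant ladder spacing) and one snapshot of the
lowest-temperature replica is appended to the pseudo-trajectory.  The whole
run is a pure function of its seed.

Moves: single-Cα repositioning, re-growth of 2/3/4-residue fragments
between fixed ends, and small rigid lattice shifts of larger (4-22
residue) fragments with the junction bonds required to stay admissible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .forcefield import ConformationEvaluator, EnergyModel
from .lattice import LatticeConformation, VectorSet, default_vector_set, project_segments
from .pdbio import ExcisedCase

__all__ = [
    "MoveSet",
    "Schedule",
    "Snapshot",
    "Trajectory",
    "LoopClosureError",
    "random_loop_insert",
    "metropolis_accept",
    "metropolis_step",
    "replica_swap",
    "run_remc",
    "run_repeats",
]


class LoopClosureError(RuntimeError):
    """Loop growth could not close onto the downstream anchor."""


@dataclass(frozen=True)
class MoveSet:
    """Move kinds and their proposal weights (normalized at use)."""

    single_ca: float = 0.50
    fragment_2: float = 0.15
    fragment_3: float = 0.10
    fragment_4: float = 0.10
    large_shift: float = 0.15

    def __post_init__(self):
        w = self.weights()
        if np.any(w <= 0):
            raise ValueError("all proposal weights must be positive")

    def weights(self) -> np.ndarray:
        w = np.array([self.single_ca, self.fragment_2, self.fragment_3,
                      self.fragment_4, self.large_shift], float)
        return w / w.sum()

    KINDS = ("single_ca", "fragment_2", "fragment_3", "fragment_4", "large_shift")


@dataclass(frozen=True)
class Schedule:
    """REMC annealing schedule in reduced temperature units."""

    n_replicas: int = 20
    t_high: float = 2.5
    t_low: float = 1.0
    anneal_factor: float = 0.98
    n_macrocycles: int = 100
    steps_per_cycle: int = 100   # Metropolis sweeps per replica per macro-cycle
    swap_interval: int = 10      # sweeps between swap attempts
    seed: int = 0

    def __post_init__(self):
        if self.n_replicas < 1 or self.t_low <= 0 or self.t_high < self.t_low:
            raise ValueError("invalid schedule")
        if not (0 < self.anneal_factor <= 1):
            raise ValueError("anneal_factor must be in (0, 1]")

    def ladder(self) -> np.ndarray:
        """Initial temperatures, lowest first, equally spaced."""
        if self.n_replicas == 1:
            return np.array([self.t_low])
        return np.linspace(self.t_low, self.t_high, self.n_replicas)

    @classmethod
    def quick(cls, seed: int = 0) -> "Schedule":
        """Desk-scale preset for tests and small fixtures."""
        return cls(n_replicas=5, t_high=2.0, t_low=1.0, anneal_factor=0.95,
                   n_macrocycles=20, steps_per_cycle=25, swap_interval=5, seed=seed)

    @classmethod
    def full(cls, seed: int = 0) -> "Schedule":
        """Full-scale preset: 20 annealed replicas."""
        return cls(seed=seed)


@dataclass
class Snapshot:
    conf: LatticeConformation
    energy: float
    cycle: int


@dataclass
class Trajectory:
    snapshots: list[Snapshot]
    run_id: int = 0
    seed: int | None = None


# --------------------------------------------------------------------------
# Bridge growth (loop insertion and fragment re-growth share this)

def _grow_bridge(a: np.ndarray, b: np.ndarray | None, n: int, vset: VectorSet,
                 rng: np.random.Generator, occupied: np.ndarray | None,
                 hardcore_lu: float, max_retries: int = 100) -> np.ndarray | None:
    """Grow n residues from anchor a, closing onto anchor b (both lattice).

    Residues are appended with random admissible virtual bonds, filtered at
    each step by reachability of b with the bonds that remain; the last two
    bonds are solved exactly via the two-bond bridge table.  Candidates
    clashing with ``occupied`` positions (closer than hardcore_lu lattice
    units) are excluded.  Returns None when every retry dead-ends.
    """
    V = vset.vectors
    max_step = np.sqrt(vset.window[1])
    hc2 = hardcore_lu ** 2
    for _ in range(max_retries):
        pos = np.empty((n, 3), dtype=int)
        p = a
        ok = True
        for k in range(n):
            cand = p + V
            if b is not None:
                m = n - k  # bonds remaining from the new residue to b
                gap = b - cand
                if m == 0:
                    ok = False
                    break
                if m == 1:
                    feas = vset.admissible_mask(gap)
                elif m == 2:
                    feas = vset.two_bond_reachable_mask(gap)
                else:
                    feas = (gap ** 2).sum(axis=1) <= (m * max_step) ** 2
            else:
                feas = np.ones(len(V), bool)
            if occupied is not None and feas.any():
                idx = np.where(feas)[0]
                d2 = ((cand[idx, None, :] - occupied[None, :, :]) ** 2).sum(axis=2)
                feas[idx[d2.min(axis=1) < hc2]] = False
            if k > 0:
                idx = np.where(feas)[0]
                if idx.size:
                    d2 = ((cand[idx, None, :] - pos[None, :k, :]) ** 2).sum(axis=2)
                    feas[idx[d2.min(axis=1) < hc2]] = False
            choices = np.where(feas)[0]
            if choices.size == 0:
                ok = False
                break
            p = cand[rng.choice(choices)]
            pos[k] = p
        if ok and (b is None or vset.contains(b - pos[-1])):
            return pos
    return None


def random_loop_insert(case: ExcisedCase, vector_set: VectorSet | None = None,
                       seed: int = 0, model: EnergyModel | None = None,
                       max_retries: int = 100) -> LatticeConformation:
    """Project the scaffold onto the lattice and grow the loop in at random.

    The two scaffold pieces flanking the gap are projected into a shared
    lattice frame; the loop is then grown residue-by-residue with random
    admissible bonds, rejecting hard-core clashes and closing exactly onto
    the downstream anchor.  On repeated closure failure the hard-core
    filter is progressively relaxed (loop-only, then none) before giving
    up with :class:`LoopClosureError`.
    """
    vset = vector_set or default_vector_set()
    model = model or EnergyModel()
    rng = np.random.default_rng(seed)
    loop = case.loop_indices
    n_res = len(case.scaffold)
    pre = [i for i in range(0, loop[0])]
    post = [i for i in range(loop[-1] + 1, n_res)]
    segs = []
    for idx in (pre, post):
        if idx:
            segs.append(np.array([case.scaffold.residues[i].ca for i in idx]))
    pos_list, offset, _ = project_segments(segs, vset)
    lattice_ca = np.zeros((n_res, 3), dtype=int)
    seg_iter = iter(pos_list)
    if pre:
        lattice_ca[pre] = next(seg_iter)
    if post:
        lattice_ca[post] = next(seg_iter)
    a = lattice_ca[loop[0] - 1] if pre else None
    b = lattice_ca[loop[-1] + 1] if post else None
    if a is None and b is None:
        raise ValueError("loop spans the whole chain; nothing to anchor on")
    if a is None:  # N-terminal loop: grow backwards from the downstream anchor
        grown = _grow_bridge(b, None, len(loop), vset, rng,
                             np.array([lattice_ca[i] for i in post]), _hc_lu(model, vset))
        if grown is None:
            raise LoopClosureError("could not grow terminal loop")
        lattice_ca[loop] = grown[::-1]
    else:
        occupied = np.array([lattice_ca[i] for i in pre + post])
        hc = _hc_lu(model, vset)
        grown = None
        for occ, hc_try in ((occupied, hc), (None, hc), (None, 0.0)):
            grown = _grow_bridge(a, b, len(loop), vset, rng, occ, hc_try,
                                 max_retries=max_retries)
            if grown is not None:
                break
        if grown is None:
            raise LoopClosureError(
                f"loop of {len(loop)} residues could not close onto its anchors"
            )
        lattice_ca[loop] = grown
    conf = LatticeConformation(case.sequence, lattice_ca, vset, offset)
    conf.validate()
    return conf


def _hc_lu(model: EnergyModel, vset: VectorSet) -> float:
    return model.hardcore_ca / vset.spacing


# --------------------------------------------------------------------------
# Moves

def _propose(ca: np.ndarray, move_set: MoveSet, vset: VectorSet,
             rng: np.random.Generator, movable: np.ndarray) -> np.ndarray | None:
    """One proposed lattice conformation (new ca array) or None (auto-reject).

    ``movable`` lists the residue indices moves may displace; proposals are
    constructed to satisfy the chain invariant by design.
    """
    kind = MoveSet.KINDS[int(np.searchsorted(np.cumsum(move_set.weights()), rng.random()))]
    n = len(ca)
    if kind == "single_ca":
        i = int(rng.choice(movable))
        new = ca.copy()
        if i == 0:
            new[0] = ca[1] - vset.vectors[rng.integers(len(vset))]
        elif i == n - 1:
            new[-1] = ca[-2] + vset.vectors[rng.integers(len(vset))]
        else:
            cands = vset.bridge_vectors(ca[i + 1] - ca[i - 1])
            if len(cands) == 0:
                return None
            new[i] = ca[i - 1] + cands[rng.integers(len(cands))]
        if np.array_equal(new, ca):
            return None
        return new
    if kind.startswith("fragment_"):
        k = int(kind[-1])
        if n <= k + 1:
            return None
        start = int(rng.integers(0, n - k + 1))
        if not np.any((movable >= start) & (movable < start + k)):
            return None
        a = ca[start - 1] if start > 0 else None
        b = ca[start + k] if start + k < n else None
        new = ca.copy()
        if a is None:  # rebuild a chain-head fragment backwards
            grown = _grow_bridge(b, None, k, vset, rng, None, 0.0, max_retries=5)
            if grown is None:
                return None
            new[start:start + k] = grown[::-1]
        else:
            grown = _grow_bridge(a, b, k, vset, rng, None, 0.0, max_retries=5)
            if grown is None:
                return None
            new[start:start + k] = grown
        return None if np.array_equal(new, ca) else new
    # large_shift: rigid displacement of a 4-22 residue fragment
    lo = min(4, n)
    hi = min(22, n)
    k = int(rng.integers(lo, hi + 1))
    start = int(rng.integers(0, n - k + 1))
    if not np.any((movable >= start) & (movable < start + k)):
        return None
    shift = rng.integers(-2, 3, size=3)
    if not shift.any():
        return None
    new = ca.copy()
    new[start:start + k] += shift
    if start > 0 and not vset.contains(new[start] - new[start - 1]):
        return None
    if start + k < n and not vset.contains(new[start + k] - new[start + k - 1]):
        return None
    return new


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Classic Metropolis criterion: accept with min(1, exp(-dE/T))."""
    if delta_e <= 0:
        return True
    if temperature <= 0 or not np.isfinite(delta_e):
        return False
    return bool(rng.random() < np.exp(-delta_e / temperature))


def metropolis_step(conf: LatticeConformation, move_set: MoveSet, model: EnergyModel,
                    restraints, temperature: float, rng: np.random.Generator
                    ) -> tuple[LatticeConformation, bool]:
    """Propose one move and accept/reject by the Metropolis criterion."""
    ev = ConformationEvaluator(conf.sequence, model, restraints)
    movable = np.arange(len(conf))
    e0 = ev.total(conf.ca_xyz())
    new_ca = _propose(conf.ca, move_set, conf.vector_set, rng, movable)
    if new_ca is None:
        return conf, False
    new = LatticeConformation(conf.sequence, new_ca, conf.vector_set, conf.offset)
    e1 = ev.total(new.ca_xyz())
    if metropolis_accept(e1 - e0, temperature, rng):
        return new, True
    return conf, False


def replica_swap(e_i: float, e_j: float, t_i: float, t_j: float,
                 rng: np.random.Generator) -> bool:
    """Standard replica-exchange acceptance for configurations at T_i, T_j."""
    arg = (1.0 / t_i - 1.0 / t_j) * (e_i - e_j)
    if arg >= 0:
        return True
    return bool(rng.random() < np.exp(arg))


# --------------------------------------------------------------------------
# The annealed REMC protocol

class _Replica:
    __slots__ = ("ca", "energy", "rng")

    def __init__(self, ca, energy, rng):
        self.ca = ca
        self.energy = energy
        self.rng = rng


def run_remc(case: ExcisedCase, model: EnergyModel, restraints,
             schedule: Schedule, vector_set: VectorSet | None = None,
             move_set: MoveSet | None = None, run_id: int = 0) -> Trajectory:
    """Annealed replica-exchange run; returns the lowest-T pseudo-trajectory.

    All replicas start from the same random-loop starting structure.  Per
    macro-cycle each replica performs ``steps_per_cycle`` sweeps (one sweep
    = one attempted move per residue) with swap attempts between adjacent
    ladder neighbours every ``swap_interval`` sweeps, after which the whole
    ladder is scaled by ``anneal_factor``; one snapshot of the lowest-
    temperature replica is stored per macro-cycle.  Bit-reproducible from
    the schedule seed.
    """
    vset = vector_set or default_vector_set()
    move_set = move_set or MoveSet()
    ss = np.random.SeedSequence(schedule.seed)
    children = ss.spawn(schedule.n_replicas + 2)
    insert_seed = int(children[-2].generate_state(1)[0] % (2 ** 31))
    swap_rng = np.random.default_rng(children[-1])

    start = random_loop_insert(case, vset, seed=insert_seed, model=model)
    seq = start.sequence
    ev = ConformationEvaluator(seq, model, restraints)
    offset = start.offset

    def xyz_of(ca):
        return (ca - offset) * vset.spacing

    e_start = ev.total(xyz_of(start.ca))
    temps = schedule.ladder().astype(float)
    replicas = [_Replica(start.ca.copy(), e_start, np.random.default_rng(children[r]))
                for r in range(schedule.n_replicas)]
    movable = np.arange(len(seq))
    n = len(seq)
    snapshots: list[Snapshot] = []
    for cycle in range(schedule.n_macrocycles):
        for sweep in range(schedule.steps_per_cycle):
            for r, rep in enumerate(replicas):
                t = temps[r]
                for _ in range(n):
                    new_ca = _propose(rep.ca, move_set, vset, rep.rng, movable)
                    if new_ca is None:
                        continue
                    e1 = ev.total(xyz_of(new_ca))
                    if metropolis_accept(e1 - rep.energy, t, rep.rng):
                        rep.ca, rep.energy = new_ca, e1
            if schedule.n_replicas > 1 and (sweep + 1) % schedule.swap_interval == 0:
                first = (sweep // schedule.swap_interval) % 2  # alternate even/odd pairs
                for r in range(first, schedule.n_replicas - 1, 2):
                    if replica_swap(replicas[r].energy, replicas[r + 1].energy,
                                    temps[r], temps[r + 1], swap_rng):
                        replicas[r].ca, replicas[r + 1].ca = replicas[r + 1].ca, replicas[r].ca
                        replicas[r].energy, replicas[r + 1].energy = (
                            replicas[r + 1].energy, replicas[r].energy)
        cold = replicas[0]
        conf = LatticeConformation(seq, cold.ca.copy(), vset, offset.copy())
        snapshots.append(Snapshot(conf, float(cold.energy), cycle))
        temps *= schedule.anneal_factor
    return Trajectory(snapshots, run_id=run_id, seed=schedule.seed)


def run_repeats(case: ExcisedCase, model: EnergyModel, restraints,
                schedule: Schedule, n_repeats: int = 3,
                vector_set: VectorSet | None = None,
                move_set: MoveSet | None = None) -> list[Trajectory]:
    """Independent repeats with seeds derived from the schedule's master seed."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    master = np.random.SeedSequence(schedule.seed)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in master.spawn(n_repeats)]
    out = []
    for r, s in enumerate(seeds):
        sched = dc_replace(schedule, seed=s)
        out.append(run_remc(case, model, restraints, sched, vector_set, move_set, run_id=r))
    return out
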