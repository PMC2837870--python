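"""Reduced-model energy function.

Six term classes, in reduced energy units (k_B = 1, well depths of order 1):

* hard-core excluded volume of the main chain (Cα) and Cβ pseudo-atoms;
* a generic, sequence-independent short-range bias that makes the chain
  behave like a polypeptide (favoring the helix and extended-strand bands
  of the r13/r14 local-geometry descriptors, with the correct handedness);
* a sequence-dependent short-range term keyed to a three-class (H/E/C)
  secondary-structure propensity of the central residue;
* square-well pairwise contacts between side-chain centers, repulsive at
  short range and attractive in a hydrophobicity-dependent well;
* a cooperative main-chain hydrogen-bond model: Cα pairs at sheet-like
  distance with the pair axis near-perpendicular to both local chain
  tangents count as bonds, and bonds adjacent in both partners earn a
  cooperativity bonus;
* flat-bottom distance-restraint energy (see :mod:`loopcg.restraints`).

All numeric parameters here are surrogate values shipped as editable
defaults; the contract of this module is the term structure, not any
particular published parameterization.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from ._kernels import HAVE_NUMBA, total_energy as kernel_total
from .lattice import CB_DISTANCE, OUT_OF_PLANE, SC_DISTANCE, LatticeConformation
from .restraints import restraint_energy_xyz

__all__ = [
    "EnergyModel",
    "ConformationEvaluator",
    "energy_total",
    "excluded_volume",
    "pair_contact_energy",
    "hbond_energy",
    "short_range_energy",
]

# residue classes ---------------------------------------------------------

HYDROPHOBIC = set("AVLIMFWCY")
POSITIVE = set("KR")
NEGATIVE = set("DE")

# Chou-Fasman-style three-class secondary-structure propensity
HELIX_FORMERS = set("AELMQKRH")
STRAND_FORMERS = set("VIYCWFT")


def ss_class(aa: str) -> str:
    if aa in HELIX_FORMERS:
        return "H"
    if aa in STRAND_FORMERS:
        return "E"
    return "C"


def residue_class(aa: str) -> str:
    if aa in POSITIVE:
        return "+"
    if aa in NEGATIVE:
        return "-"
    if aa in HYDROPHOBIC:
        return "h"
    return "p"


@dataclass
class ContactWell:
    r_rep: float
    r_min: float
    r_max: float
    eps: float  # well depth; negative = net repulsive pair

    def __post_init__(self):
        if not (self.r_rep < self.r_min < self.r_max):
            raise ValueError("contact well requires r_rep < r_min < r_max")


def _default_contact_table() -> dict[str, ContactWell]:
    """Wells keyed by unordered residue-class pair (h hydrophobic, p polar,
    +/- charged).  Hydrophobic-hydrophobic contacts are the deep wells that
    drive core packing; opposite charges attract, like charges repel."""
    return {
        "hh": ContactWell(3.5, 4.5, 6.5, 1.0),
        "hp": ContactWell(3.5, 4.5, 6.5, 0.3),
        "pp": ContactWell(3.5, 4.5, 6.5, 0.2),
        "+-": ContactWell(3.5, 4.5, 6.8, 0.6),
        "++": ContactWell(3.5, 4.5, 6.5, -0.3),
        "--": ContactWell(3.5, 4.5, 6.5, -0.3),
        "h+": ContactWell(3.5, 4.5, 6.5, 0.1),
        "h-": ContactWell(3.5, 4.5, 6.5, 0.1),
        "p+": ContactWell(3.5, 4.5, 6.5, 0.2),
        "p-": ContactWell(3.5, 4.5, 6.5, 0.2),
    }


_CONTACT_KEYS = set(_default_contact_table())


def contact_key(a: str, b: str) -> str:
    ca_, cb_ = residue_class(a), residue_class(b)
    for key in (ca_ + cb_, cb_ + ca_):
        if key in _CONTACT_KEYS:
            return key
    raise KeyError(f"no contact class for pair {a}{b}")


# short-range descriptor tables ------------------------------------------

R13_EDGES = np.linspace(3.6, 7.6, 21)        # 20 bins
R14_EDGES = np.linspace(-11.5, 11.5, 31)     # 30 bins, signed by handedness

# local-geometry bands (descriptor values of ideal secondary structure):
# right-handed α-helix: r13 ≈ 5.4 Å, signed r14 ≈ +5.0 Å;
# extended strand:      r13 ≈ 6.7 Å, |r14| ≈ 10 Å.
HELIX_R13, HELIX_R14 = 5.43, 5.05
STRAND_R13, STRAND_R14 = 6.7, 10.1


def _bin_centers(edges: np.ndarray) -> np.ndarray:
    return 0.5 * (edges[:-1] + edges[1:])


def _gauss(x, mu, sig):
    return np.exp(-((x - mu) ** 2) / (2.0 * sig ** 2))


def _generic_tables() -> tuple[np.ndarray, np.ndarray]:
    """(E13, E14) generic bias tables over the descriptor bins.

    Wells at the helix and strand bands; the helix well sits only at
    positive signed r14, encoding the right-handed chirality of the
    polypeptide — a mirror-image helix scores strictly worse.
    """
    c13 = _bin_centers(R13_EDGES)
    c14 = _bin_centers(R14_EDGES)
    e13 = -0.5 * (_gauss(c13, HELIX_R13, 0.45) + _gauss(c13, STRAND_R13, 0.45))
    e14 = -0.5 * (_gauss(c14, HELIX_R14, 0.8)
                  + _gauss(c14, STRAND_R14, 1.0)
                  + 0.6 * _gauss(c14, -STRAND_R14, 1.0))
    return e13, e14


def _sequence_tables() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-propensity-class modulation of the same descriptor bins."""
    c13 = _bin_centers(R13_EDGES)
    c14 = _bin_centers(R14_EDGES)
    zero13, zero14 = np.zeros_like(c13), np.zeros_like(c14)
    return {
        "H": (-0.4 * _gauss(c13, HELIX_R13, 0.45), -0.4 * _gauss(c14, HELIX_R14, 0.8)),
        "E": (-0.4 * _gauss(c13, STRAND_R13, 0.45),
              -0.4 * (_gauss(c14, STRAND_R14, 1.0) + _gauss(c14, -STRAND_R14, 1.0))),
        "C": (zero13, zero14),
    }


@dataclass
class HBondParams:
    d_min: float = 4.4
    d_max: float = 5.6
    colinearity: float = 0.5   # max |cos| between pair axis and either tangent
    e_hb: float = 1.0
    e_coop: float = 0.5


@dataclass
class EnergyModel:
    """Parameter container for the reduced-model energy."""

    hardcore_ca: float = 3.3
    hardcore_cb: float = 2.7
    eps_rep: float = 2.0
    contacts: dict[str, ContactWell] = field(default_factory=_default_contact_table)
    hbond: HBondParams = field(default_factory=HBondParams)
    weights: dict[str, float] = field(default_factory=lambda: {
        "excluded_volume": 1.0,
        "short_range": 1.0,
        "pair_contact": 1.0,
        "hbond": 1.0,
        "restraints": 1.0,
    })
    temperature: float = 1.0   # reduced units, for isothermal use
    min_contact_sep: int = 3

    def to_config(self) -> dict:
        return asdict(self)

    @classmethod
    def from_config(cls, cfg: dict) -> "EnergyModel":
        cfg = dict(cfg)
        if "contacts" in cfg:
            cfg["contacts"] = {k: ContactWell(**v) if isinstance(v, dict) else v
                               for k, v in cfg["contacts"].items()}
        if "hbond" in cfg and isinstance(cfg["hbond"], dict):
            cfg["hbond"] = HBondParams(**cfg["hbond"])
        return cls(**cfg)


# --------------------------------------------------------------------------
# geometry helpers (fused, allocation-light versions of the lattice-module
# pseudo-atom formulas; identical numbers by construction)

def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _pseudo_atoms(xyz: np.ndarray, sc_dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(sc, cb) positions from the Cα trace; termini copy the nearest frame."""
    n = len(xyz)
    sc = xyz.copy()
    cb = xyz.copy()
    if n < 3:
        return sc, cb
    b = xyz[1:] - xyz[:-1]
    bn = np.sqrt((b * b).sum(axis=1))[:, None]
    e1 = -b[:-1] / bn[:-1]
    e2 = b[1:] / bn[1:]
    d = -(e1 + e2)
    nrm = _cross(e1, e2)
    nn = np.sqrt((nrm * nrm).sum(axis=1))[:, None]
    good = nn[:, 0] > 1e-9
    d[good] += OUT_OF_PLANE * nrm[good] / nn[good]
    dn = np.sqrt((d * d).sum(axis=1))[:, None]
    bad = dn[:, 0] < 1e-9
    if bad.any():
        # collinear frames: any perpendicular to the chain direction
        for k in np.where(bad)[0]:
            u = e2[k]
            a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
            v = np.cross(u, a)
            d[k] = v / np.linalg.norm(v)
            dn[k] = 1.0
    d = d / dn
    sc[1:-1] = xyz[1:-1] + d * sc_dist[1:-1, None]
    cb[1:-1] = xyz[1:-1] + d * CB_DISTANCE
    sc[0] = xyz[0] + d[0] * sc_dist[0]
    sc[-1] = xyz[-1] + d[-1] * sc_dist[-1]
    cb[0] = xyz[0] + d[0] * CB_DISTANCE
    cb[-1] = xyz[-1] + d[-1] * CB_DISTANCE
    return sc, cb


def _sq_dists(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _uniform_bins(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Clamped bin indices on a uniform grid (edge descriptors clamp, not error)."""
    step = edges[1] - edges[0]
    return np.clip(((x - edges[0]) / step).astype(int), 0, len(edges) - 2)


# --------------------------------------------------------------------------
# evaluator

class ConformationEvaluator:
    """Precomputed per-sequence arrays for fast repeated energy evaluation.

    The sampler creates one evaluator per run and feeds it raw Cartesian Cα
    coordinates; the public term functions below wrap it for one-off calls
    on conformations.
    """

    def __init__(self, sequence: str, model: EnergyModel, restraint_set=None):
        self.sequence = sequence
        self.model = model
        self.restraints = restraint_set
        n = len(sequence)
        self.n = n
        self.sc_dist = np.array([SC_DISTANCE[a] for a in sequence])
        eps = np.empty((n, n))
        r_rep = np.empty((n, n))
        r_min = np.empty((n, n))
        r_max = np.empty((n, n))
        for i, a in enumerate(sequence):
            for j, b in enumerate(sequence):
                w = model.contacts[contact_key(a, b)]
                eps[i, j], r_rep[i, j], r_min[i, j], r_max[i, j] = (
                    w.eps, w.r_rep, w.r_min, w.r_max)
        self.eps = eps
        self.r_rep2, self.r_min2, self.r_max2 = r_rep ** 2, r_min ** 2, r_max ** 2
        sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        self.pair_mask = np.triu(sep >= model.min_contact_sep)
        self.nonbonded = np.triu(sep >= 2)
        self.hc_ca2 = model.hardcore_ca ** 2
        self.hc_cb2 = model.hardcore_cb ** 2
        self.e13_gen, self.e14_gen = _generic_tables()
        seq_tab = _sequence_tables()
        self.cls13 = np.array([seq_tab[ss_class(a)][0] for a in sequence])
        self.cls14 = np.array([seq_tab[ss_class(a)][1] for a in sequence])
        self._packed = None

    # ---- individual terms (take raw coordinates) ----

    def excluded_volume(self, xyz: np.ndarray, cb: np.ndarray | None = None) -> float:
        d2 = _sq_dists(xyz)
        if (d2[self.nonbonded] < self.hc_ca2).any():
            return np.inf
        if cb is None:
            _, cb = _pseudo_atoms(xyz, self.sc_dist)
        d2cb = _sq_dists(cb)
        if (d2cb[self.nonbonded] < self.hc_cb2).any():
            return np.inf
        return 0.0

    def pair_contact(self, sc: np.ndarray) -> float:
        d2 = _sq_dists(sc)
        m = self.pair_mask
        rep = (d2 < self.r_rep2) & m
        att = (d2 >= self.r_min2) & (d2 <= self.r_max2) & m
        return float(self.model.eps_rep * rep.sum() - self.eps[att].sum())

    def hbond(self, xyz: np.ndarray) -> float:
        p = self.model.hbond
        n = self.n
        if n < 4:
            return 0.0
        tang = np.empty_like(xyz)
        tang[1:-1] = xyz[2:] - xyz[:-2]
        tang[0] = xyz[1] - xyz[0]
        tang[-1] = xyz[-1] - xyz[-2]
        tang = tang / np.sqrt((tang * tang).sum(axis=1))[:, None]
        d2 = _sq_dists(xyz)
        cand = self.pair_mask & (d2 >= p.d_min ** 2) & (d2 <= p.d_max ** 2)
        I, J = np.nonzero(cand)
        if len(I) == 0:
            return 0.0
        axis = xyz[J] - xyz[I]
        axis = axis / np.sqrt((axis * axis).sum(axis=1))[:, None]
        ok = ((np.abs((axis * tang[I]).sum(axis=1)) <= p.colinearity)
              & (np.abs((axis * tang[J]).sum(axis=1)) <= p.colinearity))
        if not ok.any():
            return 0.0
        B = np.zeros((n, n), dtype=bool)
        B[I[ok], J[ok]] = True   # upper triangle, i < j
        e = -p.e_hb * B.sum()
        coop = (B[:-1, :-1] & B[1:, 1:]).sum()          # parallel register
        coop += (B[:-1, 1:] & B[1:, :-1]).sum()          # antiparallel register
        return float(e - p.e_coop * coop)

    def short_range(self, xyz: np.ndarray) -> float:
        n = self.n
        e = 0.0
        if n >= 3:
            v = xyz[2:] - xyz[:-2]
            r13 = np.sqrt((v * v).sum(axis=1))
            b13 = _uniform_bins(r13, R13_EDGES)
            e += self.e13_gen[b13].sum()
            e += self.cls13[np.arange(1, n - 1), b13].sum()
        if n >= 4:
            b = xyz[1:] - xyz[:-1]
            chir = (_cross(b[:-2], b[1:-1]) * b[2:]).sum(axis=1)
            v = xyz[3:] - xyz[:-3]
            # coplanar windows (chir ~ 0) count as right-handed so that the
            # sign is stable under rigid rotation's floating-point noise
            r14 = np.sqrt((v * v).sum(axis=1)) * np.where(chir < -1e-6, -1.0, 1.0)
            b14 = _uniform_bins(r14, R14_EDGES)
            e += self.e14_gen[b14].sum()
            e += self.cls14[np.arange(1, n - 2), b14].sum()
        return float(e)

    # ---- total ----

    def total_reference(self, xyz: np.ndarray) -> float:
        """Pure-numpy term-by-term total (the reference path)."""
        w = self.model.weights
        sc, cb = _pseudo_atoms(xyz, self.sc_dist)
        ev = self.excluded_volume(xyz, cb)
        if not np.isfinite(ev):
            return np.inf
        e = w["excluded_volume"] * ev
        e += w["short_range"] * self.short_range(xyz)
        e += w["pair_contact"] * self.pair_contact(sc)
        e += w["hbond"] * self.hbond(xyz)
        if self.restraints is not None:
            e += w["restraints"] * restraint_energy_xyz(xyz, self.restraints)
        return float(e)

    def _kernel_args(self):
        if self._packed is None:
            m = self.model
            hb = m.hbond
            if self.restraints is not None and len(self.restraints):
                ri, rj, rd0, rtol, rw = self.restraints.arrays()
            else:
                ri = rj = np.empty(0, dtype=int)
                rd0 = rtol = rw = np.empty(0)
            w = m.weights
            self._packed = (
                self.sc_dist, OUT_OF_PLANE, CB_DISTANCE,
                self.eps, self.r_rep2, self.r_min2, self.r_max2,
                m.eps_rep, m.min_contact_sep, self.hc_ca2, self.hc_cb2,
                self.e13_gen, self.e14_gen, self.cls13, self.cls14,
                float(R13_EDGES[0]), float(R13_EDGES[1] - R13_EDGES[0]),
                float(R14_EDGES[0]), float(R14_EDGES[1] - R14_EDGES[0]),
                hb.d_min ** 2, hb.d_max ** 2, hb.colinearity, hb.e_hb, hb.e_coop,
                ri.astype(np.int64), rj.astype(np.int64), rd0, rtol, rw,
                w["excluded_volume"], w["short_range"], w["pair_contact"],
                w["hbond"], w["restraints"],
            )
        return self._packed

    def total(self, xyz: np.ndarray) -> float:
        if HAVE_NUMBA:
            return float(kernel_total(np.ascontiguousarray(xyz, dtype=np.float64),
                                      *self._kernel_args()))
        return self.total_reference(xyz)


# --------------------------------------------------------------------------
# public one-off term functions on conformations

def excluded_volume(conf: LatticeConformation, model: EnergyModel) -> float:
    """+inf if any non-bonded Cα or Cβ pair violates its hard core, else 0."""
    return ConformationEvaluator(conf.sequence, model).excluded_volume(conf.ca_xyz())


def pair_contact_energy(conf: LatticeConformation, model: EnergyModel) -> float:
    """Square-well side-chain contact energy (sequence separation >= 3)."""
    ev = ConformationEvaluator(conf.sequence, model)
    sc, _ = _pseudo_atoms(conf.ca_xyz(), ev.sc_dist)
    return ev.pair_contact(sc)


def hbond_energy(conf: LatticeConformation, model: EnergyModel) -> float:
    """Cooperative main-chain hydrogen-bond energy."""
    return ConformationEvaluator(conf.sequence, model).hbond(conf.ca_xyz())


def short_range_energy(conf: LatticeConformation, model: EnergyModel) -> float:
    """Generic plus sequence-dependent short-range bias."""
    return ConformationEvaluator(conf.sequence, model).short_range(conf.ca_xyz())


def energy_total(conf: LatticeConformation, model: EnergyModel, restraints=None) -> float:
    """Weighted sum of all terms; +inf sentinel on hard-core violation."""
    return ConformationEvaluator(conf.sequence, model, restraints).total(conf.ca_xyz())
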