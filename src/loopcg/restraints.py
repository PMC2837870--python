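"""Flat-bottom Cα–Cα distance restraints.

Single-template mode reads restraints off the fixed scaffold (the non-loop
part of the structure); hybrid mode derives consensus restraints from
several template models of the same sequence, loop regions included, with
the flat-bottom width following the between-template spread.

The restraint energy is zero inside the tolerance band |d - d0| <= tol and
grows as weight * (|d - d0| - tol)^2 outside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .pdbio import ExcisedCase, Structure

__all__ = [
    "Restraint",
    "RestraintSet",
    "scaffold_restraints",
    "consensus_restraints",
    "native_loop_restraints",
    "merge_restraints",
    "restraint_energy",
    "restraint_energy_xyz",
]

DEFAULT_MIN_SEP = 5
DEFAULT_CUTOFF = 12.0
DEFAULT_MAX_COUNT = 500
DEFAULT_TOL = 0.5
SCAFFOLD_WEIGHT = 10.0   # scaffold restraints are strong: 10x the loop default
LOOP_WEIGHT = 1.0
DIVERGENCE_CAP = 3.0     # drop consensus pairs with stdev above this (Å)


@dataclass(frozen=True)
class Restraint:
    i: int
    j: int
    d0: float
    tol: float = DEFAULT_TOL
    weight: float = 1.0

    def __post_init__(self):
        if self.i >= self.j:
            raise ValueError("restraint requires i < j")
        if self.d0 <= 0 or self.tol < 0:
            raise ValueError("restraint requires d0 > 0 and tol >= 0")


@dataclass
class RestraintSet:
    restraints: list[Restraint]
    provenance: str = "scaffold"

    def __post_init__(self):
        pairs = [(r.i, r.j) for r in self.restraints]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (i, j) pair in restraint set")
        self._arr = None

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def arrays(self):
        """(idx_i, idx_j, d0, tol, weight) as numpy arrays, cached."""
        if self._arr is None:
            ii = np.array([r.i for r in self.restraints], dtype=int)
            jj = np.array([r.j for r in self.restraints], dtype=int)
            d0 = np.array([r.d0 for r in self.restraints])
            tol = np.array([r.tol for r in self.restraints])
            w = np.array([r.weight for r in self.restraints])
            self._arr = (ii, jj, d0, tol, w)
        return self._arr

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# provenance: {self.provenance}\n# i j d0 tol weight\n")
            for r in self.restraints:
                fh.write(f"{r.i} {r.j} {r.d0:.3f} {r.tol:.3f} {r.weight:.3f}\n")

    @classmethod
    def from_text(cls, path) -> "RestraintSet":
        prov = "user"
        rs = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("# provenance:"):
                    prov = line.split(":", 1)[1].strip()
                if line.startswith("#") or not line.strip():
                    continue
                f = line.split()
                rs.append(Restraint(int(f[0]), int(f[1]), float(f[2]), float(f[3]), float(f[4])))
        return cls(rs, prov)


def _subsample(restraints: list[Restraint], max_count: int, seed: int) -> list[Restraint]:
    if len(restraints) <= max_count:
        return restraints
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(restraints), size=max_count, replace=False))
    return [restraints[k] for k in keep]


def scaffold_restraints(case: ExcisedCase, max_count: int = DEFAULT_MAX_COUNT,
                        cutoff: float = DEFAULT_CUTOFF, min_sep: int = DEFAULT_MIN_SEP,
                        seed: int = 0, weight: float = SCAFFOLD_WEIGHT) -> RestraintSet:
    """Read distance restraints from the fixed (non-loop) scaffold.

    Candidate pairs are non-loop residues with chain separation >= min_sep
    and CA distance <= cutoff; targets are the observed distances.  A
    compact ~100-residue scaffold yields several hundred such pairs; beyond
    ``max_count`` a seeded uniform subsample is kept.
    """
    idx = [i for i in case.scaffold_indices() if case.scaffold.residues[i].has_ca]
    if len(idx) < 2:
        raise ValueError("scaffold has fewer than 2 coordinated residues")
    coords = np.array([case.scaffold.residues[i].ca for i in idx])
    d = squareform(pdist(coords))
    rs = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            if j - i < min_sep:
                continue
            if d[a, b] <= cutoff:
                rs.append(Restraint(i, j, float(d[a, b]), DEFAULT_TOL, weight))
    return RestraintSet(_subsample(rs, max_count, seed), "scaffold")


def consensus_restraints(templates: list[Structure], max_count: int = DEFAULT_MAX_COUNT,
                         min_sep: int = DEFAULT_MIN_SEP, cutoff: float = DEFAULT_CUTOFF,
                         seed: int = 0, weight: float = LOOP_WEIGHT,
                         divergence_cap: float = DIVERGENCE_CAP) -> RestraintSet:
    """Consensus restraints over >=2 equal-length template models.

    d0 is the across-template mean distance, the flat-bottom half-width is
    max(0.5 Å, across-template stdev); pairs more divergent than
    ``divergence_cap`` are dropped as uninformative.  Loop-region pairs are
    included — this is what lets externally built loop conformations guide
    the sampling in hybrid mode.
    """
    if len(templates) < 2:
        raise ValueError("consensus requires at least 2 templates")
    n = len(templates[0])
    if any(len(t) != n for t in templates):
        raise ValueError("templates have unequal lengths")
    coords = np.stack([t.ca_coords() for t in templates])   # (k, n, 3)
    dmats = np.stack([squareform(pdist(c)) for c in coords])
    mean = dmats.mean(axis=0)
    std = dmats.std(axis=0, ddof=0)
    rs = []
    for i in range(n):
        for j in range(i + min_sep, n):
            if mean[i, j] > cutoff or std[i, j] > divergence_cap:
                continue
            rs.append(Restraint(i, j, float(mean[i, j]),
                                float(max(DEFAULT_TOL, std[i, j])), weight))
    return RestraintSet(_subsample(rs, max_count, seed), f"consensus({len(templates)} templates)")


LOOP_MIN_SEP = 3  # loop-derived restraints keep short-range pairs: they are
                  # the pairs that actually encode the loop conformation


def native_loop_restraints(case: ExcisedCase, cutoff: float = DEFAULT_CUTOFF,
                           min_sep: int = LOOP_MIN_SEP,
                           weight: float = LOOP_WEIGHT) -> RestraintSet:
    """Restraints on the loop derived from the native coordinates.

    Benchmark-only: pairs with at least one loop residue, taken from the
    native structure (the limiting case of hybrid-mode consensus restraints
    when the templates carry the true loop).  Used by recovery tests; the
    blind pipeline never calls this.
    """
    loop = set(case.loop_indices)
    coords = {}
    for i, r in enumerate(case.scaffold.residues):
        if r.has_ca:
            coords[i] = r.ca
    for (rs, xyz), i in zip(case.native_loop, case.loop_indices):
        coords[i] = xyz
    rs_list = []
    for i in sorted(coords):
        for j in sorted(coords):
            if j - i < min_sep or (i not in loop and j not in loop):
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d <= cutoff:
                rs_list.append(Restraint(i, j, d, DEFAULT_TOL, weight))
    return RestraintSet(rs_list, "native-loop")


def merge_restraints(*sets: RestraintSet) -> RestraintSet:
    """Union of restraint sets; earlier sets win on duplicate pairs."""
    seen = {}
    for s in sets:
        for r in s:
            seen.setdefault((r.i, r.j), r)
    prov = "+".join(s.provenance for s in sets)
    return RestraintSet(list(seen.values()), prov)


def restraint_energy_xyz(xyz: np.ndarray, restraint_set: RestraintSet) -> float:
    """Flat-bottom harmonic restraint energy on raw Cα coordinates (Å)."""
    if len(restraint_set) == 0:
        return 0.0
    ii, jj, d0, tol, w = restraint_set.arrays()
    d = np.linalg.norm(xyz[ii] - xyz[jj], axis=1)
    viol = np.maximum(np.abs(d - d0) - tol, 0.0)
    return float((w * viol ** 2).sum())


def restraint_energy(conf, restraint_set: RestraintSet) -> float:
    """Restraint energy of a lattice conformation (or raw (N,3) coords)."""
    xyz = conf if isinstance(conf, np.ndarray) else conf.ca_xyz()
    return restraint_energy_xyz(np.asarray(xyz, dtype=float), restraint_set)
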