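"""Deterministic synthetic protein fixtures.

Small idealized single-domain topologies (helix-loop-helix, beta-hairpin,
three-helix) built from ideal secondary-structure elements joined by
circular-arc connectors with protein-like Cα spacing.  Every stage of the
modeling pipeline is testable against these with no external downloads:
the designated loop of each fixture is a known native conformation that
can be excised and rebuilt.

Fixtures are Cα-only.  Sequences are synthetic: alanine backbone with
leucines at core-facing positions (so hydrophobic contact wells are
exercised) and serine/glycine in connectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pdbio import ONE_TO_THREE, LoopSpec, Residue, Structure

__all__ = ["FixtureSpec", "make_helix", "make_strand", "make_fixture"]

TOPOLOGIES = ("helix-loop-helix", "beta-hairpin", "three-helix")


@dataclass(frozen=True)
class FixtureSpec:
    topology: str = "helix-loop-helix"
    n_res: tuple[int, ...] = (15, 15)   # per secondary-structure element
    loop_length: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if not (1 <= self.loop_length <= 30):
            raise ValueError("loop length must be in [1, 30]")
        total = sum(self.n_res) + self.loop_length * (len(self.n_res) - 1)
        if total > 120:
            raise ValueError(f"total fixture length {total} > 120")


def make_helix(n: int, rise: float = 1.5, radius: float = 2.3,
               twist_deg: float = 100.0) -> np.ndarray:
    """Ideal α-helix Cα trace along +z; consecutive Cα distance ≈ 3.83 Å."""
    if n < 4:
        raise ValueError("a helix needs at least 4 residues")
    t = np.deg2rad(twist_deg) * np.arange(n)
    return np.c_[radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)]


def make_strand(n: int, step_z: float = 3.3, zig: float = 0.95) -> np.ndarray:
    """Extended-strand Cα trace along +z with a pleat zigzag in x."""
    if n < 2:
        raise ValueError("a strand needs at least 2 residues")
    x = zig * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    return np.c_[x, np.zeros(n), step_z * np.arange(n)]


def _arc_points(a: np.ndarray, b: np.ndarray, n_interior: int, bulge_dir: np.ndarray,
                bond: float = 3.8) -> np.ndarray:
    """Interior points of a circular arc from a to b with ~equal 3.8 Å spacing.

    The arc lies in the plane spanned by the chord and ``bulge_dir`` and its
    sagitta is solved so that the arc length equals (n_interior + 1) * bond.
    """
    chord = b - a
    c = np.linalg.norm(chord)
    target = (n_interior + 1) * bond
    if target < c - 1e-9:
        raise ValueError(f"anchors {c:.1f} Å apart cannot be bridged by "
                         f"{n_interior + 1} bonds of {bond} Å")
    u = chord / c
    w = bulge_dir - (bulge_dir @ u) * u
    wn = np.linalg.norm(w)
    if wn < 1e-9:
        raise ValueError("bulge direction parallel to the chord")
    w = w / wn
    # solve the half-angle so that every *chord segment* between consecutive
    # points equals the bond length: 2R sin(theta/(n+1)) = bond with the
    # anchor chord c = 2R sin(theta); f(theta) monotone decreasing on (0, pi)
    m = n_interior + 1

    def f(theta):
        return bond * np.sin(theta) / np.sin(theta / m) - c

    lo, hi = 1e-6, np.pi - 1e-6
    if f(hi) > 0:
        raise ValueError("arc cannot wrap far enough; shorten the loop")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    theta = 0.5 * (lo + hi)
    radius = bond / (2.0 * np.sin(theta / m))
    center = 0.5 * (a + b) - w * radius * np.cos(theta)
    # sweep from a to b through the bulge
    angles = np.linspace(-theta, theta, n_interior + 2)[1:-1]
    pts = center[None, :] + radius * (np.outer(np.cos(angles), w)
                                      + np.outer(np.sin(angles), u))
    return pts


def _min_nonadjacent_dist(coords: np.ndarray) -> float:
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(coords))
    n = len(coords)
    mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) >= 2
    return float(d[mask].min())


def _connect(a_end: np.ndarray, b_start: np.ndarray, n_loop: int,
             centroid: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Loop points between two element anchors, bulging away from the core.

    Real connectors pack against the protein body rather than pointing into
    solvent at random: the bulge is placed in the plane of the chord and
    the structure centroid, on the outward side, then jittered slightly.
    A clash makes us rotate the bulge around the chord and retry.
    """
    chord = b_start - a_end
    mid = 0.5 * (a_end + b_start)
    out = mid - centroid
    if np.linalg.norm(out - (out @ chord) * chord / (chord @ chord)) < 1e-6:
        out = np.array([0.0, 0.0, 1.0])
    for rot in np.deg2rad([0, 40, -40, 80, -80, 120, -120, 160, 200]):
        u = chord / np.linalg.norm(chord)
        w = out - (out @ u) * u
        w = w / np.linalg.norm(w)
        v = np.cross(u, w)
        bulge = np.cos(rot) * w + np.sin(rot) * v
        try:
            pts = _arc_points(a_end, b_start, n_loop, bulge)
        except ValueError:
            raise
        jit = rng.normal(scale=0.04, size=pts.shape)
        yield_pts = pts + jit
        seg = np.linalg.norm(np.diff(np.vstack([a_end, yield_pts, b_start]), axis=0), axis=1)
        if seg.min() < 3.7 or seg.max() > 3.9:
            yield_pts = pts  # jitter broke the spacing; keep the clean arc
        yield yield_pts


def _assemble(elements: list[np.ndarray], loop_lengths: list[int],
              rng: np.random.Generator) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Concatenate elements with arc connectors; returns coords and the
    (start_index, end_index) 0-based inclusive span of each connector."""
    coords = elements[0].copy()
    spans = []
    centroid_all = np.vstack(elements).mean(axis=0)
    for elem, L in zip(elements[1:], loop_lengths):
        a_end, b_start = coords[-1], elem[0]
        placed = None
        for pts in _connect(a_end, b_start, L, centroid_all, rng):
            trial = np.vstack([coords, pts, elem])
            if _min_nonadjacent_dist(trial) >= 3.5:
                placed = pts
                break
        if placed is None:
            raise RuntimeError("fixture assembly clash could not be resolved")
        spans.append((len(coords), len(coords) + L - 1))
        coords = np.vstack([coords, placed, elem])
    return coords, spans


def _layout(spec: FixtureSpec) -> list[np.ndarray]:
    """Positioned secondary-structure elements for the topology."""
    if spec.topology == "helix-loop-helix":
        n1, n2 = spec.n_res
        h1 = make_helix(n1)
        # antiparallel packing, ~10.5 Å between the helix axes; the partner
        # axis is shifted as a whole so the cylinders keep a realistic gap
        h2 = make_helix(n2) @ _rot_x(np.pi).T
        h2 = h2 + np.array([10.5, 0.0, h1[-1][2] + 2.0])
        return [h1, h2]
    if spec.topology == "beta-hairpin":
        n1, n2 = spec.n_res
        s1 = make_strand(n1)
        s2 = make_strand(n2) @ _rot_x(np.pi).T
        s2 = s2 - s2[0] + np.array([0.0, 4.9, s1[-1][2] + 1.0])
        return [s1, s2]
    if spec.topology == "three-helix":
        n1, n2, n3 = spec.n_res
        h1 = make_helix(n1)
        h2 = make_helix(n2) @ _rot_x(np.pi).T
        h2 = h2 + np.array([10.5, 0.0, h1[-1][2] + 2.0])
        h3 = make_helix(n3) + np.array([5.2, 9.5, h2[-1][2] - 1.0])
        return [h1, h2, h3]
    raise AssertionError(spec.topology)


def _rot_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


HEPTAD = "LESATKQ"  # a/d-style core (L, A) with a polar/charged surface


def _sequence(n_total: int, loop_spans: list[tuple[int, int]]) -> str:
    """Amphipathic synthetic sequence: ~30% hydrophobic core positions on a
    heptad repeat, polar surface, serine connectors — roughly the
    composition of real small helical proteins, so the contact wells are
    exercised without an unphysical all-hydrophobic collapse drive."""
    seq = []
    in_loop = np.zeros(n_total, bool)
    for s, e in loop_spans:
        in_loop[s:e + 1] = True
    for i in range(n_total):
        seq.append("S" if in_loop[i] else HEPTAD[i % 7])
    return "".join(seq)


def make_fixture(spec: FixtureSpec) -> tuple[Structure, LoopSpec]:
    """Build a fixture structure and the LoopSpec of its designated loop.

    The designated loop is the first connector.  Deterministic for a given
    spec (seed included); consecutive Cα distances lie in the protein band
    and no non-adjacent Cα pair comes closer than 3.5 Å.
    """
    rng = np.random.default_rng(spec.seed)
    elements = _layout(spec)
    n_connectors = len(elements) - 1
    loop_lengths = [spec.loop_length] + [4] * (n_connectors - 1)
    coords, spans = _assemble(elements, loop_lengths, rng)
    seq = _sequence(len(coords), spans)
    residues = [
        Residue("A", i + 1, "", ONE_TO_THREE[aa], {"CA": coords[i].copy()})
        for i, aa in enumerate(seq)
    ]
    structure = Structure(f"{spec.topology}-{spec.seed}", residues)
    s, e = spans[0]
    loopspec = LoopSpec(structure.id[:4], s + 1, e + 1, chain="A")
    return structure, loopspec


def make_projection_suite(seed: int, n_traces: int = 50) -> list[np.ndarray]:
    """Seeded protein-like Cα traces for measuring lattice-projection accuracy.

    A mix of ideal helices, strands and assembled fixture topologies,
    20-80 residues, consecutive Cα distances in the 3.7-3.9 Å band.
    """
    rng = np.random.default_rng(seed)
    builders = [
        lambda: make_helix(int(rng.integers(20, 81))),
        lambda: make_strand(int(rng.integers(20, 45))),
        lambda: make_fixture(FixtureSpec(
            "helix-loop-helix",
            (int(rng.integers(10, 17)), int(rng.integers(10, 17))),
            int(rng.integers(4, 9)), int(rng.integers(0, 2 ** 31))))[0].ca_coords(),
        lambda: make_fixture(FixtureSpec(
            "beta-hairpin",
            (int(rng.integers(8, 13)), int(rng.integers(8, 13))),
            int(rng.integers(4, 7)), int(rng.integers(0, 2 ** 31))))[0].ca_coords(),
        lambda: make_fixture(FixtureSpec(
            "three-helix",
            tuple(int(rng.integers(10, 15)) for _ in range(3)),
            int(rng.integers(4, 8)), int(rng.integers(0, 2 ** 31))))[0].ca_coords(),
    ]
    return [builders[k % len(builders)]() for k in range(n_traces)]


def make_test_corpus(seed: int = 0) -> list[tuple[Structure, LoopSpec]]:
    """The small standard corpus used by tests and the fixtures CLI."""
    specs = [
        FixtureSpec("helix-loop-helix", (15, 15), 4, seed),
        FixtureSpec("helix-loop-helix", (12, 12), 8, seed + 1),
        FixtureSpec("beta-hairpin", (8, 8), 4, seed + 2),
        FixtureSpec("three-helix", (12, 12, 12), 6, seed + 3),
    ]
    out = []
    for sp in specs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.append(make_fixture(sp))
    return out
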