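"""Protein structure I/O and loop excision.

Structures are plain residue lists with author numbering (res_seq plus
insertion code), which is the addressing used by the benchmark loop table
("7rsa 47-50" means author residues 47..50 inclusive, declared length 4).
Only the coordinates needed by the coarse-grained pipeline are kept: every
modeled residue must carry a CA atom; other atoms are carried through when
present but never required.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Residue",
    "Structure",
    "LoopSpec",
    "ExcisedCase",
    "PDBError",
    "read_pdb",
    "write_pdb",
    "parse_benchmark_table",
    "excise_loop",
    "reinsert_loop",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class PDBError(ValueError):
    """Structured error for malformed or unsupported structure input."""


@dataclass
class Residue:
    chain_id: str
    res_seq: int
    i_code: str
    res_name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def ca(self) -> np.ndarray:
        try:
            return self.atoms["CA"]
        except KeyError:
            raise PDBError(
                f"residue {self.res_name} {self.chain_id}{self.res_seq}{self.i_code} has no CA atom"
            ) from None

    @property
    def has_ca(self) -> bool:
        return "CA" in self.atoms

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.i_code)

    @property
    def one_letter(self) -> str:
        try:
            return THREE_TO_ONE[self.res_name]
        except KeyError:
            raise PDBError(f"non-standard residue {self.res_name!r} at {self.chain_id}{self.res_seq}") from None


@dataclass
class Structure:
    """An ordered single-chain (for modeling purposes) residue list."""

    id: str
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(N, 3) CA coordinates in Å; raises if any residue lacks a CA."""
        return np.array([r.ca for r in self.residues], dtype=float)

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def select_chain(self, chain_id: str) -> "Structure":
        res = [r for r in self.residues if r.chain_id == chain_id]
        if not res:
            raise PDBError(f"chain {chain_id!r} not present in {self.id}")
        return Structure(self.id, res)

    def index_of(self, res_seq: int, i_code: str = "") -> int:
        for i, r in enumerate(self.residues):
            if r.res_seq == res_seq and r.i_code == i_code:
                return i
        raise PDBError(f"residue {res_seq}{i_code} not found in {self.id}")


@dataclass(frozen=True)
class LoopSpec:
    """A contiguous loop range in author numbering, inclusive on both ends."""

    pdb_code: str
    start: int
    end: int
    chain: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"loop end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ExcisedCase:
    """A loop-modeling problem: scaffold with the loop coordinates removed.

    The scaffold keeps the loop residues' identities (so the full sequence is
    known) but their atom dicts are emptied.  ``native_loop`` stores the
    excised CA coordinates for benchmark evaluation only; the blind modeling
    path never reads it.
    """

    scaffold: Structure
    native_loop: list[tuple[int, np.ndarray]]
    sequence: str
    loopspec: LoopSpec
    loop_indices: list[int]  # 0-based positions of the loop in the residue list

    @property
    def n_coordinated(self) -> int:
        return sum(1 for r in self.scaffold.residues if r.has_ca)

    def scaffold_indices(self) -> list[int]:
        loop = set(self.loop_indices)
        return [i for i in range(len(self.scaffold)) if i not in loop]

    def native_loop_coords(self) -> np.ndarray:
        return np.array([xyz for _, xyz in self.native_loop], dtype=float)


# --------------------------------------------------------------------------
# PDB reading / writing

def read_pdb(path, structure_id: str | None = None) -> Structure:
    """Parse ATOM records from a PDB file into a Structure.

    First MODEL only; HETATM ignored except MSE (selenomethionine), which is
    read as MET; alternate locations resolved by highest occupancy, ties by
    first occurrence.
    """
    residues: dict[tuple, Residue] = {}
    order: list[tuple] = []
    # per (residue key, atom name): best (occupancy, coords) so far
    best_alt: dict[tuple, tuple[float, np.ndarray]] = {}
    in_model = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                in_model += 1
                if in_model > 1:
                    break
                continue
            if rec == "ENDMDL":
                break
            is_atom = rec == "ATOM  "
            is_mse = rec == "HETATM" and line[17:20].strip() == "MSE"
            if not (is_atom or is_mse):
                continue
            name = line[12:16].strip()
            res_name = line[17:20].strip()
            if is_mse:
                res_name = "MET"
                if name == "SE":
                    continue
            chain_id = line[21].strip() or "A"
            res_seq = int(line[22:26])
            i_code = line[26].strip()
            try:
                occ = float(line[54:60])
            except ValueError:
                occ = 1.0
            xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            key = (chain_id, res_seq, i_code)
            if key not in residues:
                residues[key] = Residue(chain_id, res_seq, i_code, res_name)
                order.append(key)
            akey = (key, name)
            if akey not in best_alt or occ > best_alt[akey][0]:
                best_alt[akey] = (occ, xyz)
                residues[key].atoms[name] = xyz
    sid = structure_id or str(path)
    return Structure(sid, [residues[k] for k in order])


def write_pdb(structure: Structure, path) -> None:
    """Write standard fixed-column ATOM records, TER per chain, END.

    Residues without atoms (excised loop positions) are skipped on output.
    """
    lines = []
    serial = 1
    prev_chain = None
    for r in structure.residues:
        if prev_chain is not None and r.chain_id != prev_chain and lines:
            lines.append("TER")
        prev_chain = r.chain_id
        names = sorted(r.atoms, key=lambda n: (n != "N", n != "CA", n != "C", n != "O", n))
        for name in names:
            x, y, z = r.atoms[name]
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {pad_name}{'':1s}{r.res_name:>3s} {r.chain_id:1s}"
                f"{r.res_seq:4d}{r.i_code or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}"
            )
            serial += 1
    if any(r.atoms for r in structure.residues):
        lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Benchmark table

_RANGE_RE = re.compile(r"^(\S{4})\s+(\d+)-(\d+)$")


def parse_benchmark_table(text: str) -> list[LoopSpec]:
    """Parse the loop benchmark table dialect.

    Each non-empty row reads ``length<TAB>code start-end, code start-end, ...``.
    The declared row length must equal end-start+1 for every range in the row.
    """
    specs: list[LoopSpec] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        head, _, rest = line.partition("\t")
        if not rest:
            head, _, rest = line.partition(" ")
        declared = int(head)
        for token in rest.split(","):
            token = token.strip()
            if not token:
                continue
            m = _RANGE_RE.match(token)
            if m is None:
                raise ValueError(f"malformed loop token {token!r}")
            code, start, end = m.group(1).lower(), int(m.group(2)), int(m.group(3))
            spec = LoopSpec(code, start, end)
            if spec.length != declared:
                raise ValueError(
                    f"token {token!r}: range length {spec.length} != declared row length {declared}"
                )
            specs.append(spec)
    return specs


# --------------------------------------------------------------------------
# Loop excision

def excise_loop(structure: Structure, loopspec: LoopSpec) -> ExcisedCase:
    """Remove the loop range's coordinates, keeping residue identities.

    All residues in [start, end] must be present with CA coordinates
    (incomplete chains are a modeling error, not a recoverable state).
    """
    if loopspec.chain is not None:
        chain = loopspec.chain
    else:
        chains = structure.chain_ids()
        if len(chains) > 1:
            raise PDBError(
                f"{structure.id} has chains {chains}; LoopSpec must name one"
            )
        chain = chains[0]
    work = structure.select_chain(chain) if structure.chain_ids() != [chain] else structure

    loop_idx = [
        i for i, r in enumerate(work.residues)
        if loopspec.start <= r.res_seq <= loopspec.end
    ]
    if len(loop_idx) != loopspec.length:
        raise PDBError(
            f"loop {loopspec.start}-{loopspec.end} not fully resolved in {structure.id}: "
            f"found {len(loop_idx)} of {loopspec.length} residues"
        )
    if loop_idx != list(range(loop_idx[0], loop_idx[-1] + 1)):
        raise PDBError(f"loop {loopspec.start}-{loopspec.end} is not contiguous in {structure.id}")

    sequence = work.sequence  # also validates residue names
    native_loop: list[tuple[int, np.ndarray]] = []
    scaffold_res: list[Residue] = []
    loop_set = set(loop_idx)
    for i, r in enumerate(work.residues):
        if i in loop_set:
            native_loop.append((r.res_seq, r.ca.copy()))
            scaffold_res.append(replace(r, atoms={}))
        else:
            if not r.has_ca:
                raise PDBError(
                    f"scaffold residue {r.chain_id}{r.res_seq} of {structure.id} has no CA"
                )
            scaffold_res.append(replace(r, atoms={k: v.copy() for k, v in r.atoms.items()}))
    return ExcisedCase(
        scaffold=Structure(work.id, scaffold_res),
        native_loop=native_loop,
        sequence=sequence,
        loopspec=loopspec,
        loop_indices=loop_idx,
    )


def reinsert_loop(case: ExcisedCase, loop_coords: np.ndarray | None = None) -> Structure:
    """Rebuild a full structure from a case, default = the native loop.

    With ``loop_coords`` given ((L, 3) CA positions), inserts a modeled loop
    instead — the path used to emit final models.
    """
    if loop_coords is None:
        loop_coords = case.native_loop_coords()
    loop_coords = np.asarray(loop_coords, dtype=float)
    if len(loop_coords) != len(case.loop_indices):
        raise ValueError("loop_coords length does not match the excised range")
    residues = []
    it = iter(loop_coords)
    for i, r in enumerate(case.scaffold.residues):
        atoms = {k: v.copy() for k, v in r.atoms.items()}
        if i in set(case.loop_indices):
            atoms["CA"] = next(it).copy()
        residues.append(replace(r, atoms=atoms))
    return Structure(case.scaffold.id, residues)
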