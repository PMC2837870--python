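"""High-level loop-modeling pipelines tying the stages together.

Single-template mode: excise -> project -> scaffold restraints -> random
loop insertion -> annealed REMC repeats -> medoid selection.  Hybrid mode
replaces scaffold-only restraints with consensus restraints derived from
several external template models (their loop conformations included).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import restraints as rst
from .forcefield import EnergyModel
from .lattice import default_vector_set
from .pdbio import ExcisedCase, LoopSpec, Structure, excise_loop, reinsert_loop, write_pdb
from .remc import MoveSet, Schedule, Trajectory, run_repeats
from .selection import select_best_model, select_top_model

__all__ = ["ModelingResult", "model_loop_case", "model_loop", "hybrid_model_loop"]


@dataclass
class ModelingResult:
    case: ExcisedCase
    trajectories: list[Trajectory]
    top_model: Structure
    top_loop_coords: np.ndarray
    restraint_count: int
    provenance: str
    manifest: dict = field(default_factory=dict)

    def best_model(self) -> tuple[Structure, float]:
        """Benchmark oracle: closest-to-native snapshot and its loop cRMSD."""
        conf, crmsd = select_best_model(self.trajectories, self.case)
        xyz = conf.ca_xyz()
        return reinsert_loop(self.case, xyz[self.case.loop_indices]), crmsd

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pdb(self.top_model, outdir / "top_model.pdb")
        with open(outdir / "energies.tsv", "w") as fh:
            fh.write("run\tcycle\tenergy\n")
            for traj in self.trajectories:
                for s in traj.snapshots:
                    fh.write(f"{traj.run_id}\t{s.cycle}\t{s.energy:.6f}\n")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        # trajectory as a multi-MODEL Cα-trace PDB
        with open(outdir / "trajectory.pdb", "w") as fh:
            model_no = 1
            for traj in self.trajectories:
                for s in traj.snapshots:
                    fh.write(f"MODEL     {model_no:4d}\n")
                    xyz = s.conf.ca_xyz()
                    for i, (res, x) in enumerate(zip(self.case.scaffold.residues, xyz), 1):
                        fh.write(
                            f"ATOM  {i:5d}  CA  {res.res_name:>3s} {res.chain_id:1s}"
                            f"{res.res_seq:4d}    {x[0]:8.3f}{x[1]:8.3f}{x[2]:8.3f}"
                            f"  1.00  0.00\n")
                    fh.write("ENDMDL\n")
                    model_no += 1
            fh.write("END\n")
        return outdir


def model_loop_case(case: ExcisedCase, schedule: Schedule,
                    model: EnergyModel | None = None,
                    restraint_set: rst.RestraintSet | None = None,
                    n_repeats: int = 3, move_set: MoveSet | None = None,
                    provenance: str = "scaffold") -> ModelingResult:
    """Run the REMC pipeline on an already-excised case."""
    model = model or EnergyModel()
    vset = default_vector_set()
    if restraint_set is None:
        restraint_set = rst.scaffold_restraints(case, seed=schedule.seed)
    trajectories = run_repeats(case, model, restraint_set, schedule,
                               n_repeats=n_repeats, vector_set=vset, move_set=move_set)
    top_conf = select_top_model(trajectories, loop_indices=np.asarray(case.loop_indices))
    xyz = top_conf.ca_xyz()
    top_struct = reinsert_loop(case, xyz[case.loop_indices])
    manifest = {
        "seed": schedule.seed,
        "n_repeats": n_repeats,
        "schedule": asdict(schedule),
        "restraints": {"count": len(restraint_set), "provenance": restraint_set.provenance},
        "loop": {"start": case.loopspec.start, "end": case.loopspec.end,
                 "length": case.loopspec.length},
        "case_id": case.scaffold.id,
    }
    return ModelingResult(case, trajectories, top_struct, xyz[case.loop_indices],
                          len(restraint_set), provenance, manifest)


def model_loop(structure: Structure, loopspec: LoopSpec, schedule: Schedule,
               model: EnergyModel | None = None, n_repeats: int = 3) -> ModelingResult:
    """Single-template pipeline from a full structure and a loop range."""
    case = excise_loop(structure, loopspec)
    return model_loop_case(case, schedule, model, n_repeats=n_repeats)


def hybrid_model_loop(structure: Structure, loopspec: LoopSpec,
                      templates: list[Structure], schedule: Schedule,
                      model: EnergyModel | None = None,
                      n_repeats: int = 3) -> ModelingResult:
    """Hybrid pipeline: consensus restraints from external template models.

    The templates (e.g. the top-ranked models of another modeling program)
    must match the target sequence length; their loop conformations
    contribute restraints, which is what transfers their local accuracy
    into the coarse-grained sampling.
    """
    if len(templates) < 2:
        raise ValueError(
            "hybrid mode needs >= 2 template models; use the single-template "
            "pipeline (model_loop) for a lone template")
    case = excise_loop(structure, loopspec)
    consensus = rst.consensus_restraints(templates, seed=schedule.seed)
    result = model_loop_case(case, schedule, model, restraint_set=consensus,
                             n_repeats=n_repeats,
                             provenance=f"consensus({len(templates)})")
    result.manifest["templates"] = [t.id for t in templates]
    return result
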