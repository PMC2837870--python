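"""Loop-model evaluation: scaffold superposition, loop-only cRMSD,
length-bin statistics and the paired t-test.

cRMSD here is computed for Cα traces only: the structures *without* the
modeled loop are superimposed (Kabsch least squares over all non-loop
residues) and the deviation is then measured over the loop residues alone.
The loop endpoints count as loop, not scaffold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pdbio import LoopSpec, Structure

__all__ = [
    "EvaluationRecord",
    "kabsch_superpose",
    "loop_crmsd",
    "loop_crmsd_coords",
    "bin_statistics",
    "paired_t_test",
]

LENGTH_BINS = (("4-6", 4, 6), ("7-12", 7, 12), ("16-25", 16, 25))


@dataclass
class EvaluationRecord:
    case_id: str
    method: str
    loop_length: int
    top_crmsd: float
    best_crmsd: float

    def __post_init__(self):
        if self.top_crmsd < 0 or self.best_crmsd < 0:
            raise ValueError("cRMSD values must be non-negative")
        if self.best_crmsd > self.top_crmsd + 1e-9:
            raise ValueError("best_crmsd cannot exceed top_crmsd")


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of P onto Q.

    Returns (R, t, rmsd) with R a proper rotation (reflections excluded via
    the determinant correction) and t the translation such that R @ p + t
    best matches Q in the least-squares sense.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {P.shape} vs {Q.shape}")
    pm, qm = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - pm, Q - qm
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qm - R @ pm
    rmsd = float(np.sqrt(((Pc @ R.T - Qc) ** 2).sum() / len(P)))
    return R, t, rmsd


def loop_crmsd_coords(model_ca: np.ndarray, native_ca: np.ndarray,
                      loop_indices: np.ndarray) -> float:
    """Loop cRMSD from full-chain Cα coordinate arrays.

    Superposes the model's non-loop residues onto the native's, then reports
    the plain RMSD over loop residues (no second fit).
    """
    n = len(native_ca)
    if len(model_ca) != n:
        raise ValueError("model and native have different lengths")
    loop = np.asarray(loop_indices, dtype=int)
    mask = np.ones(n, bool)
    mask[loop] = False
    R, t, _ = kabsch_superpose(model_ca[mask], native_ca[mask])
    moved = model_ca[loop] @ R.T + t
    return float(np.sqrt(((moved - native_ca[loop]) ** 2).sum(axis=1).mean()))


def loop_crmsd(model: Structure, native: Structure, loopspec: LoopSpec) -> float:
    """Loop-only Cα cRMSD between a model and the native structure."""
    loop_idx = []
    for i, r in enumerate(native.residues):
        if loopspec.start <= r.res_seq <= loopspec.end:
            loop_idx.append(i)
    if len(loop_idx) != loopspec.length:
        raise ValueError(
            f"loop {loopspec.start}-{loopspec.end} incomplete in native ({len(loop_idx)} residues)"
        )
    return loop_crmsd_coords(model.ca_coords(), native.ca_coords(), np.array(loop_idx))


def bin_statistics(records: list[EvaluationRecord]) -> pd.DataFrame:
    """Per-length-bin mean cRMSDs, one row per (bin, method).

    Bins are 4-6, 7-12 and 16-25 residues; a record whose length falls in
    no bin is skipped with a warning.
    """
    if not records:
        raise ValueError("no evaluation records")
    rows = []
    for rec in records:
        label = None
        for name, lo, hi in LENGTH_BINS:
            if lo <= rec.loop_length <= hi:
                label = name
                break
        if label is None:
            warnings.warn(f"loop length {rec.loop_length} ({rec.case_id}) falls in no bin; skipped")
            continue
        rows.append({"bin": label, "method": rec.method,
                     "top_crmsd": rec.top_crmsd, "best_crmsd": rec.best_crmsd})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no records fell in any length bin")
    out = (df.groupby(["bin", "method"], sort=False)
             .agg(mean_top=("top_crmsd", "mean"),
                  mean_best=("best_crmsd", "mean"),
                  n_cases=("top_crmsd", "size"))
             .reset_index())
    order = {name: k for k, (name, _, _) in enumerate(LENGTH_BINS)}
    return out.sort_values(["bin", "method"], key=lambda s: s.map(lambda v: order.get(v, v))
                           if s.name == "bin" else s).reset_index(drop=True)


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sample paired t-test on matched cRMSD columns.

    Classic paired t on the differences with n - 1 degrees of freedom;
    zero variance of the differences leaves t undefined and raises.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if len(a) < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences; t statistic undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
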