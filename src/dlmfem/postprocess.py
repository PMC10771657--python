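"""Stress recovery and the study's two readouts.

"Tresca stress" here is the stress intensity sigma_1 - sigma_3 (twice the
maximum shear stress) — the shear-stress readout; "compressive stress" is the
magnitude of the most negative principal stress (minimum principal stress),
plotted as a positive number.  Stresses are element-constant (TET4), with no
nodal averaging; per-compartment peaks are taken over elements with a
deterministic lowest-element-id tie-break.

Readout regions: MFC/LFC (medial/lateral femoral cartilage), MM/LM
(medial/lateral meniscus), MTC/LTC (medial/lateral tibial cartilage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGION_CODES = {
    "femoral_cartilage_medial": "MFC",
    "femoral_cartilage_lateral": "LFC",
    "meniscus_medial": "MM",
    "meniscus_lateral": "LM",
    "tibial_cartilage_medial": "MTC",
    "tibial_cartilage_lateral": "LTC",
}


@dataclass
class StressField:
    tensors: np.ndarray          # (M, 3, 3) symmetric, MPa
    region: np.ndarray           # (M,) region tags

    def __post_init__(self):
        asym = np.abs(self.tensors - self.tensors.transpose(0, 2, 1)).max()
        if asym > 1e-10 * max(1.0, np.abs(self.tensors).max()):
            raise ValueError("stress tensors must be symmetric")


@dataclass
class RegionPeaks:
    tresca: dict = field(default_factory=dict)         # code -> MPa
    compressive: dict = field(default_factory=dict)    # code -> MPa (magnitude)
    element_ids: dict = field(default_factory=dict)    # code -> (tresca id, comp id)

    def as_row(self) -> dict:
        row = {}
        for code in REGION_CODES.values():
            row[f"{code}_tresca"] = self.tresca.get(code, np.nan)
            row[f"{code}_compressive"] = self.compressive.get(code, np.nan)
        return row


def recover_stresses(state, mesh, element_data) -> StressField:
    """Element-constant stress from the converged displacement field:
    sigma = C : B u per element."""
    B = element_data["B"]
    C = element_data["C"]
    u = state.displacements[mesh.tets].reshape(len(mesh.tets), 12)
    eps = np.einsum("mij,mj->mi", B, u)
    sig_v = np.einsum("mij,mj->mi", C, eps)
    M = len(mesh.tets)
    S = np.empty((M, 3, 3))
    S[:, 0, 0] = sig_v[:, 0]
    S[:, 1, 1] = sig_v[:, 1]
    S[:, 2, 2] = sig_v[:, 2]
    S[:, 1, 2] = S[:, 2, 1] = sig_v[:, 3]
    S[:, 0, 2] = S[:, 2, 0] = sig_v[:, 4]
    S[:, 0, 1] = S[:, 1, 0] = sig_v[:, 5]
    return StressField(tensors=S, region=mesh.region.copy())


def principal_stresses(tensor: np.ndarray) -> np.ndarray:
    """Sorted eigenvalues (sigma1 >= sigma2 >= sigma3); batched or single."""
    t = np.asarray(tensor, dtype=float)
    single = t.ndim == 2
    vals = np.linalg.eigvalsh(t if not single else t[None])
    vals = vals[:, ::-1]
    return vals[0] if single else vals


def tresca(tensor: np.ndarray) -> np.ndarray | float:
    """Stress intensity sigma1 - sigma3 (= 2 x max shear stress)."""
    p = principal_stresses(tensor)
    if p.ndim == 1:
        return float(p[0] - p[2])
    return p[:, 0] - p[:, 2]


def min_principal(tensor: np.ndarray):
    """(signed sigma3, compressive magnitude max(0, -sigma3))."""
    p = principal_stresses(tensor)
    if p.ndim == 1:
        s3 = float(p[2])
        return s3, max(0.0, -s3)
    s3 = p[:, 2]
    return s3, np.maximum(0.0, -s3)


def von_mises(tensor: np.ndarray):
    p = principal_stresses(tensor)
    p = np.atleast_2d(p)
    vm = np.sqrt(0.5 * ((p[:, 0] - p[:, 1]) ** 2 + (p[:, 1] - p[:, 2]) ** 2
                        + (p[:, 0] - p[:, 2]) ** 2))
    return vm[0] if len(vm) == 1 else vm


def region_peaks(field: StressField) -> RegionPeaks:
    """Per-compartment peak Tresca and compressive-magnitude stresses."""
    out = RegionPeaks()
    ts = tresca(field.tensors)
    _, comp = min_principal(field.tensors)
    for tag, code in REGION_CODES.items():
        idx = np.where(field.region == tag)[0]
        if len(idx) == 0:
            continue            # region absent: recorded as absent, not zero
        it = idx[np.argmax(ts[idx])]        # argmax -> lowest-id tie-break
        ic = idx[np.argmax(comp[idx])]
        out.tresca[code] = float(ts[it])
        out.compressive[code] = float(comp[ic])
        out.element_ids[code] = (int(it), int(ic))
    return out


def percent_change(value: float, reference: float) -> int:
    """Integer-rounded percent change vs a positive reference."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return int(round(percent_change_exact(value, reference)))


def percent_change_exact(value: float, reference: float) -> float:
    if reference <= 0:
        raise ValueError("reference must be positive")
    return (value - reference) / reference * 100.0


def comparison_table(peaks_by_model: dict, reference: str | None = None) -> pd.DataFrame:
    """Rows = model names, columns = per-region peaks; optional percent-change
    columns relative to a reference model (whose entries are 0)."""
    rows = {name: p.as_row() for name, p in peaks_by_model.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    if reference is not None:
        ref = df.loc[reference]
        for col in list(df.columns):
            df[f"{col}_pct"] = (df[col] - ref[col]) / ref[col] * 100.0
    return df


def export_vtk(path, mesh, field: StressField) -> None:
    from .io import write_vtk
    ts = tresca(field.tensors)
    s3, _ = min_principal(field.tensors)
    write_vtk(path, mesh.nodes, mesh.tets,
              cell_data={"tresca_MPa": ts, "min_principal_MPa": s3,
                         "region": field.region})
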