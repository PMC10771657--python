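"""Full resection study: geometry -> 15-model family -> solve -> result series.

The study solves the same joint 15 times, changing only the lateral meniscus
solid, under a 1150 N static stance load, and reports peak Tresca (shear) and
compressive (minimum-principal magnitude) stresses per compartment.  Three
series mirror the analyses of interest:

1. equal-ratio: 100/85/70/55/40 % residual volume in both halves,
2. same-volume pairs with unequal anterior/posterior split (groups A-E),
3. one half fixed while the other is reduced stepwise.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import GeometryConfig, KneeGeometry, MeshSizes, build_knee_geometry
from .materials import (default_material_cards, material_cards_from_dict,
                        material_cards_to_dict)
from .postprocess import (RegionPeaks, recover_stresses, region_peaks,
                          comparison_table, export_vtk)
from .resection import (MeniscusPartition, PartitionScheme, build_family,
                        enumerate_family, model_name, partition_rings,
                        split_anterior_posterior)
from .solver import (FiberBundle, LoadCase, RigidBody, StaticProblem,
                     assemble, contact_report, default_penalty, mesh_solids,
                     pair_contact, run_hertz_benchmark, run_patch_test,
                     run_uniaxial_block, solve_static)

logger = logging.getLogger("dlmfem")

EQUAL_RATIO_SERIES = ("100a100p", "85a85p", "70a70p", "55a55p", "40a40p")

PAIR_GROUPS = {
    "A": ("85a70p", "70a85p"),
    "B": ("85a55p", "55a85p"),
    "C": ("70a55p", "55a70p"),
    "D": ("70a40p", "40a70p"),
    "E": ("55a40p", "40a55p"),
}

FIXED_ANTERIOR_GROUPS = {
    "A": ("85a85p", "85a70p", "85a55p"),
    "B": ("70a85p", "70a70p", "70a55p", "70a40p"),
    "C": ("55a85p", "55a70p", "55a55p", "55a40p"),
    "D": ("40a70p", "40a55p", "40a40p"),
}

FIXED_POSTERIOR_GROUPS = {
    "A": ("85a85p", "70a85p", "55a85p"),
    "B": ("85a70p", "70a70p", "55a70p", "40a70p"),
    "C": ("85a55p", "70a55p", "55a55p", "40a55p"),
    "D": ("70a40p", "55a40p", "40a40p"),
}

# Peak stresses (MPa) reported by three knee FE studies for an intact joint:
# columns SSFC/SSM/SSTC = peak shear on femoral cartilage / meniscus / tibial
# cartilage; CSFC/CSM/CSTC = peak compressive stress on the same tissues.
LITERATURE_VALIDATION = pd.DataFrame(
    {
        "SSFC": [1.42, 1.72, 2.00],
        "SSM": [7.61, 11.45, 6.72],
        "SSTC": [2.85, 3.56, 2.40],
        "CSFC": [3.11, 6.51, 4.25],
        "CSM": [5.90, 6.61, 9.15],
        "CSTC": [3.36, 8.45, 6.81],
    },
    index=["source_model", "zhi_xu", "zhang_k"],
)


@dataclass
class StudyConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    scheme: PartitionScheme = field(default_factory=PartitionScheme)
    materials: dict = field(default_factory=default_material_cards)
    sizes: MeshSizes = field(default_factory=MeshSizes)
    axial_load: float = 1150.0            # N, compressive, on the femur
    root_stiffness: float = 5000.0        # N/mm total per meniscus (root +
                                          # capsule anchoring springs)
    # the stance response is nearly linear (conforming contact, small
    # strains): a 2-increment ramp reproduces finer ramps to displayed
    # precision, so the default study uses it
    load_case: LoadCase = field(default_factory=lambda: LoadCase(increments=2))
    smoothing_band: float = 3.0           # mm
    models: tuple | None = None           # subset of names; None = all 15
    output_dir: str | None = None
    write_fields: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "scheme": {"ring_fractions": list(self.scheme.ring_fractions),
                       "ap_split_rule": self.scheme.ap_split_rule},
            "materials": material_cards_to_dict(self.materials),
            "sizes": {"in_plane": self.sizes.in_plane,
                      "nz_cartilage": self.sizes.nz_cartilage,
                      "nz_meniscus": self.sizes.nz_meniscus},
            "axial_load": self.axial_load,
            "root_stiffness": self.root_stiffness,
            "load_case": {"increments": self.load_case.increments,
                          "tolerance": self.load_case.tolerance,
                          "max_iterations": self.load_case.max_iterations,
                          "max_penetration": self.load_case.max_penetration},
            "smoothing_band": self.smoothing_band,
            "models": list(self.models) if self.models else None,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        return cls(
            geometry=GeometryConfig.from_dict(d["geometry"]),
            scheme=PartitionScheme(
                ring_fractions=tuple(d["scheme"]["ring_fractions"]),
                ap_split_rule=d["scheme"]["ap_split_rule"]),
            materials=material_cards_from_dict(d["materials"]),
            sizes=MeshSizes(**d["sizes"]),
            axial_load=d["axial_load"],
            root_stiffness=d.get("root_stiffness", 5000.0),
            load_case=LoadCase(**d["load_case"]),
            smoothing_band=d["smoothing_band"],
            models=tuple(d["models"]) if d.get("models") else None,
            seed=d.get("seed", 0),
        )


@dataclass
class ModelResult:
    name: str
    peaks: RegionPeaks
    residual_fraction: float
    equilibrium_error: float           # |reaction - load| / load
    femur_dofs: dict
    contact: dict
    iterations: int


@dataclass
class StudyResults:
    config: StudyConfig
    models: dict                      # name -> ModelResult

    def table(self) -> pd.DataFrame:
        peaks = {k: v.peaks for k, v in self.models.items()}
        df = comparison_table(peaks)
        df["residual_fraction"] = [self.models[k].residual_fraction
                                   for k in df.index]
        df["equilibrium_error"] = [self.models[k].equilibrium_error
                                   for k in df.index]
        return df


# ---------------------------------------------------------------------------
# Single-model solve
# ---------------------------------------------------------------------------

def build_knee_problem(geometry: KneeGeometry, config: StudyConfig,
                       penalty: float | None = None):
    mesh = mesh_solids(geometry, config.sizes)
    K, data = assemble(mesh, config.materials)
    femur = RigidBody(
        name="femur", reference=np.zeros(3),
        free=("tx", "tz", "ry"),              # ML translation, axial, varus/valgus
        load={"tz": -config.axial_load},
        bonded_set="femur_bonded")
    pen = penalty if penalty is not None else \
        default_penalty(15.0, config.sizes.in_plane)
    contacts = []
    for side in ("medial", "lateral"):
        fc, me, tc = (f"femoral_cartilage_{side}", f"meniscus_{side}",
                      f"tibial_cartilage_{side}")
        contacts.append(pair_contact(
            mesh, f"{fc}_bottom_nodes", f"{me}_top", f"{fc}_bottom", pen,
            name=f"femcart-meniscus-{side}"))
        contacts.append(pair_contact(
            mesh, f"{fc}_bottom_nodes", f"{tc}_top", f"{fc}_bottom", pen,
            name=f"femcart-tibcart-{side}"))
        contacts.append(pair_contact(
            mesh, f"{me}_bottom_nodes", f"{tc}_top", f"{me}_bottom", pen,
            name=f"meniscus-tibcart-{side}"))
    fibers = []
    for lig in geometry.ligaments:
        fibers.append(FiberBundle(
            body="femur", attach_points=lig.femur_points,
            fixed_points=lig.tibia_points,
            areas=np.full(len(lig.femur_points), lig.cross_section_area),
            material=config.materials[lig.material_ref], name=lig.name))
    # compliant root/capsule anchoring of each meniscus rim
    spring_nodes, spring_k = [], []
    for side in ("medial", "lateral"):
        ids = mesh.node_sets[f"meniscus_{side}_root_nodes"]
        spring_nodes.append(ids)
        spring_k.append(np.full(len(ids), config.root_stiffness / len(ids)))
    problem = StaticProblem(
        mesh, K, [femur], contacts, fibers=fibers,
        ground_springs=(np.concatenate(spring_nodes),
                        np.concatenate(spring_k)))
    return mesh, problem, data


def solve_model(geometry: KneeGeometry, config: StudyConfig,
                name: str = "100a100p",
                residual_fraction: float = 1.0) -> ModelResult:
    mesh, problem, data = build_knee_problem(geometry, config)
    state = solve_static(problem, config.load_case)
    field_ = recover_stresses(state, mesh, data)
    peaks = region_peaks(field_)
    reaction = float(state.reactions[:, 2].sum())
    eq_err = abs(abs(reaction) - config.axial_load) / config.axial_load
    result = ModelResult(
        name=name, peaks=peaks, residual_fraction=residual_fraction,
        equilibrium_error=eq_err, femur_dofs=state.rigid_dofs["femur"],
        contact=contact_report(state), iterations=len(state.log))
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config.write_fields:
            export_vtk(out / f"{name}.vtk", mesh, field_)
    return result


# ---------------------------------------------------------------------------
# Study orchestration
# ---------------------------------------------------------------------------

def prepare_partition(config: StudyConfig):
    geometry = build_knee_geometry(config.geometry, config.sizes)
    partition = partition_rings(geometry.solid("meniscus_lateral"),
                                config.scheme, sizes=config.sizes)
    partition = split_anterior_posterior(partition)
    return geometry, partition


def run_study(config: StudyConfig) -> StudyResults:
    """Solve the whole model family with identical settings except the
    lateral meniscus solid."""
    t0 = time.time()
    geometry, partition = prepare_partition(config)
    family = build_family(partition, band_width=config.smoothing_band,
                          sizes=config.sizes)
    wanted = set(config.models) if config.models else None
    results: dict[str, ModelResult] = {}
    failures = []
    for model in family:
        if wanted is not None and model.name not in wanted:
            continue
        geom = geometry.replace_solid("meniscus_lateral", model.solid)
        t1 = time.time()
        try:
            res = solve_model(geom, config, name=model.name,
                              residual_fraction=model.realized_residual_fraction)
            results[model.name] = res
            logger.info("model %s solved in %.1f s (peak LM tresca %.3f MPa)",
                        model.name, time.time() - t1,
                        res.peaks.tresca.get("LM", float("nan")))
        except Exception as exc:   # study continues; failure recorded
            failures.append((model.name, str(exc)))
            logger.error("model %s failed: %s", model.name, exc)
    out = StudyResults(config=config, models=results)
    if config.output_dir:
        _write_outputs(out, failures)
    logger.info("study finished: %d models in %.1f s",
                len(results), time.time() - t0)
    if failures:
        raise RuntimeError(f"{len(failures)} model(s) failed to converge: "
                           f"{[f[0] for f in failures]}")
    return out


def _write_outputs(results: StudyResults, failures) -> None:
    out = Path(results.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.table().to_csv(out / "peaks.csv")
    series_equal_ratio(results).to_csv(out / "series_equal_ratio.csv")
    try:
        series_pairs(results).to_csv(out / "series_pairs.csv")
        fixed_a, fixed_p = series_fixed_one(results)
        fixed_a.to_csv(out / "series_fixed_anterior.csv")
        fixed_p.to_csv(out / "series_fixed_posterior.csv")
    except KeyError:
        pass      # subset runs may not contain every series member
    manifest = {
        "config": results.config.to_dict(),
        "models": sorted(results.models),
        "failures": failures,
    }
    (out / "study_manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# Result series
# ---------------------------------------------------------------------------

def _require(results: StudyResults, names) -> None:
    missing = [n for n in names if n not in results.models]
    if missing:
        raise KeyError(f"series member(s) missing from study: {missing}")


def series_equal_ratio(results: StudyResults) -> pd.DataFrame:
    """Equal-ratio trend (100 -> 40 %) with percent change vs the intact model."""
    names = [n for n in EQUAL_RATIO_SERIES if n in results.models]
    _require(results, names[:1])
    peaks = {n: results.models[n].peaks for n in names}
    return comparison_table(peaks, reference=names[0]).loc[list(names)]


def series_pairs(results: StudyResults) -> pd.DataFrame:
    """Same-volume pairs A-E; which member is lower per quantity.

    Group E is reported without a winner assertion: it is the documented
    exception where the two readouts disagree."""
    rows = []
    for g, (m1, m2) in PAIR_GROUPS.items():
        _require(results, (m1, m2))
        p1 = results.models[m1].peaks.as_row()
        p2 = results.models[m2].peaks.as_row()
        for q in p1:
            lower = m1 if p1[q] <= p2[q] else m2
            rows.append({"group": g, "quantity": q, m1 if True else "": p1[q],
                         "model_1": m1, "value_1": p1[q],
                         "model_2": m2, "value_2": p2[q],
                         "lower": "no assertion" if g == "E" else lower})
    df = pd.DataFrame(rows)
    return df[["group", "quantity", "model_1", "value_1",
               "model_2", "value_2", "lower"]]


def series_fixed_one(results: StudyResults):
    """Stepwise tables: anterior fixed / posterior varying, and the transpose."""
    def table(groups):
        rows = []
        for g, names in groups.items():
            _require(results, names)
            for n in names:
                row = {"group": g, "model": n}
                row.update(results.models[n].peaks.as_row())
                rows.append(row)
        return pd.DataFrame(rows).set_index(["group", "model"])
    return table(FIXED_ANTERIOR_GROUPS), table(FIXED_POSTERIOR_GROUPS)


def validate_against_literature(results: StudyResults) -> pd.DataFrame:
    """Intact-model peaks vs published ranges; flags, never hard failures.

    SSM is reported in two scopes: lateral meniscus only, and the whole
    meniscus (MM plus LM) — published tables do not always state which
    meniscus carries the peak."""
    _require(results, ("100a100p",))
    p = results.models["100a100p"].peaks
    ours = {
        "SSFC": max(p.tresca.get("MFC", 0), p.tresca.get("LFC", 0)),
        "SSM": max(p.tresca.get("MM", 0), p.tresca.get("LM", 0)),
        "SSM_lateral_only": p.tresca.get("LM", 0),
        "SSTC": max(p.tresca.get("MTC", 0), p.tresca.get("LTC", 0)),
        "CSFC": max(p.compressive.get("MFC", 0), p.compressive.get("LFC", 0)),
        "CSM": max(p.compressive.get("MM", 0), p.compressive.get("LM", 0)),
        "CSTC": max(p.compressive.get("MTC", 0), p.compressive.get("LTC", 0)),
    }
    rows = []
    for q, v in ours.items():
        col = "SSM" if q.startswith("SSM") else q
        lit = LITERATURE_VALIDATION[col]
        lo, hi = 0.5 * lit.min(), 2.0 * lit.max()
        rows.append({"quantity": q, "value_MPa": v,
                     "literature_min": lit.min(), "literature_max": lit.max(),
                     "plausible_low": lo, "plausible_high": hi,
                     "flag": "" if lo <= v <= hi else "outside plausibility band"})
    return pd.DataFrame(rows).set_index("quantity")


# ---------------------------------------------------------------------------
# Verification suite (closed-form / brute-force oracles)
# ---------------------------------------------------------------------------

def _eigen_oracle_error(seed: int = 0, n: int = 1000) -> float:
    """Principal stresses vs characteristic-polynomial roots (brute force)."""
    from .postprocess import principal_stresses
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n):
        A = rng.normal(size=(3, 3))
        S = 0.5 * (A + A.T)
        p = principal_stresses(S)
        # characteristic polynomial det(S - x I) = -x^3 + I1 x^2 - I2 x + I3
        i1 = np.trace(S)
        i2 = 0.5 * (i1 ** 2 - np.trace(S @ S))
        i3 = np.linalg.det(S)
        roots = np.sort(np.real(np.roots([1.0, -i1, i2, -i3])))[::-1]
        worst = max(worst, np.abs(roots - p).max())
    return float(worst)


def verify_suite(seed: int = 0, include_hertz: bool = True) -> dict:
    """Machine-readable benchmark report with the package's tolerances."""
    report = {}
    patch = run_patch_test()
    report["patch_test"] = {"rel_error": patch, "tolerance": 1e-8,
                            "passed": patch <= 1e-8}
    uni = run_uniaxial_block()
    report["uniaxial_block"] = {**uni, "tolerance": 0.01,
                                "passed": uni["rel_err"] <= 0.01}
    eig = _eigen_oracle_error(seed=seed)
    report["eigen_oracle"] = {"max_abs_error": eig, "tolerance": 1e-10,
                              "passed": eig <= 1e-10}
    if include_hertz:
        hz = run_hertz_benchmark()
        report["hertz_contact"] = {**hz, "tolerance": 0.05,
                                   "passed": hz["rel_err"] <= 0.05}
    return report
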