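"""Per-subject scalar attributes from the FE solution and material field.

Reduces the element-level tensors to the canonical 39-attribute vector:
five clinical values, seven morphometrics, five fall-chain forces, four
tissue-composition values and eighteen FE summary attributes (nine per
region, neck ``_N`` and trochanter ``_T``, plus the whole-bone LSR and
femoral strength).

Tissue partition: cortical bone is apparent density strictly greater
than 1.0 g/cm^3; trabecular is the rest.  TB and CT are area percentages
and sum to 100 exactly.

LSR (load-to-strength ratio): per element the ratio of compressive
principal strain demand to the compressive yield strain; the critical
region is grown greedily from the peak-ratio element through
edge-adjacent neighbours (always absorbing the highest-ratio frontier
element) until it reaches 9 mm^2, and LSR is the smallest ratio inside
that region.  By the bottleneck property this equals the best achievable
minimum over all connected regions of that area containing the peak.
FS (femoral strength) is the load at which that region reaches yield:
FP / LSR under linearity.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .cohort import SubjectRecord
from .fall import FallAttributes
from .fe import FESolution, MaterialField, TAG_FEMUR
from .morphometry import MorphometricSet, RoiPartition

__all__ = [
    "TissueAttributes",
    "MechanicalAttributes",
    "YieldModel",
    "AttributeError_",
    "ATTRIBUTE_NAMES",
    "ATTRIBUTE_UNITS",
    "tissue_attributes",
    "regional_average",
    "fracture_risk_index",
    "load_to_strength_ratio",
    "femoral_strength",
    "region_elements",
    "mechanical_attributes",
    "assemble",
]

CORTICAL_THRESHOLD = 1.0    # g/cm^3, strictly greater than => cortical

ATTRIBUTE_NAMES: tuple[str, ...] = (
    "Age", "Height", "Weight", "BMI", "BMD",
    "NW", "HAL", "NSA", "SAL", "ITW", "STW", "FA",
    "STH", "FPK", "FAT", "FP", "HP",
    "TB", "TBE", "CT", "CTE",
    "LSR", "FS",
    "S1_N", "S3_N", "E1_N", "E3_N", "MPStress_N", "MPStrain_N", "SED_N",
    "S1_T", "S3_T", "E1_T", "E3_T", "MPStress_T", "MPStrain_T", "SED_T",
    "FRI_N", "FRI_T",
)


ATTRIBUTE_UNITS: dict[str, str] = {
    "Age": "years", "Height": "cm", "Weight": "kg", "BMI": "kg/m^2",
    "BMD": "g/cm^2",
    "NW": "mm", "HAL": "mm", "NSA": "deg", "SAL": "mm", "ITW": "mm",
    "STW": "mm", "FA": "mm^2",
    "STH": "mm", "FPK": "N", "FAT": "N", "FP": "N", "HP": "MPa",
    "TB": "%", "TBE": "GPa", "CT": "%", "CTE": "GPa",
    "LSR": "-", "FS": "N",
    **{f"{q}_{r}": u for r in ("N", "T")
       for q, u in (("S1", "MPa"), ("S3", "MPa"), ("E1", "microstrain"),
                    ("E3", "microstrain"), ("MPStress", "MPa"),
                    ("MPStrain", "microstrain"), ("SED", "J/m^3"),
                    ("FRI", "-"))},
}


class AttributeError_(ValueError):
    """Raised for invalid attribute-extraction inputs."""


@dataclass(frozen=True)
class TissueAttributes:
    tb: float       # % trabecular area
    ct: float       # % cortical area
    tbe: float      # GPa mean trabecular modulus
    cte: float      # GPa mean cortical modulus
    threshold: float = CORTICAL_THRESHOLD


@dataclass(frozen=True)
class YieldModel:
    """Uniform compressive yield strain; per-element yield stress E * eps_y."""

    compressive_yield_strain: float = 7300e-6

    def __post_init__(self) -> None:
        if self.compressive_yield_strain <= 0:
            raise AttributeError_("yield strain must be positive")

    def yield_stress(self, materials: MaterialField) -> np.ndarray:
        return materials.youngs * self.compressive_yield_strain


@dataclass
class MechanicalAttributes:
    lsr: float
    fs: float
    regional: dict[str, float]      # S1_N ... FRI_T


def tissue_attributes(materials: MaterialField, mesh_areas: np.ndarray,
                      femur: np.ndarray,
                      threshold: float = CORTICAL_THRESHOLD) -> TissueAttributes:
    """Area-weighted tissue percentages and mean moduli (GPa)."""
    if not np.any(femur):
        raise AttributeError_("no femur elements")
    a = mesh_areas[femur]
    rho = materials.density[femur]
    e = materials.youngs[femur]
    cortical = rho > threshold      # strictly greater
    a_c, a_t = a[cortical].sum(), a[~cortical].sum()
    total = a_c + a_t
    ct = 100.0 * a_c / total
    cte = float((a[cortical] * e[cortical]).sum() / a_c) / 1000.0 if a_c > 0 else 0.0
    tbe = float((a[~cortical] * e[~cortical]).sum() / a_t) / 1000.0 if a_t > 0 else 0.0
    return TissueAttributes(tb=100.0 - ct, ct=ct, tbe=tbe, cte=cte,
                            threshold=threshold)


def regional_average(values: np.ndarray, areas: np.ndarray,
                     region: np.ndarray) -> float:
    """Area-weighted mean of an element field over a region index set."""
    region = np.asarray(region)
    if region.dtype == bool:
        region = np.flatnonzero(region)
    if len(region) == 0:
        raise AttributeError_("empty region")
    a = areas[region]
    return float((values[region] * a).sum() / a.sum())


def _signed_max_abs(v1: np.ndarray, v3: np.ndarray) -> np.ndarray:
    """Largest-magnitude principal value, sign preserved."""
    return np.where(np.abs(v1) >= np.abs(v3), v1, v3)


def fracture_risk_index(solution: FESolution, materials: MaterialField,
                        region: np.ndarray, yield_model: YieldModel) -> float:
    """Area-weighted mean of von Mises stress over yield stress."""
    sy = yield_model.yield_stress(materials)
    if np.any(sy[region] <= 0):
        raise AttributeError_("non-positive yield stress in region")
    return regional_average(solution.von_mises / sy, solution.mesh.areas(), region)


def load_to_strength_ratio(solution: FESolution, yield_model: YieldModel,
                           area_target: float = 9.0,
                           femur: np.ndarray | None = None,
                           ratios: np.ndarray | None = None) -> float:
    """Minimum demand/capacity ratio in the critical contiguous region.

    ``ratios`` may override the default compressive-strain ratio field
    (used by tests that exercise the region search in isolation).
    """
    mesh = solution.mesh
    areas = mesh.areas()
    if femur is None:
        femur = mesh.tags == TAG_FEMUR
    femur_idx = np.flatnonzero(femur)
    if areas[femur_idx].sum() < area_target:
        raise AttributeError_("femur area smaller than the target region")
    if ratios is None:
        ratios = np.abs(np.minimum(solution.e3, 0.0)) \
            / yield_model.compressive_yield_strain
    adj = mesh.element_adjacency()
    in_femur = np.zeros(mesh.n_elements, dtype=bool)
    in_femur[femur_idx] = True

    seed = femur_idx[int(np.argmax(ratios[femur_idx]))]
    visited = {seed}
    acc_area = areas[seed]
    lsr = ratios[seed]
    frontier = []
    for nb in adj[seed]:
        if in_femur[nb]:
            heapq.heappush(frontier, (-ratios[nb], nb))
    while acc_area < area_target and frontier:
        neg_r, k = heapq.heappop(frontier)
        if k in visited:
            continue
        visited.add(k)
        acc_area += areas[k]
        lsr = min(lsr, -neg_r)
        for nb in adj[k]:
            if in_femur[nb] and nb not in visited:
                heapq.heappush(frontier, (-ratios[nb], nb))
    if acc_area < area_target:
        raise AttributeError_("femur region disconnected below target area")
    return float(lsr)


def femoral_strength(fp: float, lsr: float) -> float:
    """Load at which the critical region reaches yield: FP / LSR."""
    if lsr <= 0:
        raise AttributeError_("LSR must be positive")
    return fp / lsr


def region_elements(solution: FESolution,
                    rois: RoiPartition) -> tuple[np.ndarray, np.ndarray]:
    """Femur element index sets for the neck and trochanteric regions."""
    mesh = solution.mesh
    cent = mesh.centroids()
    neck, troch = rois.classify_points(cent)
    femur = mesh.tags == TAG_FEMUR
    return np.flatnonzero(neck & femur), np.flatnonzero(troch & femur)


def mechanical_attributes(solution: FESolution, materials: MaterialField,
                          rois: RoiPartition, fp: float,
                          yield_model: YieldModel | None = None) -> MechanicalAttributes:
    """All 18 FE summary attributes plus LSR and FS for one subject."""
    ym = yield_model if yield_model is not None else YieldModel()
    areas = solution.mesh.areas()
    neck, troch = region_elements(solution, rois)
    if len(neck) == 0 or len(troch) == 0:
        raise AttributeError_("empty neck or trochanteric region")
    out: dict[str, float] = {}
    for suffix, region in (("N", neck), ("T", troch)):
        out[f"S1_{suffix}"] = regional_average(solution.s1, areas, region)
        out[f"S3_{suffix}"] = regional_average(solution.s3, areas, region)
        out[f"E1_{suffix}"] = regional_average(solution.e1, areas, region) * 1e6
        out[f"E3_{suffix}"] = regional_average(solution.e3, areas, region) * 1e6
        out[f"MPStress_{suffix}"] = regional_average(
            _signed_max_abs(solution.s1, solution.s3), areas, region)
        out[f"MPStrain_{suffix}"] = regional_average(
            _signed_max_abs(solution.e1, solution.e3), areas, region) * 1e6
        out[f"SED_{suffix}"] = regional_average(solution.sed, areas, region)
        out[f"FRI_{suffix}"] = fracture_risk_index(solution, materials, region, ym)
    lsr = load_to_strength_ratio(solution, ym)
    fs = femoral_strength(fp, lsr)
    return MechanicalAttributes(lsr=lsr, fs=fs, regional=out)


def assemble(record: SubjectRecord, morph: MorphometricSet,
             fall: FallAttributes, tissue: TissueAttributes,
             mech: MechanicalAttributes) -> dict[str, float]:
    """Canonical ordered 39-attribute mapping for one subject."""
    values = {
        "Age": record.age, "Height": record.height, "Weight": record.weight,
        "BMI": record.bmi, "BMD": record.bmd_total,
        "NW": morph.nw, "HAL": morph.hal, "NSA": morph.nsa, "SAL": morph.sal,
        "ITW": morph.itw, "STW": morph.stw, "FA": morph.fa,
        "STH": fall.sth, "FPK": fall.fpk, "FAT": fall.fat, "FP": fall.fp,
        "HP": fall.hp,
        "TB": tissue.tb, "TBE": tissue.tbe, "CT": tissue.ct, "CTE": tissue.cte,
        "LSR": mech.lsr, "FS": mech.fs,
        **mech.regional,
    }
    missing = [n for n in ATTRIBUTE_NAMES if n not in values
               or values[n] is None or not np.isfinite(values[n])]
    if missing:
        raise AttributeError_(f"missing attributes: {', '.join(missing)}")
    return {name: float(values[name]) for name in ATTRIBUTE_NAMES}
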