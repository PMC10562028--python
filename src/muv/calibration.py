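"""Per-energy calibration linking engine output (Gy/particle) to absolute dose.

The calibration factor is defined under reference conditions (10 x 10 cm
field, 100 cm SSD, 40 cm water cube, scoring at 10 cm depth on the central
axis) as

    F_cal = D_tps[Gy/MU] / D_mc[Gy/particle]      (particles per MU)

and applied voxel-wise as ``dose_Gy = dose_per_particle * F_cal * MU``.
The TPS value is quoted in cGy/MU; the factor of 100 is applied explicitly
here.  The reference run uses a water phantom with density 1.000 (not the
HU-0 table density of ~0.98) because calibration is defined in water; the
provenance string records this.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .beam import BeamSource
from .dicom_io import ArcBeam, ControlPoint, VMATPlan
from .geometry import trilinear
from .phantom import VoxelPhantom, water_phantom
from .transport import DoseResult, simulate_arc

# Toy TPS reference outputs at the reference point, cGy/MU (fixture values
# standing in for the planning-system calculation).
DEFAULT_REFERENCE_OUTPUT_CGY_PER_MU = {
    "6X": 0.665, "6FFF": 0.630, "10X": 0.735, "10FFF": 0.700,
}

# Packaged toy spectra per energy label: (MeV, probability) pairs.  FFF and
# flattened labels differ only in spectral weighting.
DEFAULT_SPECTRA = {
    "6X": ((0.5, 0.25), (1.5, 0.45), (3.0, 0.25), (5.5, 0.05)),
    "6FFF": ((0.3, 0.35), (1.0, 0.40), (2.5, 0.20), (5.5, 0.05)),
    "10X": ((0.5, 0.20), (2.0, 0.40), (5.0, 0.30), (9.0, 0.10)),
    "10FFF": ((0.4, 0.30), (1.5, 0.40), (4.0, 0.22), (9.0, 0.08)),
}


def default_source(energy: str, window_halfsize_mm: float = 80.0) -> BeamSource:
    """Parametric source with the packaged toy spectrum for *energy*."""
    return BeamSource(energy=energy, spectrum=DEFAULT_SPECTRA[energy],
                      window_halfsize_mm=window_halfsize_mm)


@dataclass(frozen=True)
class ReferenceMeasurement:
    d_tps_cgy_per_mu: float
    mu_ref: float
    d_mc_gy_per_particle: float
    energy: str

    def __post_init__(self) -> None:
        if min(self.d_tps_cgy_per_mu, self.mu_ref, self.d_mc_gy_per_particle) <= 0:
            raise ValueError("reference measurement values must be strictly positive")


@dataclass(frozen=True)
class CalibrationFactor:
    value: float  # particles per MU
    energy: str
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("calibration factor must be positive")


def compute_fcal(ref: ReferenceMeasurement) -> CalibrationFactor:
    """F_cal = D_tps[Gy/MU] / D_mc[Gy/particle]; the MU_ref cancels."""
    d_tps_gy_per_mu = ref.d_tps_cgy_per_mu * 0.01
    value = d_tps_gy_per_mu / ref.d_mc_gy_per_particle
    return CalibrationFactor(value=value, energy=ref.energy,
                             provenance=f"10x10 field, 100 cm SSD, water cube, "
                                        f"d=10 cm, MU_ref={ref.mu_ref}")


def apply_calibration(result: DoseResult, fcal: CalibrationFactor, mu: float,
                      energy: str | None = None) -> np.ndarray:
    """Scale Gy/particle to Gy: dose * F_cal * MU (relative errors unchanged)."""
    label = energy if energy is not None else getattr(result, "energy", None)
    if label is not None and label != fcal.energy:
        raise ValueError(f"energy mismatch: result {label} vs factor {fcal.energy}")
    if mu < 0:
        raise ValueError("MU must be non-negative")
    return result.dose * fcal.value * mu


@dataclass
class ReferenceSetup:
    phantom: VoxelPhantom
    plan: VMATPlan
    point_mm: np.ndarray  # central-axis scoring point, patient mm
    energy: str


def reference_setup(energy: str = "6X", mu_ref: float = 100.0,
                    spacing_mm: float = 5.0) -> ReferenceSetup:
    """Water cube + static open 10x10 field at 100 cm SSD.

    The phantom surface sits at the isocenter plane (y = 0, gantry 0) so
    the 10 cm depth scoring point is at patient (0, 100, 0) mm.
    """
    phantom = water_phantom(side_mm=400.0, spacing_mm=spacing_mm)
    jaws = (-50.0, 50.0, -50.0, 50.0)
    boundaries = np.array([-200.0, 200.0])
    mlc = np.array([[-200.0], [200.0]])
    cps = [
        ControlPoint(gantry_deg=0.0, jaws=jaws, mlc=mlc, cum_weight=0.0),
        ControlPoint(gantry_deg=0.0, jaws=jaws, mlc=mlc, cum_weight=1.0),
    ]
    beam = ArcBeam(energy=energy, beam_mu=mu_ref, control_points=cps,
                   leaf_boundaries=boundaries, name="reference", is_arc=False)
    plan = VMATPlan(beams=[beam], label="reference-10x10")
    return ReferenceSetup(phantom=phantom, plan=plan,
                          point_mm=np.array([0.0, 100.0, 0.0]), energy=energy)


def calibrate_energy(energy: str, histories: int = 200_000, seed: int = 0,
                     d_tps_cgy_per_mu: float | None = None,
                     n_jobs: int = 4, spacing_mm: float = 5.0
                     ) -> tuple[CalibrationFactor, DoseResult, ReferenceSetup]:
    """Run the reference condition and derive the energy's calibration factor."""
    setup = reference_setup(energy=energy, spacing_mm=spacing_mm)
    source = default_source(energy)
    result = simulate_arc(setup.phantom, source, setup.plan.beams[0],
                          histories=histories, n_jobs=n_jobs, base_seed=seed)
    result.energy = energy  # type: ignore[attr-defined]
    d_mc = float(trilinear(result.dose, result.geometry, setup.point_mm))
    if d_mc <= 0:
        raise RuntimeError("reference run scored zero dose at the reference point")
    d_tps = d_tps_cgy_per_mu or DEFAULT_REFERENCE_OUTPUT_CGY_PER_MU[energy]
    ref = ReferenceMeasurement(d_tps_cgy_per_mu=d_tps,
                               mu_ref=setup.plan.beams[0].beam_mu,
                               d_mc_gy_per_particle=d_mc, energy=energy)
    return compute_fcal(ref), result, setup


class CalibrationRegistry:
    """One calibration factor per energy label; duplicates are rejected."""

    def __init__(self) -> None:
        self._factors: dict[str, CalibrationFactor] = {}

    def register(self, fcal: CalibrationFactor) -> None:
        if fcal.energy in self._factors:
            raise ValueError(f"energy {fcal.energy} already registered")
        self._factors[fcal.energy] = fcal

    def __getitem__(self, energy: str) -> CalibrationFactor:
        return self._factors[energy]

    def __contains__(self, energy: str) -> bool:
        return energy in self._factors

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# energy\tfcal_particles_per_mu\tprovenance\n")
            for label in sorted(self._factors):
                f = self._factors[label]
                fh.write(f"{label}\t{f.value:.10e}\t{f.provenance}\n")

    @classmethod
    def load(cls, path) -> "CalibrationRegistry":
        reg = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            label, value, provenance = line.split("\t", 2)
            reg.register(CalibrationFactor(value=float(value), energy=label,
                                           provenance=provenance))
        return reg
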