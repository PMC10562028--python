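"""Photon interaction data for the four phantom materials.

Packaged, self-contained coefficient tables over 0.01-12 MeV built from
closed forms: Klein-Nishina for incoherent scattering (exact, per
electron), a power-law photoelectric term anchored to water at 10 keV, and
a linear-above-threshold pair term.  These replace external physics data
files; at therapy energies the Compton term dominates and is exact, e.g.
mu/rho(water, 1 MeV) = 0.0707 cm^2/g.

Mass energy-transfer coefficients use the Klein-Nishina energy-transfer
cross section for Compton, the full photon energy for photoelectric
absorption, and the above-threshold excess for pair production.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

R_E_CM = 2.8179403262e-13  # classical electron radius, cm
ME_C2_MEV = 0.51099895  # electron rest energy, MeV
N_AVOGADRO = 6.02214076e23

ENERGY_MIN_MEV = 0.01
ENERGY_MAX_MEV = 12.0
ENERGY_CUTOFF_MEV = 0.01  # photons below this are locally absorbed
PAIR_THRESHOLD_MEV = 2 * ME_C2_MEV


@dataclass(frozen=True)
class MaterialSpec:
    name: str
    z_over_a: float  # mean Z/A (electrons per nucleon)
    z_eff: float  # effective atomic number


MATERIALS = (
    MaterialSpec("Air", 0.49919, 7.64),
    MaterialSpec("Lung", 0.55509, 7.42),
    MaterialSpec("Tissue", 0.55509, 7.42),
    MaterialSpec("Bone", 0.51478, 12.31),
)

_WATER_PE_10KEV = 4.944  # cm^2/g, anchor for the photoelectric power law
_WATER_PAIR_SLOPE = 5.6e-4  # cm^2/g per MeV above threshold
_PE_Z_EXPONENT = 3.8


def kn_total_per_electron(energy_mev: np.ndarray) -> np.ndarray:
    """Klein-Nishina total cross section per electron, cm^2 (exact)."""
    a = np.asarray(energy_mev, dtype=float) / ME_C2_MEV
    t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - np.log(1 + 2 * a) / a)
    t2 = np.log(1 + 2 * a) / (2 * a)
    t3 = (1 + 3 * a) / (1 + 2 * a) ** 2
    return 2 * np.pi * R_E_CM**2 * (t1 + t2 - t3)


def kn_scatter_per_electron(energy_mev: np.ndarray) -> np.ndarray:
    """Klein-Nishina scattered-photon-energy cross section, cm^2 (exact)."""
    a = np.asarray(energy_mev, dtype=float) / ME_C2_MEV
    t1 = np.log(1 + 2 * a) / a**3
    t2 = 2 * (1 + a) * (2 * a**2 - 2 * a - 1) / (a**2 * (1 + 2 * a) ** 2)
    t3 = 8 * a**2 / (3 * (1 + 2 * a) ** 3)
    return np.pi * R_E_CM**2 * (t1 + t2 + t3)


def _compton_mu_rho(spec: MaterialSpec, energy: np.ndarray) -> np.ndarray:
    return kn_total_per_electron(energy) * N_AVOGADRO * spec.z_over_a


def _pe_mu_rho(spec: MaterialSpec, energy: np.ndarray) -> np.ndarray:
    water = MATERIALS[2]
    scale = (spec.z_eff / water.z_eff) ** _PE_Z_EXPONENT * (spec.z_over_a / water.z_over_a)
    return _WATER_PE_10KEV * scale * (0.01 / np.asarray(energy, dtype=float)) ** 3


def _pair_mu_rho(spec: MaterialSpec, energy: np.ndarray) -> np.ndarray:
    water = MATERIALS[2]
    scale = (spec.z_eff / water.z_eff) * (spec.z_over_a / water.z_over_a)
    excess = np.clip(np.asarray(energy, dtype=float) - PAIR_THRESHOLD_MEV, 0.0, None)
    return _WATER_PAIR_SLOPE * scale * excess


class CrossSectionTable:
    """Log-spaced per-material attenuation tables with log-E interpolation.

    Arrays are indexed ``[material, energy]`` in the order of
    :data:`MATERIALS`.  ``total`` is exactly the sum of the partials.
    """

    def __init__(self, n_energies: int = 160):
        self.energies = np.geomspace(ENERGY_MIN_MEV, ENERGY_MAX_MEV, n_energies)
        self._log_e = np.log(self.energies)
        n_mat = len(MATERIALS)
        self.photoelectric = np.empty((n_mat, n_energies))
        self.compton = np.empty((n_mat, n_energies))
        self.pair = np.empty((n_mat, n_energies))
        self.mu_tr = np.empty((n_mat, n_energies))
        kn_tot = kn_total_per_electron(self.energies)
        kn_sc = kn_scatter_per_electron(self.energies)
        transfer_fraction = 1.0 - kn_sc / kn_tot
        for m, spec in enumerate(MATERIALS):
            pe = _pe_mu_rho(spec, self.energies)
            co = _compton_mu_rho(spec, self.energies)
            pp = _pair_mu_rho(spec, self.energies)
            self.photoelectric[m] = pe
            self.compton[m] = co
            self.pair[m] = pp
            self.mu_tr[m] = (
                pe
                + co * transfer_fraction
                + pp * np.divide(self.energies - PAIR_THRESHOLD_MEV, self.energies,
                                 out=np.zeros_like(self.energies),
                                 where=self.energies > PAIR_THRESHOLD_MEV)
            )
        self.total = self.photoelectric + self.compton + self.pair
        self.material_names = tuple(m.name for m in MATERIALS)

    def _interp(self, table: np.ndarray, material: np.ndarray, energy: np.ndarray) -> np.ndarray:
        e = np.clip(np.asarray(energy, dtype=float), ENERGY_MIN_MEV, ENERGY_MAX_MEV)
        loge = np.log(e)
        mat = np.asarray(material)
        if mat.ndim == 0:
            return np.interp(loge, self._log_e, table[int(mat)])
        out = np.empty(loge.shape, dtype=float)
        for m in range(len(MATERIALS)):
            sel = mat == m
            if np.any(sel):
                out[sel] = np.interp(loge[sel], self._log_e, table[m])
        return out

    def mu_rho(self, material, energy, kind: str = "total") -> np.ndarray:
        """Mass attenuation coefficient, cm^2/g, for the requested process."""
        table = {"total": self.total, "photoelectric": self.photoelectric,
                 "compton": self.compton, "pair": self.pair,
                 "mu_tr": self.mu_tr}[kind]
        return self._interp(table, material, energy)

    def partial_fractions(self, material, energy) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(photoelectric, compton, pair) fractions of the total at energy."""
        pe = self._interp(self.photoelectric, material, energy)
        co = self._interp(self.compton, material, energy)
        pp = self._interp(self.pair, material, energy)
        tot = pe + co + pp
        return pe / tot, co / tot, pp / tot

    def transfer_fraction(self, material, energy) -> np.ndarray:
        """mu_tr / mu_total at the given energy."""
        return self._interp(self.mu_tr, material, energy) / self._interp(
            self.total, material, energy
        )


_DEFAULT_TABLE: CrossSectionTable | None = None


def default_table() -> CrossSectionTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = CrossSectionTable()
    return _DEFAULT_TABLE


# ---------------------------------------------------------------------------
# Klein-Nishina sampling
# ---------------------------------------------------------------------------

def sample_compton_batch(energy_mev: np.ndarray, rng: np.random.Generator):
    """Sample scattered energies and polar cosines from Klein-Nishina.

    Kahn-style composition-rejection on epsilon = E'/E.  Returns
    ``(E_prime, cos_theta)`` arrays matching the input shape.
    """
    e = np.asarray(energy_mev, dtype=float)
    a = e / ME_C2_MEV
    eps0 = 1.0 / (1.0 + 2.0 * a)
    a1 = -np.log(eps0)
    a2 = 0.5 * (1.0 - eps0**2)
    n = e.size
    eps = np.empty(n)
    cos_t = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        u1 = rng.random(todo.size)
        u2 = rng.random(todo.size)
        u3 = rng.random(todo.size)
        e0 = eps0[todo]
        pick_log = u1 < a1[todo] / (a1[todo] + a2[todo])
        cand = np.where(pick_log,
                        e0 * np.exp(a1[todo] * u2),
                        np.sqrt(e0**2 + (1.0 - e0**2) * u2))
        t = (1.0 - cand) / (a[todo] * cand)
        sin2 = np.clip(t * (2.0 - t), 0.0, 1.0)
        accept = u3 <= 1.0 - cand * sin2 / (1.0 + cand**2)
        done = todo[accept]
        eps[done] = cand[accept]
        cos_t[done] = 1.0 - t[accept]
        todo = todo[~accept]
    return e * eps, cos_t


def sample_compton(energy_mev: float, rng: np.random.Generator) -> tuple[float, float]:
    """Single Klein-Nishina draw: (scattered energy MeV, polar angle rad)."""
    if energy_mev <= 0:
        raise ValueError("energy must be positive")
    e_prime, cos_t = sample_compton_batch(np.array([energy_mev]), rng)
    return float(e_prime[0]), float(np.arccos(np.clip(cos_t[0], -1.0, 1.0)))


def compton_energy_at_angle(energy_mev: float, theta: float) -> float:
    """Closed-form scattered photon energy at polar angle theta."""
    a = energy_mev / ME_C2_MEV
    return energy_mev / (1.0 + a * (1.0 - np.cos(theta)))
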