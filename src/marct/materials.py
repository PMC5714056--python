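"""Material definitions, energy-dependent attenuation and HU conversions.

The package ships a small attenuation table (text fixture under
``marct/data``) holding mass attenuation and mass energy-absorption
coefficients for the phantom materials on a 24-point log energy grid from
20 keV to 2 MeV.  Linear attenuation is obtained by log-log interpolation
between grid nodes; Hounsfield units follow the scanner convention
HU = 1000 (mu - mu_w) / mu_w clamped to the fixed reconstruction range
[-1024, 3071].
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0

#: element symbol -> (Z, A) for electron-density arithmetic
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Mg": (12, 24.305), "Al": (13, 26.982), "P": (15, 30.974),
    "S": (16, 32.06), "Cl": (17, 35.45), "Ar": (18, 39.948),
    "Ca": (20, 40.078), "Ti": (22, 47.867), "Cd": (48, 112.414),
    "Sn": (50, 118.710), "Pb": (82, 207.2), "Bi": (83, 208.980),
}

_WATER_COMPOSITION = (("H", 0.1119), ("O", 0.8881))


def _electrons_per_gram(composition) -> float:
    total = 0.0
    for symbol, fraction in composition:
        if symbol not in ELEMENTS:
            known = ", ".join(sorted(ELEMENTS))
            raise KeyError(f"unknown element {symbol!r}; known elements: {known}")
        z, a = ELEMENTS[symbol]
        total += fraction * z / a
    return total


@dataclass(frozen=True)
class Material:
    """A physical material: name, bulk density and elemental composition."""

    name: str
    mass_density: float  # g/cm^3
    composition: tuple[tuple[str, float], ...]  # (element, mass fraction)

    def __post_init__(self):
        if self.mass_density <= 0:
            raise ValueError(f"mass_density must be > 0, got {self.mass_density}")
        total = sum(w for _, w in self.composition)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"mass fractions of {self.name!r} sum to {total}, expected 1")

    @property
    def relative_electron_density(self) -> float:
        """Electrons per unit volume relative to water."""
        return electron_density(self)


@dataclass(frozen=True)
class Spectrum:
    """Discrete polychromatic x-ray spectrum with normalized fluence weights."""

    kvp: float
    energies_kev: np.ndarray
    weights: np.ndarray
    reference_energy_kev: float  # effective energy used for HU reconstruction

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("spectrum weights must be >= 0 and sum to 1")
        if np.max(self.energies_kev) > self.kvp:
            raise ValueError("spectrum energies exceed the tube potential")

    def monochromatic(self, energy_kev: float | None = None) -> "Spectrum":
        """Single-bin spectrum at ``energy_kev`` (default: reference energy)."""
        e = self.reference_energy_kev if energy_kev is None else energy_kev
        return Spectrum(self.kvp, np.array([e]), np.array([1.0]), e)


class AttenuationTable:
    """Energy-dependent mass attenuation data for a fixed set of materials.

    Parameters
    ----------
    energies_kev:
        Strictly increasing energy grid covering at least [20, 2000] keV.
    materials:
        Mapping of name -> :class:`Material`.
    mu_over_rho, muen_over_rho:
        Mapping of name -> array of mass (energy-absorption) attenuation
        coefficients in cm^2/g aligned with ``energies_kev``.
    """

    def __init__(self, energies_kev, materials, mu_over_rho, muen_over_rho):
        self.energies_kev = np.asarray(energies_kev, dtype=float)
        if np.any(np.diff(self.energies_kev) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        self.materials: dict[str, Material] = dict(materials)
        self.mu_over_rho = {k: np.asarray(v, float) for k, v in mu_over_rho.items()}
        self.muen_over_rho = {k: np.asarray(v, float) for k, v in muen_over_rho.items()}
        for table in (self.mu_over_rho, self.muen_over_rho):
            for name, values in table.items():
                if values.shape != self.energies_kev.shape or np.any(values <= 0):
                    raise ValueError(f"bad attenuation row for {name!r}")

    def material(self, name: str) -> Material:
        try:
            return self.materials[name]
        except KeyError:
            known = ", ".join(sorted(self.materials))
            raise KeyError(f"unknown material {name!r}; known: {known}") from None

    def mass_attenuation(self, name: str, energy_kev) -> np.ndarray | float:
        return self._interp(self.mu_over_rho[name], energy_kev)

    def mass_energy_absorption(self, name: str, energy_kev) -> np.ndarray | float:
        return self._interp(self.muen_over_rho[name], energy_kev)

    def _interp(self, row: np.ndarray, energy_kev):
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.energies_kev[0], self.energies_kev[-1]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy {energy_kev} keV outside table range [{lo}, {hi}] keV")
        out = np.exp(np.interp(np.log(e), np.log(self.energies_kev), np.log(row)))
        return float(out) if np.isscalar(energy_kev) else out


def linear_attenuation(material: Material | str, energy_kev,
                       table: AttenuationTable) -> float | np.ndarray:
    """Linear attenuation coefficient mu in 1/cm at ``energy_kev``.

    ``material`` may be a name from the table or a :class:`Material` whose
    name is in the table (its own density is then used, so a doubled-density
    variant yields exactly twice the coefficient).
    """
    if isinstance(material, str):
        material = table.material(material)
    return table.mass_attenuation(material.name, energy_kev) * material.mass_density


def hu_from_mu(mu_image, mu_water: float, clamp: bool = True):
    """Convert a mu map (1/cm) to Hounsfield units, clamped to [-1024, 3071].

    ``clamp=False`` gives the raw scale (used internally where the saturated
    scanner range would hide structure, e.g. metal segmentation refinement).
    """
    if mu_water <= 0:
        raise ValueError("mu_water must be > 0")
    mu = np.asarray(mu_image, dtype=float)
    if not np.all(np.isfinite(mu)):
        raise ValueError("non-finite attenuation values in image")
    hu = 1000.0 * (mu - mu_water) / mu_water
    return np.clip(hu, HU_MIN, HU_MAX) if clamp else hu


def mu_from_hu(hu_image, mu_water: float):
    """Inverse of :func:`hu_from_mu` on the unclamped interval."""
    hu = np.asarray(hu_image, dtype=float)
    return mu_water * (1.0 + hu / 1000.0)


def electron_density(material: Material) -> float:
    """Electron density relative to water: rho * sum(w_i Z_i/A_i) / (same, water)."""
    water = _electrons_per_gram(_WATER_COMPOSITION) * 1.0
    return material.mass_density * _electrons_per_gram(material.composition) / water


# ---------------------------------------------------------------------------
# Packaged fixture parsing


def _data_text(filename: str) -> str:
    return (importlib.resources.files("marct") / "data" / filename).read_text()


def _parse_blocks(text: str):
    """Split the key-value + tabular fixture format into (header, lines) blocks."""
    blocks, header, lines = [], None, []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            if header is not None:
                blocks.append((header, lines))
            header, lines = line.strip("[]"), []
        else:
            lines.append(line)
    if header is not None:
        blocks.append((header, lines))
    return blocks


def load_attenuation_table(text: str | None = None) -> AttenuationTable:
    """Load the packaged attenuation table (or parse ``text`` if given)."""
    if text is None:
        text = _data_text("attenuation.txt")
    energies = None
    materials, mu, muen = {}, {}, {}
    for header, lines in _parse_blocks(text):
        fields = {ln.split(maxsplit=1)[0]: ln.split(maxsplit=1)[1] for ln in lines}
        if header == "energies_keV":
            energies = np.array(lines[0].split(), dtype=float)
        elif header.startswith("material "):
            name = header.split(maxsplit=1)[1]
            tokens = fields["composition"].split()
            comp = tuple((tokens[i], float(tokens[i + 1]))
                         for i in range(0, len(tokens), 2))
            materials[name] = Material(name, float(fields["density"]), comp)
            mu[name] = np.array(fields["mu_over_rho"].split(), dtype=float)
            muen[name] = np.array(fields["muen_over_rho"].split(), dtype=float)
        else:
            raise ValueError(f"unknown block {header!r} in attenuation table")
    if energies is None:
        raise ValueError("attenuation table has no [energies_keV] block")
    return AttenuationTable(energies, materials, mu, muen)


def load_spectrum(text: str | None = None) -> Spectrum:
    """Load the packaged 140 kVp spectrum (or parse ``text`` if given)."""
    if text is None:
        text = _data_text("spectrum_140kvp.txt")
    (header, lines), = _parse_blocks(text)
    if header != "spectrum":
        raise ValueError("expected a single [spectrum] block")
    fields = {ln.split(maxsplit=1)[0]: ln.split(maxsplit=1)[1] for ln in lines}
    return Spectrum(
        kvp=float(fields["kvp"]),
        energies_kev=np.array(fields["energies_keV"].split(), dtype=float),
        weights=np.array(fields["weights"].split(), dtype=float),
        reference_energy_kev=float(fields["reference_energy_keV"]),
    )
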