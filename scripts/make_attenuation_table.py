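"""Generate the packaged attenuation table and 140 kVp spectrum fixtures.

The runtime package only ever reads the two text files this script writes
(``src/marct/data/attenuation.txt`` and ``src/marct/data/spectrum_140kvp.txt``).
Cross sections come from a two-term model adequate for artifact genesis:

* Compton: Klein-Nishina, integrated numerically per electron (total and
  energy-transfer cross sections).
* Photoelectric: tau/rho = C * Z^3.4 / (A * E_keV^3.1) cm^2/g per element,
  with C calibrated so water totals 0.3756 cm^2/g at 30 keV.

No K-edges, coherent scattering or pair production are modelled.  The 140 kVp
spectrum is a Kramers bremsstrahlung shape filtered by 12 mm Al (a clinical
scanner's inherent + bowtie filtration is ~8-12 mm Al equivalent on axis),
binned into twelve 10 keV bins; its effective energy through 16 cm of water is
stored with the spectrum and used as the reconstruction reference energy.
"""

from __future__ import annotations

import pathlib

import numpy as np
from scipy.integrate import quad

R_E = 2.8179403262e-13  # classical electron radius, cm
N_A = 6.02214076e23
MEC2_KEV = 510.99895

ELEMENTS = {
    # symbol: (Z, A)
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Mg": (12, 24.305), "Al": (13, 26.982), "P": (15, 30.974),
    "S": (16, 32.06), "Cl": (17, 35.45), "Ar": (18, 39.948),
    "Ca": (20, 40.078), "Ti": (22, 47.867), "Cd": (48, 112.414),
    "Sn": (50, 118.710), "Pb": (82, 207.2), "Bi": (83, 208.980),
}

MATERIALS = {
    # name: (density g/cm3, {element: mass fraction})
    "air": (0.00120, {"N": 0.7552, "O": 0.2320, "Ar": 0.0128}),
    "water": (1.000, {"H": 0.1119, "O": 0.8881}),
    "solid_water": (1.004, {"H": 0.0809, "C": 0.6722, "N": 0.0240,
                            "O": 0.1984, "Cl": 0.0013, "Ca": 0.0232}),
    "lung_ln300": (0.300, {"H": 0.0809, "C": 0.6722, "N": 0.0240,
                           "O": 0.1984, "Cl": 0.0013, "Ca": 0.0232}),
    "adipose": (0.920, {"H": 0.1000, "C": 0.7120, "N": 0.0180,
                        "O": 0.1690, "Cl": 0.0010}),
    "liver": (1.096, {"H": 0.0810, "C": 0.6670, "N": 0.0250,
                      "O": 0.2020, "Cl": 0.0020, "Ca": 0.0230}),
    "inner_bone": (1.147, {"H": 0.0687, "C": 0.5305, "N": 0.0212,
                           "O": 0.2562, "P": 0.0324, "Ca": 0.0910}),
    "cortical_bone": (1.819, {"H": 0.0341, "C": 0.3141, "N": 0.0184,
                              "O": 0.3653, "Cl": 0.0004, "Ca": 0.2677}),
    "titanium": (4.540, {"Ti": 1.0}),
    "cerrobend": (9.760, {"Bi": 0.500, "Pb": 0.267, "Sn": 0.133, "Cd": 0.100}),
}

ENERGY_GRID_KEV = np.round(np.geomspace(20.0, 2000.0, 24), 2)


def kn_cross_sections(e_kev: float) -> tuple[float, float]:
    """Klein-Nishina total and energy-transfer cross sections per electron (cm^2)."""
    alpha = e_kev / MEC2_KEV

    def dsigma_domega(theta):
        ratio = 1.0 / (1.0 + alpha * (1.0 - np.cos(theta)))
        return (0.5 * R_E**2 * ratio**2
                * (ratio + 1.0 / ratio - np.sin(theta) ** 2))

    def total_integrand(theta):
        return dsigma_domega(theta) * 2.0 * np.pi * np.sin(theta)

    def transfer_integrand(theta):
        ratio = 1.0 / (1.0 + alpha * (1.0 - np.cos(theta)))
        frac_to_electron = 1.0 - ratio
        return total_integrand(theta) * frac_to_electron

    sigma, _ = quad(total_integrand, 0.0, np.pi, limit=200)
    sigma_tr, _ = quad(transfer_integrand, 0.0, np.pi, limit=200)
    return sigma, sigma_tr


def photoelectric_constant() -> float:
    """Calibrate C so that water's total mu/rho at 30 keV equals 0.3756 cm^2/g."""
    sigma, _ = kn_cross_sections(30.0)
    compton = sum(
        w * N_A * ELEMENTS[el][0] / ELEMENTS[el][1] * sigma
        for el, w in MATERIALS["water"][1].items()
    )
    pe_target = 0.3756 - compton
    pe_unit = sum(
        w * ELEMENTS[el][0] ** 3.4 / ELEMENTS[el][1] / 30.0**3.1
        for el, w in MATERIALS["water"][1].items()
    )
    return pe_target / pe_unit


def mass_coefficients(comp: dict[str, float], c_pe: float):
    """mu/rho and muen/rho (cm^2/g) on ENERGY_GRID_KEV for a composition."""
    mu, muen = [], []
    for e in ENERGY_GRID_KEV:
        sigma, sigma_tr = kn_cross_sections(float(e))
        compton = sum(w * N_A * ELEMENTS[el][0] / ELEMENTS[el][1] * sigma
                      for el, w in comp.items())
        compton_tr = sum(w * N_A * ELEMENTS[el][0] / ELEMENTS[el][1] * sigma_tr
                         for el, w in comp.items())
        pe = sum(w * c_pe * ELEMENTS[el][0] ** 3.4 / ELEMENTS[el][1] / e**3.1
                 for el, w in comp.items())
        mu.append(compton + pe)
        muen.append(compton_tr + pe)  # photoelectric: full local transfer
    return np.array(mu), np.array(muen)


def loglog_mu(energy, grid, mu):
    return float(np.exp(np.interp(np.log(energy), np.log(grid), np.log(mu))))


def make_spectrum(c_pe: float):
    """12-bin filtered-Kramers 140 kVp spectrum + effective energy through 16 cm water."""
    centers = np.arange(25.0, 140.0, 10.0)  # 25..135, 12 bins of 10 keV
    mu_al, _ = mass_coefficients({"Al": 1.0}, c_pe)
    mu_al_c = np.array([loglog_mu(e, ENERGY_GRID_KEV, mu_al) for e in centers])
    weights = (140.0 - centers) / centers * np.exp(-mu_al_c * 2.70 * 1.2)
    weights /= weights.sum()

    mu_w, _ = mass_coefficients(MATERIALS["water"][1], c_pe)
    mu_w_c = np.array([loglog_mu(e, ENERGY_GRID_KEV, mu_w) for e in centers])
    trans = float(np.sum(weights * np.exp(-mu_w_c * 16.0)))
    mu_equiv = -np.log(trans) / 16.0
    fine = np.linspace(30.0, 139.0, 2000)
    mu_fine = np.exp(np.interp(np.log(fine), np.log(ENERGY_GRID_KEV), np.log(mu_w)))
    e_ref = float(fine[np.argmin(np.abs(mu_fine - mu_equiv))])
    return centers, weights, round(e_ref, 1)


def calibrate_solid_water(c_pe: float, e_ref: float) -> None:
    """Trade C vs Ca in the solid-water surrogate until its mass attenuation
    matches water at the reference energy (the vendor does the same with
    CaCO3 loading to make the plastic water-equivalent)."""
    base = dict(MATERIALS["solid_water"][1])
    c_plus_ca = base["C"] + base["Ca"]
    mu_w, _ = mass_coefficients(MATERIALS["water"][1], c_pe)
    target = loglog_mu(e_ref, ENERGY_GRID_KEV, mu_w)

    lo, hi = 0.0, 0.20
    for _ in range(60):
        ca = 0.5 * (lo + hi)
        comp = {**base, "C": c_plus_ca - ca, "Ca": ca}
        mu, _ = mass_coefficients(comp, c_pe)
        if loglog_mu(e_ref, ENERGY_GRID_KEV, mu) < target:
            lo = ca
        else:
            hi = ca
    ca = round(0.5 * (lo + hi), 4)
    comp = {**base, "C": round(c_plus_ca - ca, 4), "Ca": ca}
    rho_sw = MATERIALS["solid_water"][0]
    MATERIALS["solid_water"] = (rho_sw, comp)
    MATERIALS["lung_ln300"] = (MATERIALS["lung_ln300"][0], comp)


def main() -> None:
    out_dir = pathlib.Path(__file__).resolve().parents[1] / "src" / "marct" / "data"
    out_dir.mkdir(parents=True, exist_ok=True)
    c_pe = photoelectric_constant()
    _, _, e_ref_pre = make_spectrum(c_pe)
    calibrate_solid_water(c_pe, e_ref_pre)

    lines = ["# marct attenuation table (generated by scripts/make_attenuation_table.py)",
             "# mu_over_rho and muen_over_rho in cm^2/g on the shared energy grid",
             "[energies_keV]",
             " ".join(f"{e:.2f}" for e in ENERGY_GRID_KEV)]
    for name, (rho, comp) in MATERIALS.items():
        mu, muen = mass_coefficients(comp, c_pe)
        lines.append(f"[material {name}]")
        lines.append(f"density {rho}")
        lines.append("composition " + " ".join(f"{el} {w}" for el, w in comp.items()))
        lines.append("mu_over_rho " + " ".join(f"{v:.6e}" for v in mu))
        lines.append("muen_over_rho " + " ".join(f"{v:.6e}" for v in muen))
    (out_dir / "attenuation.txt").write_text("\n".join(lines) + "\n")

    centers, weights, e_ref = make_spectrum(c_pe)
    spec_lines = ["# marct 140 kVp spectrum (generated by scripts/make_attenuation_table.py)",
                  "[spectrum]",
                  "kvp 140",
                  f"reference_energy_keV {e_ref}",
                  "energies_keV " + " ".join(f"{e:.1f}" for e in centers),
                  "weights " + " ".join(f"{w:.6e}" for w in weights)]
    (out_dir / "spectrum_140kvp.txt").write_text("\n".join(spec_lines) + "\n")
    print(f"wrote tables; PE constant C = {c_pe:.4f}, reference energy = {e_ref} keV")


if __name__ == "__main__":
    main()
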