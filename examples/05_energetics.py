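"""Vaporization and fusion energetics from thermodynamic series.

Computes the molar vaporization energy/enthalpy of a model liquid from a
liquid-box potential-energy series and a single-molecule (ideal-vapor)
reference, plus a fusion enthalpy from two-phase enthalpy series.
"""

import numpy as np

from glassmd import fusion_enthalpy, specific_energy, vaporization_energy
from glassmd.trajectory_io import ThermoSeries

rng = np.random.default_rng(3)
n_molecules = 600
T = 410.0

# liquid box: cohesive potential energy ~ -104 kJ/mol per molecule
liquid = ThermoSeries(
    time=np.arange(5000.0),
    potential_energy=n_molecules * (-104.8 + rng.normal(0, 0.4, 5000)))
# isolated molecule: intramolecular energy only (zero of energy)
gas = ThermoSeries(time=np.arange(5000.0),
                   potential_energy=rng.normal(0, 0.3, 5000))

vap = vaporization_energy(liquid, gas, n_molecules, temperature=T)
print(f"U_vap  = {vap.U_vap:7.2f} +/- {vap.U_vap_sd:.2f} kJ/mol")
print(f"dH_vap = {vap.H_vap:7.2f} +/- {vap.H_vap_sd:.2f} kJ/mol "
      f"(= U_vap + RT, RT = {vap.H_vap - vap.U_vap:.2f})")
print(f"specific cohesion = {specific_energy(vap.U_vap, 230.26):.3f} kJ/g "
      f"(molar mass 230.26 g/mol)")

crystal = ThermoSeries(time=np.arange(2000.0), temperature=np.full(2000, 293.0),
                       enthalpy=n_molecules * (-142.0 + rng.normal(0, 0.3, 2000)))
melt = ThermoSeries(time=np.arange(2000.0), temperature=np.full(2000, 293.0),
                    enthalpy=n_molecules * (-113.0 + rng.normal(0, 0.5, 2000)))
fus = fusion_enthalpy(crystal, melt, n_molecules, n_molecules, 293.0)
print(f"dH_fus = {fus.H_fus:7.2f} kJ/mol (liquid minus crystal)")
# dH_vap - U_vap equals RT exactly under the ideal-vapor assumption; the
# specific (per-mass) cohesion lets molecules of different size be
# compared as glass-stabilizing excipient candidates.
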