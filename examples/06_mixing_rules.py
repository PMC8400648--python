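"""Empirical mixture-Tg rules for drug-excipient compositions.

Applies the Gordon-Taylor equation (with its constant from the
Simha-Boyer density form), the Fox equation and the fusion-temperature
bracket to a drug/excipient pair, across molar compositions.
"""

from glassmd import (MixtureSpec, fox, gordon_taylor, k_simha_boyer,
                     mole_to_mass_fraction, tf_rule)

# drug: Tg 315 K, rho 1.33 g/cm3, M 236 g/mol, Tf 465 K
# excipient (nucleobase-like): Tg 430 K, rho 1.50 g/cm3, M 135 g/mol
tg1, rho1, m1, tf1 = 315.0, 1.33, 236.0, 465.0
tg2, rho2, m2 = 430.0, 1.50, 135.0

k = k_simha_boyer(rho1, tg1, rho2, tg2)
print(f"Gordon-Taylor constant (Simha-Boyer): K = {k:.3f}")
print(f"pure-drug Tg bracket from Tf: {tf_rule(tf1)[0]:.0f}-"
      f"{tf_rule(tf1)[1]:.0f} K (0.6-0.8 Tf)\n")

print(" molar ratio   w_excipient   Gordon-Taylor   Fox")
for label, x2 in (("3:1", 0.25), ("1:1", 0.50), ("1:3", 0.75)):
    w2 = mole_to_mass_fraction([1 - x2, x2], [m1, m2])[1]
    gt = gordon_taylor(tg1, tg2, w2, k)
    fx = fox(tg1, tg2, w2)
    print(f"  {label:9s}   {w2:8.3f}      {gt:7.1f} K    {fx:6.1f} K")

mix = MixtureSpec(components=("drug", "excipient"), x=[0.5, 0.5],
                  molar_mass=[m1, m2], tg=[tg1, tg2], rho=[rho1, rho2])
print(f"\nequimolar mean molar mass: {mix.mean_molar_mass:.1f} g/mol")
# Both rules interpolate between the pure-component Tg; a high-Tg
# excipient raises the mixture Tg monotonically with its mass fraction,
# which is the design lever for stabilizing amorphous drug dispersions.
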