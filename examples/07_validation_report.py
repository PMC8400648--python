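"""Recompute the validation statistics from the bundled benchmark tables.

Loads the packaged reference tables (densities, fusion enthalpies, glass
transition temperatures, vaporization enthalpies), recomputes every
per-row percent deviation and the summary statistics from the raw value
columns, and prints the full report, flagging any bundled row whose
printed deviation contradicts its own values.
"""

from glassmd import build_validation_report, render_report

report = build_validation_report()
print(render_report(report))
# The summary statistics (crystal/liquid density RMSE, fusion-enthalpy
# RMSE in % and kJ/mol, mean Tg deviation) are recomputed from the
# simulated/experimental value columns, never from pre-rounded deviation
# columns -- rounding first would bias the aggregates.
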