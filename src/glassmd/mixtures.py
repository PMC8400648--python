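"""Composition handling and empirical glass-transition mixing rules.

Gordon-Taylor, Tg = (w1 Tg1 + K w2 Tg2) / (w1 + K w2), with the constant K
estimated from pure-component densities and Tg via the Simha-Boyer form
K = (rho1 Tg1)/(rho2 Tg2); the Fox equation, 1/Tg = w1/Tg1 + w2/Tg2; and
the fusion-temperature bracket Tg ~ (0.6-0.8) Tf, common for small-molecule
pharmaceuticals.  All rules use mass fractions, so molar compositions
(1:3, 1:1, 3:1 drug:excipient and the like) are converted explicitly.

These empirical estimates are reported alongside, never blended with,
trend-shift Tg estimates from simulation scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MixtureSpec",
    "mole_to_mass_fraction",
    "gordon_taylor",
    "k_simha_boyer",
    "fox",
    "tf_rule",
    "tg_vs_composition",
]


@dataclass
class MixtureSpec:
    """A binary (or multi-component) mixture composition with properties.

    Mole fractions ``x`` and molar masses ``M`` (g/mol) are required; mass
    fractions are derived.  Optional per-component glass-transition
    temperatures, densities and fusion temperatures feed the mixing rules.
    """

    components: Sequence[str]
    x: np.ndarray
    molar_mass: np.ndarray
    tg: np.ndarray | None = None       # K
    rho: np.ndarray | None = None      # g/cm³
    tf: np.ndarray | None = None       # K

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.molar_mass = np.asarray(self.molar_mass, dtype=float)
        if abs(self.x.sum() - 1.0) > 1e-9:
            raise ValueError("mole fractions must sum to 1")
        if np.any(self.molar_mass <= 0):
            raise ValueError("molar masses must be positive")
        for name in ("tg", "rho", "tf"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))

    @property
    def w(self) -> np.ndarray:
        """Mass fractions derived from x and M."""
        return mole_to_mass_fraction(self.x, self.molar_mass)

    @property
    def mean_molar_mass(self) -> float:
        """Mole-fraction-weighted mean molar mass, g/mol."""
        return float(self.x @ self.molar_mass)


def mole_to_mass_fraction(x: Sequence[float],
                          molar_mass: Sequence[float]) -> np.ndarray:
    """w_i = x_i M_i / sum_j x_j M_j."""
    x = np.asarray(x, dtype=float)
    m = np.asarray(molar_mass, dtype=float)
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError("mole fractions must sum to 1")
    if np.any(m <= 0):
        raise ValueError("molar masses must be positive")
    wm = x * m
    return wm / wm.sum()


def gordon_taylor(tg1: float, tg2: float, w2: float, k: float) -> float:
    """Gordon-Taylor mixture Tg; w2 is the mass fraction of component 2."""
    if not 0.0 <= w2 <= 1.0:
        raise ValueError("w2 must lie in [0, 1]")
    if k <= 0:
        raise ValueError("Gordon-Taylor constant must be positive")
    w1 = 1.0 - w2
    return (w1 * tg1 + k * w2 * tg2) / (w1 + k * w2)


def k_simha_boyer(rho1: float, tg1: float, rho2: float, tg2: float) -> float:
    """Simha-Boyer estimate of the Gordon-Taylor constant from densities."""
    vals = (rho1, tg1, rho2, tg2)
    if any(v <= 0 for v in vals):
        raise ValueError("densities and Tg must be positive")
    return (rho1 * tg1) / (rho2 * tg2)


def fox(tg1: float, tg2: float, w2: float) -> float:
    """Fox-equation mixture Tg (harmonic mean in mass fraction)."""
    if not 0.0 <= w2 <= 1.0:
        raise ValueError("w2 must lie in [0, 1]")
    return 1.0 / ((1.0 - w2) / tg1 + w2 / tg2)


def tf_rule(tf: float) -> tuple[float, float]:
    """Empirical bracket (0.6 Tf, 0.8 Tf) for the glass transition."""
    if tf <= 0:
        raise ValueError("fusion temperature must be positive")
    return 0.6 * tf, 0.8 * tf


def tg_vs_composition(entries: Sequence[tuple["MixtureSpec", float, float]],
                      excipient_index: int = 1) -> pd.DataFrame:
    """Tabulate Tg against excipient mole fraction with a trend statistic.

    ``entries`` are (mixture, Tg, Tg_sd) triples sharing one component
    pair; the result is ordered by the excipient mole fraction and carries
    a Spearman rank concordance of Tg against composition in its attrs
    (``+1`` strictly rising, ``0`` flat).
    """
    if len(entries) < 2:
        raise ValueError("need at least two compositions")
    pairs = {tuple(e[0].components) for e in entries}
    if len(pairs) > 1:
        raise ValueError(f"mixed component pairs: {sorted(pairs)}")
    rows = [{"x_excipient": float(e[0].x[excipient_index]),
             "tg": float(e[1]), "tg_sd": float(e[2])} for e in entries]
    df = pd.DataFrame(rows).sort_values("x_excipient", ignore_index=True)
    if df["tg"].nunique() == 1:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(df["x_excipient"], df["tg"]).statistic)
    df.attrs["spearman_concordance"] = rho
    return df
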