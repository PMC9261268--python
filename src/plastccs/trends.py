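"""Empirical m/z - CCS trend analysis.

For ions of similar chemistry, the collision cross-section grows with
mass roughly as a power law, CCS = a * (m/z)^b.  Halogenated molecules
sit systematically below the curve of non-halogenated ones at equal
m/z, because halogens pack more mass per unit atomic radius than C, H,
N or O.  This module fits the power law (by ordinary least squares in
log-log space, which is exact and deterministic) and quantifies the
halogen depression as the mean signed residual of halogenated points
under the non-halogenated fit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

HALOGENS = ("F", "Cl", "Br", "I")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a simple molecular formula (no parentheses) to element counts."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"unparseable molecular formula: {formula!r}")
    counts: dict[str, int] = {}
    for element, num in _FORMULA_TOKEN.findall(formula):
        if element:
            counts[element] = counts.get(element, 0) + (int(num) if num else 1)
    return counts


def is_halogenated(formula: str | None = None, smiles: str | None = None) -> bool:
    """True iff the molecule contains F, Cl, Br or I.

    Uses formula parsing when a formula is given, otherwise an element
    scan of the SMILES via RDKit.
    """
    if formula:
        counts = parse_formula(formula)
        return any(h in counts for h in HALOGENS)
    if smiles:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return any(a.GetSymbol() in HALOGENS for a in mol.GetAtoms())
    raise ValueError("provide a formula or a SMILES")


@dataclass(frozen=True)
class PowerLawFit:
    """CCS = a * (m/z)^b fitted by OLS on (ln m/z, ln CCS)."""

    a: float
    b: float
    n_points: int
    r2_loglog: float
    stratum: str = "all"

    def predict(self, mz) -> np.ndarray:
        return self.a * np.asarray(mz, dtype=float) ** self.b


def fit_power_law(mz, ccs, stratum: str = "all") -> PowerLawFit:
    """Fit the m/z - CCS power law in log-log space.

    a = exp(intercept), b = slope of the OLS line through
    (ln m/z, ln CCS); requires at least 3 strictly positive points.
    """
    mz = np.asarray(mz, dtype=float)
    ccs = np.asarray(ccs, dtype=float)
    if mz.shape != ccs.shape:
        raise ValueError("m/z and CCS vectors differ in length")
    if mz.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(mz <= 0) or np.any(ccs <= 0):
        raise ValueError("m/z and CCS must be strictly positive")
    x = np.log(mz)
    y = np.log(ccs)
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - fitted) ** 2).sum()) / sstot if sstot > 0 else 1.0
    return PowerLawFit(
        a=float(np.exp(intercept)), b=float(slope),
        n_points=int(mz.size), r2_loglog=r2, stratum=stratum,
    )


def stratified_power_law(
    mz, ccs, halogenated
) -> tuple[PowerLawFit, PowerLawFit, float]:
    """Fit the power law per halogen stratum and measure their separation.

    Returns (halogenated fit, non-halogenated fit, separation), where
    the separation statistic is the mean signed relative residual of the
    halogenated points under the NON-halogenated fit:
    mean((ccs_hal - fit_nonhal(mz_hal)) / fit_nonhal(mz_hal)).
    Negative separation means halogenated compounds sit below the
    non-halogenated trend.
    """
    mz = np.asarray(mz, dtype=float)
    ccs = np.asarray(ccs, dtype=float)
    mask = np.asarray(halogenated, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty stratum: halogenated")
    if (~mask).sum() == 0:
        raise ValueError("empty stratum: non-halogenated")
    fit_hal = fit_power_law(mz[mask], ccs[mask], stratum="halogenated")
    fit_non = fit_power_law(mz[~mask], ccs[~mask], stratum="non-halogenated")
    expected = fit_non.predict(mz[mask])
    separation = float(np.mean((ccs[mask] - expected) / expected))
    return fit_hal, fit_non, separation
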