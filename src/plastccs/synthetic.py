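"""Synthetic CCS datasets with the statistical structure of literature data.

Real multi-source CCS compilations show (i) a power-law dependence of
CCS on m/z, (ii) systematically depressed CCS for halogenated
molecules at equal m/z, (iii) a subset of compounds measured by more
than one laboratory/platform with ~1% replicate scatter, and (iv) small
systematic offsets between drift-tube and traveling-wave instruments.
The generator plants exactly these effects with known parameters so the
curation, trend, selection and modeling code can be validated against
ground truth without any external download.

Generated records carry synthetic (format-valid, chemically
meaningless) InChIKeys, simple alkane-like SMILES and formulas whose
halogen content matches the planted label.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curation import ConsolidatedCCSRecord, RawCCSRecord
from .descriptors import DescriptorMatrix
from .screening import PROTON_MASS, SODIUM_CATION_MASS

_LETTERS = string.ascii_uppercase


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate a plastic-chemicals compilation.

    ``power_a``/``power_b`` set the CCS = a*(m/z)^b backbone (defaults
    chosen so CCS spans roughly 119-332 A^2 over m/z 120-1000, the range
    literature compilations of plastic-related chemicals cover);
    ``halogen_fraction`` ~28% of compounds halogenated;
    ``halogen_depression`` a 6% multiplicative CCS deficit for them;
    ``replicate_rsd`` ~1% scatter between repeated measurements;
    ``platform_offset_pct`` mean absolute drift-tube vs traveling-wave
    offset (~1.15%); ``duplicate_fraction`` ~23% of compounds measured
    by two sources.
    """

    n_compounds: int = 1000
    mz_range: tuple = (120.0, 1000.0)
    power_a: float = 11.7
    power_b: float = 0.484
    halogen_fraction: float = 0.28
    halogen_depression: float = 0.06
    replicate_rsd: float = 1.0
    platform_offset_pct: float = 1.15
    duplicate_fraction: float = 0.23
    adduct: str = "[M+H]+"
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be at least 1")
        for name in ("halogen_fraction", "halogen_depression", "duplicate_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.power_a <= 0 or self.power_b <= 0:
            raise ValueError("power-law parameters must be positive")


def _synthetic_inchikey(index: int, rng: np.random.Generator) -> str:
    """Format-valid, unique, chemically meaningless InChIKey."""
    suffix = []
    i = index
    for _ in range(6):
        suffix.append(_LETTERS[i % 26])
        i //= 26
    first = "".join(rng.choice(list(_LETTERS), size=8)) + "".join(reversed(suffix))
    second = "".join(rng.choice(list(_LETTERS), size=10))
    return f"{first}-{second}-N"


def _synthetic_structure(mz: float, n_halogens: int) -> tuple[str, str]:
    """Toy (SMILES, formula) pair with the requested halogen count."""
    n_carbons = max(2, int(mz // 30))
    smiles = "C" * (n_carbons - 1) + "Cl" * min(n_halogens, 1)
    if n_halogens == 0:
        smiles = "C" * n_carbons
    formula = f"C{n_carbons}H{2 * n_carbons + 2 - n_halogens}"
    if n_halogens:
        formula += f"Cl{n_halogens}" if n_halogens > 1 else "Cl"
    return smiles, formula


def _cation_mass(adduct: str) -> float:
    return PROTON_MASS if adduct == "[M+H]+" else SODIUM_CATION_MASS


def generate_ccs_dataset(config: SyntheticConfig) -> list[RawCCSRecord]:
    """Generate raw CCS records with planted power-law/halogen/replicate structure.

    Each compound's true CCS is a*(m/z)^b * (1 - depression) for
    halogenated compounds; every measurement multiplies it by
    (1 + eps), eps ~ N(0, replicate_rsd/100).  A ``duplicate_fraction``
    share of compounds receives a second record from a pseudo-source on
    a drift-tube platform with an additional multiplicative offset whose
    mean magnitude is ``platform_offset_pct``.  Fully deterministic
    given the seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.mz_range
    records: list[RawCCSRecord] = []
    sigma_rep = config.replicate_rsd / 100.0
    sigma_plat = config.platform_offset_pct / 100.0 * math.sqrt(math.pi / 2.0)
    cation = _cation_mass(config.adduct)
    for i in range(config.n_compounds):
        mz = float(rng.uniform(lo, hi))
        halogenated = bool(rng.random() < config.halogen_fraction)
        n_hal = int(rng.integers(1, 4)) if halogenated else 0
        true_ccs = config.power_a * mz**config.power_b
        if halogenated:
            true_ccs *= 1.0 - config.halogen_depression
        inchikey = _synthetic_inchikey(i, rng)
        smiles, formula = _synthetic_structure(mz, n_hal)
        name = f"SYN-{i:05d}"
        duplicated = bool(rng.random() < config.duplicate_fraction)

        def _record(platform: str, source: str, factor: float) -> RawCCSRecord:
            eps = float(rng.normal(0.0, sigma_rep)) if sigma_rep > 0 else 0.0
            return RawCCSRecord(
                compound_name=name,
                inchikey=inchikey,
                smiles=smiles,
                formula=formula,
                monoisotopic_mass=mz - cation,
                adduct=config.adduct,
                ccs=true_ccs * (1.0 + eps) * factor,
                ims_platform=platform,
                source_id=source,
            )

        records.append(_record("TWIMS", "synsource_A", 1.0))
        if duplicated:
            offset = float(rng.normal(0.0, sigma_plat)) if sigma_plat > 0 else 0.0
            records.append(_record("DTIMS", "synsource_B", 1.0 + offset))
    return records


def record_mz(record: RawCCSRecord) -> float:
    """Ion m/z of a record (neutral mass plus the adduct cation mass)."""
    return record.monoisotopic_mass + _cation_mass(record.adduct)


def generate_mock_descriptors(
    records: list[RawCCSRecord | ConsolidatedCCSRecord],
    n_informative: int = 4,
    n_noise: int = 20,
    seed: int = 1,
    mz_by_key: dict[str, float] | None = None,
    halogens_by_key: dict[str, int] | None = None,
) -> DescriptorMatrix:
    """Mock descriptor table keyed by InChIKey, learnable and filter-hostile.

    Informative columns are deterministic transforms of m/z and the
    halogen count (so the planted CCS law is learnable from them); noise
    columns are i.i.d. standard normal.  One constant column and one
    exact duplicate of the first informative column are planted so the
    near-zero-variance filter and the VIF pruner have something to
    remove.
    """
    from .trends import parse_formula

    keys: list[str] = []
    mzs: list[float] = []
    hals: list[float] = []
    seen = set()
    for rec in records:
        key = rec.inchikey
        if key in seen:
            continue
        seen.add(key)
        keys.append(key)
        if isinstance(rec, RawCCSRecord):
            mzs.append(record_mz(rec))
            counts = parse_formula(rec.formula)
            hals.append(float(sum(counts.get(h, 0) for h in ("F", "Cl", "Br", "I"))))
        else:
            if mz_by_key is None or halogens_by_key is None:
                raise ValueError(
                    "consolidated records need mz_by_key and halogens_by_key maps"
                )
            mzs.append(mz_by_key[key])
            hals.append(float(halogens_by_key[key]))
    mz = np.asarray(mzs)
    hal = np.asarray(hals)
    transforms = [
        ("mz", mz),
        ("sqrt_hal_mz", np.sqrt(mz) * (1.0 + hal)),
        ("mz_pow", mz**0.5),
        ("log_mz", np.log(mz)),
        ("halogen_count", hal),
        ("inv_mz", 1.0 / mz),
    ]
    if n_informative > len(transforms):
        raise ValueError(f"at most {len(transforms)} informative columns available")
    data = {name: arr for name, arr in transforms[:n_informative]}
    rng = np.random.default_rng(seed)
    for j in range(n_noise):
        data[f"noise_{j:02d}"] = rng.normal(size=len(keys))
    data["planted_constant"] = np.ones(len(keys))
    first_name = transforms[0][0]
    data["planted_duplicate"] = np.asarray(data[first_name], dtype=float).copy()
    frame = pd.DataFrame(data, index=keys, dtype=float)
    return DescriptorMatrix(frame, backend_tag="mock-synthetic")
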