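"""Suspect screening of HRMS features against predicted-CCS libraries.

A chemical-database export (e.g. an inventory of plastic-packaging or
food-contact chemicals) is first rationalized — salts, metal-containing
structures, InChIKey duplicates and molecules outside the 50-1200 Da
neutral-mass window are removed — then expanded into a screening
library of adduct m/z values ([M+H]+ and [M+Na]+) paired with
predicted CCS values.  Measured features (m/z, retention time, CCS,
intensity) match a library entry when every active tolerance holds:
|m/z error| <= 5 ppm, |CCS deviation| <= 5 % and, when retention times
are available on both sides, |dRT| within the configured window.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

from .curation import ADDUCTS

# monoisotopic cation masses, electron mass included (Da)
PROTON_MASS = 1.007276
SODIUM_CATION_MASS = 22.989218

# elements treated as metals for the salt/organometallic removal rule:
# alkali + alkaline earth, transition block, lanthanides/actinides and
# the post-transition metals; B, Si, P, S, Se and the halogens stay.
METALS = frozenset(
    """Li Na K Rb Cs Fr Be Mg Ca Sr Ba Ra
    Sc Ti V Cr Mn Fe Co Ni Cu Zn Y Zr Nb Mo Tc Ru Rh Pd Ag Cd
    Hf Ta W Re Os Ir Pt Au Hg Rf Db Sg Bh Hs
    La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu
    Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr
    Al Ga In Tl Sn Pb Bi Po""".split()
)


@dataclass(frozen=True)
class DatabaseEntry:
    """One substance from a chemical-database export."""

    name: str
    inchikey: str
    smiles: str
    formula: str
    monoisotopic_mass: float | None
    source_db: str = ""


@dataclass(frozen=True)
class ScreeningLibraryEntry:
    """A database substance expanded to one adduct with predicted CCS."""

    entry: DatabaseEntry
    adduct: str
    mz: float
    predicted_ccs: float
    rt: float | None = None


@dataclass(frozen=True)
class Feature:
    """One HRMS feature: m/z, retention time (min), CCS, intensity."""

    mz: float
    rt: float
    ccs: float
    intensity: float = 0.0


@dataclass(frozen=True)
class Tolerances:
    """Active matching tolerances; ``rt_min=None`` disables the RT filter."""

    ppm: float = 5.0
    ccs_pct: float | None = 5.0
    rt_min: float | None = None


@dataclass(frozen=True)
class MatchResult:
    feature: Feature
    library_entry: ScreeningLibraryEntry
    ppm_error: float
    ccs_deviation_pct: float | None
    rt_deviation_min: float | None
    passed_filters: frozenset = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# Database rationalization
# ---------------------------------------------------------------------------


def _elements_of(entry: DatabaseEntry) -> set[str] | None:
    """Element symbols in the structure, from SMILES if possible."""
    if entry.smiles:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(entry.smiles, sanitize=False)
        if mol is not None:
            return {a.GetSymbol() for a in mol.GetAtoms()}
    if entry.formula:
        from .trends import parse_formula

        try:
            return set(parse_formula(entry.formula))
        except ValueError:
            return None
    return None


def _neutral_mass(entry: DatabaseEntry) -> float | None:
    if entry.monoisotopic_mass is not None and entry.monoisotopic_mass > 0:
        return entry.monoisotopic_mass
    if entry.smiles:
        from rdkit import Chem
        from rdkit.Chem import Descriptors

        mol = Chem.MolFromSmiles(entry.smiles)
        if mol is not None:
            return float(Descriptors.ExactMolWt(mol))
    return None


def rationalize_database(
    entries: list[DatabaseEntry],
    mass_min: float = 50.0,
    mass_max: float = 1200.0,
) -> tuple[list[DatabaseEntry], dict]:
    """Apply the library-cleanup rules and count removals per rule.

    Rules, in order: (i) unscorable entries (neither SMILES nor formula);
    (ii) multi-component structures (salt/mixture: SMILES contains a
    component separator); (iii) structures containing a metal atom;
    (iv) InChIKey duplicates (first occurrence kept); (v) neutral
    monoisotopic mass outside [mass_min, mass_max].
    """
    retained: list[DatabaseEntry] = []
    report = {"unscorable": 0, "multi_component": 0, "metal": 0,
              "duplicate": 0, "mass_window": 0, "retained": 0}
    seen: set[str] = set()
    for entry in entries:
        if not entry.smiles and not entry.formula:
            report["unscorable"] += 1
            continue
        if entry.smiles and "." in entry.smiles:
            report["multi_component"] += 1
            continue
        elements = _elements_of(entry)
        if elements is None:
            report["unscorable"] += 1
            continue
        if elements & METALS:
            report["metal"] += 1
            continue
        if entry.inchikey in seen:
            report["duplicate"] += 1
            continue
        mass = _neutral_mass(entry)
        if mass is None or not (mass_min <= mass <= mass_max):
            report["mass_window"] += 1
            continue
        seen.add(entry.inchikey)
        retained.append(entry)
    report["retained"] = len(retained)
    return retained, report


# ---------------------------------------------------------------------------
# Library construction and matching
# ---------------------------------------------------------------------------


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """Theoretical m/z of a singly charged positive adduct."""
    if neutral_mass < 0:
        raise ValueError("neutral mass must be non-negative")
    if adduct == "[M+H]+":
        return neutral_mass + PROTON_MASS
    if adduct == "[M+Na]+":
        return neutral_mass + SODIUM_CATION_MASS
    raise ValueError(f"unsupported adduct {adduct!r}; expected one of {ADDUCTS}")


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed mass error in parts per million."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    return (observed_mz - theoretical_mz) / theoretical_mz * 1e6


def build_library(
    entries: list[DatabaseEntry],
    predicted_ccs: dict[tuple[str, str], float],
    adducts: tuple = ADDUCTS,
) -> list[ScreeningLibraryEntry]:
    """Expand database entries into adduct-specific library rows.

    ``predicted_ccs`` maps (inchikey, adduct) to the model's CCS value;
    entries lacking a prediction for an adduct are skipped for that
    adduct.
    """
    library = []
    for entry in entries:
        mass = _neutral_mass(entry)
        if mass is None:
            continue
        for adduct in adducts:
            key = (entry.inchikey, adduct)
            if key not in predicted_ccs:
                continue
            library.append(
                ScreeningLibraryEntry(
                    entry=entry,
                    adduct=adduct,
                    mz=adduct_mz(mass, adduct),
                    predicted_ccs=predicted_ccs[key],
                )
            )
    return library


def screen_features(
    features: list[Feature],
    library: list[ScreeningLibraryEntry],
    tolerances: Tolerances = Tolerances(),
) -> list[MatchResult]:
    """Match features to library entries under the active tolerances.

    All (feature, entry) pairs passing every active filter are returned,
    sorted by |ppm error| (ties by library order).  Disabling the CCS
    filter (``ccs_pct=None``) can only enlarge the match set.
    """
    if not library:
        raise ValueError("screening library is empty")
    matches: list[MatchResult] = []
    for feature in features:
        for entry in library:
            passed = set()
            ppm = ppm_error(feature.mz, entry.mz)
            if abs(ppm) > tolerances.ppm:
                continue
            passed.add("ppm")
            ccs_dev = (feature.ccs - entry.predicted_ccs) / entry.predicted_ccs * 100.0
            if tolerances.ccs_pct is not None:
                if abs(ccs_dev) > tolerances.ccs_pct:
                    continue
                passed.add("ccs")
            if tolerances.rt_min is not None and entry.rt is not None:
                if abs(feature.rt - entry.rt) > tolerances.rt_min:
                    continue
                passed.add("rt")
            matches.append(
                MatchResult(
                    feature=feature,
                    library_entry=entry,
                    ppm_error=ppm,
                    ccs_deviation_pct=ccs_dev,
                    rt_deviation_min=(feature.rt - entry.rt)
                    if entry.rt is not None else None,
                    passed_filters=frozenset(passed),
                )
            )
    return sorted(matches, key=lambda m: abs(m.ppm_error))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def load_features_csv(path) -> list[Feature]:
    """Read a feature table with header ``mz,rt,ccs,intensity``."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(Feature(mz=float(row["mz"]), rt=float(row["rt"]),
                               ccs=float(row["ccs"]),
                               intensity=float(row.get("intensity") or 0.0)))
    return out


def load_library_csv(path) -> list[ScreeningLibraryEntry]:
    """Read a library with header ``name,inchikey,formula,adduct,mz,predicted_ccs[,rt]``."""
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            entry = DatabaseEntry(
                name=row["name"], inchikey=row["inchikey"], smiles=row.get("smiles", ""),
                formula=row["formula"], monoisotopic_mass=None,
                source_db=row.get("source_db", ""),
            )
            rt = row.get("rt")
            out.append(
                ScreeningLibraryEntry(
                    entry=entry, adduct=row["adduct"], mz=float(row["mz"]),
                    predicted_ccs=float(row["predicted_ccs"]),
                    rt=float(rt) if rt else None,
                )
            )
    return out


def write_library_csv(library: list[ScreeningLibraryEntry], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "inchikey", "formula", "adduct", "mz", "predicted_ccs"])
        for e in library:
            writer.writerow([e.entry.name, e.entry.inchikey, e.entry.formula,
                             e.adduct, f"{e.mz:.6f}", f"{e.predicted_ccs:.2f}"])


def write_matches_csv(matches: list[MatchResult], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["feature_mz", "feature_rt", "feature_ccs", "name", "inchikey",
                         "adduct", "library_mz", "predicted_ccs", "ppm_error",
                         "ccs_deviation_pct"])
        for m in matches:
            writer.writerow([
                f"{m.feature.mz:.6f}", f"{m.feature.rt:.3f}", f"{m.feature.ccs:.2f}",
                m.library_entry.entry.name, m.library_entry.entry.inchikey,
                m.library_entry.adduct, f"{m.library_entry.mz:.6f}",
                f"{m.library_entry.predicted_ccs:.2f}", f"{m.ppm_error:.3f}",
                f"{m.ccs_deviation_pct:.3f}" if m.ccs_deviation_pct is not None else "",
            ])


def match_summary(matches_with_ccs, matches_without_ccs) -> dict:
    return {
        "n_candidates_without_ccs_filter": len(matches_without_ccs),
        "n_candidates_with_ccs_filter": len(matches_with_ccs),
        "reduction_pct": (
            100.0 * (1 - len(matches_with_ccs) / len(matches_without_ccs))
            if matches_without_ccs else 0.0
        ),
    }


def write_match_summary_json(summary: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
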