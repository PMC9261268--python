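"""Molecular-descriptor computation and variable selection.

A QSPR model for CCS regresses the measured cross-section on numeric
descriptors of the neutral molecule (counts, topological indices,
physicochemical estimates).  Descriptor engines produce hundreds of
columns, most of them uninformative or redundant, so the matrix is
reduced in three stages before modeling:

1. near-zero-variance filter — columns that are constant or nearly so;
2. correlation filter — keep descriptors whose Pearson correlation with
   CCS exceeds a threshold (0.6 by default, absolute value);
3. importance selection — rank the survivors by gradient-boosted-tree
   gain importance and keep the smallest prefix covering a cumulative
   importance fraction (0.99 or 0.95).

Auto-scaling (z-scoring with parameters learned on the training rows
only) sits between stages 2 and 3 so that descriptor magnitude does not
dominate kernel distances.  A variance-inflation-factor pruner is also
provided for collinearity studies.

Descriptor computation is pluggable: any backend mapping a SMILES list
to a fixed column set satisfies the contract.  The package ships an
RDKit backend and a small deterministic mock backend for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class DescriptorMatrix:
    """Compounds-by-descriptors matrix keyed by InChIKey.

    Thin wrapper over a pandas DataFrame whose index holds the compound
    keys; ``backend_tag`` records descriptor provenance.
    """

    frame: pd.DataFrame
    backend_tag: str = ""

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            raise ValueError("duplicate row keys")
        if self.frame.columns.has_duplicates:
            raise ValueError("duplicate descriptor names")

    @property
    def row_keys(self) -> list[str]:
        return list(self.frame.index)

    @property
    def col_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def select_columns(self, names: list[str]) -> "DescriptorMatrix":
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise KeyError(f"descriptor columns absent: {missing}")
        return DescriptorMatrix(self.frame[list(names)].copy(), self.backend_tag)

    def select_rows(self, keys: list[str]) -> "DescriptorMatrix":
        return DescriptorMatrix(self.frame.loc[list(keys)].copy(), self.backend_tag)

    def drop_missing_columns(self) -> tuple["DescriptorMatrix", list[str]]:
        """Drop columns containing any NaN; returns (matrix, dropped names)."""
        bad = [c for c in self.frame.columns if self.frame[c].isna().any()]
        return DescriptorMatrix(self.frame.drop(columns=bad), self.backend_tag), bad

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="inchikey")

    @classmethod
    def from_csv(cls, path, backend_tag: str = "") -> "DescriptorMatrix":
        return cls(pd.read_csv(path, index_col="inchikey"), backend_tag)


@dataclass
class ScalingParams:
    """Per-descriptor mean and sample SD learned on a training matrix."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            zero = list(self.sd.index[self.sd <= 0])
            raise ValueError(f"non-positive SD for columns {zero}; filter them first")


@dataclass
class SelectionReport:
    """Audit trail of the three-stage descriptor selection."""

    n_initial: int = 0
    n_after_variance: int | None = None
    n_after_correlation: int | None = None
    n_after_importance: int | None = None
    correlation_threshold: float = 0.6
    importance_fraction: float | None = None
    importance_seed: int | None = None
    retained_names: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_initial": self.n_initial,
            "n_after_variance": self.n_after_variance,
            "n_after_correlation": self.n_after_correlation,
            "n_after_importance": self.n_after_importance,
            "correlation_threshold": self.correlation_threshold,
            "importance_fraction": self.importance_fraction,
            "importance_seed": self.importance_seed,
            "retained_names": {k: list(v) for k, v in self.retained_names.items()},
        }


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------


class MockBackend:
    """Deterministic toy descriptor engine for tests.

    Computes a handful of cheap 2-D quantities (atom/bond/ring counts,
    exact molecular weight, a crude lipophilicity surrogate) so the
    selection pipeline can be exercised without a full descriptor set.
    """

    name = "mock"
    column_names = [
        "n_heavy_atoms",
        "n_bonds",
        "n_rings",
        "n_halogens",
        "n_heteroatoms",
        "exact_mw",
        "logp_surrogate",
    ]

    def compute(self, smiles: str) -> list[float]:
        from rdkit import Chem
        from rdkit.Chem import Crippen, Descriptors

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        halogens = sum(
            1 for a in mol.GetAtoms() if a.GetSymbol() in ("F", "Cl", "Br", "I")
        )
        hetero = sum(
            1 for a in mol.GetAtoms() if a.GetSymbol() not in ("C", "H")
        )
        return [
            float(mol.GetNumHeavyAtoms()),
            float(mol.GetNumBonds()),
            float(mol.GetRingInfo().NumRings()),
            float(halogens),
            float(hetero),
            float(Descriptors.ExactMolWt(mol)),
            float(Crippen.MolLogP(mol)),
        ]


class RDKitBackend:
    """Full 2-D RDKit descriptor set (the open-source engine adapter)."""

    name = "rdkit"

    def __init__(self) -> None:
        from rdkit.Chem import Descriptors

        self._desc_list = list(Descriptors._descList)
        self.column_names = [name for name, _ in self._desc_list]

    def compute(self, smiles: str) -> list[float]:
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        out = []
        for _, fn in self._desc_list:
            try:
                out.append(float(fn(mol)))
            except Exception:
                out.append(float("nan"))
        return out


BACKENDS = {"mock": MockBackend, "rdkit": RDKitBackend}


def compute_descriptors(
    smiles_list: list[str],
    backend,
    keys: list[str] | None = None,
) -> tuple[DescriptorMatrix, dict[str, str]]:
    """Run a descriptor backend over a SMILES list.

    Returns the matrix (one row per successful molecule, column set
    fixed by the backend) and a key -> error-message map for molecules
    the backend could not process; failures are reported, never dropped
    silently.
    """
    if isinstance(backend, str):
        backend = BACKENDS[backend]()
    if keys is None:
        keys = list(smiles_list)
    if len(keys) != len(smiles_list):
        raise ValueError("keys and smiles_list length mismatch")
    rows, ok_keys, failures = [], [], {}
    for key, smi in zip(keys, smiles_list):
        try:
            rows.append(backend.compute(smi))
            ok_keys.append(key)
        except ValueError as exc:
            failures[key] = str(exc)
    frame = pd.DataFrame(rows, index=ok_keys, columns=backend.column_names, dtype=float)
    return DescriptorMatrix(frame, backend_tag=backend.name), failures


# ---------------------------------------------------------------------------
# Selection stages
# ---------------------------------------------------------------------------


def variance_filter(
    m: DescriptorMatrix,
    freq_ratio_max: float = 19.0,
    unique_pct_min: float = 10.0,
) -> tuple[DescriptorMatrix, list[str]]:
    """Remove near-zero-variance descriptor columns.

    A column is removed when its variance is exactly zero, or when the
    frequency ratio of its most common to second most common value
    exceeds ``freq_ratio_max`` AND the percentage of distinct values
    relative to the row count is below ``unique_pct_min`` (the caret
    ``nearZeroVar`` convention).
    """
    n = m.shape[0]
    if n < 2:
        raise ValueError("variance filter needs at least two rows")
    removed = []
    for col in m.col_names:
        x = m.frame[col].to_numpy()
        counts = pd.Series(x).value_counts()
        if len(counts) == 1:
            removed.append(col)
            continue
        freq_ratio = counts.iloc[0] / counts.iloc[1]
        unique_pct = 100.0 * len(counts) / n
        if freq_ratio > freq_ratio_max and unique_pct < unique_pct_min:
            removed.append(col)
    keep = [c for c in m.col_names if c not in removed]
    if not keep:
        raise ValueError("variance filter removed every column; nothing to model")
    return m.select_columns(keep), removed


def correlation_filter(
    m: DescriptorMatrix,
    y: np.ndarray,
    r_min: float = 0.6,
    mode: str = "absolute",
) -> tuple[DescriptorMatrix, list[str]]:
    """Keep descriptors whose Pearson correlation with CCS exceeds ``r_min``.

    ``mode='absolute'`` (default) uses |r| > r_min so that strongly
    anti-correlated descriptors survive; ``mode='signed'`` requires
    r > r_min.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != m.shape[0]:
        raise ValueError("y length does not match matrix rows")
    if np.std(y) == 0:
        raise ValueError("constant CCS vector: correlation undefined")
    if mode not in ("absolute", "signed"):
        raise ValueError(f"unknown mode {mode!r}")
    X = m.values
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    sx = Xc.std(axis=0)
    if (sx == 0).any():
        zero = [m.col_names[i] for i in np.flatnonzero(sx == 0)]
        raise ValueError(f"zero-variance columns present: {zero}; run variance_filter first")
    r = (Xc.T @ yc) / (len(y) * sx * yc.std())
    stat = np.abs(r) if mode == "absolute" else r
    keep = [c for c, s in zip(m.col_names, stat) if s > r_min]
    return m.select_columns(keep), keep


def autoscale_fit(m: DescriptorMatrix) -> ScalingParams:
    """Learn per-column mean and sample SD (n-1) on a training matrix."""
    return ScalingParams(mean=m.frame.mean(), sd=m.frame.std(ddof=1))


def autoscale_apply(m: DescriptorMatrix, params: ScalingParams) -> DescriptorMatrix:
    """Z-score a matrix with stored parameters (never refit)."""
    missing = [c for c in m.col_names if c not in params.mean.index]
    if missing:
        raise KeyError(f"columns absent from scaling params: {missing}")
    scaled = (m.frame - params.mean[m.col_names]) / params.sd[m.col_names]
    return DescriptorMatrix(scaled, m.backend_tag)


def importance_select(
    m: DescriptorMatrix,
    y: np.ndarray,
    cumulative_fraction: float,
    seed: int = 1,
) -> tuple[DescriptorMatrix, SelectionReport]:
    """Keep the top descriptors by gradient-boosted-tree gain importance.

    Fits an XGBoost regressor with default settings and a fixed seed,
    ranks columns by normalized gain importance (ties broken by column
    order), and keeps the smallest prefix whose cumulative importance
    reaches ``cumulative_fraction``.
    """
    from xgboost import XGBRegressor

    if not (0 < cumulative_fraction <= 1):
        raise ValueError("cumulative_fraction must lie in (0, 1]")
    model = XGBRegressor(random_state=seed, n_jobs=1, importance_type="gain")
    model.fit(m.values, np.asarray(y, dtype=float))
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    if total <= 0:
        raise ValueError("model assigned zero importance to every column")
    imp = imp / total
    # stable sort keeps original column order among ties
    order = np.argsort(-imp, kind="stable")
    cum = np.cumsum(imp[order])
    n_keep = int(np.searchsorted(cum, cumulative_fraction - 1e-12) + 1)
    # columns with zero importance never help; trim them from the prefix
    n_keep = min(n_keep, int((imp > 0).sum()))
    keep = [m.col_names[i] for i in sorted(order[:n_keep])]
    report = SelectionReport(
        n_initial=m.shape[1],
        n_after_importance=len(keep),
        importance_fraction=cumulative_fraction,
        importance_seed=seed,
        retained_names={"importance": keep},
    )
    return m.select_columns(keep), report


def _vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column regressed on the others."""
    n, p = X.shape
    vifs = np.empty(p)
    for j in range(p):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        sst = ((yj - yj.mean()) ** 2).sum()
        if sst == 0:
            vifs[j] = np.inf
            continue
        r2 = 1.0 - (resid**2).sum() / sst
        vifs[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return vifs


def vif_prune(
    m: DescriptorMatrix, vif_max: float
) -> tuple[DescriptorMatrix, list[str]]:
    """Iteratively drop the highest-VIF column until all VIF <= ``vif_max``.

    Perfectly collinear columns have infinite VIF and are removed first;
    ties are broken by column order (earliest column wins removal),
    which makes the outcome deterministic.
    """
    current = m
    removed: list[str] = []
    while current.shape[1] > 1:
        vifs = _vif(current.values)
        worst = int(np.argmax(vifs))
        if vifs[worst] <= vif_max:
            break
        name = current.col_names[worst]
        removed.append(name)
        current = current.select_columns([c for c in current.col_names if c != name])
    return current, removed


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def select_descriptors(
    m: DescriptorMatrix,
    y: np.ndarray,
    r_min: float = 0.6,
    correlation_mode: str = "absolute",
    importance_fraction: float | None = None,
    seed: int = 1,
) -> tuple[DescriptorMatrix, ScalingParams, SelectionReport]:
    """Run the full selection pipeline on a training matrix.

    Stages: drop columns with missing values, near-zero-variance filter,
    correlation filter against CCS, auto-scaling, and (when
    ``importance_fraction`` is set) importance selection.  Returns the
    scaled retained matrix, the scaling parameters, and the audit report.
    """
    report = SelectionReport(
        n_initial=m.shape[1],
        correlation_threshold=r_min,
        importance_fraction=importance_fraction,
        importance_seed=seed,
    )
    m, _dropped_na = m.drop_missing_columns()
    m, _removed_var = variance_filter(m)
    report.n_after_variance = m.shape[1]
    report.retained_names["variance"] = m.col_names
    m, kept = correlation_filter(m, y, r_min=r_min, mode=correlation_mode)
    report.n_after_correlation = m.shape[1]
    report.retained_names["correlation"] = kept
    params = autoscale_fit(m)
    m = autoscale_apply(m, params)
    if importance_fraction is not None:
        m, frag = importance_select(m, y, importance_fraction, seed=seed)
        report.n_after_importance = m.shape[1]
        report.retained_names["importance"] = frag.retained_names["importance"]
        params = ScalingParams(
            mean=params.mean[m.col_names], sd=params.sd[m.col_names]
        )
    return m, params, report
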