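"""Reading, validation and screening of zero-inflated abundance matrices.

An abundance matrix holds non-negative intensities with rows as features
(peptides, lipids, metabolites) and columns as samples.  A stored value of
exactly zero is a point mass value (PMV): either the compound is truly
absent from the sample (biological PMV) or its abundance fell below the
instrument detection limit (technical PMV).  Missing cells are *not* a
synonym for zero and are rejected at parse time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceMatrix",
    "DesignMatrix",
    "FeatureMeta",
    "FilterReport",
    "read_abundance_matrix",
    "read_design_table",
    "compute_detection_limit",
    "detection_limits",
    "feature_meta",
    "filter_features",
    "detect_perfect_separation",
]

#: default offset subtracted from the minimum log non-PMV observation when
#: deriving the log-scale detection limit of a feature
DEFAULT_EPSILON = 0.1


@dataclass
class AbundanceMatrix:
    """Feature-by-sample matrix of non-negative abundances.

    Zeros encode point mass values; every other value is a measured
    intensity.  Feature and sample identifiers must be unique.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("abundance values must be a 2-D array")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"missing or non-finite value for feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r} (missing cells are not PMVs)"
            )
        neg = self.values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValueError(
                f"negative abundance {self.values[i, j]} for feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def pmv_mask(self) -> np.ndarray:
        """Boolean mask, True where the observation is a PMV (exact zero)."""
        return self.values == 0

    def feature(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]

    def subset(self, feature_ids: list[str]) -> "AbundanceMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return AbundanceMatrix(self.values[idx], list(feature_ids), list(self.sample_ids))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AbundanceMatrix":
        if df.shape[0] == 0:
            raise ValueError("no features")
        if df.isna().any().any():
            r, c = np.argwhere(df.isna().to_numpy())[0]
            raise ValueError(
                f"missing value for feature {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def write(self, path, delimiter: str = "\t") -> None:
        df = self.to_dataframe()
        df.index.name = "feature_id"
        df.to_csv(path, sep=delimiter)


@dataclass
class DesignMatrix:
    """Per-sample covariate matrix with an explicit intercept column.

    The first column is all ones; subsequent columns are covariates.  For a
    two-group comparison the group is coded as a 0/1 indicator, with the
    reference level being the first group label in sorted order.
    """

    matrix: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if not np.all(self.matrix[:, 0] == 1.0):
            raise ValueError("first design column must be an all-ones intercept")
        if len(self.covariate_names) != self.matrix.shape[1] - 1:
            raise ValueError("covariate_names must name every non-intercept column")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]

    def group_indicator(self, column: int = 1) -> np.ndarray:
        """0/1 group labels from a binary design column (default: first covariate)."""
        col = self.matrix[:, column]
        if not np.isin(col, (0.0, 1.0)).all():
            raise ValueError(f"design column {column} is not a 0/1 group indicator")
        return col.astype(int)

    @classmethod
    def two_group(cls, labels, reference: str | None = None) -> "DesignMatrix":
        labels = [str(x) for x in labels]
        levels = sorted(set(labels))
        if len(levels) != 2:
            raise ValueError(f"expected exactly two group labels, got {levels}")
        if reference is not None:
            if reference not in levels:
                raise ValueError(f"reference {reference!r} not among labels {levels}")
            levels = [reference] + [g for g in levels if g != reference]
        ind = np.array([levels.index(x) for x in labels], dtype=float)
        X = np.column_stack([np.ones_like(ind), ind])
        return cls(X, covariate_names=["group"])


@dataclass
class FeatureMeta:
    """Per-feature bookkeeping: detection limit and PMV counts."""

    feature_id: str
    lambda_k: float
    n_nonpmv: int
    n_pmv: int
    pmv_fraction_by_group: dict[int, float]


@dataclass
class FilterReport:
    """Outcome of feature screening: which features survive and why not."""

    kept_feature_ids: list[str]
    dropped: dict[str, str]

    @property
    def dropped_feature_ids(self) -> list[str]:
        return list(self.dropped)

    def apply(self, matrix: AbundanceMatrix) -> AbundanceMatrix:
        return matrix.subset(self.kept_feature_ids)


def read_abundance_matrix(path, delimiter: str = "\t") -> AbundanceMatrix:
    """Parse a delimited feature-by-sample table.

    First column holds feature IDs, the header row holds sample IDs.  Cells
    must be non-negative reals; empty cells raise (a zero must be written
    as ``0``).
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    if df.shape[0] == 0:
        raise ValueError("no features")
    non_numeric = df.select_dtypes(exclude="number").columns
    if len(non_numeric):
        raise ValueError(f"non-numeric abundance column(s): {list(non_numeric)}")
    return AbundanceMatrix.from_dataframe(df)


def read_design_table(
    path,
    delimiter: str = "\t",
    sample_ids: list[str] | None = None,
    group_col: str = "group",
    reference: str | None = None,
) -> DesignMatrix:
    """Read a per-sample covariate table (columns: sample_id, group, ...).

    Rows are re-ordered to match ``sample_ids`` when given.  Extra numeric
    columns become additional covariates after the group indicator.
    """
    df = pd.read_csv(path, sep=delimiter)
    if "sample_id" not in df.columns or group_col not in df.columns:
        raise ValueError(f"design table needs 'sample_id' and {group_col!r} columns")
    df = df.set_index("sample_id")
    if sample_ids is not None:
        missing = set(sample_ids) - set(df.index.astype(str))
        if missing:
            raise ValueError(f"design table missing samples: {sorted(missing)}")
        df = df.loc[[s for s in sample_ids]]
    design = DesignMatrix.two_group(df[group_col].tolist(), reference=reference)
    extra = [c for c in df.columns if c != group_col]
    if extra:
        X = np.column_stack([design.matrix] + [df[c].to_numpy(float) for c in extra])
        design = DesignMatrix(X, covariate_names=["group"] + extra)
    return design


def compute_detection_limit(feature_values, epsilon: float = DEFAULT_EPSILON) -> float:
    """Log-scale detection limit of one feature.

    lambda = min over non-PMVs of log(value) - epsilon, so the limit sits
    strictly below every observed log intensity.
    """
    v = np.asarray(feature_values, dtype=float)
    nonpmv = v[v > 0]
    if nonpmv.size == 0:
        raise ValueError("no non-PMV observations: detection limit undefined")
    return float(np.log(nonpmv.min()) - epsilon)


def detection_limits(matrix: AbundanceMatrix, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Vector of per-feature detection limits."""
    return np.array(
        [compute_detection_limit(row, epsilon) for row in matrix.values], dtype=float
    )


def feature_meta(
    matrix: AbundanceMatrix,
    design: DesignMatrix,
    epsilon: float = DEFAULT_EPSILON,
    group_col: int = 1,
) -> list[FeatureMeta]:
    groups = design.group_indicator(group_col)
    out = []
    for fid, row in zip(matrix.feature_ids, matrix.values):
        pmv = row == 0
        fractions = {int(g): float(pmv[groups == g].mean()) for g in np.unique(groups)}
        lam = compute_detection_limit(row, epsilon) if (~pmv).any() else np.nan
        out.append(
            FeatureMeta(
                feature_id=fid,
                lambda_k=lam,
                n_nonpmv=int((~pmv).sum()),
                n_pmv=int(pmv.sum()),
                pmv_fraction_by_group=fractions,
            )
        )
    return out


def detect_perfect_separation(feature_values, design: DesignMatrix, group_col: int = 1) -> bool:
    """True iff one group is all PMVs and the other all non-PMVs.

    Under this pattern the logistic component of the mixture model is
    unidentifiable (the group log-odds diverge), so such features are
    screened out rather than fitted.
    """
    v = np.asarray(feature_values, dtype=float)
    groups = design.group_indicator(group_col)
    pmv = v == 0
    a, b = pmv[groups == 0], pmv[groups == 1]
    return bool((a.all() and not b.any()) or (b.all() and not a.any()))


def filter_features(
    matrix: AbundanceMatrix,
    design: DesignMatrix,
    min_nonpmv: int = 3,
    require_mixed_per_group: bool = True,
    group_col: int = 1,
) -> FilterReport:
    """Screen features before model fitting.

    A feature is kept when it has at least ``min_nonpmv`` non-PMV
    observations overall and, when ``require_mixed_per_group`` is set, at
    least one PMV and one non-PMV observation in each group.  The per-group
    requirement also excludes perfectly separated features, which are
    reported under their own reason for diagnosis.
    """
    groups = design.group_indicator(group_col) if require_mixed_per_group else None
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for fid, row in zip(matrix.feature_ids, matrix.values):
        pmv = row == 0
        n_nonpmv = int((~pmv).sum())
        if n_nonpmv < min_nonpmv:
            dropped[fid] = f"insufficient non-PMVs ({n_nonpmv} < {min_nonpmv})"
            continue
        if require_mixed_per_group:
            if detect_perfect_separation(row, design, group_col):
                dropped[fid] = "perfect separation"
                logger.warning("feature %s dropped: perfect separation", fid)
                continue
            reason = None
            for g in (0, 1):
                sub = pmv[groups == g]
                if not sub.any():
                    reason = f"no PMV in group {g}"
                elif sub.all():
                    reason = f"no non-PMV in group {g}"
                if reason:
                    break
            if reason:
                dropped[fid] = reason
                continue
        kept.append(fid)
    return FilterReport(kept_feature_ids=kept, dropped=dropped)
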