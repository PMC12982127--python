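"""Model specification and design-matrix construction.

Covariates are typed as continuous, binary, categorical, or ordered.
Categorical and ordered covariates are treatment (reference) coded;
for ordered covariates the supplied level order determines the
reference level and the consecutive-level contrasts. Interaction terms
are written ``a:b`` and expand to products of the component columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERCEPT = "(Intercept)"

COVARIATE_TYPES = ("continuous", "binary", "categorical", "ordered")


@dataclass
class ModelSpec:
    """What to fit and how to call significance.

    Parameters
    ----------
    fixed_terms : list of str
        Metadata column names (interactions as ``a:b``).
    random_intercept_groups : list of str
        Metadata columns defining random-intercept grouping. At most
        one grouping factor is supported.
    covariate_types : dict
        Optional explicit covariate typing; inferred from dtypes when
        absent (numeric -> continuous, two unique values -> binary,
        object/categorical -> categorical).
    ordered_levels : dict
        Level order for ordered covariates, low to high.
    contrasts : list of (matrix, rhs) or None
        User contrast rows over named coefficients.
    feature_specific_covariate : pandas.DataFrame or None
        Samples x features table; feature i's column is appended to
        feature i's design (e.g. paired DNA abundance for RNA models).
    median_comparison : bool
        Test abundance coefficients against their across-feature median
        (absolute-scale inference from relative data). Default on.
    subtract_median : bool
        Report median-subtracted abundance coefficients. Default off.
    augment : bool
        Data-augment the logistic fits against separability. Default on.
    screen_prevalence : bool
        Flag and discard prevalence associations likely induced by
        abundance changes. Default on.
    fdr_level : float
        Benjamini-Hochberg target level, default 0.1.
    coef_threshold : float
        Post hoc absolute-coefficient threshold for significance calls;
        0 disables (default). 1 is a recommended conservative choice.
    """

    fixed_terms: list[str] = field(default_factory=list)
    random_intercept_groups: list[str] = field(default_factory=list)
    covariate_types: dict[str, str] = field(default_factory=dict)
    ordered_levels: dict[str, list] = field(default_factory=dict)
    contrasts: list[tuple] | None = None
    feature_specific_covariate: pd.DataFrame | None = None
    feature_specific_name: str = "fsc"
    median_comparison: bool = True
    subtract_median: bool = False
    augment: bool = True
    screen_prevalence: bool = True
    fdr_level: float = 0.1
    coef_threshold: float = 0.0
    omnibus_vars: list[str] = field(default_factory=list)
    ordered_vars: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must be in (0, 1)")
        for var, typ in self.covariate_types.items():
            if typ not in COVARIATE_TYPES:
                raise ValueError(f"unknown covariate type {typ!r} for {var!r}")
        if len(self.random_intercept_groups) > 1:
            raise ValueError("at most one random-intercept grouping factor is supported")
        for var in self.ordered_vars:
            if var not in self.covariate_types:
                self.covariate_types[var] = "ordered"


def infer_type(col: pd.Series) -> str:
    if pd.api.types.is_numeric_dtype(col):
        vals = col.dropna().unique()
        return "binary" if len(vals) <= 2 else "continuous"
    return "categorical"


@dataclass
class DesignInfo:
    """A built fixed-effects design with coefficient bookkeeping."""

    matrix: pd.DataFrame                 # n x (g+1), includes intercept
    coef_to_var: dict[str, str]          # coefficient name -> covariate
    var_levels: dict[str, list]          # categorical/ordered level order

    @property
    def coef_names(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_covariate_columns(self) -> int:
        """g: fixed-effect columns excluding the intercept."""
        return self.matrix.shape[1] - 1


def _encode_single(metadata: pd.DataFrame, var: str, spec: ModelSpec):
    """Columns (dict name -> ndarray) for one non-interaction term."""
    if var not in metadata.columns:
        raise KeyError(f"covariate {var!r} not found in metadata")
    col = metadata[var]
    typ = spec.covariate_types.get(var, infer_type(col))
    if typ in ("continuous", "binary"):
        return {var: col.to_numpy(dtype=float)}, typ, None
    if typ == "ordered" and var in spec.ordered_levels:
        levels = list(spec.ordered_levels[var])
    elif isinstance(col.dtype, pd.CategoricalDtype):
        levels = list(col.cat.categories)
    else:
        levels = sorted(col.dropna().unique())
    cols = {}
    for lev in levels[1:]:
        cols[f"{var}[{lev}]"] = (col == lev).to_numpy(dtype=float)
    return cols, typ, levels


def build_design(metadata: pd.DataFrame, spec: ModelSpec) -> DesignInfo:
    """Build the intercept-first fixed-effects design matrix."""
    n = len(metadata)
    columns: dict[str, np.ndarray] = {INTERCEPT: np.ones(n)}
    coef_to_var: dict[str, str] = {INTERCEPT: INTERCEPT}
    var_levels: dict[str, list] = {}
    for term in spec.fixed_terms:
        if ":" in term:
            parts = term.split(":")
            part_cols = []
            for p in parts:
                cols, _, levels = _encode_single(metadata, p, spec)
                if levels is not None:
                    var_levels.setdefault(p, levels)
                part_cols.append(cols)
            # cartesian product of component encodings
            combined = {"": np.ones(n)}
            for cols in part_cols:
                combined = {
                    (f"{k1}:{k2}" if k1 else k2): v1 * v2
                    for k1, v1 in combined.items()
                    for k2, v2 in cols.items()
                }
            for name, vals in combined.items():
                columns[name] = vals
                coef_to_var[name] = term
        else:
            cols, _, levels = _encode_single(metadata, term, spec)
            if levels is not None:
                var_levels[term] = levels
            for name, vals in cols.items():
                columns[name] = vals
                coef_to_var[name] = term
    matrix = pd.DataFrame(columns, index=metadata.index)
    return DesignInfo(matrix=matrix, coef_to_var=coef_to_var, var_levels=var_levels)
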