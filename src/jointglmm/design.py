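"""Deterministic algebra of the joint model.

A woman with paired binary outcomes contributes two stacked rows, one per
outcome, selected by exclusive indicator columns; both rows carry the same
covariate vector and the same random-effect indices, which is what makes the
latent intercepts *shared* between contraceptive use and HIV knowledge.

This module builds that stacked design from a per-woman table, packs/unpacks
the unconstrained parameter vector (fixed effects per outcome plus log
standard deviations of the active variance components), and evaluates linear
predictors given realized random effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .datasets import DEFAULT_COVARIATES, DatasetError

__all__ = [
    "ModelSpec",
    "ModelParams",
    "Layout",
    "StackedDesign",
    "build_stacked_design",
    "inv_logit",
    "linear_predictor",
    "DISPLAY_NAMES",
]

OUTCOME_COLUMNS = {"cuc": "y_cuc", "hiv": "y_hiv"}

#: Row labels used in reported coefficient tables.
DISPLAY_NAMES = {
    "age": "Age",
    "age_at_marriage": "Age at marriage",
    "num_children": "Children",
    "radio": "Radio",
    "tv": "Television",
    "education": "Education",
    "religion": "Religion",
    "urban": "Urban",
    "wealth": "Wealth index",
}

_LEVELS = ("individual", "cluster", "division")
_SIGMA_OF_LEVEL = {
    "individual": "sigma_u",
    "cluster": "sigma_clu",
    "division": "sigma_div",
}


@dataclass(frozen=True)
class ModelSpec:
    """Which outcomes, covariates and random-effect levels enter the model.

    ``outcomes`` is one of ``"cuc"``, ``"hiv"`` (single-outcome) or
    ``"joint"``. The individual level is only identifiable in the joint model
    (a single Bernoulli per woman carries no information about a
    woman-specific intercept), so single-outcome specs must not request it.
    """

    outcomes: str = "joint"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    levels: tuple[str, ...] = ("individual", "cluster", "division")
    random_slope: str | None = None
    slope_levels: tuple[str, ...] = ("cluster", "division")
    quadrature_order: int = 11

    def __post_init__(self):
        if self.outcomes not in ("cuc", "hiv", "joint"):
            raise ValueError(f"unknown outcomes {self.outcomes!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "levels", tuple(self.levels))
        object.__setattr__(self, "slope_levels", tuple(self.slope_levels))
        for lv in self.levels:
            if lv not in _LEVELS:
                raise ValueError(f"unknown level {lv!r}")
        if self.outcomes != "joint" and "individual" in self.levels:
            raise ValueError(
                "individual-level shared intercept is unidentifiable in a "
                "single-outcome model; drop 'individual' from levels"
            )
        for lv in self.slope_levels:
            if lv not in ("cluster", "division"):
                raise ValueError("random slopes supported at cluster/division only")
        if self.quadrature_order < 1:
            raise ValueError("quadrature_order must be >= 1")

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def joint(cls, covariates=DEFAULT_COVARIATES, order: int = 11) -> "ModelSpec":
        return cls("joint", tuple(covariates),
                   ("individual", "cluster", "division"), quadrature_order=order)

    @classmethod
    def separate(cls, outcome: str, covariates=DEFAULT_COVARIATES,
                 order: int = 11) -> "ModelSpec":
        """Per-outcome three-level model: woman < cluster < division, no shared term."""
        return cls(outcome, tuple(covariates), ("cluster", "division"),
                   quadrature_order=order)

    @classmethod
    def standard(cls, outcome: str, covariates=DEFAULT_COVARIATES) -> "ModelSpec":
        """Plain logistic regression: no random effects."""
        return cls(outcome, tuple(covariates), (), quadrature_order=1)

    @property
    def n_outcomes(self) -> int:
        return 2 if self.outcomes == "joint" else 1

    @property
    def outcome_names(self) -> tuple[str, ...]:
        return ("cuc", "hiv") if self.outcomes == "joint" else (self.outcomes,)

    def active_sigmas(self) -> tuple[str, ...]:
        names = [_SIGMA_OF_LEVEL[lv] for lv in _LEVELS if lv in self.levels]
        if self.random_slope is not None:
            if "cluster" in self.slope_levels:
                names.append("sigma_slope_clu")
            if "division" in self.slope_levels:
                names.append("sigma_slope_div")
        return tuple(names)


@dataclass
class ModelParams:
    """Unpacked parameter values: beta rows per outcome, SDs per level."""

    beta: np.ndarray  # (n_outcomes, p + 1), intercept first
    sigma_u: float = 0.0
    sigma_clu: float = 0.0
    sigma_div: float = 0.0
    sigma_slope_clu: float = 0.0
    sigma_slope_div: float = 0.0

    def __post_init__(self):
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))


@dataclass(frozen=True)
class Layout:
    """Packing map between ModelParams and the unconstrained optimizer vector.

    Beta blocks are raw; each active standard deviation is stored as log(sigma)
    so the optimizer is unconstrained and sigma stays positive.
    """

    spec: ModelSpec
    n_covariates: int
    sigma_names: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "sigma_names", self.spec.active_sigmas())

    @classmethod
    def from_spec(cls, spec: ModelSpec) -> "Layout":
        return cls(spec=spec, n_covariates=len(spec.covariates))

    @property
    def n_beta(self) -> int:
        return self.spec.n_outcomes * (self.n_covariates + 1)

    @property
    def size(self) -> int:
        return self.n_beta + len(self.sigma_names)

    def pack(self, params: ModelParams) -> np.ndarray:
        beta = np.atleast_2d(params.beta)
        if beta.shape != (self.spec.n_outcomes, self.n_covariates + 1):
            raise ValueError(
                f"beta has shape {beta.shape}, expected "
                f"{(self.spec.n_outcomes, self.n_covariates + 1)}"
            )
        logs = []
        for name in self.sigma_names:
            s = getattr(params, name)
            if s <= 0:
                raise ValueError(f"{name} must be > 0 to pack on the log scale")
            logs.append(np.log(s))
        return np.concatenate([beta.ravel(), np.asarray(logs)])

    def unpack(self, theta: np.ndarray) -> ModelParams:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.size,):
            raise ValueError(f"theta has shape {theta.shape}, expected ({self.size},)")
        beta = theta[: self.n_beta].reshape(self.spec.n_outcomes, self.n_covariates + 1)
        params = ModelParams(beta=beta)
        for k, name in enumerate(self.sigma_names):
            setattr(params, name, float(np.exp(theta[self.n_beta + k])))
        return params

    def parameter_names(self) -> list[str]:
        coef = ["Intercept"] + [DISPLAY_NAMES.get(c, c) for c in self.spec.covariates]
        names = [f"{o}:{c}" for o in self.spec.outcome_names for c in coef]
        names += [f"log_{s}" for s in self.sigma_names]
        return names


@dataclass
class StackedDesign:
    """Two rows per woman (one for single-outcome specs), sorted so that rows
    of a woman are contiguous, women of a cluster are contiguous and clusters
    of a division are contiguous — the layout the nested quadrature exploits.
    """

    spec: ModelSpec
    y: np.ndarray                 # (n_rows,) 0/1
    X: np.ndarray                 # (n_rows, p + 1)
    outcome_idx: np.ndarray       # (n_rows,) index into beta rows
    indicators: np.ndarray        # (n_rows, n_outcomes) exclusive 0/1
    woman_of_row: np.ndarray      # (n_rows,) woman code
    slope_z: np.ndarray | None    # (n_rows,) slope covariate values, if any
    # grouping (codes are 0..k-1 in sorted order)
    woman_row_starts: np.ndarray      # (n_women + 1,) row offsets
    cluster_woman_starts: np.ndarray  # (n_clusters + 1,) woman offsets
    division_cluster_starts: np.ndarray  # (n_divisions + 1,) cluster offsets
    cluster_of_woman: np.ndarray      # (n_women,)
    division_of_cluster: np.ndarray   # (n_clusters,)
    woman_labels: np.ndarray
    cluster_labels: np.ndarray
    division_labels: np.ndarray

    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def n_women(self) -> int:
        return len(self.woman_row_starts) - 1

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_woman_starts) - 1

    @property
    def n_divisions(self) -> int:
        return len(self.division_cluster_starts) - 1

    def division_of_row(self) -> np.ndarray:
        return self.division_of_cluster[self.cluster_of_woman[self.woman_of_row]]

    def cluster_of_row(self) -> np.ndarray:
        return self.cluster_of_woman[self.woman_of_row]


def _starts_from_codes(codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Offsets of contiguous groups in a sorted code array."""
    counts = np.bincount(codes, minlength=n_groups)
    return np.concatenate([[0], np.cumsum(counts)])


def build_stacked_design(data: pd.DataFrame, spec: ModelSpec) -> StackedDesign:
    """Stack a per-woman table into the two-rows-per-woman design of the
    joint model (one row per woman for single-outcome specs)."""
    unknown = [c for c in spec.covariates if c not in data.columns]
    if unknown:
        raise DatasetError(f"unknown covariate column(s): {', '.join(unknown)}")
    if spec.random_slope is not None and spec.random_slope not in data.columns:
        raise DatasetError(f"unknown random-slope covariate {spec.random_slope!r}")

    df = data.sort_values(
        ["division_id", "cluster_id", "woman_id"], kind="mergesort"
    ).reset_index(drop=True)

    ndiv = df.groupby("cluster_id")["division_id"].nunique()
    if (ndiv > 1).any():
        raise DatasetError("cluster_id maps to multiple divisions")

    div_codes, div_labels = pd.factorize(df["division_id"])
    clu_codes, clu_labels = pd.factorize(df["cluster_id"])
    n_women = len(df)

    Xw = np.column_stack([np.ones(n_women)] +
                         [df[c].to_numpy(dtype=float) for c in spec.covariates])
    n_out = spec.n_outcomes
    rep = np.repeat(np.arange(n_women), n_out)

    y_cols = [OUTCOME_COLUMNS[o] for o in spec.outcome_names]
    for col in y_cols:
        vals = df[col].to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise DatasetError(f"{col} contains non-binary values")
    y = np.column_stack([df[c].to_numpy(dtype=np.int8) for c in y_cols]).ravel()

    outcome_idx = np.tile(np.arange(n_out), n_women)
    indicators = np.eye(n_out, dtype=np.int8)[outcome_idx]

    clu_of_woman = clu_codes
    div_of_cluster = np.empty(len(clu_labels), dtype=np.int64)
    div_of_cluster[clu_codes] = div_codes  # consistent: nesting checked above

    slope_z = None
    if spec.random_slope is not None:
        slope_z = df[spec.random_slope].to_numpy(dtype=float)[rep]

    return StackedDesign(
        spec=spec,
        y=y,
        X=Xw[rep],
        outcome_idx=outcome_idx,
        indicators=indicators,
        woman_of_row=rep,
        slope_z=slope_z,
        woman_row_starts=np.arange(0, n_out * n_women + 1, n_out),
        cluster_woman_starts=_starts_from_codes(clu_of_woman, len(clu_labels)),
        division_cluster_starts=_starts_from_codes(div_of_cluster, len(div_labels)),
        cluster_of_woman=clu_of_woman,
        division_of_cluster=div_of_cluster,
        woman_labels=df["woman_id"].to_numpy(),
        cluster_labels=np.asarray(clu_labels),
        division_labels=np.asarray(div_labels),
    )


def inv_logit(eta):
    """Inverse logit 1/(1+exp(-eta)); underflow-safe at extreme arguments."""
    return expit(eta)


def fixed_predictor(design: StackedDesign, params: ModelParams) -> np.ndarray:
    """x'beta_i per row (the row's outcome selects the beta block)."""
    etas = design.X @ np.atleast_2d(params.beta).T  # (rows, n_outcomes)
    return np.take_along_axis(etas, design.outcome_idx[:, None], axis=1).ravel()


def linear_predictor(design: StackedDesign, params: ModelParams,
                     effects: Mapping[str, np.ndarray]) -> np.ndarray:
    """Row-wise eta = x'beta_i + b_div + b_clu + u (+ slope terms).

    ``effects`` maps level names (``division``, ``cluster``, ``woman`` and
    optionally ``slope_cluster``/``slope_division``) to arrays indexed by the
    design's unit codes; levels absent from the spec may be omitted.
    """
    eta = fixed_predictor(design, params)
    div_row = design.division_of_row()
    clu_row = design.cluster_of_row()

    def _get(name, n_units):
        if name not in effects:
            raise KeyError(f"missing effects for level {name!r}")
        arr = np.asarray(effects[name], dtype=float)
        if arr.shape != (n_units,):
            raise ValueError(f"effects[{name!r}] has shape {arr.shape}, "
                             f"expected ({n_units},)")
        return arr

    if "division" in design.spec.levels:
        eta = eta + _get("division", design.n_divisions)[div_row]
    if "cluster" in design.spec.levels:
        eta = eta + _get("cluster", design.n_clusters)[clu_row]
    if "individual" in design.spec.levels:
        eta = eta + _get("woman", design.n_women)[design.woman_of_row]
    if design.spec.random_slope is not None:
        if "cluster" in design.spec.slope_levels:
            eta = eta + _get("slope_cluster", design.n_clusters)[clu_row] * design.slope_z
        if "division" in design.spec.slope_levels:
            eta = eta + _get("slope_division", design.n_divisions)[div_row] * design.slope_z
    return eta
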