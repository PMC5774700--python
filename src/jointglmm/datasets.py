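"""Synthetic multistage-survey data with the nesting the joint model assumes.

The generator emulates the structure of a national demographic and health
survey: women nested in enumeration-area clusters nested in administrative
divisions, two correlated binary outcomes per woman (current contraceptive
use and HIV/STD knowledge), and household/demographic covariates whose
marginal distributions default to the published sample frequency table.

Outcomes are generated from the same shared-random-intercept logistic model
the estimation module fits: one normal intercept per division, per cluster
and per woman, each entering both outcomes' linear predictors with loading 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "PUBLISHED_COUNTS",
    "DEFAULT_COVARIATES",
    "SimConfig",
    "TrueParameters",
    "ConfigError",
    "DatasetError",
    "default_marginals",
    "default_true_parameters",
    "generate_structure",
    "simulate_outcomes",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "validate_dataset",
]

DIVISION_NAMES = (
    "Barisal", "Chittagong", "Dhaka", "Khulna", "Rajshahi", "Rangpur", "Sylhet",
)

#: Published sample frequency table of the 2011 survey round the generator
#: emulates; these counts are the source of every default marginal below and
#: of the descriptive worked examples in the reporting module.
PUBLISHED_COUNTS: dict[str, dict] = {
    "cuc": {"no": 6507, "yes": 9677},
    "hiv_knowledge": {"no": 4772, "yes": 11412},
    "radio": {"no": 14743, "yes": 1443},
    "tv": {"no": 8790, "yes": 7396},
    "education": {"no education": 4416, "primary": 4903, "secondary": 5604, "higher": 1263},
    "religion": {"islam": 14323, "other": 1861},
    "residence": {"small city": 1840, "town": 3835, "countryside": 10509},
    "wealth": {"poorest": 2865, "poorer": 3012, "middle": 3093, "richer": 3403, "richest": 3811},
    "division": {
        "Barisal": 1852, "Chittagong": 2579, "Dhaka": 2807, "Khulna": 2413,
        "Rajshahi": 2376, "Rangpur": 2289, "Sylhet": 1868,
    },
}

#: Continuous / count covariates: published mean, SD and observed range.
PUBLISHED_CONTINUOUS: dict[str, dict] = {
    "age": {"mean": 31.42, "sd": 9.19, "low": 13, "high": 49},
    "age_at_marriage": {"mean": 15.65, "sd": 2.94, "low": 10, "high": 48},
    "num_children": {"mean": 2.40, "sd": 1.59, "low": 0, "high": 10},
}

DEFAULT_COVARIATES = (
    "age", "age_at_marriage", "num_children", "radio", "tv",
    "education", "religion", "urban", "wealth",
)

REQUIRED_COLUMNS = (
    "division_id", "cluster_id", "woman_id",
    *DEFAULT_COVARIATES, "y_cuc", "y_hiv",
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class DatasetError(ValueError):
    """Dataset violates the documented schema."""


def _props(counts: Mapping[str, int]) -> list[float]:
    total = sum(counts.values())
    return [c / total for c in counts.values()]


def default_marginals() -> dict[str, dict]:
    """Per-covariate marginal settings derived from the published table.

    Binary covariates carry a success probability; ordinal covariates a level
    list with probabilities; age-like covariates a bounded rounded-normal
    (mean/sd/low/high). ``urban`` collapses small city + town vs countryside.
    """
    res = PUBLISHED_COUNTS["residence"]
    urban = (res["small city"] + res["town"]) / sum(res.values())
    marg: dict[str, dict] = {}
    for name in ("age", "age_at_marriage", "num_children"):
        marg[name] = {"dist": "truncnorm_int", **PUBLISHED_CONTINUOUS[name]}
    marg["radio"] = {"dist": "bernoulli", "p": _props(PUBLISHED_COUNTS["radio"])[1]}
    marg["tv"] = {"dist": "bernoulli", "p": _props(PUBLISHED_COUNTS["tv"])[1]}
    marg["education"] = {
        "dist": "categorical", "levels": [0, 1, 2, 3],
        "probs": _props(PUBLISHED_COUNTS["education"]),
    }
    marg["religion"] = {"dist": "bernoulli", "p": _props(PUBLISHED_COUNTS["religion"])[0]}
    marg["urban"] = {"dist": "bernoulli", "p": urban}
    marg["wealth"] = {
        "dist": "categorical", "levels": [1, 2, 3, 4, 5],
        "probs": _props(PUBLISHED_COUNTS["wealth"]),
    }
    return marg


def _validate_marginal(name: str, spec: Mapping) -> None:
    dist = spec.get("dist")
    if dist == "bernoulli":
        p = spec["p"]
        if not 0.0 <= p <= 1.0:
            raise ConfigError(f"{name}: bernoulli p={p} outside [0, 1]")
    elif dist == "categorical":
        probs = np.asarray(spec["probs"], dtype=float)
        if len(probs) != len(spec["levels"]):
            raise ConfigError(f"{name}: levels/probs length mismatch")
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-8:
            raise ConfigError(
                f"{name}: categorical probabilities must be non-negative and sum "
                f"to 1 (got sum {probs.sum():.6f})"
            )
    elif dist == "truncnorm_int":
        if spec["sd"] <= 0 or spec["low"] > spec["high"]:
            raise ConfigError(f"{name}: invalid truncnorm_int settings")
    else:
        raise ConfigError(f"{name}: unknown distribution {dist!r}")


@dataclass(frozen=True)
class SimConfig:
    """Survey-structure settings.

    Defaults mirror the emulated survey round: 7 divisions, ~85 clusters per
    division and ~27 women per cluster (~16,000 women in total).
    """

    n_divisions: int = 7
    clusters_per_division: int | Sequence[int] = 85
    women_per_cluster: int | tuple[int, int] = 27
    covariate_marginals: Mapping[str, dict] = field(default_factory=default_marginals)
    seed: int = 0

    def validate(self) -> None:
        if self.n_divisions < 1:
            raise ConfigError("n_divisions must be >= 1")
        for c in self._clusters_list():
            if c < 1:
                raise ConfigError("clusters_per_division entries must be >= 1")
        w = self.women_per_cluster
        if isinstance(w, tuple):
            if w[0] < 1 or w[1] < w[0]:
                raise ConfigError("women_per_cluster range must be 1 <= low <= high")
        elif w < 1:
            raise ConfigError("women_per_cluster must be >= 1")
        for name, spec in self.covariate_marginals.items():
            _validate_marginal(name, spec)

    def _clusters_list(self) -> list[int]:
        c = self.clusters_per_division
        if isinstance(c, int):
            return [c] * self.n_divisions
        c = list(c)
        if len(c) != self.n_divisions:
            raise ConfigError("clusters_per_division list length != n_divisions")
        return c


@dataclass(frozen=True)
class TrueParameters:
    """Generative parameters of the shared-random-intercept logistic model.

    ``beta_cuc``/``beta_hiv`` are log-odds coefficient vectors (intercept
    first, then one entry per name in ``covariates``). The sigmas are the
    standard deviations of the normal random intercepts shared by both
    outcomes at the woman, cluster and division levels.
    """

    covariates: tuple[str, ...]
    beta_cuc: np.ndarray
    beta_hiv: np.ndarray
    sigma_u: float = 0.0
    sigma_clu: float = 0.0
    sigma_div: float = 0.0
    slope_covariate: str | None = None
    sigma_slope_clu: float = 0.0
    sigma_slope_div: float = 0.0

    def __post_init__(self):
        bc = np.asarray(self.beta_cuc, dtype=float)
        bh = np.asarray(self.beta_hiv, dtype=float)
        object.__setattr__(self, "beta_cuc", bc)
        object.__setattr__(self, "beta_hiv", bh)
        p = len(self.covariates)
        if bc.shape != (p + 1,):
            raise ConfigError(
                f"beta_cuc has length {bc.shape[0]}, expected {p + 1} "
                "(intercept + covariates)"
            )
        if bh.shape != (p + 1,):
            raise ConfigError(
                f"beta_hiv has length {bh.shape[0]}, expected {p + 1} "
                "(intercept + covariates)"
            )
        for s in ("sigma_u", "sigma_clu", "sigma_div",
                  "sigma_slope_clu", "sigma_slope_div"):
            if getattr(self, s) < 0:
                raise ConfigError(f"{s} must be >= 0")
        if self.slope_covariate is not None and self.slope_covariate not in self.covariates:
            raise ConfigError(f"slope_covariate {self.slope_covariate!r} not in covariates")


def default_true_parameters() -> TrueParameters:
    """Default generative parameters.

    Slopes are the joint-model log odds ratios of the emulated study; the
    intercepts were calibrated once by Monte Carlo so that, with the default
    covariate marginals and variance components, simulated marginal
    prevalences match the published sample (59.8% contraceptive use, 70.5%
    HIV knowledge). Cluster/division SDs are the square roots of the reported
    variance components (0.050, 0.204); the woman-level shared SD, which the
    study does not report, is set to 1.0 (moderate latent heterogeneity).
    """
    # order: age, age_at_marriage, num_children, radio, tv, education,
    #        religion, urban, wealth
    slopes_cuc = np.log([0.99, 1.01, 1.10, 1.00, 1.03, 1.03, 0.91, 1.05, 0.99])
    slopes_hiv = np.log([1.00, 1.00, 0.98, 1.03, 1.10, 1.16, 1.02, 1.04, 1.05])
    return TrueParameters(
        covariates=DEFAULT_COVARIATES,
        beta_cuc=np.concatenate([[0.468], slopes_cuc]),
        beta_hiv=np.concatenate([[0.731], slopes_hiv]),
        sigma_u=1.0,
        sigma_clu=float(np.sqrt(0.050)),
        sigma_div=float(np.sqrt(0.204)),
    )


def _trunc_normal_int(rng: np.random.Generator, n: int, mean: float, sd: float,
                      low: int, high: int) -> np.ndarray:
    """Rounded normal draws restricted to [low, high] by rejection."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = np.rint(rng.normal(mean, sd, size=(n - filled) * 2 + 8))
        ok = draw[(draw >= low) & (draw <= high)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take].astype(np.int64)
        filled += take
    return out


def _draw_covariate(rng: np.random.Generator, spec: Mapping, n: int) -> np.ndarray:
    dist = spec["dist"]
    if dist == "bernoulli":
        return (rng.random(n) < spec["p"]).astype(np.int64)
    if dist == "categorical":
        return rng.choice(np.asarray(spec["levels"]), size=n, p=spec["probs"])
    if dist == "truncnorm_int":
        return _trunc_normal_int(rng, n, spec["mean"], spec["sd"], spec["low"], spec["high"])
    raise ConfigError(f"unknown distribution {dist!r}")


def generate_structure(config: SimConfig) -> pd.DataFrame:
    """Draw the nested ids and covariates; outcome columns are set to -1.

    Clusters are equal-probability (no size-proportional selection) and
    covariates are drawn independently of each other.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    clusters = config._clusters_list()
    if config.n_divisions == len(DIVISION_NAMES):
        div_names = list(DIVISION_NAMES)
    else:
        div_names = [f"div{i + 1:02d}" for i in range(config.n_divisions)]

    div_col, clu_col = [], []
    for d, name in enumerate(div_names):
        for c in range(clusters[d]):
            w = config.women_per_cluster
            n_w = int(rng.integers(w[0], w[1] + 1)) if isinstance(w, tuple) else w
            div_col.extend([name] * n_w)
            clu_col.extend([f"{name}_c{c + 1:03d}"] * n_w)
    n = len(div_col)
    df = pd.DataFrame({
        "division_id": div_col,
        "cluster_id": clu_col,
        "woman_id": np.arange(1, n + 1, dtype=np.int64),
    })
    for name, spec in config.covariate_marginals.items():
        df[name] = _draw_covariate(rng, spec, n)
    df["y_cuc"] = -1
    df["y_hiv"] = -1
    return df


def simulate_outcomes(data: pd.DataFrame, params: TrueParameters,
                      seed: int) -> pd.DataFrame:
    """Fill the two binary outcomes from the shared-intercept logistic model.

    One normal draw per division, per cluster and per woman enters both
    outcomes' linear predictors with loading 1; outcomes are then independent
    Bernoulli given the effects.
    """
    missing = [c for c in params.covariates if c not in data.columns]
    if missing:
        raise DatasetError(f"missing covariate column(s): {', '.join(missing)}")
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(len(data))] +
                        [data[c].to_numpy(dtype=float) for c in params.covariates])

    div_codes, _ = pd.factorize(data["division_id"])
    clu_codes, _ = pd.factorize(data["cluster_id"])
    b_div = rng.normal(0.0, params.sigma_div, size=div_codes.max() + 1)
    b_clu = rng.normal(0.0, params.sigma_clu, size=clu_codes.max() + 1)
    u = rng.normal(0.0, params.sigma_u, size=len(data))

    offset = b_div[div_codes] + b_clu[clu_codes] + u
    if params.slope_covariate is not None:
        z = data[params.slope_covariate].to_numpy(dtype=float)
        g_div = rng.normal(0.0, params.sigma_slope_div, size=div_codes.max() + 1)
        g_clu = rng.normal(0.0, params.sigma_slope_clu, size=clu_codes.max() + 1)
        offset = offset + g_div[div_codes] * z + g_clu[clu_codes] * z

    out = data.copy()
    p_cuc = expit(X @ params.beta_cuc + offset)
    p_hiv = expit(X @ params.beta_hiv + offset)
    out["y_cuc"] = (rng.random(len(data)) < p_cuc).astype(np.int64)
    out["y_hiv"] = (rng.random(len(data)) < p_hiv).astype(np.int64)
    return out


def generate_dataset(config: SimConfig, params: TrueParameters | None = None,
                     outcome_seed: int | None = None) -> pd.DataFrame:
    """Structure + outcomes in one call (outcome seed derived from config.seed)."""
    params = params if params is not None else default_true_parameters()
    df = generate_structure(config)
    if outcome_seed is None:
        outcome_seed = (config.seed + 1) % (2 ** 31)
    return simulate_outcomes(df, params, seed=outcome_seed)


def validate_dataset(data: pd.DataFrame) -> None:
    """Schema checks: columns, binary outcomes, ordinal ranges, nesting."""
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise DatasetError(f"missing column(s): {', '.join(missing)}")
    for col in ("y_cuc", "y_hiv"):
        vals = data[col].to_numpy()
        bad = np.flatnonzero(~np.isin(vals, (0, 1)))
        if bad.size:
            raise DatasetError(
                f"{col} must be 0/1; first offending row index {int(bad[0])} "
                f"has value {vals[bad[0]]!r}"
            )
    if not data["woman_id"].is_unique:
        raise DatasetError("woman_id values must be unique")
    if not np.isin(data["education"].to_numpy(), (0, 1, 2, 3)).all():
        raise DatasetError("education must be in {0,1,2,3}")
    if not np.isin(data["wealth"].to_numpy(), (1, 2, 3, 4, 5)).all():
        raise DatasetError("wealth must be in {1,...,5}")
    ndiv = data.groupby("cluster_id")["division_id"].nunique()
    bad_clusters = ndiv[ndiv > 1]
    if len(bad_clusters):
        raise DatasetError(
            f"cluster(s) mapped to multiple divisions: {list(bad_clusters.index[:5])}"
        )


def write_dataset(data: pd.DataFrame, path) -> None:
    validate_dataset(data)
    data.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_dataset(df)
    return df
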