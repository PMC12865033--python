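"""Synthetic population-survey generation, missingness injection and splitting.

The generator emulates a merged general-population health survey: eight
sociodemographic variables, the three Minimum European Health Module
(MEHM) items — self-perceived health (``sph``, 1 best..5 worst), chronic
morbidity (``chr``, 0/1) and the Global Activity Limitation Indicator
(``gali``, 1 severely limited..3 not limited) — the five EQ-5D-5L
dimension levels, and the EQ-5D-5L index ``eq5i`` scored from those
levels with a value set.

The joint distribution is a Gaussian copula around a single latent
health score: age and log-income are correlated with the latent score,
each MEHM item and each EQ-5D dimension is an ordinal cut of its own
noisy projection of the score.  Default loadings and thresholds were
frozen once from a moment-matching calibration at n = 50,000
(``scripts/calibrate_generator.py``) so that the generated data shows

* the ceiling effect of population samples (~70% of index values in
  [0.75, 1.00], mean ~0.88);
* predictor-index Pearson correlations near (+0.61 gali, -0.56 sph,
  -0.39 chr, +0.23 household income).

Missingness is injected per variable as MCAR (non-recorded items) or
MAR (income nonresponse driven by self-perceived health), averaging 3%
of cells with a per-variable maximum of 22%; the outcome ``eq5i`` is
never made missing.  Splitting is stratified by sex and age group in a
60/20/20 ratio with largest-remainder rounding inside every stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .valueset import ValueSet, default_value_set

__all__ = [
    "PopulationConfig",
    "MissingnessSpec",
    "SplitSpec",
    "ConfigurationError",
    "CalibrationError",
    "AGE_GROUP_EDGES",
    "age_group",
    "generate_population",
    "default_missingness_spec",
    "inject_missingness",
    "split_stratified",
]

SURVEY_COLUMNS = [
    "rid", "sex", "age", "edugr", "stype", "fam", "work", "hhn",
    "inc_hh", "sph", "chr", "gali", "mo", "sc", "ua", "pd", "ad", "eq5i",
]

#: age-group bin edges (years, right-open) used for stratification
AGE_GROUP_EDGES = np.array([18, 25, 35, 45, 55, 65, 75, 85, 96])


class ConfigurationError(ValueError):
    """A configuration references something unknown or inconsistent."""


class CalibrationError(ValueError):
    """The requested latent correlation structure is unsatisfiable."""


def _cuts(probs: Sequence[float]) -> np.ndarray:
    """Standard-normal thresholds realising the given category probabilities."""
    c = np.cumsum(probs)[:-1]
    return stats.norm.ppf(c)


# ---------------------------------------------------------------------------
# configuration

#: marginal category probabilities (survey training-sample composition)
DEFAULT_CATEGORY_DISTRIBUTIONS: dict[str, tuple[float, ...]] = {
    # 1 = female, 2 = male
    "sex": (0.528, 0.472),
    # eight age groups 18-24 .. 85+
    "age_group": (0.072, 0.117, 0.178, 0.179, 0.201, 0.193, 0.053, 0.007),
    # 1 primary, 2 secondary, 3 tertiary
    "edugr": (0.170, 0.593, 0.237),
    # 1 capital, 2 town, 3 village
    "stype": (0.200, 0.532, 0.268),
    # 1 married/partnered, 2 single, 3 widowed/divorced
    "fam": (0.55, 0.27, 0.18),
    # 1 employed, 2 retired, 3 other inactive
    "work": (0.55, 0.30, 0.15),
    # self-perceived health 1 very good .. 5 very bad
    "sph": (0.17, 0.36, 0.31, 0.12, 0.04),
    # activity limitation 1 severe .. 3 none
    "gali": (0.08, 0.27, 0.65),
    # chronic morbidity prevalence P(chr = 1)
    "chr": (0.40,),
    # per-dimension EQ-5D level probabilities 1..5 (shared across dimensions)
    "dim": (0.60, 0.21, 0.14, 0.036, 0.014),
}

#: latent-model coefficients frozen by the calibration script
DEFAULT_LATENT_MODEL: dict[str, float] = {
    "lam_dim": 0.75,    # loading of each EQ-5D dimension on the health score
    "lam_sph": 0.71,    # loading of self-perceived health (sign flipped)
    "lam_gali": 0.79,   # loading of activity limitation
    "lam_chr": 0.595,   # loading of chronic morbidity (sign flipped)
    "r_age_health": -0.32,   # latent corr(age, health)
    "r_inc_health": 0.34,    # latent corr(log-income, health)
    "r_age_inc": -0.05,      # latent corr(age, log-income)
    "income_median": 300.0,  # thousand HUF / month, household
    "income_sigma": 0.50,    # log-scale spread of household income
}

DEFAULT_TARGET_CORRELATIONS: dict[str, float] = {
    "gali": 0.61, "sph": -0.56, "chr": -0.39, "inc_hh": 0.23,
}


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of the synthetic survey generator."""

    n: int = 10_000
    seed: int = 0
    category_distributions: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_DISTRIBUTIONS)
    )
    latent_model: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENT_MODEL)
    )
    target_correlations: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TARGET_CORRELATIONS)
    )
    ceiling_share: float = 0.70
    value_set: ValueSet | None = None  # None -> bundled default

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        if not 0 < self.ceiling_share < 1:
            raise ConfigurationError("ceiling_share must lie in (0, 1)")
        for var, probs in self.category_distributions.items():
            if var == "chr":
                if not 0 <= probs[0] <= 1:
                    raise ConfigurationError("chr prevalence outside [0, 1]")
                continue
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"category probabilities for {var!r} sum to {sum(probs)}, not 1"
                )
        for var, r in self.target_correlations.items():
            if not -1 < r < 1:
                raise ConfigurationError(
                    f"target correlation for {var!r} must lie in (-1, 1), got {r}"
                )


def _latent_corr_matrix(lm: Mapping[str, float]) -> np.ndarray:
    """3x3 correlation of (age, log-income, health); must be positive definite."""
    r = np.array([
        [1.0, lm["r_age_inc"], lm["r_age_health"]],
        [lm["r_age_inc"], 1.0, lm["r_inc_health"]],
        [lm["r_age_health"], lm["r_inc_health"], 1.0],
    ])
    if np.linalg.eigvalsh(r).min() <= 1e-10:
        pairs = {
            ("age", "inc_hh"): lm["r_age_inc"],
            ("age", "health"): lm["r_age_health"],
            ("inc_hh", "health"): lm["r_inc_health"],
        }
        worst = max(pairs, key=lambda p: abs(pairs[p]))
        raise CalibrationError(
            "latent correlation matrix is not positive definite; "
            f"largest-magnitude pair is {worst} = {pairs[worst]:+.3f}"
        )
    return r


def age_group(age: "np.ndarray | pd.Series") -> np.ndarray:
    """Bin age in years into the eight survey age groups (1..8)."""
    return np.digitize(np.asarray(age), AGE_GROUP_EDGES[1:-1], right=False) + 1


# ---------------------------------------------------------------------------
# generation

def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Generate ``config.n`` complete survey records.

    Returns a DataFrame with columns ``rid, sex, age, edugr, stype, fam,
    work, hhn, inc_hh, sph, chr, gali, mo, sc, ua, pd, ad, eq5i`` and no
    missing cells; ``eq5i`` is the value-set score of the generated
    five-dimension state.
    """
    vs = config.value_set if config.value_set is not None else default_value_set()
    if not isinstance(vs, ValueSet):
        raise ConfigurationError(f"unknown value set reference: {vs!r}")
    cat = config.category_distributions
    lm = config.latent_model
    n = config.n
    rng = np.random.default_rng(config.seed)

    corr = _latent_corr_matrix(lm)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 3)) @ chol.T
    z_age, z_inc, z_h = z[:, 0], z[:, 1], z[:, 2]

    # age: inverse-CDF through the age-group histogram, uniform within group
    group_probs = np.asarray(cat["age_group"])
    cum = np.concatenate([[0.0], np.cumsum(group_probs)])
    cum[-1] = 1.0
    u_age = stats.norm.cdf(z_age)
    grp = np.clip(np.searchsorted(cum, u_age, side="right") - 1, 0, 7)
    frac = (u_age - cum[grp]) / np.maximum(cum[grp + 1] - cum[grp], 1e-12)
    lo, hi = AGE_GROUP_EDGES[grp], AGE_GROUP_EDGES[grp + 1]
    age = np.floor(lo + frac * (hi - lo)).astype(int).clip(18, 95)

    inc_hh = np.round(
        lm["income_median"] * np.exp(lm["income_sigma"] * z_inc), 1
    )

    def ordinal(loading: float, probs: Sequence[float], healthier_high: bool) -> np.ndarray:
        """Ordinal cut of a noisy projection of the health score."""
        sgn = 1.0 if healthier_high else -1.0
        lat = loading * sgn * z_h + np.sqrt(1 - loading**2) * rng.standard_normal(n)
        return (np.searchsorted(_cuts(probs), lat, side="right") + 1).astype(int)

    dims = {
        d: ordinal(lm["lam_dim"], cat["dim"], healthier_high=False)
        for d in ("mo", "sc", "ua", "pd", "ad")
    }
    sph = ordinal(lm["lam_sph"], cat["sph"], healthier_high=False)
    gali = ordinal(lm["lam_gali"], cat["gali"], healthier_high=True)
    chr_lat = lm["lam_chr"] * -z_h + np.sqrt(1 - lm["lam_chr"] ** 2) * rng.standard_normal(n)
    chr_ = (chr_lat > stats.norm.ppf(1 - cat["chr"][0])).astype(int)

    sex = rng.choice([1, 2], size=n, p=cat["sex"])
    edugr = rng.choice([1, 2, 3], size=n, p=cat["edugr"])
    stype = rng.choice([1, 2, 3], size=n, p=cat["stype"])
    fam = rng.choice([1, 2, 3], size=n, p=cat["fam"])
    # employment follows age: retirement probability rises around 62
    p_ret = special.expit((age - 62) / 4.0)
    work = np.where(
        rng.random(n) < p_ret, 2,
        np.where(rng.random(n) < cat["work"][2] / (cat["work"][0] + cat["work"][2]), 3, 1),
    )
    hhn = np.clip(1 + rng.poisson(1.3, size=n), 1, 10)

    levels = np.column_stack([dims[d] for d in ("mo", "sc", "ua", "pd", "ad")])
    eq5i = np.round(vs.index_array(levels), 6)

    table = pd.DataFrame({
        "rid": np.arange(n),
        "sex": sex, "age": age, "edugr": edugr, "stype": stype,
        "fam": fam, "work": work, "hhn": hhn,
        "inc_hh": inc_hh, "sph": sph, "chr": chr_, "gali": gali,
        "mo": dims["mo"], "sc": dims["sc"], "ua": dims["ua"],
        "pd": dims["pd"], "ad": dims["ad"],
        "eq5i": eq5i,
    })
    return table


# ---------------------------------------------------------------------------
# missingness

@dataclass(frozen=True)
class MissingnessSpec:
    """Per-variable missingness mechanisms.

    ``mechanisms`` maps a column name to either ``("mcar", rate)`` or
    ``("mar", rate, drivers, coefficients)`` where ``rate`` is the mean
    missingness probability, ``drivers`` the observed columns the
    logistic nonresponse model depends on (standardised within the
    table), and ``coefficients`` the matching slopes; the intercept is
    solved so the expected rate equals ``rate``.  ``eq5i`` may never be
    targeted, and MAR driver columns must themselves have no mechanism.
    """

    mechanisms: Mapping[str, tuple] = field(default_factory=dict)
    max_rate: float = 0.22

    def __post_init__(self) -> None:
        driver_cols: set[str] = set()
        for col, mech in self.mechanisms.items():
            if col == "eq5i":
                raise ValueError("the outcome eq5i may not be made missing")
            kind, rate = mech[0], mech[1]
            if kind not in ("mcar", "mar"):
                raise ValueError(f"unknown mechanism {kind!r} for {col!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"rate for {col!r} outside [0, 1]: {rate}")
            if rate > self.max_rate + 1e-12:
                raise ValueError(
                    f"rate for {col!r} ({rate}) exceeds the per-variable "
                    f"maximum {self.max_rate}"
                )
            if kind == "mar":
                driver_cols.update(mech[2])
        for d in driver_cols:
            mech = self.mechanisms.get(d)
            if mech is not None and mech[1] > 0:
                raise ValueError(
                    f"MAR driver column {d!r} is itself made missing by this spec"
                )

    @property
    def mean_rate(self) -> float:
        rates = [m[1] for m in self.mechanisms.values()]
        return float(np.mean(rates)) if rates else 0.0


def default_missingness_spec() -> MissingnessSpec:
    """Defaults: 3% of cells missing on average, income MAR at 22%.

    Non-recorded items are MCAR; income nonresponse is MAR, driven by
    self-perceived health with a positive slope (worse health, more
    nonresponse), so ``sph`` itself is kept fully observed.  Rates over
    the 16 non-outcome columns average exactly 0.03.
    """
    mechanisms: dict[str, tuple] = {
        "inc_hh": ("mar", 0.22, ("sph",), (0.8,)),
        "gali": ("mcar", 0.03),
        "chr": ("mcar", 0.03),
        "fam": ("mcar", 0.04),
        "work": ("mcar", 0.04),
        "hhn": ("mcar", 0.04),
        "edugr": ("mcar", 0.02),
        "stype": ("mcar", 0.02),
        "mo": ("mcar", 0.008),
        "sc": ("mcar", 0.008),
        "ua": ("mcar", 0.008),
        "pd": ("mcar", 0.008),
        "ad": ("mcar", 0.008),
        # sex, age, sph: never missing (strata columns / MAR driver)
    }
    return MissingnessSpec(mechanisms=mechanisms)


def inject_missingness(
    table: pd.DataFrame, spec: MissingnessSpec, seed: int
) -> pd.DataFrame:
    """Blank cells of a copy of ``table`` according to ``spec``.

    Observed cells keep their values; ``eq5i`` is untouched.  MAR
    nonresponse probability is logistic in the standardised driver
    columns with the intercept solved so the mean probability equals the
    configured rate.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col, mech in spec.mechanisms.items():
        if col not in table.columns:
            raise ValueError(f"missingness target column {col!r} not in table")
        kind, rate = mech[0], mech[1]
        if rate == 0:
            continue
        if kind == "mcar":
            mask = rng.random(len(table)) < rate
        else:
            drivers, coefs = mech[2], mech[3]
            missing_drivers = [d for d in drivers if d not in table.columns]
            if missing_drivers:
                raise ValueError(f"MAR driver columns missing: {missing_drivers}")
            eta = np.zeros(len(table))
            for d, c in zip(drivers, coefs):
                v = table[d].to_numpy(dtype=float)
                sd = v.std()
                eta += c * (v - v.mean()) / (sd if sd > 0 else 1.0)
            # intercept such that mean probability hits the target rate
            b0 = optimize.brentq(
                lambda b: special.expit(b + eta).mean() - rate, -30, 30
            )
            mask = rng.random(len(table)) < special.expit(b0 + eta)
        out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# splitting

@dataclass(frozen=True)
class SplitSpec:
    """Stratified split configuration (default 60/20/20 by sex x age group)."""

    ratios: tuple[float, float, float] = (0.60, 0.20, 0.20)
    strata: tuple[str, ...] = ("sex", "age_group")
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"split ratios sum to {sum(self.ratios)}, not 1")


def _largest_remainder(n: int, ratios: Sequence[float]) -> np.ndarray:
    exact = np.asarray(ratios) * n
    base = np.floor(exact).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:rem]] += 1
    return base


def split_stratified(
    table: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split into (train, validation, test) stratified by ``spec.strata``.

    Within every stratum the subset counts follow the ratios with
    largest-remainder rounding; strata smaller than 3 are assigned as a
    whole by one ratio-weighted draw (with a warning).  Deterministic
    given ``spec.seed``.
    """
    spec = spec or SplitSpec()
    rng = np.random.default_rng(spec.seed)
    keys = pd.DataFrame(index=table.index)
    for col in spec.strata:
        if col == "age_group" and "age_group" not in table.columns:
            if "age" not in table.columns:
                raise ValueError("stratum column 'age'/'age_group' missing")
            keys[col] = age_group(table["age"])
        else:
            if col not in table.columns:
                raise ValueError(f"stratum column {col!r} missing from table")
            if table[col].isna().any():
                raise ValueError(f"stratum column {col!r} contains missing values")
            keys[col] = table[col]

    assignment = np.empty(len(table), dtype=int)
    pos = {idx: i for i, idx in enumerate(table.index)}
    for _, idx in sorted(
        keys.groupby(list(spec.strata), sort=True).groups.items(),
        key=lambda kv: str(kv[0]),
    ):
        rows = np.array([pos[i] for i in idx])
        if len(rows) < 3:
            warnings.warn(
                f"stratum with {len(rows)} respondent(s) assigned by one "
                "weighted draw", stacklevel=2,
            )
            assignment[rows] = rng.choice(3, p=spec.ratios)
            continue
        counts = _largest_remainder(len(rows), spec.ratios)
        perm = rng.permutation(len(rows))
        labels = np.repeat([0, 1, 2], counts)
        assignment[rows[perm]] = labels
    parts = tuple(
        table.iloc[assignment == j].reset_index(drop=True) for j in range(3)
    )
    return parts  # type: ignore[return-value]
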