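"""Variability estimation, lognormal machinery and the shared/unshared budget.

Uncertainty of a dose factor splits into two classes.  *Unshared* (inherent)
components reflect true individual variability — bone micro/macro
architecture, tissue density, chemical composition, and the distribution of
active marrow over the skeleton — and differ from person to person.
*Shared* (introduced) components come from modelling simplifications — shape
stylization, voxelization, restricted segment geometry and the uniform
cortical-shell assumption — and are common to every individual evaluated
with the model.  Components are combined in quadrature within each class and
the two class totals combine in quadrature into the overall uncertainty.

Segment-level dose-factor distributions are treated as lognormal; the
(mu, s) parameterization used throughout is

    mu = ln(mean / sqrt(cv^2 + 1)),   s = sqrt(ln(cv^2 + 1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


# ---------------------------------------------------------------------------
# lognormal machinery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LognormalDF:
    """Lognormal distribution stated by its arithmetic mean and CV."""

    mu: float
    s: float

    @property
    def mean(self) -> float:
        return math.exp(self.mu + 0.5 * self.s * self.s)

    @property
    def cv(self) -> float:
        return math.sqrt(math.exp(self.s * self.s) - 1.0)

    def quantile(self, p: float) -> float:
        from scipy import stats
        return math.exp(self.mu + float(stats.norm.ppf(p)) * self.s)

    def ci90(self) -> tuple[float, float]:
        return self.quantile(0.05), self.quantile(0.95)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.lognormal(self.mu, self.s, size=n)


def lognormal_from_mean_cv(mean: float, cv: float) -> LognormalDF:
    """Lognormal parameters matching an arithmetic mean and a CV."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    s2 = math.log(cv * cv + 1.0)
    return LognormalDF(mu=math.log(mean) - 0.5 * s2, s=math.sqrt(s2))


# ---------------------------------------------------------------------------
# variability estimation and pooling
# ---------------------------------------------------------------------------

def variability_rmsd(df_true: float, df_samples: Sequence[float]) -> float:
    """Relative RMSD of randomized dose factors about the population value.

    The deviation is taken about the dose factor of the population-mean model
    (not the sample mean), so a biased sample contributes its bias.
    """
    s = np.asarray(df_samples, dtype=float)
    if s.size < 1:
        raise ValueError("empty sample")
    if df_true <= 0:
        raise ValueError("df_true must be > 0")
    return float(np.sqrt(np.mean((df_true - s) ** 2)) / df_true)


def pool_transform(
    df_samples: Sequence[float],
    df_true: float,
    sigma_var: float,
) -> np.ndarray:
    """Standardize segment dose factors for pooling across segments.

    DF~ = (DF_true - DF_sample) / sigma_var.  Pooled over segments whose DFs
    may differ by an order of magnitude, the standardized values share a mean
    near 0 and an SD near 1, making their distribution shape comparable.
    """
    if sigma_var <= 0:
        raise ValueError("sigma_var must be > 0")
    s = np.asarray(df_samples, dtype=float)
    return (df_true - s) / sigma_var


def fit_pooled_distribution(values: Sequence[float]) -> dict:
    """Fit normal and 3-parameter (shifted) lognormal models to pooled values.

    The shift parameter accommodates the negative tail of standardized
    values; both skew orientations are tried (standardizing deviations about
    the population value mirrors the skew of the underlying dose factors)
    and the better one is kept.  Returns parameters and log-likelihoods.
    """
    from scipy import stats

    v = np.asarray(values, dtype=float)
    loc_n, scale_n = stats.norm.fit(v)
    ll_norm = float(np.sum(stats.norm.logpdf(v, loc_n, scale_n)))

    best = None
    for sign in (1.0, -1.0):
        with np.errstate(invalid="ignore", divide="ignore"):
            shape, loc_l, scale_l = stats.lognorm.fit(sign * v)
            ll = float(np.sum(stats.lognorm.logpdf(sign * v, shape,
                                                   loc_l, scale_l)))
        if np.isfinite(ll) and (best is None or ll > best["loglik"]):
            best = {"shape": float(shape), "loc": float(loc_l),
                    "scale": float(scale_l), "loglik": ll,
                    "mirrored": sign < 0}
    return {
        "normal": {"loc": float(loc_n), "scale": float(scale_n),
                   "loglik": ll_norm},
        "lognormal3": best,
        "preferred": "lognormal3"
        if best is not None and best["loglik"] > ll_norm else "normal",
    }


# ---------------------------------------------------------------------------
# uncertainty budget
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BudgetComponent:
    """One named uncertainty contribution with its shared/unshared class."""

    label: str
    delta: float  # relative standard uncertainty, fraction
    shared: bool

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


def compose_budget(
    components: Sequence[BudgetComponent],
) -> tuple[float, float, float]:
    """Quadrature totals: (delta_shared, delta_unshared, delta_overall)."""
    sh = math.sqrt(sum(c.delta ** 2 for c in components if c.shared))
    un = math.sqrt(sum(c.delta ** 2 for c in components if not c.shared))
    return sh, un, math.hypot(sh, un)


# stylization uncertainty by size class (fraction); the largest classes are
# insensitive to shape and size, so stylization is neglected for them
_STYLIZATION = {
    "TBV1": None, "TBV2": 0.15, "TBV3": 0.13, "TBV4": 0.07,
    "CBV1": None, "CBV2": 0.15, "CBV3": 0.10, "CBV4": 0.14,
    "CBV5": 0.09, "CBV6": 0.04,
}

#: classes whose circumscribed-box edges all exceed the 1.1 cm pathlength cut;
#: these behave as "large" for the density budget
_LARGE_CLASSES = {"TBV1", "CBV1", "CBV2", "CBV3"}

VOXELIZATION_DELTA = 0.01
CORTICAL_UNIFORMITY_DELTA = 0.07
CHEMICAL_COMPOSITION_DELTA = 0.04
MICROARCHITECTURE_DELTA_DEFAULT = 0.20  # mean over segments; true range 5-60%
RESTRICTION_DELTA = 0.05

_DENSITY = {
    ("TBV", True): 0.04,   # large segments, trabecular source
    ("TBV", False): 0.06,  # small segments, trabecular source
    ("CBV", True): 0.0,    # large segments, cortical source: negligible
    ("CBV", False): 0.13,  # small segments, cortical source
}


def budget_lookup(
    size_class,
    source: str | None = None,
    micro_delta: float | None = None,
    restricted: bool = False,
) -> list[BudgetComponent]:
    """Applicable budget components for a segment of a given size class.

    ``size_class`` is a class name ("TBV2", "CBV4", ...) or an enum with a
    matching ``value``.  ``micro_delta`` overrides the default 20% micro- and
    macro-architecture variability with a segment-specific estimate (e.g.
    from :func:`variability_rmsd`).  ``restricted`` adds the crossfire
    adjustment uncertainty for segments cut out of larger bones.
    """
    name = getattr(size_class, "value", size_class)
    if name not in _STYLIZATION:
        raise KeyError(f"unknown size class {name!r}")
    src = source or name[:3]
    if src not in ("TBV", "CBV"):
        raise ValueError(f"source must be 'TBV' or 'CBV', got {src!r}")

    comps: list[BudgetComponent] = []
    styl = _STYLIZATION[name]
    if styl is not None:
        comps.append(BudgetComponent("shape_stylization", styl, shared=True))
    comps.append(BudgetComponent("voxelization", VOXELIZATION_DELTA, shared=True))
    if restricted:
        comps.append(BudgetComponent("model_restriction", RESTRICTION_DELTA,
                                     shared=True))
    if src == "CBV":
        comps.append(BudgetComponent("cortical_uniformity",
                                     CORTICAL_UNIFORMITY_DELTA, shared=True))
    comps.append(BudgetComponent(
        "microarchitecture_variability",
        MICROARCHITECTURE_DELTA_DEFAULT if micro_delta is None else micro_delta,
        shared=False))
    comps.append(BudgetComponent("chemical_composition",
                                 CHEMICAL_COMPOSITION_DELTA, shared=False))
    dens = _DENSITY[(src, name in _LARGE_CLASSES)]
    if dens > 0:
        comps.append(BudgetComponent("bone_density", dens, shared=False))
    return comps
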