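"""Bone-segment domain model and the stochastic individual-variability sampler.

A hematopoietic bone segment is described by a stylized outer shape, a
cortical shell of mean thickness ``Ct.Th`` covering a subset of its surfaces,
and a rod-like trabecular microarchitecture summarized by mean trabecular
thickness ``Tb.Th``, mean trabecular separation ``Tb.Sp`` and the bone volume
fraction of spongiosa ``BV/TV``.  Individual (person-to-person) variability of
these parameters is modelled with truncated correlated distributions: normal
marginals for macroscopic linear dimensions and cortical thickness, lognormal
marginals for the microarchitecture parameters.  Macro parameters are
positively correlated with each other; ``Tb.Th`` and ``Tb.Sp`` are negatively
correlated (thinner trabeculae tend to be spaced further apart).

Correlated draws use a Gaussian copula: correlated standard normals are drawn
first, truncated to the central confidence mass (default 90%, i.e. the 10%
tail mass is treated as outliers and redrawn), and then mapped through each
marginal's quantile transform.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


class ShapeKind(enum.Enum):
    BOX = "box"
    ELLIPTIC_CYLINDER = "elliptic_cylinder"
    DEFORMED_CYLINDER = "deformed_cylinder"
    ELLIPSOID = "ellipsoid"
    TRIANGULAR_PYRAMID = "triangular_pyramid"
    TUBE = "tube"


#: number of dims each shape kind expects
DIM_COUNTS = {
    ShapeKind.BOX: 3,                  # three edges
    ShapeKind.ELLIPTIC_CYLINDER: 3,    # a x b x H (full axes of the elliptic base)
    ShapeKind.DEFORMED_CYLINDER: 5,    # a x b x c x d x H (two elliptic bases)
    ShapeKind.ELLIPSOID: 3,            # l x m x n (full axes)
    ShapeKind.TRIANGULAR_PYRAMID: 3,   # base legs a, b and height H
    ShapeKind.TUBE: 3,                 # inner radius, outer radius, H
}

#: number of distinct surfaces (for cortical coverage masks)
SURFACE_COUNTS = {
    ShapeKind.BOX: 6,                  # -x, +x, -y, +y, -z, +z faces
    ShapeKind.ELLIPTIC_CYLINDER: 3,    # lateral, bottom, top
    ShapeKind.DEFORMED_CYLINDER: 3,    # lateral, bottom, top
    ShapeKind.ELLIPSOID: 1,
    ShapeKind.TRIANGULAR_PYRAMID: 4,   # base + three slant faces
    ShapeKind.TUBE: 4,                 # outer lateral, inner lateral, bottom, top
}


@dataclass(frozen=True)
class ShapeSpec:
    """Stylized segment shape: a kind plus its ordered linear dimensions (cm).

    Dimension conventions: ``a x b x H`` for elliptic cylinders (a, b full
    axes of the base), ``a x b x c x d x H`` for deformed cylinders (a, c the
    major and b, d the minor full axes of the two bases), ``l x m x n`` full
    axes for ellipsoids, three edges for boxes, base legs plus height for
    triangular pyramids, and (inner radius, outer radius, height) for tubes.
    """

    kind: ShapeKind
    dims: tuple[float, ...]

    def __post_init__(self) -> None:
        kind = ShapeKind(self.kind)
        object.__setattr__(self, "kind", kind)
        dims = tuple(float(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        if len(dims) != DIM_COUNTS[kind]:
            raise ValueError(
                f"{kind.value} expects {DIM_COUNTS[kind]} dims, got {len(dims)}"
            )
        if any(d <= 0 for d in dims):
            raise ValueError(f"all dims must be > 0, got {dims}")
        if kind is ShapeKind.TUBE and dims[0] >= dims[1]:
            raise ValueError("tube inner radius must be smaller than outer radius")

    @property
    def surface_count(self) -> int:
        return SURFACE_COUNTS[self.kind]

    @property
    def circumscribed_box(self) -> tuple[float, float, float]:
        """Edges of the axis-aligned box circumscribing the shape (cm)."""
        d = self.dims
        if self.kind is ShapeKind.BOX:
            return d
        if self.kind in (ShapeKind.ELLIPTIC_CYLINDER, ShapeKind.ELLIPSOID,
                         ShapeKind.TRIANGULAR_PYRAMID):
            return d
        if self.kind is ShapeKind.DEFORMED_CYLINDER:
            a, b, c, dd, h = d
            # bottom major axis along x, top major axis along y
            return (max(a, dd), max(b, c), h)
        if self.kind is ShapeKind.TUBE:
            return (2 * d[1], 2 * d[1], d[2])
        raise AssertionError(self.kind)


@dataclass(frozen=True)
class MicroSpec:
    """Spongiosa microarchitecture summary.

    All lengths in cm.  ``tb_th_sd`` / ``tb_sp_sd`` are the intra-specimen
    standard deviations of individual trabecular thickness and separation.
    ``bvtv_range`` is the admissible (min, max) interval for the bone volume
    fraction; generated realizations are constrained to stay inside it.
    """

    tb_th: float
    tb_th_sd: float
    tb_sp: float
    tb_sp_sd: float
    bvtv: float
    bvtv_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not (0 <= self.bvtv < 1):
            raise ValueError(f"bvtv must be in [0, 1), got {self.bvtv}")
        lo, hi = self.bvtv_range
        if not (lo <= self.bvtv <= hi):
            raise ValueError(f"bvtv_range {self.bvtv_range} must contain bvtv={self.bvtv}")
        if self.tb_th < 0 or self.tb_sp < 0 or self.tb_th_sd < 0 or self.tb_sp_sd < 0:
            raise ValueError("microarchitecture lengths must be nonnegative")


@dataclass(frozen=True)
class VariabilityModel:
    """Individual-variability model for one segment.

    ``macro_cv`` is the coefficient of variation of each linear dimension
    (scalar applied to all dims, or one value per dim); ``ct_th_cv`` that of
    the cortical thickness.  Macro parameters follow truncated normals.
    ``tb_th_cv`` / ``tb_sp_cv`` parameterize truncated lognormals for the
    microarchitecture.  ``macro_corr`` is the common pairwise correlation of
    the macro block (positive), ``micro_corr`` the Tb.Th-Tb.Sp correlation
    (negative).  ``truncation`` is the central confidence mass retained.
    """

    macro_cv: float | tuple[float, ...] = 0.0
    ct_th_cv: float = 0.0
    tb_th_cv: float = 0.0
    tb_sp_cv: float = 0.0
    macro_corr: float = 0.5
    micro_corr: float = -0.5
    truncation: float = 0.90

    def __post_init__(self) -> None:
        cvs = list(np.atleast_1d(self.macro_cv)) + [
            self.ct_th_cv, self.tb_th_cv, self.tb_sp_cv]
        if any(c < 0 for c in cvs):
            raise ValueError("CVs must be >= 0")
        if not (abs(self.macro_corr) < 1 and abs(self.micro_corr) < 1):
            raise ValueError("|correlations| must be < 1")
        if not (0 < self.truncation <= 1):
            raise ValueError("truncation must be in (0, 1]")

    def macro_cvs(self, ndims: int) -> np.ndarray:
        cv = np.atleast_1d(np.asarray(self.macro_cv, dtype=float))
        if cv.size == 1:
            return np.full(ndims, cv[0])
        if cv.size != ndims:
            raise ValueError(f"macro_cv has {cv.size} entries for {ndims} dims")
        return cv


@dataclass(frozen=True)
class SegmentSpec:
    """One bone segment: shape, cortical shell, microarchitecture, marrow mass."""

    site_id: str
    segment_id: str
    shape: ShapeSpec
    ct_th: float
    micro: MicroSpec
    marrow_mass: float
    cortical_coverage: tuple[bool, ...] | None = None
    variability: VariabilityModel = field(default_factory=VariabilityModel)

    def __post_init__(self) -> None:
        if self.ct_th < 0:
            raise ValueError("ct_th must be >= 0")
        if self.marrow_mass <= 0:
            raise ValueError("marrow_mass must be > 0")
        cov = self.cortical_coverage
        if cov is None:
            cov = tuple(True for _ in range(self.shape.surface_count))
        else:
            cov = tuple(bool(c) for c in cov)
            if len(cov) != self.shape.surface_count:
                raise ValueError(
                    f"coverage mask length {len(cov)} does not match the "
                    f"{self.shape.surface_count} surfaces of a {self.shape.kind.value}"
                )
        object.__setattr__(self, "cortical_coverage", cov)


# ---------------------------------------------------------------------------
# correlated truncated sampling
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    s2 = math.log(cv * cv + 1.0)
    mu = math.log(mean) - 0.5 * s2
    return mu, math.sqrt(s2)


def implied_bvtv(micro: MicroSpec, tb_th: float, tb_sp: float) -> float:
    """BV/TV implied by a (Tb.Th, Tb.Sp) realization.

    For an orthogonal rod lattice the bone volume fraction scales as the rod
    cross-section over the squared lattice period, f ~ Tb.Th^2 / (Tb.Sp+Tb.Th)^2.
    The value is anchored so that the population-mean microarchitecture maps
    exactly onto the population-mean BV/TV.
    """
    l0 = micro.tb_sp + micro.tb_th
    l1 = tb_sp + tb_th
    return micro.bvtv * (tb_th / micro.tb_th) ** 2 * (l0 / l1) ** 2


def _truncated_correlated_normals(
    rng: np.random.Generator,
    n: int,
    corr: np.ndarray,
    z_cut: float,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Draw n vectors of correlated standard normals, every coordinate within
    +/- z_cut (componentwise rejection, redrawing whole vectors)."""
    k = corr.shape[0]
    chol = np.linalg.cholesky(corr)
    out = np.empty((n, k))
    filled = 0
    attempts = 0
    while filled < n:
        m = max(n - filled, 64)
        z = rng.standard_normal((m, k)) @ chol.T
        ok = np.all(np.abs(z) <= z_cut, axis=1)
        z = z[ok]
        take = min(len(z), n - filled)
        out[filled:filled + take] = z[:take]
        filled += take
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("truncated sampling did not converge")
    return out


def _corr_matrix(k: int, rho: float) -> np.ndarray:
    c = np.full((k, k), rho)
    np.fill_diagonal(c, 1.0)
    return c


class BvtvRangeError(RuntimeError):
    """Raised when no microarchitecture draw satisfies the BV/TV range."""


def sample_segment_params(
    spec: SegmentSpec,
    n: int,
    seed: int,
    max_resample: int = 1000,
) -> list[SegmentSpec]:
    """Draw ``n`` individual-variability realizations of a segment.

    Macro dims and cortical thickness are drawn from correlated truncated
    normals; Tb.Th and Tb.Sp from negatively correlated truncated lognormals.
    Each realization's implied BV/TV is checked against ``micro.bvtv_range``
    and rejected draws are resampled (up to ``max_resample`` attempts per
    realization).  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    var = spec.variability
    rng = np.random.default_rng(seed)
    ndims = len(spec.shape.dims)
    macro_cvs = var.macro_cvs(ndims)

    from scipy import stats

    if var.truncation >= 1.0:
        z_cut = np.inf
        inflate = 1.0
    else:
        z_cut = float(stats.norm.ppf(0.5 + var.truncation / 2.0))
        # symmetric truncation at +/- z_cut shrinks the SD; inflate the
        # underlying scale so realized draws carry the stated CVs
        mass = 2.0 * stats.norm.cdf(z_cut) - 1.0
        shrink = math.sqrt(1.0 - 2.0 * z_cut * stats.norm.pdf(z_cut) / mass)
        inflate = 1.0 / shrink

    macro_corr = _corr_matrix(ndims + 1, var.macro_corr)  # dims + ct_th
    micro_corr = _corr_matrix(2, var.micro_corr)

    mu_th, s_th = (0.0, 0.0)
    mu_sp, s_sp = (0.0, 0.0)
    if var.tb_th_cv > 0:
        mu_th, s_th = _lognormal_params(spec.micro.tb_th, var.tb_th_cv)
        s_th *= inflate
    if var.tb_sp_cv > 0:
        mu_sp, s_sp = _lognormal_params(spec.micro.tb_sp, var.tb_sp_cv)
        s_sp *= inflate

    dims0 = np.asarray(spec.shape.dims)
    out: list[SegmentSpec] = []
    for _ in range(n):
        # macro block: dims then ct_th
        z = _truncated_correlated_normals(rng, 1, macro_corr, z_cut)[0]
        for attempt in range(max_resample):
            dims = dims0 * (1.0 + macro_cvs * inflate * z[:ndims])
            ct_th = spec.ct_th * (1.0 + var.ct_th_cv * inflate * z[ndims])
            if np.all(dims > 0) and ct_th >= 0:
                break
            z = _truncated_correlated_normals(rng, 1, macro_corr, z_cut)[0]
        else:
            raise RuntimeError(
                f"segment {spec.segment_id}: could not draw positive macro dims")

        # micro block: (tb_th, tb_sp) with negative correlation
        for attempt in range(max_resample):
            zm = _truncated_correlated_normals(rng, 1, micro_corr, z_cut)[0]
            tb_th = (math.exp(mu_th + s_th * zm[0])
                     if var.tb_th_cv > 0 else spec.micro.tb_th)
            tb_sp = (math.exp(mu_sp + s_sp * zm[1])
                     if var.tb_sp_cv > 0 else spec.micro.tb_sp)
            bvtv = implied_bvtv(spec.micro, tb_th, tb_sp)
            lo, hi = spec.micro.bvtv_range
            if lo <= bvtv <= hi:
                break
        else:
            raise BvtvRangeError(
                f"segment {spec.segment_id}: no (Tb.Th, Tb.Sp) draw satisfied "
                f"bvtv_range {spec.micro.bvtv_range} after {max_resample} attempts")

        micro = replace(spec.micro, tb_th=tb_th, tb_sp=tb_sp, bvtv=bvtv)
        shape = ShapeSpec(spec.shape.kind, tuple(dims))
        out.append(replace(spec, shape=shape, ct_th=ct_th, micro=micro))
    return out


# ---------------------------------------------------------------------------
# minimum sample size via bootstrap variance-of-variance
# ---------------------------------------------------------------------------

def normalized_rmsd(df_true: float, df_samples: Sequence[float]) -> float:
    """Relative RMSD of dose-factor realizations about the population value."""
    s = np.asarray(df_samples, dtype=float)
    if s.size == 0:
        raise ValueError("empty sample")
    if df_true <= 0:
        raise ValueError("df_true must be > 0")
    return float(np.sqrt(np.mean((df_true - s) ** 2)) / df_true)


def min_sample_size(
    df_samples: Sequence[float],
    df_true: float | None = None,
    threshold: float = 0.15,
    n_grid: Sequence[int] | None = None,
    n_boot: int = 500,
    seed: int = 0,
    min_n: int = 5,
) -> tuple[int, dict[int, float]]:
    """Smallest sample size at which the normalized-RMSD estimator stabilizes.

    For each candidate size ``n`` the relative variance of the normalized RMSD
    estimator (VOV) is estimated by bootstrap resampling of the supplied dose
    factor realizations.  Returns the smallest ``n`` with VOV below
    ``threshold`` together with the full VOV-vs-n curve.
    """
    s = np.asarray(df_samples, dtype=float)
    if s.size < 20:
        raise ValueError(f"need at least 20 DF realizations, got {s.size}")
    if df_true is None:
        df_true = float(np.mean(s))
    if n_grid is None:
        n_grid = range(min_n, s.size + 1)
    n_grid = sorted(set(int(n) for n in n_grid))
    if n_grid[-1] > s.size:
        raise ValueError(
            f"requested sample size {n_grid[-1]} exceeds the {s.size} "
            "available realizations")

    rng = np.random.default_rng(seed)
    rel_dev2 = ((df_true - s) / df_true) ** 2
    if np.allclose(rel_dev2, 0.0):
        # constant series: the estimator has zero variance at any n
        return n_grid[0], {n: 0.0 for n in n_grid}

    curve: dict[int, float] = {}
    for n in n_grid:
        idx = rng.integers(0, s.size, size=(n_boot, n))
        delta = np.sqrt(np.mean(rel_dev2[idx], axis=1))
        m = np.mean(delta)
        curve[n] = float(np.var(delta) / (m * m)) if m > 0 else 0.0

    for n in n_grid:
        if curve[n] < threshold:
            return n, curve
    raise RuntimeError(
        f"VOV never fell below {threshold} for sample sizes up to {n_grid[-1]}")
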