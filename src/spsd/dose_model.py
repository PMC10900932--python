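"""Analytic dose-factor model for bone-marrow dosimetry of 89Sr and 90Sr(+90Y).

Dose factors DF(AM<-TBV) and DF(AM<-CBV) convert the radionuclide activity
concentration in trabecular or cortical bone (Bq/g) into the dose rate in
active marrow (Gy/s).  All DF values here are carried on the 1e-11 scale,
i.e. a stored value of 5.92 means 5.92e-11 Gy/s per Bq/g of the parent
nuclide (for 90Sr the secular-equilibrium 90Y contribution is included but
normalization is per parent decay).

For segments whose spongiosa linear dimensions exceed two mean electron
pathlengths (~0.46 cm), DF(AM<-TBV) depends on the bone volume fraction only
and follows a saturating exponential in BV/TV.  DF(AM<-CBV) is obtained from
it through the cortical self-attenuation ratio, exponential in Ct.Th, times
the cortical-to-trabecular volume ratio.  Residual uncertainties of the fits
follow printed empirical laws.  Small segments additionally receive a
crossfire (restricted-geometry) adjustment driven by the spongiosa surface
area.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .phantom_geometry import AnalyticSolid, DerivedGeometry
from .uncertainty_engine import LognormalDF, lognormal_from_mean_cv

MEV_TO_J = 1.602176634e-13

#: BV/TV interval on which the TBV fit is defined
BVTV_FIT_INTERVAL = (0.01, 0.52)
#: Ct.Th interval (cm) on which the energy-ratio fit is defined
CTTH_FIT_INTERVAL = (0.01, 0.41)

#: average residual uncertainty of the cortical/trabecular energy-deposition
#: ratio (evaluated at Ct.Th = 0.21 cm; the residuals range from 4% to 20%)
ENERGY_RATIO_DELTA = 0.10


@dataclass(frozen=True)
class Nuclide:
    """Analytic constants of one strontium source nuclide.

    ``a_tbv``/``b_tbv`` parameterize DF(AM<-TBV) = a_tbv*(1 - exp(-b_tbv*BV/TV));
    ``a_f``/``b_f`` parameterize the cortical-to-trabecular energy-deposition
    ratio Fc(Ct.Th) = a_f*exp(-b_f*Ct.Th).
    """

    name: str
    a_tbv: float
    b_tbv: float
    a_f: float
    b_f: float


SR90 = Nuclide("Sr90", a_tbv=28.0, b_tbv=0.897, a_f=0.435, b_f=4.98)
SR89 = Nuclide("Sr89", a_tbv=13.9, b_tbv=1.06, a_f=0.431, b_f=6.915)

NUCLIDES: dict[str, Nuclide] = {"Sr90": SR90, "Sr89": SR89}


def get_nuclide(name: str | Nuclide) -> Nuclide:
    if isinstance(name, Nuclide):
        return name
    try:
        return NUCLIDES[name]
    except KeyError:
        raise KeyError(f"unknown nuclide {name!r}; known: {sorted(NUCLIDES)}")


def nuclide_registry_json() -> str:
    """Serialized read-only registry of the analytic nuclide constants."""
    return json.dumps({k: vars(v) for k, v in NUCLIDES.items()}, indent=2)


class Source(enum.Enum):
    TBV = "TBV"
    CBV = "CBV"


@dataclass(frozen=True)
class DoseFactor:
    """A dose factor with its relative standard uncertainty.

    ``value`` is on the 1e-11 (Gy/s per Bq/g of parent) scale; ``delta`` is a
    fraction.  ``distribution`` carries the matching lognormal parameters.
    """

    value: float
    nuclide: str
    source: Source
    delta: float

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("dose factor must be >= 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")

    @property
    def distribution(self) -> LognormalDF:
        return lognormal_from_mean_cv(self.value, self.delta)


# ---------------------------------------------------------------------------
# electron pathlength
# ---------------------------------------------------------------------------

def mean_free_path(bvtv) -> float | np.ndarray:
    """Mean electron pathlength (CSDA) in spongiosa, cm.

    lambda = 0.112 + 0.099*exp(-1.526*BV/TV); between 0.15 and 0.2 cm for
    physiological bone volume fractions.
    """
    b = np.asarray(bvtv, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("bvtv must lie in [0, 1]")
    out = 0.112 + 0.099 * np.exp(-1.526 * b)
    return float(out) if np.isscalar(bvtv) else out


def max_pathlength(bvtv) -> float | np.ndarray:
    """Maximum electron pathlength, approximately five mean pathlengths."""
    out = 5.0 * np.asarray(mean_free_path(bvtv))
    return float(out) if np.isscalar(bvtv) else out


# ---------------------------------------------------------------------------
# size classification
# ---------------------------------------------------------------------------

class SizeClass(enum.Enum):
    TBV1 = "TBV1"
    TBV2 = "TBV2"
    TBV3 = "TBV3"
    TBV4 = "TBV4"
    CBV1 = "CBV1"
    CBV2 = "CBV2"
    CBV3 = "CBV3"
    CBV4 = "CBV4"
    CBV5 = "CBV5"
    CBV6 = "CBV6"


def classify_segment(geom: DerivedGeometry) -> tuple[SizeClass, SizeClass]:
    """Assign the (TBV, CBV) size classes of a segment.

    Classification uses the circumscribed-box edges and the spongiosa volume
    V_s.  The volume rules dominate: a segment with V_s below the small-volume
    cut belongs to the smallest class regardless of its edges.
    """
    edges = np.asarray(geom.circumscribed_box, dtype=float)
    v_s = geom.v_s
    n_small = int(np.count_nonzero(edges < 1.1))

    if v_s < 1.1:
        tbv = SizeClass.TBV4
    elif n_small == 0:
        tbv = SizeClass.TBV1
    elif n_small == 1:
        tbv = SizeClass.TBV2
    else:
        tbv = SizeClass.TBV3

    if v_s < 0.2:
        cbv = SizeClass.CBV6
    elif np.all(edges > 2.8):
        cbv = SizeClass.CBV1
    elif np.all(edges > 1.5):
        cbv = SizeClass.CBV2
    elif np.all(edges > 1.1):
        cbv = SizeClass.CBV3
    elif v_s > 1.6:
        cbv = SizeClass.CBV4
    else:
        cbv = SizeClass.CBV5
    return tbv, cbv


# ---------------------------------------------------------------------------
# analytic dose factors
# ---------------------------------------------------------------------------

def df_tbv_uncertainty(df_value: float) -> float:
    """Residual relative uncertainty of the TBV fit as a function of DF.

    delta = 0.063 + 0.1*exp(-0.373*DF) with DF on the 1e-11 scale; decreases
    from ~15% at the lower end of the fit interval to 6.5% at the upper end.
    """
    if df_value < 0:
        raise ValueError("df_value must be >= 0 on the 1e-11 scale")
    return 0.063 + 0.1 * math.exp(-0.373 * df_value)


def df_tbv_analytic(bvtv: float, nuclide: str | Nuclide) -> DoseFactor:
    """Analytic DF(AM<-TBV) for large segments (all dimensions > 2*lambda).

    DF = a_tbv*(1 - exp(-b_tbv*BV/TV)) on the 1e-11 scale, with the residual
    uncertainty law attached.  Outside the fitted BV/TV interval the function
    extrapolates with a warning.
    """
    if bvtv < 0:
        raise ValueError("bvtv must be >= 0")
    lo, hi = BVTV_FIT_INTERVAL
    if not (lo <= bvtv <= hi):
        warnings.warn(
            f"BV/TV={bvtv:g} outside the fitted interval [{lo}, {hi}]; "
            "extrapolating", stacklevel=2)
    nuc = get_nuclide(nuclide)
    value = nuc.a_tbv * (1.0 - math.exp(-nuc.b_tbv * bvtv))
    return DoseFactor(value=value, nuclide=nuc.name, source=Source.TBV,
                      delta=df_tbv_uncertainty(value))


def energy_ratio(ct_th: float, nuclide: str | Nuclide) -> float:
    """Cortical-to-trabecular energy-deposition ratio Fc(Ct.Th).

    Fc = a_f*exp(-b_f*Ct.Th); cortical self-attenuation makes it decay with
    cortical thickness.  Warns outside the fitted Ct.Th interval.
    """
    if ct_th < 0:
        raise ValueError("ct_th must be >= 0")
    lo, hi = CTTH_FIT_INTERVAL
    if not (lo <= ct_th <= hi):
        warnings.warn(
            f"Ct.Th={ct_th:g} cm outside the fitted interval [{lo}, {hi}]; "
            "extrapolating", stacklevel=2)
    nuc = get_nuclide(nuclide)
    return nuc.a_f * math.exp(-nuc.b_f * ct_th)


def df_cbv_analytic(
    bvtv: float,
    ct_th: float,
    v_cbv: float,
    v_tbv: float,
    nuclide: str | Nuclide,
    energy_ratio_delta: float = ENERGY_RATIO_DELTA,
) -> DoseFactor:
    """Analytic DF(AM<-CBV) composed from the TBV fit and the energy ratio.

    DF(AM<-CBV) = DF(AM<-TBV) * Fc(Ct.Th) * V_CBV/V_TBV.  The uncertainty
    combines the energy-ratio residual with the TBV residual in quadrature.
    """
    if v_tbv <= 0:
        raise ValueError("V_TBV must be > 0")
    if v_cbv < 0:
        raise ValueError("V_CBV must be >= 0")
    df_tbv = df_tbv_analytic(bvtv, nuclide)
    fc = energy_ratio(ct_th, nuclide)
    value = df_tbv.value * fc * (v_cbv / v_tbv)
    delta = math.hypot(energy_ratio_delta, df_tbv.delta)
    return DoseFactor(value=value, nuclide=df_tbv.nuclide, source=Source.CBV,
                      delta=delta)


def df_from_energy(e_mev: float, m_source: float, m_marrow: float) -> float:
    """DF from a mean absorbed energy per decay, on the 1e-11 scale.

    ``e_mev`` is the mean energy absorbed in bone marrow per decay in the
    source tissue (MeV); masses in g.  At unit activity concentration
    (1 Bq/g of source) the decay rate is m_source Bq, so

        DF = e_mev * MEV_TO_J * m_source / (m_marrow * 1e-3 kg)  [Gy/s per Bq/g]

    returned divided by 1e-11 to match the canonical scale.  The mass ratio
    makes DF an intensive quantity: scaling both masses leaves it unchanged.
    """
    if m_source <= 0 or m_marrow <= 0:
        raise ValueError("masses must be > 0")
    if e_mev < 0:
        raise ValueError("energy must be >= 0")
    gy_per_s = e_mev * MEV_TO_J * m_source / (m_marrow * 1e-3)
    return gy_per_s / 1e-11


# ---------------------------------------------------------------------------
# restricted-geometry (crossfire) adjustment
# ---------------------------------------------------------------------------

SS_CROSSFIRE_THRESHOLD = 6.0  # cm^2; larger spongiosa surfaces need no adjustment
RESTRICTION_DELTA = 0.05


def restricted_geometry_adjustment(
    spongiosa: AnalyticSolid,
    bvtv: float,
) -> tuple[float, float]:
    """Crossfire multiplier for segments cut out of a larger bone.

    If the spongiosa surface area exceeds 6 cm^2 the crossfire contribution
    from adjacent bone is negligible and the multiplier is 1.  Otherwise each
    linear dimension is extended by two mean electron pathlengths and the
    multiplier is (SS_ext/SS)^0.28 with a 5% relative standard uncertainty.
    """
    ss = spongiosa.surface_area
    if ss <= 0:
        raise ValueError("spongiosa surface area must be > 0")
    if ss > SS_CROSSFIRE_THRESHOLD:
        return 1.0, 0.0
    ss_ext = spongiosa.extended(2.0 * mean_free_path(bvtv)).surface_area
    return (ss_ext / ss) ** 0.28, RESTRICTION_DELTA
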