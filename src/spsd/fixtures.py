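"""Reference tables and builders for the adult-male skeletal model.

The CSV tables shipped with the package hold the reference data the toolkit
is calibrated against: simulated media compositions, the six small reference
phantoms, the adult-male hematopoietic-site layout, measured active-marrow
fractions with their variability, the bone-density sensitivity table, the
cortical-nonuniformity experiment, and the adult-male skeletal-average dose
factors with their uncertainty split.  Each table is checksummed so silent
edits are caught at load time.

Where a printed linear dimension disagreed with the volume columns of the
same table, the dimensions were reconciled against the volumes (which
over-determine them); the stored values reproduce every printed volume to
within rounding.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .phantom_geometry import Media
from .segment_model import MicroSpec, SegmentSpec, ShapeKind, ShapeSpec, VariabilityModel

_CHECKSUMS = {
    "am_fractions_adult": "c3eb3924d06b0a507cc56e175158fdd6a05fe695a58b2b0539732ba9666e6dba",
    "cortical_randomization": "8368812dd5ee3930642cd758c19faaea1428e75f0e1db6f4e0f99da9e97bc0a9",
    "density_differences": "b369e63dcf35b0878f06279be265ecf756db96b74f463655fe4a9965458c7a8b",
    "media": "52acbaac579cf2d746e5a8f46576eee5b75adb406e3f3ff07d1dd3a543d9f649",
    "segment_counts_adult": "3481f7fc47f232ff6d3bb0ddc15b5f4403477f01f32c3e4a3cbc8569f922bc94",
    "skeletal_df_adult": "6feeb95a5527f95e753598998705ff5158820b015d181311bd84304a8e71589c",
    "small_phantoms": "ae7fc58855c8cf881a734d203196c2b6343461e920784a9836e0b561b1affda1",
}

BONE_DENSITY = 1.9       # g/cm^3, adult cortical/trabecular bone
BONE_DENSITY_NEWBORN = 1.65
MARROW_DENSITY = 0.98


def load_fixture(name: str) -> pd.DataFrame:
    """Load a named reference table, verifying its checksum."""
    if name not in _CHECKSUMS:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_CHECKSUMS)}")
    ref = resources.files("spsd").joinpath(f"data/{name}.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"fixture {name!r} failed its checksum; the shipped table was modified")
    return pd.read_csv(ref.open("r"))


def media_basic() -> tuple[Media, Media]:
    """Basic (bone, marrow) media: densities 1.9 and 0.98 g/cm^3."""
    df = load_fixture("media").set_index("element")
    bone = Media("bone", BONE_DENSITY,
                 df["bone_basic"][df["bone_basic"] > 0].to_dict())
    marrow = Media("bone_marrow", MARROW_DENSITY,
                   df["marrow_basic"][df["marrow_basic"] > 0].to_dict())
    return bone, marrow


def media_alternative() -> tuple[Media, Media]:
    """Alternative media (dentin-like bone, water-like marrow).

    The published fraction sets for these media do not close to 1 within
    0.001, so the tolerance is relaxed accordingly.
    """
    df = load_fixture("media").set_index("element")
    bone = Media("bone_alt", BONE_DENSITY,
                 df["bone_alt"][df["bone_alt"] > 0].to_dict(),
                 fraction_tol=0.02)
    marrow = Media("bone_marrow_alt", MARROW_DENSITY,
                   df["marrow_alt"][df["marrow_alt"] > 0].to_dict(),
                   fraction_tol=0.02)
    return bone, marrow


_COVERAGE = {
    # lateral-only coverage for cylinder-like shapes: (lateral, bottom, top)
    (ShapeKind.ELLIPTIC_CYLINDER, "lateral"): (True, False, False),
    (ShapeKind.DEFORMED_CYLINDER, "lateral"): (True, False, False),
    (ShapeKind.ELLIPSOID, "all"): (True,),
}


def small_phantom_specs(variability: VariabilityModel | None = None) -> list[SegmentSpec]:
    """The six small reference phantoms as segment specifications."""
    df = load_fixture("small_phantoms")
    _, marrow = media_basic()
    specs = []
    for _, row in df.iterrows():
        kind = ShapeKind(row["shape"])
        dims = tuple(float(x) for x in str(row["dims"]).split(";"))
        shape = ShapeSpec(kind, dims)
        cov = _COVERAGE.get((kind, row["coverage"]))
        micro = MicroSpec(
            tb_th=row["tb_th"], tb_th_sd=0.1 * row["tb_th"],
            tb_sp=row["tb_sp"], tb_sp_sd=0.05 * row["tb_sp"],
            bvtv=row["bvtv"],
            bvtv_range=(0.8 * row["bvtv"], 1.2 * row["bvtv"]),
        )
        specs.append(SegmentSpec(
            site_id="reference", segment_id=f"small-{int(row['n'])}",
            shape=shape, ct_th=row["ct_th"], micro=micro,
            marrow_mass=float(row["v_bmv"]) * marrow.density,
            cortical_coverage=cov,
            variability=variability or VariabilityModel(),
        ))
    return specs


def am_distribution_adult():
    """Adult AM distribution with the overall site-specific CVs."""
    from .skeleton_aggregation import AMDistribution

    df = load_fixture("am_fractions_adult")
    return AMDistribution(
        sites=tuple(df["site"]),
        fractions=tuple(df["campbell_fraction"]),
        cvs=tuple(df["assumed_cv"]),
        provenance="measured",
    )


# Representative segment parameters per adult site used by the synthetic
# skeleton builder: (n_segments, bvtv, ct_th, circumscribed edges, V_s).
# Dimensions follow the site anatomy coarsely: vertebral bodies and pelvic
# segments are "large" (all edges above the 1.1 cm pathlength cut); sternum,
# clavicles and the cranial tables are thin in at least one dimension.
_ADULT_SITE_SEGMENTS: dict[str, list[tuple[float, float, tuple[float, float, float], float]]] = {
    "Head": [(0.45, 0.25, (15.0, 12.0, 0.7), 35.0)],
    "Scapulae+ribs+clavicles": [
        (0.18, 0.05, (12.0, 8.0, 0.8), 18.0),
        (0.13, 0.08, (20.0, 1.0, 0.9), 8.0),
        (0.20, 0.10, (13.0, 1.2, 1.2), 9.0),
    ],
    "Sternum": [(0.17, 0.06, (14.0, 3.0, 1.0), 20.0)],
    "Cervical spine": [(0.26, 0.04, (2.5, 2.3, 1.4), 5.0),
                       (0.24, 0.04, (2.8, 2.5, 1.5), 6.5)],
    "Thoracic spine": [(0.22, 0.045, (3.2, 2.8, 2.0), 13.0),
                       (0.20, 0.05, (3.5, 3.0, 2.2), 16.0)],
    "Lumbar spine": [(0.20, 0.05, (4.5, 3.4, 2.7), 28.0),
                     (0.19, 0.05, (4.8, 3.5, 2.9), 32.0)],
    "Sacrum": [(0.25, 0.06, (10.0, 4.0, 1.6), 30.0),
               (0.22, 0.05, (5.0, 3.0, 1.0), 9.0)],
    "Femora upper half": [(0.30, 0.20, (5.0, 4.5, 4.0), 45.0)],
    "Humeri upper half": [(0.28, 0.16, (4.5, 4.0, 3.5), 30.0)],
    "Pelvic bones": [(0.22, 0.10, (12.0, 10.0, 1.3), 60.0),
                     (0.24, 0.12, (6.0, 5.0, 2.0), 25.0)],
}


def synthetic_adult_skeleton(nuclide: str = "Sr90", source: str = "TBV"):
    """Synthetic adult-male skeleton with analytic segment dose factors.

    Segment dose factors come from the analytic TBV/CBV surrogates evaluated
    on representative per-site bone-volume fractions, cortical thicknesses
    and sizes; uncertainty budgets are attached per size class.  This is a
    stand-in for the full per-segment morphometric appendix, which is not
    part of the shipped tables; site identities and AM weights are real.
    """
    from .dose_model import classify_segment, df_cbv_analytic, df_tbv_analytic
    from .phantom_geometry import DerivedGeometry
    from .skeleton_aggregation import SiteRecord
    from .uncertainty_engine import budget_lookup

    bone, marrow = media_basic()
    records = []
    for site, segs in _ADULT_SITE_SEGMENTS.items():
        dfs, masses, budgets = [], [], []
        for bvtv, ct_th, edges, v_s in segs:
            v_tbv = bvtv * v_s
            v_bmv = v_s - v_tbv
            # cortical shell volume approximated from the box envelope
            area = 2 * (edges[0] * edges[1] + edges[0] * edges[2]
                        + edges[1] * edges[2])
            v_cbv = min(ct_th * area, 0.8 * v_s)
            geom = DerivedGeometry(
                v_s=v_s, ss=area, v_tbv=v_tbv, v_bmv=v_bmv, v_cbv=v_cbv,
                m_tbv=v_tbv * bone.density, m_bmv=v_bmv * marrow.density,
                m_cbv=v_cbv * bone.density, circumscribed_box=edges)
            tbv_class, cbv_class = classify_segment(geom)
            if source == "TBV":
                df = df_tbv_analytic(bvtv, nuclide)
                cls = tbv_class
            else:
                df = df_cbv_analytic(bvtv, ct_th, v_cbv, v_tbv, nuclide)
                cls = cbv_class
            dfs.append(df.value)
            masses.append(v_bmv * marrow.density)
            budgets.append(tuple(budget_lookup(cls, source)))
        records.append(SiteRecord(site_id=site, segment_dfs=tuple(dfs),
                                  marrow_masses=tuple(masses),
                                  segment_budgets=tuple(budgets)))
    return records
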