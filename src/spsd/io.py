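"""File formats: segment tables (CSV), run configs (YAML/JSON), results.

CSV dialect is UTF-8, comma-separated, '.' decimal, with a mandatory header
row.  Dose-factor columns are always on the 1e-11 Gy/s per Bq/g scale and the
column headers say so.  Shape dims are serialized as a ';'-delimited list.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .segment_model import (
    MicroSpec,
    SegmentSpec,
    ShapeKind,
    ShapeSpec,
    VariabilityModel,
)

SEGMENT_COLUMNS = [
    "site_id", "segment_id", "shape_kind", "dims_cm", "ct_th_cm",
    "cortical_coverage", "tb_th_cm", "tb_th_sd_cm", "tb_sp_cm", "tb_sp_sd_cm",
    "bvtv", "bvtv_min", "bvtv_max", "marrow_mass_g",
]


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one toolkit run."""

    nuclide: str = "Sr90"
    seed: int = 0
    resolution_cm: float | None = None       # absolute voxel edge, or
    resolution_tbth_factor: float = 0.75     # fraction of Tb.Th when relative
    rho: float = 0.5
    n_outer: int = 400
    n_inner: int = 250
    budget_overrides: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if self.nuclide not in ("Sr90", "Sr89"):
            raise ValueError(f"unknown nuclide {self.nuclide!r}")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if self.resolution_cm is not None and self.resolution_cm <= 0:
            raise ValueError("resolution must be > 0")
        if self.n_outer < 1 or self.n_inner < 1:
            raise ValueError("Monte Carlo sizes must be >= 1")

    def resolution_for(self, tb_th: float) -> float:
        if self.resolution_cm is not None:
            return self.resolution_cm
        return self.resolution_tbth_factor * tb_th

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
            else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _segment_row(spec: SegmentSpec) -> dict[str, Any]:
    return {
        "site_id": spec.site_id,
        "segment_id": spec.segment_id,
        "shape_kind": spec.shape.kind.value,
        "dims_cm": ";".join(f"{d:.6g}" for d in spec.shape.dims),
        "ct_th_cm": spec.ct_th,
        "cortical_coverage": "".join("1" if c else "0"
                                     for c in spec.cortical_coverage),
        "tb_th_cm": spec.micro.tb_th,
        "tb_th_sd_cm": spec.micro.tb_th_sd,
        "tb_sp_cm": spec.micro.tb_sp,
        "tb_sp_sd_cm": spec.micro.tb_sp_sd,
        "bvtv": spec.micro.bvtv,
        "bvtv_min": spec.micro.bvtv_range[0],
        "bvtv_max": spec.micro.bvtv_range[1],
        "marrow_mass_g": spec.marrow_mass,
    }


def write_segments(specs: Sequence[SegmentSpec], path: str | Path) -> None:
    pd.DataFrame([_segment_row(s) for s in specs],
                 columns=SEGMENT_COLUMNS).to_csv(path, index=False)


def read_segments(
    path: str | Path,
    variability: VariabilityModel | None = None,
) -> list[SegmentSpec]:
    """Read a segment table; reports malformed rows with their position."""
    df = pd.read_csv(path)
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    specs = []
    for i, row in df.iterrows():
        try:
            shape = ShapeSpec(ShapeKind(row["shape_kind"]),
                              tuple(float(x) for x in str(row["dims_cm"]).split(";")))
            micro = MicroSpec(
                tb_th=float(row["tb_th_cm"]), tb_th_sd=float(row["tb_th_sd_cm"]),
                tb_sp=float(row["tb_sp_cm"]), tb_sp_sd=float(row["tb_sp_sd_cm"]),
                bvtv=float(row["bvtv"]),
                bvtv_range=(float(row["bvtv_min"]), float(row["bvtv_max"])),
            )
            cov = tuple(c == "1" for c in str(row["cortical_coverage"]))
            specs.append(SegmentSpec(
                site_id=str(row["site_id"]), segment_id=str(row["segment_id"]),
                shape=shape, ct_th=float(row["ct_th_cm"]), micro=micro,
                marrow_mass=float(row["marrow_mass_g"]),
                cortical_coverage=cov,
                variability=variability or VariabilityModel(),
            ))
        except (ValueError, KeyError) as exc:
            raise ValueError(
                f"{path}: row {i + 1} (segment "
                f"{row.get('segment_id', '?')}): {exc}") from exc
    return specs


def variability_from_file(path: str | Path) -> VariabilityModel:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
        else json.loads(text)
    macro_cv = data.get("macro_cv", 0.0)
    if isinstance(macro_cv, list):
        macro_cv = tuple(macro_cv)
    return VariabilityModel(
        macro_cv=macro_cv,
        ct_th_cv=data.get("ct_th_cv", 0.0),
        tb_th_cv=data.get("tb_th_cv", 0.0),
        tb_sp_cv=data.get("tb_sp_cv", 0.0),
        macro_corr=data.get("macro_corr", 0.5),
        micro_corr=data.get("micro_corr", -0.5),
        truncation=data.get("truncation", 0.90),
    )


def write_results_json(records: Sequence[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(list(records), indent=2) + "\n")


def write_results_csv(records: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(list(records)).to_csv(path, index=False)
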