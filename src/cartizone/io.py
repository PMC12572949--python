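"""File formats and validation.

Conventions, stated once: all coordinates are mm; pixel indices are 0-based
with pixel centres at (i + 0.5) * pixel_spacing; the image y-axis points
downward; CSV artifacts are UTF-8, comma-separated, '.' decimal, with a
mandatory header row.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .quant import CartilageSegmentation

COHORT_COLUMNS = ["subject_id", "sex", "age_group", "side", "site",
                  "reading_index", "thickness_mm"]
VALID_SEX = {"female", "male"}
VALID_AGE = {"young", "middle", "older", "retirement"}
VALID_SIDE = {"left", "right"}
VALID_REGION = {"lateral", "middle", "medial"}


class SchemaError(ValueError):
    """A table failed validation; the message names offending rows."""


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Load and validate a long-format cohort CSV (one row per reading)."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    if len(df) == 0:
        raise SchemaError("cohort table is empty")
    problems = []
    thick = pd.to_numeric(df["thickness_mm"], errors="coerce")
    for idx in df.index[thick.isna()]:
        problems.append(f"row {idx}: non-numeric thickness_mm")
    for idx in df.index[thick <= 0]:
        problems.append(f"row {idx}: nonpositive thickness_mm")
    for col, valid in (("sex", VALID_SEX), ("age_group", VALID_AGE),
                       ("side", VALID_SIDE), ("site", VALID_REGION)):
        bad = ~df[col].isin(valid)
        for idx in df.index[bad][:5]:
            problems.append(f"row {idx}: unknown {col} {df.loc[idx, col]!r}")
    if problems:
        raise SchemaError("; ".join(problems[:20]))
    out = df.copy()
    out["thickness_mm"] = thick
    out["reading_index"] = out["reading_index"].astype(int)
    return out


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def subject_site_means(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-subject, per-site mean over the repeated readings.

    This is the subject-level thickness used for all between-group
    comparisons (the protocol averages the triplicate images).
    """
    return (cohort
            .groupby(["subject_id", "sex", "age_group", "side", "site"],
                     as_index=False)["thickness_mm"].mean())


# --------------------------------------------------------------------------
# geometry artifacts


def write_polylines_csv(seg: CartilageSegmentation, path: str | Path) -> None:
    """Boundary polylines as (x_mm, y_mm, boundary_label) rows; the notch
    point is a single 'notch' row."""
    rows = [(x, y, "bone") for x, y in seg.bone]
    rows += [(x, y, "synovial") for x, y in seg.synovial]
    rows.append((seg.notch[0], seg.notch[1], "notch"))
    pd.DataFrame(rows, columns=["x_mm", "y_mm", "boundary_label"]) \
        .to_csv(path, index=False)


def read_polylines_csv(path: str | Path, image_id: str = "",
                       pixel_spacing: float | None = None
                       ) -> CartilageSegmentation:
    df = pd.read_csv(path)
    need = {"x_mm", "y_mm", "boundary_label"}
    if not need <= set(df.columns):
        raise SchemaError(f"polyline CSV needs columns {sorted(need)}")
    bone = df[df.boundary_label == "bone"][["x_mm", "y_mm"]].to_numpy()
    syn = df[df.boundary_label == "synovial"][["x_mm", "y_mm"]].to_numpy()
    notch = df[df.boundary_label == "notch"][["x_mm", "y_mm"]].to_numpy()
    if len(notch) != 1:
        raise SchemaError("polyline CSV must contain exactly one notch row")
    return CartilageSegmentation(bone=bone, synovial=syn, notch=notch[0],
                                 pixel_spacing=pixel_spacing,
                                 image_id=image_id)


def write_mask(mask: np.ndarray, sidecar: dict, path: str | Path) -> None:
    """Binary mask as PNG (0/255) plus a JSON sidecar next to it."""
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_mask(path: str | Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    mask = np.asarray(iio.imread(path)) > 0
    if mask.ndim == 3:
        mask = mask[..., 0]
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() \
        else {}
    return mask, sidecar


# --------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Umbrella pipeline configuration (YAML-serialisable)."""

    cohort_csv: str = ""
    out_dir: str = "cartizone_out"
    seed: int = 0
    alpha: float = 0.05
    sig_tiers: tuple[float, float] = (0.05, 0.001)
    t_variant: str = "pooled"  # or "welch"
    cv_variant: str = "sqrt_expm1"
    convention: str = "absolute_mm"
    half_width_mm: float = 4.8
    fraction: float = 0.25
    mc_replicates: int = 200_000
    log_level: str = "INFO"
    # synthetic-cohort calibration, used when cohort_csv is empty
    synth_sem_pct: float = 1.8
    synth_between_sd: float = 0.30

    def __post_init__(self) -> None:
        for name in ("alpha", "fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for tier in self.sig_tiers:
            if not 0 < tier < 1:
                raise ValueError("significance tiers must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "sig_tiers" in data:
            data["sig_tiers"] = tuple(data["sig_tiers"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sig_tiers"] = list(self.sig_tiers)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
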