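"""Congener concentration profiles and their elementary transforms.

A :class:`CongenerProfile` holds the 16-congener concentration vector
(ng m⁻³) for one PM2.5 sample together with school/zone/site metadata and
per-congener method detection limits (MDL).  Non-detects and missing values
are imputed at MDL/2 before any downstream statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .registry import CONGENERS, HMW_CONGENERS, LMW_CONGENERS

#: Total sampled air volume (m3) for one 24 h low-volume run at 5 L/min.
STUDY_AIR_VOLUME_M3 = 7.2


@dataclass(frozen=True)
class ExtractMeasurement:
    """GC-MS extract reading for one congener in one sample.

    ``c_determined`` is the instrument concentration in the final extract
    (ng mL⁻¹); ``dilution_factor`` is the dimensionless multiplier absorbing
    extract volume and dilution; ``air_volume`` the sampled air volume (m3).
    """

    c_determined: float
    dilution_factor: float = 1.0
    air_volume: float = STUDY_AIR_VOLUME_M3


def concentration_from_extract(m: ExtractMeasurement) -> float:
    """Airborne concentration (ng m⁻³) from an extract measurement.

    C = C_determined (ng mL⁻¹) x dilution factor / air volume (m3).
    """
    if m.air_volume <= 0:
        raise ValueError(f"air_volume must be positive, got {m.air_volume}")
    if m.dilution_factor < 1:
        raise ValueError(
            f"dilution_factor must be >= 1, got {m.dilution_factor}"
        )
    return m.c_determined * m.dilution_factor / m.air_volume


@dataclass(frozen=True)
class CongenerProfile:
    """One sample's 16-congener concentration vector with metadata.

    ``conc`` maps every registry congener to a nonnegative concentration in
    ng m⁻³, or ``None`` for a missing/non-detect entry.  ``mdl`` maps
    congeners to method detection limits used for MDL/2 imputation.
    """

    sample_id: str
    school: str = ""
    zone: str = "exposed"  # exposed | comparative
    site: str = "outdoor"  # indoor | outdoor
    conc: dict[str, float | None] = field(default_factory=dict)
    mdl: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.zone not in ("exposed", "comparative"):
            raise ValueError(f"unknown zone {self.zone!r}")
        if self.site not in ("indoor", "outdoor"):
            raise ValueError(f"unknown site {self.site!r}")
        full = {c: self.conc.get(c) for c in CONGENERS}
        for c, v in full.items():
            if v is not None and (math.isnan(v) or v < 0):
                if math.isnan(v):
                    full[c] = None
                else:
                    raise ValueError(f"negative concentration for {c}: {v}")
        object.__setattr__(self, "conc", full)

    @property
    def is_imputed(self) -> bool:
        return all(v is not None for v in self.conc.values())

    def _require_imputed(self, op: str):
        missing = [c for c, v in self.conc.items() if v is None]
        if missing:
            raise ValueError(
                f"{op} requires an imputed profile; {self.sample_id} is "
                f"missing {missing} (apply impute_below_mdl first)"
            )


def impute_below_mdl(p: CongenerProfile) -> CongenerProfile:
    """Replace missing or below-MDL entries by MDL/2.

    Detected values at or above their MDL pass through unchanged, so the
    operation is idempotent.  A missing value without an MDL on record is an
    error naming the congener.
    """
    out: dict[str, float | None] = {}
    for c, v in p.conc.items():
        mdl = p.mdl.get(c)
        if v is None or (mdl is not None and v < mdl):
            if mdl is None:
                raise ValueError(
                    f"cannot impute {c} in sample {p.sample_id}: "
                    "no MDL on record"
                )
            out[c] = mdl / 2.0
        else:
            out[c] = v
    return replace(p, conc=out)


def total_pahs(p: CongenerProfile) -> float:
    """Sum of the 16 congener concentrations (ng m⁻³)."""
    p._require_imputed("total_pahs")
    return sum(p.conc[c] for c in CONGENERS)


def lmw_hmw_split(p: CongenerProfile) -> tuple[float, float]:
    """(LMW total, HMW total) in ng m⁻³.

    LMW = 2-3 ring congeners {NAP, ACY, ACP, FLU, PHE, ANT}; HMW = the
    remaining ten 4-6 ring congeners.  The two parts sum to ``total_pahs``.
    """
    p._require_imputed("lmw_hmw_split")
    lmw = sum(p.conc[c] for c in LMW_CONGENERS)
    hmw = sum(p.conc[c] for c in HMW_CONGENERS)
    return lmw, hmw


# ---------------------------------------------------------------------------
# tabular interfaces

def profiles_to_frame(profiles: list[CongenerProfile]) -> pd.DataFrame:
    """Samples x (metadata + 16 congeners) DataFrame; missing -> NaN."""
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, "school": p.school,
               "zone": p.zone, "site": p.site}
        for c in CONGENERS:
            v = p.conc[c]
            row[c] = float("nan") if v is None else v
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample_id", "school", "zone", "site",
                                       *CONGENERS])


def frame_to_profiles(df: pd.DataFrame,
                      mdl: dict[str, float] | None = None
                      ) -> list[CongenerProfile]:
    """Inverse of :func:`profiles_to_frame`; empty cells become missing."""
    missing_cols = [c for c in CONGENERS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"sample table lacks congener columns {missing_cols}")
    out = []
    for _, row in df.iterrows():
        conc = {c: (None if pd.isna(row[c]) else float(row[c]))
                for c in CONGENERS}
        out.append(CongenerProfile(
            sample_id=str(row["sample_id"]),
            school=str(row.get("school", "")),
            zone=str(row.get("zone", "exposed")),
            site=str(row.get("site", "outdoor")),
            conc=conc,
            mdl=dict(mdl or {}),
        ))
    return out


def read_samples_csv(path, mdl_path=None) -> list[CongenerProfile]:
    """Read the sample CSV (and optional companion MDL CSV).

    Sample columns: ``sample_id, school, zone, site`` followed by the 16
    congener abbreviations; empty cells are treated as missing/non-detect.
    MDL CSV columns: ``congener, mdl_ng_m3``.
    """
    df = pd.read_csv(path)
    mdl = read_mdl_csv(mdl_path) if mdl_path is not None else None
    return frame_to_profiles(df, mdl)


def read_mdl_csv(path) -> dict[str, float]:
    mdl_df = pd.read_csv(path)
    return dict(zip(mdl_df["congener"], mdl_df["mdl_ng_m3"].astype(float)))


def write_samples_csv(profiles: list[CongenerProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)
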