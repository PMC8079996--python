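"""Trait-table ingestion, source merging and dimensionless life-history metrics.

Three dimensionless metrics summarize a species' life history on a common
scale regardless of its absolute size or pace of life:

* **LRE** (lifetime reproductive effort):
  ``litter_size * litters_per_year * mass_at_independence / adult_body_mass
  * adult_lifespan`` — the fraction of adult mass allocated to offspring per
  year, integrated over the adult lifespan.
* **RRL** (relative reproductive lifespan): ``adult_lifespan /
  female_maturity_age`` — reproductive time relative to time spent growing.
* **ROS** (relative offspring size): ``mass_at_independence /
  adult_body_mass``.

Adult lifespan is maximum longevity minus age at female maturity (the time
from maturity to death), switchable to raw longevity for sensitivity runs.
Mass at independence means fledging mass for birds, weaning mass for
mammals, hatchling mass for reptiles and offspring/egg mass for amphibians.
Missing fields make a metric *undefined* (never zero); a species enters the
metric table only when all three metrics are computable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CLADES",
    "TRAIT_FIELDS",
    "AllometryParams",
    "MetricConfig",
    "standardize_table",
    "merge_trait_sources",
    "svl_to_mass",
    "amphibian_mean_mass",
    "adult_lifespan",
    "compute_lre",
    "compute_rrl",
    "compute_ros",
    "build_metric_table",
]

CLADES = ("Amphibia", "Reptilia", "Mammalia", "Aves")

TRAIT_FIELDS = (
    "adult_body_mass",
    "litter_size",
    "litters_per_year",
    "mass_at_independence",
    "max_longevity",
    "female_maturity_age",
    "svl_min",
    "svl_max",
)

METRIC_COLUMNS = (
    "species", "clade", "mass_g", "lre", "rrl", "ros",
    "log_mass", "log_lre", "log_rrl", "log_ros",
)


@dataclass(frozen=True)
class AllometryParams:
    """Power-law mass-from-length allometry ``mass = a * svl ** b``.

    ``a`` is in g * mm^(-b); ``b`` is dimensionless.  Coefficients are
    group-specific (frogs vs salamanders) and must be supplied by the user —
    there is no universal default.
    """

    group: str
    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("allometry coefficients must be positive")


@dataclass
class MetricConfig:
    """Options controlling metric computation.

    adult_lifespan_mode:
        ``"longevity_minus_maturity"`` (default; lifespan = maximum longevity
        minus female maturity age) or ``"raw_longevity"``.
    amphibian_mass_mode:
        ``"max_mass"`` (default; use the reported adult body mass, which for
        amphibian sources is a maximum) or ``"mean_mass_from_svl"`` (convert
        min and max snout–vent lengths with the group allometries and
        average the two masses).
    allometry:
        group name -> AllometryParams, required for the SVL mode.
    field_map:
        source column name -> canonical TraitRecord field, applied by
        ``standardize_table``.
    """

    adult_lifespan_mode: str = "longevity_minus_maturity"
    amphibian_mass_mode: str = "max_mass"
    allometry: dict = field(default_factory=dict)
    field_map: dict = field(default_factory=dict)
    prefer_offspring_mass: bool = True

    def __post_init__(self):
        if self.adult_lifespan_mode not in ("longevity_minus_maturity", "raw_longevity"):
            raise ValueError(f"bad adult_lifespan_mode {self.adult_lifespan_mode!r}")
        if self.amphibian_mass_mode not in ("max_mass", "mean_mass_from_svl"):
            raise ValueError(f"bad amphibian_mass_mode {self.amphibian_mass_mode!r}")


def normalize_species(name: str) -> str:
    """Trim and underscore species names so they match Newick tip labels."""
    return str(name).strip().replace(" ", "_")


def standardize_table(df: pd.DataFrame, field_map: Mapping | None = None) -> pd.DataFrame:
    """Rename source columns to canonical fields and normalize species names.

    Raises on unknown clade labels, duplicate species and non-positive trait
    values (trait fields are strictly positive when present).
    """
    out = df.copy()
    if field_map:
        out = out.rename(columns=dict(field_map))
    if "species" not in out.columns:
        raise ValueError("table must have a 'species' column")
    out["species"] = out["species"].map(normalize_species)
    dupes = out["species"][out["species"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate species in table: {sorted(set(dupes))}")
    if "clade" in out.columns:
        bad = set(out["clade"].dropna()) - set(CLADES)
        if bad:
            raise ValueError(f"unknown clade labels: {sorted(bad)}")
    for f in TRAIT_FIELDS:
        if f in out.columns:
            col = pd.to_numeric(out[f], errors="coerce")
            nonpos = out.loc[col.notna() & (col <= 0), "species"].tolist()
            if nonpos:
                raise ValueError(f"non-positive {f} for species: {nonpos[:5]}")
            out[f] = col
    return out


def merge_trait_sources(primary: pd.DataFrame, supplement: pd.DataFrame) -> pd.DataFrame:
    """Merge a primary and a supplementary trait table.

    Primary values always win; only fields missing in the primary are filled
    from the supplement, and species present only in the supplement are
    appended whole.  Per-field provenance is recorded in ``<field>_source``
    columns (``"primary"`` / ``"supplement"``).
    """
    for name, df in (("primary", primary), ("supplement", supplement)):
        d = df["species"][df["species"].duplicated()].tolist()
        if d:
            raise ValueError(f"duplicate species in {name} table: {sorted(set(d))}")
    fields_p = [c for c in primary.columns if c in TRAIT_FIELDS]
    fields_s = [c for c in supplement.columns if c in TRAIT_FIELDS]
    if set(fields_p) != set(fields_s):
        raise ValueError(
            f"schema mismatch: primary has {sorted(fields_p)}, "
            f"supplement has {sorted(fields_s)}"
        )
    p = primary.set_index("species")
    s = supplement.set_index("species")
    all_sp = list(p.index) + [sp for sp in s.index if sp not in set(p.index)]
    out = pd.DataFrame(index=pd.Index(all_sp, name="species"))
    for meta in ("clade", "order"):
        if meta in p.columns or meta in s.columns:
            pv = p[meta] if meta in p.columns else pd.Series(dtype=object)
            sv = s[meta] if meta in s.columns else pd.Series(dtype=object)
            out[meta] = pv.reindex(all_sp).fillna(sv.reindex(all_sp))
    for f in fields_p:
        pv = p[f].reindex(all_sp)
        sv = s[f].reindex(all_sp) if f in s.columns else pd.Series(np.nan, index=all_sp)
        out[f] = pv.fillna(sv)
        src = pd.Series(pd.NA, index=out.index, dtype=object)
        src[sv.notna()] = "supplement"
        src[pv.notna()] = "primary"
        src[out[f].isna()] = pd.NA
        out[f + "_source"] = src
    return out.reset_index()


# ---------------------------------------------------------------------------
# Scalar metric operations
# ---------------------------------------------------------------------------


def _get(record, key):
    try:
        v = record[key]
    except (KeyError, IndexError):
        return None
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def svl_to_mass(svl: float, params: AllometryParams) -> float:
    """Convert snout–vent length (mm) to body mass (g): ``a * svl ** b``."""
    if svl <= 0:
        raise ValueError(f"svl must be positive, got {svl}")
    return params.a * svl**params.b


def amphibian_mean_mass(svl_min: float, svl_max: float, params: AllometryParams) -> float:
    """Mean of the masses converted from the minimum and maximum SVL."""
    if svl_min > svl_max:
        raise ValueError(f"svl_min {svl_min} > svl_max {svl_max}")
    return 0.5 * (svl_to_mass(svl_min, params) + svl_to_mass(svl_max, params))


def adult_lifespan(record, mode: str = "longevity_minus_maturity") -> float | None:
    """Time from female maturity to death, in years.

    Returns ``None`` if a component is missing; raises if maturity is at or
    beyond maximum longevity (such records must be flagged, not passed on).
    """
    lon = _get(record, "max_longevity")
    mat = _get(record, "female_maturity_age")
    if mode == "raw_longevity":
        return lon
    if lon is None or mat is None:
        return None
    if mat >= lon:
        raise ValueError(
            f"female maturity age ({mat}) is not before maximum longevity ({lon})"
        )
    return lon - mat


def compute_lre(record, lifespan_mode: str = "longevity_minus_maturity") -> float | None:
    """Lifetime reproductive effort; ``None`` when any component is missing."""
    ls = _get(record, "litter_size")
    lpy = _get(record, "litters_per_year")
    mi = _get(record, "mass_at_independence")
    am = _get(record, "adult_body_mass")
    span = adult_lifespan(record, lifespan_mode)
    if None in (ls, lpy, mi, am, span):
        return None
    if min(ls, lpy, mi, am) <= 0:
        raise ValueError("LRE components must be positive")
    return ls * lpy * mi / am * span


def compute_rrl(record, lifespan_mode: str = "longevity_minus_maturity") -> float | None:
    """Relative reproductive lifespan; ``None`` when a component is missing."""
    mat = _get(record, "female_maturity_age")
    span = adult_lifespan(record, lifespan_mode)
    if mat is None or span is None:
        return None
    if mat <= 0:
        raise ValueError("female maturity age must be positive")
    return span / mat


def compute_ros(record) -> float | None:
    """Relative offspring size; ``None`` when a mass is missing."""
    mi = _get(record, "mass_at_independence")
    am = _get(record, "adult_body_mass")
    if mi is None or am is None:
        return None
    if mi <= 0 or am <= 0:
        raise ValueError("masses must be positive")
    return mi / am


# ---------------------------------------------------------------------------
# Table-level computation
# ---------------------------------------------------------------------------


def _resolve_mass(df: pd.DataFrame, config: MetricConfig) -> pd.Series:
    """Adult body mass per species, honouring the amphibian mass mode."""
    mass = df["adult_body_mass"].astype(float).copy()
    if config.amphibian_mass_mode == "mean_mass_from_svl" and "svl_min" in df.columns:
        amph = df.get("clade", pd.Series(index=df.index, dtype=object)) == "Amphibia"
        for i in df.index[amph]:
            grp = df.at[i, "order"] if "order" in df.columns else None
            params = config.allometry.get(grp)
            lo, hi = df.at[i, "svl_min"], df.at[i, "svl_max"]
            if params is None or pd.isna(lo) or pd.isna(hi):
                continue  # fall back to reported mass
            mass.at[i] = amphibian_mean_mass(float(lo), float(hi), params)
    return mass


def build_metric_table(
    records: pd.DataFrame, config: MetricConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Compute LRE, RRL and ROS for every species with complete components.

    Returns the metric table (one row per species with all three metrics)
    and a completeness report: counts retained and dropped per clade, drop
    counts per missing field, and species flagged for maturity >= longevity.
    The result is independent of input row order (output sorted by species
    within clade).
    """
    config = config or MetricConfig()
    df = records.copy()
    if "species" not in df.columns:
        raise ValueError("records must have a 'species' column")
    df["species"] = df["species"].map(normalize_species)

    mass = _resolve_mass(df, config)
    lon = df["max_longevity"].astype(float)
    mat = df["female_maturity_age"].astype(float)

    flagged = df["species"][(lon.notna() & mat.notna()) & (mat >= lon)].tolist()
    ok_span = lon.notna() & mat.notna() & (mat < lon)
    if config.adult_lifespan_mode == "raw_longevity":
        span = lon.where(lon.notna())
        span[~lon.notna()] = np.nan
    else:
        span = (lon - mat).where(ok_span)

    with np.errstate(invalid="ignore", divide="ignore"):
        ros = df["mass_at_independence"] / mass
        rrl = span / mat
        lre = df["litter_size"] * df["litters_per_year"] * ros * span

    keep = lre.notna() & rrl.notna() & ros.notna()
    out = pd.DataFrame(
        {
            "species": df["species"],
            "clade": df.get("clade", pd.Series(index=df.index, dtype=object)),
            "mass_g": mass,
            "lre": lre,
            "rrl": rrl,
            "ros": ros,
        }
    )
    if "order" in df.columns:
        out["order"] = df["order"]
    out = out[keep].copy()
    for col, src in (("log_mass", "mass_g"), ("log_lre", "lre"),
                     ("log_rrl", "rrl"), ("log_ros", "ros")):
        out[col] = np.log(out[src].astype(float))
    out = out.sort_values(["clade", "species"], kind="mergesort").reset_index(drop=True)

    drop_fields = {}
    dropped = df[~keep]
    component_fields = (
        "adult_body_mass", "litter_size", "litters_per_year",
        "mass_at_independence", "max_longevity", "female_maturity_age",
    )
    for f in component_fields:
        if f in df.columns:
            n_missing = int(dropped[f].isna().sum())
            if n_missing:
                drop_fields[f] = n_missing
    per_clade = {}
    clades = df.get("clade")
    if clades is not None:
        for cl in pd.unique(clades.dropna()):
            mask = clades == cl
            per_clade[str(cl)] = {
                "input": int(mask.sum()),
                "retained": int((mask & keep).sum()),
                "dropped": int((mask & ~keep).sum()),
            }
    report = {
        "n_input": int(len(df)),
        "n_retained": int(keep.sum()),
        "n_dropped": int((~keep).sum()),
        "dropped_by_missing_field": drop_fields,
        "flagged_maturity_ge_longevity": sorted(flagged),
        "per_clade": per_clade,
        "adult_lifespan_mode": config.adult_lifespan_mode,
        "amphibian_mass_mode": config.amphibian_mass_mode,
    }
    return out, report


def write_metric_csv(metric_df: pd.DataFrame, path) -> None:
    metric_df.to_csv(path, index=False)


def write_report_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
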