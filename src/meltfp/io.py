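"""File formats: plate-export CSV curves, library JSON, run configuration.

Two CSV dialects stand in for an instrument melt export:

* ``long`` — columns ``well, primer, temperature_C, fluorescence`` (one row
  per reading; optional ``species`` / ``population`` label columns).
* ``wide`` — first column ``temperature_C``, one column per well with the
  primer encoded in the header as ``well|primer``.

All readers validate rather than coerce: a ragged temperature grid, a
non-numeric cell or a malformed library document is rejected with a message
naming the offending well, row or JSON pointer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields as dc_fields
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .grid import TemperatureGrid
from .matching import ReferenceLibrary
from .processing import MeltCurve, MeltFingerprint, MeltPeak, ProcessingConfig
from .synth import CurveRecord, LabeledCurveSet

__all__ = [
    "read_melt_curves",
    "write_melt_curves",
    "read_library",
    "write_library",
    "read_fingerprints",
    "write_fingerprints",
    "RunConfig",
    "load_config",
]

LONG_COLUMNS = ["well", "primer", "temperature_C", "fluorescence"]


def _numeric(series: pd.Series, name: str) -> np.ndarray:
    vals = pd.to_numeric(series, errors="coerce")
    bad = vals.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"non-numeric value {series[row]!r} in column {name!r} at row {row + 2}"
        )
    if vals.isna().any():
        row = int(vals.isna().idxmax())
        raise ValueError(f"missing value in column {name!r} at row {row + 2}")
    return vals.to_numpy(dtype=float)


def write_melt_curves(
    path,
    curves: Union[LabeledCurveSet, Sequence[MeltCurve]],
    dialect: str = "long",
) -> None:
    """Write curves to CSV. A LabeledCurveSet keeps its labels (long only)."""
    labeled = isinstance(curves, LabeledCurveSet)
    records = list(curves) if labeled else [None] * len(curves)
    mcs = [r.curve for r in curves] if labeled else list(curves)
    if dialect == "long":
        frames = []
        for mc, rec in zip(mcs, records):
            df = pd.DataFrame({
                "well": mc.id, "primer": mc.primer,
                "temperature_C": np.round(mc.temperatures, 4),
                "fluorescence": mc.fluorescence,
            })
            if labeled:
                df["species"] = rec.species
                df["population"] = rec.population if rec.population is not None else ""
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    elif dialect == "wide":
        base = mcs[0].temperatures
        data = {"temperature_C": np.round(base, 4)}
        for mc in mcs:
            if mc.temperatures.shape != base.shape or not np.allclose(mc.temperatures, base):
                raise ValueError(f"well {mc.id!r} is not on the shared grid")
            data[f"{mc.id}|{mc.primer}"] = mc.fluorescence
        pd.DataFrame(data).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _sniff_dialect(path) -> str:
    header = pd.read_csv(path, nrows=0).columns.tolist()
    if header[:4] == LONG_COLUMNS:
        return "long"
    if header and header[0] == "temperature_C":
        return "wide"
    raise ValueError(
        f"cannot sniff curve CSV dialect from header {header[:5]}"
    )


def read_melt_curves(
    path, dialect: Optional[str] = None
) -> Union[list[MeltCurve], LabeledCurveSet]:
    """Read a curve CSV; returns a LabeledCurveSet when label columns exist.

    All wells must share one uniform temperature grid; otherwise the
    offending well and both grids are reported.
    """
    if dialect is None:
        dialect = _sniff_dialect(path)
    df = pd.read_csv(path, dtype=str)
    if dialect == "long":
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"long curve CSV is missing columns {missing}")
        temps = _numeric(df["temperature_C"], "temperature_C")
        fluor = _numeric(df["fluorescence"], "fluorescence")
        df = df.assign(_t=temps, _f=fluor)
        labeled = "species" in df.columns
        curves, records = [], []
        ref_grid: Optional[np.ndarray] = None
        ref_well = ""
        for (well, primer), g in df.groupby(["well", "primer"], sort=False):
            if g.duplicated("_t").any():
                raise ValueError(f"well {well!r}: duplicate temperature rows")
            g = g.sort_values("_t")
            t = g["_t"].to_numpy()
            TemperatureGrid.from_temperatures(t)
            if ref_grid is None:
                ref_grid, ref_well = t, str(well)
            elif t.shape != ref_grid.shape or not np.allclose(t, ref_grid):
                raise ValueError(
                    f"well {well!r} grid [{t[0]:.4g}..{t[-1]:.4g}] x{t.size} "
                    f"differs from well {ref_well!r} grid "
                    f"[{ref_grid[0]:.4g}..{ref_grid[-1]:.4g}] x{ref_grid.size}"
                )
            mc = MeltCurve(id=str(well), primer=str(primer),
                           temperatures=t, fluorescence=g["_f"].to_numpy())
            curves.append(mc)
            if labeled:
                pop = g["population"].iloc[0] if "population" in g else ""
                records.append(CurveRecord(
                    curve=mc, species=str(g["species"].iloc[0]),
                    population=(str(pop) if isinstance(pop, str) and pop else None),
                    replicate_id=str(well)))
        if labeled:
            return LabeledCurveSet(records=tuple(records),
                                   grid=TemperatureGrid.from_temperatures(ref_grid))
        return curves
    if dialect == "wide":
        temps = _numeric(df["temperature_C"], "temperature_C")
        TemperatureGrid.from_temperatures(temps)
        curves = []
        for col in df.columns[1:]:
            if "|" not in col:
                raise ValueError(f"wide column {col!r} is not 'well|primer'")
            well, primer = col.split("|", 1)
            curves.append(MeltCurve(id=well, primer=primer, temperatures=temps,
                                    fluorescence=_numeric(df[col], col)))
        return curves
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Library / fingerprint JSON
# ---------------------------------------------------------------------------


def write_library(path, lib: ReferenceLibrary) -> None:
    """Library JSON: {"species": {sp: {primer: {"peaks": [...]}}}, "meta": {}}.

    Tm is serialized to 4 decimals, which round-trips 0.1 °C-precision
    values exactly.
    """
    doc: dict = {"species": {}, "meta": dict(lib.meta)}
    for (sp, pr), fp in sorted(lib.fingerprints.items()):
        doc["species"].setdefault(sp, {})[pr] = {
            "peaks": [
                {"tm": round(p.tm, 4), "height": round(p.height, 6)}
                for p in fp.peaks
            ]
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_library(path) -> ReferenceLibrary:
    """Read and validate a library JSON document.

    Schema violations are rejected with a JSON-pointer-style path to the
    offending element.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "species" not in doc:
        raise ValueError("library schema error at /: missing 'species'")
    fingerprints = {}
    for sp, primers in doc["species"].items():
        if not isinstance(primers, dict):
            raise ValueError(f"library schema error at /species/{sp}: not an object")
        for pr, entry in primers.items():
            ptr = f"/species/{sp}/{pr}"
            if not isinstance(entry, dict) or "peaks" not in entry:
                raise ValueError(f"library schema error at {ptr}: missing 'peaks'")
            peaks = []
            for i, p in enumerate(entry["peaks"]):
                if not isinstance(p, dict) or "tm" not in p:
                    raise ValueError(
                        f"library schema error at {ptr}/peaks/{i}: missing 'tm'")
                h = float(p.get("height", 1.0))
                peaks.append(MeltPeak(tm=float(p["tm"]), height=h,
                                      prominence=h, width=0.0))
            if (sp, pr) in fingerprints:
                raise ValueError(f"duplicate library entry at {ptr}")
            fingerprints[(sp, pr)] = MeltFingerprint(
                primer=pr, peaks=tuple(sorted(peaks, key=lambda q: q.tm)),
                source_id=f"lib:{sp}")
    species = tuple(sorted({sp for sp, _ in fingerprints}))
    prs = tuple(sorted({pr for _, pr in fingerprints}))
    return ReferenceLibrary(species=species, primers=prs,
                            fingerprints=fingerprints,
                            meta=doc.get("meta", {}))


def write_fingerprints(path, fps: Sequence[tuple[MeltFingerprint, dict]]) -> None:
    """Fingerprints JSON: a list of {id, primer, peaks, ...labels}."""
    doc = []
    for fp, labels in fps:
        doc.append({
            "id": fp.source_id, "primer": fp.primer,
            "peaks": [{"tm": round(p.tm, 4), "height": round(p.height, 6)}
                      for p in fp.peaks],
            **labels,
        })
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_fingerprints(path) -> list[tuple[MeltFingerprint, dict]]:
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for i, entry in enumerate(doc):
        for key in ("id", "primer", "peaks"):
            if key not in entry:
                raise ValueError(f"fingerprint schema error at /{i}: missing {key!r}")
        peaks = tuple(
            MeltPeak(tm=float(p["tm"]), height=float(p.get("height", 1.0)),
                     prominence=float(p.get("height", 1.0)), width=0.0)
            for p in sorted(entry["peaks"], key=lambda q: q["tm"])
        )
        fp = MeltFingerprint(primer=entry["primer"], peaks=peaks,
                             source_id=entry["id"])
        labels = {k: v for k, v in entry.items()
                  if k not in ("id", "primer", "peaks")}
        out.append((fp, labels))
    return out


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Flat, versioned run configuration (YAML-compatible key-value file)."""

    config_version: int = 1
    grid_start: float = 55.0
    grid_stop: float = 95.0
    grid_step: float = 0.1
    pre_region: Optional[tuple[float, float]] = None
    post_region: Optional[tuple[float, float]] = None
    smooth_window: float = 1.5
    min_prominence: float = 0.05
    min_height: float = 0.02
    min_separation: float = 0.8
    tolerance: float = 0.3
    unmatched_penalty: float = 1.0
    reject_threshold: float = 0.5
    uniqueness_threshold: float = 0.25
    seed: int = 0
    replicates: int = 3
    tm_jitter_sd: Optional[float] = None
    noise_sd: Optional[float] = None
    amplitude_jitter_cv: Optional[float] = None

    def processing(self) -> ProcessingConfig:
        return ProcessingConfig(
            pre_region=self.pre_region, post_region=self.post_region,
            smooth_window=self.smooth_window,
            min_prominence=self.min_prominence,
            min_height=self.min_height,
            min_separation=self.min_separation,
        )

    def grid(self) -> TemperatureGrid:
        return TemperatureGrid(self.grid_start, self.grid_stop, self.grid_step)


def load_config(path) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping of keys to values")
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    version = doc.get("config_version", 1)
    if version != 1:
        raise ValueError(f"unsupported config_version {version}")
    for key in ("pre_region", "post_region"):
        if doc.get(key) is not None:
            doc[key] = tuple(float(x) for x in doc[key])
    return RunConfig(**doc)
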