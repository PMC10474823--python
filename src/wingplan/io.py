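"""Readers, writers and run configuration.

Morphometric tables are delimited text (comma or tab) with one row per
specimen.  Header names are resolved case-insensitively through a synonym
map, and a per-file unit declaration (mm or cm) converts lengths to the
canonical internal unit, cm, on ingest.  Rows missing any required value
are skipped with a logged warning, never imputed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

from .estimators import FoldedWingMeasurements, InvalidMeasurementError
from .pgls import Phylogeny
from .spreadwing import WingImage

__all__ = [
    "RunConfig",
    "COLUMN_SYNONYMS",
    "read_morphometrics",
    "write_morphometrics",
    "read_newick",
    "read_wing_image",
    "write_mask_png",
    "run_report",
]

logger = logging.getLogger("wingplan")

#: editable header-synonym map; keys are canonical names, values the accepted
#: spellings after lowercasing and stripping non-alphanumerics
COLUMN_SYNONYMS = {
    "specimen_id": ["specimen_id", "specimenid", "id", "catalog", "catalognumber"],
    "species": ["species", "taxon", "scientificname"],
    "wingspan": ["wingspan", "ws", "span"],
    "wing_length": ["wing_length", "winglength", "wl", "winglengthmm", "winglengthcm"],
    "s1": ["s1", "wing_width", "wingwidth", "secondary1", "s1mm", "s1cm"],
}

_UNIT_TO_CM = {"cm": 1.0, "mm": 0.1}


@dataclass
class RunConfig:
    """Resolved options of one run; serialisable so runs are reproducible."""

    units: str = "cm"
    model: str = "ellipse-triangle"
    diff_mode: str = "ratio-of-means"
    box_policy: str = "strict"  # or "clamp"
    seed: int = 0
    percent_decimals: int = 1
    area_sig_figs: int = 4

    def __post_init__(self):
        if self.units not in _UNIT_TO_CM:
            raise ValueError(f"units must be mm or cm, got {self.units!r}")
        if self.box_policy not in ("strict", "clamp"):
            raise ValueError(f"box_policy must be strict or clamp, got {self.box_policy!r}")

    @property
    def clamp(self) -> bool:
        return self.box_policy == "clamp"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def _norm_header(name: str) -> str:
    return "".join(ch for ch in str(name).lower() if ch.isalnum() or ch == "_").strip("_")


def _resolve_columns(columns, synonyms=None) -> dict:
    synonyms = synonyms or COLUMN_SYNONYMS
    resolved = {}
    normed = {_norm_header(c): c for c in columns}
    for canonical, names in synonyms.items():
        for cand in names:
            key = _norm_header(cand)
            if key in normed:
                resolved[canonical] = normed[key]
                break
    return resolved


def _read_delimited(path) -> pd.DataFrame:
    """Comma or tab delimited text; '.' is the only accepted decimal mark."""
    head = Path(path).read_text().splitlines()
    if not head:
        raise ValueError(f"{path}: empty file")
    sep = "\t" if head[0].count("\t") >= head[0].count(",") and "\t" in head[0] else ","
    return pd.read_csv(path, sep=sep)


def read_morphometrics(
    path,
    units: str = "cm",
    *,
    synonyms: Optional[dict] = None,
    strict: bool = False,
) -> list[FoldedWingMeasurements]:
    """Read folded-wing measurement records from a delimited table.

    Lengths are converted from ``units`` to cm.  Rows with missing or
    non-positive WS/WL/S1 are skipped with a warning unless ``strict``.
    Raises a schema error listing the headers found when a required column
    cannot be resolved.
    """
    try:
        factor = _UNIT_TO_CM[units]
    except KeyError:
        raise ValueError(f"units must be mm or cm, got {units!r}") from None
    df = _read_delimited(path)
    cols = _resolve_columns(df.columns, synonyms)
    required = ["wingspan", "wing_length", "s1"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(
            f"{path}: could not resolve required column(s) {missing}; "
            f"found headers {list(df.columns)}"
        )
    records = []
    for idx, row in df.iterrows():
        rid = str(row[cols["specimen_id"]]) if "specimen_id" in cols else f"row{idx}"
        species = str(row[cols["species"]]) if "species" in cols else ""
        try:
            vals = [float(row[cols[c]]) for c in required]
            if any(np.isnan(v) for v in vals):
                raise InvalidMeasurementError("missing value")
            records.append(
                FoldedWingMeasurements(
                    wingspan=vals[0] * factor,
                    wing_length=vals[1] * factor,
                    wing_width=vals[2] * factor,
                    specimen_id=rid,
                    species=species,
                )
            )
        except (ValueError, TypeError, InvalidMeasurementError) as exc:
            if strict:
                raise InvalidMeasurementError(f"{path} row {idx} ({rid}): {exc}") from exc
            logger.warning("skipping row %s (%s): %s", idx, rid, exc)
    return records


def write_morphometrics(records, path) -> None:
    """Write measurement records as CSV (cm), full float precision."""
    pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "species": r.species,
                "wingspan": repr(r.wingspan),
                "wing_length": repr(r.wing_length),
                "s1": repr(r.wing_width),
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def read_newick(path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    text = Path(path).read_text()
    return Phylogeny.from_newick(text)


def read_wing_image(path, scale: float) -> WingImage:
    """Read a PNG/TIFF image as grayscale with a pixels-per-cm scale."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return WingImage(arr, scale)


def write_mask_png(mask, path) -> None:
    """Write a binary mask as an 8-bit PNG (255 = wing)."""
    Image.fromarray((np.asarray(mask.pixels, bool) * 255).astype(np.uint8)).save(path)


def run_report(results: dict, config: RunConfig, out_prefix) -> dict:
    """Write a run's results as JSON (+ CSV for tabular parts).

    ``results`` maps names to scalars, dicts or DataFrames.  DataFrames go
    to ``<prefix>_<name>.csv``; everything lands in ``<prefix>.json``
    together with the resolved configuration and package version, so a
    report is self-describing and byte-reproducible for a fixed config and
    seed.
    """
    from . import __version__

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    payload = {"wingplan_version": __version__, "config": json.loads(config.to_json())}
    written = {}
    for name, value in results.items():
        if isinstance(value, pd.DataFrame):
            csv_path = out_prefix.parent / f"{out_prefix.name}_{name}.csv"
            value.to_csv(csv_path, index=False)
            written[name] = str(csv_path)
            payload[name] = value.to_dict(orient="records")
        else:
            payload[name] = value
    json_path = out_prefix.with_suffix(".json")
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
    written["json"] = str(json_path)
    return written
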