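"""File I/O: historical-control CSV, mixture JSON, YAML configuration, and
run metadata.

Endpoint convention, fixed throughout: the endpoint is mean change from
baseline where larger values are worse, and the treatment effect delta is
control minus treatment mean change (positive delta = benefit). Every
report written here states it in its header/metadata.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hierarchical_map import HistoricalStudy, MapConfig
from .mixtures import NormalMixture

__all__ = [
    "read_historical_csv",
    "load_psp_historical",
    "write_mixture_json",
    "read_mixture_json",
    "load_map_config",
    "run_metadata",
    "ENDPOINT_NOTE",
]

ENDPOINT_NOTE = (
    "endpoint: mean change from baseline (higher = worse); "
    "delta = control minus treatment mean change (positive = benefit)"
)

_EXPECTED_COLUMNS = ["study", "n", "mean", "se"]


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


def read_historical_csv(path) -> list[HistoricalStudy]:
    """Parse a CSV of historical control summaries with header
    `study,n,mean,se`, validating every row; errors name row and column."""
    df = pd.read_csv(path)
    if list(df.columns) != _EXPECTED_COLUMNS:
        raise SchemaError(
            f"{path}: expected columns {_EXPECTED_COLUMNS}, found {list(df.columns)}"
        )
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")
    studies = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        for col in ("n", "mean", "se"):
            if not np.isfinite(pd.to_numeric(row[col], errors="coerce")):
                raise SchemaError(f"{path}: row {rowno}, column {col!r}: not numeric")
        n = float(row["n"])
        if n != int(n) or n < 1:
            raise SchemaError(f"{path}: row {rowno}, column 'n': must be a positive integer")
        if float(row["se"]) <= 0:
            raise SchemaError(f"{path}: row {rowno}, column 'se': must be positive")
        studies.append(
            HistoricalStudy(str(row["study"]), int(n), float(row["mean"]), float(row["se"]))
        )
    return studies


def load_psp_historical() -> list[HistoricalStudy]:
    """The packaged PSP Phase II placebo-arm summaries (PSPRS change at
    week 52): three randomized studies, n = 153, 31, 59."""
    with resources.as_file(resources.files("ecborrow.data") / "psp_table1.csv") as p:
        return read_historical_csv(p)


def write_mixture_json(mix: NormalMixture, path, extra: dict | None = None) -> None:
    payload = {"endpoint_convention": ENDPOINT_NOTE, **mix.to_dict()}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_mixture_json(path) -> NormalMixture:
    return NormalMixture.from_dict(json.loads(Path(path).read_text()))


def load_map_config(path) -> MapConfig:
    """Read the `map:` block of a YAML config into a MapConfig; keys mirror
    the dataclass fields and omitted keys keep their defaults."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    block = doc.get("map", doc)
    allowed = set(MapConfig.__dataclass_fields__)
    unknown = set(block) - allowed
    if unknown:
        raise SchemaError(f"{path}: unknown map config keys {sorted(unknown)}")
    return MapConfig(**block)


def run_metadata(seed: int | None, config: dict) -> dict:
    """Provenance block for output JSON: seed, config hash, and versions of
    the numerical libraries of record."""
    import scipy

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "endpoint_convention": ENDPOINT_NOTE,
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
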