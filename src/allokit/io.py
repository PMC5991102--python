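"""Delimited-text I/O for induction tables, event tables and posterior draws.

All tables are CSV with a header row; provenance (package version, seed,
config hash) is written as ``#``-prefixed comment lines that the readers
skip.  Concentrations are stored in molar; values with unit suffixes
(``"500 uM"``, ``"5mM"``) are normalized on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__

__all__ = [
    "parse_concentration",
    "read_induction_table",
    "write_table",
    "read_event_table",
    "read_config",
    "config_hash",
]

INDUCTION_COLUMNS = (
    "operator",
    "d_eps_ra_kT",
    "repressors",
    "iptg_M",
    "fold_change",
    "replicate",
)
_UNIT_FACTORS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9}


def parse_concentration(value) -> float:
    """Concentration in molar from a number or a suffixed string."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip().lower().replace(" ", "")
    for suffix in sorted(_UNIT_FACTORS, key=len, reverse=True):
        if text.endswith(suffix):
            return float(text[: -len(suffix)]) * _UNIT_FACTORS[suffix]
    return float(text)


def _provenance(seed: Optional[int], extra: Optional[dict] = None) -> str:
    fields = {"version": __version__}
    if seed is not None:
        fields["seed"] = seed
    if extra:
        fields.update(extra)
    return "".join(f"# {k}: {v}\n" for k, v in fields.items())


def write_table(
    table: pd.DataFrame,
    path,
    seed: Optional[int] = None,
    extra_provenance: Optional[dict] = None,
) -> None:
    """Write a CSV with a provenance comment header.

    Missing values (e.g. undefined EC50s, failed gates) are written as the
    explicit marker ``NA`` rather than dropped.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance(seed, extra_provenance))
        table.to_csv(fh, index=False, na_rep="NA")


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such table: {path}")
    return pd.read_csv(path, comment="#", na_values=["NA"])


def read_induction_table(path) -> pd.DataFrame:
    """Read a tidy induction table, checking columns and normalizing units."""
    table = _read_csv(path)
    missing = [c for c in INDUCTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: induction table missing columns {missing}")
    table["iptg_M"] = table["iptg_M"].map(parse_concentration)
    return table


def read_event_table(path) -> pd.DataFrame:
    table = _read_csv(path)
    missing = [c for c in ("fsc", "ssc", "fl") if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: event table missing columns {missing}")
    return table


def read_config(path) -> dict:
    """Read a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping of blocks")
    return config


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, for provenance headers."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
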