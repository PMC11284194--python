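"""Case-table and report I/O plus run configuration.

The interchange format is UTF-8 comma-delimited CSV with "." decimals. Report
files start with ``#``-prefixed provenance headers (tool version, seed,
config hash) so every output is reproducible from config + seed alone;
``pandas.read_csv(..., comment="#")`` reads them back.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigError, SchemaError
from .schema import DEFAULT_SCHEMA

__all__ = ["RunConfig", "read_case_table", "write_case_table", "write_report", "read_config"]

_INT_NA_COLUMNS = ("hunt_hess", "fisher_grade", "fda_category", "mrs_discharge")


@dataclass
class RunConfig:
    """Options threaded through the simulate - derive - match - compare chain."""

    seed: int = 0
    n_aoi: int = 14
    n_reference: int = 36
    rupture_rate: float = 0.5
    variant: str = "plain"
    k: int = 3
    fallback_merge: bool = True
    alpha: float = 0.05
    correction: str = "none"  # none | holm
    out_dir: str = "results"
    case_table: str = ""  # empty -> simulate

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.variant not in ("plain", "inverse_distance", "minmax_inverse"):
            raise ConfigError(f"unknown matching variant {self.variant!r}")
        if self.correction not in ("none", "holm"):
            raise ConfigError(f"unknown correction {self.correction!r}")

    def digest(self) -> str:
        # analysis-relevant options only: output location must not change the hash
        payload = ";".join(
            f"{f.name}={getattr(self, f.name)}" for f in fields(self) if f.name != "out_dir"
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_config(path: str | Path) -> RunConfig:
    """Parse a ``key = value`` text file into a :class:`RunConfig`."""
    kwargs: dict = {}
    casts = {f.name: f.type for f in fields(RunConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in casts:
            raise ConfigError(f"{path}:{lineno}: unknown option {key!r}")
        kind = casts[key]
        if kind == "int":
            kwargs[key] = int(value)
        elif kind == "float":
            kwargs[key] = float(value)
        elif kind == "bool":
            kwargs[key] = value.lower() in ("1", "true", "yes", "on")
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def read_case_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a case-table CSV."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"case table {path} does not exist")
    df = pd.read_csv(path, comment="#", dtype={"case_id": str})
    for col in _INT_NA_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    return DEFAULT_SCHEMA.validate(df)


def write_case_table(cases: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cases.to_csv(path, index=False)


def _header(seed: int, config: RunConfig | None) -> str:
    digest = config.digest() if config is not None else "n/a"
    return f"# aneumatch {__version__} seed={seed} config={digest}\n"


def write_report(results: dict[str, pd.DataFrame], out_dir: str | Path, seed: int,
                 config: RunConfig | None = None, summary: str | None = None) -> list[Path]:
    """Write each named frame as a provenance-stamped CSV, plus a text summary.

    Returns the written paths. Deterministic for fixed inputs: no timestamps.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in results.items():
        path = out / f"{name}.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_header(seed, config))
            frame.to_csv(fh, index=False)
        written.append(path)
    if summary is not None:
        path = out / "summary.txt"
        path.write_text(_header(seed, config) + summary, encoding="utf-8")
        written.append(path)
    return written
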