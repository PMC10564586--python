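"""CSV reading, pipeline configuration and artifact writing.

Interchange format is plain UTF-8 CSV with a ``year,value`` header, period
decimal separator, one series per file.  Every written artifact embeds the
configuration fingerprint and package version so identical inputs and
configuration reproduce byte-identical numeric content.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .series import Indicator, ObservationSeries, Sex

__all__ = ["PipelineConfig", "read_series_csv", "write_forecast_csv",
           "write_diagnostics_csv", "write_model_json"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the published pipeline; the defaults reproduce it exactly."""

    prefix_value: float = 10.0
    grid_step_years: int = 5
    horizon_steps: int = 2
    rounding_digits: int = 1
    prevalence_prefix: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def fingerprint(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def read_series_csv(path: str | Path,
                    indicator: Indicator | str = Indicator.HEIGHT,
                    sex: Sex | str = Sex.BOYS,
                    age_years: int | None = None) -> ObservationSeries:
    """Parse a ``year,value`` CSV into a validated observation series."""
    path = Path(path)
    points: list[tuple[int, float]] = []
    seen: dict[int, int] = {}
    with path.open(newline="") as f:
        reader = csv.reader(f)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if [h.strip().lower() for h in header[:2]] != ["year", "value"]:
            raise ValueError(f"{path}: expected header 'year,value', got {header!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            try:
                year, value = int(row[0]), float(row[1])
            except (ValueError, IndexError):
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}") from None
            if year in seen:
                raise ValueError(f"{path}:{lineno}: duplicate year {year} "
                                 f"(first seen at line {seen[year]})")
            if value <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive value {value}")
            seen[year] = lineno
            points.append((year, value))
    if not points:
        raise ValueError(f"{path}: no data rows")
    points.sort()
    return ObservationSeries(indicator=Indicator(indicator), sex=Sex(sex),
                             age_years=age_years, points=tuple(points))


def _version() -> str:
    from . import __version__
    return __version__


def _stamp(config: PipelineConfig) -> str:
    return f"greytrend {_version()} config {config.fingerprint()}"


def write_model_json(path: str | Path, model, config: PipelineConfig) -> None:
    payload = model.to_dict()
    payload["_meta"] = {"package": f"greytrend {_version()}",
                        "config": asdict(config),
                        "config_fingerprint": config.fingerprint()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_diagnostics_csv(path: str | Path, diagnostics, config: PipelineConfig) -> None:
    lines = [f"# {_stamp(config)}"]
    lines.append(diagnostics.table.to_csv(index=False).rstrip("\n"))
    summary = diagnostics.to_dict()
    lines.append("")
    lines.extend(f"# {k}: {v}" for k, v in summary.items())
    Path(path).write_text("\n".join(lines) + "\n")


def write_forecast_csv(path: str | Path, record, config: PipelineConfig) -> None:
    lines = [f"# {_stamp(config)}", "year,value,kind"]
    for year, value in sorted(record.fitted.items()):
        lines.append(f"{year},{value!r},fitted")
    for year, value in sorted(record.predicted.items()):
        lines.append(f"{year},{value!r},predicted")
    Path(path).write_text("\n".join(lines) + "\n")
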