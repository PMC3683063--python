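"""File dialects, scenario configs, run manifests and human-readable reports.

Dialects (all plain text):

- growth-curve CSV: header ``time_h,<well>,<well>,...``; one row per reading.
- rate-design CSV: columns ``concentration`` and ``rate_per_h`` (or
  ``doubling_min``), optional ``replicate``.
- trace TSV: columns ``position``, one per unit spectrum, final ``mixed``.
- composition CSV (written): ``index,population,level,fraction,below_detection``.

Readers validate rather than coerce: a missing time column, non-monotone
times or a non-numeric cell is an error, never a silent fix.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .batch import CompetitionSeries
from .kinetics import GrowthCurve, RateConcentrationDesign
from .unmix import TraceMatrix, UnmixResult

__all__ = [
    "read_growth_csv",
    "write_growth_csv",
    "read_rate_design_csv",
    "write_rate_design_csv",
    "read_trace_tsv",
    "write_trace_tsv",
    "write_series_csv",
    "RunManifest",
    "report_lines",
    "GrowthCsvError",
]

class GrowthCsvError(ValueError):
    """Malformed growth-curve CSV; message aggregates per-column problems."""


def _read_numeric_csv(path: str | Path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    problems = []
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            problems.append(f"column {col!r}: non-numeric value at row {bad[0]}")
        df[col] = coerced
    if problems:
        raise GrowthCsvError("; ".join(problems))
    return df


def read_growth_csv(
    path: str | Path,
    condition: str = "anaerobic",
) -> list[GrowthCurve]:
    """Read a growth-curve CSV (``time_h`` column + one column per well)."""
    df = _read_numeric_csv(path)
    if "time_h" not in df.columns:
        raise GrowthCsvError("missing required 'time_h' column")
    t = df["time_h"].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        raise GrowthCsvError("column 'time_h': missing value")
    if not np.all(np.diff(t) > 0):
        raise GrowthCsvError("column 'time_h': times not strictly increasing")
    wells = [c for c in df.columns if c != "time_h"]
    if not wells:
        raise GrowthCsvError("no well columns found")
    return [
        GrowthCurve(times=t, od=df[w].to_numpy(dtype=float),
                    replicate_id=str(w), condition=condition)
        for w in wells
    ]


def write_growth_csv(path: str | Path, curves: Sequence[GrowthCurve]) -> None:
    t = curves[0].times
    for c in curves[1:]:
        if not np.array_equal(c.times, t):
            raise ValueError("all curves must share one time grid")
    df = pd.DataFrame({"time_h": t})
    for c in curves:
        df[c.replicate_id or f"well{len(df.columns)}"] = c.od
    df.to_csv(path, index=False)


def read_rate_design_csv(path: str | Path) -> RateConcentrationDesign:
    """Read a rate-design CSV; ``doubling_min`` is converted to a rate (1/h)."""
    df = _read_numeric_csv(path)
    if "concentration" not in df.columns:
        raise GrowthCsvError("missing required 'concentration' column")
    if "rate_per_h" in df.columns:
        rates = df["rate_per_h"].to_numpy(dtype=float)
    elif "doubling_min" in df.columns:
        rates = np.log(2.0) / (df["doubling_min"].to_numpy(dtype=float) / 60.0)
    else:
        raise GrowthCsvError("need a 'rate_per_h' or 'doubling_min' column")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return RateConcentrationDesign(
        concentrations=df["concentration"].to_numpy(dtype=float),
        rates=rates, replicate=rep)


def write_rate_design_csv(path: str | Path,
                          design: RateConcentrationDesign) -> None:
    df = pd.DataFrame({"concentration": design.concentrations,
                       "rate_per_h": design.rates})
    if design.replicate is not None:
        df["replicate"] = design.replicate
    df.to_csv(path, index=False)


def read_trace_tsv(path: str | Path) -> TraceMatrix:
    """Read a trace TSV: ``position`` column, unit-spectrum columns, ``mixed``."""
    df = _read_numeric_csv(path, sep="\t")
    for col in ("position", "mixed"):
        if col not in df.columns:
            raise GrowthCsvError(f"missing required {col!r} column")
    labels = [c for c in df.columns if c not in ("position", "mixed")]
    if not labels:
        raise GrowthCsvError("no unit-spectrum columns found")
    return TraceMatrix(
        positions=df["position"].to_numpy(),
        unit_spectra=df[labels].to_numpy(dtype=float),
        mixed=df["mixed"].to_numpy(dtype=float),
        labels=tuple(labels),
    )


def write_trace_tsv(path: str | Path, tm: TraceMatrix) -> None:
    df = pd.DataFrame({"position": tm.positions})
    for j, lab in enumerate(tm.labels):
        df[lab] = tm.unit_spectra[:, j]
    df["mixed"] = tm.mixed
    df.to_csv(path, sep="\t", index=False)


def write_series_csv(path: str | Path, series: CompetitionSeries) -> None:
    """Write a composition series in tidy long form."""
    series.tidy().to_csv(path, index=False)


@dataclass(frozen=True)
class RunManifest:
    """Provenance record emitted once per pipeline invocation."""

    command: str
    config_hash: str
    seed: int | None
    version: str
    outputs: tuple[str, ...]
    timestamp: str

    @classmethod
    def create(cls, command: str, config: Mapping | None, seed: int | None,
               outputs: Sequence[str | Path]) -> "RunManifest":
        from . import __version__

        blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
        return cls(
            command=command,
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            seed=seed,
            version=__version__,
            outputs=tuple(str(o) for o in outputs),
            timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def report_lines(outputs: Mapping[str, object]) -> list[str]:
    """Human-readable summary of computed scenario/analysis outputs.

    Pure formatting: accepts a mapping of names to result objects
    (ScenarioOutcome, UnmixResult, plain mappings) and renders one block per
    entry.
    """
    from .scenarios import ScenarioOutcome

    lines: list[str] = []
    for name, obj in outputs.items():
        lines.append(f"== {name} ==")
        if isinstance(obj, ScenarioOutcome):
            w = obj.winner()
            if w is not None:
                final = obj.strain_series.fractions.iloc[-1]
                lines.append(f"  winner: {w} "
                             f"(final fractions: "
                             f"{', '.join(f'{k}={v:.3f}' for k, v in final.items())})")
            for k, v in obj.extras.items():
                if isinstance(v, (int, float, str)):
                    lines.append(f"  {k}: {v}")
        elif isinstance(obj, UnmixResult):
            props = ", ".join(
                f"{lab}={p:.3f}{'*' if flag else ''}"
                for lab, p, flag in zip(obj.labels, obj.proportions,
                                        obj.below_detection))
            lines.append(f"  proportions: {props} (* below detection limit)")
            lines.append(f"  R^2 = {obj.r_squared:.4f}, p = {obj.p_value:.3g}")
        elif isinstance(obj, Mapping):
            for k, v in obj.items():
                lines.append(f"  {k}: {v}")
        else:
            lines.append(f"  {obj}")
    return lines
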