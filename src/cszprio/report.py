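"""Run manifests and report writing shared by the CLI and the library."""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .scoring import DiseaseScore, scores_to_frame

__all__ = ["RunManifest", "write_weight_report", "write_priority_list", "plot_data"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every output file.

    Captures the input files (with content digests), the package version,
    seeds, and the options in effect, so a run can be reproduced exactly.
    """

    command: str
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    options: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _digest(p)

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


def write_weight_report(
    tables: Mapping[str, pd.DataFrame], directory: str | Path, prefix: str = "weights"
) -> list[Path]:
    """Write one Table-2-style CSV per criterion set plus a JSON consistency
    summary; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    consistency_summary = {}
    for set_id, table in tables.items():
        out = directory / f"{prefix}_{set_id}.csv"
        table.to_csv(out, index=False)
        written.append(out)
        if "consistency" in table.attrs:
            consistency_summary[set_id] = table.attrs["consistency"]
    summary_path = directory / f"{prefix}_consistency.json"
    summary_path.write_text(json.dumps(consistency_summary, indent=2) + "\n")
    written.append(summary_path)
    return written


def write_priority_list(
    scores: Sequence[DiseaseScore],
    directory: str | Path,
    *,
    n_participants: int,
    n_questions: int,
) -> list[Path]:
    """Write the ranked priority list (CSV + JSON) and plot-ready long data."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = scores_to_frame(
        scores, n_participants=n_participants, n_questions=n_questions
    )
    csv_path = directory / "priority_list.csv"
    df.to_csv(csv_path, index=False)
    json_path = directory / "priority_list.json"
    json_path.write_text(df.to_json(orient="records", indent=2) + "\n")
    long_path = directory / "priority_plot_data.csv"
    plot_data(scores).to_csv(long_path, index=False)
    return [csv_path, json_path, long_path]


def plot_data(scores: Sequence[DiseaseScore]) -> pd.DataFrame:
    """Long-format normalized scores for dot-and-range charts: one row per
    (disease, estimate) with estimate in {initial, lower, upper}."""
    rows = []
    for s in scores:
        for estimate, value in (
            ("initial", s.normalized),
            ("lower", s.normalized_low),
            ("upper", s.normalized_high),
        ):
            rows.append(
                {"disease_id": s.disease_id, "rank": s.rank, "estimate": estimate, "value": value}
            )
    return pd.DataFrame(rows)
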