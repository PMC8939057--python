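"""Readers, writers and run configuration.

Responses travel as plain CSV (one row per person, item columns with
categories 1..5, covariate columns, mandatory ``pid`` column); analysis
configuration as YAML.  Reports are written as CSV tables mirroring the
summary/per-item layouts plus a JSON trace and a run log carrying the seeds
and a configuration hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pcm import ResponseMatrix
from .shortening import ContentFlags, ShorteningConfig, ShorteningTrace
from .testlets import ConversionTable

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "read_responses_csv",
    "write_responses_csv",
    "write_reports",
    "write_conversion_csv",
]

COVARIATE_COLUMNS = ("gender", "country", "age", "age_group")
SUMMARY_COLUMNS = [
    "analysis",
    "item_res_mean",
    "item_res_sd",
    "person_res_mean",
    "person_res_sd",
    "chisq",
    "chisq_p",
    "psi",
    "unidim_pct",
    "unidim_ci_low",
    "unidim_ci_high",
]


@dataclass
class AnalysisConfig:
    """Validated run configuration (YAML-serialisable)."""

    subscale_map: dict[str, str]
    min_items: int = 3
    alpha: float = 0.01
    n_class_intervals: int | None = None
    extreme_adjust: float = 0.3
    dif_factors: tuple[str, ...] = ("gender", "age_group", "country")
    content_categories: dict[str, int] = field(default_factory=dict)
    protected_items: tuple[str, ...] = ()
    label_prefix: str = "SCALE"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        for item in self.content_categories:
            if item not in self.subscale_map:
                raise ValueError(f"content flag for unknown item {item!r}")
        for item in self.protected_items:
            if item not in self.subscale_map:
                raise ValueError(f"protected unknown item {item!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "dif_factors" in raw:
            raw["dif_factors"] = tuple(raw["dif_factors"])
        if "protected_items" in raw:
            raw["protected_items"] = tuple(raw["protected_items"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "subscale_map": dict(self.subscale_map),
            "min_items": self.min_items,
            "alpha": self.alpha,
            "n_class_intervals": self.n_class_intervals,
            "extreme_adjust": self.extreme_adjust,
            "dif_factors": list(self.dif_factors),
            "content_categories": dict(self.content_categories),
            "protected_items": list(self.protected_items),
            "label_prefix": self.label_prefix,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(
            {
                "subscale_map": self.subscale_map,
                "min_items": self.min_items,
                "alpha": self.alpha,
                "n_class_intervals": self.n_class_intervals,
                "extreme_adjust": self.extreme_adjust,
                "dif_factors": list(self.dif_factors),
                "content_categories": self.content_categories,
                "protected_items": list(self.protected_items),
                "label_prefix": self.label_prefix,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def shortening_config(self) -> ShorteningConfig:
        return ShorteningConfig(
            min_items=self.min_items,
            alpha=self.alpha,
            n_class_intervals=self.n_class_intervals,
            extreme_adjust=self.extreme_adjust,
            dif_factors=self.dif_factors,
            content=ContentFlags(
                categories=dict(self.content_categories),
                protected=set(self.protected_items),
            ),
            label_prefix=self.label_prefix,
        )


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------


def read_responses_csv(path: str | Path, config: AnalysisConfig) -> ResponseMatrix:
    """Load survey responses; categories 1..5 are recoded to 0..4 and
    incomplete rows dropped (complete-case contract, with a logged count)."""
    df = pd.read_csv(path)
    if "pid" not in df.columns:
        raise ValueError("responses CSV requires a 'pid' column")
    if df["pid"].duplicated().any():
        dup = df.loc[df["pid"].duplicated(), "pid"].iloc[0]
        raise ValueError(f"duplicate person id {dup!r}")
    df = df.set_index("pid")
    items = list(config.subscale_map)
    unknown = [c for c in df.columns if c not in items and c not in COVARIATE_COLUMNS]
    if unknown:
        raise ValueError(f"unknown item column(s): {unknown}")
    missing_items = [i for i in items if i not in df.columns]
    if missing_items:
        raise ValueError(f"missing item column(s): {missing_items}")

    complete = df[items].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d incomplete rows (complete-case contract)", n_dropped)
    df = df.loc[complete]

    raw = df[items]
    bad = (raw < 1) | (raw > 5) | (raw != raw.round())
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"invalid category {raw.iat[r, c]!r} at pid={raw.index[r]!r}, "
            f"item {raw.columns[c]!r} (must be an integer 1..5)"
        )
    scores = (raw.astype(int) - 1)
    covars = [c for c in COVARIATE_COLUMNS if c in df.columns]
    return ResponseMatrix(
        scores=scores,
        person_factors=df[covars].copy(),
        subscale_map=dict(config.subscale_map),
        max_scores={i: 4 for i in items},
    )


def write_responses_csv(responses: ResponseMatrix, path: str | Path) -> None:
    """Inverse of :func:`read_responses_csv` (scores recoded back to 1..5)."""
    out = (responses.scores + 1).copy()
    for c in responses.person_factors.columns:
        out[c] = responses.person_factors[c]
    out.index.name = "pid"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_conversion_csv(table: ConversionTable, path: str | Path) -> None:
    table.to_csv_frame().to_csv(path, index=False)


def write_reports(
    trace: ShorteningTrace,
    outdir: str | Path,
    *,
    config: AnalysisConfig | None = None,
) -> list[Path]:
    """Serialize a shortening trace: summary CSV (one row per analysis),
    per-item CSVs, DIF CSVs, the JSON trace and a run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rows = [s.report.summary_row() for s in trace.steps]
    if trace.testlet_report is not None:
        rows.append(trace.testlet_report.summary_row())
    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    p = outdir / "summary_fit.csv"
    summary.to_csv(p, index=False)
    written.append(p)

    item_rows = []
    for s in trace.steps:
        t = s.report.item_table.copy()
        t.insert(0, "analysis", s.label)
        item_rows.append(t.reset_index())
    p = outdir / "item_fit.csv"
    pd.concat(item_rows, ignore_index=True).to_csv(p, index=False)
    written.append(p)

    dif_rows = []
    for s in trace.steps:
        if s.dif is not None:
            t = s.dif.table.copy()
            t.insert(0, "analysis", s.label)
            dif_rows.append(t)
    if dif_rows:
        p = outdir / "dif_tables.csv"
        pd.concat(dif_rows, ignore_index=True).to_csv(p, index=False)
        written.append(p)

    p = outdir / "trace.json"
    p.write_text(trace.to_json())
    written.append(p)

    p = outdir / "run_log.txt"
    lines = [f"final_roster: {','.join(trace.final_roster)}"]
    if config is not None:
        lines.insert(0, f"config_hash: {config.digest()}")
        lines.insert(1, f"seed: {config.seed}")
    for s in trace.steps:
        for sub, rec in s.removed.items():
            lines.append(f"{s.label}: removed {rec['rationale']}")
    p.write_text("\n".join(lines) + "\n")
    written.append(p)
    return written
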