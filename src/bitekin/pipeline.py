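"""End-to-end orchestration: directory of bite tables -> reports.

For every bite CSV in the input directory the pipeline reads and (if
needed) calibrates the landmark table, builds the kinematic profile,
segments the phases, scores the behaviours and summarizes the bite.
Across bites it then fits the lever model on the ventral-expansion
intervals and runs the behavioural statistics (logistic fits of event
presence on algal length, and the unequal-variance comparison of first
vs second opening durations).

Per-bite failures are reported and skipped; the pipeline fails only if
every bite fails. Reruns with the same inputs and configuration are
deterministic; the run log echoes every threshold that affects output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from . import __version__
from .errors import BitekinError, SeparationError, StatsError
from .io import CalibrationScale, apply_calibration, read_landmark_table
from .lever import fit_lever_model, measure_levers, observe_bite
from .phases import PhaseParams, analyze_bite
from .stats import fit_logistic, heteroscedastic_compare, mean_se, odds_crossing

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_dir: Path
    output_dir: Path
    params: PhaseParams = field(default_factory=PhaseParams)
    seed: int = 0
    write_profiles: bool = True

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if not self.input_dir.is_dir():
            raise BitekinError(f"input dir does not exist: {self.input_dir}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Build a run configuration from a YAML file.

        Recognized keys: ``input_dir``, ``output_dir``, ``seed``,
        ``write_profiles`` and a ``params`` mapping whose entries
        override individual :class:`PhaseParams` thresholds. Keyword
        arguments (e.g. from CLI flags) override the file.
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        params_kw = raw.pop("params", {}) or {}
        unknown = set(params_kw) - {f.name for f in dataclasses.fields(PhaseParams)}
        if unknown:
            raise BitekinError(f"unknown phase parameters in config: {sorted(unknown)}")
        kw = {k: v for k, v in raw.items() if v is not None}
        kw.update({k: v for k, v in overrides.items() if v is not None})
        kw.setdefault("params", PhaseParams(**params_kw))
        return cls(**kw)


def _summary_row(name: str, summary) -> Dict:
    row = {"bite": name}
    row.update(dataclasses.asdict(summary))
    return row


def load_bite(path: Path):
    """Read a bite table and calibrate it to mm if it is in pixels."""
    lset = read_landmark_table(path)
    if lset.meta.units == "px":
        if lset.meta.mm_per_pixel is None:
            raise BitekinError(f"{path}: pixel units but no mm_per_pixel in sidecar")
        scale = CalibrationScale(lset.meta.mm_per_pixel)
        lset = apply_calibration(lset, scale)
    return lset


def run_pipeline(config: RunConfig) -> Dict:
    """Run the full analysis over a directory of bites; returns the report
    dict that is also written to ``stats_report.json``."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    bite_files = sorted(config.input_dir.glob("*.csv"))
    bite_files = [p for p in bite_files if not p.name.startswith("behavior")]
    if not bite_files:
        raise BitekinError(f"no bite CSV files in {config.input_dir}")

    rows: List[Dict] = []
    lever_obs = []
    failures: Dict[str, str] = {}
    for path in bite_files:
        try:
            lset = load_bite(path)
            profile, cycles, seg, summary = analyze_bite(lset, config.params)
            rows.append(_summary_row(path.stem, summary))
            if config.write_profiles:
                profile.to_frame().to_csv(out / f"profile_{path.stem}.csv", index=False)
            obs = observe_bite(lset, profile, seg, measure_levers(lset))
            if obs is not None:
                lever_obs.append(obs)
        except BitekinError as exc:
            log.error("bite %s failed: %s", path.name, exc)
            failures[path.name] = str(exc)
    if not rows:
        raise BitekinError("all bites failed")

    summaries = pd.DataFrame(rows)
    summaries.to_csv(out / "summaries.csv", index=False)

    lever_fit = fit_lever_model(lever_obs)
    lever_report = {
        "n_observations": len(lever_obs),
        "observations": [dataclasses.asdict(o) for o in lever_obs],
        "input_regression": dataclasses.asdict(lever_fit.input_regression)
        if lever_fit.input_regression
        else None,
        "output_regression": dataclasses.asdict(lever_fit.output_regression)
        if lever_fit.output_regression
        else None,
    }
    pd.DataFrame([dataclasses.asdict(o) for o in lever_obs]).to_csv(
        out / "lever_observations.csv", index=False
    )

    stats_report: Dict = {"events": {}, "durations": {}}
    # logistic fits of event presence on algal length
    for event, col in (("ventral_expansion", "ventral_expansion"), ("suction", "suction_1")):
        sub = summaries.dropna(subset=["algal_length_mm"])
        sub = sub[sub[col].notna()]
        if len(sub) >= 10:
            try:
                fit = fit_logistic(
                    np.column_stack(
                        [sub["algal_length_mm"], sub[col].astype(float)]
                    )
                )
                stats_report["events"][event] = {
                    "intercept": fit.intercept,
                    "slope": fit.slope,
                    "z_slope": fit.z_slope,
                    "p_slope": fit.p_slope,
                    "crossing_mm": odds_crossing(fit),
                    "n": fit.n,
                }
            except (SeparationError, StatsError) as exc:
                stats_report["events"][event] = {"error": str(exc)}
        else:
            stats_report["events"][event] = {"error": "too few observations"}

    first = summaries["first_opening_ms"].dropna().to_numpy(float)
    second = summaries["second_opening_ms"].dropna().to_numpy(float)
    for name, vals in (("first_opening_ms", first), ("second_opening_ms", second)):
        if len(vals) >= 2:
            m, se = mean_se(vals)
            stats_report["durations"][name] = {"mean": m, "se": se, "n": len(vals)}
    if len(first) >= 3 and len(second) >= 3:
        cmp_ = heteroscedastic_compare(first, second)
        stats_report["durations"]["first_vs_second"] = dataclasses.asdict(cmp_)

    report = {
        "version": __version__,
        "seed": config.seed,
        "params": dataclasses.asdict(config.params),
        "n_bites": len(rows),
        "failures": failures,
        "lever_model": lever_report,
        "stats": stats_report,
    }
    (out / "stats_report.json").write_text(json.dumps(report, indent=2, default=float))
    # run log: everything that could change the output, plus outcomes
    lines = [
        f"bitekin {__version__}",
        f"seed: {config.seed}",
        f"input: {config.input_dir}",
        "params: " + json.dumps(dataclasses.asdict(config.params)),
        f"bites analyzed: {len(rows)}",
    ]
    lines += [f"failed: {name}: {msg}" for name, msg in failures.items()]
    (out / "run.log").write_text("\n".join(lines) + "\n")
    log.info("analyzed %d bite(s), %d failure(s)", len(rows), len(failures))
    return report
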