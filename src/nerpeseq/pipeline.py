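"""End-to-end orchestration: FASTQ in, tables and summary out.

``run_pipeline`` processes the control and experiment read sets, derives the
normalization factors from the control templates, fits the model and writes
every table, the JSON summary, both filter reports and a run log into the
output directory.  All behaviour is driven by a :class:`RunConfig` (loadable
from YAML), which is echoed verbatim into the output directory so a run can
be reproduced from its artifacts alone.
"""

from __future__ import annotations

import dataclasses
import importlib.metadata
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .construct import ConstructSpec
from .model import PrimerExtensionModel, PrimerExtensionResults, SUMMARY_SCHEMA
from .reads import process_fastq, write_pairs_tsv
from .stats import DegenerateControlError

logger = logging.getLogger("nerpeseq")


class ConfigError(Exception):
    """Invalid or unresolvable run configuration (exit code 2)."""


class DataError(Exception):
    """Input data cannot support the analysis (exit code 3)."""


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    experiment_r1: str
    experiment_r2: str
    control_r1: str
    control_r2: str
    out_dir: str
    construct: Optional[str] = None  # YAML path; None = package default construct
    min_mean_q: float = 30.0
    min_base_q: int = 20
    max_disagreements: int = 0
    normalize: bool = True
    seed: Optional[int] = None  # recorded in the log; the analysis itself is
    # deterministic, the seed matters only for upstream simulation

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        try:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        except OSError as e:
            raise ConfigError(f"cannot read config {path}: {e}") from e
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} is not a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"experiment_r1", "experiment_r2", "control_r1",
                   "control_r2", "out_dir"} - set(data)
        if missing:
            raise ConfigError(f"missing config keys: {sorted(missing)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("experiment_r1", "experiment_r2", "control_r1", "control_r2"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise ConfigError(f"{name}: no such file: {p}")
        if self.construct is not None and not Path(self.construct).is_file():
            raise ConfigError(f"construct: no such file: {self.construct}")


def _version() -> str:
    try:
        return importlib.metadata.version("nerpeseq")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def run_pipeline(config: RunConfig) -> PrimerExtensionResults:
    """Execute extraction + statistics for one experiment/control pair."""
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n"
    )

    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        spec = (ConstructSpec.from_yaml(config.construct)
                if config.construct else ConstructSpec())
        logger.info("nerpeseq %s, seed=%s", _version(), config.seed)
        logger.info("construct: %s", spec.to_dict())

        filt = dict(
            min_mean_q=config.min_mean_q,
            min_base_q=config.min_base_q,
            max_disagreements=config.max_disagreements,
        )
        ctl_pairs, ctl_report = process_fastq(
            config.control_r1, config.control_r2, spec, **filt
        )
        logger.info("control: %s", ctl_report.to_dict())
        pairs, report = process_fastq(
            config.experiment_r1, config.experiment_r2, spec, **filt
        )
        logger.info("experiment: %s", report.to_dict())

        write_pairs_tsv(ctl_pairs, outdir / "control_pairs.tsv")
        write_pairs_tsv(pairs, outdir / "experiment_pairs.tsv")
        ctl_report.save(outdir / "control_filter_report.json")
        report.save(outdir / "experiment_filter_report.json")

        if not pairs:
            raise DataError("no experiment reads passed the filters")
        if config.normalize and not ctl_pairs:
            raise DataError("no control reads passed the filters")

        try:
            model = PrimerExtensionModel(
                pairs,
                ctl_pairs if config.normalize else None,
                normalize=config.normalize,
            )
            results = model.fit()
        except DegenerateControlError as e:
            raise DataError(str(e)) from e

        results.save(outdir)
        logger.info("summary: %s", results.to_dict())
        return results
    finally:
        logger.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# Run comparison
# ---------------------------------------------------------------------------


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        elif isinstance(v, (int, float)) and not isinstance(v, bool):
            out[key] = float(v)
    return out


def compare_runs(summary_a: dict | str | Path, summary_b: dict | str | Path) -> pd.DataFrame:
    """Per-statistic deltas and ratios between two run summaries.

    Accepts summary dicts or paths to ``summary.json`` files; both must carry
    the same schema tag.
    """

    def load(s):
        if isinstance(s, (str, Path)):
            with open(s) as fh:
                return json.load(fh)
        return s

    a, b = load(summary_a), load(summary_b)
    if a.get("schema") != SUMMARY_SCHEMA or b.get("schema") != SUMMARY_SCHEMA:
        raise DataError(
            f"summary schema mismatch: {a.get('schema')!r} vs {b.get('schema')!r}"
        )
    fa, fb = _flatten(a), _flatten(b)
    keys = sorted(set(fa) & set(fb))
    rows = []
    for k in keys:
        va, vb = fa[k], fb[k]
        rows.append(
            {
                "statistic": k,
                "a": va,
                "b": vb,
                "delta": vb - va,
                "ratio": vb / va if va != 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("statistic")
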