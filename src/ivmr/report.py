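"""Pipeline glue: run read -> harmonize -> estimate -> diagnose and write a report bundle.

The JSON report echoes every configuration value used, so a run is fully
reproducible from the report alone; results files are deterministic given the
same inputs and seed (no timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__, diagnostics, estimators, summary_data

__all__ = ["RunConfig", "run_mr"]

logger = logging.getLogger(__name__)

VALID_METHODS = ("ivw", "ivw-fixed", "egger", "weighted-median")


@dataclass
class RunConfig:
    """Configuration for one end-to-end MR run."""

    exposure: str
    outcome: str
    out_dir: str
    exposure_scale: str = summary_data.SCALE_PERCENT
    outcome_scale: str = summary_data.SCALE_ODDS_RATIO
    exposure_columns: dict = field(default_factory=dict)
    outcome_columns: dict = field(default_factory=dict)
    sd_scale: float = 0.65
    methods: tuple = ("ivw", "egger", "weighted-median")
    palindromic_policy: str = "flag"
    n_boot: int = 1000
    seed: int | None = None
    n_exposure: float | None = None
    funnel_y: str = "precision"

    def __post_init__(self) -> None:
        if not self.sd_scale > 0:
            raise ValueError("sd_scale must be positive")
        unknown = set(self.methods) - set(VALID_METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}; valid: {VALID_METHODS}")
        if "weighted-median" in self.methods and self.seed is None:
            raise ValueError("a seed is required when the weighted-median method is requested")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)


def _stage(name: str):
    """Tag exceptions raised inside a pipeline stage with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise RuntimeError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def run_mr(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle to ``config.out_dir``.

    Writes ``report.json`` (config echo, per-method estimates, diagnostics),
    ``harmonized.tsv``, ``funnel.tsv`` and ``forest.tsv``.  Returns the report
    dict.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("read"):
        exp_read = summary_data.read_associations(
            config.exposure, column_map=config.exposure_columns or None,
            scale=config.exposure_scale, trait="exposure",
        )
        out_read = summary_data.read_associations(
            config.outcome, column_map=config.outcome_columns or None,
            scale=config.outcome_scale, trait="outcome",
        )
        exposure = summary_data.convert_to_log_scale(exp_read.records)
        outcome = summary_data.convert_to_log_scale(out_read.records)

    with _stage("harmonize"):
        iset = summary_data.harmonize(
            exposure, outcome,
            palindromic_policy=config.palindromic_policy, sd_scale=config.sd_scale,
        )
        summary_data.write_instruments(iset, out_dir / "harmonized.tsv")

    with _stage("estimate"):
        results = []
        pooled = None
        for method in config.methods:
            if method == "ivw":
                est = estimators.ivw(iset, model="random")
                pooled = est
            elif method == "ivw-fixed":
                est = estimators.ivw(iset, model="fixed")
            elif method == "egger":
                est = estimators.egger(iset)
            else:
                est = estimators.weighted_median(iset, n_boot=config.n_boot, seed=config.seed)
            results.append(est.to_dict())
            logger.info("%s: %s", method, format_or_line(est))

    with _stage("diagnose"):
        diag = diagnostics.compute_diagnostics(
            iset, pooled=pooled, n_exposure=config.n_exposure, funnel_y=config.funnel_y,
        )
        diag.funnel.to_csv(out_dir / "funnel.tsv", sep="\t", index=False)
        diag.forest.to_csv(out_dir / "forest.tsv", sep="\t", index=False)

    report = {
        "ivmr_version": __version__,
        "config": {
            **asdict(config),
            "methods": list(config.methods),
        },
        "n_exposure_records": len(exp_read.records),
        "n_outcome_records": len(out_read.records),
        "n_rejected_rows": {"exposure": exp_read.n_rejected, "outcome": out_read.n_rejected},
        "n_instruments": iset.L,
        "excluded_rsids": sorted(
            {r.rsid for r in exposure} - set(iset.rsids)
        ),
        "results": results,
        "diagnostics": diag.to_json_dict(),
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def format_or_line(est: estimators.CausalEstimate) -> str:
    """Render an estimate as ``OR (CI_low to CI_high)`` with 2 decimals."""
    e = estimators.to_odds_ratio(est) if est.scale == "log-odds" else est
    return f"{e.beta:.2f} ({e.ci_low:.2f} to {e.ci_high:.2f})"
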