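"""End-to-end orchestration: generate -> score -> analyze -> relate.

A :class:`RunConfig` captures everything that determines a run — trial
design, calibration overrides, index variable sets, inference settings,
forest settings and the master seed — and is serializable to YAML/JSON
so a run can be reproduced bit-for-bit.  The master seed is split into
named substreams (generation, forest) so changing forest settings never
perturbs the simulated data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .inference import fisher_lsd, oneway_anova, percent_changes, correlation_panel
from .relationships import linear_fit, rf_importance
from .scoring import (
    DEFAULT_EMF_ENZYMES,
    DEFAULT_SQI_PROPERTIES,
    ScoreTable,
    score_dataset,
)
from .trial import (
    Direction,
    EffectTable,
    PlotRecord,
    TrialDesign,
    default_calibration,
    generate_trial,
    read_records,
    records_to_frame,
    write_records,
)

__all__ = ["RunConfig", "RunSummary", "run_all", "substream_seed"]

#: Physicochemical predictors offered to the yield random forest.
RF_FEATURES = ("salt", "pH", "Na", "TN", "avN", "avP", "avK", "SOC")


def substream_seed(master_seed: int, stream: str) -> int:
    """Derive a named substream seed (< 2^31) from the master seed."""
    digest = hashlib.sha256(f"{master_seed}/{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything that determines one pipeline run."""

    seed: int = 0
    treatments: tuple[str, ...] = ("CK", "CS", "CB")
    replicates: int = 3
    cv: float = 0.05
    baseline_overrides: dict[str, float] = field(default_factory=dict)
    multiplier_overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    sqi_properties: list[str] = field(
        default_factory=lambda: list(DEFAULT_SQI_PROPERTIES)
    )
    emf_enzymes: list[str] = field(default_factory=lambda: list(DEFAULT_EMF_ENZYMES))
    sqi_variant: str = "printed"
    alpha: float = 0.05
    reference: str = "CK"
    protected_lsd: bool = False
    rf_trees: int = 500
    input_csv: str | None = None
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["treatments"] = list(self.treatments)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "treatments" in d:
            d["treatments"] = tuple(d["treatments"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunSummary:
    """All outputs of one run, traceable to the config that made them."""

    config: RunConfig
    records: list[PlotRecord]
    scores: ScoreTable
    comparisons: pd.DataFrame
    correlations_r: pd.DataFrame
    correlations_p: pd.DataFrame
    regressions: pd.DataFrame
    importance: pd.DataFrame
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "comparisons": self.comparisons.to_dict(orient="records"),
            "regressions": self.regressions.to_dict(orient="records"),
            "importance": self.importance.to_dict(orient="records"),
        }


def _calibrated_inputs(config: RunConfig):
    specs, effects = default_calibration(cv=config.cv)
    if config.baseline_overrides:
        specs = [
            dataclasses.replace(s, baseline_mean=config.baseline_overrides.get(s.name, s.baseline_mean))
            for s in specs
        ]
    if config.multiplier_overrides:
        mult = dict(effects.multipliers)
        for trt, props in config.multiplier_overrides.items():
            for prop, m in props.items():
                mult[(trt, prop)] = m
        effects = EffectTable(multipliers=mult, reference=effects.reference)
    return specs, effects


def _direction_map(names: list[str]) -> dict[str, Direction]:
    specs, _ = default_calibration()
    known = {s.name: s.direction for s in specs}
    out: dict[str, Direction] = {}
    for n in names:
        d = known.get(n, Direction.MORE_IS_BETTER)
        # variables outside the built-in scored panel default to more-is-better
        out[n] = d if d is not Direction.NOT_SCORED else Direction.MORE_IS_BETTER
    return out


def comparison_table(
    frame: pd.DataFrame,
    variables: list[str],
    alpha: float = 0.05,
    reference: str = "CK",
    protected: bool = False,
) -> pd.DataFrame:
    """Per-variable ANOVA + LSD letters + percent change, long format."""
    rows = []
    for var in variables:
        anova = oneway_anova(frame[var].to_numpy(float), frame["treatment"].to_numpy(),
                             variable=var)
        lsd = fisher_lsd(anova, alpha=alpha, protected=protected)
        pct = {c.treatment: c.value for c in percent_changes(frame, var, reference)}
        for trt in anova.groups:
            rows.append({
                "variable": var,
                "treatment": trt,
                "mean": anova.means[trt],
                "se": anova.se[trt],
                "letter": lsd.letters[trt],
                "pct_change_vs_ref": pct.get(trt),
                "F": anova.F,
                "p": anova.p,
            })
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> RunSummary:
    """Execute the full pipeline under one config; optionally write outputs.

    Stages: simulate (or load) plot records; score SQI/EMF; compare all
    measured variables plus the composite indices across treatments;
    regress yield/EMF on SQI and yield on EMF; rank yield drivers with
    the random forest.
    """
    if config.input_csv is not None:
        records = read_records(config.input_csv)
    else:
        specs, effects = _calibrated_inputs(config)
        design = TrialDesign(
            treatments=config.treatments,
            replicates=config.replicates,
            seed=substream_seed(config.seed, "generate"),
        )
        records = generate_trial(design, specs, effects)
    frame = records_to_frame(records)

    scores = score_dataset(
        frame,
        sqi_properties=_direction_map(config.sqi_properties),
        emf_enzymes=config.emf_enzymes,
        variant=config.sqi_variant,
    )
    merged = frame.merge(
        scores.frame[["treatment", "replicate", "SQI", "EMF"]],
        on=["treatment", "replicate"],
    )

    measured = [c for c in frame.columns if c not in ("treatment", "replicate")]
    comparisons = comparison_table(
        merged, measured + ["SQI", "EMF"],
        alpha=config.alpha, reference=config.reference,
        protected=config.protected_lsd,
    )
    panel_vars = [v for v in measured if v != "yield"]
    panel = correlation_panel(merged, panel_vars)

    regs = []
    for x, ylab in (("SQI", "yield"), ("SQI", "EMF"), ("EMF", "yield")):
        fit = linear_fit(merged[x], merged[ylab], predictor=x, response=ylab)
        regs.append(dataclasses.asdict(fit))
    regressions = pd.DataFrame(regs)

    feat_names = [f for f in RF_FEATURES if f in merged.columns]
    imp = rf_importance(
        merged[feat_names], merged["yield"].to_numpy(float),
        n_trees=config.rf_trees, seed=substream_seed(config.seed, "forest"),
    )
    importance = imp.importance.rename("inc_mse_pct").rename_axis("feature").reset_index()
    importance["n_trees"] = imp.n_trees
    importance["max_features"] = imp.max_features

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_plots": len(records),
    }
    summary = RunSummary(
        config=config,
        records=records,
        scores=scores,
        comparisons=comparisons,
        correlations_r=panel.r,
        correlations_p=panel.p,
        regressions=regressions,
        importance=importance,
        provenance=provenance,
    )
    if config.out_dir is not None:
        _write_outputs(summary, Path(config.out_dir))
    return summary


def _write_outputs(summary: RunSummary, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = "%.12g"
    write_records(summary.records, out_dir / "plots.csv")
    summary.scores.frame.to_csv(out_dir / "scores.csv", index=False, float_format=fmt)
    summary.comparisons.to_csv(out_dir / "comparisons.csv", index=False, float_format=fmt)
    summary.correlations_r.to_csv(out_dir / "correlations_r.csv", float_format=fmt)
    summary.correlations_p.to_csv(out_dir / "correlations_p.csv", float_format=fmt)
    summary.regressions.to_csv(out_dir / "regressions.csv", index=False, float_format=fmt)
    summary.importance.to_csv(out_dir / "importance.csv", index=False, float_format=fmt)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary.to_json_dict(), fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
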