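"""Stage-oriented pipeline: simulate -> features -> sequence -> model -> report.

Each stage reads its predecessors' CSV/JSON artifacts from the output
directory and appends a manifest entry recording the config hash, seed,
package version, and timing, so a run is fully reproducible from
(config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import f_oneway

from . import __version__, kinematics, layout as lay, models, scanpath, simulate
from .gaze import AoiRegions, amgr as compute_amgr, dwell_times, gaze_frequency
from .simulate import SimParams, Trial

logger = logging.getLogger(__name__)

STAGES = ("simulate", "features", "sequence", "model", "report")

__all__ = ["PipelineConfig", "run", "STAGES", "PipelineError"]


class PipelineError(RuntimeError):
    """Missing upstream artifacts or invalid configuration."""


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_participants: int = 12
    n_trials_per_cell: int = 3
    target_halo: float = 10.0
    margin_pad: float = 20.0
    kde_bandwidth: float = 15.0
    write_allocation_maps: bool = False
    scoring_match: float = 1.0
    scoring_mismatch: float = 0.0
    scoring_gap: float = 0.0
    scoring_graded: bool = False
    export_fasta: bool = False
    n_surrogates: int = 2000
    loocv_unit: str = "trial"  # "trial" | "participant"
    penalty_C: str | float = "cv"
    judgment_offsets_step: float = 5.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise PipelineError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        if self.loocv_unit not in ("trial", "participant"):
            raise PipelineError(
                f"loocv_unit: expected 'trial' or 'participant', got {self.loocv_unit!r}"
            )
        if self.n_participants < 1 or self.n_trials_per_cell < 1:
            raise PipelineError("n_participants / n_trials_per_cell must be >= 1")


def _provenance(df: pd.DataFrame, stage: str, config: PipelineConfig) -> pd.DataFrame:
    df = df.copy()
    df["stage"] = stage
    df["seed"] = config.seed
    df["config_hash"] = config.digest()
    return df


def _require(outdir: Path, name: str, stage: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise PipelineError(
            f"stage '{stage}' needs {path} - run the upstream stage first"
        )
    return path


def _append_manifest(outdir: Path, entry: dict) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"runs": []}
    manifest["runs"].append(entry)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _load_trials(outdir: Path, stage: str) -> list[Trial]:
    meta = pd.read_csv(_require(outdir, "trials.csv", stage))
    samples = pd.read_csv(_require(outdir, "samples.csv", stage))
    return simulate.trials_from_frames(meta, samples)


def _regions(config: PipelineConfig) -> dict[int, AoiRegions]:
    return {
        cid: AoiRegions.from_layout(
            lay.build_layout(cid), config.target_halo, config.margin_pad
        )
        for cid in range(1, 9)
    }


def _sim_params(config: PipelineConfig) -> SimParams:
    return SimParams(
        n_participants=config.n_participants,
        n_trials_per_cell=config.n_trials_per_cell,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    params = _sim_params(config)
    trials, truth = simulate.generate_dataset(params)
    meta, samples = simulate.trials_to_frames(trials)
    _provenance(meta, "simulate", config).to_csv(outdir / "trials.csv", index=False)
    samples.to_csv(outdir / "samples.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    offsets = np.arange(-35.0, 35.0 + 1e-9, config.judgment_offsets_step)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    judgment = simulate.simulate_judgment(offsets, params, rng)
    _provenance(judgment, "simulate", config).to_csv(
        outdir / "judgment.csv", index=False
    )


def stage_features(config: PipelineConfig, outdir: Path) -> None:
    trials = _load_trials(outdir, "features")
    geo = lay.feature_table(lay.full_design())
    _provenance(geo, "features", config).to_csv(
        outdir / "geometry_features.csv", index=False
    )
    regions = _regions(config)
    rows = []
    for trial in trials:
        reg = regions[trial.condition_id]
        d = dwell_times(trial.gaze, reg)
        rows.append(
            {
                "trial_id": trial.trial_id,
                "participant_id": trial.participant_id,
                "condition": trial.condition_id,
                "target_offset_cm": trial.target_offset_cm,
                "choice": 1 if trial.chosen_side == "right" else 0,
                "dwell_T": d["T"],
                "dwell_P": d["P"],
                "dwell_SL": d["S_left"],
                "dwell_SR": d["S_right"],
                "amgr": compute_amgr(trial.gaze, reg) if reg.has_margins else np.nan,
            }
        )
    _provenance(pd.DataFrame(rows), "features", config).to_csv(
        outdir / "gaze_features.csv", index=False
    )
    freq = gaze_frequency(trials, regions, merge_margins=True)
    _provenance(freq, "features", config).to_csv(
        outdir / "gaze_frequency.csv", index=False
    )
    if config.write_allocation_maps:
        from .gaze import GridSpec, allocation_map

        maps_dir = outdir / "allocation_maps"
        maps_dir.mkdir(exist_ok=True)
        for (cid, offset), group in _group_trials(trials):
            gaze_all = pd.concat([t.gaze for t in group], ignore_index=True)
            layout = lay.build_layout(cid)
            grid = GridSpec.from_layout(layout)
            amap = allocation_map(
                gaze_all, regions[cid], grid, bandwidth=config.kde_bandwidth,
                duration_s=sum(t.duration_s for t in group),
            )
            np.savetxt(maps_dir / f"map_c{cid}_t{offset:+.0f}.tsv", amap, delimiter="\t")


def _group_trials(trials):
    keys = sorted({(t.condition_id, t.target_offset_cm) for t in trials})
    for key in keys:
        yield key, [
            t for t in trials if (t.condition_id, t.target_offset_cm) == key
        ]


def stage_sequence(config: PipelineConfig, outdir: Path) -> None:
    trials = _load_trials(outdir, "sequence")
    regions = _regions(config)
    sequences = [
        scanpath.encode_sequence(t, regions[t.condition_id]) for t in trials
    ]
    seq_df = pd.DataFrame(
        {
            "trial_id": [s.trial_id for s in sequences],
            "condition": [s.condition_id for s in sequences],
            "symbols": [s.string for s in sequences],
        }
    )
    _provenance(seq_df, "sequence", config).to_csv(
        outdir / "sequences.csv", index=False
    )
    if config.export_fasta:
        scanpath.export_fasta(sequences, outdir / "sequences.fasta")
    scheme = scanpath.ScoringScheme(
        match=config.scoring_match,
        mismatch=config.scoring_mismatch,
        gap=config.scoring_gap,
        graded=config.scoring_graded,
    )
    groups: dict[int, list] = {}
    for s in sequences:
        groups.setdefault(s.condition_id, []).append(s)
    mean, sd, scores = scanpath.similarity_matrix(groups, scheme)
    mean.to_csv(outdir / "similarity_mean.csv")
    sd.to_csv(outdir / "similarity_sd.csv")
    _provenance(scores, "sequence", config).to_csv(
        outdir / "similarity_scores.csv", index=False
    )
    # plain one-way F statistic over within-condition score groups; post hocs
    # and distributional tests are left to external tools
    within = [
        scores[(scores.condition_a == c) & (scores.condition_b == c)]["score"]
        for c in sorted(groups)
        if len(groups[c]) > 1
    ]
    fstat = f_oneway(*within) if len(within) > 1 else None
    chars = {}
    for cid, seqs in groups.items():
        center, objective = scanpath.characteristic_sequence(seqs)
        chars[cid] = center
        if np.any(np.diff(objective) > 1e-6):
            logger.warning("DBA objective increased for condition %s", cid)
    char_df = pd.DataFrame(chars)
    char_df.index.name = "segment"
    char_df.to_csv(outdir / "characteristic_sequences.csv")
    summary = {
        "f_statistic": float(fstat.statistic) if fstat else None,
        "f_pvalue": float(fstat.pvalue) if fstat else None,
    }
    (outdir / "sequence_summary.json").write_text(json.dumps(summary, indent=2))


def stage_model(config: PipelineConfig, outdir: Path) -> None:
    geo = pd.read_csv(_require(outdir, "geometry_features.csv", "model"))
    gf = pd.read_csv(_require(outdir, "gaze_features.csv", "model"))
    df = gf.merge(
        geo[["condition", "target_offset_cm", "delta_theta", "delta_d", "amr"]],
        on=["condition", "target_offset_cm"],
        how="left",
        suffixes=("", "_geo"),
    )
    obst = df[df["condition"] != 1].reset_index(drop=True)
    rng = np.random.default_rng(config.seed)

    # univariate table (delta_theta pooled; delta_d / amr per target position)
    uni_rows = []
    fit = models.fit_univariate(obst["delta_theta"], obst["choice"], "delta_theta")
    uni_rows.append({"target": "all", "feature": "delta_theta",
                     "coef": fit.coef, "p_value": fit.p_value,
                     "separated": fit.separated})
    for offset, label in ((0.0, "middle"), (-30.0, "left"), (30.0, "right")):
        sub = obst[obst["target_offset_cm"] == offset]
        for feat in ("delta_d", "amr"):
            try:
                f = models.fit_univariate(sub[feat], sub["choice"], feat)
                uni_rows.append({"target": label, "feature": feat, "coef": f.coef,
                                 "p_value": f.p_value, "separated": f.separated})
            except ValueError as exc:
                uni_rows.append({"target": label, "feature": feat, "coef": np.nan,
                                 "p_value": np.nan, "separated": str(exc)})
    _provenance(pd.DataFrame(uni_rows), "model", config).to_csv(
        outdir / "univariate_fits.csv", index=False
    )

    # multivariate model with bootstrap, partition, LOOCV
    mv = models.fit_multivariate(
        obst[["delta_theta", "delta_d", "amr"]], obst["choice"],
        penalty_C=config.penalty_C, rng=rng,
    )
    boot = models.bootstrap_effects(
        obst[["delta_theta", "delta_d", "amr"]], obst["choice"],
        n_surrogates=config.n_surrogates, rng=rng, standardize=True,
    )
    unit_ids = obst["participant_id"] if config.loocv_unit == "participant" else None
    mv.loocv_mean, mv.loocv_sd = models.loocv_accuracy(
        obst[["delta_theta", "delta_d", "amr"]], obst["choice"], unit_ids=unit_ids
    )
    for name, b in boot.items():
        mv.ci[name] = b["ci"]

    # AMGR models on rows with defined AMGR
    defined = obst[~obst["amgr"].isna()]
    amgr_fits = models.fit_amgr_models(
        defined["amgr"], defined["amr"], defined["choice"]
    )

    judgment = pd.read_csv(_require(outdir, "judgment.csv", "model"))
    curve = models.judgment_threshold(judgment)

    out = {
        "multivariate": {
            "coefficients": mv.coefficients,
            "intercept": mv.intercept,
            "selected": list(mv.selected),
            "penalty_C": mv.penalty_C,
            "partition_shares_pct": mv.partition_shares,
            "ci": {k: list(v) for k, v in mv.ci.items()},
            "bootstrap": boot,
            "loocv_accuracy_pct": {"mean": mv.loocv_mean, "sd": mv.loocv_sd},
        },
        "amgr": {
            "univariate": dataclasses.asdict(amgr_fits["univariate"]),
            "bivariate": amgr_fits["bivariate"],
        },
        "judgment": dataclasses.asdict(curve),
        "provenance": {"seed": config.seed, "config_hash": config.digest(),
                       "version": __version__},
    }
    (outdir / "model_fits.json").write_text(
        json.dumps(out, indent=2, sort_keys=True, default=_json_default)
    )


def stage_report(config: PipelineConfig, outdir: Path) -> None:
    trials = _load_trials(outdir, "report")
    layouts = {cid: lay.build_layout(cid) for cid in range(1, 9)}
    speed = kinematics.speed_summary(trials, layouts)
    _provenance(speed, "report", config).to_csv(
        outdir / "speed_summary.csv", index=False
    )
    foot_table, r, p = kinematics.start_foot_summary(trials)
    foot_table.to_csv(outdir / "start_foot_pct.csv")
    gf = pd.read_csv(_require(outdir, "gaze_features.csv", "report"))
    geo = pd.read_csv(_require(outdir, "geometry_features.csv", "report"))
    merged = gf.merge(
        geo[["condition", "target_offset_cm", "delta_theta", "delta_d", "amr"]],
        on=["condition", "target_offset_cm"], how="left", suffixes=("", "_geo"),
    )
    obst = merged[merged["condition"] != 1]
    for feat in ("delta_d", "delta_theta", "amr"):
        table = models.choice_probability_table(obst, feat, bins=6)
        _provenance(table, "report", config).to_csv(
            outdir / f"choice_prob_{feat}.csv", index=False
        )
    summary = {
        "n_trials": len(trials),
        "start_foot_choice_correlation": None if np.isnan(r) else r,
        "start_foot_choice_correlation_p": None if np.isnan(p) else p,
        "provenance": {"seed": config.seed, "config_hash": config.digest(),
                       "version": __version__},
    }
    (outdir / "report.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default)
    )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "features": stage_features,
    "sequence": stage_sequence,
    "model": stage_model,
    "report": stage_report,
}


def run(stage: str, config: PipelineConfig, outdir) -> None:
    """Run one stage or ``"all"``; artifacts land in ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = STAGES if stage == "all" else (stage,)
    for name in stages:
        if name not in _STAGE_FUNCS:
            raise PipelineError(f"unknown stage {name!r}; expected one of {STAGES}")
        t0 = time.time()
        logger.info("stage %s starting", name)
        _STAGE_FUNCS[name](config, outdir)
        # timings go to the log, not the manifest, so equal-seed runs
        # produce byte-identical manifests
        _append_manifest(
            outdir,
            {
                "stage": name,
                "seed": config.seed,
                "config_hash": config.digest(),
                "version": __version__,
            },
        )
        logger.info("stage %s done in %.1fs", name, time.time() - t0)
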