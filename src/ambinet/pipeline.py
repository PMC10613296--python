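"""Configuration, validation and end-to-end orchestration.

A :class:`RunConfig` (JSON-serializable) drives ``simulate -> analyze ->
report`` over the enabled stages.  One global seed expands into
per-stage seeds via a fixed counter scheme (``SeedSequence([seed,
stage_counter])``), so each stage is individually reproducible.

Conventions used throughout the package: time in seconds relative to
stimulus onset, 0-based sample indexing, half-open bins ``[t, t + dt)``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasets import EEGEpochs, SpikeDataset, write_behavior_csv
from .design import MORPH_GRID

_STAGE_COUNTERS = {"behavior": 1, "spikes": 2, "eeg": 3, "dtf": 4, "prediction": 5}


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(seed), _STAGE_COUNTERS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "ambinet_run"
    stages: "dict[str, bool]" = field(
        default_factory=lambda: {
            "behavior": True,
            "spikes": True,
            "eeg": True,
            "dtf": True,
            "prediction": True,
        }
    )
    behavior: dict = field(
        default_factory=lambda: {
            "n_control": 12,
            "n_patients": 12,
            "control_rt_gain": 0.15,
            "patient_rt_gain": 0.30,
            "patient_alpha_slope": 0.06,
            "n_trials_per_level": 36,
        }
    )
    spikes: dict = field(
        default_factory=lambda: {
            "n_neurons": 20,
            "n_trials_per_level": 60,
            "early_onset_s": 0.3,
            "late_onset_s": 0.6,
            "n_perm": 200,
        }
    )
    eeg: dict = field(
        default_factory=lambda: {"n_participants": 10, "n_trials_per_condition": 30,
                                 "cfc_n_perm": 100}
    )
    dtf: dict = field(default_factory=lambda: {"n_trials": 40, "n_perm": 200})
    prediction: dict = field(default_factory=lambda: {"a": 2.4739, "b": -0.1329})

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cfg, key)
            if isinstance(default, dict) and isinstance(value, dict):
                default.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    @property
    def config_hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    version: str
    seed: int
    outputs: "dict[str, dict]" = field(default_factory=dict)
    wall_time_s: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=str)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    Each stage simulates its inputs with the stage seed, runs the
    corresponding analysis, and writes its outputs (CSV/JSON) into
    ``config.out_dir``.  A stage failure aborts with the stage name.
    """
    t_start = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config.config_hash, __version__, config.seed)
    (out_dir / "config.json").write_text(config.to_json())

    order = ["behavior", "spikes", "eeg", "dtf", "prediction"]
    runners = {
        "behavior": _run_behavior,
        "spikes": _run_spikes,
        "eeg": _run_eeg,
        "dtf": _run_dtf,
        "prediction": _run_prediction,
    }
    state: dict = {}
    for stage in order:
        if not config.stages.get(stage, False):
            continue
        try:
            report.outputs[stage] = runners[stage](config, out_dir, state)
            report.outputs[stage]["config_hash"] = config.config_hash
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    report.wall_time_s = time.time() - t_start
    (out_dir / "report.json").write_text(report.to_json())
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _run_behavior(config: RunConfig, out_dir: Path, state: dict) -> dict:
    from .behavior import ambiguity_sensitivity, fit_psychometric, modulation_index
    from .simulate import BehaviorTruth, gen_behavior

    p = config.behavior
    base = stage_seed(config.seed, "behavior")
    sessions = []
    for g, (n, gain, alpha) in {
        "control": (p["n_control"], p["control_rt_gain"], 0.12),
        "patient": (p["n_patients"], p["patient_rt_gain"], p["patient_alpha_slope"]),
    }.items():
        for i in range(n):
            truth = BehaviorTruth(
                alpha_slope=alpha,
                rt_ambiguity_gain=gain,
                n_trials_per_level=p["n_trials_per_level"],
                seed=base + hash(g) % 1000 + i,
            )
            sessions.append(gen_behavior(truth, f"{g}_{i:02d}", group_label=g))
    write_behavior_csv(sessions, out_dir / "behavior_trials.csv")
    rows = []
    for s in sessions:
        fit = fit_psychometric(s)
        rows.append(
            {
                "participant_id": s.participant_id,
                "group_label": s.group_label,
                "p_inf": fit.p_inf,
                "x_half": fit.x_half,
                "alpha_slope": fit.alpha_slope,
                "converged": fit.converged,
                "delta_rt_s": ambiguity_sensitivity(s).delta_rt,
                "rt_modulation": modulation_index(s, "rt").value,
            }
        )
    fits = pd.DataFrame(rows)
    fits.to_csv(out_dir / "behavior_fits.csv", index=False)
    state["behavior_fits"] = fits
    return {"files": ["behavior_trials.csv", "behavior_fits.csv"],
            "n_participants": len(sessions)}


def _run_spikes(config: RunConfig, out_dir: Path, state: dict) -> dict:
    from .simulate import SpikeTruth, gen_spikes
    from .spikes import (
        filter_units,
        group_cumulative_curves,
        latency_permutation,
        population_binomial,
        select_ambiguity_neurons,
        selection_table,
    )

    p = config.spikes
    base = stage_seed(config.seed, "spikes")
    early = gen_spikes(
        SpikeTruth(
            n_neurons=p["n_neurons"], region_label="amygdala",
            baseline_rate=15.0, modulation_per_level=-5.0,
            onset_latency_s=p["early_onset_s"],
            n_trials_per_level=p["n_trials_per_level"], seed=base,
        )
    )
    late = gen_spikes(
        SpikeTruth(
            n_neurons=p["n_neurons"], region_label="dmPFC",
            baseline_rate=5.0, modulation_per_level=5.0,
            onset_latency_s=p["late_onset_s"],
            n_trials_per_level=p["n_trials_per_level"], seed=base + 1,
        )
    )
    dataset = SpikeDataset(list(early) + list(late))
    dataset.write_csv(out_dir / "spikes.csv")
    kept = filter_units(dataset)
    sel = selection_table(select_ambiguity_neurons(kept))
    sel.to_csv(out_dir / "spike_selection.csv", index=False)
    k = int(sel["selected"].sum())
    pref_a, non_a, times = group_cumulative_curves(
        kept.by_region("amygdala"), "anchor", "high"
    )
    pref_b, non_b, _ = group_cumulative_curves(
        kept.by_region("dmPFC"), "high", "anchor"
    )
    perm = latency_permutation(
        pref_a, non_a, pref_b, non_b, times, n_perm=p["n_perm"], seed=base + 2
    )
    result = {
        "n_units": len(kept),
        "n_selected": k,
        "binomial_p": population_binomial(k, len(kept)),
        "latency_amygdala_ms": perm.latency_a_ms,
        "latency_dmpfc_ms": perm.latency_b_ms,
        "latency_diff_ms": perm.observed_diff_ms,
        "permutation_p": perm.p_value,
        "n_perm": perm.n_perm,
    }
    (out_dir / "latency_report.json").write_text(json.dumps(result, indent=1))
    return {"files": ["spikes.csv", "spike_selection.csv", "latency_report.json"],
            **result}


def _run_eeg(config: RunConfig, out_dir: Path, state: dict) -> dict:
    from .cfc import amplitude_cfc, cfc_condition_contrast
    from .coherence import band_coherence_table, coherence_condition_contrast
    from .design import AMBIGUITY_LEVELS
    from .simulate import EEGTruth, gen_eeg_epochs

    p = config.eeg
    base = stage_seed(config.seed, "eeg")
    coh_rows, cfc_rows = [], []
    for i in range(p["n_participants"]):
        truth = EEGTruth(
            n_trials_per_condition=p["n_trials_per_condition"], seed=base + i
        )
        epochs = gen_eeg_epochs(truth)
        if i == 0:
            epochs.save(out_dir / "epochs_example.h5")
        table = band_coherence_table(epochs)
        table["participant"] = i
        coh_rows.append(table)
        for cond in AMBIGUITY_LEVELS:
            r = amplitude_cfc(
                epochs, condition=cond, n_perm=p["cfc_n_perm"], seed=base + i
            )
            cfc_rows.append(
                {"participant": i, "condition": cond,
                 "index": r.modulation_index, "p_value": r.p_value}
            )
    coh = pd.concat(coh_rows, ignore_index=True)
    coh.to_csv(out_dir / "coherence.csv", index=False)
    cfc = pd.DataFrame(cfc_rows)
    cfc.to_csv(out_dir / "cfc.csv", index=False)
    coh_wide = (
        coh[coh["channel"] == "Cz"]
        .pivot(index="participant", columns="condition", values="coherence")
        [list(AMBIGUITY_LEVELS)]
    )
    cfc_wide = cfc.pivot(index="participant", columns="condition", values="index")[
        list(AMBIGUITY_LEVELS)
    ]
    coh_stats = coherence_condition_contrast(coh_wide)
    cfc_stats = cfc_condition_contrast(cfc_wide)
    (out_dir / "eeg_contrasts.json").write_text(
        json.dumps({"coherence": coh_stats, "cfc": cfc_stats}, indent=1)
    )
    return {
        "files": ["coherence.csv", "cfc.csv", "eeg_contrasts.json",
                  "epochs_example.h5"],
        "coherence_F": coh_stats["statistic"],
        "coherence_p": coh_stats["p_value"],
        "cfc_F": cfc_stats["statistic"],
        "cfc_p": cfc_stats["p_value"],
    }


def _run_dtf(config: RunConfig, out_dir: Path, state: dict) -> dict:
    from .dtf import dtf_significance
    from .simulate import MVARTruth, gen_mvar_series

    p = config.dtf
    base = stage_seed(config.seed, "dtf")
    series = gen_mvar_series(MVARTruth(n_trials=p["n_trials"], seed=base))
    series.save(out_dir / "sources.h5")
    res = dtf_significance(series, order=2, n_perm=p["n_perm"], seed=base)
    summary = {
        "source_names": res.source_names,
        "band_mean": res.band_mean().tolist(),
        "p_values": res.p_values.tolist(),
        "significant": res.significant.tolist(),
        "n_perm": res.n_perm,
        "seed": res.seed,
    }
    (out_dir / "dtf_summary.json").write_text(json.dumps(summary, indent=1))
    np.save(out_dir / "dtf_gamma2.npy", res.gamma2)
    n_sig = int(res.significant.sum())
    return {"files": ["sources.h5", "dtf_summary.json", "dtf_gamma2.npy"],
            "n_significant_pairs": n_sig}


def _run_prediction(config: RunConfig, out_dir: Path, state: dict) -> dict:
    from .prediction import compare_groups, predict_connectivity

    fits = state.get("behavior_fits")
    if fits is None:
        fits_path = Path(config.out_dir) / "behavior_fits.csv"
        if not fits_path.exists():
            raise ValueError("prediction stage needs the behavior stage outputs")
        fits = pd.read_csv(fits_path)
    p = config.prediction
    groups = {
        g: sub["delta_rt_s"].to_numpy() for g, sub in fits.groupby("group_label")
    }
    preds = fits[["participant_id", "group_label", "delta_rt_s"]].copy()
    preds["predicted_y"] = predict_connectivity(
        preds["delta_rt_s"].to_numpy(), a=p["a"], b=p["b"]
    )
    preds.to_csv(out_dir / "predictions.csv", index=False)
    comp = compare_groups(groups, control_label="control", a=p["a"], b=p["b"])
    comp.to_csv(out_dir / "prediction_comparison.csv", index=False)
    return {
        "files": ["predictions.csv", "prediction_comparison.csv"],
        "comparisons": comp.to_dict(orient="records"),
    }


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(paths: "dict[str, str]") -> "list[str]":
    """Schema and unit sanity checks; reports problems, never mutates.

    ``paths`` may contain ``behavior_csv``, ``spike_csv`` and
    ``epochs_h5`` entries.
    """
    problems: list[str] = []
    if "behavior_csv" in paths:
        try:
            df = pd.read_csv(paths["behavior_csv"])
            for col in ("participant_id", "morph_pct", "choice", "rt_s"):
                if col not in df.columns:
                    problems.append(f"behavior CSV: missing column {col!r}")
            if "morph_pct" in df.columns:
                off = set(df["morph_pct"].dropna().unique()) - set(MORPH_GRID)
                if off:
                    problems.append(
                        f"behavior CSV: morph levels off the grid: {sorted(off)}"
                    )
            if "rt_s" in df.columns:
                rt = df["rt_s"].dropna()
                if len(rt) and rt.median() >= 10:
                    problems.append(
                        "behavior CSV: rt_s values look like milliseconds "
                        "(median >= 10); expected seconds"
                    )
        except Exception as exc:
            problems.append(f"behavior CSV: unreadable ({exc})")
    if "spike_csv" in paths:
        try:
            df = pd.read_csv(paths["spike_csv"])
            for col in ("neuron_id", "region", "trial_id", "spike_time_s",
                        "ambiguity_level"):
                if col not in df.columns:
                    problems.append(f"spike CSV: missing column {col!r}")
        except Exception as exc:
            problems.append(f"spike CSV: unreadable ({exc})")
    if "epochs_h5" in paths:
        try:
            EEGEpochs.load(paths["epochs_h5"])
        except Exception as exc:
            problems.append(f"epoch container: {exc}")
    return problems
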