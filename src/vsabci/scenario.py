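"""Scenario-driven end-to-end runs: YAML config -> simulate -> decode -> report.

A scenario file describes one reproducible experiment::

    seed: 123
    conditions: [overt, covert, free]
    paradigm: {reps_min: 10, reps_max: 15}      # optional overrides
    profiles:
      covert: {p3_jitter_sd_ms: 60.0}           # optional overrides
    noise: {rms_uv: 6.0}
    decoder: tlda
    plan: within                                 # within | cross_condition | k_sweep

Every artifact carries a manifest (canonical config hash + seed) so outputs
are reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from vsabci.decoders import make_decoder
from vsabci.errors import DomainError
from vsabci.evaluate import (
    accuracy_by_k,
    blockwise_cv,
    cross_condition_eval,
    format_reps,
    reps_to_threshold,
)
from vsabci.gaze import dwell_summary, fuse_binocular
from vsabci.paradigm import (
    ConditionProfile,
    NoiseSpec,
    ParadigmConfig,
    default_condition_profiles,
    default_erp_model,
    simulate_session,
)
from vsabci.preprocess import detect_bad_channels, Recording, standard_chain
from vsabci.sessionio import read_session, write_session

_TOP_KEYS = {
    "seed", "conditions", "paradigm", "profiles", "noise", "decoder", "plan",
    "quantize_bits",
}
_PLANS = ("within", "cross_condition", "k_sweep")


def load_scenario(path: str | Path) -> dict:
    """Load and validate a scenario YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise DomainError(f"{path}: scenario must be a mapping")
    return validate_scenario(raw)


def validate_scenario(raw: dict) -> dict:
    unknown = sorted(set(raw) - _TOP_KEYS)
    if unknown:
        raise DomainError(f"scenario: unknown keys {unknown}")
    missing = [k for k in ("seed",) if k not in raw]
    if "conditions" not in raw:
        missing.append("conditions")
    if missing:
        raise DomainError(f"scenario: missing required keys {missing}")
    for section, cls in (
        ("paradigm", ParadigmConfig),
        ("noise", NoiseSpec),
    ):
        extra = sorted(
            set(raw.get(section, {})) - {f.name for f in dataclasses.fields(cls)}
        )
        if extra:
            raise DomainError(f"scenario.{section}: unknown keys {extra}")
    prof_fields = {f.name for f in dataclasses.fields(ConditionProfile)}
    for cond, over in raw.get("profiles", {}).items():
        extra = sorted(set(over) - prof_fields)
        if extra:
            raise DomainError(f"scenario.profiles.{cond}: unknown keys {extra}")
    if raw.get("plan", "within") not in _PLANS:
        raise DomainError(
            f"scenario.plan: {raw.get('plan')!r} not one of {_PLANS}"
        )
    return raw


def scenario_hash(scenario: dict) -> str:
    canon = json.dumps(scenario, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def build_components(scenario: dict):
    cfg = ParadigmConfig(
        conditions=tuple(scenario["conditions"]), **scenario.get("paradigm", {})
    )
    profiles = default_condition_profiles()
    for cond, over in scenario.get("profiles", {}).items():
        profiles[cond] = dataclasses.replace(profiles[cond], **over)
    noise = NoiseSpec(**scenario.get("noise", {}))
    return cfg, default_erp_model(), profiles, noise


def run_simulate(scenario: dict, out_dir: str | Path, force: bool = False) -> Path:
    """Simulate the scenario's session and write it with a manifest."""
    cfg, erp, profiles, noise = build_components(scenario)
    session = simulate_session(
        cfg, erp, profiles, noise,
        seed=int(scenario["seed"]), conditions=scenario["conditions"],
    )
    out_dir = Path(out_dir)
    write_session(
        session, out_dir, quantize_bits=scenario.get("quantize_bits"), force=force
    )
    manifest = {
        "config_hash": scenario_hash(scenario),
        "seed": int(scenario["seed"]),
        "n_blocks": int(len(session.blocks)),
        "n_events": int(len(session.events)),
        "conditions": list(scenario["conditions"]),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def _estimate_to_dict(est) -> dict:
    return {
        "accuracy": est.point, "ci_low": est.ci_low, "ci_high": est.ci_high,
        "n_selections": est.n_selections, "n_bootstrap": est.n_bootstrap,
    }


def run_decode(
    session_dir: str | Path,
    decoder: str = "tlda",
    plan: str = "within",
    out_dir: str | Path = "decode_out",
    seed: int = 0,
    run_ransac: bool = True,
    make_figures: bool = True,
) -> dict:
    """Preprocess a stored session, decode it per ``plan``, write reports.

    Returns the report dict; writes ``report.json``, per-fold CSVs, a gaze
    summary, and figures into ``out_dir``.
    """
    if plan not in _PLANS:
        raise DomainError(f"unknown plan {plan!r}; valid options: {_PLANS}")
    make_decoder(decoder)  # fail fast on unknown names
    session = read_session(session_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    quality = detect_bad_channels(_bandpassed(session)) if run_ransac else None
    epochs = standard_chain(session)
    factory = lambda: make_decoder(decoder)  # noqa: E731

    conditions = sorted(session.events["condition"].unique())
    report: dict = {
        "version": 1,
        "decoder": decoder,
        "plan": plan,
        "seed": seed,
        "conditions": conditions,
        "parameters": {
            "bandpass_hz": [0.5, 16.0],
            "epoch_window_s": [-0.1, 0.9],
            "feature_window_ms": [0.0, 800.0],
            "decimation": 20,
            "keep_repetitions": 10,
        },
    }
    if quality is not None:
        (out_dir / "channel_quality.json").write_text(
            json.dumps(quality.to_json_dict(), indent=2)
        )
        report["bad_channels"] = quality.bads

    if plan == "within":
        within = {}
        for cond in conditions:
            cv = blockwise_cv(epochs, factory, condition=cond, seed=seed)
            within[cond] = _estimate_to_dict(cv.estimate)
            cv.folds.to_csv(out_dir / f"folds_{cond}.csv", index=False)
        report["within_condition"] = within
        if make_figures:
            from vsabci.evaluate import AccuracyEstimate
            from vsabci.plots import accuracy_bars

            ests = {
                c: AccuracyEstimate(
                    point=d["accuracy"], ci_low=d["ci_low"], ci_high=d["ci_high"],
                    n_selections=d["n_selections"], n_bootstrap=d["n_bootstrap"],
                )
                for c, d in within.items()
            }
            accuracy_bars(ests, out_dir / "within_condition.png")
    elif plan == "cross_condition":
        res = cross_condition_eval(epochs, factory, conditions=conditions, seed=seed)
        report["cross_condition"] = {
            f"{a}->{b}": _estimate_to_dict(est) for (a, b), est in res.matrix.items()
        }
        if make_figures:
            from vsabci.plots import cross_condition_heatmap

            cross_condition_heatmap(res, out_dir / "cross_condition.png")
    else:  # k_sweep
        sweep = {}
        for cond in conditions:
            curve = accuracy_by_k(epochs, factory, condition=cond, seed=seed)
            sweep[cond] = {
                "by_k": {str(k): _estimate_to_dict(v) for k, v in curve.items()},
                "reps_to_80pct": reps_to_threshold(curve, 0.8),
            }
        report["k_sweep"] = sweep

    fused = fuse_binocular(session.gaze)
    dwell = dwell_summary(fused, session.blocks, session.config.target_positions)
    dwell.to_csv(out_dir / "gaze_dwell.csv", index=False)
    report["gaze_labels"] = dwell.groupby("condition")["label"].agg(list).to_dict()
    if make_figures:
        from vsabci.plots import gaze_heatmap

        gaze_heatmap(fused, session.config.target_positions, out_dir / "gaze.png")

    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _bandpassed(session):
    from vsabci.preprocess import bandpass

    return bandpass(Recording.from_session(session))


def run_report(report_paths: list[str | Path], out_path: str | Path) -> str:
    """Merge decode reports into one human-readable markdown summary."""
    if not report_paths:
        raise DomainError("at least one report is required")
    reports = []
    for p in report_paths:
        r = json.loads(Path(p).read_text())
        if r.get("version") != 1:
            raise DomainError(f"{p}: unsupported report version {r.get('version')}")
        reports.append((Path(p), r))

    lines = ["# Decoding summary", ""]
    for p, r in reports:
        lines.append(f"## {p} — decoder `{r['decoder']}`, plan `{r['plan']}`")
        if "within_condition" in r:
            lines.append("")
            lines.append("| condition | accuracy | 95% CI | n |")
            lines.append("|---|---|---|---|")
            for cond, d in r["within_condition"].items():
                lines.append(
                    f"| {cond} | {d['accuracy']:.3f} | "
                    f"[{d['ci_low']:.3f}, {d['ci_high']:.3f}] | {d['n_selections']} |"
                )
        if "cross_condition" in r:
            lines.append("")
            lines.append("| train→test | accuracy | 95% CI |")
            lines.append("|---|---|---|")
            for pair, d in r["cross_condition"].items():
                lines.append(
                    f"| {pair} | {d['accuracy']:.3f} | "
                    f"[{d['ci_low']:.3f}, {d['ci_high']:.3f}] |"
                )
        if "k_sweep" in r:
            lines.append("")
            lines.append("| condition | repetitions to 80% |")
            lines.append("|---|---|")
            for cond, d in r["k_sweep"].items():
                lines.append(f"| {cond} | {format_reps(d['reps_to_80pct'])} |")
        lines.append("")
    text = "\n".join(lines)
    Path(out_path).write_text(text)
    return text
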