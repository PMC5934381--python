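"""End-to-end pipeline driver, transect persistence and fixture generation.

``run_pipeline`` chains the stages of a transmission experiment —
synthesize stimuli per locality, simulate transects at each site, score the
degradation table, standardize and average, contrast local against foreign
origins — writing all tables plus a manifest. Every stochastic stage draws its
seed deterministically from the single config seed, so a run is reproducible
from (config, seed) alone.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from callprop import io
from callprop.metrics import (
    CalibrationReference,
    average_replicates,
    degradation_table,
    local_vs_foreign_summary,
    standardize_by_origin,
)
from callprop.presets import ILLUSTRATIVE_LOCALITIES
from callprop.propagation import TransectConfig, TransectRecording, simulate_transect
from callprop.synthesis import build_stimulus_train, synthesize_call
from callprop.types import CallParameters, StimulusSpec, Waveform

logger = logging.getLogger("callprop")

__version__ = "0.1.0"


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    version: str
    config_hash: str
    seed: int
    stage_counts: dict[str, int] = field(default_factory=dict)
    files: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
        return path


def _stage_seed(base_seed: int, *indices: int) -> int:
    """Deterministic child seed (< 2^31) for one stage/site/transect/origin."""
    ss = np.random.SeedSequence([int(base_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % 2**31)


def _parse_bands(raw: Any) -> tuple:
    if not raw:
        return ()
    bands = []
    for item in raw:
        (lo, hi), coef = (item[0][0], item[0][1]), item[1]
        bands.append(((float(lo), float(hi)), float(coef)))
    return tuple(bands)


def parse_config(cfg: Mapping[str, Any]) -> dict[str, Any]:
    """Validate and normalize a pipeline config mapping."""
    if "localities" not in cfg or not cfg["localities"]:
        raise ValueError("config must define at least one locality")
    localities = {
        label: CallParameters.from_dict(d, label=label)
        for label, d in cfg["localities"].items()
    }
    sites = list(cfg.get("sites", localities))
    missing = [s for s in sites if s not in localities]
    if missing:
        raise ValueError(f"sites reference undefined localities: {missing}")
    stim_cfg = cfg.get("stimulus", {})
    spec = StimulusSpec(
        n_replicates=int(stim_cfg.get("n_replicates", 5)),
        inter_stimulus_interval=float(stim_cfg.get("inter_stimulus_interval", 6.0)),
    )
    t = dict(cfg.get("transect", {}))
    transect = TransectConfig(
        distances=tuple(float(d) for d in t.get("distances", (0.5, 2, 4, 8, 16))),
        reference_distance=float(t.get("reference_distance", 0.5)),
        source_level_db=float(t.get("source_level_db", 90.0)),
        excess_attenuation=_parse_bands(t.get("excess_attenuation")),
        reverb_decay_s=float(t.get("reverb_decay_s", 0.0)),
        reverb_tail_to_direct=float(t.get("reverb_tail_to_direct", 0.05)),
        noise_level_db=(
            None if t.get("noise_level_db") is None else float(t["noise_level_db"])
        ),
        lead_noise_s=float(t.get("lead_noise_s", 1.0)),
        seed=0,
    )
    return {
        "localities": localities,
        "sites": sites,
        "stimulus": spec,
        "transect": transect,
        "n_transects": int(cfg.get("n_transects", 3)),
        "permutations": int(cfg.get("permutations", 999)),
        "seed": int(cfg.get("seed", 0)),
        "outdir": Path(cfg.get("outdir", "callprop_out")),
        "write_wavs": bool(cfg.get("write_wavs", False)),
    }


def run_pipeline(
    cfg: Mapping[str, Any], outdir: str | Path | None = None
) -> RunManifest:
    """Execute synth -> simulate -> degrade -> summarize and write all outputs."""
    parsed = parse_config(cfg)
    out = Path(outdir) if outdir is not None else parsed["outdir"]
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__, config_hash=io.config_hash(cfg), seed=parsed["seed"]
    )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # Stage 1: stimuli.
        trains: dict[str, Waveform] = {}
        for label, params in parsed["localities"].items():
            call = synthesize_call(params)
            trains[label] = build_stimulus_train(call, parsed["stimulus"])
            if parsed["write_wavs"]:
                p = io.write_wav(out / "stimuli" / f"{label}.wav", trains[label])
                manifest.files.append(str(p.relative_to(out)))
        logger.info("synth: %d stimuli", len(trains))
        manifest.stage_counts["stimuli"] = len(trains)

        # Stages 2-3: transects and scoring.
        tables = []
        site_transects: dict[str, list[str]] = {}
        for si, site in enumerate(parsed["sites"]):
            site_transects[site] = []
            for t in range(parsed["n_transects"]):
                transect_id = f"{site}/T{t + 1}"
                site_transects[site].append(transect_id)
                for oi, (origin, train) in enumerate(trains.items()):
                    tcfg = TransectConfig(
                        **{
                            **asdict_config(parsed["transect"]),
                            "seed": _stage_seed(parsed["seed"], 1, si, t, oi),
                        }
                    )
                    rec = simulate_transect(train, tcfg)
                    if parsed["write_wavs"]:
                        files = save_transect(
                            rec, out / "transects", transect_id.replace("/", "_"), origin,
                            parsed["localities"][origin],
                        )
                        manifest.files.extend(str(f.relative_to(out)) for f in files)
                    tables.append(
                        degradation_table(
                            rec, parsed["localities"][origin], transect_id
                        )
                    )
        raw_table = pd.concat(tables, ignore_index=True)
        logger.info("degrade: %d rows", len(raw_table))
        manifest.stage_counts["degradation_rows"] = len(raw_table)

        # Stage 4: standardize + average.
        std = standardize_by_origin(
            raw_table, reference_distance=parsed["transect"].reference_distance
        )
        averaged = average_replicates(std)

        # Stage 5: local-vs-foreign contrast per site.
        summaries = []
        for si, site in enumerate(parsed["sites"]):
            if len(parsed["localities"]) < 2:
                break
            sub = averaged[averaged["transect"].str.startswith(f"{site}/")]
            rep = local_vs_foreign_summary(
                sub,
                locality=site,
                n_permutations=parsed["permutations"],
                seed=_stage_seed(parsed["seed"], 2, si),
            )
            rep.insert(0, "site", site)
            summaries.append(rep)

        for name, df in (
            ("degradation_table.csv", std),
            ("degradation_averaged.csv", averaged),
        ):
            df.to_csv(out / name, index=False, float_format="%.10g")
            manifest.files.append(name)
        if summaries:
            summary = pd.concat(summaries, ignore_index=True)
            summary.to_csv(out / "local_vs_foreign.csv", index=False, float_format="%.10g")
            manifest.files.append("local_vs_foreign.csv")
            manifest.stage_counts["summary_rows"] = len(summary)

        manifest.warnings = sorted({str(w.message) for w in caught})

    manifest.write(out / "manifest.json")
    manifest.files.append("manifest.json")
    return manifest


def asdict_config(tcfg: TransectConfig) -> dict[str, Any]:
    return {
        "distances": tcfg.distances,
        "reference_distance": tcfg.reference_distance,
        "source_level_db": tcfg.source_level_db,
        "excess_attenuation": tcfg.excess_attenuation,
        "reverb_decay_s": tcfg.reverb_decay_s,
        "reverb_tail_to_direct": tcfg.reverb_tail_to_direct,
        "noise_level_db": tcfg.noise_level_db,
        "lead_noise_s": tcfg.lead_noise_s,
        "seed": tcfg.seed,
    }


# ---------------------------------------------------------------------------
# Transect persistence (WAV + sidecar markers + meta)
# ---------------------------------------------------------------------------

def save_transect(
    rec: TransectRecording,
    outdir: str | Path,
    transect: str,
    origin: str,
    params: CallParameters,
) -> list[Path]:
    """Write one transect recording set: per-distance WAVs, markers, meta, tone."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for d, wave in rec.recordings.items():
        files.append(io.write_wav(outdir / f"{transect}_{origin}_{d:g}m.wav", wave))
    onsets = rec.stimulus_annotations.get("replicate_onsets_s", np.array([]))
    rows = [{"label": "noise", "start_s": rec.noise_span_s[0], "stop_s": rec.noise_span_s[1]}]
    for i, o in enumerate(onsets):
        rows.append(
            {
                "label": f"replicate_{i}",
                "start_s": float(o),
                "stop_s": float(o) + params.call_duration,
            }
        )
    files.append(
        io.write_markers(outdir / f"{transect}_{origin}_markers.csv", pd.DataFrame(rows))
    )
    meta = {
        "transect": transect,
        "origin": origin,
        "calibration": {
            "tone_rms_digital": float(rec.calibration.tone_rms_digital),
            "tone_level_db": float(rec.calibration.tone_level_db),
            "tone_frequency_hz": float(rec.calibration.tone_frequency_hz),
        },
        "distances": [float(d) for d in rec.config.distances],
        "reference_distance": float(rec.config.reference_distance),
        "reverb_decay_s": float(rec.config.reverb_decay_s),
        "params": params.to_dict(),
    }
    meta_path = outdir / f"{transect}_{origin}_meta.yaml"
    with open(meta_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    files.append(meta_path)
    files.append(
        io.write_wav(outdir / f"{transect}_{origin}_tone.wav", rec.calibration_tone())
    )
    return files


def load_transect(
    indir: str | Path, transect: str, origin: str
) -> tuple[TransectRecording, CallParameters]:
    """Rebuild a TransectRecording (and its origin parameters) from disk."""
    indir = Path(indir)
    with open(indir / f"{transect}_{origin}_meta.yaml", "r", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    params = CallParameters.from_dict(meta["params"])
    markers = io.read_markers(indir / f"{transect}_{origin}_markers.csv")
    noise_row = markers[markers["label"] == "noise"]
    noise_span = (
        (float(noise_row["start_s"].iloc[0]), float(noise_row["stop_s"].iloc[0]))
        if not noise_row.empty
        else (0.0, 0.0)
    )
    reps = markers[markers["label"].str.startswith("replicate_")]
    onsets = reps["start_s"].to_numpy(dtype=float)
    recordings = {
        float(d): io.read_wav(indir / f"{transect}_{origin}_{d:g}m.wav")
        for d in meta["distances"]
    }
    calib = CalibrationReference(**meta["calibration"])
    config = TransectConfig(
        distances=tuple(float(d) for d in meta["distances"]),
        reference_distance=float(meta["reference_distance"]),
        reverb_decay_s=float(meta.get("reverb_decay_s", 0.0)),
        lead_noise_s=noise_span[1] - noise_span[0],
    )
    rec = TransectRecording(
        recordings=recordings,
        calibration=calib,
        noise_span_s=noise_span,
        config=config,
        stimulus_annotations={"replicate_onsets_s": onsets},
    )
    return rec, params


def discover_transects(indir: str | Path) -> list[tuple[str, str]]:
    """(transect, origin) pairs present in a directory of saved transects."""
    pairs = []
    for meta in sorted(Path(indir).glob("*_meta.yaml")):
        with open(meta, "r", encoding="utf-8") as fh:
            m = yaml.safe_load(fh)
        pairs.append((m["transect"], m["origin"]))
    return pairs


# ---------------------------------------------------------------------------
# Fixture battery
# ---------------------------------------------------------------------------

def generate_fixtures(seed: int, outdir: str | Path) -> list[Path]:
    """Write a small test battery under ``outdir``.

    Three illustrative localities: a clean stimulus WAV each, one simulated
    transect each (five distances, WAV + markers + meta + tone), and an
    expected-feature CSV whose values come from construction arithmetic (the
    oracle), not from the analysis chain.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    spec = StimulusSpec(n_replicates=2, inter_stimulus_interval=0.5)
    expected_rows = []
    for oi, (label, params) in enumerate(ILLUSTRATIVE_LOCALITIES.items()):
        call = synthesize_call(params)
        train = build_stimulus_train(call, spec)
        files.append(io.write_wav(outdir / f"stimulus_{label}.wav", train))
        tcfg = TransectConfig(
            noise_level_db=40.0, seed=_stage_seed(seed, 0, oi)
        )
        rec = simulate_transect(train, tcfg)
        files.extend(save_transect(rec, outdir, "T1", label, params))
        expected_rows.append(
            {
                "locality": label,
                "call_duration": params.call_duration,
                "n_pulses": params.n_pulses,
                "mean_pulse_duration": params.pulse_duration,
                "mean_inter_pulse_interval": (
                    params.inter_pulse_interval if params.n_pulses > 1 else np.nan
                ),
                "pulse_rate": params.n_pulses / params.call_duration,
                "modulation_depth": params.modulation_depth,
                "dominant_frequency": params.dominant_frequency,
            }
        )
    expected = pd.DataFrame(expected_rows)
    path = outdir / "expected_features.csv"
    expected.to_csv(path, index=False)
    files.append(path)
    return files
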