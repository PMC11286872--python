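"""Configuration, fixtures, and output management.

Configs are flat YAML/JSON mappings validated against the known model
parameters (unknown keys are rejected so typos cannot silently fall back to
defaults).  Traces and tables export as UTF-8 comma-separated CSV with a
header row and 9-significant-digit floats, for reproducible diffs; frames
export as PNG with signed intensity mapped around mid-gray so dark
(OFF-driven) percept regions stay visible.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .electrodes import Electrode, ElectrodeArray
from .percept import PerceptMovie
from .retinotopy import PRESETS, RetinoMap
from .sheet import SheetSpec, generate_maps
from .temporal import PulseTrain, ResponseTrace, TemporalParams

_FLOAT_FMT = "%.9g"


# ---------------------------------------------------------------------------
# configuration


_TEMPORAL_KEYS = {f.name for f in dataclasses.fields(TemporalParams)}
_TRAIN_KEYS = {f.name for f in dataclasses.fields(PulseTrain)}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    """Load a YAML or JSON config mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    return data


def save_config(cfg: dict, path) -> None:
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(cfg, indent=2, sort_keys=True))
    else:
        p.write_text(yaml.safe_dump(cfg, sort_keys=True))


def temporal_params_from_config(cfg: dict) -> TemporalParams:
    block = cfg.get("temporal", {})
    unknown = set(block) - _TEMPORAL_KEYS
    if unknown:
        raise ConfigError(f"unknown temporal parameter(s): {sorted(unknown)}")
    return TemporalParams(**block)


def pulse_train_from_config(cfg: dict) -> PulseTrain:
    block = cfg.get("train")
    if block is None:
        raise ConfigError("missing required key 'train'")
    unknown = set(block) - _TRAIN_KEYS
    if unknown:
        raise ConfigError(f"unknown pulse-train parameter(s): {sorted(unknown)}")
    for req in ("amplitude", "pulse_width", "frequency", "train_duration"):
        if req not in block:
            raise ConfigError(f"missing required key 'train.{req}'")
    return PulseTrain(**block)


def retinomap_from_config(cfg: dict) -> RetinoMap:
    block = cfg.get("retinomap", "standard")
    if isinstance(block, str):
        try:
            return PRESETS[block]
        except KeyError:
            raise ConfigError(f"unknown retinomap preset {block!r}") from None
    unknown = set(block) - {"k", "a", "squish", "hemisphere"}
    if unknown:
        raise ConfigError(f"unknown retinomap parameter(s): {sorted(unknown)}")
    return RetinoMap(**block)


# ---------------------------------------------------------------------------
# tables, traces, arrays


def trace_to_csv(trace: ResponseTrace, path) -> None:
    """2-column CSV: time_ms,value."""
    df = pd.DataFrame({"time_ms": trace.time, "value": trace.value})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def trace_from_csv(path) -> ResponseTrace:
    df = pd.read_csv(path)
    return ResponseTrace(df["time_ms"].to_numpy(), df["value"].to_numpy())


def array_to_csv(array: ElectrodeArray, path) -> None:
    rows = [{"id": e.id, "x_mm": e.position.real, "y_mm": e.position.imag,
             "rad_mm": e.rad_e, "kind": e.kind, "s": e.s}
            for e in array]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def array_from_csv(path) -> ElectrodeArray:
    df = pd.read_csv(path)
    els = [Electrode(id=str(r.id), position=complex(r.x_mm, r.y_mm),
                     rad_e=float(r.rad_mm), kind=str(r.kind), s=float(r.s))
           for r in df.itertuples()]
    return ElectrodeArray(els)


def frame_to_png(frame: np.ndarray, path, s_out: float = 10.0) -> None:
    """Export a signed-intensity frame as 8-bit PNG (0 -> mid-gray)."""
    import imageio.v3 as iio
    scaled = np.clip(frame / s_out, -1.0, 1.0)
    img = np.round((scaled + 1.0) * 127.5).astype(np.uint8)
    iio.imwrite(Path(path), img[::-1])   # image row 0 at top = max y


def movie_to_pngs(movie: PerceptMovie, directory, s_out: float = 10.0,
                  ) -> list[Path]:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, fr in enumerate(movie.frames):
        p = d / f"frame_{i:04d}.png"
        frame_to_png(fr, p, s_out)
        paths.append(p)
    return paths


def movie_to_gif(movie: PerceptMovie, path, s_out: float = 10.0,
                 fps: int = 20) -> None:
    import imageio.v3 as iio
    frames = [np.round((np.clip(fr / s_out, -1, 1) + 1) * 127.5
                       ).astype(np.uint8)[::-1]
              for fr in movie.frames]
    iio.imwrite(Path(path), frames, duration=1000 // fps, loop=0)


def write_manifest(path, seed: int, config: dict | None = None,
                   extra: dict | None = None) -> None:
    """Run manifest: seed, parameters, package version, platform."""
    man = {"package": "cortisim", "version": __version__, "seed": seed,
           "python": platform.python_version(),
           "config": config or {}}
    if extra:
        man.update(extra)
    Path(path).write_text(json.dumps(man, indent=2, sort_keys=True,
                                     default=str))


def load_summary_table(path) -> pd.DataFrame:
    """Hook for replotting published summary tables (thresholds, sizes).

    Thin CSV reader: any table with an ``electrode`` column plus stimulus
    and measurement columns can be fed to
    :func:`cortisim.psychophysics.fit_sensitivity`.  No such data ships
    with the package.
    """
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(seed: int = 0) -> dict:
    """Small deterministic assets for tests and demos.

    A 10x10 mm sheet at 0.1 mm spacing, a 3-electrode array, reference pulse
    trains (including the classic 2 ms / 75 Hz / 50 ms demonstration train),
    and a synthetic threshold table generated at a known sensitivity
    (s = 0.8) for closed-loop recovery tests.
    """
    from .psychophysics import (STANDARD_TRAIN, calibrate_theta_thresh,
                                find_threshold)
    from .sheet import sheet_center_for_ecc

    sheet = generate_maps(SheetSpec(center=sheet_center_for_ecc(5.0),
                                    extent=(10.0, 10.0), spacing=0.1,
                                    seed=seed))
    center = sheet_center_for_ecc(5.0)
    array = ElectrodeArray([
        Electrode(id=f"e{i}", position=center + complex(0.0, (i - 1) * 2.0),
                  rad_e=0.25, s=0.57)
        for i in range(3)])
    fig1_train = PulseTrain(amplitude=60.0, pulse_width=2.0, frequency=75.0,
                            train_duration=0.05)
    trains = {"demo": fig1_train, "standard": STANDARD_TRAIN}

    s_true = 0.8
    theta = calibrate_theta_thresh()
    rows = []
    for pw in (0.1, 0.25, 0.5):
        for f in (25.0, 50.0):
            tr = PulseTrain(amplitude=1.0, pulse_width=pw, frequency=f,
                            train_duration=0.5)
            res = find_threshold(tr, s_true, theta_thresh=theta)
            rows.append({"electrode": "fix0", "pulse_width": pw,
                         "frequency": f, "train_duration": 0.5,
                         "threshold": res.threshold})
    thresholds = pd.DataFrame(rows)
    return {"sheet": sheet, "array": array, "trains": trains,
            "thresholds": thresholds, "s_true": s_true, "seed": seed}
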