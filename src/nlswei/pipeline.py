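"""End-to-end experiment driver: compress, propagate, reconstruct, report.

Runs the full compression-enhanced SWEI study: for each compression level
the phantom is quasi-statically compressed, a shear-wave push is simulated
on the pre-strained medium, the modulus map is reconstructed by directional
filtering + time of flight, and the per-level ROI summary (moduli, strains,
stresses, contrast) is assembled into one report.  Fully deterministic for
a given configuration.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .compress import DeformedState, roi_statistics, staged_compression
from .phantom import PhantomModel, build_phantom
from .swei import (ContrastReport, build_report, directional_filter,
                   modulus_map, tof_speed)
from .wavesim import ExcitationSpec, WaveRecord, extract_profiles, simulate_wave

__all__ = ["ExperimentConfig", "run_experiment", "speed_increase_ratio",
           "paper_config", "fast_config"]


@dataclass
class ExperimentConfig:
    """All knobs of one experiment run; serializes round-trip to YAML."""

    levels: list = field(default_factory=lambda: [0.0, 0.10, 0.20, 0.30])
    mech_spacing: float = 1.0        # mm, mechanics mesh
    mech_substep: float = 0.01       # compression increment per solve step
    output_spacing: float = 0.2      # mm, wave/reconstruction grid
    record_duration: float = 40.0    # ms
    excitation: dict = field(default_factory=lambda: asdict(ExcitationSpec()))
    x_range: tuple = (2.0, 35.0)     # one-sided reconstruction band, mm
    surr_offset: tuple = (10.0, 0.0)  # surrounding-ROI displacement, mm
    tangent_mode: str = "stress"
    arrival: str = "front"
    density: float = 1000.0
    phantom: dict = field(default_factory=dict)   # build_phantom overrides
    out_dir: str | None = None
    seed: int = 0   # only randomized test fixtures consume this

    def __post_init__(self) -> None:
        lv = list(self.levels)
        if any(b < a for a, b in zip(lv, lv[1:])):
            raise ValueError("levels must be ascending")
        if any(not (0.0 <= v <= 0.35) for v in lv):
            raise ValueError("levels must lie in [0, 0.35]")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["x_range"] = list(d["x_range"])
        d["surr_offset"] = list(d["surr_offset"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["x_range"] = tuple(d.get("x_range", (2.0, 35.0)))
        d["surr_offset"] = tuple(d.get("surr_offset", (10.0, 0.0)))
        return cls(**d)


def paper_config(**overrides) -> ExperimentConfig:
    """The default reproduction configuration (full phantom, four levels)."""
    return ExperimentConfig(**overrides)


def fast_config(**overrides) -> ExperimentConfig:
    """Coarse, short configuration for quick runs and CI-style tests."""
    base = dict(levels=[0.0, 0.20], mech_spacing=2.0, mech_substep=0.02,
                output_spacing=0.4, record_duration=25.0)
    base.update(overrides)
    return ExperimentConfig(**base)


def _build(config: ExperimentConfig) -> PhantomModel:
    return build_phantom(density=config.density, **config.phantom)


def run_experiment(config: ExperimentConfig,
                   phantom: PhantomModel | None = None,
                   log=None) -> ContrastReport:
    """Run the multi-level experiment; returns the contrast report.

    If ``config.out_dir`` is set, writes per-level modulus maps (.npz),
    displacement-profile CSVs at the four Fig.-2-style lateral positions,
    the summary report CSV and a JSON run log there.
    """
    t_start = time.time()
    ph = phantom if phantom is not None else _build(config)
    exc = ExcitationSpec(**config.excitation)
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def say(msg):
        if log:
            log(msg)

    say(f"solving compression levels {config.levels}")
    states = staged_compression(ph, config.levels, spacing=config.mech_spacing,
                                substep=config.mech_substep,
                                tangent_mode=config.tangent_mode)
    maps, runlog = [], []
    for st in states:
        t0 = time.time()
        rec = simulate_wave(st, ph, exc, config.record_duration,
                            spacing=config.output_spacing,
                            density=config.density)
        filt = directional_filter(rec, "forward")
        sm = tof_speed(filt, x_range=config.x_range, arrival=config.arrival)
        gm = modulus_map(sm, config.density)
        maps.append(gm)
        say(f"level {st.compression_level:.2f}: wave+reconstruction "
            f"{time.time() - t0:.1f} s")
        runlog.append({"level": st.compression_level,
                       "wave_seconds": round(time.time() - t0, 2),
                       "residual": st.residual})
        if out is not None:
            tag = f"{int(round(st.compression_level * 100)):02d}"
            np.savez_compressed(out / f"modulus_map_{tag}.npz",
                                modulus=gm.modulus, valid=gm.valid,
                                x=gm.x, y=gm.y, label=gm.label,
                                level=gm.compression_level)
            _write_profiles(rec, out / f"profiles_{tag}.csv")
    report = build_report(maps, states, ph, surr_offset=config.surr_offset)
    if out is not None:
        report.to_csv(out / "report.csv")
        (out / "run_log.json").write_text(json.dumps(
            {"levels": runlog, "total_seconds": round(time.time() - t_start, 2)},
            indent=2))
    return report


def _write_profiles(rec: WaveRecord, path,
                    positions=(10.2, 13.3, 20.2, 23.3), depth: float = 20.0):
    import pandas as pd
    prof = extract_profiles(rec, list(positions), y=depth)
    df = pd.DataFrame({"time_ms": prof["time"],
                       **{f"x_{p}mm_um": prof[p] for p in positions}})
    df.to_csv(path, index=False)


def speed_increase_ratio(report: ContrastReport,
                         level_lo: float = 0.0, level_hi: float = 0.30) -> float:
    """Ratio of tumor to surrounding shear-wave-speed increase factors.

    (c_tumor(hi)/c_tumor(lo)) / (c_surr(hi)/c_surr(lo)); > 1 means the
    tumor's wave speed grew faster with compression than the background's.
    """
    df = report.table
    rows = {round(lv, 6): df[np.isclose(df["level"], lv)] for lv in (level_lo, level_hi)}
    for lv, r in rows.items():
        if len(r) != 1:
            raise ValueError(f"report has no unique row at level {lv}")
    lo = rows[round(level_lo, 6)].iloc[0]
    hi = rows[round(level_hi, 6)].iloc[0]
    return float((hi["c_tumor"] / lo["c_tumor"]) / (hi["c_surr"] / lo["c_surr"]))
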