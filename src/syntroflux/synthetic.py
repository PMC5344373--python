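"""Synthetic batch datasets with the structure of the co-culture assays.

Generates triplicate time courses for the four nitrogen regimes from
known ground-truth parameters: the noise-free community simulation is
mapped through the observation model (OD600, HPLC/GC metabolite
channels, per-species qPCR) and per-channel measurement noise plus
limit-of-detection censoring is applied.  Because the truth is known by
construction, these datasets drive parameter-recovery tests without any
external data.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as _config
from .dfba import SimulationConfig, TimeCourse, simulate_batch
from .fitting import ObservationModel, default_observation_model, map_trajectory

__all__ = [
    "NoiseSpec",
    "SyntheticDataset",
    "default_noise",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

_COLUMNS = ["time_h", "channel", "replicate", "value", "units"]
_UNITS = {"od600": "OD600"}


def _units_for(channel: str) -> str:
    if channel in _UNITS:
        return _UNITS[channel]
    if channel.startswith("copies_"):
        return "copies/mL"
    return "mM"


@dataclass
class NoiseSpec:
    """Per-channel noise model and limit-of-detection censoring.

    ``channels``: channel -> (kind, sd); kind 'additive_gaussian' with sd
    in channel units, or 'multiplicative_lognormal' with sd in log10
    units.  ``limit_of_detection``: observations below the LoD are
    censored to exactly 0 (never emitted strictly between 0 and LoD).
    """

    channels: dict[str, tuple[str, float]] = field(default_factory=dict)
    limit_of_detection: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, (kind, sd) in self.channels.items():
            if kind not in ("additive_gaussian", "multiplicative_lognormal"):
                raise ValueError(f"unknown noise kind {kind!r} for {ch!r}")
            if sd < 0:
                raise ValueError(f"negative sd for channel {ch!r}")
        for ch, lod in self.limit_of_detection.items():
            if lod < 0:
                raise ValueError(f"negative LoD for channel {ch!r}")


def default_noise(obs_model: ObservationModel | None = None) -> NoiseSpec:
    """Instrument-matched defaults: additive Gaussian for HPLC/GC/OD,
    lognormal (0.1 log10 units) for qPCR; small LoDs on gas/ion channels."""
    obs_model = obs_model or default_observation_model()
    channels: dict[str, tuple[str, float]] = {}
    for ch, sd, kind in obs_model.observed_channels:
        channels[ch] = (
            "multiplicative_lognormal" if kind == "lognormal"
            else "additive_gaussian",
            sd,
        )
    lod = {"h2": 0.02, "no2": 0.01, "no3": 0.05}
    for ch in channels:
        if ch.startswith("copies_"):
            lod[ch] = 1e4
    return NoiseSpec(channels=channels, limit_of_detection=lod)


@dataclass
class SyntheticDataset:
    observations: pd.DataFrame  # long format, _COLUMNS
    truth_params: dict
    truth_timecourse: TimeCourse | None
    condition: str
    seed: int

    def truth_hash(self) -> str:
        return _hash_params(self.truth_params)


def _hash_params(params: dict) -> str:
    canon = json.dumps(params, sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def generate_dataset(
    condition: str,
    truth_params: dict | None = None,
    obs_model: ObservationModel | None = None,
    noise: NoiseSpec | None = None,
    n_replicates: int = 3,
    sampling_times: np.ndarray | None = None,
    seed: int = 0,
    species: tuple[str, ...] = ("clostridium", "wolinella"),
    sim_config: SimulationConfig | None = None,
) -> SyntheticDataset:
    """Simulate one condition with known parameters and emit noisy
    replicate observations.

    Deterministic per seed: the same seed gives byte-identical datasets.
    With all noise sds at zero the observations equal the mapped
    noise-free trajectory exactly.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    obs_model = obs_model or default_observation_model(species)
    noise = noise if noise is not None else default_noise(obs_model)
    unknown = set(noise.channels) - set(obs_model.channel_names())
    if unknown:
        raise ValueError(f"noise spec for unobserved channels: {sorted(unknown)}")
    sim_config = sim_config or SimulationConfig()
    cond = _config.condition(condition, params=truth_params)
    com = _config.build_community(cond, species=species)
    tc = simulate_batch(com, cond.initial_state, sim_config)
    tc.condition = condition

    if sampling_times is None:
        sampling_times = np.linspace(0.0, sim_config.t_end, 10)
    sampling_times = np.asarray(sampling_times, dtype=float)
    clean = map_trajectory(tc, obs_model, sampling_times)

    rng = np.random.default_rng(seed)
    records = []
    for rep in range(1, n_replicates + 1):
        for ch in obs_model.channel_names():
            if ch not in clean.columns:
                continue
            vals = clean[ch].to_numpy(dtype=float)
            kind, sd = noise.channels.get(ch, ("additive_gaussian", 0.0))
            if sd > 0:
                if kind == "additive_gaussian":
                    vals = vals + rng.normal(0.0, sd, size=vals.shape)
                else:
                    vals = vals * 10.0 ** rng.normal(0.0, sd, size=vals.shape)
            vals = np.maximum(vals, 0.0)
            lod = noise.limit_of_detection.get(ch, 0.0)
            if lod > 0:
                vals = np.where(vals < lod, 0.0, vals)
            for t, v in zip(sampling_times, vals):
                records.append((t, ch, rep, v, _units_for(ch)))
    obs = pd.DataFrame(records, columns=_COLUMNS).sort_values(
        ["time_h", "channel", "replicate"], kind="stable"
    ).reset_index(drop=True)
    return SyntheticDataset(
        observations=obs,
        truth_params=dict(cond.parameters),
        truth_timecourse=tc,
        condition=condition,
        seed=seed,
    )


def write_dataset(dataset: SyntheticDataset, path) -> None:
    """Write observations (CSV) plus a metadata sidecar (JSON) holding the
    seed, condition, truth parameters and a truth hash."""
    path = Path(path)
    dataset.observations.to_csv(path, index=False)
    meta = {
        "condition": dataset.condition,
        "seed": dataset.seed,
        "truth_params": dataset.truth_params,
        "truth_hash": dataset.truth_hash(),
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2, default=float))


def read_dataset(path) -> SyntheticDataset:
    """Round-trip reader with schema validation and tamper detection.

    A missing column fails loudly with the offending line context; a
    truth-hash mismatch between sidecar and parameters warns.
    """
    path = Path(path)
    obs = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(
            f"{path}:1: malformed dataset, missing columns {missing}; "
            f"found {list(obs.columns)}"
        )
    bad = obs[obs["value"].isna()]
    if not bad.empty:
        raise ValueError(
            f"{path}:{bad.index[0] + 2}: non-numeric or missing value"
        )
    meta_path = path.with_suffix(".meta.json")
    truth_params: dict = {}
    condition = ""
    seed = -1
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        truth_params = meta.get("truth_params", {})
        condition = meta.get("condition", "")
        seed = meta.get("seed", -1)
        if meta.get("truth_hash") and _hash_params(truth_params) != meta["truth_hash"]:
            warnings.warn(
                f"{meta_path}: truth hash mismatch — parameters may have "
                "been tampered with", stacklevel=2,
            )
    return SyntheticDataset(
        observations=obs,
        truth_params=truth_params,
        truth_timecourse=None,
        condition=condition,
        seed=seed,
    )
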