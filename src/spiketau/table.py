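"""Trial-aligned spike tables: the interchange object between all stages.

A :class:`SpikeTable` bundles three tidy tables:

``neurons``
    one row per unit: ``neuron_id, unit_type, depth_um, session_id``
``trials``
    one row per (neuron, trial): ``trial_id, neuron_id, condition,
    stimulus_type, stimulus_location, fixation_on, stimulus_on,
    stimulus_off, trial_end`` (event times in ms, fixation onset at 0)
``spikes``
    one row per spike: ``neuron_id, trial_id, spike_time_ms``

All times are milliseconds relative to fixation onset; analysis windows are
half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

NEURON_COLUMNS = ["neuron_id", "unit_type", "depth_um", "session_id"]
TRIAL_COLUMNS = [
    "trial_id",
    "neuron_id",
    "condition",
    "stimulus_type",
    "stimulus_location",
    "fixation_on",
    "stimulus_on",
    "stimulus_off",
    "trial_end",
]
SPIKE_COLUMNS = ["neuron_id", "trial_id", "spike_time_ms"]


class SpikeTableError(ValueError):
    """Raised when a spike table violates its referential or range invariants."""


@dataclass
class SpikeTable:
    neurons: pd.DataFrame
    trials: pd.DataFrame
    spikes: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._train_cache: dict[int, dict[int, np.ndarray]] = {}

    # ------------------------------------------------------------------ access
    def neuron_ids(self) -> np.ndarray:
        return self.neurons["neuron_id"].to_numpy()

    def trials_for(
        self,
        neuron_id: int,
        condition: str | None = None,
        stimulus_type: str | None = None,
        stimulus_location: int | None = None,
    ) -> pd.DataFrame:
        t = self.trials[self.trials["neuron_id"] == neuron_id]
        if condition is not None:
            t = t[t["condition"] == condition]
        if stimulus_type is not None:
            t = t[t["stimulus_type"] == stimulus_type]
        if stimulus_location is not None:
            t = t[t["stimulus_location"] == stimulus_location]
        return t

    def _trains(self, neuron_id: int) -> dict[int, np.ndarray]:
        cached = self._train_cache.get(neuron_id)
        if cached is None:
            s = self.spikes[self.spikes["neuron_id"] == neuron_id]
            tids = s["trial_id"].to_numpy()
            times = s["spike_time_ms"].to_numpy(dtype=float)
            order = np.lexsort((times, tids))
            tids, times = tids[order], times[order]
            bounds = np.flatnonzero(np.diff(tids)) + 1
            cached = {
                int(t[0]): t_times
                for t, t_times in zip(
                    np.split(tids, bounds), np.split(times, bounds)
                )
                if len(t)
            }
            self._train_cache[neuron_id] = cached
        return cached

    def spike_trains(self, neuron_id: int, trial_ids) -> list[np.ndarray]:
        """Per-trial sorted spike-time arrays (empty array for spikeless trials)."""
        trains = self._trains(neuron_id)
        empty = np.empty(0, dtype=float)
        return [trains.get(int(t), empty) for t in trial_ids]

    # -------------------------------------------------------------- validation
    def validate(self) -> "SpikeTable":
        for name, df, cols in (
            ("neurons", self.neurons, NEURON_COLUMNS),
            ("trials", self.trials, TRIAL_COLUMNS),
            ("spikes", self.spikes, SPIKE_COLUMNS),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SpikeTableError(f"{name} table is missing columns {missing}")

        known_neurons = set(self.neurons["neuron_id"])
        orphan = ~self.trials["neuron_id"].isin(known_neurons)
        if orphan.any():
            row = int(np.flatnonzero(orphan.to_numpy())[0])
            raise SpikeTableError(
                f"trials row {row} references unknown neuron_id "
                f"{self.trials['neuron_id'].iloc[row]}"
            )

        trial_key = pd.MultiIndex.from_frame(self.trials[["neuron_id", "trial_id"]])
        spike_key = pd.MultiIndex.from_frame(self.spikes[["neuron_id", "trial_id"]])
        orphan = ~spike_key.isin(trial_key)
        if orphan.any():
            row = int(np.flatnonzero(orphan)[0])
            raise SpikeTableError(
                f"spikes row {row} references unknown (neuron_id, trial_id) "
                f"{tuple(self.spikes.iloc[row][['neuron_id', 'trial_id']])}"
            )

        ends = self.trials.set_index(["neuron_id", "trial_id"])["trial_end"]
        t = self.spikes["spike_time_ms"].to_numpy(dtype=float)
        end_per_spike = ends.loc[spike_key].to_numpy(dtype=float)
        bad = (t < 0) | (t > end_per_spike)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SpikeTableError(
                f"spikes row {row}: spike_time_ms {t[row]} outside [0, trial_end]"
            )

        n_loc = self.meta.get("n_locations")
        if n_loc is not None:
            loc = self.trials["stimulus_location"].to_numpy()
            bad = (loc < 1) | (loc > n_loc)
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise SpikeTableError(
                    f"trials row {row}: stimulus_location {loc[row]} outside 1..{n_loc}"
                )
        return self


def write_spike_table(table: SpikeTable, directory: str | Path) -> Path:
    """Write neurons.csv / trials.csv / spikes.csv (+ meta.json) to ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table.neurons.to_csv(directory / "neurons.csv", index=False)
    table.trials.to_csv(directory / "trials.csv", index=False)
    table.spikes.to_csv(directory / "spikes.csv", index=False)
    if table.meta:
        (directory / "meta.json").write_text(json.dumps(table.meta, indent=2, default=str))
    return directory


def read_spike_table(directory: str | Path, validate: bool = True) -> SpikeTable:
    """Read a spike table written by :func:`write_spike_table`.

    Unknown extra columns are preserved with a warning; missing files or
    referential-integrity violations raise :class:`SpikeTableError` naming the
    offending file or row.
    """
    import warnings

    directory = Path(directory)
    frames = {}
    for name, cols in (
        ("neurons", NEURON_COLUMNS),
        ("trials", TRIAL_COLUMNS),
        ("spikes", SPIKE_COLUMNS),
    ):
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SpikeTableError(f"missing required file {path}")
        df = pd.read_csv(path)
        extra = [c for c in df.columns if c not in cols]
        if extra:
            warnings.warn(f"{path.name}: preserving unrecognized columns {extra}")
        frames[name] = df
    meta_path = directory / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    table = SpikeTable(frames["neurons"], frames["trials"], frames["spikes"], meta)
    return table.validate() if validate else table
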