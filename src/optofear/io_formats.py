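"""Readers/writers for the file formats the pipeline touches.

NeuroSuite spike-time dialect: a ``.res`` file holds one integer sample
index per line; the paired ``.clu`` file holds the number of clusters on
its first line followed by one cluster id per spike. Clusters 0 and 1 are
the artifact/noise and multi-unit buckets by convention and are excluded
from analysis by default.

All CSVs are comma-separated UTF-8 with a mandatory header. The time base
is seconds with 0 = recording start, shared by all files of a recording.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import FormatError, InvalidParameterError, RecordingSet, SpikeTrain, StimProtocol

log = logging.getLogger("optofear")

#: "digitized at 32,556 kHz" is an evident unit typo for 32,556 samples/s.
DEFAULT_SAMPLING_RATE = 32556.0

FREEZING_COLUMNS = ("animal_id", "group", "stage", "percent_freezing")


def _read_int_lines(source, name: str) -> np.ndarray:
    path = Path(source)
    values = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                values.append(int(token))
            except ValueError:
                raise FormatError(f"{name}: non-integer token {token!r} on line {lineno}")
    return np.asarray(values, dtype=np.int64)


def read_res_clu(
    res_source,
    clu_source,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    exclude_clusters=(0, 1),
    site_id: str = "site0",
    group_label: str = "ChR2",
    duration: float | None = None,
) -> RecordingSet:
    """Read a NeuroSuite .res/.clu pair into a RecordingSet.

    Spike times are ``sample_index / sampling_rate`` seconds. One SpikeTrain
    is produced per retained cluster, ordered by cluster id.
    """
    if sampling_rate <= 0:
        raise InvalidParameterError("sampling_rate must be positive")
    samples = _read_int_lines(res_source, ".res")
    clu = _read_int_lines(clu_source, ".clu")
    if clu.size != samples.size + 1:
        raise FormatError(
            f".clu must have len(.res)+1 lines; got {clu.size} vs {samples.size} spikes"
        )
    n_clusters, labels = int(clu[0]), clu[1:]
    if np.unique(labels).size > n_clusters:
        raise FormatError(
            f".clu header announces {n_clusters} clusters but "
            f"{np.unique(labels).size} distinct labels appear"
        )
    order = np.argsort(samples, kind="stable")
    samples, labels = samples[order], labels[order]
    if duration is None:
        duration = (samples.max() + 1) / sampling_rate if samples.size else 1.0

    trains = []
    for cluster in np.unique(labels):
        if cluster in exclude_clusters:
            continue
        times = samples[labels == cluster] / sampling_rate
        trains.append(SpikeTrain(f"{site_id}_c{int(cluster)}", times, float(duration)))
    if not trains:
        log.warning("no clusters retained after excluding %s", tuple(exclude_clusters))
    return RecordingSet(
        trains=tuple(trains),
        sampling_rate=sampling_rate,
        site_id=site_id,
        group_label=group_label,
    )


def write_res_clu(
    recording: RecordingSet, res_path, clu_path, start_cluster: int = 2
) -> None:
    """Write a RecordingSet as a .res/.clu pair (clusters numbered from 2)."""
    samples, labels = [], []
    for k, train in enumerate(recording.trains):
        s = np.round(train.spike_times * recording.sampling_rate).astype(np.int64)
        samples.append(s)
        labels.append(np.full(s.size, start_cluster + k, dtype=np.int64))
    samples = np.concatenate(samples) if samples else np.empty(0, dtype=np.int64)
    labels = np.concatenate(labels) if labels else np.empty(0, dtype=np.int64)
    order = np.argsort(samples, kind="stable")
    samples, labels = samples[order], labels[order]
    n_clusters = start_cluster + len(recording.trains)
    Path(res_path).write_text("\n".join(map(str, samples)) + ("\n" if samples.size else ""))
    with Path(clu_path).open("w", encoding="utf-8") as fh:
        fh.write(f"{n_clusters}\n")
        for label in labels:
            fh.write(f"{label}\n")


def read_events_csv(
    source,
    pulse_rate: float = 20.0,
    pulse_width: float = 0.010,
    inter_train_gap: float = 30.0,
    baseline_s: float = 0.0,
) -> StimProtocol:
    """Read pulse onsets from a (onset_s, train_id) CSV.

    Geometry (rate, width) is not stored in the file and must be supplied
    (typically from the run config). Unsorted rows are sorted with a warning.
    """
    df = pd.read_csv(source)
    for col in ("onset_s", "train_id"):
        if col not in df.columns:
            raise FormatError(f"events CSV missing required column {col!r}")
    onsets = df["onset_s"].to_numpy(dtype=float)
    train_ids = df["train_id"].to_numpy()
    if onsets.size and onsets.min() < 0:
        raise FormatError("negative pulse onset in events CSV")
    if onsets.size and np.any(np.diff(onsets) < 0):
        log.warning("events CSV rows unsorted; sorting by onset")
        order = np.argsort(onsets, kind="stable")
        onsets, train_ids = onsets[order], train_ids[order]
    return StimProtocol(
        pulse_onsets=onsets,
        pulse_width=pulse_width,
        pulse_rate=pulse_rate,
        inter_train_gap=inter_train_gap,
        baseline_s=baseline_s,
        train_ids=np.asarray(train_ids, dtype=int) if onsets.size else None,
    )


def write_events_csv(protocol: StimProtocol, path) -> None:
    train_ids = (
        protocol.train_ids
        if protocol.train_ids is not None
        else np.zeros(protocol.n_pulses, dtype=int)
    )
    pd.DataFrame({"onset_s": protocol.pulse_onsets, "train_id": train_ids}).to_csv(
        path, index=False
    )


def validate_freezing_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a freezing table in place and return it.

    Requires the columns (animal_id, group, stage, percent_freezing); a
    'session' column is added (single session) when absent. Percentages must
    lie in [0, 100] and (animal, session, stage) must be unique.
    """
    missing = [c for c in FREEZING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"freezing table missing columns {missing}")
    if "session" not in df.columns:
        df = df.assign(session="session0")
    pct = pd.to_numeric(df["percent_freezing"], errors="coerce")
    bad = df.index[pct.isna() | (pct < 0) | (pct > 100)]
    if len(bad):
        row = df.loc[bad[0]]
        raise FormatError(
            f"percent_freezing out of [0, 100] for animal {row['animal_id']!r} "
            f"stage {row['stage']!r} (row {bad[0]})"
        )
    df = df.assign(percent_freezing=pct)
    dup = df.duplicated(subset=["animal_id", "session", "stage"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise FormatError(
            f"duplicated (animal, session, stage) = "
            f"({row['animal_id']!r}, {row['session']!r}, {row['stage']!r})"
        )
    return df


def read_freezing_csv(source, stage_vocabulary=None) -> pd.DataFrame:
    """Read and validate a per-animal, per-stage percent-freezing CSV."""
    df = validate_freezing_table(pd.read_csv(source))
    if stage_vocabulary is not None:
        unknown = set(df["stage"]) - set(stage_vocabulary)
        if unknown:
            raise FormatError(
                f"stages outside protocol vocabulary: {sorted(unknown)}; "
                f"valid: {sorted(stage_vocabulary)}"
            )
    return df


def write_freezing_csv(df: pd.DataFrame, path) -> None:
    validate_freezing_table(df).to_csv(path, index=False)


def read_config(source) -> dict:
    """Read a TOML key/value run configuration."""
    import tomllib

    with Path(source).open("rb") as fh:
        return tomllib.load(fh)


def write_config(config: dict, path) -> None:
    """Write a flat dict as a TOML key/value file (strings, numbers, bools)."""
    lines = []
    for key, value in config.items():
        if isinstance(value, bool):
            rendered = "true" if value else "false"
        elif isinstance(value, (int, float)):
            rendered = repr(value)
        elif isinstance(value, str):
            rendered = json.dumps(value)
        else:
            raise InvalidParameterError(f"unsupported config value for {key!r}")
        lines.append(f"{key} = {rendered}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
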