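"""Reading, writing and validating motor-unit discharge recordings.

The atomic datum is a :class:`DischargeTrain` — the discharge times of one
motor unit in one trial, stored as integer sample indices at the recording
sampling rate (2048 Hz by default, matching high-density surface EMG
acquisition systems).  Trials bundle trains with optionally co-recorded
force and target-trajectory signals; cohorts bundle trials and enforce the
matched-unit contract (a unit tracked in one trial of a participant/muscle
group must be present in every trial of that group).

Two on-disk representations are supported:

* a portable long-format CSV dialect with a JSON sidecar (``fs``,
  per-trial lengths) and one two-column CSV per trial for force/target;
* MATLAB ``.mat`` containers (v7 via :mod:`scipy.io`, v7.3/HDF5 via
  :mod:`h5py`) driven by an explicit layout mapping, for published data
  deposits whose internal variable naming varies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MUSCLES = ("TA", "FDI", "VM", "VL")
DEFAULT_FS = 2048.0

#: manual-editing QC band on inter-spike intervals, strict inequalities
ISI_SHORT_MS = 20.0
ISI_LONG_MS = 250.0


class FormatError(ValueError):
    """Raised when a file does not conform to the expected dialect."""


class RecordingValidationError(ValueError):
    """Raised when data violate a structural invariant (e.g. unmatched units)."""


class UnsupportedFormatError(FormatError):
    """Raised for container versions the deposit reader cannot handle."""


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


@dataclass
class DischargeTrain:
    """Discharge times of one motor unit, as sample indices at ``fs``."""

    unit_id: str
    discharge_samples: np.ndarray
    fs: float = DEFAULT_FS
    trial_length: int | None = None

    def __post_init__(self) -> None:
        self.discharge_samples = np.asarray(self.discharge_samples, dtype=np.int64)
        if self.fs <= 0:
            raise RecordingValidationError(f"unit {self.unit_id}: fs must be > 0")
        d = self.discharge_samples
        if d.size and d[0] < 0:
            raise RecordingValidationError(f"unit {self.unit_id}: negative sample index")
        if d.size > 1 and not np.all(np.diff(d) > 0):
            raise RecordingValidationError(
                f"unit {self.unit_id}: discharge samples not strictly increasing"
            )
        if self.trial_length is not None and d.size and d[-1] >= self.trial_length:
            raise RecordingValidationError(
                f"unit {self.unit_id}: discharge index beyond trial length"
            )

    @property
    def n_discharges(self) -> int:
        return int(self.discharge_samples.size)

    def discharge_times_s(self) -> np.ndarray:
        return self.discharge_samples / self.fs

    def isis_s(self) -> np.ndarray:
        """Inter-spike intervals in seconds (empty for 0 or 1 discharge)."""
        return np.diff(self.discharge_samples) / self.fs

    @classmethod
    def from_times_s(
        cls,
        unit_id: str,
        times_s: Sequence[float],
        fs: float = DEFAULT_FS,
        trial_length: int | None = None,
    ) -> "DischargeTrain":
        """Build a train from discharge times in seconds (round half up)."""
        return cls(unit_id, _round_half_up(np.asarray(times_s) * fs), fs, trial_length)


@dataclass
class TrialRecording:
    participant: str
    muscle: str
    trial_index: int
    trains: list[DischargeTrain]
    force: np.ndarray | None = None   # %MVC, sampled at fs
    target: np.ndarray | None = None  # %MVC, same length as force

    def __post_init__(self) -> None:
        if self.muscle not in MUSCLES:
            raise RecordingValidationError(
                f"unknown muscle {self.muscle!r}; expected one of {MUSCLES}"
            )
        if self.trial_index < 1:
            raise RecordingValidationError("trial_index must be >= 1")
        fss = {t.fs for t in self.trains}
        if len(fss) > 1:
            raise RecordingValidationError(
                f"{self.key()}: trains carry different sampling rates {sorted(fss)}"
            )
        if self.force is not None:
            self.force = np.asarray(self.force, dtype=float)
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)
        if (
            self.force is not None
            and self.target is not None
            and len(self.force) != len(self.target)
        ):
            raise RecordingValidationError(
                f"{self.key()}: force and target lengths differ"
            )

    @property
    def fs(self) -> float:
        return self.trains[0].fs if self.trains else DEFAULT_FS

    def key(self) -> tuple[str, str, int]:
        return (self.participant, self.muscle, self.trial_index)

    def unit_ids(self) -> list[str]:
        return [t.unit_id for t in self.trains]


@dataclass
class CohortDataset:
    trials: list[TrialRecording]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.trials:
            raise RecordingValidationError("cohort has no trials")
        seen: set[tuple[str, str, int]] = set()
        for tr in self.trials:
            if tr.key() in seen:
                raise RecordingValidationError(f"duplicate trial {tr.key()}")
            seen.add(tr.key())

    def groups(self) -> dict[tuple[str, str], list[TrialRecording]]:
        """Trials grouped by (participant, muscle), sorted by trial index."""
        out: dict[tuple[str, str], list[TrialRecording]] = {}
        for tr in self.trials:
            out.setdefault((tr.participant, tr.muscle), []).append(tr)
        for v in out.values():
            v.sort(key=lambda t: t.trial_index)
        return out

    def validate_matched_units(self, allow_unmatched: bool = False) -> None:
        """Enforce that unit_ids agree across all trials of each group."""
        for (participant, muscle), trials in self.groups().items():
            sets = [set(t.unit_ids()) for t in trials]
            union = set().union(*sets)
            for t, s in zip(trials, sets):
                missing = union - s
                if missing:
                    msg = (
                        f"{participant}/{muscle}: unit(s) {sorted(missing)} absent "
                        f"from trial {t.trial_index} (matched-unit contract)"
                    )
                    if allow_unmatched:
                        logger.warning(msg)
                    else:
                        raise RecordingValidationError(msg)


# ---------------------------------------------------------------------------
# ISI quality-control flagging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ISIFlag:
    """One suspicious inter-spike interval.

    ``position`` is the 1-based index of the ISI (between discharges
    ``position-1`` and ``position`` in 0-based discharge numbering).
    """

    position: int
    isi_ms: float
    kind: str  # "short" | "long"


def validate_isi(
    train: DischargeTrain,
    short_ms: float = ISI_SHORT_MS,
    long_ms: float = ISI_LONG_MS,
) -> list[ISIFlag]:
    """Flag ISIs strictly below ``short_ms`` or strictly above ``long_ms``.

    Flag-only QC, mirroring manual editing of decomposed spike trains;
    the train itself is never mutated.  Boundary values are not flagged.
    """
    isis_ms = train.isis_s() * 1000.0
    flags: list[ISIFlag] = []
    for i, isi in enumerate(isis_ms, start=1):
        if isi < short_ms:
            flags.append(ISIFlag(i, float(isi), "short"))
        elif isi > long_ms:
            flags.append(ISIFlag(i, float(isi), "long"))
    return flags


# ---------------------------------------------------------------------------
# Portable CSV dialect
# ---------------------------------------------------------------------------

_SPIKE_COLUMNS = ("participant", "muscle", "trial", "unit_id")


def _force_filename(participant: str, muscle: str, trial: int) -> str:
    return f"force_{participant}_{muscle}_{trial}.csv"


def write_cohort_csv(cohort: CohortDataset, directory: str | Path) -> Path:
    """Write a cohort in the portable dialect; returns the spikes CSV path.

    Layout: ``spikes.csv`` (long format, integer sample indices),
    ``spikes.json`` sidecar with ``fs`` and per-trial lengths, and one
    ``force_<participant>_<muscle>_<trial>.csv`` per trial with force data.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    lengths: dict[str, int | None] = {}
    fss = {tr.fs for tr in cohort.trials}
    if len(fss) > 1:
        raise RecordingValidationError("portable dialect requires a single fs per cohort")
    fs = fss.pop()
    for tr in cohort.trials:
        key = f"{tr.participant}|{tr.muscle}|{tr.trial_index}"
        length = None
        for train in tr.trains:
            if train.trial_length is not None:
                length = train.trial_length
            for s in train.discharge_samples:
                rows.append(
                    (tr.participant, tr.muscle, tr.trial_index, train.unit_id, int(s))
                )
        if length is None and tr.force is not None:
            length = len(tr.force)
        lengths[key] = length
        if tr.force is not None or tr.target is not None:
            n = len(tr.force) if tr.force is not None else len(tr.target)
            df = pd.DataFrame(
                {
                    "force": tr.force if tr.force is not None else np.full(n, np.nan),
                    "target": tr.target if tr.target is not None else np.full(n, np.nan),
                }
            )
            df.to_csv(directory / _force_filename(*tr.key()), index=False)
    spikes = pd.DataFrame(
        rows, columns=[*_SPIKE_COLUMNS[:3], "unit_id", "discharge_sample"]
    )
    # preserve unit ordering within each trial exactly as given
    path = directory / "spikes.csv"
    spikes.to_csv(path, index=False)
    sidecar = {
        "fs": fs,
        "trial_length_samples": lengths,
        "metadata": {k: v for k, v in cohort.metadata.items() if _jsonable(v)},
    }
    (directory / "spikes.json").write_text(json.dumps(sidecar, indent=1))
    return path


def _jsonable(v: Any) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_cohort_csv(path: str | Path, allow_unmatched: bool = False) -> CohortDataset:
    """Read a cohort from the portable CSV dialect.

    ``path`` is the spikes CSV; a sidecar ``<stem>.json`` next to it supplies
    ``fs`` (defaulting to 2048 Hz with a warning) and trial lengths.  Either
    a ``discharge_sample`` (integer) or a ``discharge_time_s`` column is
    accepted; times are converted by rounding half up to the nearest sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in _SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    has_sample = "discharge_sample" in df.columns
    has_time = "discharge_time_s" in df.columns
    if not (has_sample or has_time):
        raise FormatError(
            f"{path.name}: need a discharge_sample or discharge_time_s column"
        )

    sidecar_path = path.with_suffix(".json")
    sidecar: dict[str, Any] = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    fs = float(sidecar.get("fs", 0) or 0)
    if fs <= 0:
        logger.warning("no fs in sidecar; defaulting to %.0f Hz", DEFAULT_FS)
        fs = DEFAULT_FS
    lengths = sidecar.get("trial_length_samples", {}) or {}

    trials: list[TrialRecording] = []
    for (participant, muscle, trial), sub in df.groupby(
        ["participant", "muscle", "trial"], sort=False
    ):
        trial = int(trial)
        key = f"{participant}|{muscle}|{trial}"
        length = lengths.get(key)
        length = int(length) if length is not None else None
        trains = []
        for unit_id, usub in sub.groupby("unit_id", sort=False):
            if has_sample:
                samples = usub["discharge_sample"].to_numpy(dtype=np.int64)
            else:
                samples = _round_half_up(usub["discharge_time_s"].to_numpy() * fs)
            if samples.size > 1 and not np.all(np.diff(samples) > 0):
                raise RecordingValidationError(
                    f"unit {unit_id!r} in {key}: non-monotone discharge times"
                )
            trains.append(DischargeTrain(str(unit_id), samples, fs, length))
        force = target = None
        fpath = path.parent / _force_filename(str(participant), str(muscle), trial)
        if fpath.exists():
            fdf = pd.read_csv(fpath)
            if "force" in fdf and not fdf["force"].isna().all():
                force = fdf["force"].to_numpy(dtype=float)
            if "target" in fdf and not fdf["target"].isna().all():
                target = fdf["target"].to_numpy(dtype=float)
        trials.append(
            TrialRecording(str(participant), str(muscle), trial, trains, force, target)
        )
    cohort = CohortDataset(trials, metadata=dict(sidecar.get("metadata", {})))
    cohort.validate_matched_units(allow_unmatched=allow_unmatched)
    return cohort


# ---------------------------------------------------------------------------
# MAT-container deposit reader
# ---------------------------------------------------------------------------

def read_deposit(
    path: str | Path,
    layout: Mapping[str, Any],
    allow_unmatched: bool = False,
) -> CohortDataset:
    """Read discharge trains from a MATLAB container using a layout mapping.

    The internal variable naming of published deposits varies, so the caller
    supplies ``layout``::

        {
          "fs_key": "fsamp",            # optional; defaults to 2048 Hz
          "index_base": 1,               # 1 for MATLAB-style indices
          "entries": [
            {"participant": "P01", "muscle": "TA", "trial": 1,
             "key": "MUPulses_t1"},      # cell array of per-unit pulse indices
            ...
          ],
        }

    Both MAT v7 (read via scipy.io) and v7.3/HDF5 (read via h5py) are
    supported; for v7.3 the keyed variable may be a group of per-unit
    datasets, a 2-D dataset, or a cell array of object references.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries = layout.get("entries")
    if not entries:
        raise FormatError("layout must contain a non-empty 'entries' list")
    index_base = int(layout.get("index_base", 1))

    variables, fmt = _load_mat_variables(
        path, [e["key"] for e in entries], layout.get("fs_key")
    )

    fs_key = layout.get("fs_key")
    fs = None
    if fs_key is not None and fs_key in variables:
        fs = float(np.asarray(variables[fs_key]).ravel()[0])
    if fs is None or fs <= 0:
        logger.warning("container has no sampling rate; defaulting to %.0f Hz", DEFAULT_FS)
        fs = DEFAULT_FS

    trials: list[TrialRecording] = []
    for entry in entries:
        key = entry["key"]
        if key not in variables:
            raise FormatError(
                f"layout mismatch: variable {key!r} not found in {path.name}"
            )
        pulse_lists = variables[key]
        trains = []
        for j, pulses in enumerate(pulse_lists):
            samples = np.sort(np.asarray(pulses, dtype=np.int64).ravel()) - index_base
            unit_id = f"MU{j + 1:02d}"
            trains.append(DischargeTrain(unit_id, samples, fs))
        trials.append(
            TrialRecording(
                str(entry["participant"]), str(entry["muscle"]),
                int(entry["trial"]), trains,
            )
        )
    cohort = CohortDataset(
        trials,
        metadata={"source": str(path), "container_format": fmt, "layout": dict(layout)},
    )
    cohort.validate_matched_units(allow_unmatched=allow_unmatched)
    return cohort


def _load_mat_variables(
    path: Path, keys: Iterable[str], fs_key: str | None
) -> tuple[dict[str, Any], str]:
    wanted = set(keys) | ({fs_key} if fs_key else set())
    try:
        from scipy.io import loadmat
        from scipy.io.matlab import MatReadError

        raw = loadmat(path, simplify_cells=True)
        out: dict[str, Any] = {}
        for k in wanted:
            if k in raw:
                out[k] = _normalize_cell(raw[k])
        return out, "mat-v7"
    except (MatReadError, NotImplementedError, ValueError):
        pass  # likely v7.3 (HDF5) — fall through to h5py
    import h5py

    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise UnsupportedFormatError(
            f"{path.name}: not a readable MAT v7 or v7.3 container"
        ) from exc
    with f:
        out = {}
        for k in wanted:
            if k in f:
                out[k] = _read_h5_variable(f, f[k])
        return out, "mat-v7.3"


def _normalize_cell(value: Any) -> Any:
    """Coerce scipy cell-array results to a list of 1-D arrays (or a scalar)."""
    if isinstance(value, np.ndarray) and value.dtype == object:
        return [np.asarray(v).ravel() for v in value.ravel()]
    if isinstance(value, list):
        return [np.asarray(v).ravel() for v in value]
    arr = np.asarray(value)
    if arr.ndim <= 1 or min(arr.shape) == 1:
        return arr
    return [row for row in arr]


def _read_h5_variable(f: Any, node: Any) -> Any:
    import h5py

    if isinstance(node, h5py.Group):  # group of per-unit datasets
        return [np.asarray(node[name]).ravel() for name in sorted(node)]
    if h5py.check_dtype(ref=node.dtype) is not None:  # MATLAB cell array
        refs = np.asarray(node).ravel()
        return [np.asarray(f[r]).ravel() for r in refs]
    data = np.asarray(node)
    if data.ndim <= 1:
        return data.ravel()
    return [row.ravel() for row in data]
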