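"""Session data model, on-disk bundle format, configuration, and result output.

A *session* is the unit of analysis: a set of trials from a delayed
match-to-sample orientation discrimination experiment, with spike counts for
each simultaneously recorded neuron in four epochs per trial (pre-target,
pre-test, target-evoked, test-evoked) plus, optionally, a ladder of earlier
200-ms pre-test windows used for window sweeps.

On disk a session is a plain-text bundle: ``trials.csv`` with the trial
metadata, one ``counts_<epoch>.csv`` per epoch (header row = neuron ids), and
a ``session.json`` sidecar holding window lengths and provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("statepop")

#: Epochs every session must carry.
CORE_EPOCHS = ("pre_target", "pre_test", "target_evoked", "test_evoked")

#: Offsets (ms before stimulus onset) of the 200-ms pre-test window ladder.
LADDER_OFFSETS = (0, 200, 400, 600, 800)

TRIAL_COLUMNS = (
    "trial_index",
    "target_orientation",
    "delta_theta",
    "is_match",
    "delay_ms",
    "delay_mode",
    "outcome",
)


class SchemaError(ValueError):
    """Bundle components disagree in shape or columns."""


class SessionValidationError(ValueError):
    """A session violates a structural invariant (counts, metadata)."""


class InsufficientDataError(ValueError):
    """Too few trials (or neurons) survive for the requested analysis."""


class MissingEpochError(KeyError):
    """A requested epoch / window offset is not stored in the session."""


def ladder_epoch(alignment: str, window_offset_ms: int) -> str:
    """Epoch key for a 200-ms window ending ``window_offset_ms`` before onset."""
    if alignment not in ("pre_test", "pre_target"):
        raise ValueError(f"unknown alignment {alignment!r}")
    if window_offset_ms == 0:
        return alignment
    return f"{alignment}_off{window_offset_ms}"


@dataclass(frozen=True)
class TrialInfo:
    """Metadata of one trial.

    ``delta_theta`` is the signed orientation difference (degrees) between the
    test and target gratings; 0 on match trials.  ``outcome`` is the animal's
    behavioral result, ``correct`` or ``incorrect``.
    """

    trial_index: int
    target_orientation: float
    delta_theta: float
    is_match: bool
    delay_ms: float
    delay_mode: str  # {fixed, random}
    outcome: str  # {correct, incorrect}

    def __post_init__(self) -> None:
        if not 0 <= self.target_orientation < 180:
            raise SessionValidationError(
                f"target_orientation {self.target_orientation} outside [0, 180)"
            )
        if self.is_match != (self.delta_theta == 0):
            raise SessionValidationError(
                "is_match must hold exactly when delta_theta == 0"
            )
        if self.delay_mode not in ("fixed", "random"):
            raise SessionValidationError(f"unknown delay_mode {self.delay_mode!r}")
        if self.outcome not in ("correct", "incorrect"):
            raise SessionValidationError(f"unknown outcome {self.outcome!r}")


@dataclass
class AnalysisConfig:
    """Knobs shared by all analysis stages.

    Parameters
    ----------
    alignment
        Which stimulus the pre-stimulus window is aligned to.
    window_offset_ms
        Offset of the 200-ms window before onset (0 = immediately before).
    delta_theta_filter
        Maximum ``|delta_theta|`` (degrees) kept; harder-than-threshold trials
        only, matching the exclusion of easy discriminations.
    include_match
        Whether match (delta_theta == 0) trials enter the behavioral
        denominators alongside non-match trials.
    pool_cap
        Maximum number of neuron subsets enumerated per pool size.
    rng_seed
        Seed for every stochastic analysis step (pool subsampling, bootstrap).
    ridge
        Relative ridge coefficient for scatter/covariance inversion.
    subtract_baseline
        Subtract the same-trial pre-stimulus counts (window-scaled) from
        evoked counts before state comparisons / decoding.
    behavior_delta_denominator
        "session" (session-wide fraction correct) or "high".
    """

    alignment: str = "pre_test"
    window_offset_ms: int = 0
    delta_theta_filter: float = 10.0
    include_match: bool = True
    pool_cap: int = 2000
    rng_seed: int = 0
    ridge: float = 1e-6
    subtract_baseline: bool = False
    behavior_delta_denominator: str = "session"

    def __post_init__(self) -> None:
        if self.alignment not in ("pre_test", "pre_target"):
            raise ValueError(f"unknown alignment {self.alignment!r}")
        if self.window_offset_ms not in LADDER_OFFSETS:
            raise ValueError(
                f"window_offset_ms must be one of {LADDER_OFFSETS}, "
                f"got {self.window_offset_ms}"
            )
        if self.pool_cap < 1:
            raise ValueError("pool_cap must be >= 1")
        if self.behavior_delta_denominator not in ("session", "high"):
            raise ValueError(
                f"unknown behavior_delta_denominator "
                f"{self.behavior_delta_denominator!r}"
            )


@dataclass
class SessionData:
    """Trial-structured spike counts for one recording (or synthetic) session.

    ``counts`` maps epoch name to a (n_trials, n_neurons) integer matrix;
    ``window_ms`` maps epoch name to the window length used to count spikes.
    ``provenance`` records where the data came from; synthetic sessions store
    the per-trial latent state and planted parameters there for recovery tests.
    """

    session_id: str
    counts: dict[str, np.ndarray]
    window_ms: dict[str, float]
    trials: list[TrialInfo]
    neuron_ids: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.neuron_ids:
            n = next(iter(self.counts.values())).shape[1]
            self.neuron_ids = [f"n{i}" for i in range(n)]
        self.validate()

    # -- structural invariants -------------------------------------------------
    def validate(self) -> None:
        for epoch in CORE_EPOCHS:
            if epoch not in self.counts:
                raise SessionValidationError(f"missing core epoch {epoch!r}")
        shape = (self.n_trials, self.n_neurons)
        for epoch, mat in self.counts.items():
            mat = np.asarray(mat)
            if mat.shape != shape:
                raise SchemaError(
                    f"epoch {epoch!r} has shape {mat.shape}, expected {shape}"
                )
            if not np.issubdtype(mat.dtype, np.integer):
                if not np.all(np.equal(np.mod(mat, 1), 0)):
                    raise SessionValidationError(
                        f"epoch {epoch!r} has non-integer counts"
                    )
                self.counts[epoch] = mat.astype(np.int64)
            if np.any(mat < 0):
                raise SessionValidationError(f"epoch {epoch!r} has negative counts")
            if epoch not in self.window_ms or self.window_ms[epoch] <= 0:
                raise SessionValidationError(f"epoch {epoch!r} needs window_ms > 0")
        if len(self.neuron_ids) != self.n_neurons:
            raise SchemaError("neuron_ids length does not match count matrices")
        for t, info in enumerate(self.trials):
            if info.trial_index != t:
                raise SchemaError("trials must be listed in trial_index order")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_neurons(self) -> int:
        return next(iter(self.counts.values())).shape[1]

    def trial_table(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.trials])[
            list(TRIAL_COLUMNS)
        ]

    def correct_mask(self) -> np.ndarray:
        return np.array([t.outcome == "correct" for t in self.trials])

    def rates(self, epoch: str) -> np.ndarray:
        """Counts converted to spks/s using the epoch window length."""
        if epoch not in self.counts:
            raise MissingEpochError(epoch)
        return self.counts[epoch] / (self.window_ms[epoch] / 1000.0)

    def subset(self, idx: Sequence[int]) -> "SessionData":
        """Return the session restricted to ``idx`` (trial order preserved,
        trial indices renumbered).  Per-trial provenance arrays are subset too.
        """
        idx = np.asarray(idx, dtype=int)
        trials = [
            dataclasses.replace(self.trials[i], trial_index=j)
            for j, i in enumerate(idx)
        ]
        prov = dict(self.provenance)
        for key, val in list(prov.items()):
            if isinstance(val, (list, np.ndarray)) and len(val) == self.n_trials:
                prov[key] = list(np.asarray(val)[idx])
        return SessionData(
            session_id=self.session_id,
            counts={e: m[idx] for e, m in self.counts.items()},
            window_ms=dict(self.window_ms),
            trials=trials,
            neuron_ids=list(self.neuron_ids),
            provenance=prov,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionData):
            return NotImplemented
        return (
            self.session_id == other.session_id
            and self.neuron_ids == other.neuron_ids
            and self.trials == other.trials
            and set(self.counts) == set(other.counts)
            and all(np.array_equal(self.counts[e], other.counts[e]) for e in self.counts)
            and self.window_ms == other.window_ms
        )


# -- bundle I/O ----------------------------------------------------------------

def save_session(session: SessionData, path: str | Path) -> Path:
    """Write a session bundle (trials.csv + counts_*.csv + session.json)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    session.trial_table().to_csv(path / "trials.csv", index=False)
    for epoch, mat in session.counts.items():
        pd.DataFrame(mat, columns=session.neuron_ids).to_csv(
            path / f"counts_{epoch}.csv", index=False
        )
    sidecar = {
        "session_id": session.session_id,
        "window_ms": session.window_ms,
        "neuron_ids": session.neuron_ids,
        "epochs": sorted(session.counts),
        "provenance": _jsonable(session.provenance),
    }
    (path / "session.json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def load_session(path: str | Path) -> SessionData:
    """Read a session bundle written by :func:`save_session`.

    Raises ``FileNotFoundError`` for missing components, :class:`SchemaError`
    for shape mismatches, and :class:`SessionValidationError` for invalid
    counts.  Row order is preserved as trial order.
    """
    path = Path(path)
    sidecar = json.loads((path / "session.json").read_text())
    trials_df = pd.read_csv(path / "trials.csv")
    missing = set(TRIAL_COLUMNS) - set(trials_df.columns)
    if missing:
        raise SchemaError(f"trials.csv missing columns {sorted(missing)}")
    trials = [
        TrialInfo(
            trial_index=int(row.trial_index),
            target_orientation=float(row.target_orientation),
            delta_theta=float(row.delta_theta),
            is_match=bool(row.is_match),
            delay_ms=float(row.delay_ms),
            delay_mode=str(row.delay_mode),
            outcome=str(row.outcome),
        )
        for row in trials_df.itertuples(index=False)
    ]
    counts = {}
    for epoch in sidecar["epochs"]:
        df = pd.read_csv(path / f"counts_{epoch}.csv")
        if len(df) != len(trials):
            raise SchemaError(
                f"counts_{epoch}.csv has {len(df)} rows but metadata has "
                f"{len(trials)} trials"
            )
        counts[epoch] = df.to_numpy()
    return SessionData(
        session_id=sidecar["session_id"],
        counts=counts,
        window_ms={k: float(v) for k, v in sidecar["window_ms"].items()},
        trials=trials,
        neuron_ids=list(sidecar["neuron_ids"]),
        provenance=sidecar.get("provenance", {}),
    )


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


# -- result output -------------------------------------------------------------

def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    extra_manifest: Mapping | None = None,
) -> dict:
    """Write one CSV per result table plus a JSON run manifest.

    Column order is taken from each table as given, so identical runs produce
    byte-identical CSVs; the manifest records content hashes for each file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, table in tables.items():
        fp = out_dir / f"{name}.csv"
        table.to_csv(fp, index=False)
        files[fp.name] = {
            "rows": int(len(table)),
            "sha256": hashlib.sha256(fp.read_bytes()).hexdigest(),
        }
    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config": _jsonable(dataclasses.asdict(config)) if config else None,
        "files": files,
    }
    if extra_manifest:
        manifest.update(_jsonable(dict(extra_manifest)))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# -- trial filtering -----------------------------------------------------------

def filter_trials(session: SessionData, config: AnalysisConfig) -> SessionData:
    """Restrict to discrimination trials with ``|delta_theta| <= filter``.

    Positive and negative orientation differences are pooled.  Match trials
    are kept unless ``config.include_match`` is false.  If the surviving trial
    count is odd the last trial in temporal order is dropped so that median
    splits divide trials into exactly equal halves.
    """
    keep = []
    for t in session.trials:
        if abs(t.delta_theta) > config.delta_theta_filter:
            continue
        if not config.include_match and t.is_match:
            continue
        keep.append(t.trial_index)
    if len(keep) % 2 == 1:
        keep = keep[:-1]
    if len(keep) < 4:
        raise InsufficientDataError(
            f"only {len(keep)} trials survive filtering; need >= 4"
        )
    return session.subset(keep)
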