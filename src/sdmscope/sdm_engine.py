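"""Event-triggered acquisition loop on a virtual clock.

An initial low-dose scan visits every field of view once; a classifier
scores each acquisition, and positive predictions trigger an optimized
multimodal scan.  Two trigger modes exist: BATCH collects and scores all
initial acquisitions first, then iterates the positive list in scan order;
IMMEDIATE runs the optimized scan at a positive FOV before the initial
scan resumes.  The virtual clock advances by the declared duration of
every action, and the sample evolves with the clock, so late triggers can
miss events.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .classifiers import TrainedModel, normalize_tensor
from .synthetic_scope import (
    Fate,
    ImageStack,
    Modality,
    SimConfig,
    VirtualSample,
    map_grid_points,
    render_brightfield,
    render_brillouin_map,
    render_fluorescence,
)


class TriggerMode(str, Enum):
    BATCH = "BATCH"
    IMMEDIATE = "IMMEDIATE"


class Action(str, Enum):
    ACQUIRE_INITIAL = "ACQUIRE_INITIAL"
    PREDICT = "PREDICT"
    TRIGGER = "TRIGGER"
    ACQUIRE_OPTIMIZED = "ACQUIRE_OPTIMIZED"
    RESUME = "RESUME"


class Pattern(str, Enum):
    RASTER = "RASTER"
    SERPENTINE = "SERPENTINE"


@dataclass(frozen=True)
class ScanSettings:
    modalities: tuple[Modality, ...] = (Modality.FLUOR,)
    exposure_s: dict = dataclasses.field(default_factory=lambda: {"FLUOR": 0.1})
    power_level: dict = dataclasses.field(default_factory=dict)
    frame_interval_s: float = 10.0
    n_frames: int = 1
    brillouin_fov_um: float = 10.0
    brillouin_step_um: float = 1.0
    brillouin_dwell_s: float = 0.1

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for m in self.modalities:
            if Modality(m) is Modality.BRILLOUIN:
                continue
            if self.exposure_for(Modality(m)) <= 0:
                raise ValueError(f"exposure for {m} must be > 0")

    def exposure_for(self, modality: Modality) -> float:
        return float(self.exposure_s.get(modality.value, 0.1))

    def brillouin_n_points(self) -> int:
        n = len(map_grid_points(self.brillouin_fov_um, self.brillouin_step_um))
        return n * n

    def frame_duration_s(self) -> float:
        """Acquisition time of one optimized frame across its modalities."""
        total = 0.0
        for m in self.modalities:
            m = Modality(m)
            if m is Modality.BRILLOUIN:
                total += self.brillouin_dwell_s * self.brillouin_n_points()
            else:
                total += self.exposure_for(m)
        return total


@dataclass(frozen=True)
class GridPosition:
    row: int
    col: int
    fov_index: int


@dataclass
class LogEntry:
    clock_s: float
    fov_index: int
    action: Action
    duration_s: float = 0.0
    modality: Optional[str] = None
    score: Optional[float] = None
    label: Optional[int] = None

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["action"] = self.action.value
        return d


@dataclass
class SessionLog:
    entries: list[LogEntry] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: int = 0
    sample_hash: str = ""

    def append(self, entry: LogEntry) -> None:
        if self.entries and entry.clock_s < self.entries[-1].clock_s:
            raise ValueError("clock must be nondecreasing")
        self.entries.append(entry)

    def by_action(self, action: Action) -> list[LogEntry]:
        return [e for e in self.entries if e.action is action]

    def write_jsonl(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(json.dumps({"_meta": {"seed": self.seed,
                                           "sample_hash": self.sample_hash,
                                           "config": self.config}}) + "\n")
            for e in self.entries:
                fh.write(json.dumps(e.to_json()) + "\n")

    @classmethod
    def read_jsonl(cls, path) -> "SessionLog":
        path = Path(path)
        log = cls()
        with path.open() as fh:
            for line in fh:
                rec = json.loads(line)
                if "_meta" in rec:
                    log.seed = rec["_meta"]["seed"]
                    log.sample_hash = rec["_meta"]["sample_hash"]
                    log.config = rec["_meta"]["config"]
                    continue
                rec["action"] = Action(rec["action"])
                log.entries.append(LogEntry(**rec))
        return log


@dataclass
class CaptureReport:
    n_true_events: int
    n_triggered: int
    n_true_captures: int
    n_false_triggers: int
    capture_rate: float
    mean_detection_lead_s: float


# ---------------------------------------------------------------------------
# grid planning


def plan_grid(
    n_rows: int,
    n_cols: int,
    fov_um: float = 39.0,
    overlap_um: float = 0.0,
    pattern: Pattern = Pattern.RASTER,
) -> list[GridPosition]:
    """Ordered FOV visit plan; row-major, serpentine reverses odd rows."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if overlap_um >= fov_um:
        raise ValueError("overlap must be smaller than the FOV")
    positions = []
    for r in range(n_rows):
        cols = range(n_cols)
        if Pattern(pattern) is Pattern.SERPENTINE and r % 2 == 1:
            cols = reversed(range(n_cols))
        for c in cols:
            positions.append(GridPosition(row=r, col=c, fov_index=r * n_cols + c))
    return positions


# ---------------------------------------------------------------------------
# classifier adapters


class ModelAdapter:
    """Scores an initial-scan ImageStack; subclass or duck-type."""

    def score_stack(self, stack: ImageStack) -> float:  # pragma: no cover
        raise NotImplementedError


class TrainedModelAdapter(ModelAdapter):
    def __init__(self, model: TrainedModel):
        self.model = model

    def score_stack(self, stack: ImageStack) -> float:
        x = normalize_tensor(stack.data)
        t, z, h, w = self.model.arch.input_shape
        if x.shape != (t, z, h, w):
            raise ValueError(f"stack shape {x.shape} does not match model "
                             f"input {self.model.arch.input_shape}")
        return float(self.model.predict_scores(x[None])[0])

    @property
    def threshold(self) -> float:
        return self.model.decision_threshold


class OracleModel(ModelAdapter):
    """Reads the ground truth: positive while an EVENT cell is inside its
    cue window (or transitioning) at acquisition time."""

    def __init__(self, sample: VirtualSample):
        self.sample = sample
        self.threshold = 0.5

    def score_stack(self, stack: ImageStack) -> float:
        t = float(stack.timestamps_s[-1])
        cfg = self.sample.config
        for cell in self.sample.cells_at(stack.position):
            if cell.fate is not Fate.EVENT:
                continue
            t0 = cell.onset_time_s
            if t0 - cfg.cue_lead_time_s <= t < t0 + cfg.onset_duration_s:
                return 1.0
        return 0.0


class ConstantModel(ModelAdapter):
    def __init__(self, score: float):
        self._score = score
        self.threshold = 0.5

    def score_stack(self, stack: ImageStack) -> float:
        return self._score


class RandomModel(ModelAdapter):
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.threshold = 0.5

    def score_stack(self, stack: ImageStack) -> float:
        return float(self.rng.uniform())


# ---------------------------------------------------------------------------
# the session loop


class VirtualScope:
    """Thin simulator handle used by the engine to acquire images."""

    def __init__(self, sample: VirtualSample, render: bool = True):
        self.sample = sample
        self.render = render

    def acquire_initial(self, fov_index: int, time_s: float,
                        settings: ScanSettings) -> ImageStack:
        cfg = self.sample.config
        if not self.render:
            return ImageStack(
                data=np.zeros((1, cfg.n_zplanes, 1, 1)),
                timestamps_s=np.array([time_s]),
                modality=Modality.FLUOR, position=fov_index)
        mod = Modality(settings.modalities[0])
        if mod is Modality.BRIGHTFIELD:
            return render_brightfield(self.sample, fov_index, time_s)
        return render_fluorescence(self.sample, fov_index, time_s)


def run_session(
    scope: VirtualScope,
    model: ModelAdapter,
    grid: Sequence[GridPosition],
    initial: ScanSettings,
    optimized: ScanSettings,
    mode: TriggerMode = TriggerMode.IMMEDIATE,
    clock_start_s: float = 0.0,
    move_overhead_s: float = 0.5,
    seed: int = 0,
) -> SessionLog:
    """Run one single-pass self-driving session against the simulator.

    Every FOV gets exactly one ACQUIRE_INITIAL; a FOV that triggers is
    excluded from re-triggering within the session.
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    for m in initial.modalities:
        if Modality(m) is Modality.BRILLOUIN:
            raise ValueError("BRILLOUIN is not allowed in the initial scan")
    mode = TriggerMode(mode)

    log = SessionLog(seed=seed, sample_hash=scope.sample.hash,
                     config={"mode": mode.value,
                             "initial": _settings_dict(initial),
                             "optimized": _settings_dict(optimized),
                             "move_overhead_s": move_overhead_s})
    clock = clock_start_s
    triggered: set[int] = set()
    init_mod = Modality(initial.modalities[0]).value
    init_exp = initial.exposure_for(Modality(initial.modalities[0]))

    def do_optimized(fov: int) -> None:
        nonlocal clock
        for k in range(optimized.n_frames):
            for m in optimized.modalities:
                m = Modality(m)
                if m is Modality.BRILLOUIN:
                    dur = optimized.brillouin_dwell_s * optimized.brillouin_n_points()
                else:
                    dur = optimized.exposure_for(m)
                log.append(LogEntry(clock_s=clock, fov_index=fov,
                                    action=Action.ACQUIRE_OPTIMIZED,
                                    duration_s=dur, modality=m.value))
                clock += dur
            if k < optimized.n_frames - 1:
                gap = max(0.0, optimized.frame_interval_s
                          - optimized.frame_duration_s())
                clock += gap

    pending_scores: list[tuple[int, float]] = []
    for pos in grid:
        fov = pos.fov_index
        dur = move_overhead_s + init_exp
        log.append(LogEntry(clock_s=clock, fov_index=fov,
                            action=Action.ACQUIRE_INITIAL, duration_s=dur,
                            modality=init_mod))
        acq_time = clock + move_overhead_s
        clock += dur
        stack = scope.acquire_initial(fov, acq_time, initial)
        if mode is TriggerMode.IMMEDIATE:
            score = model.score_stack(stack)
            label = int(score >= model.threshold)
            log.append(LogEntry(clock_s=clock, fov_index=fov,
                                action=Action.PREDICT, score=score, label=label))
            if label and fov not in triggered:
                triggered.add(fov)
                log.append(LogEntry(clock_s=clock, fov_index=fov,
                                    action=Action.TRIGGER, score=score, label=1))
                do_optimized(fov)
                log.append(LogEntry(clock_s=clock, fov_index=fov,
                                    action=Action.RESUME))
        else:
            pending_scores.append((fov, model.score_stack(stack)))

    if mode is TriggerMode.BATCH:
        positives = []
        for fov, score in pending_scores:
            label = int(score >= model.threshold)
            log.append(LogEntry(clock_s=clock, fov_index=fov,
                                action=Action.PREDICT, score=score, label=label))
            if label and fov not in triggered:
                triggered.add(fov)
                positives.append((fov, score))
        for fov, score in positives:  # iterated in initial-scan order
            log.append(LogEntry(clock_s=clock, fov_index=fov,
                                action=Action.TRIGGER, score=score, label=1))
            clock += move_overhead_s
            do_optimized(fov)
    return log


def _settings_dict(s: ScanSettings) -> dict:
    d = dataclasses.asdict(s)
    d["modalities"] = [Modality(m).value for m in s.modalities]
    return d


# ---------------------------------------------------------------------------
# scoring


def score_session(log: SessionLog, sample: VirtualSample) -> CaptureReport:
    """Score a session against ground truth.

    A trigger is a true capture iff its FOV hosts an EVENT cell and the
    first optimized frame starts before t0 + onset_duration; detection
    lead is t0 minus the trigger time.
    """
    if log.sample_hash and log.sample_hash != sample.hash:
        raise ValueError("session log and sample hashes do not match")
    cfg = sample.config
    visited = {e.fov_index for e in log.by_action(Action.ACQUIRE_INITIAL)}
    event_cells = {c.fov_index: c for c in sample.cells
                   if c.fate is Fate.EVENT and c.fov_index in visited}

    first_opt: dict[int, float] = {}
    for e in log.by_action(Action.ACQUIRE_OPTIMIZED):
        first_opt.setdefault(e.fov_index, e.clock_s)

    triggers = log.by_action(Action.TRIGGER)
    n_captures = 0
    n_false = 0
    leads = []
    for trig in triggers:
        cell = event_cells.get(trig.fov_index)
        start = first_opt.get(trig.fov_index, trig.clock_s)
        if cell is not None and start < cell.onset_time_s + cfg.onset_duration_s:
            n_captures += 1
            leads.append(cell.onset_time_s - trig.clock_s)
        elif cell is None:
            n_false += 1
    n_events = len(event_cells)
    rate = n_captures / n_events if n_events else 0.0
    lead = float(np.mean(leads)) if leads else float("nan")
    return CaptureReport(n_true_events=n_events, n_triggered=len(triggers),
                         n_true_captures=n_captures, n_false_triggers=n_false,
                         capture_rate=rate, mean_detection_lead_s=lead)
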