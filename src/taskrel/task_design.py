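"""Trial schedules and stimulus metadata for the two control-task variants.

Each task variant presents 100 back-to-back 3 s trials (20 each of auditory,
visual, motor, cognitive and null) in a fixed pseudo-random order, followed by
a 10 s buffer, for a total run of 310 s.  The "cognitive" condition is an
eye-movement trial in one variant and a brief working-memory trial in the
other; the sensory/motor conditions are identical across variants.

The original stimulus-delivery order is not published, so this module ships a
single canonical permutation generated from a fixed, documented seed under the
constraint that no condition occurs more than three times in a row.  The
"reversed" order is the exact reversal of that sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

CONDITIONS: tuple[str, ...] = ("auditory", "visual", "motor", "cognitive", "null")
ACTIVE_CONDITIONS: tuple[str, ...] = ("auditory", "visual", "motor", "cognitive")
VARIANTS: tuple[str, ...] = ("eye-movement", "working-memory")
ORDERS: tuple[str, ...] = ("forward", "reversed")

TRIAL_DURATION_S = 3.0
TRIALS_PER_CONDITION = 20
N_TRIALS = TRIALS_PER_CONDITION * len(CONDITIONS)
BUFFER_S = 10.0
RUN_DURATION_S = N_TRIALS * TRIAL_DURATION_S + BUFFER_S  # 310 s

# Seed fixing the shipped "standardized" pseudo-random order; the published
# sequence is not recoverable, so this canonical stand-in is part of the
# package contract and must never change.
_CANONICAL_ORDER_SEED = 1861
_MAX_CONSECUTIVE = 3


class ScheduleConfigError(ValueError):
    """Unknown task variant or trial order."""


class Trial(NamedTuple):
    onset: float
    duration: float
    condition: str


@dataclass(frozen=True)
class EventSchedule:
    """Ordered trial list for one run of one task variant.

    Attributes
    ----------
    variant : str
        ``"eye-movement"`` or ``"working-memory"``; decides the semantics of
        the ``cognitive`` condition only — the trial sequence is shared.
    order : str
        ``"forward"`` or ``"reversed"``.
    trials : tuple of Trial
        100 trials with onsets 0, 3, ..., 297 s and 3 s durations.
    buffer : float
        Silent tail after the last trial, seconds.
    """

    variant: str
    order: str
    trials: tuple[Trial, ...]
    buffer: float = BUFFER_S

    @property
    def duration(self) -> float:
        """Total run duration in seconds (trials plus buffer)."""
        last = self.trials[-1]
        return last.onset + last.duration + self.buffer

    def condition_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CONDITIONS}
        for t in self.trials:
            counts[t.condition] += 1
        return counts

    def onsets_for(self, condition: str) -> np.ndarray:
        return np.array([t.onset for t in self.trials if t.condition == condition])


@dataclass(frozen=True)
class StimulusParams:
    """Immutable stimulus metadata for the audiovisual trial types.

    Pure tones C4 D4 E4 F4 A4 B4 for the auditory trials, a drifting sine
    grating for the visual trials, three 1 s button cues per motor trial,
    six eye-movement targets on an 8.75 deg circle, and 4-letter strings
    with 50% match probability for the working-memory trials.
    """

    tone_frequencies_hz: tuple[float, ...] = (261.63, 293.66, 329.63, 349.23, 440.0, 493.88)
    tone_duration_s: float = 0.5
    grating_spatial_freq_cpd: float = 1.2
    grating_drift_cps: float = 6.0
    grating_reversal_s: float = 0.5
    motor_cue_count: int = 3
    motor_cue_duration_s: float = 1.0
    eye_target_radius_deg: float = 8.75
    eye_targets_per_trial: int = 6
    wm_string_length: int = 4
    wm_match_proportion: float = 0.5

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


def _canonical_condition_sequence() -> list[str]:
    """The fixed pseudo-random forward sequence of 100 condition labels.

    Rejection-samples seeded permutations until no condition runs longer
    than three consecutive trials.
    """
    rng = np.random.default_rng(_CANONICAL_ORDER_SEED)
    labels = np.repeat(CONDITIONS, TRIALS_PER_CONDITION)
    while True:
        seq = rng.permutation(labels)
        run, longest = 1, 1
        for prev, cur in zip(seq[:-1], seq[1:]):
            run = run + 1 if cur == prev else 1
            longest = max(longest, run)
        if longest <= _MAX_CONSECUTIVE:
            return list(seq)


_FORWARD_SEQUENCE = _canonical_condition_sequence()


def generate_schedule(variant: str, order: str = "forward") -> EventSchedule:
    """Build the trial schedule for one task variant and presentation order.

    Deterministic: repeated calls with the same arguments return identical
    schedules, and ``reversed`` is the exact reversal of ``forward``.
    """
    if variant not in VARIANTS:
        raise ScheduleConfigError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if order not in ORDERS:
        raise ScheduleConfigError(f"unknown order {order!r}; expected one of {ORDERS}")
    seq = _FORWARD_SEQUENCE if order == "forward" else list(reversed(_FORWARD_SEQUENCE))
    trials = tuple(
        Trial(onset=i * TRIAL_DURATION_S, duration=TRIAL_DURATION_S, condition=c)
        for i, c in enumerate(seq)
    )
    return EventSchedule(variant=variant, order=order, trials=trials)


# ---------------------------------------------------------------------------
# Serialization: BIDS events.tsv and FSL 3-column EV files
# ---------------------------------------------------------------------------

DIALECTS = ("bids_events_tsv", "fsl_ev3col")


def write_events(schedule: EventSchedule, dialect: str, out: str | Path) -> list[Path]:
    """Serialize a schedule's events.

    ``bids_events_tsv`` writes a single tab-separated file (columns onset,
    duration, trial_type) plus a JSON sidecar recording variant/order/buffer;
    ``fsl_ev3col`` writes one 3-column text file per *active* condition
    (onset, duration, weight 1.0) into the directory ``out`` — null trials
    are the implicit baseline and never get a regressor file.

    Returns the list of files written.
    """
    out = Path(out)
    if dialect == "bids_events_tsv":
        out.parent.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            {
                "onset": [t.onset for t in schedule.trials],
                "duration": [t.duration for t in schedule.trials],
                "trial_type": [t.condition for t in schedule.trials],
            }
        )
        df.to_csv(out, sep="\t", index=False, float_format="%.1f")
        sidecar = out.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"variant": schedule.variant, "order": schedule.order, "buffer": schedule.buffer},
                indent=2,
            )
            + "\n"
        )
        return [out, sidecar]
    if dialect == "fsl_ev3col":
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for cond in ACTIVE_CONDITIONS:
            p = out / f"{cond}.txt"
            rows = [f"{t.onset:.1f}\t{t.duration:.1f}\t1.0" for t in schedule.trials if t.condition == cond]
            p.write_text("\n".join(rows) + "\n")
            paths.append(p)
        return paths
    raise ScheduleConfigError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def read_events(path: str | Path) -> EventSchedule:
    """Read a BIDS events.tsv (with its JSON sidecar) back into a schedule."""
    path = Path(path)
    # keep_default_na: the "null" trial type is a label, not a missing value
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    meta = json.loads(path.with_suffix(".json").read_text())
    trials = tuple(
        Trial(onset=float(r.onset), duration=float(r.duration), condition=str(r.trial_type))
        for r in df.itertuples()
    )
    return EventSchedule(
        variant=meta["variant"], order=meta["order"], trials=trials, buffer=float(meta["buffer"])
    )
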