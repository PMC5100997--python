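"""Offline segmentation of grip-force traces into effort and rest epochs.

The detector works on the force signal normalized by the calibration maximal
force and on its temporal derivative (first difference times the sampling
rate, standard deviation taken over the whole trial).  Samples with
derivative above +1 sd and force above half-maximum are tentative effort
onsets; samples with derivative below -1 sd and force below half-maximum
are tentative offsets.  Two cleanup rules resolve multiplicity: among
several onsets before an offset, the one with minimum force is kept; among
several offsets between two onsets, only the last is kept.  An effort still
sustained at trial end receives an offset at the trial end and is flagged
truncated.  The first rest duration is the elapsed time from trial onset to
the first effort onset.

The module also implements the payoff rule (pence proportional to incentive
times seconds above the force target) and the compliance filter that
excludes a visit when any condition totals fewer than three effort or three
rest epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ConditionSummary
from .model import Condition
from .simulate import ForceTrace

__all__ = [
    "EpochSegmentation",
    "QCResult",
    "detect_epochs",
    "compute_payoff",
    "qc_visit",
    "condition_summaries",
]


@dataclass
class EpochSegmentation:
    """Detected effort/rest epochs of one trial."""

    onsets: np.ndarray            # effort onset times, s
    offsets: np.ndarray           # effort offset times, s
    first_rest: float             # trial start -> first onset, s
    trial_length: float
    truncated_final: bool = False

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.onsets.size != self.offsets.size:
            raise ValueError("onsets and offsets must pair up")
        if self.onsets.size and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_efforts(self) -> int:
        return int(self.onsets.size)

    @property
    def effort_durations(self) -> np.ndarray:
        return self.offsets - self.onsets

    @property
    def rest_durations(self) -> np.ndarray:
        """First rest, then the gaps between successive efforts.

        A zero-length first rest (effort from the very first sample) is not
        a rest and is dropped.
        """
        if self.onsets.size == 0:
            return np.array([self.first_rest])
        gaps = self.onsets[1:] - self.offsets[:-1]
        rests = np.concatenate([[self.first_rest], gaps])
        return rests[rests > 0]

    @property
    def n_rests(self) -> int:
        return int(self.rest_durations.size)


def detect_epochs(trace: ForceTrace) -> EpochSegmentation:
    """Segment one force trace into effort epochs by the threshold rules.

    A trace with no detected onset yields an empty segmentation whose first
    rest spans the whole trial (a compliant algorithm output, not an error).
    NaNs in the force signal are an error.
    """
    f = np.asarray(trace.f, dtype=float)
    t = np.asarray(trace.t, dtype=float)
    if f.size < 2:
        raise ValueError("trace must have at least 2 samples")
    if np.any(np.isnan(f)):
        raise ValueError("force signal contains NaNs")
    fs = trace.fs
    trial_length = trace.trial_length
    d = np.zeros_like(f)
    d[1:] = np.diff(f) * fs
    sd = d.std()
    onset_idx = np.flatnonzero((d > sd) & (f > 0.5))
    offset_idx = np.flatnonzero((d < -sd) & (f < 0.5))

    # merge candidates into a time-ordered event list and pair them up
    events = sorted(
        [(i, 0) for i in onset_idx] + [(i, 1) for i in offset_idx]
    )
    # discard offsets before any onset
    k = 0
    while k < len(events) and events[k][1] == 1:
        k += 1
    events = events[k:]

    onsets, offsets = [], []
    truncated = False
    pos = 0
    while pos < len(events):
        # consecutive onset candidates before the next offset: keep min force
        group = []
        while pos < len(events) and events[pos][1] == 0:
            group.append(events[pos][0])
            pos += 1
        onset = min(group, key=lambda i: f[i])
        # consecutive offset candidates before the next onset: keep the last
        group2 = []
        while pos < len(events) and events[pos][1] == 1:
            group2.append(events[pos][0])
            pos += 1
        if group2:
            offset_t = t[group2[-1]]
        else:
            offset_t = trial_length   # effort sustained at trial end
            truncated = True
        onsets.append(t[onset])
        offsets.append(offset_t)
    if not onsets:
        return EpochSegmentation(
            onsets=[], offsets=[], first_rest=trial_length,
            trial_length=trial_length,
        )
    return EpochSegmentation(
        onsets=onsets, offsets=offsets, first_rest=onsets[0],
        trial_length=trial_length, truncated_final=truncated,
    )


def compute_payoff(
    trace: ForceTrace,
    cond: Condition | None = None,
    target: float | None = None,
    k: float = 1.0,
) -> float:
    """Trial payoff: k * incentive (pence) * seconds with force >= target.

    ``target`` defaults to the condition's difficulty fraction.  The
    proportionality constant ``k`` (pence per pence-second) is a
    configuration choice; group contrasts are invariant to it.
    """
    if k <= 0:
        raise ValueError("payoff constant k must be positive")
    cond = cond if cond is not None else trace.cond
    target = target if target is not None else cond.difficulty_frac
    if not (0.0 < target <= 1.0):
        raise ValueError("force target must lie in (0, 1]")
    seconds_above = float(np.sum(np.asarray(trace.f) >= target)) / trace.fs
    return k * cond.incentive_pence * seconds_above


@dataclass
class QCResult:
    """Visit-level compliance check outcome."""

    passed: bool
    effort_counts: dict
    rest_counts: dict
    failing_conditions: list
    incomplete_design: bool = False


def qc_visit(segs_by_condition: dict, min_epochs: int = 3) -> QCResult:
    """Compliance filter: every condition needs >= 3 effort and rest epochs.

    ``segs_by_condition`` maps each of the 9 conditions to its trials'
    segmentations; counts pool over a condition's trials (truncated epochs
    included).  A missing condition fails with the incomplete-design flag.
    """
    effort_counts, rest_counts, failing = {}, {}, []
    incomplete = len(segs_by_condition) < 9
    for cond, segs in segs_by_condition.items():
        ne = sum(s.n_efforts for s in segs)
        nr = sum(s.n_rests for s in segs)
        effort_counts[cond] = ne
        rest_counts[cond] = nr
        if ne < min_epochs or nr < min_epochs:
            failing.append(cond)
    return QCResult(
        passed=(not failing) and not incomplete,
        effort_counts=effort_counts,
        rest_counts=rest_counts,
        failing_conditions=failing,
        incomplete_design=incomplete,
    )


def condition_summaries(
    segs_by_condition: dict,
    include_truncated: bool = False,
) -> ConditionSummary:
    """Per-condition mean effort and rest durations, pooled over trials.

    Final epochs censored by the trial end are excluded from the means by
    default (their durations are incomplete); set ``include_truncated`` to
    keep them.  An empty condition is an error.
    """
    conds, te, tr, ne, nr = [], [], [], [], []
    for cond, segs in segs_by_condition.items():
        eff, rest = [], []
        for s in segs:
            durs = s.effort_durations
            if s.truncated_final and not include_truncated and durs.size:
                durs = durs[:-1]
            eff.extend(durs)
            rest.extend(s.rest_durations)
        if not eff or not rest:
            raise ValueError(f"condition {cond} has no usable epochs")
        conds.append(cond)
        te.append(float(np.mean(eff)))
        tr.append(float(np.mean(rest)))
        ne.append(len(eff))
        nr.append(len(rest))
    return ConditionSummary(
        conditions=conds, te=np.array(te), tr=np.array(tr),
        n_effort=np.array(ne), n_rest=np.array(nr),
    )
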