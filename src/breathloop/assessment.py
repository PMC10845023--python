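"""Scoring of the eyes-closed interoceptive attention-to-breathing task.

Participants breathe naturally and tap a key every two breaths for five
minutes (two 2.5-minute blocks).  There is no external stimulus, so the
response time (RT) of a trial is the interval since the preceding tap.
Trials are classified as *attended* (consistent breath monitoring) when the
RT lies within one median absolute deviation (MAD) of the median RT, and
*distracted* otherwise.  The MAD is unscaled — no 1.4826 normal-consistency
factor — because the threshold is stated directly in MAD units.

By default the rule is two-sided (|RT − median| ≤ MAD): both unusually slow
and unusually fast taps indicate a lost breath count.  A one-sided variant
(only slow RTs distracted) is available via ``sidedness``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .training import SimulatedUser

__all__ = ["TrialSeries", "classify_trials", "simulate_assessment_run"]

ATTENDED = "attended"
DISTRACTED = "distracted"


@dataclass(frozen=True)
class TrialSeries:
    """Ordered RTs of one assessment run with attended/distracted labels."""

    rts: tuple[float, ...]
    labels: tuple[str, ...]
    median_rt: float
    mad_rt: float
    block_id: tuple[int, ...] | None = None

    @property
    def n_attended(self) -> int:
        return sum(1 for lab in self.labels if lab == ATTENDED)

    @property
    def n_distracted(self) -> int:
        return sum(1 for lab in self.labels if lab == DISTRACTED)

    def counts(self) -> dict[str, int]:
        return {ATTENDED: self.n_attended, DISTRACTED: self.n_distracted}


def classify_trials(
    rts, sidedness: str = "two-sided", block_id=None
) -> TrialSeries:
    """Label each trial attended vs distracted by the median/MAD rule.

    attended  iff |rt − median(rts)| ≤ MAD(rts)   (two-sided, default)
    attended  iff rt − median(rts) ≤ MAD(rts)     (one-sided)

    where MAD = median(|rts − median(rts)|), unscaled.  Ties at exactly one
    MAD count as attended.  Requires at least 3 strictly positive RTs.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.ndim != 1 or rts.size < 3:
        raise ValueError("classification needs at least 3 trials")
    if np.any(rts <= 0) or not np.all(np.isfinite(rts)):
        raise ValueError("response times must be positive and finite")
    if sidedness not in ("two-sided", "one-sided"):
        raise ValueError("sidedness must be 'two-sided' or 'one-sided'")

    median = float(np.median(rts))
    mad = float(np.median(np.abs(rts - median)))
    dev = rts - median
    if sidedness == "two-sided":
        attended = np.abs(dev) <= mad
    else:
        attended = dev <= mad
    labels = tuple(ATTENDED if a else DISTRACTED for a in attended)
    bid = tuple(int(b) for b in block_id) if block_id is not None else None
    if bid is not None and len(bid) != rts.size:
        raise ValueError("block_id length must match rts")
    return TrialSeries(tuple(rts.tolist()), labels, median, mad, bid)


def simulate_assessment_run(
    user: SimulatedUser,
    duration_s: float = 300.0,
    breaths_per_tap: int = 2,
    seed: int | np.random.Generator = 0,
    sidedness: str = "two-sided",
) -> tuple[np.ndarray, TrialSeries]:
    """Simulate one assessment run and score it.

    Tap times come from the user's breath/lapse model (a tap every
    ``breaths_per_tap`` breaths; lapses stretch or shorten intervals).  RTs
    are the inter-tap intervals — the first tap, with no predecessor, yields
    no trial.  The run ends at ``duration_s`` (the closing beep).  The two
    2.5-minute blocks are pooled before computing the median and MAD.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mu = np.log(user.breath_period_mean) - 0.5 * np.log(
        1.0 + (user.breath_period_sd / user.breath_period_mean) ** 2
    )
    sigma = np.sqrt(
        np.log(1.0 + (user.breath_period_sd / user.breath_period_mean) ** 2)
    )
    taps = []
    t = 0.0
    while True:
        periods = rng.lognormal(mu, sigma, size=breaths_per_tap)
        interval = float(periods.sum())
        lapsed = rng.random(breaths_per_tap) < user.lapse_rate
        if lapsed.any():
            if rng.random() < 0.5:
                interval *= float(rng.uniform(1.6, 3.0))
            else:
                interval *= float(rng.uniform(0.3, 0.6))
        t += interval
        if t > duration_s:
            break
        taps.append(t)
    taps = np.asarray(taps)

    rts = np.diff(taps)
    block_edge = duration_s / 2.0
    block_id = (taps[1:] >= block_edge).astype(int)  # block of the closing tap
    series = classify_trials(rts, sidedness=sidedness, block_id=block_id)
    return taps, series
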