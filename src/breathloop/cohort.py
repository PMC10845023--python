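"""Synthetic study cohorts with configurable ground-truth effects.

Generates complete two-group trial datasets — behavioral scale scores at
three timepoints, training adherence, and per-network alpha source activity
— whose per-group, per-timepoint means and SDs match a configured
specification, and whose cross-variable structure (adherence vs outcome
gain, DMN change vs self-compassion change, baseline DMN vs DMN change) is
induced through a Gaussian copula on latent scores.  Rank correlations
survive the monotone truncation to scale ranges, so the configured Spearman
targets hold in expectation.

The construction per outcome and group, with timepoint summaries
(m1, s1), (m2, s2):

    T1 = m1 + s1 * e1,           e1 ~ N(0, 1)
    T2 = m2 + s2 * e2,           e2 = r_tt*e1 + gamma*u + delta*z

where ``u`` is the latent adherence score (training group), ``gamma`` is
set from the target Spearman between sessions and the T2-T1 change via the
Pearson equivalent 2*sin(pi*rho/6), and ``delta`` completes unit variance.
Network activity uses a change-score construction with an explicit
baseline-vs-change coupling (regression to the mean plus the configured
coupling), feasibility-checked against the requested SDs.

Dropout at follow-up is missing completely at random; downstream analysis
is complete-case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import training as tr
from .assessment import ATTENDED, DISTRACTED

__all__ = [
    "OutcomeSpec",
    "NetworkSpec",
    "CohortSpec",
    "EEGCohortSpec",
    "InfeasibleSpecError",
    "generate_cohort",
    "generate_eeg_cohort",
    "default_cohort_spec",
]

TRAINING = "training"
CONTROL = "control"


class InfeasibleSpecError(ValueError):
    """A requested correlation structure is not positive semi-definite."""


def _rank_to_pearson(rho: float) -> float:
    """Pearson correlation giving Spearman rho under bivariate normality."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


@dataclass(frozen=True)
class OutcomeSpec:
    """Per-group mean/SD summaries of one behavioral outcome.

    ``timepoints`` maps 'T1'/'T2'/'T3' to (mean, sd); ``scale_range`` clips
    generated scores to the instrument's range; ``sessions_rho`` is the
    target Spearman between sessions completed and the T2-T1 change
    (training group only).
    """

    timepoints: dict[str, tuple[float, float]]
    scale_range: tuple[float, float] = (1.0, 5.0)
    sessions_rho: float = 0.0


@dataclass(frozen=True)
class NetworkSpec:
    """Per-group network activity summaries (1e-4 source units).

    ``baseline_change_rho`` couples baseline activity with the T2-T1 change
    (the regression-to-baseline structure); ``behavior_coupling`` loads the
    change on the standardized self-compassion change (negative: subjects
    who improve most suppress the network most).
    """

    timepoints: dict[str, tuple[float, float]]
    baseline_change_rho: float = 0.0
    behavior_coupling: float = 0.0


@dataclass(frozen=True)
class CohortSpec:
    n_training: int = 22
    n_control: int = 21
    outcomes: dict[str, dict[str, OutcomeSpec]] = field(default_factory=dict)
    networks: dict[str, dict[str, NetworkSpec]] = field(default_factory=dict)
    test_retest_r: float = 0.7
    sessions_mean: float = 40.64
    sessions_sd: float = 17.79
    sessions_bounds: tuple[float, float] = (0.0, 60.0)
    dropout_t3: tuple[int, int] = (2, 1)  # (training, control), MCAR
    usr_coupling: float = -0.8  # corr(total change, USR change)

    def __post_init__(self) -> None:
        if self.n_training <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")
        if any(
            d < 0 or d >= n
            for d, n in zip(self.dropout_t3, (self.n_training, self.n_control))
        ):
            raise ValueError("dropout must satisfy 0 <= dropout < n")


def default_cohort_spec() -> CohortSpec:
    """Study-sized cohort with the trial's reported outcome summaries.

    Group sizes 22/21; self-compassion, state mindfulness and the three
    burnout subscales at their published per-group means/SDs; adherence
    40.64 (SD 17.79) sessions truncated to 0-60; Spearman targets 0.52
    (sessions vs self-compassion gain) and 0.38 (vs mindfulness gain);
    network activity per the published summaries with a -0.74
    baseline-vs-change DMN coupling and a -0.368 DMN-change vs
    self-compassion-change coupling; follow-up dropout 2/1.
    """
    o = {
        "self_compassion": {
            TRAINING: OutcomeSpec(
                {"T1": (2.69, 0.57), "T2": (3.02, 0.58), "T3": (3.14, 0.55)},
                sessions_rho=0.52,
            ),
            CONTROL: OutcomeSpec(
                {"T1": (3.09, 0.73), "T2": (3.15, 0.67), "T3": (3.29, 0.54)},
            ),
        },
        "state_mindfulness": {
            TRAINING: OutcomeSpec(
                {"T1": (2.94, 0.79), "T2": (3.37, 0.85), "T3": (3.41, 1.08)},
                sessions_rho=0.38,
            ),
            CONTROL: OutcomeSpec(
                {"T1": (3.22, 0.94), "T2": (3.25, 0.82), "T3": (3.55, 0.78)},
            ),
        },
        "usr": {
            # uncompassionate self-responding: change-driven (means chosen so
            # the published change scores -0.42 (0.55) post and -0.82 (1.27)
            # at follow-up arise); unreversed 1-5 scale
            TRAINING: OutcomeSpec(
                {"T1": (2.95, 0.70), "T2": (2.53, 0.75), "T3": (2.13, 0.95)},
            ),
            CONTROL: OutcomeSpec(
                {"T1": (2.70, 0.75), "T2": (2.62, 0.72), "T3": (2.55, 0.75)},
            ),
        },
        "mbi_ee": {
            TRAINING: OutcomeSpec(
                {"T1": (16.27, 4.45), "T2": (15.0, 5.86)}, scale_range=(0, 54)
            ),
            CONTROL: OutcomeSpec(
                {"T1": (24.05, 10.22), "T2": (23.05, 12.45)}, scale_range=(0, 54)
            ),
        },
        "mbi_pa": {
            TRAINING: OutcomeSpec(
                {"T1": (21.41, 3.63), "T2": (21.64, 4.41)}, scale_range=(0, 48)
            ),
            CONTROL: OutcomeSpec(
                {"T1": (32.86, 6.73), "T2": (34.67, 7.77)}, scale_range=(0, 48)
            ),
        },
        "mbi_dp": {
            TRAINING: OutcomeSpec(
                {"T1": (5.36, 3.33), "T2": (4.5, 3.71)}, scale_range=(0, 30)
            ),
            CONTROL: OutcomeSpec(
                {"T1": (9.29, 7.93), "T2": (7.57, 7.37)}, scale_range=(0, 30)
            ),
        },
    }
    n = {
        "FPN": {
            TRAINING: NetworkSpec(
                {"T1": (3.08, 3.14), "T2": (1.96, 1.45)},
                baseline_change_rho=-0.92,
            ),
            CONTROL: NetworkSpec(
                {"T1": (3.45, 3.39), "T2": (1.08, 3.08)},
                baseline_change_rho=-0.5,
            ),
        },
        "CON": {
            TRAINING: NetworkSpec(
                {"T1": (2.55, 2.18), "T2": (1.44, 1.76)},
                baseline_change_rho=-0.65,
            ),
            CONTROL: NetworkSpec(
                {"T1": (1.88, 1.77), "T2": (4.57, 9.86)},
            ),
        },
        "DMN": {
            TRAINING: NetworkSpec(
                {"T1": (11.92, 12.55), "T2": (1.44, 11.66)},
                baseline_change_rho=_rank_to_pearson(-0.74),
                behavior_coupling=_rank_to_pearson(-0.368),
            ),
            CONTROL: NetworkSpec(
                {"T1": (4.94, 7.10), "T2": (10.26, 15.43)},
                behavior_coupling=_rank_to_pearson(-0.368),
            ),
        },
    }
    return CohortSpec(outcomes=o, networks=n)


# ---------------------------------------------------------------------------
# Behavioral generation
# ---------------------------------------------------------------------------

def _draw_outcome(
    spec: OutcomeSpec,
    r_tt: float,
    u: np.ndarray,
    rng: np.random.Generator,
    name: str,
) -> dict[str, np.ndarray]:
    """Latent-normal draws of one outcome for one group; returns T->scores."""
    n = u.size
    m1, s1 = spec.timepoints["T1"]
    e1 = rng.standard_normal(n)
    out = {"T1": m1 + s1 * e1}
    for tp in ("T2", "T3"):
        if tp not in spec.timepoints:
            continue
        m2, s2 = spec.timepoints[tp]
        sd_delta = math.sqrt(
            max(s1**2 + s2**2 - 2.0 * r_tt * s1 * s2, 1e-12)
        )
        gamma = (
            _rank_to_pearson(spec.sessions_rho) * sd_delta / s2
            if spec.sessions_rho
            else 0.0
        )
        resid = 1.0 - r_tt**2 - gamma**2
        if resid < 0:
            raise InfeasibleSpecError(
                f"outcome {name!r} {tp}: test-retest r={r_tt} with sessions "
                f"target rho={spec.sessions_rho} is not a valid correlation "
                "structure"
            )
        e2 = r_tt * e1 + gamma * u + math.sqrt(resid) * rng.standard_normal(n)
        out[tp] = m2 + s2 * e2
    lo, hi = spec.scale_range
    return {tp: np.clip(v, lo, hi) for tp, v in out.items()}


def _draw_network(
    spec: NetworkSpec,
    b1: np.ndarray,
    z_beh: np.ndarray,
    rng: np.random.Generator,
    name: str,
) -> dict[str, np.ndarray]:
    """Baseline + coupled change construction for one network and group."""
    n = b1.size
    m1, s1 = spec.timepoints["T1"]
    m2, s2 = spec.timepoints["T2"]
    rho_b = spec.baseline_change_rho
    alpha_c = spec.behavior_coupling
    resid = 1.0 - rho_b**2 - alpha_c**2
    if resid < 0:
        raise InfeasibleSpecError(
            f"network {name!r}: baseline coupling {rho_b} and behavior "
            f"coupling {alpha_c} exceed unit variance"
        )
    disc = s1**2 * rho_b**2 - s1**2 + s2**2
    if disc < 0:
        raise InfeasibleSpecError(
            f"network {name!r}: SD pair ({s1}, {s2}) with baseline-change "
            f"coupling {rho_b} admits no change-score SD"
        )
    sd_delta = -s1 * rho_b + math.sqrt(disc)
    z = rho_b * b1 + alpha_c * z_beh + math.sqrt(resid) * rng.standard_normal(n)
    t1 = m1 + s1 * b1
    delta = (m2 - m1) + sd_delta * z
    return {"T1": t1, "T2": t1 + delta}


def generate_cohort(
    spec: CohortSpec | None = None,
    seed: int | np.random.Generator = 0,
    include_training_logs: bool = True,
    user: tr.SimulatedUser | None = None,
    training_config: tr.TrainingConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[tr.SessionLog]]]:
    """Generate a complete synthetic trial dataset.

    Returns ``(outcomes, activity, session_logs)``: a long-format outcome
    table (participant x timepoint rows), a long-format network activity
    table (participant x timepoint x network x condition='mean'), and, when
    ``include_training_logs``, per-participant training session logs from
    the closed-loop engine (which also supply ``final_level``).  Adherence
    heterogeneity enters the engine through per-participant lapse rates.
    """
    spec = spec or default_cohort_spec()
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cfg = training_config or tr.TrainingConfig()
    base_user = user or tr.SimulatedUser(
        motivation_mean=spec.sessions_mean,
        motivation_sd=spec.sessions_sd,
        motivation_bounds=spec.sessions_bounds,
    )

    frames = []
    activity_rows = []
    logs: dict[str, list[tr.SessionLog]] = {}
    for group, n in ((TRAINING, spec.n_training), (CONTROL, spec.n_control)):
        pids = [f"{group[0]}{i + 1:02d}" for i in range(n)]
        # adherence: latent u -> exact truncated-normal marginal (copula map)
        u = rng.standard_normal(n)
        lo, hi = spec.sessions_bounds
        a = (lo - spec.sessions_mean) / spec.sessions_sd
        b = (hi - spec.sessions_mean) / spec.sessions_sd
        sessions = sps.truncnorm.ppf(
            sps.norm.cdf(u), a, b, loc=spec.sessions_mean, scale=spec.sessions_sd
        )
        sessions = np.round(sessions).astype(int)

        draws: dict[str, dict[str, np.ndarray]] = {}
        for name, per_group in spec.outcomes.items():
            if group not in per_group:
                continue
            draws[name] = _draw_outcome(
                per_group[group], spec.test_retest_r, u, rng, name
            )

        # USR change coupled to the total self-compassion change; CSR is the
        # algebraic complement total = (csr - usr + 6) / 2
        if "self_compassion" in draws and "usr" in draws:
            sc, us = draws["self_compassion"], draws["usr"]
            for tp in ("T2", "T3"):
                if tp not in sc or tp not in us:
                    continue
                d_tot = sc[tp] - sc["T1"]
                z_tot = (d_tot - d_tot.mean()) / max(d_tot.std(), 1e-9)
                d_usr = us[tp] - us["T1"]
                rho = spec.usr_coupling
                mixed = (
                    d_usr.mean()
                    + d_usr.std()
                    * (rho * z_tot + math.sqrt(1 - rho**2)
                       * (d_usr - d_usr.mean()) / max(d_usr.std(), 1e-9))
                )
                us[tp] = np.clip(us["T1"] + mixed, 1.0, 5.0)
            draws["csr"] = {
                tp: np.clip(2.0 * sc[tp] - 6.0 + us[tp], 1.0, 5.0)
                for tp in sc
                if tp in us
            }

        # standardized self-compassion change drives the DMN coupling
        if "self_compassion" in draws and "T2" in draws["self_compassion"]:
            d = draws["self_compassion"]["T2"] - draws["self_compassion"]["T1"]
            z_beh = (d - d.mean()) / max(d.std(), 1e-9)
        else:
            z_beh = rng.standard_normal(n)

        net_draws = {}
        for name, per_group in spec.networks.items():
            if group not in per_group:
                continue
            b1 = rng.standard_normal(n)
            net_draws[name] = _draw_network(
                per_group[group], b1, z_beh, rng, name
            )

        # follow-up dropout, missing completely at random
        n_drop = spec.dropout_t3[0 if group == TRAINING else 1]
        dropped = set(rng.choice(n, size=n_drop, replace=False).tolist())

        final_levels = np.full(n, np.nan)
        if include_training_logs and group == TRAINING:
            # Heterogeneous lapse rates give heterogeneous level progression.
            # Lapse propensity shares a latent engagement trait with
            # adherence (less motivated trainees are also more distracted),
            # which is what couples sessions completed to final level.
            engagement = 0.6 * u + 0.8 * rng.standard_normal(n)
            lapses = 0.12 * (1.0 - sps.norm.cdf(engagement))
            for i, pid in enumerate(pids):
                pu = replace(base_user, lapse_rate=float(lapses[i]))
                slog, state = tr.simulate_participant_course(
                    pu, cfg, seed=rng, n_sessions=int(sessions[i])
                )
                logs[pid] = slog
                final_levels[i] = state.level

        timepoints = sorted(
            {tp for d in draws.values() for tp in d}
        ) or ["T1"]
        for tp in timepoints:
            rows = {
                "participant_id": pids,
                "group": group,
                "timepoint": tp,
                "sessions_completed": sessions if group == TRAINING else np.nan,
                "final_level": final_levels if group == TRAINING else np.nan,
            }
            for name, d in draws.items():
                rows[name] = d.get(tp, np.full(n, np.nan))
            f = pd.DataFrame(rows)
            if tp == "T3":
                value_cols = list(draws)
                f.loc[f.index[list(dropped)], value_cols] = np.nan
            frames.append(f)

        for name, d in net_draws.items():
            for tp, vals in d.items():
                for pid, v in zip(pids, vals):
                    activity_rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "timepoint": tp,
                            "network": name,
                            "condition": "mean",
                            "activity": float(v),
                        }
                    )

    outcomes = pd.concat(frames, ignore_index=True)
    activity = pd.DataFrame(activity_rows)
    return outcomes, activity, logs


# ---------------------------------------------------------------------------
# EEG-level generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EEGCohortSpec:
    """Forward-model EEG cohort: per-network oscillator amplitude courses.

    ``amplitudes`` maps network -> (T1 mean, T2 mean) in 1e-4 source units;
    amplitudes below ``amp_floor`` are clipped (source power cannot be
    negative).  ``between_subject_cv`` and ``session_cv`` are lognormal
    coefficients of variation for stable subject traits and session-level
    state; ``distracted_factor`` raises DMN-style activity on distracted
    trials.  ``baseline_coupling`` (negative) makes high-baseline subjects
    suppress more, the switchable baseline-vs-change relation.
    """

    n_subjects: int = 17
    amplitudes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "DMN": (10.0, 5.0), "FPN": (3.0, 3.0), "CON": (3.0, 3.0)
        }
    )
    between_subject_cv: float = 0.3
    session_cv: float = 0.1
    distracted_factor: float = 1.5
    baseline_coupling: float = 0.0
    amp_floor: float = 0.2
    duration_s: float = 100.0
    srate: float = 250.0
    noise_sd: float = 1.0
    p_distracted: float = 0.3


def _condition_amplitudes(level: float, factor: float) -> dict[str, float]:
    # attended/distracted split around the level mean
    att = 2.0 * level / (1.0 + factor)
    return {ATTENDED: att, DISTRACTED: att * factor}


def generate_eeg_cohort(
    spec: EEGCohortSpec,
    leadfield,
    seed: int | np.random.Generator = 0,
):
    """Yield per-subject, per-timepoint synthetic EEG recordings.

    Yields ``(subject_id, timepoint, recording, true_levels)`` where
    ``true_levels`` maps each network to the session's true mean amplitude.
    Subject trait amplitudes are lognormal around the spec means; the T2/T1
    amplitude ratio follows the spec's mean course, modulated by the
    baseline coupling when enabled; session-level lognormal jitter adds
    test-retest variability.
    """
    from .eeg import simulate_eeg_session

    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sigma_b = math.sqrt(math.log(1.0 + spec.between_subject_cv**2))
    sigma_s = math.sqrt(math.log(1.0 + spec.session_cv**2))
    for i in range(spec.n_subjects):
        sid = f"s{i + 1:02d}"
        trait_z = {net: rng.standard_normal() for net in spec.amplitudes}
        for tp_idx, tp in enumerate(("T1", "T2")):
            levels = {}
            for net, (m1, m2) in spec.amplitudes.items():
                trait = math.exp(sigma_b * trait_z[net] - 0.5 * sigma_b**2)
                mean_tp = m1 if tp == "T1" else m2
                level = mean_tp * trait
                if tp == "T2" and spec.baseline_coupling and m1 > 0:
                    # high-baseline subjects move further toward the T2 mean
                    c = abs(spec.baseline_coupling)
                    level = mean_tp * trait ** (1.0 - 2.0 * c)
                jitter = math.exp(
                    sigma_s * rng.standard_normal() - 0.5 * sigma_s**2
                )
                levels[net] = max(level * jitter, spec.amp_floor)
            amps = {
                net: _condition_amplitudes(
                    lvl, spec.distracted_factor if net == "DMN" else 1.0
                )
                for net, lvl in levels.items()
            }
            rec, conds, taps = simulate_eeg_session(
                amps,
                leadfield,
                seed=rng,
                duration_s=spec.duration_s,
                srate=spec.srate,
                noise_sd=spec.noise_sd,
                p_distracted=spec.p_distracted,
            )
            yield sid, tp, rec, levels
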