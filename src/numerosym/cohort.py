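"""Synthetic participant cohorts with the covariance structure the analysis assumes.

A cohort draw produces one :class:`~numerosym.observer.ObserverParams` per
participant: a two-regime Weber curve, condition-dependent underestimation
biases, and an AQ score constructed jointly with the participant's symmetry
susceptibility so that AQ correlates with the estimation-regime symmetry
bias at a configurable target r (higher AQ -> weaker underestimation -> bias
value closer to zero, a positive correlation on the bias scale).

Bias profiles are resolved per (condition, standard N): an exact-N entry
wins over the condition's regime-level entry ("estimation" for N <= N',
"density" above), and anything unspecified — the random condition in
particular — is unbiased.  Within a participant, all symmetric-condition
biases share a single susceptibility latent, so a participant who
underestimates vertical symmetry strongly also does so for double symmetry;
this is what makes a single AQ correlation meaningful.

``simulate_experiment`` runs the full staircase x observer chain for every
cell of a design.  Seeds form a spawn hierarchy (master -> participant ->
staircase) so adding a participant never perturbs the others' trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import staircase as st
from .designs import ExperimentDesign, regime_of
from .observer import ObserverParams, p_test_more

#: control-task symmetry-detection accuracies (group means per standard)
DEFAULT_DETECTION_ACCURACY = {
    8: 0.991, 12: 0.997, 24: 0.983, 50: 0.997,
    100: 0.994, 200: 0.982, 300: 0.986, 400: 0.955,
}

#: vertical symmetry: ~7% underestimation in the estimation regime, ~3% in density
DEFAULT_BIAS_PROFILE = {
    ("vertical", "estimation"): (-7.0, 2.5),
    ("vertical", "density"): (-3.0, 2.5),
    ("random", "estimation"): (0.0, 1.0),
    ("random", "density"): (0.0, 1.0),
}

#: three-condition profile with per-N entries (double symmetry deepens the bias)
EXP2_BIAS_PROFILE = {
    ("vertical", 12): (-8.0, 2.5),
    ("vertical", 48): (-7.0, 2.5),
    ("vertical", 200): (-4.0, 2.5),
    ("double", 12): (-14.0, 2.5),
    ("double", 48): (-9.0, 2.5),
    ("double", 200): (-7.0, 2.5),
    ("random", "estimation"): (0.0, 1.0),
    ("random", "density"): (0.0, 1.0),
}


@dataclass
class CohortSpec:
    """Generative description of a simulated sample.

    Weber-curve defaults follow the group curve (plateau 0.25 switching near
    100 into a square-root decline); the AQ mean/sd (17 +/- 6) are synthetic
    defaults for a neurotypical sample, and ``aq_bias_correlation`` is the
    target Pearson r between AQ and the estimation-regime symmetry bias.
    """

    n_participants: int = 19
    wf0_mean: float = 0.25
    wf0_sd: float = 0.03
    n_switch_mean: float = 100.0
    n_switch_sd: float = 0.0
    alpha_mean: float = 0.5
    alpha_sd: float = 0.0
    bias_profile: dict = field(default_factory=lambda: dict(DEFAULT_BIAS_PROFILE))
    aq_mean: float = 17.0
    aq_sd: float = 6.0
    aq_bias_correlation: float = 0.51
    detection_accuracy: dict = field(
        default_factory=lambda: dict(DEFAULT_DETECTION_ACCURACY)
    )
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need >= 2 participants")
        if not abs(self.aq_bias_correlation) < 1:
            raise ValueError("|aq_bias_correlation| must be < 1")
        if min(self.wf0_sd, self.n_switch_sd, self.alpha_sd, self.aq_sd) < 0:
            raise ValueError("sds must be >= 0")
        if self.aq_bias_correlation != 0 and self.aq_sd == 0:
            raise ValueError("nonzero AQ-bias correlation requires aq_sd > 0")


def _resolve_bias(profile: dict, condition: str, n: int) -> tuple[float, float] | None:
    if (condition, n) in profile:
        return profile[(condition, n)]
    return profile.get((condition, regime_of(n)))


def generate_cohort(
    spec: CohortSpec, standards: tuple[int, ...] = (8, 12, 24, 48, 50, 100, 200, 300, 400)
) -> list[ObserverParams]:
    """Draw per-participant generative parameters, reproducibly.

    ``standards`` lists every numerosity a downstream design may use, so each
    observer carries a concrete bias for each (condition, N) cell.
    """
    root = np.random.SeedSequence(spec.master_seed)
    children = root.spawn(spec.n_participants)
    r = spec.aq_bias_correlation
    cohort = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        z_bias = rng.standard_normal()  # shared symmetry-susceptibility latent
        z_aq = rng.standard_normal()
        aq_latent = spec.aq_mean + spec.aq_sd * (r * z_bias + math.sqrt(1 - r * r) * z_aq)
        aq = int(np.clip(round(aq_latent), 0, 50))
        bias = {}
        for cond in ("random", "vertical", "double"):
            for n in standards:
                entry = _resolve_bias(spec.bias_profile, cond, n)
                if entry is None:
                    continue
                mean, sd = entry
                if cond == "random":
                    bias[(cond, n)] = mean + sd * rng.standard_normal()
                else:
                    bias[(cond, n)] = mean + sd * z_bias
        wf0 = max(0.02, spec.wf0_mean + spec.wf0_sd * rng.standard_normal())
        n_switch = max(1.0, spec.n_switch_mean + spec.n_switch_sd * rng.standard_normal())
        alpha = max(0.0, spec.alpha_mean + spec.alpha_sd * rng.standard_normal())
        cohort.append(
            ObserverParams(
                wf0=wf0,
                n_switch=n_switch,
                alpha=alpha,
                bias_percent=bias,
                symmetry_detection_accuracy=dict(spec.detection_accuracy),
                aq_score=aq,
                participant_id=f"S{i + 1:02d}",
            )
        )
    return cohort


#: sd (log10 units) of the placement jitter around the QUEST recommendation.
#: Placing every trial exactly at the tracked 50% point leaves the
#: psychometric slope (hence JND and Wf) unidentified; jitter of about one
#: kernel width samples the +/-1 JND flanks where slope information lives.
PLACEMENT_JITTER_SD = st.DEFAULT_BETA


def _run_staircase(
    params: ObserverParams,
    condition: str,
    n_standard: int,
    session: int,
    n_trials: int,
    rng: np.random.Generator,
    quest_kwargs: dict,
    placement_jitter_sd: float = PLACEMENT_JITTER_SD,
) -> list[dict]:
    state = st.quest_create(**quest_kwargs)
    lo, hi = state.grid[0], state.grid[-1]
    rows = []
    for t in range(n_trials):
        intensity = st.quest_next(state)
        if placement_jitter_sd:
            intensity += placement_jitter_sd * rng.standard_normal()
        n_test = st.intensity_to_n_test(intensity, n_standard)
        shown = float(np.clip(math.log10(n_test / n_standard), lo, hi))
        p = p_test_more(n_test, n_standard, condition, params)
        response = bool(rng.random() < p)
        state = st.quest_update(state, shown, response)
        rows.append(
            {
                "participant_id": params.participant_id,
                "condition": condition,
                "n_standard": n_standard,
                "n_test": n_test,
                "standard_first": bool(rng.random() < 0.5),
                "response_test_more": response,
                "session": session,
                "trial_index": t,
            }
        )
    return rows


def simulate_experiment(
    cohort: list[ObserverParams],
    design: ExperimentDesign,
    master_seed: int = 0,
    quest_kwargs: dict | None = None,
    placement_jitter_sd: float = PLACEMENT_JITTER_SD,
) -> pd.DataFrame:
    """Full trial table for a cohort run through a design.

    One independent QUEST staircase per participant x condition x standard x
    session, ``trials_per_session`` trials each; both sessions are later
    pooled for fitting.  Deterministic in ``master_seed``.
    """
    quest_kwargs = quest_kwargs or {}
    for params in cohort:
        for cond in design.conditions:
            if cond != "random" and all(c != cond for c, _ in params.bias_percent):
                raise ValueError(
                    f"design condition {cond!r} absent from bias profile of "
                    f"participant {params.participant_id}"
                )
    root = np.random.SeedSequence(master_seed)
    rows: list[dict] = []
    for params, child in zip(cohort, root.spawn(len(cohort))):
        cells = [
            (c, n, s)
            for c in design.conditions
            for n in design.standards
            for s in range(1, design.sessions + 1)
        ]
        for (cond, n_std, session), cell_seed in zip(cells, child.spawn(len(cells))):
            rng = np.random.default_rng(cell_seed)
            rows.extend(
                _run_staircase(
                    params, cond, n_std, session,
                    design.trials_per_session, rng, quest_kwargs,
                    placement_jitter_sd,
                )
            )
    df = pd.DataFrame(rows)
    df.insert(1, "experiment", design.name)
    return df


def simulate_control(
    cohort: list[ObserverParams],
    standards: tuple[int, ...] = (8, 12, 24, 50, 100, 200, 300, 400),
    n_trials: int = 50,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Symmetry-identification control task: per-participant accuracy per N."""
    root = np.random.SeedSequence(master_seed)
    rows = []
    for params, child in zip(cohort, root.spawn(len(cohort))):
        for n, seed in zip(standards, child.spawn(len(standards))):
            rng = np.random.default_rng(seed)
            acc = params.symmetry_detection_accuracy[n]
            correct = int(np.sum(rng.random(n_trials) < acc))
            rows.append(
                {
                    "participant_id": params.participant_id,
                    "n_standard": n,
                    "n_trials": n_trials,
                    "n_correct": correct,
                    "accuracy": correct / n_trials,
                }
            )
    return pd.DataFrame(rows)
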