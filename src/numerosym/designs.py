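"""Experiment designs: standards, conditions, sessions and trial counts.

The main comparison task manipulates the standard numerosity across sessions
and pairs it with a QUEST-driven test.  The first experiment spans both the
estimation and density regimes with eight standards and two conditions
(random vs vertically symmetric standard); the second samples three
standards with a doubly symmetric condition added.  Every participant runs
two 50-trial sessions per standard x condition, pooled for fitting, giving
1600 and 900 trials per participant respectively.  The control task is a
single 50-trial symmetry-identification block per standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ExperimentDesign:
    name: str
    standards: tuple[int, ...]
    conditions: tuple[str, ...]
    sessions: int = 2
    trials_per_session: int = 50
    # presentation metadata only (no rendering/timing is simulated)
    presentation_ms: int = 300
    isi_ms: int = 500

    @property
    def trials_per_participant(self) -> int:
        return (
            len(self.standards)
            * len(self.conditions)
            * self.sessions
            * self.trials_per_session
        )


EXP1 = ExperimentDesign(
    name="exp1",
    standards=(8, 12, 24, 50, 100, 200, 300, 400),
    conditions=("random", "vertical"),
)

EXP2 = ExperimentDesign(
    name="exp2",
    standards=(12, 48, 200),
    conditions=("random", "vertical", "double"),
)

CONTROL = ExperimentDesign(
    name="control",
    standards=(8, 12, 24, 50, 100, 200, 300, 400),
    conditions=("vertical",),
    sessions=1,
    trials_per_session=50,
)

DESIGNS = {"exp1": EXP1, "exp2": EXP2, "control": CONTROL}

#: standards at or below the regime switch (~100) count as estimation regime
REGIME_SWITCH_DEFAULT = 100


def regime_of(n_standard: int, n_switch: float = REGIME_SWITCH_DEFAULT) -> str:
    return "estimation" if n_standard <= n_switch else "density"
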