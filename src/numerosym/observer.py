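"""Generative observer model for 2IFC numerosity comparison.

A simulated participant carries a two-regime Weber curve (constant Weber
fraction Wf0 up to the switching numerosity N', then declining as a power
-alpha), a condition- and numerosity-dependent multiplicative bias on the
perceived standard, a symmetry-detection accuracy for the control task, and
an AQ score.

The decision model places all noise on the test-numerosity axis: the
probability of responding "test more numerous" is a single cumulative
Gaussian in the test numerosity, centred on the biased standard, with sd
derived from the Weber fraction at the standard.  This matches the
psychometric model fitted downstream; a two-interval noise combination is a
documented extension, not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import ndtr
from scipy.stats import norm

#: Phi^-1(0.75): converts a 50%->75% JND into a Gaussian sd.
Z75 = float(norm.ppf(0.75))

CONDITIONS = ("random", "vertical", "double")


@dataclass
class ObserverParams:
    """Generative parameters of one simulated participant.

    ``bias_percent`` maps (condition, standard N) to a percent bias on the
    perceived standard (negative = the standard is underestimated, so the
    point of subjective equality of the test falls below N).  Conditions
    absent from the mapping default to 0 (the random condition is unbiased).
    ``symmetry_detection_accuracy`` maps N to the probability of correctly
    identifying the symmetric interval in the control task.
    """

    wf0: float = 0.25
    n_switch: float = 100.0
    alpha: float = 0.5
    bias_percent: dict = field(default_factory=dict)  # (condition, n_standard) -> percent
    symmetry_detection_accuracy: dict = field(default_factory=dict)  # n -> prob
    aq_score: int = 17
    lapse_rate: float = 0.0
    participant_id: str = "obs"

    def __post_init__(self) -> None:
        if self.wf0 <= 0:
            raise ValueError("wf0 must be > 0")
        if self.n_switch < 1:
            raise ValueError("n_switch must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5)")
        for acc in self.symmetry_detection_accuracy.values():
            if not 0.5 <= acc <= 1.0:
                raise ValueError("symmetry detection accuracy must be in [0.5, 1]")

    def bias_for(self, condition: str, n_standard: int) -> float:
        return float(self.bias_percent.get((condition, int(n_standard)), 0.0))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bias_percent"] = [
            {"condition": c, "n_standard": n, "bias": b}
            for (c, n), b in self.bias_percent.items()
        ]
        d["symmetry_detection_accuracy"] = [
            {"n": n, "accuracy": a} for n, a in self.symmetry_detection_accuracy.items()
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverParams":
        d = dict(d)
        d["bias_percent"] = {
            (e["condition"], int(e["n_standard"])): float(e["bias"])
            for e in d.get("bias_percent", [])
        }
        d["symmetry_detection_accuracy"] = {
            int(e["n"]): float(e["accuracy"])
            for e in d.get("symmetry_detection_accuracy", [])
        }
        return cls(**d)


def weber_fraction_at(n: float, params: ObserverParams) -> float:
    """Two-regime Weber fraction: Wf0 for n <= N', else Wf0 (n/N')^-alpha."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n <= params.n_switch:
        return params.wf0
    return params.wf0 * (n / params.n_switch) ** (-params.alpha)


def p_test_more(
    n_test: float, n_standard: float, condition: str, params: ObserverParams
) -> float:
    """P(respond "test more numerous") for a single trial.

    Phi((n_test - PSE) / sigma) with PSE = N (1 + bias/100) and
    sigma = Wf(N) * N / Phi^-1(0.75), optionally mixed with a symmetric lapse.
    """
    if n_test < 1 or n_standard < 1:
        raise ValueError("numerosities must be >= 1")
    pse = n_standard * (1.0 + params.bias_for(condition, n_standard) / 100.0)
    sigma = weber_fraction_at(n_standard, params) * n_standard / Z75
    p = float(ndtr((n_test - pse) / sigma))
    if params.lapse_rate:
        p = params.lapse_rate / 2.0 + (1.0 - params.lapse_rate) * p
    return p


def simulate_trial(
    n_test: int,
    n_standard: int,
    condition: str,
    params: ObserverParams,
    rng: np.random.Generator | int,
) -> bool:
    """One Bernoulli 2IFC response ("test more"), reproducible from the rng."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    return bool(rng.random() < p_test_more(n_test, n_standard, condition, params))


def simulate_symmetry_judgment(
    n: int, params: ObserverParams, rng: np.random.Generator | int
) -> bool:
    """One control-task response: correctly identified the symmetric interval."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    try:
        acc = params.symmetry_detection_accuracy[int(n)]
    except KeyError:
        raise KeyError(f"no symmetry-detection accuracy configured for N={n}") from None
    return bool(rng.random() < acc)
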