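"""Two-state Viterbi estimate of per-slice alignment correctness.

As the banded DP proceeds slice by slice, the increase of the minimum score
from one slice to the next is an observed per-64-bp error count.  A two-state
hidden Markov model -- "correctly aligned" emitting errors at a 20% rate,
"wrongly aligned" at 50% -- is run over these observations with Viterbi's
algorithm.  Slice n is *guaranteed correct* when the predecessor of the wrong
state at slice n+1 is the correct state at n (every continuation, right or
wrong, passes through the correct state there), and symmetrically *guaranteed
wrong*.  The flags drive band ramping, termination, and clipping of the final
alignment.

Emissions are Binomial(64, rate) at the clamped score increment; transitions
are symmetric and rare (default stay probability 1 - 1e-5 per slice) so one
noisy slice cannot flip the state.  All arithmetic is in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .bitdp import WORD

CORRECT = 0
WRONG = 1


@dataclass(frozen=True)
class EmissionModel:
    """Per-state per-slice error rates and the state-transition probability."""

    rate_correct: float = 0.20
    rate_wrong: float = 0.50
    p_switch: float = 1e-5
    init_correct: float = 0.5

    def log_emission(self, state: int, delta: int) -> float:
        rate = self.rate_correct if state == CORRECT else self.rate_wrong
        k = max(0, min(WORD, delta))
        return (
            math.lgamma(WORD + 1)
            - math.lgamma(k + 1)
            - math.lgamma(WORD - k + 1)
            + k * math.log(rate)
            + (WORD - k) * math.log1p(-rate)
        )

    def log_transition(self, a: int, b: int) -> float:
        return math.log(self.p_switch) if a != b else math.log1p(-self.p_switch)


@dataclass
class CorrectnessState:
    """Viterbi log-probabilities and predecessor pointers after one slice."""

    log_correct: float
    log_wrong: float
    pred_correct: int | None  # state index at the previous slice, None at slice 0
    pred_wrong: int | None


def viterbi_step(
    prev: CorrectnessState | None, delta: int, model: EmissionModel
) -> CorrectnessState:
    """Standard Viterbi update for one slice's score increment."""
    e_c = model.log_emission(CORRECT, delta)
    e_w = model.log_emission(WRONG, delta)
    if prev is None:
        p0 = math.log(model.init_correct)
        p1 = math.log1p(-model.init_correct)
        return CorrectnessState(p0 + e_c, p1 + e_w, None, None)
    cand_cc = prev.log_correct + model.log_transition(CORRECT, CORRECT)
    cand_wc = prev.log_wrong + model.log_transition(WRONG, CORRECT)
    cand_cw = prev.log_correct + model.log_transition(CORRECT, WRONG)
    cand_ww = prev.log_wrong + model.log_transition(WRONG, WRONG)
    if cand_cc >= cand_wc:
        lc, pc = cand_cc + e_c, CORRECT
    else:
        lc, pc = cand_wc + e_c, WRONG
    if cand_ww >= cand_cw:
        lw, pw = cand_ww + e_w, WRONG
    else:
        lw, pw = cand_cw + e_w, CORRECT
    return CorrectnessState(lc, lw, pc, pw)


class CorrectnessTracker:
    """Viterbi trace over slices with guaranteed-correct/wrong bookkeeping.

    Flags for slice n become available once slice n+1 has been observed.
    """

    def __init__(self, model: EmissionModel | None = None) -> None:
        self.model = model or EmissionModel()
        self.states: list[CorrectnessState] = []
        self.guaranteed_correct: list[bool] = []
        self.guaranteed_wrong: list[bool] = []

    def observe(self, delta: int) -> CorrectnessState:
        prev = self.states[-1] if self.states else None
        st = viterbi_step(prev, delta, self.model)
        self.states.append(st)
        self.guaranteed_correct.append(False)
        self.guaranteed_wrong.append(False)
        if len(self.states) >= 2:
            n = len(self.states) - 2
            self.guaranteed_correct[n] = st.pred_wrong == CORRECT
            self.guaranteed_wrong[n] = st.pred_correct == WRONG
        return st

    @property
    def n_slices(self) -> int:
        return len(self.states)

    @property
    def wrong_dominant(self) -> bool:
        if not self.states:
            return False
        return self.states[-1].log_wrong > self.states[-1].log_correct

    @property
    def correct_dominant(self) -> bool:
        if not self.states:
            return True
        return self.states[-1].log_correct >= self.states[-1].log_wrong

    def last_guaranteed_correct(self) -> int | None:
        for n in range(len(self.guaranteed_correct) - 1, -1, -1):
            if self.guaranteed_correct[n]:
                return n
        return None

    def first_guaranteed_wrong(self) -> int | None:
        for n, flag in enumerate(self.guaranteed_wrong):
            if flag:
                return n
        return None

    def truncate(self, keep: int) -> None:
        """Drop all state beyond the first ``keep`` slices (for re-alignment)."""
        del self.states[keep:]
        del self.guaranteed_correct[keep:]
        del self.guaranteed_wrong[keep:]
        for n in range(len(self.guaranteed_correct)):
            self.guaranteed_correct[n] = False
            self.guaranteed_wrong[n] = False
        for n in range(1, len(self.states)):
            self.guaranteed_correct[n - 1] = self.states[n].pred_wrong == CORRECT
            self.guaranteed_wrong[n - 1] = self.states[n].pred_correct == WRONG


def control_extension(
    tracker: CorrectnessTracker, ramped: bool
) -> str:
    """Decide the next action: 'continue', 'ramp', or 'terminate'.

    Ramping (re-aligning from the last guaranteed-correct slice with the wider
    band B) triggers as soon as the wrong state dominates -- a looser condition
    than a guaranteed-wrong slice -- but at most once per wrong-dip; a
    guaranteed-wrong slice always terminates the extension.
    """
    if tracker.first_guaranteed_wrong() is not None:
        return "terminate"
    if tracker.wrong_dominant and not ramped:
        return "ramp"
    return "continue"
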