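"""Five-choice staircase risk elicitation.

Participants make five binary choices between a guaranteed amount and a
50:50 gamble of 300 vs 0 points.  The guaranteed amount starts at 160 and
bisects with halving steps (+-80, 40, 20, 10): gambling raises it, playing
safe lowers it.  The five choices identify one of 32 terminal positions
(1 = most risk-averse, all safe; 32 = least, all gamble), which maps
linearly onto a risk aversion score in [0, 2] with higher values more
risk-averse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

FIRST_AMOUNT = 160
STEPS = (80, 40, 20, 10)
GAMBLE_WIN = 300
N_ROUNDS = 5
N_POSITIONS = 32


@dataclass(frozen=True)
class StaircaseRecord:
    """One participant's complete staircase outcome."""

    choices: Sequence[bool]          # True = gamble, False = safe
    guaranteed_amounts: Sequence[int]
    position: int                    # 1..32
    score: float                     # in [0, 2], higher = more risk-averse


def guaranteed_amount(round_k: int, prior_choices: Sequence[bool]) -> int:
    """Guaranteed amount offered in round ``round_k`` (1-based) given the
    gamble/safe choices of the earlier rounds."""
    if not 1 <= round_k <= N_ROUNDS:
        raise ValueError(f"round must be 1..{N_ROUNDS}, got {round_k!r}")
    if len(prior_choices) < round_k - 1:
        raise ValueError("not enough prior choices for this round")
    amount = FIRST_AMOUNT
    for k in range(round_k - 1):
        step = STEPS[k]
        amount += step if prior_choices[k] else -step
    return amount


def amounts_for(choices: Sequence[bool]) -> List[int]:
    """The five guaranteed amounts implied by a full choice sequence."""
    if len(choices) != N_ROUNDS:
        raise ValueError(f"exactly {N_ROUNDS} choices required")
    return [guaranteed_amount(k, choices) for k in range(1, N_ROUNDS + 1)]


def choices_to_position(choices: Sequence[bool]) -> int:
    """Bisection path to staircase position: ``1 + sum gamble_k * 2^(5-k)``.

    A bijection between the 32 choice sequences and positions 1..32; all
    safe gives 1 (most risk-averse), all gamble gives 32.
    """
    if len(choices) != N_ROUNDS:
        raise ValueError(f"exactly {N_ROUNDS} choices required")
    return 1 + sum(int(c) << (N_ROUNDS - 1 - k) for k, c in enumerate(choices))


def position_to_score(position: int) -> float:
    """Linear inversion of the staircase position onto [0, 2]:
    ``2 * (32 - position) / 31`` (position 1 -> 2.0, position 32 -> 0.0)."""
    if not 1 <= position <= N_POSITIONS:
        raise ValueError(f"position must be 1..{N_POSITIONS}, got {position!r}")
    return 2.0 * (N_POSITIONS - position) / (N_POSITIONS - 1)


def score_choices(choices: Sequence[bool]) -> StaircaseRecord:
    """Full record (amounts, position, score) for a choice sequence."""
    position = choices_to_position(choices)
    return StaircaseRecord(
        choices=tuple(bool(c) for c in choices),
        guaranteed_amounts=tuple(amounts_for(choices)),
        position=position,
        score=position_to_score(position),
    )


def certainty_equivalent(r_true: float) -> float:
    """Safe/gamble threshold implied by a risk parameter: ``160 * (2 - r)``.

    Decreasing in r, and spanning (0, 320) over r in (0, 2) so that every
    terminal position — including the all-gamble path whose final guaranteed
    amount (310) exceeds the gamble's best outcome — is reachable by some
    responder.  Near risk neutrality (r = 1) the threshold is 160, close to
    the gamble's expected value of 150.
    """
    if not 0.0 < r_true < 2.0:
        raise ValueError(f"r_true must lie in (0, 2), got {r_true!r}")
    return FIRST_AMOUNT * (2.0 - r_true)


def simulate_staircase(
    r_true: float, rng: Optional[np.random.Generator] = None
) -> StaircaseRecord:
    """Deterministic threshold responder: choose safe iff the guaranteed
    amount is at least the certainty equivalent implied by ``r_true``.

    The resulting score is a weakly monotone (nondecreasing) function of
    ``r_true``.  The generator argument is accepted for interface parity
    with stochastic responders but unused by the threshold rule.
    """
    ce = certainty_equivalent(r_true)
    choices: List[bool] = []
    for k in range(1, N_ROUNDS + 1):
        amount = guaranteed_amount(k, choices)
        choices.append(amount < ce)  # gamble when the sure thing is too small
    return score_choices(choices)
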