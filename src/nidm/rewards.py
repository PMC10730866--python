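"""Point rewards and risk-perceived utility.

Realized per-round points for node *i* with *t* relations, triad proportion
*x* and disease state *s* are

    U_i = scale * [ b1*t + b2*(1 - 2|x - alpha| / max(alpha, 1-alpha))
                    - (c1*t + c2*t^2) - sigma*[s == I] ]

with the relation part floored at zero (the published rule) and the triad
part allowed to go negative.  For decision-making, susceptible agents replace
the objective infection cost ``sigma`` with a perceived cost
``sigma^r * pi^(2-r)`` that amplifies both severity and exposure for
risk-averse agents (r > 1) and discounts them for risk-seeking agents
(r < 1); see :func:`perceived_infection_cost`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_core import DiseaseState, ParamSet, SimNetwork, local_triad_proportion


@dataclass(frozen=True)
class RewardBreakdown:
    """Stage-3 reward of one node, split into its three components (scaled
    points; the penalty is reported positive and subtracted in ``total``)."""

    relation_points: float
    triad_points: float
    infection_penalty: float

    @property
    def total(self) -> float:
        return self.relation_points + self.triad_points - self.infection_penalty


def relation_value(t: int, p: ParamSet) -> float:
    """Unscaled relation term ``b1*t - (c1*t + c2*t^2)``, optionally floored
    at zero. Under defaults this is unimodal with its maximum 2.388 at t=6."""
    if t < 0:
        raise ValueError("number of relations cannot be negative")
    value = p.b1 * t - (p.c1 * t + p.c2 * t * t)
    if p.clamp_relation_reward:
        value = max(0.0, value)
    return value


def relation_points(t: int, p: ParamSet) -> float:
    """Scaled relation reward in points (100 at t=6 under defaults)."""
    return p.scale * relation_value(t, p)


def triad_value(x: float, p: ParamSet) -> float:
    """Unscaled triad term ``b2 * (1 - 2|x - alpha| / max(alpha, 1-alpha))``.

    Maximal (``b2``) at ``x == alpha``; linear on each side; never clamped,
    so a maximally mis-clustered node loses as much as the optimum gains.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"triad proportion must lie in [0, 1], got {x!r}")
    return p.b2 * (1.0 - 2.0 * abs(x - p.alpha) / max(p.alpha, 1.0 - p.alpha))


def triad_points(x: float, p: ParamSet) -> float:
    """Scaled triad reward in points (20.94, printed 21, at the optimum under
    defaults)."""
    return p.scale * triad_value(x, p)


def infection_penalty(state: DiseaseState, p: ParamSet) -> float:
    """Scaled penalty: ``scale * sigma`` (about 14 points) while infected,
    zero for susceptible and recovered nodes."""
    state = DiseaseState(state)
    return p.scale * p.sigma if state is DiseaseState.I else 0.0


def round_reward(net: SimNetwork, i: int, p: ParamSet) -> RewardBreakdown:
    """Realized stage-3 reward of node *i* on the current network."""
    t = net.degree(i)
    x = local_triad_proportion(net, i)
    return RewardBreakdown(
        relation_points=relation_points(t, p),
        triad_points=triad_points(x, p),
        infection_penalty=infection_penalty(net.state[i], p),
    )


def perceived_infection_cost(r: float, pi: float, p: ParamSet) -> float:
    """Perceived infection cost ``w * sigma^r * pi^(2-r)`` (unscaled).

    ``r`` is the risk perception parameter in (0, 2): 1.0 is risk-neutral
    (the cost reduces to ``sigma * pi``), larger values amplify both the
    perceived severity and the perceived exposure.  ``pi`` is the objective
    per-round infection probability. ``w`` (``ext_risk_weight``) is a
    behavioral extension knob, 1 by default.
    """
    if not 0.0 < r < 2.0:
        raise ValueError(f"risk perception parameter must lie in (0, 2), got {r!r}")
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"infection probability must lie in [0, 1], got {pi!r}")
    if pi == 0.0:
        return 0.0
    return p.ext_risk_weight * (p.sigma ** r) * (pi ** (2.0 - r))
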