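"""Exchange-protocol prisoner's dilemma and dyadic cooperation indices.

Each player holds an endowment of 150 JPY and chooses how much of it to
transfer to the partner.  Transferred money is doubled on delivery; the
giver keeps the remainder.  With offers ``a`` and ``b``::

    payoff_A = E - a + k*b        payoff_B = E - b + k*a

with endowment ``E = 150`` and doubling factor ``k = 2``.  Giving less
strictly dominates regardless of the partner's offer, so the game is a
continuous-cooperation prisoner's dilemma.

The dyad-level behavioral measures are proportions of the joint
endowment transferred, ``(a + b) / (2 E)``: computed on offers made
*before* the conversation (toward a stranger) this is the pair's trait
*cooperativeness*; on offers made *after* the conversation (toward the
partner) it is the pair's *cooperative behavior*.

Payoff-matrix orientation: when a matrix cell is written for a row
labelled by B's cooperation level and a column labelled by A's, the
left-hand value of the cell is B's payoff and the right-hand value A's.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

ENDOWMENT = 150
DOUBLING = 2

__all__ = [
    "ENDOWMENT",
    "DOUBLING",
    "Offer",
    "GameOutcome",
    "CoopIndex",
    "payoff",
    "coop_index",
    "read_offers_csv",
    "write_offers_csv",
]


@dataclass(frozen=True)
class Offer:
    """A single transfer decision, in integer JPY within [0, ENDOWMENT]."""

    amount: int

    def __post_init__(self) -> None:
        amount = self.amount
        if isinstance(amount, bool) or not float(amount).is_integer():
            raise ValueError(f"offer must be an integer JPY amount, got {amount!r}")
        if not 0 <= amount <= ENDOWMENT:
            raise ValueError(f"offer {amount!r} outside [0, {ENDOWMENT}] JPY")


@dataclass(frozen=True)
class GameOutcome:
    """Per-player payoffs for one play of the game, in JPY."""

    payoff_a: int
    payoff_b: int

    @property
    def total(self) -> int:
        return self.payoff_a + self.payoff_b


@dataclass(frozen=True)
class CoopIndex:
    """Proportion of the joint endowment transferred, in [0, 1]."""

    value: float


def _as_amount(offer: "Offer | int", step: int | None = None) -> int:
    amount = offer.amount if isinstance(offer, Offer) else Offer(offer).amount
    if step is not None and amount % step != 0:
        raise ValueError(f"offer {amount} is not a multiple of the allowed step {step}")
    return int(amount)


def payoff(offer_a: "Offer | int", offer_b: "Offer | int", *, step: int | None = None) -> GameOutcome:
    """Payoffs for offers ``a`` and ``b`` under the exchange protocol.

    Parameters
    ----------
    offer_a, offer_b:
        Integer JPY offers in [0, 150] (or :class:`Offer` instances).
    step:
        Optional granularity restriction, e.g. ``step=10`` allows only
        multiples of 10 JPY.

    Returns
    -------
    GameOutcome
        ``payoff_a = 150 - a + 2 b`` and ``payoff_b = 150 - b + 2 a``.
    """
    a = _as_amount(offer_a, step)
    b = _as_amount(offer_b, step)
    return GameOutcome(payoff_a=ENDOWMENT - a + DOUBLING * b, payoff_b=ENDOWMENT - b + DOUBLING * a)


def coop_index(offer_a: "Offer | int", offer_b: "Offer | int", *, step: int | None = None) -> CoopIndex:
    """Dyadic cooperation index ``(a + b) / (2 * ENDOWMENT)``.

    Applied to pre-conversation offers this measures the pair's
    cooperativeness; applied to post-conversation offers it measures the
    pair's cooperative behavior.
    """
    a = _as_amount(offer_a, step)
    b = _as_amount(offer_b, step)
    return CoopIndex(value=(a + b) / (DOUBLING * ENDOWMENT))


OFFER_COLUMNS = ["dyad_id", "participant_id", "session", "offer_jpy"]
_SESSIONS = {"pre", "post"}


def read_offers_csv(path: "str | Path") -> pd.DataFrame:
    """Read an offers table (columns dyad_id, participant_id, session, offer_jpy).

    ``session`` is ``pre`` (toward a stranger, before the conversation) or
    ``post`` (toward the partner, after it).  Offers are validated against
    the endowment range.
    """
    df = pd.read_csv(path)
    missing = [c for c in OFFER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"offers file {path} missing columns {missing}")
    bad_session = set(df["session"].unique()) - _SESSIONS
    if bad_session:
        raise ValueError(f"offers file {path} has unknown sessions {sorted(bad_session)}")
    for amount in df["offer_jpy"]:
        Offer(amount)
    return df[OFFER_COLUMNS].copy()


def write_offers_csv(df: pd.DataFrame, path: "str | Path") -> None:
    df[OFFER_COLUMNS].to_csv(path, index=False)


def dyad_coop_indices(offers: pd.DataFrame) -> pd.DataFrame:
    """Per-dyad cooperativeness (pre) and cooperative behavior (post).

    Returns a frame with one row per dyad: ``dyad_id``,
    ``cooperativeness`` and ``coop_behavior``.
    """
    rows = []
    for dyad_id, group in offers.groupby("dyad_id", sort=True):
        row: dict = {"dyad_id": dyad_id}
        for session, col in (("pre", "cooperativeness"), ("post", "coop_behavior")):
            sub = group[group["session"] == session]
            if len(sub) != 2:
                raise ValueError(
                    f"dyad {dyad_id!r} session {session!r}: expected 2 offers, got {len(sub)}"
                )
            a, b = sub["offer_jpy"].tolist()
            row[col] = coop_index(int(a), int(b)).value
        rows.append(row)
    return pd.DataFrame(rows, columns=["dyad_id", "cooperativeness", "coop_behavior"])
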