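"""Scoring of the 50-item Autism-spectrum Quotient questionnaire.

Each item is answered on a 4-point scale (strongly agree, slightly agree,
slightly disagree, strongly disagree).  One point is scored when the response
falls on the item's autistic-characteristic pole — slightly or strongly, the
strength never matters — giving a total from 0 to 50 that decomposes exactly
into five 10-item subscales (attention switching, attention to detail,
imagination, communication, social skills).  Totals at or above 32 are
flagged: published norms place scores of 32+ in the range where a clinical
assessment is recommended.

The item key and subscale map ship as an editable JSON data file since they
belong to the published instrument, not to this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

CLINICAL_THRESHOLD = 32
N_ITEMS = 50

#: canonical response levels; numeric codes 1-4 map in this order
LEVELS = ("strongly agree", "slightly agree", "slightly disagree", "strongly disagree")
_AGREE = {"strongly agree", "slightly agree", 1, 2, "1", "2"}
_DISAGREE = {"slightly disagree", "strongly disagree", 3, 4, "3", "4"}


def _load_key() -> dict:
    with resources.files("numerosym.data").joinpath("aq_key.json").open() as fh:
        return json.load(fh)


_KEY = _load_key()
AGREE_SCORED = frozenset(_KEY["agree_scored"])
SUBSCALES = {name: tuple(items) for name, items in _KEY["subscales"].items()}


@dataclass(frozen=True)
class AQScore:
    participant_id: str
    total: int
    subscales: dict  # subscale name -> 0..10
    clinical_flag: bool


def _is_agree(response) -> bool:
    if response in _AGREE:
        return True
    if response in _DISAGREE:
        return False
    raise ValueError(f"invalid AQ response level: {response!r}")


def score_aq(responses: dict, participant_id: str = "") -> AQScore:
    """Score one complete 50-item response set.

    ``responses`` maps item number (1..50) to a response level (string or
    1-4 code).  Missing or extra items and invalid levels raise; there is no
    imputation.
    """
    items = set(responses)
    if items != set(range(1, N_ITEMS + 1)):
        missing = sorted(set(range(1, N_ITEMS + 1)) - items)
        extra = sorted(items - set(range(1, N_ITEMS + 1)))
        raise ValueError(f"incomplete response set: missing {missing}, extra {extra}")
    item_scores = {}
    for item, resp in responses.items():
        agree = _is_agree(resp)
        characteristic = agree if item in AGREE_SCORED else not agree
        item_scores[item] = int(characteristic)
    subscales = {
        name: sum(item_scores[i] for i in items_) for name, items_ in SUBSCALES.items()
    }
    total = sum(item_scores.values())
    assert total == sum(subscales.values())
    return AQScore(participant_id, total, subscales, flag_clinical(total))


def flag_clinical(total: int) -> bool:
    """True at or above the clinical-assessment threshold of 32.

    Scores "below 32" are unflagged, so the boundary value 32 itself flags.
    """
    return total >= CLINICAL_THRESHOLD


def score_aq_table(df: pd.DataFrame) -> pd.DataFrame:
    """Score a CSV-shaped table: participant_id, item_01 .. item_50.

    Returns one row per participant with total, the five subscale scores and
    the clinical flag.
    """
    cols = [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"AQ table missing columns: {missing}")
    rows = []
    for _, rec in df.iterrows():
        responses = {i: rec[f"item_{i:02d}"] for i in range(1, N_ITEMS + 1)}
        s = score_aq(responses, participant_id=str(rec["participant_id"]))
        rows.append(
            {
                "participant_id": s.participant_id,
                "total": s.total,
                **s.subscales,
                "clinical_flag": s.clinical_flag,
            }
        )
    return pd.DataFrame(rows)
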