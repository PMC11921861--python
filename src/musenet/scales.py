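"""Scoring of the four self-report instruments and internal consistency.

The instruments are the 10-item Kessler psychological distress scale (K10,
anxiety + depression subscales with four risk levels), the 20-item Toronto
Alexithymia Scale (TAS-20, facets DIF / DDF / EOT with clinical cutoffs),
the 12-item Regulatory Emotional Self-Efficacy scale (RESE, dimensions
POS / DES / ANG) and the 13-item Healthy-Unhealthy Music Scale (HUMS,
subscales HMU / UHMU).  All items are 5-point Likert responses coded 1..5.

Item-to-subscale assignments that the instruments' short descriptions leave
implicit (the K10 anxiety/depression split, TAS-20 facet membership and
reverse keying, the RESE and HUMS item blocks) default to the standard
published keying but are configurable keyword arguments on every scorer.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, LikertRangeError, SchemaError

# ---------------------------------------------------------------------------
# Default item keying (1-based item numbers within each instrument)
# ---------------------------------------------------------------------------

#: K10 subscale split (anxiety 4 items, depression 6 items).  The instrument
#: description does not print the split; this is the widely used assignment.
K10_ANXIETY_ITEMS: tuple[int, ...] = (2, 3, 5, 6)
K10_DEPRESSION_ITEMS: tuple[int, ...] = (1, 4, 7, 8, 9, 10)

#: Standard TAS-20 facet membership: DIF 7 items, DDF 5 items, EOT 8 items.
TAS_FACETS: dict[str, tuple[int, ...]] = {
    "DIF": (1, 3, 6, 7, 9, 13, 14),
    "DDF": (2, 4, 11, 12, 17),
    "EOT": (5, 8, 10, 15, 16, 18, 19, 20),
}
#: Standard TAS-20 reverse-keyed items (recoded as 6 - x before summation).
TAS_REVERSE_ITEMS: tuple[int, ...] = (4, 5, 10, 18, 19)

#: RESE dimensions, four items each, in instrument order.
RESE_DIMENSIONS: dict[str, tuple[int, ...]] = {
    "POS": (1, 2, 3, 4),
    "DES": (5, 6, 7, 8),
    "ANG": (9, 10, 11, 12),
}

#: HUMS subscales: healthy use 5 items, unhealthy use 8 items.  Shipped as
#: contiguous blocks; override to match a specific questionnaire export.
HUMS_HMU_ITEMS: tuple[int, ...] = (1, 2, 3, 4, 5)
HUMS_UHMU_ITEMS: tuple[int, ...] = (6, 7, 8, 9, 10, 11, 12, 13)

#: Expected item counts per instrument.
ITEM_COUNTS: dict[str, int] = {"K10": 10, "TAS": 20, "RESE": 12, "HUMS": 13}

#: K10 risk-level cutoffs: 10-19 level 1 (low), 20-24 level 2, 25-29 level 3,
#: 30-50 level 4 (high risk of mental illness).
K10_LEVEL_BINS: tuple[int, ...] = (19, 24, 29)

#: TAS-20 total-score categories: <=51 none, 52-60 possible, >=61 present.
TAS_CATEGORY_BINS: tuple[int, ...] = (51, 60)
TAS_CATEGORY_LABELS: tuple[str, ...] = ("none", "possible", "present")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_likert(responses: pd.DataFrame, n_items: int | None = None,
                    instrument: str = "") -> pd.DataFrame:
    """Validate a respondents x items Likert matrix.

    Checks the column count (when ``n_items`` is given) and that every entry
    is an integer in 1..5.  Returns the validated frame unchanged.

    Raises
    ------
    SchemaError
        Wrong number of item columns.
    LikertRangeError
        An entry outside {1, 2, 3, 4, 5}, naming respondent and item.
    """
    if n_items is not None and responses.shape[1] != n_items:
        raise SchemaError(
            f"{instrument or 'instrument'} expects {n_items} item columns, "
            f"got {responses.shape[1]}"
        )
    values = responses.to_numpy()
    bad = ~np.isin(values, [1, 2, 3, 4, 5])
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise LikertRangeError(responses.index[i], responses.columns[j],
                               values[i, j])
    return responses


def _items(responses: pd.DataFrame, numbers: Iterable[int]) -> pd.DataFrame:
    """Select item columns by 1-based position within the instrument."""
    return responses.iloc[:, [k - 1 for k in numbers]]


# ---------------------------------------------------------------------------
# Instrument scorers
# ---------------------------------------------------------------------------

def score_k10(responses: pd.DataFrame,
              anxiety_items: Sequence[int] = K10_ANXIETY_ITEMS,
              depression_items: Sequence[int] = K10_DEPRESSION_ITEMS,
              ) -> pd.DataFrame:
    """Score the K10: anxiety (4-20), depression (6-30), total (10-50), level.

    The risk level is the step function 10-19 -> 1, 20-24 -> 2, 25-29 -> 3,
    30-50 -> 4.
    """
    validate_likert(responses, ITEM_COUNTS["K10"], "K10")
    if set(anxiety_items) & set(depression_items):
        raise SchemaError("anxiety and depression item sets overlap")
    if len(anxiety_items) + len(depression_items) != 10:
        raise SchemaError("K10 subscales must partition the 10 items")
    anxiety = _items(responses, anxiety_items).sum(axis=1)
    depression = _items(responses, depression_items).sum(axis=1)
    total = anxiety + depression
    level = np.digitize(total, K10_LEVEL_BINS, right=True) + 1
    return pd.DataFrame(
        {"anxiety": anxiety, "depression": depression,
         "k10_total": total, "k10_level": level},
        index=responses.index,
    )


def score_tas20(responses: pd.DataFrame,
                facets: Mapping[str, Sequence[int]] = TAS_FACETS,
                reverse_items: Sequence[int] = TAS_REVERSE_ITEMS,
                ) -> pd.DataFrame:
    """Score the TAS-20: facet sums, total, category and dominant facet.

    Reverse-keyed items are recoded 6 - x before summation.  The total-score
    category uses the cutoffs <=51 none / 52-60 possible / >=61 present.
    The dominant facet is the argmax of the per-item facet means; exact ties
    are reported joined by "/" in the fixed order DIF, DDF, EOT.
    """
    validate_likert(responses, ITEM_COUNTS["TAS"], "TAS-20")
    covered = sorted(k for items in facets.values() for k in items)
    if covered != list(range(1, 21)):
        raise SchemaError("TAS-20 facets must partition items 1..20")
    recoded = responses.copy()
    for k in reverse_items:
        recoded.iloc[:, k - 1] = 6 - recoded.iloc[:, k - 1]

    out = pd.DataFrame(index=responses.index)
    means = {}
    for name, items in facets.items():
        block = _items(recoded, items)
        out[name.lower()] = block.sum(axis=1)
        means[name] = block.mean(axis=1)
    out["tas_total"] = out[[f.lower() for f in facets]].sum(axis=1)
    cat = np.digitize(out["tas_total"], TAS_CATEGORY_BINS, right=True)
    out["tas_category"] = np.asarray(TAS_CATEGORY_LABELS)[cat]

    mean_mat = pd.DataFrame(means)[list(facets)]
    best = mean_mat.max(axis=1)
    is_best = mean_mat.eq(best, axis=0)
    out["dominant_facet"] = [
        "/".join(name for name in facets if row[name])
        for _, row in is_best.iterrows()
    ]
    return out


def score_rese(responses: pd.DataFrame,
               dimensions: Mapping[str, Sequence[int]] = RESE_DIMENSIONS,
               ) -> pd.DataFrame:
    """Score the RESE: POS, DES and ANG sums, each four items, range 4-20."""
    validate_likert(responses, ITEM_COUNTS["RESE"], "RESE")
    out = pd.DataFrame(index=responses.index)
    for name, items in dimensions.items():
        out[name.lower()] = _items(responses, items).sum(axis=1)
    return out


def score_hums(responses: pd.DataFrame,
               hmu_items: Sequence[int] = HUMS_HMU_ITEMS,
               uhmu_items: Sequence[int] = HUMS_UHMU_ITEMS,
               ) -> pd.DataFrame:
    """Score the HUMS: healthy use (5 items, 5-25) and unhealthy (8, 8-40)."""
    validate_likert(responses, ITEM_COUNTS["HUMS"], "HUMS")
    return pd.DataFrame(
        {"hmu": _items(responses, hmu_items).sum(axis=1),
         "uhmu": _items(responses, uhmu_items).sum(axis=1)},
        index=responses.index,
    )


# ---------------------------------------------------------------------------
# Whole-battery scoring
# ---------------------------------------------------------------------------

def split_instruments(items: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a combined item frame into per-instrument frames.

    Columns are matched case-insensitively against the naming convention
    ``K10_1..K10_10``, ``TAS_1..TAS_20``, ``RESE_1..RESE_12`` and
    ``HUMS_1..HUMS_13``.
    """
    out: dict[str, pd.DataFrame] = {}
    upper = {c.upper(): c for c in items.columns}
    for inst, k in ITEM_COUNTS.items():
        names = [f"{inst}_{i}" for i in range(1, k + 1)]
        missing = [n for n in names if n not in upper]
        if missing:
            raise SchemaError(f"missing {inst} item columns: {missing}")
        out[inst] = items[[upper[n] for n in names]]
    return out


def score_battery(items: pd.DataFrame, dropna: bool = True,
                  impute: bool = False) -> pd.DataFrame:
    """Score all four instruments from one combined item frame.

    Missing responses are handled by listwise deletion by default
    (``dropna=True``); with ``impute=True`` each missing entry is replaced by
    the rounded per-item mean instead.
    """
    if impute:
        items = items.apply(lambda c: c.fillna(round(c.mean())))
    elif dropna:
        items = items.dropna()
    items = items.astype(int)
    parts = split_instruments(items)
    return pd.concat(
        [score_k10(parts["K10"]), score_tas20(parts["TAS"]),
         score_rese(parts["RESE"]), score_hums(parts["HUMS"])],
        axis=1,
    )


# ---------------------------------------------------------------------------
# Internal consistency
# ---------------------------------------------------------------------------

def cronbach_alpha(responses: pd.DataFrame) -> float:
    """Cronbach's alpha, ``k/(k-1) * (1 - sum(item var) / var(total))``.

    Variances are sample variances (ddof=1).  Requires at least two items,
    three respondents and a non-degenerate total score.
    """
    if responses.shape[1] < 2:
        raise SchemaError("alpha needs at least 2 items")
    if responses.shape[0] < 3:
        raise SchemaError("alpha needs at least 3 respondents")
    values = responses.to_numpy(dtype=float)
    k = values.shape[1]
    total_var = values.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DegenerateDataError("total score has zero variance; "
                                  "alpha is undefined")
    item_var = values.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1 - item_var / total_var)
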