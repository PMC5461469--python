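"""Regulatory-redundancy analyses over dossier study tables.

Implements the desk statistics of the dossier analysis:

* per-hazard prevalence of the GHS oral-toxicity statements H300-H305 and
  the conclusive non-toxic complement;
* inter-guideline agreement at the 2,000 mg/kg b.w. LD50 class boundary;
* the 28-day-NOAEL screening rule for acute toxicity ("Bulgheroni" rule):
  a 2x2 table of NOAEL <= 200 vs > 200 mg/kg against LD50 < 2,000 vs
  >= 2,000, with its negative/positive predictive values and the count of
  acute studies the rule would have made avoidable;
* the 28-day -> 90-day NOAEL predictivity question ("Taylor" constraints:
  reliable studies, no positive oral-route hazards, limit-dose 28-day
  result), conditional on a high (>= 1,000 mg/kg/day) 28-day NOAEL;
* the factor-3 DNEL rule: the fraction of matched key-study pairs whose
  90-day NOAEL is at least one third of the 28-day NOAEL.

Boundary conventions: NOAEL <= 200 is the "predict toxic" row; LD50 >=
2,000 is the negative class; a 90-day NOAEL of exactly one third counts
as within the factor-3 limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dossier import (
    ACUTE_GUIDELINES,
    SelectionRule,
    StudyRecord,
    SubstanceRecord,
    aggregate_dataset,
    studies_to_frame,
)

__all__ = [
    "ContingencyTable",
    "hazard_prevalence",
    "oral_nontoxic_percent",
    "guideline_agreement",
    "pair_noael_ld50",
    "BulgheroniResult",
    "bulgheroni_table",
    "taylor_filter",
    "taylor_predictivity",
    "factor3_check",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts; rows = rule prediction, columns = observed class.

    For the NOAEL screening rule: tp = (NOAEL <= 200 and LD50 < 2,000),
    fp = (<= 200, >= 2,000), fn = (> 200, < 2,000),
    tn = (> 200, >= 2,000).
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def npv(self) -> float | None:
        """Percent of rule-negative (> 200) substances that are non-toxic."""
        denom = self.tn + self.fn
        return None if denom == 0 else 100.0 * self.tn / denom

    @property
    def ppv(self) -> float | None:
        """Percent of rule-positive (<= 200) substances that are toxic."""
        denom = self.tp + self.fp
        return None if denom == 0 else 100.0 * self.tp / denom


# ---------------------------------------------------------------------------
# hazard prevalence (Table-1-style)


def hazard_prevalence(
    substances: Sequence[SubstanceRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-hazard status counts and the conclusive-positive percent.

    The percent is positive / (positive + negative) * 100 rounded to one
    decimal ("negative" = conclusive but not sufficient for
    classification); it is NaN when no conclusive record exists.
    Accepts SubstanceRecords or a frame of status strings indexed by
    substance with one column per hazard code.
    """
    if isinstance(substances, pd.DataFrame):
        flags = substances
    else:
        flags = pd.DataFrame(
            [s.hazard_flags for s in substances],
            index=[s.substance_id for s in substances],
        )
    rows = []
    for code in flags.columns:
        counts = flags[code].value_counts()
        pos = int(counts.get("positive", 0))
        neg = int(counts.get("negative", 0))
        row = {
            "hazard": code,
            "positive": pos,
            "negative": neg,
            "data_lacking": int(counts.get("data_lacking", 0)),
            "inconclusive": int(counts.get("inconclusive", 0)),
            "conclusive_positive_pct": (
                round(100.0 * pos / (pos + neg), 1) if pos + neg else np.nan
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("hazard")


def oral_nontoxic_percent(prevalence: pd.DataFrame) -> float:
    """Percent of substances with no oral-ingestion hazard (H300-H303).

    Computed as 100 minus the sum of the four rounded per-hazard
    conclusive-positive percentages, matching the convention of quoting
    each hazard at one decimal.
    """
    codes = [c for c in ("H300", "H301", "H302", "H303") if c in prevalence.index]
    if len(codes) != 4:
        raise ValueError("prevalence table must cover H300-H303")
    return round(100.0 - float(
        prevalence.loc[codes, "conclusive_positive_pct"].sum()
    ), 1)


# ---------------------------------------------------------------------------
# guideline agreement (Table-2-style)


def guideline_agreement(
    studies: Iterable[StudyRecord], threshold: float = 2000.0
) -> pd.DataFrame:
    """Percent agreement between acute guidelines at the LD50 class boundary.

    Off-diagonal (A, B): over substances with at least one study under
    each guideline, agreement iff the per-guideline mean LD50s fall in the
    same class (< threshold vs >= threshold). Diagonal (A, A): over
    substances with >= 2 studies under A, agreement iff all of its
    A-studies classify identically. Returns a frame with MultiIndex
    columns ``(pct, n)``; the matrix is symmetric.
    """
    frame = studies_to_frame(
        [s for s in studies if s.endpoint == "acute_oral"]
    )
    gls = [g for g in ACUTE_GUIDELINES if g in set(frame["guideline"])]
    toxic = frame["value"] < threshold
    frame = frame.assign(toxic=toxic)
    per_gl_mean = frame.groupby(["guideline", "substance_id"])["value"].mean()
    pct = pd.DataFrame(index=gls, columns=gls, dtype=float)
    n_mat = pd.DataFrame(0, index=gls, columns=gls, dtype=int)
    for i, a in enumerate(gls):
        for b in gls[i:]:
            if a == b:
                counts = frame[frame["guideline"] == a].groupby("substance_id")
                multi = counts.filter(lambda g: len(g) >= 2)
                if len(multi) == 0:
                    continue
                consistent = multi.groupby("substance_id")["toxic"].nunique() == 1
                n = len(consistent)
                value = 100.0 * consistent.mean()
            else:
                ids_a = per_gl_mean.loc[a]
                ids_b = per_gl_mean.loc[b]
                common = ids_a.index.intersection(ids_b.index)
                n = len(common)
                if n == 0:
                    continue
                agree = (ids_a.loc[common] < threshold) == (
                    ids_b.loc[common] < threshold
                )
                value = 100.0 * agree.mean()
            pct.loc[a, b] = pct.loc[b, a] = value
            n_mat.loc[a, b] = n_mat.loc[b, a] = n
    return pd.concat({"pct": pct, "n": n_mat}, axis=1)


# ---------------------------------------------------------------------------
# Bulgheroni 28d-NOAEL screening rule (Table-3-style)


def pair_noael_ld50(
    studies: Iterable[StudyRecord], scope: str = "all"
) -> pd.DataFrame:
    """Per-substance (mean 28d NOAEL, mean acute LD50) under a study scope.

    ``scope="key_only"`` keeps key studies and drops read-across for the
    acute side (the white-cell convention); ``scope="all"`` keeps
    everything. Substances lacking either endpoint are dropped.
    """
    if scope == "key_only":
        acute_rule = SelectionRule(key_only=True, include_read_across=False)
    elif scope == "all":
        acute_rule = SelectionRule()
    else:
        raise ValueError(f"unknown study scope {scope!r}")
    studies = list(studies)
    noael = aggregate_dataset(studies, SelectionRule(), "repeated_28d")
    ld50 = aggregate_dataset(studies, acute_rule, "acute_oral")
    pairs = noael.join(ld50, how="inner", lsuffix="_noael28", rsuffix="_ld50")
    return pairs.rename(
        columns={"mean_value_noael28": "noael28", "mean_value_ld50": "ld50"}
    )[["noael28", "ld50"]]


@dataclass(frozen=True)
class BulgheroniResult:
    table: ContingencyTable
    npv_pct: float | None
    ppv_pct: float | None
    avoidable_count: int
    n_substances: int


def bulgheroni_table(
    studies: Iterable[StudyRecord],
    *,
    noael_threshold: float = 200.0,
    ld50_threshold: float = 2000.0,
    scope: str = "all",
) -> BulgheroniResult:
    """The 28d-NOAEL screening contingency table and its statistics.

    The avoidable-study count is the (> threshold NOAEL, >= threshold
    LD50) cell: the acute studies the rule would have correctly called
    negative. Percentages are rounded to one decimal.
    """
    pairs = pair_noael_ld50(studies, scope)
    if len(pairs) == 0:
        raise ValueError("no substances with both a 28d NOAEL and an acute LD50")
    low_noael = pairs["noael28"] <= noael_threshold
    toxic = pairs["ld50"] < ld50_threshold
    table = ContingencyTable(
        tp=int((low_noael & toxic).sum()),
        fp=int((low_noael & ~toxic).sum()),
        fn=int((~low_noael & toxic).sum()),
        tn=int((~low_noael & ~toxic).sum()),
    )
    return BulgheroniResult(
        table=table,
        npv_pct=None if table.npv is None else round(table.npv, 1),
        ppv_pct=None if table.ppv is None else round(table.ppv, 1),
        avoidable_count=table.tn,
        n_substances=len(pairs),
    )


# ---------------------------------------------------------------------------
# Taylor constraints and 28d -> 90d predictivity


def taylor_filter(
    substances: Sequence[SubstanceRecord],
    studies: Iterable[StudyRecord],
    *,
    limit_dose: float = 1000.0,
) -> pd.DataFrame:
    """Substance-level constraint flags for the 90-day redundancy claim.

    A substance passes when it has at least one 28-day study with Klimisch
    <= 2 and no positive flag among the tracked H3xx hazards. The separate
    ``high_dose_high_noael`` flag records whether a reliable 28-day study
    reached the limit dose, i.e. reported a NOAEL >= ``limit_dose``.
    """
    studies = list(studies)
    frame = studies_to_frame(studies)
    s28 = frame[(frame["endpoint"] == "repeated_28d") & (frame["klimisch"] <= 2)]
    reliable_ids = set(s28["substance_id"])
    high_ids = set(s28[s28["value"] >= limit_dose]["substance_id"])
    rows = []
    for sub in substances:
        no_positive = all(
            status != "positive" for status in sub.hazard_flags.values()
        )
        rows.append(
            {
                "substance_id": sub.substance_id,
                "passes": sub.substance_id in reliable_ids and no_positive,
                "high_dose_high_noael": sub.substance_id in high_ids,
            }
        )
    return pd.DataFrame(rows).set_index("substance_id")


def noael_pairs(studies: Iterable[StudyRecord],
                selection: SelectionRule = SelectionRule()) -> pd.DataFrame:
    """Matched per-substance mean 28d/90d NOAELs (inner join)."""
    studies = list(studies)
    n28 = aggregate_dataset(studies, selection, "repeated_28d")
    n90 = aggregate_dataset(studies, selection, "repeated_90d")
    pairs = n28.join(n90, how="inner", lsuffix="_28", rsuffix="_90")
    return pairs.rename(
        columns={"mean_value_28": "noael28", "mean_value_90": "noael90"}
    )[["noael28", "noael90"]]


def taylor_predictivity(
    pairs: pd.DataFrame, threshold: float = 1000.0
) -> dict:
    """Among pairs with 28d NOAEL >= threshold, percent with high 90d NOAEL.

    Returns ``{"n_high28", "pct_high90_given_high28"}``; the percent is
    None when no pair qualifies. Both thresholds are inclusive (>=).
    """
    high28 = pairs[pairs["noael28"] >= threshold]
    n = len(high28)
    if n == 0:
        return {"n_high28": 0, "pct_high90_given_high28": None}
    pct = 100.0 * float((high28["noael90"] >= threshold).mean())
    return {"n_high28": n, "pct_high90_given_high28": round(pct, 1)}


def factor3_check(pairs: pd.DataFrame) -> dict:
    """Share of pairs whose 90d NOAEL is at least one third of the 28d NOAEL.

    A pair is *below* when noael90 < noael28 / 3 strictly; exactly one
    third counts as within the limit. Returns counts and the
    percent-within at one decimal. Zero pairs is an error.
    """
    if len(pairs) == 0:
        raise ValueError("no matched 28d/90d pairs")
    below = pairs["noael90"] < pairs["noael28"] / 3.0
    n = len(pairs)
    n_below = int(below.sum())
    return {
        "n_pairs": n,
        "n_below_one_third": n_below,
        "pct_within": round(100.0 * (n - n_below) / n, 1),
    }
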