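"""Trio expression-pattern classification.

Each gene in a (parent1, parent2, F1) trio is assigned one of five
qualitative models from the on/off state of its three members:

* PCE  — parental co-silence: both parents on, hybrid off
* PSE  — parent-specific: exactly one parent on, hybrid off
* HSE  — hybrid-specific: hybrid on, both parents off
* SPE  — single-parent expression: hybrid on plus exactly one parent
* PHCE — parental-hybrid co-expression: all three on

PHCE genes are placed on the dominance scale through the A statistic

    A = (Pmax - F1) / (Pmax - Pmin)

where Pmax/Pmin are the higher- and lower-expressing parent.  A is 0 at the
high parent, 1 at the low parent and 0.5 at the midparent; A < 0 means the
hybrid exceeds the high parent and A >= 1 that it falls below the low
parent.  Seven half-open intervals partition the line into positive
super-dominance (PSD), positive dominance (PD), partial positive dominance
(PPD), mid-parent (MP), partial negative dominance (PND), negative
dominance (ND) and negative super-dominance (NSD).

Interval bounds are lower-inclusive/upper-exclusive and compared directly
(no epsilon).  When both parental means are exactly equal the ratio is
undefined; the call is then made by sign (F1 above the common parental
value -> PSD, below -> NSD, equal -> MP) with ``a_value`` left undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

QUALITATIVE_MODELS = ("PCE", "PSE", "HSE", "SPE", "PHCE")
#: PAV (presence-absence variation) models: everything but PHCE.
PAV_MODELS = ("PCE", "PSE", "HSE", "SPE")
#: Dominance categories ordered by increasing A.
CATEGORIES = ("PSD", "PD", "PPD", "MP", "PND", "ND", "NSD")
#: Interval boundaries; category i covers [b[i-1], b[i]) with open ends beyond.
CATEGORY_BOUNDARIES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

#: The eleven terminal classes: PAV models plus PHCE expanded to categories.
TERMINAL_CLASSES = PAV_MODELS + CATEGORIES


class ClassificationError(ValueError):
    """Raised on trios that violate the classification contract."""


@dataclass(frozen=True)
class TrioExpression:
    """One gene's aggregated expression in a parent1/parent2/F1 trio."""

    gene_id: str
    hybrid: str
    tissue: str
    p1_value: float
    p2_value: float
    f1_value: float
    p1_expressed: bool
    p2_expressed: bool
    f1_expressed: bool

    @property
    def p_max(self) -> float:
        return max(self.p1_value, self.p2_value)

    @property
    def p_min(self) -> float:
        return min(self.p1_value, self.p2_value)


@dataclass(frozen=True)
class PatternCall:
    """Classification result for one trio."""

    gene_id: str
    hybrid: str
    tissue: str
    model: str
    expressing_parent: str  # "parent1" | "parent2" | "both" | "none"
    a_value: Optional[float]  # defined iff model == PHCE and Pmax > Pmin
    category: Optional[str]  # defined iff model == PHCE

    @property
    def terminal_class(self) -> str:
        """The 11-way class label: PAV model, or the category for PHCE."""
        return self.category if self.model == "PHCE" else self.model


# -- scalar (reference) path -------------------------------------------------


def classify_qualitative(
    p1_expressed: bool, p2_expressed: bool, f1_expressed: bool
) -> tuple[str, str]:
    """Assign the qualitative model from the three on/off flags.

    Returns ``(model, expressing_parent)``; ``expressing_parent`` identifies
    which parent is on for the one-parent models PSE and SPE.
    """
    if not (p1_expressed or p2_expressed or f1_expressed):
        raise ClassificationError(
            "trio with no expressed member; such genes must be excluded upstream"
        )
    n_parents = int(p1_expressed) + int(p2_expressed)
    if f1_expressed:
        if n_parents == 2:
            return "PHCE", "both"
        if n_parents == 1:
            return "SPE", "parent1" if p1_expressed else "parent2"
        return "HSE", "none"
    if n_parents == 2:
        return "PCE", "both"
    return "PSE", "parent1" if p1_expressed else "parent2"


def compute_a_value(p_max: float, p_min: float, f1_value: float) -> float:
    """A = (Pmax - F1) / (Pmax - Pmin); requires Pmax > Pmin."""
    if p_max <= p_min:
        raise ClassificationError("A undefined for Pmax <= Pmin; use the sign rule")
    return (p_max - f1_value) / (p_max - p_min)


def classify_quantitative(a: float) -> str:
    """Map a finite A value to its dominance category via the interval table."""
    if not math.isfinite(a):
        raise ClassificationError(f"A must be finite, got {a}")
    for i, bound in enumerate(CATEGORY_BOUNDARIES):
        if a < bound:
            return CATEGORIES[i]
    return CATEGORIES[-1]  # A >= 1.0


def classify_trio(t: TrioExpression) -> PatternCall:
    """Classify one trio: qualitative model plus, for PHCE, the A category.

    This scalar path is written as a plain truth-table/interval walk and
    doubles as the reference implementation against which the vectorized
    :func:`classify_trios` is cross-checked.
    """
    model, expressing_parent = classify_qualitative(
        t.p1_expressed, t.p2_expressed, t.f1_expressed
    )
    a_value: Optional[float] = None
    category: Optional[str] = None
    if model == "PHCE":
        if t.p_max > t.p_min:
            a_value = compute_a_value(t.p_max, t.p_min, t.f1_value)
            category = classify_quantitative(a_value)
        else:
            # equal parental means: ordering semantics of A by sign, no division
            if t.f1_value > t.p_max:
                category = "PSD"
            elif t.f1_value < t.p_min:
                category = "NSD"
            else:
                category = "MP"
    return PatternCall(
        gene_id=t.gene_id,
        hybrid=t.hybrid,
        tissue=t.tissue,
        model=model,
        expressing_parent=expressing_parent,
        a_value=a_value,
        category=category,
    )


# -- vectorized path ---------------------------------------------------------


def classify_trios(trios: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification of a trio table from :func:`~triopattern.io.build_trios`.

    Returns one row per input trio with columns ``gene_id, hybrid, tissue,
    model, expressing_parent, a_value, category``; ``a_value``/``category``
    are NaN/empty outside PHCE.
    """
    p1e = trios["p1_expressed"].to_numpy(dtype=bool)
    p2e = trios["p2_expressed"].to_numpy(dtype=bool)
    f1e = trios["f1_expressed"].to_numpy(dtype=bool)
    if not (p1e | p2e | f1e).all():
        n = int((~(p1e | p2e | f1e)).sum())
        raise ClassificationError(
            f"{n} trios with no expressed member; exclude them upstream"
        )

    n_parents = p1e.astype(np.int8) + p2e.astype(np.int8)
    model = np.select(
        [
            f1e & (n_parents == 2),
            f1e & (n_parents == 1),
            f1e & (n_parents == 0),
            ~f1e & (n_parents == 2),
        ],
        ["PHCE", "SPE", "HSE", "PCE"],
        default="PSE",
    )
    expressing_parent = np.select(
        [n_parents == 2, (n_parents == 1) & p1e, (n_parents == 1) & p2e],
        ["both", "parent1", "parent2"],
        default="none",
    )

    p1 = trios["p1_value"].to_numpy(dtype=float)
    p2 = trios["p2_value"].to_numpy(dtype=float)
    f1 = trios["f1_value"].to_numpy(dtype=float)
    p_max = np.maximum(p1, p2)
    p_min = np.minimum(p1, p2)

    phce = model == "PHCE"
    regular = phce & (p_max > p_min)
    degenerate = phce & (p_max == p_min)

    a_value = np.full(len(trios), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        a_value[regular] = (p_max[regular] - f1[regular]) / (
            p_max[regular] - p_min[regular]
        )

    category = np.full(len(trios), "", dtype=object)
    # digitize with the printed lower-inclusive bounds: A<0 -> 0 (PSD), ... A>=1 -> 6 (NSD)
    idx = np.digitize(a_value[regular], CATEGORY_BOUNDARIES, right=False)
    category[regular] = np.asarray(CATEGORIES, dtype=object)[idx]
    category[degenerate] = np.select(
        [f1[degenerate] > p_max[degenerate], f1[degenerate] < p_min[degenerate]],
        ["PSD", "NSD"],
        default="MP",
    )

    return pd.DataFrame(
        {
            "gene_id": trios["gene_id"].to_numpy(),
            "hybrid": trios["hybrid"].to_numpy(),
            "tissue": trios["tissue"].to_numpy(),
            "model": model,
            "expressing_parent": expressing_parent,
            "a_value": a_value,
            "category": category,
        }
    )


def terminal_classes(calls: pd.DataFrame) -> pd.Series:
    """11-way class labels for a call table: PAV model, or category for PHCE."""
    return pd.Series(
        np.where(calls["model"].to_numpy() == "PHCE", calls["category"], calls["model"]),
        index=calls.index,
        name="terminal_class",
    )


def write_calls(calls: pd.DataFrame, path) -> None:
    """Write a pattern-call table as TSV."""
    calls.to_csv(path, sep="\t", index=False, float_format="%.6g")
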