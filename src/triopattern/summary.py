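"""Diallel-wide summaries of pattern calls.

Four summary layers sit on top of the trio classifier:

* parental asymmetry — for a pair of inbreds, how many genes are more
  abundant in one parent than the other (and the ~3:1 type ratios);
* pattern-proportion tables per hybrid x tissue;
* focal-hybrid contrasts — a class proportion in one hybrid against the
  unweighted mean of the same proportion in all other hybrids;
* hybrid-specific gene sets — the Venn-exclusive region of each hybrid's
  qualifying set within a tissue.

The differential-expression rule used for the asymmetry counts and the
qualifying sets is a reconstruction (the source data state the comparison
but not its criterion): by default a fold-change rule
|log2((a+1)/(b+1))| >= 1 on replicate-mean FPKM, optionally tightened by a
Welch test on log2(FPKM+1) replicates with Benjamini-Hochberg FDR <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CATEGORIES, PAV_MODELS, QUALITATIVE_MODELS
from .io import EXPRESSION_THRESHOLD, ExpressionDataset, aggregate_replicates


class SummaryError(ValueError):
    """Raised on inputs that violate a summary operation's contract."""


def format_percent(x: float) -> str:
    """Percentage with two decimals, half-up rounding (e.g. 0.43725 -> '43.73').

    The proportion is converted to Decimal via its shortest repr before the
    x100 scaling, so decimal-looking inputs round the way a reader expects.
    """
    return str((Decimal(repr(x)) * 100).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# -- differential-expression rule -------------------------------------------


@dataclass(frozen=True)
class DegRule:
    """Criterion for calling a gene differential between two expression vectors.

    ``fold_change``: |log2((a+pc)/(b+pc))| >= min_abs_log2fc on aggregated means.
    ``welch``: the fold-change criterion plus a Welch two-sample t test on
    log2(FPKM+pc) replicate values with BH FDR <= alpha across genes.
    """

    method: Literal["fold_change", "welch"] = "fold_change"
    min_abs_log2fc: float = 1.0
    pseudocount: float = 1.0
    alpha: float = 0.05

    def passes(
        self,
        mean_a: np.ndarray,
        mean_b: np.ndarray,
        reps_a: Optional[np.ndarray] = None,
        reps_b: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Boolean per-gene mask of genes passing the rule."""
        lfc = np.log2((mean_a + self.pseudocount) / (mean_b + self.pseudocount))
        mask = np.abs(lfc) >= self.min_abs_log2fc
        if self.method == "welch":
            if reps_a is None or reps_b is None:
                raise SummaryError("welch rule needs replicate-level values")
            la = np.log2(reps_a + self.pseudocount)
            lb = np.log2(reps_b + self.pseudocount)
            res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
            pvals = np.nan_to_num(res.pvalue, nan=1.0)
            from statsmodels.stats.multitest import multipletests

            qvals = multipletests(pvals, method="fdr_bh")[1]
            mask = mask & (qvals <= self.alpha)
        return mask


# -- parental asymmetry ------------------------------------------------------


@dataclass
class ParentalAsymmetry:
    """Counts of genes more/less/equally abundant between two inbred parents."""

    parent_a: str
    parent_b: str
    tissue: str
    n_gt: int
    n_lt: int
    n_eq: int

    @property
    def ratio(self) -> float:
        if self.n_lt == 0:
            raise SummaryError("ratio undefined: no genes with a < b")
        return self.n_gt / self.n_lt


def parental_asymmetry(
    ds: ExpressionDataset,
    parent_a: str,
    parent_b: str,
    tissue: str,
    deg_rule: DegRule = DegRule(),
    threshold: float = EXPRESSION_THRESHOLD,
    expressed_only: bool = False,
) -> ParentalAsymmetry:
    """Count genes by abundance direction between two parents in one tissue.

    Genes failing the differential rule count as equal (``n_eq``); with
    ``expressed_only`` the comparison is restricted to genes expressed in at
    least one of the two parents.
    """
    prof_a = aggregate_replicates(ds, parent_a, tissue, threshold)
    prof_b = aggregate_replicates(ds, parent_b, tissue, threshold)
    mean_a = prof_a.values.to_numpy()
    mean_b = prof_b.values.to_numpy()

    keep = np.ones(len(mean_a), dtype=bool)
    if expressed_only:
        keep = prof_a.expressed.to_numpy() | prof_b.expressed.to_numpy()

    reps_a = ds.matrix[ds.sample_columns(parent_a, tissue)].to_numpy()
    reps_b = ds.matrix[ds.sample_columns(parent_b, tissue)].to_numpy()
    differential = deg_rule.passes(mean_a, mean_b, reps_a, reps_b)

    gt = keep & differential & (mean_a > mean_b)
    lt = keep & differential & (mean_a < mean_b)
    eq = keep & ~(gt | lt)
    return ParentalAsymmetry(
        parent_a=parent_a,
        parent_b=parent_b,
        tissue=tissue,
        n_gt=int(gt.sum()),
        n_lt=int(lt.sum()),
        n_eq=int(eq.sum()),
    )


def ratio_flags(
    asym: ParentalAsymmetry, target_ratio: float, tolerance: float = 0.1
) -> bool:
    """True iff n_gt/n_lt is within ``tolerance`` (relative) of ``target_ratio``."""
    if asym.n_lt == 0:
        raise SummaryError("ratio undefined: n_lt = 0")
    return abs(asym.n_gt / asym.n_lt - target_ratio) <= tolerance * target_ratio


# -- pattern proportions -----------------------------------------------------


@dataclass
class PatternSummary:
    """Counts and proportions of pattern calls for one hybrid x tissue."""

    hybrid: str
    tissue: str
    model_counts: dict[str, int]
    category_counts: dict[str, int]
    n_total: int = field(init=False)
    n_pav: int = field(init=False)
    n_phce: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_total = sum(self.model_counts.values())
        self.n_pav = sum(self.model_counts[m] for m in PAV_MODELS)
        self.n_phce = self.model_counts["PHCE"]

    @property
    def pav_proportion(self) -> float:
        """Share of PAV-type calls (PCE+PSE+HSE+SPE) among all calls."""
        return self.n_pav / self.n_total

    @property
    def pav_shares(self) -> dict[str, float]:
        """Each PAV model's share within the PAV calls."""
        if self.n_pav == 0:
            return {m: float("nan") for m in PAV_MODELS}
        return {m: self.model_counts[m] / self.n_pav for m in PAV_MODELS}

    @property
    def phce_shares(self) -> dict[str, float]:
        """Each dominance category's share within the PHCE calls."""
        if self.n_phce == 0:
            return {c: float("nan") for c in CATEGORIES}
        return {c: self.category_counts[c] / self.n_phce for c in CATEGORIES}

    def class_proportion(self, cls: str) -> float:
        """Proportion for one class label.

        PAV models are reported as within-PAV shares, dominance categories as
        within-PHCE shares, and the pseudo-class ``"PAV"`` as the PAV share of
        all calls — matching how the summaries are quoted per hybrid.
        """
        if cls == "PAV":
            return self.pav_proportion
        if cls in PAV_MODELS:
            return self.pav_shares[cls]
        if cls in CATEGORIES:
            return self.phce_shares[cls]
        raise SummaryError(f"unknown class {cls!r}")


def summarize_patterns(calls: pd.DataFrame, hybrid: str, tissue: str) -> PatternSummary:
    """Tabulate one hybrid x tissue slice of a pattern-call table."""
    sel = calls[(calls["hybrid"] == hybrid) & (calls["tissue"] == tissue)]
    if sel.empty:
        raise SummaryError(f"no calls for hybrid {hybrid!r} in tissue {tissue!r}")
    mc = sel["model"].value_counts()
    cc = sel.loc[sel["model"] == "PHCE", "category"].value_counts()
    return PatternSummary(
        hybrid=hybrid,
        tissue=tissue,
        model_counts={m: int(mc.get(m, 0)) for m in QUALITATIVE_MODELS},
        category_counts={c: int(cc.get(c, 0)) for c in CATEGORIES},
    )


def summaries_to_frame(summaries: list[PatternSummary]) -> pd.DataFrame:
    """Long-format table of all counts and proportions, one row per class."""
    rows = []
    for s in summaries:
        for m in QUALITATIVE_MODELS:
            rows.append((s.hybrid, s.tissue, "model", m, s.model_counts[m],
                         s.model_counts[m] / s.n_total))
        for m in PAV_MODELS:
            rows.append((s.hybrid, s.tissue, "pav_share", m, s.model_counts[m],
                         s.pav_shares[m]))
        for c in CATEGORIES:
            rows.append((s.hybrid, s.tissue, "phce_share", c, s.category_counts[c],
                         s.phce_shares[c]))
        rows.append((s.hybrid, s.tissue, "pav_of_all", "PAV", s.n_pav, s.pav_proportion))
    return pd.DataFrame(
        rows, columns=["hybrid", "tissue", "level", "class", "count", "proportion"]
    )


# -- focal contrasts ---------------------------------------------------------


@dataclass
class FocalContrast:
    """One class proportion in a focal hybrid vs the mean of the others."""

    focal_hybrid: str
    tissue: str
    cls: str
    focal_proportion: float
    rest_mean_proportion: float
    relative_excess: Optional[float]  # None when rest_mean == 0


def focal_contrast(
    summaries: list[PatternSummary], focal_hybrid: str, tissue: str, cls: str
) -> FocalContrast:
    """Contrast a class proportion in the focal hybrid against the rest.

    ``rest_mean`` is the unweighted arithmetic mean of the per-hybrid
    proportions over the non-focal hybrids (hybrids are averaged as units,
    not pooled by gene counts); ``relative_excess = focal/rest_mean - 1``.
    """
    in_tissue = [s for s in summaries if s.tissue == tissue]
    focal = [s for s in in_tissue if s.hybrid == focal_hybrid]
    rest = [s for s in in_tissue if s.hybrid != focal_hybrid]
    if not focal:
        raise SummaryError(f"no summary for focal hybrid {focal_hybrid!r} in {tissue!r}")
    if not rest:
        raise SummaryError("focal contrast needs at least one non-focal hybrid")
    focal_p = focal[0].class_proportion(cls)
    rest_mean = float(np.mean([s.class_proportion(cls) for s in rest]))
    excess = focal_p / rest_mean - 1.0 if rest_mean > 0 else None
    return FocalContrast(
        focal_hybrid=focal_hybrid,
        tissue=tissue,
        cls=cls,
        focal_proportion=focal_p,
        rest_mean_proportion=rest_mean,
        relative_excess=excess,
    )


def contrasts_to_frame(contrasts: list[FocalContrast]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.focal_hybrid, c.tissue, c.cls, c.focal_proportion,
             c.rest_mean_proportion,
             np.nan if c.relative_excess is None else c.relative_excess)
            for c in contrasts
        ],
        columns=["focal_hybrid", "tissue", "class", "focal_proportion",
                 "rest_mean_proportion", "relative_excess"],
    )


# -- hybrid-specific gene sets -----------------------------------------------


@dataclass
class SpecificGeneSet:
    """Genes exclusive to one hybrid's qualifying set within a tissue."""

    hybrid: str
    tissue: str
    gene_ids: frozenset[str]


def hybrid_specific_genes(
    qualifying_sets: Mapping[str, set[str]], tissue: str
) -> list[SpecificGeneSet]:
    """Venn-exclusive region per hybrid: genes in no other hybrid's set."""
    if len(qualifying_sets) < 2:
        raise SummaryError("need qualifying sets for at least two hybrids")
    hybrids = sorted(qualifying_sets)
    out = []
    for h in hybrids:
        others: set[str] = set()
        for o in hybrids:
            if o != h:
                others |= set(qualifying_sets[o])
        out.append(
            SpecificGeneSet(hybrid=h, tissue=tissue,
                            gene_ids=frozenset(set(qualifying_sets[h]) - others))
        )
    return out


def hybrid_deg_sets(
    trios: pd.DataFrame,
    calls: pd.DataFrame,
    deg_rule: DegRule = DegRule(),
) -> dict[str, set[str]]:
    """Qualifying gene set per hybrid: its differentially expressed genes.

    A gene qualifies for a hybrid if its trio call is a PAV model (an on/off
    difference is differential by construction) or if it is PHCE and the
    hybrid's mean differs from at least one parent under ``deg_rule``'s
    fold-change criterion.
    """
    merged = trios.merge(calls[["gene_id", "hybrid", "tissue", "model"]],
                         on=["gene_id", "hybrid", "tissue"])
    pc = deg_rule.pseudocount
    lfc1 = np.log2((merged["f1_value"] + pc) / (merged["p1_value"] + pc))
    lfc2 = np.log2((merged["f1_value"] + pc) / (merged["p2_value"] + pc))
    phce_deg = (merged["model"] == "PHCE") & (
        (lfc1.abs() >= deg_rule.min_abs_log2fc) | (lfc2.abs() >= deg_rule.min_abs_log2fc)
    )
    qualifying = merged["model"].isin(PAV_MODELS) | phce_deg
    sets: dict[str, set[str]] = {h: set() for h in merged["hybrid"].unique()}
    for h, genes in merged.loc[qualifying].groupby("hybrid")["gene_id"]:
        sets[h] = set(genes)
    return sets


def hybrid_expressed_sets(trios: pd.DataFrame) -> dict[str, set[str]]:
    """Alternative qualifying set: genes expressed in the hybrid."""
    on = trios.loc[trios["f1_expressed"]]
    return {h: set(g) for h, g in on.groupby("hybrid")["gene_id"]}
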