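"""Synthetic diallel FPKM datasets with planted expression patterns.

The generator emulates the study design the pipeline targets: 4 inbred
parents (Z, C, M, Q) crossed into the 6 NCII hybrids, 3 tissues (L, E, S),
3 biological replicates — 90 samples in the shared-parents layout.  For
each gene x cross x tissue a terminal pattern class is drawn from a
configurable mix over the 11 classes (4 PAV models + 7 dominance
categories), noise-free genotype means are planted to realize that class
exactly, and multiplicative log-normal replicate noise with a chosen CV is
added on top.

Planting rules
--------------
* "On" levels come from a log-normal baseline, floored well above the
  1-FPKM expression threshold; "off" levels are ``off_value`` (default 0).
* PHCE genes get a parental gap of at least 2-fold; the F1 mean is placed
  so the exact A value sits at the midpoint of the target category's
  interval (open-ended intervals use +/-0.3 beyond the boundary:
  PSD -> A = -0.3, NSD -> A = 1.3), keeping every planted gene at least
  0.1 away from the nearest category boundary.
* For NSD the parental fold is capped near 2 so the planted F1 stays
  safely above the expression threshold.

Because crosses share parents, exact per-cross pattern control is
impossible with only 10 genotypes; the default layout therefore plants
parental values per (gene, cross) into cross-specific parental
pseudo-genotypes (e.g. ``ZC_Z``).  A ``shared_parents`` mode instead
plants one value per true parent and lets hybrid patterns emerge, with the
ground truth recorded post hoc from the noise-free means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify
from .classify import CATEGORIES, PAV_MODELS, TERMINAL_CLASSES
from .io import (
    EXPRESSION_THRESHOLD,
    CrossSpec,
    ExpressionDataset,
    SampleMeta,
    write_dataset,
)

DEFAULT_PARENTS = ("Z", "C", "M", "Q")
DEFAULT_CROSSES = (
    CrossSpec("ZC", "Z", "C"),
    CrossSpec("ZM", "Z", "M"),
    CrossSpec("ZQ", "Z", "Q"),
    CrossSpec("CM", "C", "M"),
    CrossSpec("CQ", "C", "Q"),
    CrossSpec("MQ", "M", "Q"),
)
DEFAULT_TISSUES = ("L", "E", "S")

#: Exact A value planted for each dominance category: interval midpoints,
#: with the open-ended intervals placed 0.3 beyond their boundary.
A_TARGETS = {
    "PSD": -0.3,
    "PD": 0.1,
    "PPD": 0.3,
    "MP": 0.5,
    "PND": 0.7,
    "ND": 0.9,
    "NSD": 1.3,
}


class SimulationError(ValueError):
    """Raised on infeasible simulation configurations."""


def default_pattern_mix() -> dict[str, float]:
    """Default class mix echoing the reported diallel-wide proportions.

    PAV patterns make up 19.18% of classified genes, dominated by SPE
    (43.73% of PAVs) and PSE (41.07%); within the PHCE remainder the
    transgressive categories NSD (31.06%) and PSD (24.30%) lead, with the
    five middle categories sharing the rest equally.
    """
    pav_total = 0.1918
    pav_within = {"SPE": 0.4373, "PSE": 0.4107, "PCE": 0.10, "HSE": 0.052}
    phce_within = {"NSD": 0.3106, "PSD": 0.2430}
    middle = (1.0 - sum(phce_within.values())) / 5
    for c in ("PD", "PPD", "MP", "PND", "ND"):
        phce_within[c] = middle
    mix = {m: pav_total * s for m, s in pav_within.items()}
    mix.update({c: (1.0 - pav_total) * s for c, s in phce_within.items()})
    return mix


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``pattern_mix`` maps each of the 11 terminal classes to its target
    proportion; it may also be keyed per ``(hybrid, tissue)`` via
    ``pattern_mix_overrides`` to plant e.g. an elevated SPE share in one
    focal hybrid's seed tissue.
    """

    n_genes: int = 2000
    parents: Sequence[str] = DEFAULT_PARENTS
    crosses: Sequence[CrossSpec] = DEFAULT_CROSSES
    tissues: Sequence[str] = DEFAULT_TISSUES
    n_replicates: int = 3
    pattern_mix: Optional[dict[str, float]] = None
    pattern_mix_overrides: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=dict
    )
    baseline_log_mean: float = 3.0  # ln FPKM; e^3 ~ 20 FPKM typical "on" level
    baseline_log_sd: float = 0.8
    noise_cv: float = 0.1
    off_value: float = 0.0
    expression_threshold: float = EXPRESSION_THRESHOLD
    shared_parents: bool = False
    p_parent_off: float = 0.15  # shared-parents mode only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern_mix is None:
            self.pattern_mix = default_pattern_mix()
        for label, mix in [(None, self.pattern_mix)] + list(
            self.pattern_mix_overrides.items()
        ):
            _check_mix(mix, label)
        if self.noise_cv < 0:
            raise SimulationError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")
        if self.off_value >= self.expression_threshold:
            raise SimulationError(
                "off_value must lie below the expression threshold; otherwise "
                "PAV and transgressive plantings are infeasible"
            )

    def mix_for(self, hybrid: str, tissue: str) -> dict[str, float]:
        return self.pattern_mix_overrides.get((hybrid, tissue), self.pattern_mix)

    def to_yaml(self, path) -> None:
        d = {
            "n_genes": self.n_genes,
            "parents": list(self.parents),
            "crosses": [[c.hybrid, c.parent1, c.parent2] for c in self.crosses],
            "tissues": list(self.tissues),
            "n_replicates": self.n_replicates,
            "pattern_mix": self.pattern_mix,
            "pattern_mix_overrides": {
                f"{h}:{t}": m for (h, t), m in self.pattern_mix_overrides.items()
            },
            "baseline_log_mean": self.baseline_log_mean,
            "baseline_log_sd": self.baseline_log_sd,
            "noise_cv": self.noise_cv,
            "off_value": self.off_value,
            "expression_threshold": self.expression_threshold,
            "shared_parents": self.shared_parents,
            "p_parent_off": self.p_parent_off,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "crosses" in d:
            d["crosses"] = [CrossSpec(*c) for c in d["crosses"]]
        if "pattern_mix_overrides" in d:
            d["pattern_mix_overrides"] = {
                tuple(k.split(":")): v for k, v in d["pattern_mix_overrides"].items()
            }
        return cls(**d)


def _check_mix(mix: Mapping[str, float], label) -> None:
    unknown = set(mix) - set(TERMINAL_CLASSES)
    if unknown:
        raise SimulationError(f"pattern_mix {label or ''}: unknown classes {sorted(unknown)}")
    total = sum(mix.get(c, 0.0) for c in TERMINAL_CLASSES)
    if abs(total - 1.0) > 1e-9:
        raise SimulationError(f"pattern_mix {label or ''} sums to {total}, expected 1")
    if any(v < 0 for v in mix.values()):
        raise SimulationError("pattern_mix proportions must be >= 0")


# -- planting ---------------------------------------------------------------

# floors for "on" levels, in units of the expression threshold; PHCE Pmin is
# floored higher so the planted NSD F1 (0.7-0.76 x Pmin) stays clearly on
_ON_FLOOR = 2.0
_PHCE_PMIN_FLOOR = 2.5
# parental fold gap: >= 2 always; capped near 2 for NSD so F1 > 0 stays expressed
_FOLD_RANGE = (2.0, 6.0)
_FOLD_RANGE_NSD = (2.0, 2.2)


def _on_levels(rng: np.random.Generator, size: int, cfg: SimulationConfig,
               floor: float = _ON_FLOOR) -> np.ndarray:
    levels = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, size))
    return np.maximum(levels, floor * cfg.expression_threshold)


def _plant_trio_means(
    rng: np.random.Generator, classes: np.ndarray, cfg: SimulationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Noise-free (p1, p2, f1) means realizing each gene's planted class.

    Returns (p1, p2, f1, a_target); a_target is NaN for PAV classes.  Which
    parent carries the higher (or sole) expression is randomized per gene.
    """
    n = len(classes)
    off = cfg.off_value
    hi = np.full(n, off, dtype=float)   # higher/sole parent level
    lo = np.full(n, off, dtype=float)   # lower parent level
    f1 = np.full(n, off, dtype=float)
    a_target = np.full(n, np.nan)

    is_phce = np.isin(classes, CATEGORIES)
    idx = np.flatnonzero(is_phce)
    if idx.size:
        pmin = _on_levels(rng, idx.size, cfg, floor=_PHCE_PMIN_FLOOR)
        log_fold = rng.uniform(0.0, 1.0, idx.size)
        fold = np.empty(idx.size)
        nsd = classes[idx] == "NSD"
        fold[~nsd] = np.exp(
            math.log(_FOLD_RANGE[0])
            + log_fold[~nsd] * (math.log(_FOLD_RANGE[1]) - math.log(_FOLD_RANGE[0]))
        )
        fold[nsd] = _FOLD_RANGE_NSD[0] + log_fold[nsd] * (
            _FOLD_RANGE_NSD[1] - _FOLD_RANGE_NSD[0]
        )
        pmax = pmin * fold
        a = np.array([A_TARGETS[c] for c in classes[idx]])
        hi[idx] = pmax
        lo[idx] = pmin
        f1[idx] = pmax - a * (pmax - pmin)
        a_target[idx] = a

    for cls, parents_on, hybrid_on in (
        ("PCE", 2, False),
        ("PSE", 1, False),
        ("HSE", 0, True),
        ("SPE", 1, True),
    ):
        m = np.flatnonzero(classes == cls)
        if not m.size:
            continue
        if parents_on >= 1:
            hi[m] = _on_levels(rng, m.size, cfg)
        if parents_on == 2:
            lo[m] = _on_levels(rng, m.size, cfg)
        if hybrid_on:
            f1[m] = _on_levels(rng, m.size, cfg)

    # randomize which named parent is the high/sole expresser
    swap = rng.random(n) < 0.5
    p1 = np.where(swap, lo, hi)
    p2 = np.where(swap, hi, lo)
    return p1, p2, f1, a_target


def _noisy_replicates(
    rng: np.random.Generator, means: np.ndarray, n_replicates: int, cv: float
) -> np.ndarray:
    """(genes x replicates) matrix: mean x log-normal multiplier with unit mean."""
    reps = np.repeat(means[:, None], n_replicates, axis=1)
    if cv > 0:
        sigma = math.sqrt(math.log1p(cv**2))
        mult = np.exp(rng.normal(-sigma**2 / 2, sigma, reps.shape))
        reps = reps * mult
    return reps


# -- the generator -----------------------------------------------------------


def simulate(cfg: SimulationConfig) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Generate a dataset and its ground truth.

    Returns ``(dataset, truth)`` where ``truth`` has one row per classifiable
    gene x hybrid x tissue with columns ``gene_id, hybrid, tissue,
    true_model, true_class, a_target``.
    """
    rng = np.random.default_rng(cfg.seed)
    gene_ids = np.array([f"g{i:05d}" for i in range(cfg.n_genes)])
    if cfg.shared_parents:
        return _simulate_shared(cfg, rng, gene_ids)
    return _simulate_independent(cfg, rng, gene_ids)


def _draw_classes(
    rng: np.random.Generator, cfg: SimulationConfig, hybrid: str, tissue: str
) -> np.ndarray:
    mix = cfg.mix_for(hybrid, tissue)
    probs = np.array([mix.get(c, 0.0) for c in TERMINAL_CLASSES])
    return rng.choice(np.array(TERMINAL_CLASSES, dtype=object), size=cfg.n_genes,
                      p=probs / probs.sum())


def _simulate_independent(cfg, rng, gene_ids):
    columns: dict[str, np.ndarray] = {}
    samples: list[SampleMeta] = []
    design: list[CrossSpec] = []
    truth_rows = []

    def add_genotype(genotype: str, tissue: str, means: np.ndarray) -> None:
        reps = _noisy_replicates(rng, means, cfg.n_replicates, cfg.noise_cv)
        for r in range(cfg.n_replicates):
            sid = f"{genotype}_{tissue}{r + 1}"
            columns[sid] = reps[:, r]
            samples.append(SampleMeta(sid, genotype, tissue, r + 1))

    for cross in cfg.crosses:
        pseudo1 = f"{cross.hybrid}_{cross.parent1}"
        pseudo2 = f"{cross.hybrid}_{cross.parent2}"
        design.append(CrossSpec(cross.hybrid, pseudo1, pseudo2))
        for tissue in cfg.tissues:
            classes = _draw_classes(rng, cfg, cross.hybrid, tissue)
            p1, p2, f1, a_target = _plant_trio_means(rng, classes, cfg)
            add_genotype(pseudo1, tissue, p1)
            add_genotype(pseudo2, tissue, p2)
            add_genotype(cross.hybrid, tissue, f1)
            truth_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": gene_ids,
                        "hybrid": cross.hybrid,
                        "tissue": tissue,
                        "true_model": [
                            c if c in PAV_MODELS else "PHCE" for c in classes
                        ],
                        "true_class": classes,
                        "a_target": a_target,
                    }
                )
            )

    matrix = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    ds = ExpressionDataset(matrix=matrix, samples=samples, design=design)
    truth = pd.concat(truth_rows, ignore_index=True)
    return ds, truth


def _simulate_shared(cfg, rng, gene_ids):
    n = cfg.n_genes
    parent_means: dict[tuple[str, str], np.ndarray] = {}
    for parent in cfg.parents:
        for tissue in cfg.tissues:
            on = rng.random(n) >= cfg.p_parent_off
            means = np.where(on, _on_levels(rng, n, cfg), cfg.off_value)
            parent_means[(parent, tissue)] = means

    phce_within = {c: cfg.pattern_mix.get(c, 0.0) for c in CATEGORIES}
    phce_total = sum(phce_within.values())
    phce_probs = np.array(
        [phce_within[c] / phce_total if phce_total > 0 else 1 / 7 for c in CATEGORIES]
    )

    columns: dict[str, np.ndarray] = {}
    samples: list[SampleMeta] = []

    def add_genotype(genotype: str, tissue: str, means: np.ndarray) -> None:
        reps = _noisy_replicates(rng, means, cfg.n_replicates, cfg.noise_cv)
        for r in range(cfg.n_replicates):
            sid = f"{genotype}_{tissue}{r + 1}"
            columns[sid] = reps[:, r]
            samples.append(SampleMeta(sid, genotype, tissue, r + 1))

    thr = cfg.expression_threshold
    hybrid_means: dict[tuple[str, str], np.ndarray] = {}
    for cross in cfg.crosses:
        for tissue in cfg.tissues:
            p1 = parent_means[(cross.parent1, tissue)]
            p2 = parent_means[(cross.parent2, tissue)]
            p1_on, p2_on = p1 >= thr, p2 >= thr
            n_on = p1_on.astype(int) + p2_on.astype(int)
            f1 = np.full(n, cfg.off_value)
            u = rng.random(n)
            # both parents off: HSE with prob 0.5, else silent everywhere
            m = (n_on == 0) & (u < 0.5)
            f1[m] = _on_levels(rng, int(m.sum()), cfg)
            # one parent on: SPE with prob 0.5, else PSE (hybrid off)
            m = (n_on == 1) & (u < 0.5)
            f1[m] = _on_levels(rng, int(m.sum()), cfg)
            # both on: PCE with prob 0.05, else PHCE at a drawn A target
            both = n_on == 2
            phce = both & (u >= 0.05)
            cats = rng.choice(np.array(CATEGORIES, dtype=object),
                              size=int(phce.sum()), p=phce_probs)
            a = np.array([A_TARGETS[c] for c in cats])
            pmax = np.maximum(p1[phce], p2[phce])
            pmin = np.minimum(p1[phce], p2[phce])
            f1[phce] = np.maximum(pmax - a * (pmax - pmin), 0.0)
            hybrid_means[(cross.hybrid, tissue)] = f1

    for parent in cfg.parents:
        for tissue in cfg.tissues:
            add_genotype(parent, tissue, parent_means[(parent, tissue)])
    for cross in cfg.crosses:
        for tissue in cfg.tissues:
            add_genotype(cross.hybrid, tissue, hybrid_means[(cross.hybrid, tissue)])

    matrix = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    ds = ExpressionDataset(matrix=matrix, samples=samples, design=list(cfg.crosses))

    # ground truth post hoc: classify the noise-free means
    truth_rows = []
    for cross in cfg.crosses:
        for tissue in cfg.tissues:
            p1 = parent_means[(cross.parent1, tissue)]
            p2 = parent_means[(cross.parent2, tissue)]
            f1 = hybrid_means[(cross.hybrid, tissue)]
            trios = pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "hybrid": cross.hybrid,
                    "tissue": tissue,
                    "p1_value": p1,
                    "p2_value": p2,
                    "f1_value": f1,
                    "p1_expressed": p1 >= thr,
                    "p2_expressed": p2 >= thr,
                    "f1_expressed": f1 >= thr,
                }
            )
            any_on = trios.p1_expressed | trios.p2_expressed | trios.f1_expressed
            calls = classify.classify_trios(trios.loc[any_on].reset_index(drop=True))
            truth_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": calls["gene_id"],
                        "hybrid": cross.hybrid,
                        "tissue": tissue,
                        "true_model": calls["model"],
                        "true_class": classify.terminal_classes(calls),
                        "a_target": calls["a_value"],
                    }
                )
            )
    truth = pd.concat(truth_rows, ignore_index=True)
    return ds, truth


def write_simulation(
    cfg: SimulationConfig, outdir
) -> tuple[ExpressionDataset, pd.DataFrame, dict[str, Path]]:
    """Run :func:`simulate` and write matrix/samples/design/ground-truth TSVs."""
    outdir = Path(outdir)
    ds, truth = simulate(cfg)
    paths = write_dataset(ds, outdir)
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    truth.to_csv(paths["ground_truth"], sep="\t", index=False, float_format="%.6g")
    paths["config"] = outdir / "sim_config.yaml"
    cfg.to_yaml(paths["config"])
    return ds, truth, paths


# -- recovery scoring --------------------------------------------------------


@dataclass
class RecoveryReport:
    """Confusion matrix of planted vs called classes, plus overall accuracy.

    Rows are planted classes, columns called classes; the extra ``excluded``
    column counts planted trios the pipeline dropped (all three members
    below the expression threshold after noise), which score as errors.
    """

    confusion: pd.DataFrame
    accuracy: float
    n_total: int
    n_excluded: int

    def per_class_accuracy(self) -> pd.Series:
        totals = self.confusion.sum(axis=1)
        diag = pd.Series(
            [self.confusion.loc[c, c] for c in self.confusion.index],
            index=self.confusion.index,
        )
        return diag / totals.replace(0, np.nan)


def recovery_report(calls: pd.DataFrame, truth: pd.DataFrame) -> RecoveryReport:
    """Score a call table against planted truth on matching trio keys."""
    keys = ["gene_id", "hybrid", "tissue"]
    called = calls[keys].copy()
    called["called_class"] = classify.terminal_classes(calls).to_numpy()
    merged = truth[keys + ["true_class"]].merge(called, on=keys, how="outer",
                                                indicator=True)
    if (merged["_merge"] == "right_only").any():
        extra = merged.loc[merged["_merge"] == "right_only", keys].head()
        raise SimulationError(f"calls contain trios absent from truth, e.g.\n{extra}")
    merged["called_class"] = merged["called_class"].fillna("excluded")

    labels = list(TERMINAL_CLASSES)
    confusion = (
        pd.crosstab(merged["true_class"], merged["called_class"])
        .reindex(index=labels, columns=labels + ["excluded"], fill_value=0)
    )
    n_total = len(merged)
    n_correct = int(sum(confusion.loc[c, c] for c in labels))
    return RecoveryReport(
        confusion=confusion,
        accuracy=n_correct / n_total,
        n_total=n_total,
        n_excluded=int(confusion["excluded"].sum()),
    )


# -- demo annotations --------------------------------------------------------


def make_gene_sets(
    gene_ids: Sequence[str],
    n_sets: int = 25,
    mean_size: int = 40,
    seed: int = 0,
) -> dict[str, tuple[str, list[str]]]:
    """Random gene-set annotations over the given universe (synthetic, for
    exercising the enrichment stage; sizes are Poisson around ``mean_size``)."""
    rng = np.random.default_rng(seed)
    genes = np.asarray(gene_ids)
    out = {}
    for i in range(n_sets):
        size = max(5, int(rng.poisson(mean_size)))
        size = min(size, len(genes))
        members = sorted(rng.choice(genes, size=size, replace=False).tolist())
        out[f"SET{i:03d}"] = (f"synthetic pathway {i}", members)
    return out


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    lines = [
        "\t".join([set_id, name, *members])
        for set_id, (name, members) in sorted(sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")
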