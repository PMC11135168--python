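"""Dose-structured experiments built on the LLR pathway-activity scores.

These drivers reproduce the study designs a dose-response analysis needs:
per-dose contrasts against the unirradiated group, progressive inclusion of
low-dose groups in ascending or descending order, top-k ranked-list
intersection curves, the pooled low-dose joint contrast, and dose profiles
of selected pathways under a fixed trained contrast model.  All outputs are
long-format DataFrames ready for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .activity import (
    aggregated_differential_score,
    compute_llr,
    contrast_samples,
    fit_gene_gaussians,
    normalize_llr,
    orient_llr_by_class,
    pathway_activity_scores,
    rank_pathways,
    score_contrast,
)
from .io import DoseClass, ExpressionMatrix, GeneSetCollection, SampleAnnotation


@dataclass(frozen=True)
class RankedList:
    """A labelled ranking of pathways, best first, with aligned scores."""

    label: str
    pathway_ids: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.pathway_ids)) != len(self.pathway_ids):
            raise ValueError("ranked list contains duplicate pathway ids")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError("ranked-list scores must be non-increasing")

    @classmethod
    def from_table(cls, table: pd.DataFrame, label: str, score_col: str = "aggregated_score") -> "RankedList":
        ordered = table.sort_values("rank") if "rank" in table.columns else table
        return cls(label, tuple(ordered.index), tuple(float(v) for v in ordered[score_col]))


@dataclass(frozen=True)
class IntersectionCurve:
    """count(k) = size of the intersection of all lists' top-k prefixes."""

    k_values: tuple[int, ...]
    counts: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_values, "n_common": self.counts})


def _zero_vs_group(
    m: ExpressionMatrix,
    zero_ids: Sequence[str],
    group_ids: Sequence[str],
    gs: GeneSetCollection,
    subset: Sequence[str],
) -> pd.DataFrame:
    """Score a zero-vs-arbitrary-group contrast over a chosen scoring subset.

    The group is relabelled as the LOW class internally so the standard
    two-class machinery applies regardless of the group's actual doses.
    """
    ann = [
        SampleAnnotation(s, "na", 0.0, DoseClass.ZERO) for s in zero_ids
    ] + [SampleAnnotation(s, "na", 0.005, DoseClass.LOW) for s in group_ids]
    contrast = (DoseClass.ZERO, DoseClass.LOW)
    sub = m.subset_samples(list(zero_ids) + list(group_ids))
    model = fit_gene_gaussians(sub, ann, contrast)
    llr = orient_llr_by_class(normalize_llr(compute_llr(model, sub), model), ann, contrast)
    return aggregated_differential_score(llr, gs, subset)


def _samples_at_dose(annotations: Sequence[SampleAnnotation], dose: float) -> list[str]:
    return [a.sample_id for a in annotations if a.dose_gy == dose]


def per_dose_scores(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    gs: GeneSetCollection,
    doses: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Aggregated differential activity per pathway for each non-zero dose.

    Each dose group is contrasted against the zero-dose reference group and
    the t statistics are taken over that dose group's samples, giving a
    box-plot-ready long table (dose, pathway_id, aggregated_score,
    pathway_t, n_samples).
    """
    zero_ids = _samples_at_dose(annotations, 0.0)
    if doses is None:
        doses = sorted({a.dose_gy for a in annotations if a.dose_gy > 0})
    frames = []
    for dose in doses:
        group = _samples_at_dose(annotations, dose)
        if not group:
            raise ValueError(f"no samples at dose {dose} Gy")
        table = _zero_vs_group(m, zero_ids, group, gs, subset=group)
        table = table.reset_index()
        table.insert(0, "dose_gy", dose)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def progressive_inclusion(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    gs: GeneSetCollection,
    order: str = "ascending",
) -> pd.DataFrame:
    """Score growing unions of low-dose groups against the zero-dose group.

    The two-phenotype model is fitted once on the full zero-vs-low contrast;
    step i then takes the aggregated t statistics over the pooled samples of
    the first i low-dose groups in the requested dose order (``ascending``
    starts from the smallest dose, ``descending`` from the low/high
    threshold downwards).  Keeping the model fixed isolates what the steps
    are meant to show: the growth of the t magnitude as more low-dose
    samples support the same effect.
    """
    if order not in ("ascending", "descending"):
        raise ValueError(f"order must be ascending or descending, got {order!r}")
    zero_ids = _samples_at_dose(annotations, 0.0)
    low_doses = sorted(
        {a.dose_gy for a in annotations if a.dose_class == DoseClass.LOW},
        reverse=(order == "descending"),
    )
    if not low_doses:
        raise ValueError("no low-dose samples present")
    all_low = [s for d in low_doses for s in _samples_at_dose(annotations, d)]
    ann = [SampleAnnotation(s, "na", 0.0, DoseClass.ZERO) for s in zero_ids] + [
        SampleAnnotation(s, "na", 0.005, DoseClass.LOW) for s in all_low
    ]
    contrast = (DoseClass.ZERO, DoseClass.LOW)
    sub_m = m.subset_samples(zero_ids + all_low)
    model = fit_gene_gaussians(sub_m, ann, contrast)
    llr = orient_llr_by_class(normalize_llr(compute_llr(model, sub_m), model), ann, contrast)
    frames = []
    pooled: list[str] = []
    for step, dose in enumerate(low_doses, start=1):
        pooled = pooled + _samples_at_dose(annotations, dose)
        table = aggregated_differential_score(llr, gs, pooled).reset_index()
        table.insert(0, "doses_included", "+".join(str(d) for d in sorted(low_doses[:step])))
        table.insert(0, "step", step)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def topk_intersection(lists: Sequence[RankedList], k_max: int) -> IntersectionCurve:
    """Count pathways common to every list's top-k prefix, for k = 1..k_max."""
    if len(lists) < 2:
        raise ValueError("need at least two ranked lists")
    shortest = min(len(rl.pathway_ids) for rl in lists)
    if k_max > shortest:
        raise ValueError(f"k_max {k_max} exceeds shortest list length {shortest}")
    counts = []
    for k in range(1, k_max + 1):
        common = set(lists[0].pathway_ids[:k])
        for rl in lists[1:]:
            common &= set(rl.pathway_ids[:k])
        counts.append(len(common))
    return IntersectionCurve(tuple(range(1, k_max + 1)), tuple(counts))


def low_dose_joint_analysis(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    gs: GeneSetCollection,
) -> tuple[pd.DataFrame, RankedList]:
    """Pool all LOW-class samples into one contrast against ZERO and rank.

    Identical to the generic two-class analysis with LOW/ZERO labels; the
    t statistics use all contrast samples.
    """
    table = score_contrast(m, annotations, gs, (DoseClass.ZERO, DoseClass.LOW))
    return table, RankedList.from_table(table, "low_dose_joint")


def per_dose_ranked_lists(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    gs: GeneSetCollection,
    doses: Sequence[float] | None = None,
) -> dict[float, RankedList]:
    """Independent zero-vs-single-dose rankings, one list per dose."""
    long = per_dose_scores(m, annotations, gs, doses)
    lists = {}
    for dose, chunk in long.groupby("dose_gy"):
        ranked = rank_pathways(chunk.set_index("pathway_id"))
        lists[float(dose)] = RankedList.from_table(ranked, f"{dose}Gy")
    return lists


def dose_profile(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    gs: GeneSetCollection,
    pathway_ids: Sequence[str],
    model_contrast: tuple[DoseClass, DoseClass] = (DoseClass.ZERO, DoseClass.LOW),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply one trained contrast model unchanged to samples of every dose.

    The two-class model is fitted on the ``model_contrast`` samples only and
    its standardised LLRs are then evaluated for all samples.  Scores are
    reported on the convention that positive S_j favours the *dosed*
    (second) class.  Returns a violin-plot-ready long table
    (dose_gy, sample_id, pathway_id, s_j) and a per-dose summary with mean
    and median.
    """
    unknown = [p for p in pathway_ids if p not in gs]
    if unknown:
        raise ValueError(f"unknown pathway ids: {unknown}")
    ids1, ids2 = contrast_samples(annotations, model_contrast)
    fit_m = m.subset_samples(ids1 + ids2)
    model = fit_gene_gaussians(fit_m, annotations, model_contrast)
    llr = normalize_llr(compute_llr(model, m), model)
    sub = GeneSetCollection()
    for pid in pathway_ids:
        sub.add(pid, gs.name(pid), gs.members(pid))
    scores = pathway_activity_scores(llr, sub)
    dose_by_sample = {a.sample_id: a.dose_gy for a in annotations}
    long = scores.reset_index(names="pathway_id").melt(
        id_vars="pathway_id", var_name="sample_id", value_name="s_j"
    )
    # positive S favours the dosed (second contrast) class
    long["s_j"] = -long["s_j"]
    long.insert(0, "dose_gy", long["sample_id"].map(dose_by_sample))
    summary = (
        long.groupby(["pathway_id", "dose_gy"])["s_j"]
        .agg(mean="mean", median="median", n="size")
        .reset_index()
    )
    return long, summary
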