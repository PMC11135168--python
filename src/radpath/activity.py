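"""Probabilistic pathway activity inference from two-phenotype gene LLRs.

For a contrast of two phenotype classes (e.g. unirradiated vs low dose),
each gene's expression is modelled as Gaussian within each class.  The
per-gene log-likelihood ratio

    L_k(x) = ln f_k^1(x) - ln f_k^2(x)

says which phenotype an observed expression value favours.  Raw LLRs are
standardised gene-wise to zero mean and unit second moment over the
contrast samples, class-oriented (class-2 samples negated, so a genuine
difference pushes every sample's score positive), and summed over a
pathway's member genes to give the per-sample pathway activity score

    S_j = sum_k Lhat_k(x_{j,k}).

A pathway's discriminative power is summarised by the aggregated
differential activity score: the mean over member genes of the absolute
one-sample t statistic of the oriented standardised LLRs against mean 0.
Without the standardisation and orientation the sign of the summed LLR is
exactly the decision statistic of an equal-prior Gaussian naive Bayes
classifier; the standardisation is what makes the scheme diverge from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DoseClass, ExpressionMatrix, GeneSetCollection, SampleAnnotation

#: Floor applied to every standard deviation to guard zero-variance genes.
SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class GeneLLRModel:
    """Per-gene two-class Gaussian parameters and LLR standardisation constants.

    All arrays are aligned with ``gene_ids``.  ``norm_mean``/``norm_sd`` are
    the first moment and root second central moment (population convention)
    of the raw LLR over the pooled contrast samples used for fitting.
    """

    gene_ids: tuple[str, ...]
    contrast: tuple[DoseClass, DoseClass]
    mu1: np.ndarray
    sd1: np.ndarray
    mu2: np.ndarray
    sd2: np.ndarray
    norm_mean: np.ndarray
    norm_sd: np.ndarray

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass(frozen=True)
class LLRMatrix:
    """Genes x samples matrix of (possibly standardised/oriented) LLR values."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    normalized: bool = False
    class_oriented: bool = False

    def sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}


def contrast_samples(
    annotations: Sequence[SampleAnnotation], contrast: tuple[DoseClass, DoseClass]
) -> tuple[list[str], list[str]]:
    """Sample ids of the two contrast classes, in annotation order."""
    c1, c2 = contrast
    ids1 = [a.sample_id for a in annotations if a.dose_class == c1]
    ids2 = [a.sample_id for a in annotations if a.dose_class == c2]
    return ids1, ids2


def fit_gene_gaussians(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    contrast: tuple[DoseClass, DoseClass],
    sigma_floor: float = SIGMA_FLOOR,
) -> GeneLLRModel:
    """Fit per-gene, per-class Gaussians and LLR standardisation constants.

    Class parameters are the sample mean and population (ddof=0) standard
    deviation within each class, floored at ``sigma_floor``.  The
    standardisation constants are the mean and root mean squared deviation
    of the raw LLR over all pooled contrast samples — the same samples the
    Gaussians were fitted on.
    """
    ids1, ids2 = contrast_samples(annotations, contrast)
    for label, ids in zip(contrast, (ids1, ids2)):
        if len(ids) < 2:
            raise ValueError(f"contrast class {label} has {len(ids)} samples; need >= 2")

    x1 = m.subset_samples(ids1).values
    x2 = m.subset_samples(ids2).values
    mu1, sd1 = np.nanmean(x1, axis=1), np.nanstd(x1, axis=1)
    mu2, sd2 = np.nanmean(x2, axis=1), np.nanstd(x2, axis=1)
    sd1 = np.maximum(np.nan_to_num(sd1), sigma_floor)
    sd2 = np.maximum(np.nan_to_num(sd2), sigma_floor)
    mu1, mu2 = np.nan_to_num(mu1), np.nan_to_num(mu2)

    pooled = m.subset_samples(ids1 + ids2).values
    raw = _gaussian_llr(pooled, mu1, sd1, mu2, sd2)
    norm_mean = np.nanmean(raw, axis=1)
    norm_sd = np.sqrt(np.nanmean((raw - norm_mean[:, None]) ** 2, axis=1))
    norm_sd = np.maximum(np.nan_to_num(norm_sd), sigma_floor)
    norm_mean = np.nan_to_num(norm_mean)

    return GeneLLRModel(
        gene_ids=m.gene_ids,
        contrast=contrast,
        mu1=mu1,
        sd1=sd1,
        mu2=mu2,
        sd2=sd2,
        norm_mean=norm_mean,
        norm_sd=norm_sd,
    )


def _gaussian_llr(
    x: np.ndarray, mu1: np.ndarray, sd1: np.ndarray, mu2: np.ndarray, sd2: np.ndarray
) -> np.ndarray:
    """ln N(x; mu1, sd1) - ln N(x; mu2, sd2), vectorised genes x samples."""
    mu1, sd1 = mu1[:, None], sd1[:, None]
    mu2, sd2 = mu2[:, None], sd2[:, None]
    return (
        -np.log(sd1)
        - 0.5 * ((x - mu1) / sd1) ** 2
        + np.log(sd2)
        + 0.5 * ((x - mu2) / sd2) ** 2
    )


def compute_llr(model: GeneLLRModel, m: ExpressionMatrix) -> LLRMatrix:
    """Raw per-gene LLRs (natural log) for every sample of ``m``.

    Genes of ``m`` missing from the model are omitted with a warning; a
    not-detected expression value yields an LLR of 0 (uninformative).
    """
    model_idx = model.gene_index()
    keep = [g for g in m.gene_ids if g in model_idx]
    dropped = len(m.gene_ids) - len(keep)
    if dropped:
        warnings.warn(f"{dropped} genes absent from the LLR model were omitted")
    rows = [model_idx[g] for g in keep]
    sub = m.subset_genes(keep)
    raw = _gaussian_llr(
        sub.values, model.mu1[rows], model.sd1[rows], model.mu2[rows], model.sd2[rows]
    )
    raw = np.nan_to_num(raw)
    return LLRMatrix(tuple(keep), m.sample_ids, raw)


def normalize_llr(llr: LLRMatrix, model: GeneLLRModel) -> LLRMatrix:
    """Standardise each gene's LLRs by the model's stored moments."""
    if llr.normalized:
        raise ValueError("LLR matrix is already normalized")
    model_idx = model.gene_index()
    rows = [model_idx[g] for g in llr.gene_ids]
    mean = model.norm_mean[rows][:, None]
    sd = model.norm_sd[rows][:, None]
    if np.any(sd <= SIGMA_FLOOR):
        warnings.warn("normalisation sd at floor for some genes")
    return replace(llr, values=(llr.values - mean) / sd, normalized=True)


def orient_llr_by_class(
    llr: LLRMatrix,
    annotations: Sequence[SampleAnnotation],
    contrast: tuple[DoseClass, DoseClass],
) -> LLRMatrix:
    """Negate class-2 samples' LLRs so both classes score positive under a
    genuine difference (class-1 samples keep f1/f2, class-2 use f2/f1)."""
    c1, c2 = contrast
    by_id = {a.sample_id: a.dose_class for a in annotations}
    signs = np.empty(len(llr.sample_ids))
    for j, sid in enumerate(llr.sample_ids):
        cls = by_id.get(sid)
        if cls == c1:
            signs[j] = 1.0
        elif cls == c2:
            signs[j] = -1.0
        else:
            raise ValueError(f"sample {sid} is not labelled with a contrast class")
    return replace(llr, values=llr.values * signs[None, :], class_oriented=not llr.class_oriented)


def pathway_activity_scores(llr: LLRMatrix, gs: GeneSetCollection) -> pd.DataFrame:
    """Per-sample pathway activity S_j = sum of member-gene LLR entries.

    Returns a pathways x samples DataFrame indexed by pathway id.
    """
    gene_idx = {g: i for i, g in enumerate(llr.gene_ids)}
    rows = []
    for pid in gs.pathway_ids():
        members = [gene_idx[g] for g in gs.members(pid) if g in gene_idx]
        rows.append(llr.values[members, :].sum(axis=0) if members else np.zeros(len(llr.sample_ids)))
    return pd.DataFrame(rows, index=gs.pathway_ids(), columns=list(llr.sample_ids))


def _one_sample_t(values: np.ndarray, axis: int = -1, sigma_floor: float = SIGMA_FLOOR) -> np.ndarray:
    """t = mean / (sd / sqrt(n)) against mean 0, sample sd (ddof=1), floored."""
    n = values.shape[axis]
    mean = values.mean(axis=axis)
    sd = values.std(axis=axis, ddof=1)
    floored = np.maximum(sd, sigma_floor)
    if np.any(sd < sigma_floor):
        warnings.warn("zero-variance values in t statistic; sd floored")
    return mean / (floored / np.sqrt(n))


def aggregated_differential_score(
    llr: LLRMatrix,
    gs: GeneSetCollection,
    sample_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Aggregated differential activity score per pathway over a sample subset.

    Per member gene, the one-sample t statistic of its (oriented,
    standardised) LLRs over the subset against mean 0; the pathway's
    ``aggregated_score`` is the mean absolute t over member genes.  The
    one-sample t of the summed pathway score S_j over the same subset is
    reported alongside as ``pathway_t`` — the pathway-level reading of the
    same null.
    """
    subset = list(sample_subset) if sample_subset is not None else list(llr.sample_ids)
    if len(subset) < 2:
        raise ValueError("sample subset must contain >= 2 samples")
    col_idx = llr.sample_index()
    cols = [col_idx[s] for s in subset]
    sub = llr.values[:, cols]
    gene_idx = {g: i for i, g in enumerate(llr.gene_ids)}

    records = []
    gene_t_by_pathway: dict[str, dict[str, float]] = {}
    for pid in gs.pathway_ids():
        member_genes = sorted(g for g in gs.members(pid) if g in gene_idx)
        members = [gene_idx[g] for g in member_genes]
        if not members:
            records.append((pid, gs.name(pid), 0, 0.0, 0.0, len(subset)))
            gene_t_by_pathway[pid] = {}
            continue
        gene_t = _one_sample_t(sub[members, :], axis=1)
        s_j = sub[members, :].sum(axis=0)
        pathway_t = float(_one_sample_t(s_j))
        records.append(
            (pid, gs.name(pid), len(members), float(np.abs(gene_t).mean()), pathway_t, len(subset))
        )
        gene_t_by_pathway[pid] = dict(zip(member_genes, (float(t) for t in np.atleast_1d(gene_t))))

    table = pd.DataFrame(
        records,
        columns=["pathway_id", "name", "n_members", "aggregated_score", "pathway_t", "n_samples"],
    ).set_index("pathway_id")
    table.attrs["gene_t"] = gene_t_by_pathway
    return table


def rank_pathways(table: pd.DataFrame, rank_by: str = "aggregated_score") -> pd.DataFrame:
    """Rank pathways by descending score (ties by pathway id) and add p-values.

    Two-sided p-values come from the pathway-level one-sample t against
    Student's t with n-1 degrees of freedom; Benjamini-Hochberg adjusted
    p-values are reported alongside.
    """
    if rank_by not in table.columns:
        raise ValueError(f"rank_by column {rank_by!r} not in table")
    out = table.sort_values([rank_by, "pathway_id"], ascending=[False, True], kind="mergesort")
    out = out.copy()
    df = out["n_samples"] - 1
    out["p_value"] = 2.0 * stats.t.sf(np.abs(out["pathway_t"]), df)
    out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1] if len(out) else []
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def score_contrast(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    gs: GeneSetCollection,
    contrast: tuple[DoseClass, DoseClass],
    sample_subset: Sequence[str] | None = None,
    rank_by: str = "aggregated_score",
) -> pd.DataFrame:
    """Full pipeline for one contrast: fit, LLR, standardise, orient, score, rank.

    ``sample_subset`` defaults to all contrast samples.
    """
    ids1, ids2 = contrast_samples(annotations, contrast)
    sub = m.subset_samples(ids1 + ids2)
    model = fit_gene_gaussians(sub, annotations, contrast)
    llr = orient_llr_by_class(normalize_llr(compute_llr(model, sub), model), annotations, contrast)
    table = aggregated_differential_score(llr, gs, sample_subset)
    return rank_pathways(table, rank_by=rank_by)
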