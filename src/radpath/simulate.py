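"""Synthetic dose-structured expression studies with planted pathway effects.

The generator emulates the design of a blood-irradiation study: seven dose
levels (0 to 0.5 Gy) with fixed per-dose sample counts, per-gene Gaussian
log-scale expression, and coordinated mean shifts confined to designated
"responsive" pathways.  Low-responsive pathways follow a monotone
dose-response curve over the low-dose range (saturating by default) that
stays flat beyond it; high-responsive pathways switch on only above the
low/high threshold.  The two responsive sets are disjoint by default, so the
zero-vs-low and zero-vs-high contrasts have distinct planted answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import (
    DEFAULT_DOSE_THRESHOLD_GY,
    ExpressionMatrix,
    GeneSetCollection,
    SampleAnnotation,
    assign_dose_class,
    write_annotations,
    write_expression_matrix,
    write_gmt,
)

#: Dose levels (Gy) of the emulated study design.
DEFAULT_DOSE_LEVELS_GY = (0.0, 0.005, 0.01, 0.025, 0.05, 0.1, 0.5)
#: Per-dose sample counts of the emulated design (121 samples in total).
DEFAULT_SAMPLES_PER_DOSE = (18, 16, 18, 18, 17, 18, 16)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    ``effect_size`` is the planted mean shift in units of the gene's
    baseline standard deviation at full response (curve value 1).
    ``effect_curve`` shapes the dose dependence of low-responsive pathways
    over the low-dose range: ``saturating`` (half-maximal at ``d_half``),
    ``linear``, or ``step``.
    """

    n_genes: int = 1000
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 40)
    gene_overlap_allowed: bool = True
    dose_levels_gy: tuple[float, ...] = DEFAULT_DOSE_LEVELS_GY
    samples_per_dose: tuple[int, ...] = DEFAULT_SAMPLES_PER_DOSE
    low_responsive_pathways: frozenset[str] = frozenset()
    high_responsive_pathways: frozenset[str] = frozenset()
    effect_size: float = 0.8
    effect_curve: str = "saturating"
    d_half_gy: float = 0.05
    noise_sd: float = 1.0
    dose_threshold_gy: float = DEFAULT_DOSE_THRESHOLD_GY
    baseline_mean: tuple[float, float] = (7.0, 2.0)
    baseline_sd_range: tuple[float, float] = (0.3, 1.0)
    donor_effect_sd: float = 0.0
    n_donors: int = 5
    not_detected_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_dose) != len(self.dose_levels_gy):
            raise ValueError("samples_per_dose must align 1:1 with dose_levels_gy")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid pathway size range {self.pathway_size_range}")
        if self.effect_curve not in ("linear", "saturating", "step"):
            raise ValueError(f"unknown effect_curve {self.effect_curve!r}")


@dataclass
class GroundTruth:
    """Planted answers: responsive pathways per contrast and per-gene shifts.

    ``shift_by_dose[d][k]`` is the mean shift (expression units) applied to
    gene index ``k`` at dose ``d``.
    """

    low_responsive: frozenset[str]
    high_responsive: frozenset[str]
    responsive_by_contrast: dict[str, frozenset[str]] = field(default_factory=dict)
    shift_by_dose: dict[float, np.ndarray] = field(default_factory=dict)


def default_responsive_ids(n_pathways: int, n_low: int = 3, n_high: int = 3) -> tuple[frozenset[str], frozenset[str]]:
    """Disjoint low-/high-responsive pathway ids from the generated naming."""
    if n_low + n_high > n_pathways:
        raise ValueError("more responsive pathways requested than exist")
    ids = [_pathway_id(i, n_pathways) for i in range(n_pathways)]
    return frozenset(ids[:n_low]), frozenset(ids[n_low : n_low + n_high])


def _pathway_id(i: int, n_pathways: int) -> str:
    width = max(3, len(str(n_pathways)))
    return f"path{i:0{width}d}"


def generate_gene_sets(cfg: SyntheticConfig) -> GeneSetCollection:
    """Draw ``cfg.n_pathways`` gene sets with sizes uniform in the size range.

    Without overlap the sets partition a prefix of the gene pool, so the
    total size must fit in ``n_genes``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_pathways)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    gs = GeneSetCollection()
    if cfg.gene_overlap_allowed:
        for i, size in enumerate(sizes):
            pid = _pathway_id(i, cfg.n_pathways)
            members = rng.choice(cfg.n_genes, size=size, replace=False)
            gs.add(pid, f"synthetic pathway {i}", [genes[k] for k in members])
    else:
        if sizes.sum() > cfg.n_genes:
            raise ValueError(
                f"disjoint pathways need {sizes.sum()} genes but only {cfg.n_genes} exist"
            )
        cursor = 0
        for i, size in enumerate(sizes):
            pid = _pathway_id(i, cfg.n_pathways)
            gs.add(pid, f"synthetic pathway {i}", genes[cursor : cursor + size])
            cursor += size
    return gs


def effect_curve_value(cfg: SyntheticConfig, dose_gy: float, responsive_class: str) -> float:
    """Fraction of the full effect applied at ``dose_gy``.

    Low-responsive: monotone curve with value 0 at dose 0 and 1 at the
    low/high threshold, flat at 1 above it.  High-responsive: 0 up to the
    threshold, 1 above.
    """
    if dose_gy < 0:
        raise ValueError("negative dose")
    if responsive_class == "high":
        return 1.0 if dose_gy > cfg.dose_threshold_gy else 0.0
    if responsive_class != "low":
        raise ValueError(f"unknown responsive class {responsive_class!r}")
    if dose_gy == 0:
        return 0.0
    d_max = cfg.dose_threshold_gy
    if cfg.effect_curve == "step":
        return 1.0
    if cfg.effect_curve == "linear":
        return min(dose_gy / d_max, 1.0)
    raw = dose_gy / (dose_gy + cfg.d_half_gy)
    return min(raw / (d_max / (d_max + cfg.d_half_gy)), 1.0)


def generate_dataset(
    cfg: SyntheticConfig, gs: GeneSetCollection
) -> tuple[ExpressionMatrix, list[SampleAnnotation], GroundTruth]:
    """Simulate expression under the per-gene Gaussian model with planted shifts.

    Baseline gene k is Normal(mu_k, sigma_k) with mu_k ~ Normal(7, 2) and
    sigma_k ~ Uniform(0.3, 1.0) drawn once per gene.  Member genes of a
    responsive pathway receive a mean shift of
    ``effect_size * sigma_k * curve(dose)``.  Bit-identical under a fixed
    seed.
    """
    for pid in cfg.low_responsive_pathways | cfg.high_responsive_pathways:
        if pid not in gs:
            raise ValueError(f"responsive pathway {pid!r} not in the gene-set collection")
    rng = np.random.default_rng(cfg.seed + 1)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}

    mu = rng.normal(cfg.baseline_mean[0], cfg.baseline_mean[1], size=cfg.n_genes)
    sigma = rng.uniform(*cfg.baseline_sd_range, size=cfg.n_genes) * cfg.noise_sd

    # Per-gene full-response shift for each responsive class; a gene in
    # several responsive pathways of the same class shifts once.
    shift_full = {"low": np.zeros(cfg.n_genes), "high": np.zeros(cfg.n_genes)}
    for cls, pids in (("low", cfg.low_responsive_pathways), ("high", cfg.high_responsive_pathways)):
        members: set[str] = set()
        for pid in pids:
            members |= gs.members(pid)
        for g in members:
            if g in gene_index:
                k = gene_index[g]
                shift_full[cls][k] = cfg.effect_size * sigma[k]

    annotations: list[SampleAnnotation] = []
    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    shift_by_dose: dict[float, np.ndarray] = {}
    donor_offsets = (
        rng.normal(0.0, cfg.donor_effect_sd, size=cfg.n_donors)
        if cfg.donor_effect_sd > 0
        else np.zeros(cfg.n_donors)
    )

    counter = 0
    for dose, n_samples in zip(cfg.dose_levels_gy, cfg.samples_per_dose):
        shift = (
            shift_full["low"] * effect_curve_value(cfg, dose, "low")
            + shift_full["high"] * effect_curve_value(cfg, dose, "high")
        )
        shift_by_dose[dose] = shift
        for _ in range(n_samples):
            donor = counter % cfg.n_donors
            sid = f"s{counter:04d}"
            x = rng.normal(mu + shift + donor_offsets[donor], sigma)
            columns.append(x)
            sample_ids.append(sid)
            annotations.append(
                assign_dose_class(
                    SampleAnnotation(sid, f"donor{donor}", float(dose)), cfg.dose_threshold_gy
                )
            )
            counter += 1

    values = np.column_stack(columns)
    if cfg.not_detected_fraction > 0:
        mask = rng.random(values.shape) < cfg.not_detected_fraction
        values = np.where(mask, np.nan, values)

    matrix = ExpressionMatrix(tuple(genes), tuple(sample_ids), values)
    truth = GroundTruth(
        low_responsive=frozenset(cfg.low_responsive_pathways),
        high_responsive=frozenset(cfg.high_responsive_pathways),
        responsive_by_contrast={
            "zero_vs_low": frozenset(cfg.low_responsive_pathways),
            "zero_vs_high": frozenset(cfg.low_responsive_pathways | cfg.high_responsive_pathways),
        },
        shift_by_dose=shift_by_dose,
    )
    return matrix, annotations, truth


def write_study(
    cfg: SyntheticConfig, out_dir: str | Path
) -> tuple[ExpressionMatrix, list[SampleAnnotation], GroundTruth]:
    """Generate a complete study and write expression/annotations/GMT files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gs = generate_gene_sets(cfg)
    matrix, annotations, truth = generate_dataset(cfg, gs)
    write_expression_matrix(matrix, out / "expression.tsv")
    write_annotations(annotations, out / "annotations.tsv")
    write_gmt(gs, out / "pathways.gmt")
    return matrix, annotations, truth
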