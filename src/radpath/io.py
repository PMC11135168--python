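"""Input/output and filtering for dose-structured expression studies.

Expression matrices are genes x samples, log-scale, read from TSV/CSV with
the first column holding gene identifiers and the header row holding sample
identifiers.  Cells that the platform did not detect are carried as NaN.
Gene sets come from standard GMT files; sample annotations from a TSV with
columns ``sample_id``, ``donor_id``, ``dose_gy``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Tokens interpreted as "not detected" when reading expression tables
#: (case-insensitive).  The detection call of the original platform is not
#: part of the file format, so this is a configurable convention.
DEFAULT_NA_TOKENS = ("", "na", "nan", "null")

#: Dose (Gy) separating the low-dose from the high-dose regime, inclusive on
#: the low side: regulatory guidance places "low dose" at or below 0.1 Gy.
DEFAULT_DOSE_THRESHOLD_GY = 0.1


class DoseClass(enum.Enum):
    """Exposure category of a sample: unirradiated, low dose, or high dose."""

    ZERO = "zero"
    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log-scale expression values for ``gene_ids`` (rows) x ``sample_ids``.

    ``values[i, j]`` is the expression of gene ``gene_ids[i]`` in sample
    ``sample_ids[j]``; NaN marks a value the platform did not detect.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for label, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {label} ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.sample_index()
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, tuple(sample_ids), self.values[:, cols])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(tuple(gene_ids), self.sample_ids, self.values[rows, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample metadata: donor, absorbed dose in Gy, and dose class."""

    sample_id: str
    donor_id: str
    dose_gy: float
    dose_class: DoseClass | None = None

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ValueError(f"negative dose for sample {self.sample_id}: {self.dose_gy}")


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways): id -> (display name, member gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self.sets

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id][1]

    def name(self, pathway_id: str) -> str:
        return self.sets[pathway_id][0]

    def pathway_ids(self) -> list[str]:
        return list(self.sets)

    def add(self, pathway_id: str, name: str, members: Iterable[str]) -> None:
        if pathway_id in self.sets:
            raise ValueError(f"duplicate pathway id {pathway_id!r}")
        memberset = frozenset(members)
        if not memberset:
            raise ValueError(f"pathway {pathway_id!r} has no members")
        self.sets[pathway_id] = (name, memberset)


def read_expression_matrix(
    path: str | Path,
    dialect: str = "tsv",
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS,
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    Parameters
    ----------
    path
        TSV/CSV file; header row = sample ids, first column = gene ids.
    dialect
        ``"tsv"`` or ``"csv"``.
    na_tokens
        Case-insensitive cell tokens parsed as not-detected (NaN).
    transpose
        Set when the file is samples x genes.
    """
    sep = {"tsv": "\t", "csv": ","}[dialect]
    na_values = sorted({t for tok in na_tokens for t in (tok, tok.upper(), tok.lower(), tok.capitalize())})
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=na_values, keep_default_na=False, dtype=str
    )
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    values = df.apply(pd.to_numeric, axis=0).to_numpy(dtype=float)
    return ExpressionMatrix(
        gene_ids=tuple(str(g) for g in df.index),
        sample_ids=tuple(str(s) for s in df.columns),
        values=values,
    )


def write_expression_matrix(m: ExpressionMatrix, path: str | Path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    m.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line ``name TAB description TAB gene ...``.

    Duplicate genes within one line are counted once.  Lines with fewer than
    three fields are rejected with the offending line number.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            pathway_id, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            collection.add(pathway_id, description, genes)
    return collection


def write_gmt(gs: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in gs.pathway_ids():
            members = sorted(gs.members(pid))
            fh.write("\t".join([pid, gs.name(pid), *members]) + "\n")


def read_annotations(path: str | Path, threshold_gy: float = DEFAULT_DOSE_THRESHOLD_GY) -> list[SampleAnnotation]:
    """Read a sample annotation TSV (sample_id, donor_id, dose_gy)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    required = {"sample_id", "donor_id", "dose_gy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    return [
        assign_dose_class(
            SampleAnnotation(str(r.sample_id), str(r.donor_id), float(r.dose_gy)),
            threshold_gy,
        )
        for r in df.itertuples()
    ]


def write_annotations(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "donor_id": [a.donor_id for a in annotations],
            "dose_gy": [a.dose_gy for a in annotations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def assign_dose_class(
    a: SampleAnnotation, low_high_threshold_gy: float = DEFAULT_DOSE_THRESHOLD_GY
) -> SampleAnnotation:
    """Classify a sample's dose: 0 -> ZERO, (0, threshold] -> LOW, above -> HIGH."""
    if a.dose_gy < 0:
        raise ValueError(f"negative dose: {a.dose_gy}")
    if a.dose_gy == 0:
        cls = DoseClass.ZERO
    elif a.dose_gy <= low_high_threshold_gy:
        cls = DoseClass.LOW
    else:
        cls = DoseClass.HIGH
    return replace(a, dose_class=cls)


def filter_undetected_genes(m: ExpressionMatrix, frac: float = 0.75) -> ExpressionMatrix:
    """Drop genes not detected in at least ``frac`` of samples (inclusive).

    Emulates detection-based probe filtering: a gene whose NaN fraction is
    ``>= frac`` is removed.  Sample set and surviving gene order are kept.
    """
    if not 0 < frac <= 1:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    nan_frac = np.isnan(m.values).mean(axis=1)
    keep = nan_frac < frac
    return ExpressionMatrix(
        gene_ids=tuple(g for g, k in zip(m.gene_ids, keep) if k),
        sample_ids=m.sample_ids,
        values=m.values[keep, :],
    )


def restrict_gene_sets(gs: GeneSetCollection, m: ExpressionMatrix) -> GeneSetCollection:
    """Intersect every pathway with the measured genes; drop emptied pathways."""
    measured = set(m.gene_ids)
    out = GeneSetCollection()
    for pid in gs.pathway_ids():
        members = gs.members(pid) & measured
        if members:
            out.add(pid, gs.name(pid), members)
    return out


def zscore_samples(m: ExpressionMatrix) -> ExpressionMatrix:
    """Optional per-sample z-scoring (mean 0, sd 1 per column); off by default
    in every pipeline — inputs are assumed already normalized and log-scale."""
    v = m.values
    mu = np.nanmean(v, axis=0, keepdims=True)
    sd = np.nanstd(v, axis=0, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return ExpressionMatrix(m.gene_ids, m.sample_ids, (v - mu) / sd)


def split_by_class(
    annotations: Sequence[SampleAnnotation],
) -> Mapping[DoseClass, list[SampleAnnotation]]:
    groups: dict[DoseClass, list[SampleAnnotation]] = {c: [] for c in DoseClass}
    for a in annotations:
        if a.dose_class is None:
            raise ValueError(f"sample {a.sample_id} has no dose class assigned")
        groups[a.dose_class].append(a)
    return groups
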