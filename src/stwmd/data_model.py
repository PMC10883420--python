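"""Core containers and I/O for spatio-temporal expression tensors.

The central object is :class:`ExpressionTensor`, a four-way array
``y[t, i, r, g]`` indexed by developmental stage ``t``, sample ``i`` within
stage, brain region ``r`` and gene ``g``.  Stage ``t = 0`` is the reference
(control) stage.  Because stages may hold different numbers of samples the
sample axis is padded to the largest stage; an explicit boolean ``observed``
mask records which cells were actually measured.  Unobserved cells are never
encoded by sentinel values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DomainError,
    DuplicateCellError,
    FormatError,
)

LONG_COLUMNS = ("stage", "sample", "region", "gene", "value")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Tunable parameters of the full pipeline.

    Parameters mirror the method's published defaults where one exists:
    fold-change weight threshold ``fc_threshold`` = 1.5, normalization
    constant ``norm_constant`` = 3 (values constrained to [1, 4]), CART
    complexity parameter ``cp`` = 0.05, 20x5-fold cross-validation and
    100 subsample-stability runs at 80%.
    """

    fc_threshold: float = 1.5
    norm_constant: float = 3.0
    reference_stage: str | None = None
    min_regions: int = 1

    # pre-weighting gene screen
    prescreen_mode: str = "per_region_de"  # per_region_de | top_fraction | none
    prescreen_alpha: float = 0.05
    prescreen_fc: float = 1.5
    top_fraction: float = 0.05

    # DE on the weighted (region-collapsed, [1, a+1]-scaled) data.  The
    # fold-change evidence is already encoded in the Eq.-style weights, so the
    # pipeline default keeps only the significance gate (de_fc = 1 disables
    # the FC gate); set de_fc > 1 to re-enable it.
    de_alpha: float = 0.05
    de_fc: float = 1.0

    # clustering
    embedding: str = "none"  # none | tsne | umap
    k: int | None = None
    k_min: int = 2
    k_max: int = 8

    # staging trees
    cp: float = 0.05
    cv_folds: int = 5
    cv_repeats: int = 20
    stability_runs: int = 100
    stability_fraction: float = 0.8

    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise DomainError(f"fc_threshold must exceed 1, got {self.fc_threshold}")
        if self.norm_constant <= 0:
            raise DomainError(f"norm_constant must be positive, got {self.norm_constant}")
        if not 0 < self.top_fraction <= 1:
            raise DomainError(f"top_fraction must lie in (0, 1], got {self.top_fraction}")
        if not 0 < self.cp < 1:
            raise DomainError(f"cp must lie in (0, 1), got {self.cp}")
        if not 0 < self.stability_fraction < 1:
            raise DomainError(
                f"stability_fraction must lie in (0, 1), got {self.stability_fraction}"
            )
        if self.cv_folds < 2:
            raise DomainError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.prescreen_mode not in ("per_region_de", "top_fraction", "none"):
            raise ConfigurationError(f"unknown prescreen mode {self.prescreen_mode!r}")
        if self.embedding not in ("none", "tsne", "umap"):
            raise ConfigurationError(f"unknown embedding {self.embedding!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))  # type: ignore[arg-type]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"config file {path} must hold a key-value mapping")
        return cls.from_mapping(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# the tensor
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTensor:
    """Four-way expression array with stage/sample/region/gene labels.

    ``values`` has shape ``(T+1, max_t N_t, R, G)`` and holds NaN outside the
    ``observed`` mask (including the padding beyond each stage's sample
    count).  ``normalized`` records whether min-max region normalization has
    been applied, together with the constant ``norm_constant`` used.
    """

    stages: list[str]
    samples_per_stage: list[list[str]]
    regions: list[str]
    genes: list[str]
    values: np.ndarray
    observed: np.ndarray
    normalized: bool = False
    norm_constant: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        S, Imax, R, G = self.values.shape
        if self.observed.shape != self.values.shape:
            raise ConfigurationError("values and observed shapes differ")
        if len(self.stages) != S or len(self.samples_per_stage) != S:
            raise ConfigurationError("stage labels inconsistent with value shape")
        if len(self.regions) != R or len(self.genes) != G:
            raise ConfigurationError("region/gene labels inconsistent with value shape")
        for labels, what in (
            (self.stages, "stage"),
            (self.regions, "region"),
            (self.genes, "gene"),
        ):
            if len(set(labels)) != len(labels):
                raise ConfigurationError(f"duplicate {what} labels")
        for t, ids in enumerate(self.samples_per_stage):
            if len(ids) < 1:
                raise ConfigurationError(f"stage {self.stages[t]!r} has no samples")
            if len(set(ids)) != len(ids):
                raise ConfigurationError(f"duplicate sample ids in stage {self.stages[t]!r}")
            if len(ids) > Imax:
                raise ConfigurationError("sample axis smaller than a stage's sample count")
            # padding beyond N_t must be unobserved
            if self.observed[t, len(ids):].any():
                raise ConfigurationError("observed mask set in sample padding")
        obs_vals = self.values[self.observed]
        if obs_vals.size and (not np.all(np.isfinite(obs_vals))):
            raise DomainError("observed expression values must be finite")
        if not self.normalized and obs_vals.size and np.any(obs_vals < 0):
            raise DomainError("observed expression values must be nonnegative")

    # -- conveniences -------------------------------------------------------

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def sample_counts(self) -> list[int]:
        return [len(ids) for ids in self.samples_per_stage]

    def stage_index(self, stage: str) -> int:
        try:
            return self.stages.index(stage)
        except ValueError:
            raise ConfigurationError(f"unknown stage {stage!r}") from None

    def sample_labels(self) -> list[tuple[str, str]]:
        """Flat ``(stage, sample)`` pairs in stage-major order."""
        return [
            (stage, sid)
            for stage, ids in zip(self.stages, self.samples_per_stage)
            for sid in ids
        ]

    def replace(self, **kwargs) -> "ExpressionTensor":
        return dataclasses.replace(self, **kwargs)


def _order_stages(stages_in_file_order: Sequence[str], reference_stage: str | None) -> list[str]:
    stages = list(dict.fromkeys(stages_in_file_order))
    if reference_stage is not None:
        if reference_stage not in stages:
            raise ConfigurationError(
                f"reference stage {reference_stage!r} absent from data (stages: {stages})"
            )
        stages.remove(reference_stage)
        stages.insert(0, reference_stage)
    return stages


def tensor_from_long(
    frame: pd.DataFrame, reference_stage: str | None = None
) -> ExpressionTensor:
    """Build a tensor from a long-format table (stage, sample, region, gene, value)."""
    missing = [c for c in LONG_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = frame.loc[:, list(LONG_COLUMNS)].copy()
    for col in ("stage", "sample", "region", "gene"):
        df[col] = df[col].astype(str)
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        bad = df.loc[values.isna()].iloc[0]
        raise FormatError(f"non-numeric value for {tuple(bad[:4])!r}")
    if (values < 0).any():
        bad = df.loc[values < 0].iloc[0]
        raise DomainError(f"negative expression value for {tuple(bad[:4])!r}")
    df["value"] = values.astype(float)

    dup = df.duplicated(subset=["stage", "sample", "region", "gene"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise DuplicateCellError(
            f"duplicate cell (stage={bad['stage']!r}, sample={bad['sample']!r}, "
            f"region={bad['region']!r}, gene={bad['gene']!r})"
        )

    stages = _order_stages(df["stage"].tolist(), reference_stage)
    regions = list(dict.fromkeys(df["region"].tolist()))
    genes = list(dict.fromkeys(df["gene"].tolist()))

    samples_per_stage: list[list[str]] = []
    for stage in stages:
        ids = list(dict.fromkeys(df.loc[df["stage"] == stage, "sample"].tolist()))
        samples_per_stage.append(ids)

    S = len(stages)
    Imax = max(len(ids) for ids in samples_per_stage)
    R, G = len(regions), len(genes)
    values_arr = np.full((S, Imax, R, G), np.nan)
    observed = np.zeros((S, Imax, R, G), dtype=bool)

    t_idx = df["stage"].map({s: i for i, s in enumerate(stages)}).to_numpy()
    sample_pos = {
        (stage, sid): j
        for stage, ids in zip(stages, samples_per_stage)
        for j, sid in enumerate(ids)
    }
    i_idx = np.fromiter(
        (sample_pos[(s, x)] for s, x in zip(df["stage"], df["sample"])),
        dtype=int,
        count=len(df),
    )
    r_idx = df["region"].map({r: i for i, r in enumerate(regions)}).to_numpy()
    g_idx = df["gene"].map({g: i for i, g in enumerate(genes)}).to_numpy()
    values_arr[t_idx, i_idx, r_idx, g_idx] = df["value"].to_numpy()
    observed[t_idx, i_idx, r_idx, g_idx] = True

    return ExpressionTensor(
        stages=stages,
        samples_per_stage=samples_per_stage,
        regions=regions,
        genes=genes,
        values=values_arr,
        observed=observed,
    )


def load_long_table(path: str | Path, reference_stage: str | None = None) -> ExpressionTensor:
    """Read the canonical long-format TSV (UTF-8, tab separated, '.' decimal)."""
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path} is empty") from None
    return tensor_from_long(frame, reference_stage=reference_stage)


def load_wide_bundle(
    directory: str | Path, reference_stage: str | None = None
) -> ExpressionTensor:
    """Load a bundle of per-stage per-sample gene x region wide TSV matrices.

    Files must be named ``<stage>__<sample>.tsv`` with genes as rows and
    regions as columns; the bundle is converted to the long representation on
    load so there is a single internal data path.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        raise FormatError(f"no .tsv files found in {directory}")
    records = []
    for p in paths:
        stem = p.stem
        if "__" not in stem:
            raise FormatError(f"wide-bundle file {p.name} is not named <stage>__<sample>.tsv")
        stage, sample = stem.split("__", 1)
        wide = pd.read_csv(p, sep="\t", index_col=0)
        long = wide.stack().rename("value").reset_index()
        long.columns = ["gene", "region", "value"]
        long["stage"] = stage
        long["sample"] = sample
        records.append(long[list(LONG_COLUMNS)])
    frame = pd.concat(records, ignore_index=True)
    return tensor_from_long(frame, reference_stage=reference_stage)


def write_long_table(tensor: ExpressionTensor, path: str | Path) -> None:
    """Write the observed cells of a tensor back to long-format TSV."""
    t, i, r, g = np.nonzero(tensor.observed)
    stage = [tensor.stages[k] for k in t]
    sample = [tensor.samples_per_stage[a][b] for a, b in zip(t, i)]
    frame = pd.DataFrame(
        {
            "stage": stage,
            "sample": sample,
            "region": [tensor.regions[k] for k in r],
            "gene": [tensor.genes[k] for k in g],
            "value": tensor.values[t, i, r, g],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Outcome of the minimum-regions-per-sample screen."""

    min_regions: int
    flagged: list[tuple[str, str]]
    regions_per_sample: dict[tuple[str, str], int]
    samples_per_stage: dict[str, int]
    gene_missingness: pd.Series
    tensor: ExpressionTensor | None = None  # filtered tensor when drop=True


def validate_tensor(
    tensor: ExpressionTensor, min_regions: int = 1, drop: bool = False
) -> ValidationReport:
    """Flag (optionally drop) stage-samples observed in fewer than ``min_regions`` regions.

    This generalizes the keep-only-samples-with-at-least-three-brain-regions
    rule used for sparse developmental datasets.  Dropping every sample of a
    stage is a fatal configuration error.
    """
    region_observed = tensor.observed.any(axis=3)  # (S, Imax, R): region measured for sample
    counts: dict[tuple[str, str], int] = {}
    flagged: list[tuple[str, str]] = []
    keep: list[list[str]] = []
    for t, (stage, ids) in enumerate(zip(tensor.stages, tensor.samples_per_stage)):
        kept = []
        for i, sid in enumerate(ids):
            n_regions = int(region_observed[t, i].sum())
            counts[(stage, sid)] = n_regions
            if n_regions < min_regions:
                flagged.append((stage, sid))
            else:
                kept.append(sid)
        keep.append(kept)

    # fraction of stage-samples where a gene was measured in no region at all
    # (padding rows are all-False in the mask so the plain sum is exact)
    seen = tensor.observed.any(axis=2).sum(axis=(0, 1))  # per gene
    gene_missing = 1.0 - seen / sum(tensor.sample_counts)
    gene_missingness = pd.Series(gene_missing, index=tensor.genes, name="missing_fraction")

    filtered = None
    if drop and flagged:
        empty = [s for s, kept in zip(tensor.stages, keep) if not kept]
        if empty:
            raise ConfigurationError(
                f"min_regions={min_regions} removes every sample of stage(s) {empty}"
            )
        Imax = max(len(k) for k in keep)
        S, _, R, G = tensor.values.shape
        values = np.full((S, Imax, R, G), np.nan)
        observed = np.zeros((S, Imax, R, G), dtype=bool)
        for t, (ids, kept) in enumerate(zip(tensor.samples_per_stage, keep)):
            src = [ids.index(sid) for sid in kept]
            values[t, : len(src)] = tensor.values[t, src]
            observed[t, : len(src)] = tensor.observed[t, src]
        filtered = ExpressionTensor(
            stages=list(tensor.stages),
            samples_per_stage=keep,
            regions=list(tensor.regions),
            genes=list(tensor.genes),
            values=values,
            observed=observed,
            normalized=tensor.normalized,
            norm_constant=tensor.norm_constant,
        )
    elif drop:
        filtered = tensor
    else:
        empty = [s for s, kept in zip(tensor.stages, keep) if not kept]
        if empty:
            raise ConfigurationError(
                f"min_regions={min_regions} flags every sample of stage(s) {empty}"
            )

    return ValidationReport(
        min_regions=min_regions,
        flagged=flagged,
        regions_per_sample=counts,
        samples_per_stage={s: len(k) for s, k in zip(tensor.stages, keep)},
        gene_missingness=gene_missingness,
        tensor=filtered,
    )


# ---------------------------------------------------------------------------
# matrix writers
# ---------------------------------------------------------------------------

def write_matrix(obj, path: str | Path) -> None:
    """Write a WeightedExpression or a ContrastResult table as TSV (genes as rows)."""
    frame = obj.to_frame()
    frame.to_csv(path, sep="\t")


def read_weighted_frame(path: str | Path) -> pd.DataFrame:
    """Read back a weighted-expression TSV written by :func:`write_matrix`.

    Columns are ``stage:sample`` composite labels, genes are the index.
    """
    return pd.read_csv(path, sep="\t", index_col=0)
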