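"""Spatio-temporal weighting: region normalization, fold-change weights,
weight adjustment and region-collapsing aggregation.

The spatial (brain-region) axis is collapsed in three steps:

1. min-max normalize each sample's regional profile of a gene into
   ``[1, a + 1]`` (default ``a = 3``, so [1, 4]);
2. per (stage, region, gene), compute the fold change of the stage mean
   against the reference stage and keep ``|log2 FC|`` as a weight only when
   it clears ``log2 f`` (default ``f = 1.5``) — otherwise the weight is 0, so
   regions where a gene is not differentially expressed cannot dilute, and
   oppositely-regulated regions cannot cancel, the signal;
3. form the weighted average of the sample's normalized regional values.

The plain across-region average is provided as the comparison baseline.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExpressionTensor
from .errors import ConfigurationError, DomainError

_EPS = 1e-12


@dataclass
class WeightTensor:
    """Per (stage, region, gene) fold changes and adjusted weights.

    ``fc[0] == 1`` by construction at the reference stage.  ``adjusted`` is
    ``None`` until :func:`adjust_weights` has run; afterwards it is
    ``|log2fc|`` where that magnitude reaches ``log2(threshold)`` and 0
    elsewhere.  ``observed`` marks (t, r, g) cells whose fold change is
    defined (both stage means computable).
    """

    stages: list[str]
    regions: list[str]
    genes: list[str]
    reference_stage: str
    fc: np.ndarray
    log2fc: np.ndarray
    observed: np.ndarray
    adjusted: np.ndarray | None = None
    threshold: float | None = None

    def to_frame(self) -> pd.DataFrame:
        t, r, g = np.nonzero(self.observed)
        frame = pd.DataFrame(
            {
                "stage": [self.stages[k] for k in t],
                "region": [self.regions[k] for k in r],
                "gene": [self.genes[k] for k in g],
                "fc": self.fc[t, r, g],
                "log2fc": self.log2fc[t, r, g],
            }
        )
        if self.adjusted is not None:
            frame["adjusted"] = self.adjusted[t, r, g]
        return frame


@dataclass
class WeightedExpression:
    """Region-collapsed expression ``y_fc[t, i, g]`` per stage-sample per gene."""

    stages: list[str]
    samples_per_stage: list[list[str]]
    genes: list[str]
    values: np.ndarray  # (S, Imax, G), NaN where unobserved
    observed: np.ndarray
    mode: str  # "stw" | "stw_signed" | "region_mean"
    fallback_count: int = 0

    def sample_labels(self) -> list[tuple[str, str]]:
        return [
            (stage, sid)
            for stage, ids in zip(self.stages, self.samples_per_stage)
            for sid in ids
        ]

    def to_frame(self) -> pd.DataFrame:
        """Genes x stage-samples matrix with ``stage:sample`` column labels."""
        cols, data = [], []
        for t, (stage, ids) in enumerate(zip(self.stages, self.samples_per_stage)):
            for i, sid in enumerate(ids):
                cols.append(f"{stage}:{sid}")
                data.append(self.values[t, i])
        frame = pd.DataFrame(np.column_stack(data), index=self.genes, columns=cols)
        frame.index.name = "gene"
        return frame

    def stage_of_columns(self) -> np.ndarray:
        """Stage label per column of :meth:`to_frame`."""
        return np.array([s for s, _ in self.sample_labels()])


# ---------------------------------------------------------------------------
# step 1: normalization
# ---------------------------------------------------------------------------

def normalize_regions(tensor: ExpressionTensor, a: float = 3.0) -> ExpressionTensor:
    """Min-max normalize each sample's regional profile into ``[1, a + 1]``.

    For each (stage, sample, gene), over that sample's observed regions::

        y_norm = (y - min_r y) / (max_r y - min_r y) * a + 1

    A regionally constant profile (max == min) maps to 1 everywhere, keeping
    the output deterministic and inside the stated range.  The transform is
    invariant to positive affine rescaling of a sample's regional values.
    """
    if a <= 0:
        raise DomainError(f"normalization constant a must be positive, got {a}")
    if tensor.normalized:
        raise ConfigurationError("tensor is already normalized")
    vals = np.where(tensor.observed, tensor.values, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN region slices
        mn = np.nanmin(vals, axis=2, keepdims=True)
        mx = np.nanmax(vals, axis=2, keepdims=True)
    rng = mx - mn
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(rng > 0, (vals - mn) / rng, 0.0)
    out = np.where(tensor.observed, frac * a + 1.0, np.nan)
    return tensor.replace(values=out, normalized=True, norm_constant=float(a))


# ---------------------------------------------------------------------------
# step 2: fold-change weights
# ---------------------------------------------------------------------------

def _stage_means(tensor: ExpressionTensor) -> tuple[np.ndarray, np.ndarray]:
    """Mean over observed samples per (stage, region, gene) and its support."""
    vals = np.where(tensor.observed, tensor.values, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(vals, axis=1)  # (S, R, G)
    support = tensor.observed.sum(axis=1) > 0  # (S, R, G)
    return means, support


def compute_fold_change(
    tensor: ExpressionTensor, reference_stage: str | None = None
) -> WeightTensor:
    """Fold change of each stage's regional mean against the reference stage.

    Requires a normalized tensor: normalization bounds every value below by 1,
    so the reference-stage means (the denominators) are always positive and
    the ratio is defined.  The reference stage itself has FC = 1 everywhere.
    """
    if not tensor.normalized:
        raise ConfigurationError(
            "compute_fold_change expects a normalized tensor (run normalize_regions first)"
        )
    ref = tensor.stages[0] if reference_stage is None else reference_stage
    t0 = tensor.stage_index(ref)
    if t0 != 0:
        raise ConfigurationError(
            f"reference stage {ref!r} must be at index 0 (reorder at load time)"
        )
    means, support = _stage_means(tensor)
    denom = means[t0]  # (R, G)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = means / denom[None]
    observed = support & support[t0][None]
    fc = np.where(observed, fc, np.nan)
    fc[t0] = np.where(support[t0], 1.0, np.nan)
    observed[t0] = support[t0]
    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.log2(fc)
    return WeightTensor(
        stages=list(tensor.stages),
        regions=list(tensor.regions),
        genes=list(tensor.genes),
        reference_stage=ref,
        fc=fc,
        log2fc=log2fc,
        observed=observed,
    )


def adjust_weights(weights: WeightTensor, f: float = 1.5) -> WeightTensor:
    """Threshold and rectify the log2 fold changes into nonnegative weights.

    ``adjusted = -log2fc`` where ``log2fc < -log2 f``; ``log2fc`` where
    ``log2fc >= log2 f``; 0 otherwise.  Down-regulation therefore contributes
    a positive weight of the same magnitude as an equally strong
    up-regulation, and sub-threshold regions are silenced so they cannot
    dilute or counterbalance the differential signal.
    """
    if f <= 1:
        raise DomainError(f"weight threshold f must exceed 1, got {f}")
    cut = np.log2(f)
    lfc = weights.log2fc
    adjusted = np.where(lfc >= cut, lfc, np.where(lfc < -cut, -lfc, 0.0))
    adjusted = np.where(weights.observed, adjusted, np.nan)
    return dataclasses.replace(weights, adjusted=adjusted, threshold=float(f))


# ---------------------------------------------------------------------------
# step 3: weighted aggregation
# ---------------------------------------------------------------------------

def weight_expression(
    tensor: ExpressionTensor,
    weights: WeightTensor,
    genes: list[str] | None = None,
    signed: bool = False,
) -> WeightedExpression:
    """Collapse regions into one value per (stage, sample, gene).

    ``y_fc(t, i, g) = sum_r y_norm(t, i, r, g) w(t, r, g) / sum_r w(t, r, g)``
    over the regions observed for sample ``i`` whose weight is defined.

    Two conventions close the gaps the fold-change definition leaves open:

    * the reference stage (all fold changes exactly 1) borrows, per
      (region, gene), the mean of the adjusted weights over the non-reference
      stages, keeping it on the same weighted scale;
    * any (t, i, g) whose weights sum to (numerically) zero falls back to the
      arithmetic mean of the observed regional values, and the number of such
      cells is reported as ``fallback_count``.

    With ``signed=True`` the raw signed ``log2fc`` is used instead of the
    adjusted weights — the unstable convention the adjustment exists to fix,
    kept for demonstrating the counterbalance effect.
    """
    if not tensor.normalized:
        raise ConfigurationError("weight_expression expects a normalized tensor")
    if not signed and weights.adjusted is None:
        raise ConfigurationError("weights have not been adjusted (run adjust_weights)")
    if weights.genes != tensor.genes or weights.regions != tensor.regions:
        raise ConfigurationError("weight tensor labels do not match expression tensor")

    W = weights.log2fc if signed else weights.adjusted
    W = np.where(weights.observed, W, np.nan)
    t0 = 0
    non_ref = np.arange(len(tensor.stages)) != t0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref_w = np.nanmean(W[non_ref], axis=0)  # (R, G)
    W = W.copy()
    W[t0] = ref_w

    if genes is not None:
        gidx = [tensor.genes.index(g) for g in genes]
    else:
        gidx = slice(None)
        genes = list(tensor.genes)

    vals = np.where(tensor.observed, tensor.values, np.nan)[:, :, :, gidx]
    Wsub = W[:, None, :, gidx]  # broadcast over samples
    contrib = tensor.observed[:, :, :, gidx] & np.isfinite(Wsub) & np.isfinite(vals)
    w_eff = np.where(contrib, Wsub, 0.0)
    v_eff = np.where(contrib, vals, 0.0)
    num = (v_eff * w_eff).sum(axis=2)  # (S, Imax, G')
    den = w_eff.sum(axis=2)

    cell_observed = np.isfinite(vals).any(axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        plain_mean = np.nanmean(vals, axis=2)
    degenerate = cell_observed & (np.abs(den) < _EPS)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out = np.where(degenerate, plain_mean, out)
    out = np.where(cell_observed, out, np.nan)

    return WeightedExpression(
        stages=list(tensor.stages),
        samples_per_stage=[list(ids) for ids in tensor.samples_per_stage],
        genes=list(genes),
        values=out,
        observed=cell_observed,
        mode="stw_signed" if signed else "stw",
        fallback_count=int(degenerate.sum()),
    )


def region_mean_baseline(
    tensor: ExpressionTensor, genes: list[str] | None = None
) -> WeightedExpression:
    """Unweighted arithmetic mean over observed regions — the comparison baseline."""
    if genes is not None:
        gidx = [tensor.genes.index(g) for g in genes]
    else:
        gidx = slice(None)
        genes = list(tensor.genes)
    vals = np.where(tensor.observed, tensor.values, np.nan)[:, :, :, gidx]
    cell_observed = np.isfinite(vals).any(axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(vals, axis=2)
    out = np.where(cell_observed, out, np.nan)
    return WeightedExpression(
        stages=list(tensor.stages),
        samples_per_stage=[list(ids) for ids in tensor.samples_per_stage],
        genes=list(genes),
        values=out,
        observed=cell_observed,
        mode="region_mean",
    )


# ---------------------------------------------------------------------------
# pre-weighting gene screens
# ---------------------------------------------------------------------------

def prescreen_genes(
    tensor: ExpressionTensor,
    mode: str = "per_region_de",
    *,
    alpha: float = 0.05,
    f: float = 1.5,
    q: float = 0.05,
    norm_constant: float = 3.0,
) -> list[str]:
    """Select the genes worth weighting.

    ``per_region_de``
        Run the moderated-t differential test within every region for every
        stage pair on the raw tensor and return the union of significant
        genes (adjusted p <= alpha and fold change >= f) across regions and
        pairs.
    ``top_fraction``
        For every stage pair, rank genes by the across-region mean of the
        pairwise ``|log2 FC|`` of normalized stage means and keep the top
        fraction ``q``; return the union over pairs.  This is the screen of
        choice when most genes change and per-region testing is uninformative.
    """
    from .diffexpr import moderated_t_test, select_degs

    if mode == "per_region_de":
        if tensor.normalized:
            raise ConfigurationError("per_region_de prescreen runs on the raw tensor")
        selected: dict[str, None] = {}
        S = tensor.n_stages
        for r in range(len(tensor.regions)):
            for ta in range(S):
                for tb in range(ta + 1, S):
                    cols_a = _region_matrix(tensor, ta, r)
                    cols_b = _region_matrix(tensor, tb, r)
                    if cols_a.shape[1] < 2 or cols_b.shape[1] < 2:
                        continue
                    matrix = np.concatenate([cols_a, cols_b], axis=1)
                    groups = np.array(
                        [tensor.stages[ta]] * cols_a.shape[1]
                        + [tensor.stages[tb]] * cols_b.shape[1]
                    )
                    res = moderated_t_test(
                        matrix,
                        groups,
                        genes=tensor.genes,
                        contrast=(tensor.stages[ta], tensor.stages[tb]),
                    )
                    res = select_degs(res, alpha=alpha, f=f)
                    for gene, direction in zip(res.genes, res.direction):
                        if direction != "ns":
                            selected.setdefault(gene, None)
        return [g for g in tensor.genes if g in selected]

    if mode == "top_fraction":
        if not 0 < q <= 1:
            raise DomainError(f"top fraction q must lie in (0, 1], got {q}")
        norm = tensor if tensor.normalized else normalize_regions(tensor, norm_constant)
        means, support = _stage_means(norm)  # (S, R, G)
        G = len(tensor.genes)
        n_top = int(np.ceil(q * G))
        selected = {}
        S = tensor.n_stages
        for ta in range(S):
            for tb in range(ta + 1, S):
                with np.errstate(invalid="ignore", divide="ignore"):
                    lfc = np.abs(np.log2(means[tb] / means[ta]))  # (R, G)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    score = np.nanmean(lfc, axis=0)  # (G,)
                score = np.where(np.isfinite(score), score, -np.inf)
                top = np.argsort(-score, kind="stable")[:n_top]
                for gi in top:
                    if np.isfinite(score[gi]):
                        selected.setdefault(tensor.genes[gi], None)
        return [g for g in tensor.genes if g in selected]

    if mode == "none":
        return list(tensor.genes)
    raise ConfigurationError(f"unknown prescreen mode {mode!r}")


def _region_matrix(tensor: ExpressionTensor, t: int, r: int) -> np.ndarray:
    """Genes x samples matrix of one region at one stage (observed samples only)."""
    n = len(tensor.samples_per_stage[t])
    block = tensor.values[t, :n, r, :]  # (N_t, G)
    obs = tensor.observed[t, :n, r, :]
    keep = obs.all(axis=1)  # samples with the full gene panel in this region
    if not keep.any():
        keep = obs.any(axis=1)
    return block[keep].T
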