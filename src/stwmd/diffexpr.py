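"""Two-group differential expression with an empirical-Bayes moderated t-test.

The statistic follows the classic variance-shrinkage construction: a pooled
per-gene residual variance ``s_g^2`` with ``d_g`` degrees of freedom is
shrunk toward a prior ``(d0, s0^2)`` fitted across genes by the method of
moments on ``log s_g^2``, giving the posterior variance

    s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

and a t-statistic with ``d0 + d_g`` degrees of freedom.  ``prior_df = 0``
disables shrinkage and recovers the ordinary pooled-variance two-sample t.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConfigurationError, DomainError

_D0_CAP = 1e6  # "effectively infinite" prior degrees of freedom


@dataclass
class ContrastResult:
    """Per-gene statistics for one two-group (stage pair) contrast."""

    contrast: tuple[str, str]
    genes: list[str]
    mean_a: np.ndarray
    mean_b: np.ndarray
    log2fc: np.ndarray  # b vs a
    t_stat: np.ndarray
    df_total: np.ndarray
    p: np.ndarray
    p_adj: np.ndarray
    direction: np.ndarray  # 'up' | 'down' | 'ns'
    d0: float
    s0_sq: float
    zero_variance: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "gene": self.genes,
                "log2FC": self.log2fc,
                "t": self.t_stat,
                "p": self.p,
                "p_adj": self.p_adj,
                "direction": self.direction,
            }
        ).set_index("gene")
        return frame


def _trigamma_inverse(y: float) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        raise DomainError("trigamma inverse requires a positive target")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s_sq: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-inverse-chi-square variance prior.

    Works on ``e_g = log s_g^2 - digamma(d/2) + log(d/2)`` whose mean and
    variance identify ``s0^2`` and ``d0`` through digamma/trigamma moments;
    ``d0`` is obtained by trigamma inversion and capped at 1e6 when the
    observed spread of log-variances is no larger than expected under a
    common variance.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    ok = np.isfinite(s_sq) & (s_sq > 0)
    if ok.sum() < 2:
        return _D0_CAP, float(np.nanmean(s_sq[ok])) if ok.any() else 1.0
    z = np.log(s_sq[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    target = e_var - float(special.polygamma(1, df / 2.0))
    if target <= 0:
        d0 = _D0_CAP
    else:
        d0 = min(2.0 * _trigamma_inverse(target), _D0_CAP)
    s0_sq = float(
        np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return d0, s0_sq


def moderated_t_test(
    matrix: np.ndarray | pd.DataFrame,
    groups: Sequence[str],
    *,
    genes: Sequence[str] | None = None,
    contrast: tuple[str, str] | None = None,
    prior_df: float | None = None,
    log_input: bool = False,
) -> ContrastResult:
    """Moderated two-sample t-test per gene (rows) between two groups (columns).

    ``prior_df=None`` fits the prior from the data; ``prior_df=0`` disables
    shrinkage (plain pooled t); any other value fixes ``d0``.  ``log_input``
    states whether the matrix is already on a log2 scale, in which case the
    fold change is the mean difference; otherwise it is the log2 ratio of the
    group means (which must then be positive).
    """
    if isinstance(matrix, pd.DataFrame):
        genes = list(matrix.index) if genes is None else list(genes)
        matrix = matrix.to_numpy(dtype=float)
    else:
        matrix = np.asarray(matrix, dtype=float)
        if genes is None:
            genes = [f"g{i}" for i in range(matrix.shape[0])]
        genes = list(genes)
    if not np.all(np.isfinite(matrix)):
        raise DomainError("expression matrix contains non-finite values")
    groups = np.asarray([str(g) for g in groups])
    levels = list(dict.fromkeys(groups))
    if len(levels) != 2:
        raise ConfigurationError(f"exactly two groups required, got {levels}")
    if contrast is None:
        contrast = (levels[0], levels[1])
    a, b = contrast
    ia, ib = groups == a, groups == b
    na, nb = int(ia.sum()), int(ib.sum())
    if na < 2 or nb < 2:
        raise ConfigurationError(
            f"each group needs >= 2 samples (got {a}: {na}, {b}: {nb})"
        )

    xa, xb = matrix[:, ia], matrix[:, ib]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    df = na + nb - 2
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    s_sq = ss / df
    zero_var = s_sq <= 0

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s_sq, df)
    else:
        d0 = float(prior_df)
        s0_sq = float(np.median(s_sq[~zero_var])) if (~zero_var).any() else 1.0
        if d0 < 0:
            raise DomainError("prior_df must be nonnegative")

    if d0 > 0:
        s_post = (d0 * s0_sq + df * s_sq) / (d0 + df)
    else:
        s_post = s_sq
    df_total = np.full(len(genes), min(d0 + df, _D0_CAP))

    delta = mean_b - mean_a
    se = np.sqrt(s_post * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = delta / se
    # genes flat in both groups: no evidence either way unless the means differ
    t = np.where((se == 0) & (delta == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(t), 1.0, p)
    p = np.where(np.isinf(t), 0.0, p)

    if log_input:
        log2fc = delta
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            log2fc = np.log2(mean_b / mean_a)

    return ContrastResult(
        contrast=(a, b),
        genes=genes,
        mean_a=mean_a,
        mean_b=mean_b,
        log2fc=log2fc,
        t_stat=t,
        df_total=df_total,
        p=p,
        p_adj=bh_adjust(p),
        direction=np.full(len(genes), "ns", dtype=object),
        d0=float(d0),
        s0_sq=float(s0_sq),
        zero_variance=zero_var,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1, rank-monotone)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DomainError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def select_degs(result: ContrastResult, alpha: float = 0.05, f: float = 1.5) -> ContrastResult:
    """Call genes up/down/ns by the joint significance and fold-change gates.

    ``up``: adjusted p <= alpha and log2FC >= log2 f; ``down``: adjusted
    p <= alpha and log2FC <= -log2 f; ``ns`` otherwise.  ``f = 1`` disables
    the fold-change gate.  Idempotent.
    """
    if f < 1:
        raise DomainError(f"fold-change gate f must be >= 1, got {f}")
    cut = np.log2(f)
    sig = result.p_adj <= alpha
    with np.errstate(invalid="ignore"):
        up = sig & (result.log2fc >= cut) & np.isfinite(result.log2fc)
        down = sig & (result.log2fc <= -cut) & np.isfinite(result.log2fc)
    if f == 1:  # a zero log2FC is neither direction; break the tie by sign of t
        down &= result.log2fc < 0
        up &= result.log2fc > 0
    direction = np.where(up, "up", np.where(down, "down", "ns")).astype(object)
    return dataclasses.replace(result, direction=direction)


@dataclass
class DegUnion:
    """Union of DEGs over contrasts, with per-gene contrast/direction provenance."""

    genes: list[str]
    provenance: dict[str, list[tuple[tuple[str, str], str]]]

    def __len__(self) -> int:
        return len(self.genes)


def pairwise_union(results: Sequence[ContrastResult]) -> DegUnion:
    """Union of non-ns genes across contrasts (order-independent)."""
    provenance: dict[str, list[tuple[tuple[str, str], str]]] = {}
    for res in results:
        for gene, direction in zip(res.genes, res.direction):
            if direction != "ns":
                provenance.setdefault(gene, []).append((res.contrast, str(direction)))
    # keep the gene order of the first contrast that lists them
    seen = []
    for res in results:
        for gene in res.genes:
            if gene in provenance and gene not in seen:
                seen.append(gene)
    return DegUnion(genes=seen, provenance=provenance)


def pairwise_contrasts(
    weighted,
    *,
    alpha: float = 0.05,
    f: float = 1.0,
    prior_df: float | None = None,
) -> list[ContrastResult]:
    """All unordered stage-pair contrasts on a weighted expression object.

    The earlier stage (smaller stage index) is the baseline of each pair.
    """
    frame = weighted.to_frame()
    stage_of = weighted.stage_of_columns()
    results = []
    S = len(weighted.stages)
    for ta in range(S):
        for tb in range(ta + 1, S):
            sa, sb = weighted.stages[ta], weighted.stages[tb]
            cols = np.isin(stage_of, [sa, sb])
            sub = frame.loc[:, cols]
            res = moderated_t_test(
                sub.to_numpy(),
                stage_of[cols],
                genes=list(frame.index),
                contrast=(sa, sb),
            )
            results.append(select_degs(res, alpha=alpha, f=f))
    return results
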