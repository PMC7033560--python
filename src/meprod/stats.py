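"""Differential-translation statistics and structure analyses.

Fold changes are ``log2(mean_treated / mean_control)`` over replicate
relative-translation values; significance comes from an unpaired, two-sided,
equal-variance (pooled) Student's t-test with Benjamini–Hochberg FDR
adjustment across all testable proteins. A protein whose treated signal drops
entirely below baseline (all treated replicates zero while the control mean is
positive) has no computable fold change and is classified *not determinable*
(n.d.); such proteins are excluded from the BH family.

Structure analyses operate on row-standardized (Z-score) matrices:
hierarchical clustering on Euclidean distances, classical (Torgerson)
multidimensional scaling, ternary fold-change shares, and a per-protein
dose-response linear screen.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress
from scipy.stats import t as t_dist

from .design import PlexDesign
from .errors import DesignError, MeprodError

logger = logging.getLogger("meprod")

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_UNCHANGED = "unchanged"
CLASS_ND = "not_determinable"


@dataclass
class TranslationStat:
    """Per-protein differential-translation result for one contrast."""

    master_accession: str
    mean_control: float
    mean_treated: float
    log2fc: float
    t_stat: float
    p: float
    adj_p: float
    regulation_class: str = CLASS_UNCHANGED


@dataclass
class StandardizedMatrix:
    """Row-wise Z-scores: each non-constant row has mean 0 and sample SD 1."""

    values: pd.DataFrame
    row_order: list[str]
    column_order: list[str]
    constant_rows: list[str]


@dataclass
class ClusteringResult:
    """Agglomerative clustering output: SciPy linkage matrix plus leaf order."""

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]


@dataclass
class LinearScreenResult:
    """Ordinary least-squares dose-response fit for one protein."""

    master_accession: str
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    is_linear_responder: bool


# ---------------------------------------------------------------------------
# primitives


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``adj_(i) = min_{j >= i} p_(j) * n / j`` over the sorted p-values, clipped
    at 1; ties are handled by a stable sort so the result is order-independent.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise MeprodError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    # p * (n / rank): the factor is >= 1 and exactly 1 at rank n, so the
    # adjusted value can never round below the raw p-value
    ranked = p[order] * (n / np.arange(1, n + 1))
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adj
    return out


def pooled_t_test(
    treated: Sequence[float], control: Sequence[float]
) -> tuple[float, float]:
    """Unpaired, two-sided Student's t-test with pooled (equal) variance.

    Returns ``(t, p)``. Degenerate zero-variance groups are resolved by the
    mean difference: identical means give ``t = 0, p = 1``; distinct means
    with zero pooled variance give ``t = ±inf, p = 0``.
    """
    a = np.asarray(treated, dtype=float)
    b = np.asarray(control, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise MeprodError("t-test requires at least two replicates per group")
    diff = a.mean() - b.mean()
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if se == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / se
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), min(p, 1.0)


# ---------------------------------------------------------------------------
# differential translation


def fold_change_stats(
    protein_table: pd.DataFrame,
    design: PlexDesign,
    treated_condition: str,
    control_condition: str,
) -> list[TranslationStat]:
    """Per-protein fold change, t-test and BH FDR for one contrast.

    *protein_table* is indexed by accession with one column per sample channel
    (extra columns such as ``n_peptides`` are ignored). Proteins with missing
    replicate cells in the contrast are excluded (no imputation); proteins
    whose control mean is zero are excluded with a logged count; proteins with
    ``mean_treated == 0`` are flagged not determinable and kept outside the
    BH family.
    """
    for cond in (treated_condition, control_condition):
        if cond not in design.conditions:
            raise DesignError(
                f"condition {cond!r} not in design (have {list(design.conditions)})"
            )
        if len(design.channels_for(cond)) < 2:
            raise DesignError(
                f"condition {cond!r} has fewer than two replicate channels"
            )
    treated_cols = [c.channel_id for c in design.channels_for(treated_condition)]
    control_cols = [c.channel_id for c in design.channels_for(control_condition)]
    for col in treated_cols + control_cols:
        if col not in protein_table.columns:
            raise MeprodError(f"protein table lacks channel column {col!r}")

    stats: list[TranslationStat] = []
    n_missing = 0
    n_zero_control = 0
    for acc, row in protein_table.iterrows():
        tv = row[treated_cols].to_numpy(dtype=float)
        cv = row[control_cols].to_numpy(dtype=float)
        if not (np.isfinite(tv).all() and np.isfinite(cv).all()):
            n_missing += 1
            continue
        mean_t, mean_c = float(tv.mean()), float(cv.mean())
        if mean_c <= 0:
            n_zero_control += 1
            continue
        if mean_t == 0.0:
            stats.append(
                TranslationStat(
                    master_accession=str(acc),
                    mean_control=mean_c,
                    mean_treated=0.0,
                    log2fc=math.nan,
                    t_stat=math.nan,
                    p=math.nan,
                    adj_p=math.nan,
                    regulation_class=CLASS_ND,
                )
            )
            continue
        t, p = pooled_t_test(tv, cv)
        stats.append(
            TranslationStat(
                master_accession=str(acc),
                mean_control=mean_c,
                mean_treated=mean_t,
                log2fc=math.log2(mean_t / mean_c),
                t_stat=t,
                p=p,
                adj_p=math.nan,
                regulation_class=CLASS_UNCHANGED,
            )
        )
    if n_missing:
        logger.info("contrast skipped %d proteins with missing replicate cells", n_missing)
    if n_zero_control:
        logger.info("contrast excluded %d proteins with zero control mean", n_zero_control)

    tested = [s for s in stats if s.regulation_class != CLASS_ND]
    if tested:
        adj = benjamini_hochberg([s.p for s in tested])
        for s, a in zip(tested, adj):
            s.adj_p = float(a)
    stats.sort(key=lambda s: s.master_accession)
    return stats


def classify_regulation(
    stats: Sequence[TranslationStat], fc_cut: float = 0.5, p_cut: float = 0.05
) -> list[TranslationStat]:
    """Assign {up, down, unchanged, not_determinable} classes.

    ``down`` requires ``adj_p < p_cut`` (strict) and ``log2fc <= -fc_cut``
    (inclusive); ``up`` mirrors it. The n.d. flag takes precedence.
    """
    out = []
    for s in stats:
        if s.regulation_class == CLASS_ND:
            out.append(replace(s))
            continue
        if s.adj_p < p_cut and s.log2fc <= -fc_cut:
            cls = CLASS_DOWN
        elif s.adj_p < p_cut and s.log2fc >= fc_cut:
            cls = CLASS_UP
        else:
            cls = CLASS_UNCHANGED
        out.append(replace(s, regulation_class=cls))
    return out


# ---------------------------------------------------------------------------
# structure analyses


def zscore_standardize(matrix: pd.DataFrame, axis: str = "rows") -> StandardizedMatrix:
    """Center each row to mean 0 and scale to unit sample variance (ddof=1).

    Rows with fewer than two finite values are excluded; constant rows map to
    all-zero and are recorded in ``constant_rows``. ``axis="columns"``
    standardizes columns instead (via transposition).
    """
    if axis == "columns":
        std = zscore_standardize(matrix.T, axis="rows")
        return StandardizedMatrix(
            values=std.values.T,
            row_order=list(matrix.index.astype(str)),
            column_order=std.row_order,
            constant_rows=std.constant_rows,
        )
    if axis != "rows":
        raise MeprodError(f"axis must be 'rows' or 'columns' (got {axis!r})")

    data = matrix.astype(float)
    finite_counts = np.isfinite(data.to_numpy()).sum(axis=1)
    keep = finite_counts >= 2
    dropped = int((~keep).sum())
    if dropped:
        logger.info("z-score standardization dropped %d rows with <2 finite values", dropped)
    data = data.loc[keep]
    means = data.mean(axis=1, skipna=True)
    sds = data.std(axis=1, ddof=1, skipna=True)
    constant = sds == 0
    safe_sds = sds.where(~constant, 1.0)
    z = data.sub(means, axis=0).div(safe_sds, axis=0)
    z.loc[constant] = 0.0
    return StandardizedMatrix(
        values=z,
        row_order=list(z.index.astype(str)),
        column_order=list(z.columns.astype(str)),
        constant_rows=list(z.index[constant].astype(str)),
    )


def _matrix_values(Z: StandardizedMatrix | pd.DataFrame) -> pd.DataFrame:
    return Z.values if isinstance(Z, StandardizedMatrix) else Z


def _check_finite(frame: pd.DataFrame) -> None:
    arr = frame.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))
        cells = [
            (str(frame.index[i]), str(frame.columns[j])) for i, j in bad[:10]
        ]
        raise MeprodError(f"non-finite values at cells {cells}")


def hierarchical_cluster(
    Z: StandardizedMatrix | pd.DataFrame,
    on: str = "columns",
    method: str = "average",
) -> ClusteringResult:
    """Agglomerative clustering on pairwise Euclidean distances.

    Average linkage by default (configurable); SciPy's deterministic
    input-order tie-breaking applies. Returns the linkage matrix (merge
    heights in column 2) and the dendrogram leaf order.
    """
    frame = _matrix_values(Z)
    _check_finite(frame)
    if on == "columns":
        data = frame.to_numpy(dtype=float).T
        labels = [str(c) for c in frame.columns]
    elif on == "rows":
        data = frame.to_numpy(dtype=float)
        labels = [str(i) for i in frame.index]
    else:
        raise MeprodError(f"on must be 'rows' or 'columns' (got {on!r})")
    if data.shape[0] < 2:
        raise MeprodError("clustering requires at least two observations")
    link = linkage(data, method=method, metric="euclidean")
    order = [labels[i] for i in leaves_list(link)]
    return ClusteringResult(linkage=link, labels=labels, leaf_order=order)


def mds_embed(Z: StandardizedMatrix | pd.DataFrame) -> pd.DataFrame:
    """Classical (Torgerson) MDS of the samples (columns) into <=2 dimensions.

    Double-centers the squared Euclidean distance matrix and takes the top
    spectral coordinates. The sign of each axis is fixed so the first sample's
    coordinate is non-negative, making the embedding fully deterministic. Two
    samples give a 1-D result; rank-deficient input yields zero coordinates
    (with a warning for the fully degenerate case).
    """
    frame = _matrix_values(Z)
    _check_finite(frame)
    n = frame.shape[1]
    if n < 2:
        raise MeprodError("MDS requires at least two samples")
    X = frame.to_numpy(dtype=float).T  # samples x features
    D = squareform(pdist(X, metric="euclidean"))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    idx = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[idx], eigvecs[:, idx]
    ndim = min(2, n - 1)
    tol = max(eigvals.max(), 0.0) * 1e-12
    coords = np.zeros((n, ndim))
    for k in range(ndim):
        if eigvals[k] > tol:
            coords[:, k] = eigvecs[:, k] * math.sqrt(eigvals[k])
    if not np.any(np.abs(coords) > 0):
        warnings.warn("degenerate input: all samples identical; zero coordinates")
    for k in range(ndim):
        if coords[0, k] < 0:
            coords[:, k] = -coords[:, k]
    return pd.DataFrame(
        coords,
        index=[str(c) for c in frame.columns],
        columns=[f"dim{k + 1}" for k in range(ndim)],
    )


def ternary_shares(fold_change_table: pd.DataFrame) -> pd.DataFrame:
    """Per-protein shares of absolute log2 fold change across >=2 treatments.

    ``share_i = |fc_i| / sum_j |fc_j|`` so shares sum to 1 per protein;
    proteins whose fold changes are all zero are excluded (logged).
    """
    if fold_change_table.shape[1] < 2:
        raise MeprodError("ternary shares require at least two treatments")
    _check_finite(fold_change_table)
    absfc = fold_change_table.astype(float).abs()
    totals = absfc.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.info("ternary shares excluded %d all-zero proteins", int(zero.sum()))
    kept = absfc.loc[~zero]
    return kept.div(totals.loc[~zero], axis=0)


def titration_linear_screen(
    merged_table: pd.DataFrame,
    doses: Sequence[float],
    p_cut: float = 0.05,
    require_negative_slope: bool = True,
) -> list[LinearScreenResult]:
    """Per-protein OLS fit of relative translation against dose.

    The slope p-value is the standard t-test on the regression slope; raw
    (unadjusted) p-values drive selection. By default a linear responder must
    have ``p_slope < p_cut`` and a negative slope (translation falling with
    dose); both are parameters since the exact screening rule is a
    reconstruction. Proteins with fewer than three finite points are skipped.
    """
    doses_arr = np.asarray(doses, dtype=float)
    if doses_arr.size < 3:
        raise MeprodError("linear screen requires at least three dose levels")
    if doses_arr.size != merged_table.shape[1]:
        raise MeprodError(
            f"dose vector length {doses_arr.size} does not match "
            f"{merged_table.shape[1]} table columns"
        )
    results: list[LinearScreenResult] = []
    skipped = 0
    values = merged_table.to_numpy(dtype=float)
    for acc, y in zip(merged_table.index, values):
        mask = np.isfinite(y)
        if mask.sum() < 3:
            skipped += 1
            continue
        x, yy = doses_arr[mask], y[mask]
        if np.ptp(yy) == 0.0:
            results.append(
                LinearScreenResult(
                    master_accession=str(acc),
                    slope=0.0,
                    intercept=float(yy[0]),
                    r_squared=0.0,
                    p_slope=1.0,
                    is_linear_responder=False,
                )
            )
            continue
        fit = linregress(x, yy)
        selected = fit.pvalue < p_cut and (
            fit.slope < 0 if require_negative_slope else True
        )
        results.append(
            LinearScreenResult(
                master_accession=str(acc),
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r_squared=float(fit.rvalue) ** 2,
                p_slope=float(fit.pvalue),
                is_linear_responder=bool(selected),
            )
        )
    if skipped:
        logger.info("linear screen skipped %d proteins with <3 finite points", skipped)
    return results
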