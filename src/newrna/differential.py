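"""Mini-bulk differential expression and drug-panel dose-response.

The mini-bulk design compares few treated replicates (three per
compound) against controls sampled from a DMSO pool, which makes naive
per-gene variance estimates unstable.  The pipeline therefore:

1. fits the mean-variance trend across genes (lowess by default, linear
   optionally) and uses the predicted variance as a *floor* -- a gene
   whose observed group variance falls below the trend is tested with
   the predicted value instead (flooring can only make tests more
   conservative);
2. runs a Welch t-test on the floored variances per gene, on
   log2(CPM + 1) new-RNA expression;
3. corrects across genes with the two-stage (Benjamini-Krieger-
   Yekutieli) linear step-up FDR procedure.

For the dose-response panel, log2 new expression is regressed on
log10(dose in nM) across the five-dose grid, with untreated controls
entered one decade below the lowest dose; slopes are tested per gene and
corrected per drug with the same two-stage FDR.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix

__all__ = [
    "variance_floor",
    "adjusted_t_test",
    "two_stage_fdr",
    "de_compound",
    "de_screen",
    "dose_response_fit",
    "cluster_responses",
]

logger = logging.getLogger(__name__)


class DegenerateFitError(ValueError):
    pass


class InsufficientReplicatesError(ValueError):
    pass


# --------------------------------------------------------------------------
# variance floor
# --------------------------------------------------------------------------

def variance_floor(
    means: Sequence[float],
    variances: Sequence[float],
    method: str = "lowess",
    frac: float = 0.3,
) -> Callable[[np.ndarray], np.ndarray]:
    """Fit the expected-variance-given-expression trend.

    Returns a function mapping mean expression to predicted variance
    (clipped below at 0).  ``method`` is "lowess" (default, span
    ``frac``) or "linear" (least squares of variance on mean).
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if len(means) < 10:
        raise ValueError("need at least 10 genes to fit a variance trend")
    if np.all(variances == 0):
        raise DegenerateFitError("all observed variances are zero")
    if method == "linear":
        slope, intercept = np.polyfit(means, variances, deg=1)

        def predict(m):
            return np.clip(slope * np.asarray(m, dtype=float) + intercept, 0.0, None)

        return predict
    if method == "lowess":
        from statsmodels.nonparametric.smoothers_lowess import lowess

        fitted = lowess(variances, means, frac=frac, return_sorted=True)
        xs, ys = fitted[:, 0], np.clip(fitted[:, 1], 0.0, None)

        def predict(m):
            return np.interp(np.asarray(m, dtype=float), xs, ys)

        return predict
    raise ValueError(f"unknown method {method!r}")


# --------------------------------------------------------------------------
# floored Welch t-test
# --------------------------------------------------------------------------

def _welch_floored(mt, vt, nt, mc, vc, nc):
    """Welch statistic and two-sided p on (already floored) variances."""
    mt, vt, mc, vc = (np.asarray(a, dtype=float) for a in (mt, vt, mc, vc))
    se2 = vt / nt + vc / nc
    diff = mt - mc
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, diff / np.sqrt(se2), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
        df_num = se2**2
        df_den = (vt / nt) ** 2 / (nt - 1) + (vc / nc) ** 2 / (nc - 1)
        dof = np.where(df_den > 0, df_num / df_den, 1.0)
    p = np.where(se2 > 0, 2.0 * stats.t.sf(np.abs(t), dof), np.where(diff == 0, 1.0, 0.0))
    return t, p, diff


def adjusted_t_test(
    treated: Sequence[float],
    control: Sequence[float],
    floor: Callable[[np.ndarray], np.ndarray] | None,
) -> tuple[float, float, float]:
    """Variance-floored Welch t-test for one gene.

    Each group's variance is replaced by ``max(observed, floor(group
    mean))``; the statistic is Welch's t with Welch-Satterthwaite
    degrees of freedom on the floored variances; the p-value is
    two-sided.  Returns (t, p, mean_diff).
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need at least 2 values per group")
    mt, mc = treated.mean(), control.mean()
    vt, vc = treated.var(ddof=1), control.var(ddof=1)
    if floor is not None:
        vt = max(vt, float(floor(mt)))
        vc = max(vc, float(floor(mc)))
    t, p, diff = _welch_floored(mt, vt, len(treated), mc, vc, len(control))
    return float(t), float(p), float(diff)


# --------------------------------------------------------------------------
# two-stage FDR (Benjamini-Krieger-Yekutieli linear step-up)
# --------------------------------------------------------------------------

def _bh_n_rejected(p_sorted: np.ndarray, level: float) -> int:
    m = len(p_sorted)
    ok = np.nonzero(p_sorted <= level * np.arange(1, m + 1) / m)[0]
    return int(ok[-1] + 1) if len(ok) else 0


def two_stage_fdr(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Two-stage linear step-up q-values.

    Stage 1 estimates the number of true nulls m0 by a first BH pass at
    level alpha/(1+alpha); stage 2 applies the step-up with the level
    rescaled by m0.  The returned q-values satisfy q <= alpha exactly
    when the two-stage procedure rejects at alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    r1 = _bh_n_rejected(p_sorted, alpha / (1.0 + alpha))
    # when stage 1 rejects nothing or everything the m0 estimate is
    # uninformative and the full m is used (BKY Definition 6 convention)
    m0 = m if r1 in (0, m) else m - r1
    out = np.empty(m)
    raw = p_sorted * (1.0 + alpha) * m0 / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    out[order] = q_sorted
    return out


# --------------------------------------------------------------------------
# compound screen differential expression
# --------------------------------------------------------------------------

def _log2_cpm(values: pd.DataFrame) -> pd.DataFrame:
    cpm = values / values.sum(axis=0) * 1e6
    return np.log2(cpm + 1.0)


def _compound_rng(seed: int, compound_id: str) -> np.random.Generator:
    digest = hashlib.blake2s(str(compound_id).encode(), digest_size=4).digest()
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, int.from_bytes(digest, "big")])
    )


def de_compound(
    expr: ExpressionMatrix,
    compound_id: str,
    treated_samples: Sequence[str],
    dmso_pool: Sequence[str],
    n_controls: int = 10,
    seed: int = 0,
    layer: str = "new",
    transform: str = "log2_cpm",
    floor_method: str = "lowess",
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential expression of one compound against sampled controls.

    Exactly three treated replicates are required; ``n_controls`` DMSO
    samples are drawn without replacement with an RNG seeded from
    (seed, compound_id), so draws are independent across compounds and
    reproducible.  Expression is log2(CPM+1) of the chosen layer unless
    ``transform="none"``.
    """
    if len(treated_samples) != 3:
        raise InsufficientReplicatesError(
            f"{compound_id}: need exactly 3 treated replicates, got {len(treated_samples)}"
        )
    if len(dmso_pool) < n_controls:
        raise InsufficientReplicatesError(
            f"{compound_id}: control pool smaller than n_controls={n_controls}"
        )
    values = expr[layer]
    if transform == "log2_cpm":
        values = _log2_cpm(values)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    rng = _compound_rng(seed, compound_id)
    controls = list(rng.choice(np.asarray(dmso_pool, dtype=object), size=n_controls, replace=False))
    tmat = values[list(treated_samples)].to_numpy()
    cmat = values[controls].to_numpy()
    mt, mc = tmat.mean(axis=1), cmat.mean(axis=1)
    vt, vc = tmat.var(axis=1, ddof=1), cmat.var(axis=1, ddof=1)
    floor = variance_floor(
        np.concatenate([mt, mc]), np.concatenate([vt, vc]), method=floor_method
    )
    vt_f = np.maximum(vt, floor(mt))
    vc_f = np.maximum(vc, floor(mc))
    t, p, diff = _welch_floored(mt, vt_f, tmat.shape[1], mc, vc_f, cmat.shape[1])
    q = two_stage_fdr(p, alpha=fdr_alpha)
    return pd.DataFrame(
        {
            "gene_id": values.index,
            "compound_id": compound_id,
            "mean_diff": diff,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "variance_floored_treated": vt_f > vt,
            "variance_floored_control": vc_f > vc,
        }
    ).reset_index(drop=True)


def de_screen(
    expr: ExpressionMatrix,
    design: Mapping[str, Sequence[str]],
    dmso_pool: Sequence[str],
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`de_compound` for every compound in ``design``
    (compound_id -> treated sample names), skipping compounds without
    exactly three replicates."""
    results = []
    for compound_id, samples in design.items():
        try:
            results.append(de_compound(expr, compound_id, samples, dmso_pool, **kwargs))
        except InsufficientReplicatesError as exc:
            logger.warning("skipping compound: %s", exc)
    if not results:
        return pd.DataFrame()
    return pd.concat(results, ignore_index=True)


# --------------------------------------------------------------------------
# dose-response fits
# --------------------------------------------------------------------------

def dose_response_fit(
    values: pd.DataFrame,
    doses_nM: Mapping[str, float],
    drug_id: str = "drug",
    pseudo_dose: float | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene linear fit of expression on log10(dose).

    ``values`` is genes x samples (log2 new expression); ``doses_nM``
    maps sample -> dose in nM, with 0 (or None/NaN) marking untreated
    controls, which enter at a pseudo-dose one decade below the lowest
    real dose.  Requires at least 3 distinct dose levels.  The slope is
    expression change per log10 dose unit; p-values are two-sided
    t-tests on the slope; q-values are two-stage FDR across genes.
    """
    samples = [s for s in values.columns if s in doses_nM]
    doses = np.array(
        [np.nan if doses_nM[s] in (None,) else float(doses_nM[s]) for s in samples]
    )
    positive = doses[np.isfinite(doses) & (doses > 0)]
    if len(positive) == 0:
        raise ValueError("no positive doses supplied")
    if pseudo_dose is None:
        pseudo_dose = positive.min() / 10.0
    doses = np.where(np.isfinite(doses) & (doses > 0), doses, pseudo_dose)
    x = np.log10(doses)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct dose levels")
    y = values[samples].to_numpy(dtype=float)
    n = len(x)
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    slope = (y @ xc) / sxx
    intercept = y.mean(axis=1) - slope * x.mean()
    resid = y - (intercept[:, None] + slope[:, None] * x[None, :])
    sse = np.sum(resid**2, axis=1)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / dof / sxx)
        t = np.where(se > 0, slope / se, np.where(slope == 0, 0.0, np.inf))
    p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), dof), np.where(slope == 0, 1.0, 0.0))
    q = two_stage_fdr(p, alpha=fdr_alpha)
    return pd.DataFrame(
        {
            "gene_id": values.index,
            "drug_id": drug_id,
            "slope": slope,
            "intercept": intercept,
            "p_value": p,
            "q_value": q,
        }
    ).reset_index(drop=True)


# --------------------------------------------------------------------------
# response clustering
# --------------------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: pd.Series
    distance: pd.DataFrame
    dropped: list


def cluster_responses(slopes: pd.DataFrame, r_cutoff: float = 0.33) -> ClusterResult:
    """Average-linkage clustering of drugs on dose-response slopes.

    Drug-drug distance is 1 - Pearson correlation between slope
    vectors; flat clusters are cut at distance 1 - ``r_cutoff``.
    Constant slope columns have undefined correlation and are dropped
    with a warning.
    """
    dropped = [c for c in slopes.columns if slopes[c].std(ddof=0) == 0]
    if dropped:
        warnings.warn(f"dropping constant-slope drugs: {dropped}")
    kept = slopes.drop(columns=dropped)
    if kept.shape[1] < 2:
        raise ValueError("need at least 2 drugs with non-constant slopes")
    corr = kept.corr(method="pearson")
    dist = 1.0 - corr
    condensed = squareform(dist.to_numpy(), checks=False)
    condensed = np.clip(condensed, 0.0, None)
    Z = linkage(condensed, method="average")
    flat = fcluster(Z, t=1.0 - r_cutoff, criterion="distance")
    labels = pd.Series(flat, index=kept.columns, name="cluster")
    return ClusterResult(linkage=Z, labels=labels, distance=dist, dropped=dropped)
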