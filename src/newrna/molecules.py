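"""Single-molecule new/old classification by binomial likelihood ratio.

Each stitched molecule with n convertible positions and k specific
mismatches is tested with H0: per-position mismatch rate p = p_e against
HA: p = p_c (p_c > p_e).  The likelihood ratio is monotone in k, so the
non-randomized Neyman-Pearson test of size <= alpha rejects (calls the
molecule "new") iff k >= k*, with k* the smallest count whose upper
binomial tail under H0 does not exceed alpha.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom

__all__ = ["critical_k", "classify_molecules", "cell_new_fraction", "new_count_matrix"]

DEFAULT_ALPHA = 0.05


class DegenerateRatesError(ValueError):
    pass


def critical_k(n: int, p_e: float, alpha: float = DEFAULT_ALPHA) -> int:
    """Smallest k* with P(K >= k* | K ~ Binomial(n, p_e)) <= alpha.

    A molecule with n = 0 cannot reject H0; k* is defined as 1
    (unreachable), so it is always called old.  With p_e = 0 any
    conversion is impossible under H0, hence k* = 1.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n == 0:
        return 1
    if p_e == 0:
        return 1
    # P(K >= k) = sf(k - 1); find the smallest k in 1..n+1
    ks = np.arange(1, n + 2)
    tails = binom.sf(ks - 1, n, p_e)
    ok = np.nonzero(tails <= alpha)[0]
    return int(ks[ok[0]])


def critical_k_vector(ns: np.ndarray, p_e: float, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Vectorized :func:`critical_k` over an array of n values."""
    ns = np.asarray(ns, dtype=int)
    uniq = np.unique(ns)
    table = {int(n): critical_k(int(n), p_e, alpha) for n in uniq}
    return np.array([table[int(n)] for n in ns])


def classify_molecules(
    molecules: pd.DataFrame,
    p_c: float,
    p_e: float,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Call each molecule new or old at level alpha.

    ``molecules`` needs columns n and k (plus any identifiers, which are
    carried through).  Requires p_c > p_e: the alternative fixes the
    rejection direction.  Adds columns ``critical_k`` and ``call``.
    """
    if not p_c > p_e:
        raise DegenerateRatesError(f"degenerate rates: p_c={p_c} <= p_e={p_e}")
    out = molecules.copy()
    kstar = critical_k_vector(out["n"].to_numpy(), p_e, alpha)
    out["critical_k"] = kstar
    out["call"] = np.where(out["k"].to_numpy() >= kstar, "new", "old")
    return out


def cell_new_fraction(calls: pd.DataFrame, cell_col: str = "cell_id") -> pd.Series:
    """Fraction of molecules called new, per cell."""
    if len(calls) == 0:
        raise ValueError("need at least one molecule")
    return calls.groupby(cell_col)["call"].apply(lambda s: (s == "new").mean())


def new_count_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Per cell x gene table of new and old molecule counts.

    Output columns: cell_id, gene_id, n_new, n_old -- the input for
    bursting inference (n_new) and for exporting count matrices to
    standard count-based differential-expression tools.
    """
    tab = (
        calls.groupby(["cell_id", "gene_id", "call"]).size().unstack(fill_value=0)
    )
    for col in ("new", "old"):
        if col not in tab.columns:
            tab[col] = 0
    tab = tab.rename(columns={"new": "n_new", "old": "n_old"}).reset_index()
    return tab[["cell_id", "gene_id", "n_new", "n_old"]]
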