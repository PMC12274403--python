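"""Promoter ChIP-peak enrichment and GO overrepresentation.

Promoter windows span 1,000 bp upstream to 100 bp downstream of the
TSS, oriented by gene strand (0-based half-open internally, width
1,100).  Per DNA-binding factor, a 2x2 table of up-/down-regulated
genes with/without a peak in the promoter is tested with a two-sided
Fisher exact test (exact hypergeometric enumeration: the p-value is the
sum of probabilities of all tables no more probable than the observed
one), with the fold change the ratio of peak-containing fractions and
Benjamini-Hochberg correction across factors.

GO overrepresentation compares a study set against an
expression-matched (or up-regulated) background: chi-square when every
expected count exceeds ten, Fisher exact otherwise, with two-stage FDR
across terms and obsolete terms excluded from the universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2_contingency, hypergeom
from statsmodels.stats.multitest import multipletests

from .differential import two_stage_fdr

__all__ = [
    "PromoterWindow",
    "promoter_window",
    "gene_windows",
    "peak_in_promoter",
    "fisher_exact_two_sided",
    "factor_enrichment",
    "region_enrichment",
    "expression_matched_background",
    "go_overrepresentation",
]

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100


@dataclass
class PromoterWindow:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str


def promoter_window(
    gene_id: str,
    tss: int,
    strand: str,
    chrom: str,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> PromoterWindow:
    """Strand-aware promoter window around a 1-based TSS.

    Upstream/downstream are measured in transcription direction: a
    plus-strand gene with TSS 10,000 gets [9000, 10100); the mirrored
    minus-strand window is [9900, 11000).  Windows are truncated at the
    chromosome start.
    """
    if tss <= 0:
        raise ValueError("TSS must be a positive 1-based coordinate")
    if strand not in "+-":
        raise ValueError(f"invalid strand {strand!r}")
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream, tss + upstream
    return PromoterWindow(gene_id, chrom, max(0, start), end, strand)


def gene_windows(
    annotation: pd.DataFrame,
    region: str = "promoter",
    downstream_extent: int = 1000,
) -> pd.DataFrame:
    """Region windows per gene from a TSS/TES annotation table.

    Regions (our scheme, configurable): ``promoter`` = TSS-1000..TSS+100,
    ``gene_body`` = TSS+100..TES, ``downstream`` = TES..TES+1000, all in
    transcription direction.  ``annotation`` needs gene_id, chrom, tss,
    strand and (for non-promoter regions) tes.
    """
    rows = []
    for g in annotation.itertuples(index=False):
        if region == "promoter":
            w = promoter_window(g.gene_id, int(g.tss), g.strand, g.chrom)
            start, end = w.start, w.end
        elif region == "gene_body":
            if g.strand == "+":
                start, end = int(g.tss) + PROMOTER_DOWNSTREAM, int(g.tes)
            else:
                start, end = int(g.tes), int(g.tss) - PROMOTER_DOWNSTREAM
        elif region == "downstream":
            if g.strand == "+":
                start, end = int(g.tes), int(g.tes) + downstream_extent
            else:
                start, end = int(g.tes) - downstream_extent, int(g.tes)
        else:
            raise ValueError(f"unknown region {region!r}")
        start = max(0, start)
        if end > start:
            rows.append((g.gene_id, g.chrom, start, end, g.strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def peak_in_promoter(windows: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Boolean gene x factor table: any >= 1 bp peak/window overlap.

    ``windows``: gene_id, chrom, start, end (0-based half-open).
    ``peaks``: BED-style chrom, start, end, name where ``name`` is the
    factor id (a single unnamed factor is fine).
    """
    peaks = peaks.copy()
    if "name" not in peaks.columns:
        peaks["name"] = "peak"
    trees: dict[tuple[str, str], IntervalTree] = {}
    for row in peaks.itertuples(index=False):
        if row.end <= row.start:
            continue
        trees.setdefault((row.name, row.chrom), IntervalTree()).addi(row.start, row.end)
    factors = sorted(peaks["name"].unique())
    peak_chroms = {c for (_, c) in trees}
    missing = sorted(set(windows["chrom"]) - peak_chroms)
    if missing:
        counts = windows["chrom"].value_counts()
        warnings.warn(
            "windows on chromosomes absent from the peak file: "
            + ", ".join(f"{c} ({counts[c]} windows)" for c in missing)
        )
    out = pd.DataFrame(
        False, index=pd.Index(windows["gene_id"], name="gene_id"), columns=factors
    )
    for row in windows.itertuples(index=False):
        for factor in factors:
            tree = trees.get((factor, row.chrom))
            if tree is not None and tree.overlap(row.start, row.end):
                out.at[row.gene_id, factor] = True
    return out


# --------------------------------------------------------------------------
# Fisher exact test (two-sided, exact enumeration)
# --------------------------------------------------------------------------

def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    The p-value sums the probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's
    (with a tiny relative tolerance for floating-point ties).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n1, n2 = a + b, c + d
    K = a + c
    N = n1 + n2
    xs = np.arange(max(0, K - n2), min(K, n1) + 1)
    pmf = hypergeom.pmf(xs, N, K, n1)
    p_obs = hypergeom.pmf(a, N, K, n1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return min(p, 1.0)


@dataclass
class EnrichmentResult:
    factor_id: str
    n_up_with_peak: int
    n_up_total: int
    n_down_with_peak: int
    n_down_total: int
    fold_change: float
    p_value: float
    q_value: float = np.nan


def _fold_change(a: int, n1: int, c: int, n2: int) -> float:
    if n1 == 0 or n2 == 0:
        return np.nan
    if c == 0:
        return np.inf if a > 0 else np.nan
    return (a / n1) / (c / n2)


def factor_enrichment(
    up_genes: Iterable[str],
    down_genes: Iterable[str],
    peak_table: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-factor promoter-peak enrichment of up- vs down-regulated genes.

    ``peak_table`` is the boolean gene x factor table from
    :func:`peak_in_promoter`.  Factors whose 2x2 table has a zero peak
    margin (no gene with a peak, or every gene with one) are skipped.
    Benjamini-Hochberg q-values across tested factors; significance is
    conventionally read at q < ``alpha``.
    """
    up = [g for g in up_genes if g in peak_table.index]
    down = [g for g in down_genes if g in peak_table.index]
    if len(up) == 0 or len(down) == 0:
        raise ValueError("both gene sets must be nonempty (after restriction)")
    rows = []
    skipped = []
    for factor in peak_table.columns:
        a = int(peak_table.loc[up, factor].sum())
        c = int(peak_table.loc[down, factor].sum())
        n1, n2 = len(up), len(down)
        if a + c == 0 or (a == n1 and c == n2):
            skipped.append((factor, "degenerate peak margin"))
            continue
        p = fisher_exact_two_sided([[a, n1 - a], [c, n2 - c]])
        rows.append(
            {
                "factor_id": factor,
                "n_up_with_peak": a,
                "n_up_total": n1,
                "n_down_with_peak": c,
                "n_down_total": n2,
                "fold_change": _fold_change(a, n1, c, n2),
                "p_value": p,
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["q_value"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result["significant"] = result["q_value"] < alpha
    result.attrs["skipped"] = skipped
    return result


def region_enrichment(
    up_genes: Iterable[str],
    down_genes: Iterable[str],
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    regions: Sequence[str] = ("promoter", "gene_body", "downstream"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Factor enrichment per genomic region relative to the gene.

    Runs the promoter machinery for each region definition, reporting
    both nominal and BH-adjusted p-values with a ``region`` column.
    """
    frames = []
    for region in regions:
        windows = gene_windows(annotation, region=region)
        table = peak_in_promoter(windows, peaks)
        res = factor_enrichment(up_genes, down_genes, table, alpha=alpha)
        res.insert(0, "region", region)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# expression-matched backgrounds and GO overrepresentation
# --------------------------------------------------------------------------

def expression_matched_background(
    input_genes: Iterable[str],
    expression: pd.Series,
    max_rank_diff: int = 100,
    max_unmatched_frac: float = 0.10,
) -> tuple[list, dict]:
    """Pick a background matched on average expression rank.

    Genes are ranked by expression; for each input gene the search
    alternates up/down the ranking to the nearest unused non-input gene.
    An input gene with no unused neighbour within ``max_rank_diff``
    ranks stays unmatched; if more than ``max_unmatched_frac`` of the
    input becomes unmatchable the search aborts.  Returns the matched
    background list and the input -> match map.
    """
    input_genes = list(dict.fromkeys(input_genes))
    missing = [g for g in input_genes if g not in expression.index]
    if missing:
        raise ValueError(f"input genes absent from expression ranking: {missing[:5]}")
    if len(expression) < 2 * len(input_genes):
        raise ValueError("expression universe smaller than twice the input set")
    ranked = expression.sort_values(ascending=False).index.to_list()
    rank_of = {g: i for i, g in enumerate(ranked)}
    in_input = set(input_genes)
    used: set = set()
    match_map: dict = {}
    unmatched = 0
    budget = max_unmatched_frac * len(input_genes)
    for gene in sorted(input_genes, key=rank_of.get):
        r = rank_of[gene]
        found = None
        for d in range(1, max_rank_diff + 1):
            for cand_rank in (r + d, r - d):
                if 0 <= cand_rank < len(ranked):
                    cand = ranked[cand_rank]
                    if cand not in in_input and cand not in used:
                        found = cand
                        break
            if found:
                break
        if found is None:
            unmatched += 1
            if unmatched > budget:
                warnings.warn(
                    f"aborting expression matching: {unmatched} of "
                    f"{len(input_genes)} input genes unmatchable"
                )
                break
        else:
            used.add(found)
            match_map[gene] = found
    return list(match_map.values()), match_map


def go_overrepresentation(
    study_genes: Iterable[str],
    background_genes: Iterable[str],
    gene2go: pd.DataFrame,
    ontology: pd.DataFrame | None = None,
    expected_threshold: float = 10.0,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """GO term overrepresentation of a study set vs a background set.

    Per term the 2x2 table (study/background x in-term/not) is tested
    with chi-square (no continuity correction) when all expected counts
    exceed ``expected_threshold``, otherwise with the exact Fisher
    test.  Obsolete ontology terms are excluded; q-values are two-stage
    FDR across tested terms.  The background may be an
    expression-matched set or the opposite-direction gene set.
    """
    study = list(dict.fromkeys(study_genes))
    background = list(dict.fromkeys(background_genes))
    if not study or not background:
        raise ValueError("study and background sets must be nonempty")
    term_names = {}
    valid_terms = None
    if ontology is not None:
        keep = ontology[~ontology["is_obsolete"]]
        valid_terms = set(keep["term_id"])
        term_names = dict(zip(keep["term_id"], keep["name"]))
    members: dict[str, set] = {
        term: set(grp["gene_id"]) for term, grp in gene2go.groupby("go_id")
    }
    n1, n2 = len(study), len(background)
    study_set, bg_set = set(study), set(background)
    rows = []
    for term, genes in sorted(members.items()):
        if valid_terms is not None and term not in valid_terms:
            continue
        a = len(study_set & genes)
        c = len(bg_set & genes)
        if a + c == 0:
            continue
        table = np.array([[a, n1 - a], [c, n2 - c]], dtype=float)
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if np.all(expected > expected_threshold):
            _, p, _, _ = chi2_contingency(table, correction=False)
            test = "chi2"
        else:
            p = fisher_exact_two_sided([[a, n1 - a], [c, n2 - c]])
            test = "fisher"
        rows.append(
            {
                "term_id": term,
                "name": term_names.get(term, ""),
                "n_study_in_term": a,
                "n_study": n1,
                "n_background_in_term": c,
                "n_background": n2,
                "fold_change": _fold_change(a, n1, c, n2),
                "test": test,
                "p_value": float(p),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["q_value"] = two_stage_fdr(result["p_value"], alpha=fdr_alpha)
    return result
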