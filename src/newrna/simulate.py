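"""Synthetic-data generators for 4sU conversion sequencing.

Every generator in this module emulates the statistical structure the
inference code assumes, so the whole toolkit is testable without any
sequencing data:

* :func:`simulate_reads` draws per-read conversion counts from the
  two-component binomial mixture -- a read from a gene with new-RNA
  fraction ``pi`` is "labeled" with probability ``pi`` and then shows
  ``k ~ Binomial(n, p_c + p_e)`` specific mismatches among its ``n``
  convertible positions, otherwise ``k ~ Binomial(n, p_e)``.
* :func:`simulate_minibulk_screen` builds replicate expression matrices
  with compound effects spiked into treated wells only.
* :func:`simulate_telegraph_labeled` is an exact (event-driven) stochastic
  simulation of the two-state promoter, counting transcripts born during
  the labeling window that survive degradation.

All generators take an explicit integer seed and use one private RNG
stream per call; a fixed seed gives byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "TelegraphConfig",
    "simulate_reads",
    "simulate_minibulk_screen",
    "simulate_telegraph_labeled",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def _check_prob(name: str, value: float, *, strict_upper: bool = False) -> None:
    upper_ok = value < 1 if strict_upper else value <= 1
    if not (0 <= value and upper_ok):
        raise ConfigurationError(f"{name}={value!r} is not a valid probability")


@dataclass
class SimulationConfig:
    """Configuration for the per-read conversion-count generator.

    Parameters
    ----------
    n_genes : int
        Number of genes to simulate.
    reads_per_gene : int or sequence of int
        Reads drawn for each gene (scalar broadcasts).
    p_c, p_e : float
        Conversion probability of a labeled position and the background
        error probability.  A labeled read converts each of its ``n``
        positions with probability ``p_c + p_e``; an unlabeled read with
        probability ``p_e``.
    pi_per_gene : float or sequence of float
        New-RNA fraction per gene (scalar broadcasts).
    n_length_dist : tuple (low, high) or callable(rng, size) -> int array
        Distribution of the number of convertible positions per read.
        The default is uniform on [20, 200], spanning the T-content of
        realistic 100-150 bp reads.
    sample_id : str
        Sample label written into the output table.
    seed : int
        RNG seed; fixed seed implies byte-identical output.
    """

    n_genes: int
    reads_per_gene: int | Sequence[int]
    p_c: float
    p_e: float
    pi_per_gene: float | Sequence[float]
    n_length_dist: tuple[int, int] | Callable = (20, 200)
    sample_id: str = "sample1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        _check_prob("p_c", self.p_c)
        _check_prob("p_e", self.p_e, strict_upper=True)
        self._pi = np.broadcast_to(
            np.asarray(self.pi_per_gene, dtype=float), (self.n_genes,)
        ).copy()
        if np.any((self._pi < 0) | (self._pi > 1)):
            raise ConfigurationError("all pi values must lie in [0, 1]")
        self._reads = np.broadcast_to(
            np.asarray(self.reads_per_gene, dtype=int), (self.n_genes,)
        ).copy()
        if np.any(self._reads < 0):
            raise ConfigurationError("reads_per_gene must be non-negative")


def _draw_n(cfg: SimulationConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    if callable(cfg.n_length_dist):
        n = np.asarray(cfg.n_length_dist(rng, size), dtype=int)
    else:
        low, high = cfg.n_length_dist
        n = rng.integers(low, high + 1, size=size)
    if np.any(n < 0):
        raise ConfigurationError("n_length_dist produced negative position counts")
    return n


def simulate_reads(cfg: SimulationConfig) -> pd.DataFrame:
    """Draw per-read conversion counts under the binomial mixture.

    Returns a DataFrame with columns ``sample_id, gene_id, read_id, n, k,
    true_label`` where ``true_label`` is 1 for reads drawn from the
    labeled (new-RNA) component.  Ground truth is retained so recovery of
    ``pi``, ``p_c`` and ``p_e`` can be checked directly.
    """
    rng = np.random.default_rng(cfg.seed)
    total = int(cfg._reads.sum())
    gene_idx = np.repeat(np.arange(cfg.n_genes), cfg._reads)
    n = _draw_n(cfg, rng, total)
    labeled = rng.random(total) < cfg._pi[gene_idx]
    rate = np.where(labeled, min(cfg.p_c + cfg.p_e, 1.0), cfg.p_e)
    k = rng.binomial(n, rate)
    return pd.DataFrame(
        {
            "sample_id": cfg.sample_id,
            "gene_id": np.char.add("g", gene_idx.astype(str)),
            "read_id": np.char.add("r", np.arange(total).astype(str)),
            "n": n,
            "k": k,
            "true_label": labeled.astype(int),
        }
    )


def _default_sd(mean_log2: np.ndarray) -> np.ndarray:
    # monotone decreasing noise on log2 scale, typical of expression data
    return 0.1 + 1.5 * np.exp(-np.asarray(mean_log2, dtype=float) / 3.0)


def simulate_minibulk_screen(
    n_genes: int,
    n_compounds: int,
    replicates: int = 3,
    n_controls: int = 12,
    effect_spec: Mapping[tuple[str, str], float] | None = None,
    noise_sd: Callable[[np.ndarray], np.ndarray] = _default_sd,
    frac_affected: float = 0.0,
    effect_size: float = 2.0,
    seed: int = 0,
    log_scale: bool = False,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a mini-bulk compound screen with known treatment effects.

    Gene baselines are drawn on log2 scale (Uniform(2, 12)); per-gene
    noise follows the monotone mean-variance relation ``noise_sd``.
    Affected (gene, compound) pairs are shifted by their log2 effect in
    the treated replicates only.  ``effect_spec`` maps
    ``(gene_id, compound_id) -> log2 fold change``; alternatively a
    random ``frac_affected`` of genes per compound is shifted by
    ``+/- effect_size``.  Returns the expression matrix (linear scale
    unless ``log_scale``) with layer ``"new"`` plus the ground-truth
    effect table.
    """
    if replicates < 2:
        raise ConfigurationError("replicates must be >= 2")
    if n_controls < 2:
        raise ConfigurationError("n_controls must be >= 2")
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    compounds = [f"cmp{i}" for i in range(n_compounds)]
    base = rng.uniform(2.0, 12.0, size=n_genes)
    sd = noise_sd(base)

    effects: dict[tuple[str, str], float] = dict(effect_spec or {})
    if effect_spec is None and frac_affected > 0:
        n_hit = int(round(frac_affected * n_genes))
        for cmp_id in compounds:
            hit = rng.choice(n_genes, size=n_hit, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_hit)
            for gi, s in zip(hit, signs):
                effects[(genes[gi], cmp_id)] = s * effect_size

    columns: dict[str, np.ndarray] = {}
    for j in range(n_controls):
        columns[f"DMSO_{j}"] = base + sd * rng.standard_normal(n_genes)
    shift = np.zeros(n_genes)
    for cmp_id in compounds:
        shift[:] = 0.0
        for (g, c), lfc in effects.items():
            if c == cmp_id:
                shift[genes.index(g)] = lfc
        for r in range(replicates):
            columns[f"{cmp_id}_rep{r}"] = base + shift + sd * rng.standard_normal(n_genes)

    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    if not log_scale:
        values = 2.0**values
    truth = pd.DataFrame(
        [(g, c, lfc) for (g, c), lfc in sorted(effects.items())],
        columns=["gene_id", "compound_id", "log2fc"],
    )
    expr = ExpressionMatrix({"new": values})
    return expr, truth


@dataclass
class TelegraphConfig:
    """Two-state promoter simulation parameters (rates per hour)."""

    k_on: float
    k_off: float
    k_syn: float
    k_deg: float
    t_label: float
    n_cells: int
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_syn", "k_deg"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.t_label <= 0:
            raise ConfigurationError("t_label must be > 0")
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be >= 1")


def stationary_on_probability(k_on: float, k_off: float) -> float:
    """Stationary probability of the ON promoter state.

    When both switching rates vanish the promoter never moves; the ON
    state is then used iff ``k_off == 0`` (the constitutive limit).
    """
    if k_on + k_off > 0:
        return k_on / (k_on + k_off)
    return 1.0 if k_off == 0 else 0.0


def simulate_telegraph_labeled(cfg: TelegraphConfig) -> np.ndarray:
    """Exact stochastic simulation of labeled-molecule counts per cell.

    The promoter starts in its stationary state; the labeled counter
    starts at 0 at labeling onset.  Transcripts born in ``[0, t_label]``
    are labeled and may degrade before the end of the window.  Returns an
    integer array of length ``n_cells`` with the labeled count at
    ``t_label``.
    """
    # plain-Python Gillespie loop; random.Random is much faster than
    # per-scalar numpy Generator calls at this event granularity
    seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0])
    rng = random.Random(seed)
    p_on = stationary_on_probability(cfg.k_on, cfg.k_off)
    k_on, k_off, k_syn, k_deg, t_end = (
        cfg.k_on,
        cfg.k_off,
        cfg.k_syn,
        cfg.k_deg,
        cfg.t_label,
    )
    counts = np.zeros(cfg.n_cells, dtype=int)
    for i in range(cfg.n_cells):
        on = rng.random() < p_on
        t = 0.0
        x = 0
        while True:
            r_switch = k_off if on else k_on
            r_syn = k_syn if on else 0.0
            r_deg = k_deg * x
            total = r_switch + r_syn + r_deg
            if total <= 0.0:
                break
            t += rng.expovariate(total)
            if t >= t_end:
                break
            u = rng.random() * total
            if u < r_switch:
                on = not on
            elif u < r_switch + r_syn:
                x += 1
            else:
                x -= 1
        counts[i] = x
    return counts
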