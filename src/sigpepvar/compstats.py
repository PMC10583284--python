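"""Descriptive statistics of a signal-peptide collection.

Region length distributions, per-region residue composition,
cleavage-site-anchored position frequencies (the table behind the
signal-peptidase rarity rule and sequence logos), per-position
information content in bits, a Pearson utility for score/expression
correlation, and gene-level aggregation of classified variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scistats

from .errors import AnnotationError, SigPepVarError
from .mapping import Region, SignalPeptide
from .scales import AMINO_ACIDS

#: Default cleavage-anchored window (inclusive, no zero position).
DEFAULT_WINDOW: tuple[int, int] = (-6, 1)


def _window_positions(window: tuple[int, int]) -> list[int]:
    lo, hi = window
    if lo == 0 or hi == 0:
        # The cleavage-relative axis has no zero; an endpoint of 0 names a
        # position that does not exist and would hide a coordinate bug.
        raise AnnotationError("cleavage-relative windows must not name position 0")
    if lo > hi:
        raise AnnotationError(f"empty window {window}")
    positions = [p for p in range(lo, hi + 1) if p != 0]
    if -1 not in positions:
        raise AnnotationError(f"window {window} must include position -1")
    return positions


@dataclass(frozen=True)
class PositionFrequencyTable:
    """Residue counts and fractions at cleavage-relative positions.

    Peptides shorter than the window contribute only to the positions they
    define, so denominators are per-position rather than ``n_sequences``.
    No pseudocounts: a residue never observed at a position has frequency
    exactly 0, which the cleavage-site rule relies on to flag
    never-observed residues.
    """

    window: tuple[int, int]
    freqs: Mapping[int, Mapping[str, float]]
    counts: Mapping[int, Mapping[str, int]]
    n_sequences: int

    def positions(self) -> list[int]:
        return sorted(self.freqs)

    def frequency(self, position: int, residue: str) -> float:
        """Fraction of sequences carrying ``residue`` at cleavage-relative
        ``position``; 0.0 for residues never observed there."""
        if position not in self.freqs:
            raise AnnotationError(
                f"cleavage-relative position {position} absent from the "
                f"frequency table (window {self.window})"
            )
        return self.freqs[position].get(residue.upper(), 0.0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: position, residue, count, fraction."""
        rows = [
            (pos, res, self.counts[pos].get(res, 0), self.freqs[pos].get(res, 0.0))
            for pos in self.positions()
            for res in AMINO_ACIDS
        ]
        return pd.DataFrame(rows, columns=["position", "residue", "count", "fraction"])


@dataclass(frozen=True)
class RegionComposition:
    """Per-region residue fractions and region-length statistics."""

    frequencies: Mapping[str, Mapping[str, float]]
    median_lengths: Mapping[str, float]
    length_histograms: Mapping[str, Mapping[int, int]] = field(default_factory=dict)


def _require_nonempty(peptides: Sequence[SignalPeptide]) -> None:
    if not peptides:
        raise SigPepVarError("empty peptide collection")


def region_length_stats(peptides: Sequence[SignalPeptide]) -> RegionComposition:
    """Median and histogram of region lengths; 'total' excludes the +1 residue."""
    _require_nonempty(peptides)
    lengths = {
        "N": [sp.n_end for sp in peptides],
        "H": [sp.h_end - sp.n_end for sp in peptides],
        "C": [sp.sp_len - sp.h_end for sp in peptides],
        "total": [sp.sp_len for sp in peptides],
    }
    medians = {k: float(np.median(v)) for k, v in lengths.items()}
    hists = {
        k: dict(sorted(pd.Series(v).value_counts().items())) for k, v in lengths.items()
    }
    return RegionComposition(frequencies={}, median_lengths=medians,
                             length_histograms=hists)


def region_residue_frequencies(peptides: Sequence[SignalPeptide]) -> RegionComposition:
    """Pooled residue fractions per region across the collection."""
    _require_nonempty(peptides)
    pools = {
        "N": "".join(sp.n_region for sp in peptides),
        "H": "".join(sp.h_region for sp in peptides),
        "C": "".join(sp.c_region for sp in peptides),
    }
    freqs: dict[str, dict[str, float]] = {}
    for region, pool in pools.items():
        total = len(pool)
        freqs[region] = {res: pool.count(res) / total for res in AMINO_ACIDS}
    stats = region_length_stats(peptides)
    return RegionComposition(frequencies=freqs,
                             median_lengths=stats.median_lengths,
                             length_histograms=stats.length_histograms)


def position_frequency_table(
    peptides: Sequence[SignalPeptide],
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> PositionFrequencyTable:
    """Count residues at cleavage-relative positions across wild-type peptides.

    ``window`` is inclusive and must exclude 0 (no zero position exists) and
    include −1 to be usable by the cleavage-site rule.
    """
    _require_nonempty(peptides)
    positions = _window_positions(window)
    counts: dict[int, dict[str, int]] = {p: {} for p in positions}
    for sp in peptides:
        for rel in positions:
            # protein position of cleavage-relative rel
            pos = sp.sp_len + 1 + rel if rel < 0 else sp.sp_len + rel
            if 1 <= pos <= len(sp.sequence):
                res = sp.sequence[pos - 1]
                counts[rel][res] = counts[rel].get(res, 0) + 1
    freqs: dict[int, dict[str, float]] = {}
    for rel, c in counts.items():
        total = sum(c.values())
        freqs[rel] = {res: n / total for res, n in c.items()} if total else {}
    return PositionFrequencyTable(
        window=window, freqs=freqs, counts=counts, n_sequences=len(peptides)
    )


def information_content(table: PositionFrequencyTable) -> dict[int, float]:
    """Per-position information content in bits.

    ``IC(pos) = log2(20) + Σ_r p_r log2 p_r`` with the ``0·log 0 ≡ 0``
    convention: 0 bits for a uniform position, log2(20) ≈ 4.3219 bits for
    a fully conserved one.  Letter heights in a logo are ``p_r × IC(pos)``.
    """
    ic: dict[int, float] = {}
    for pos in table.positions():
        entropy = -sum(
            p * math.log2(p) for p in table.freqs[pos].values() if p > 0.0
        )
        ic[pos] = math.log2(20) - entropy
    return ic


def expression_correlation(
    scores: Iterable[float], observed: Iterable[float]
) -> tuple[float, float]:
    """Pearson r and r² between Boman-change scores and measured mRNA changes.

    A pure utility for reproducing score/expression correlation statistics
    when experimental expression measurements are supplied alongside the
    computed scores.
    """
    x = np.asarray(list(scores), dtype=float)
    y = np.asarray(list(observed), dtype=float)
    if x.shape != y.shape:
        raise SigPepVarError("scores and observed values must be paired")
    if x.size < 3:
        raise SigPepVarError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise SigPepVarError("zero variance in one of the vectors")
    r = float(_scistats.pearsonr(x, y).statistic)
    return r, r * r


#: Canonical order for Venn cell keys built from region letters.
_VENN_ORDER = "NHC"


def _venn_key(regions: frozenset[str]) -> str:
    return "".join(r for r in _VENN_ORDER if r in regions)


def gene_region_overlap(results: Iterable) -> dict[str, int]:
    """Gene-level Venn cells over the regions hit by each gene's PPVs.

    For every non-empty subset of {N, H, C} (PLUS1 counted with C), the
    number of genes whose PPVs hit exactly that subset; the ``no_ppv``
    cell counts genes that have variants but no PPV.  Cells over subsets
    sum to the number of genes with at least one PPV.
    """
    per_gene: dict[str, set[str]] = {}
    for res in results:
        gene = res.gene
        per_gene.setdefault(gene, set())
        if res.is_ppv:
            region = res.mapped.region
            letter = "C" if region is Region.PLUS1 else region.value
            per_gene[gene].add(letter)
    cells = {_venn_key(frozenset(s)): 0 for s in _all_subsets()}
    cells["no_ppv"] = 0
    for regions in per_gene.values():
        if regions:
            cells[_venn_key(frozenset(regions))] += 1
        else:
            cells["no_ppv"] += 1
    return cells


def _all_subsets() -> list[frozenset[str]]:
    letters = list(_VENN_ORDER)
    out: list[frozenset[str]] = []
    for mask in range(1, 8):
        out.append(frozenset(l for i, l in enumerate(letters) if mask >> i & 1))
    return out


def plot_logo(table: PositionFrequencyTable, ax=None):
    """Logo-style stacked-bar plot of per-position letter heights (bits).

    Optional hook; requires matplotlib.  Letters are drawn as stacked bars
    annotated with residue codes, tallest on top, height ``p × IC``.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + len(table.positions()), 3))
    ic = information_content(table)
    for x, pos in enumerate(table.positions()):
        bottom = 0.0
        stack = sorted(table.freqs[pos].items(), key=lambda kv: kv[1])
        for res, p in stack:
            h = p * ic[pos]
            if h <= 0:
                continue
            ax.bar(x, h, bottom=bottom, width=0.8, edgecolor="white")
            if h > 0.15:
                ax.text(x, bottom + h / 2, res, ha="center", va="center", fontsize=7)
            bottom += h
    ax.set_xticks(range(len(table.positions())))
    ax.set_xticklabels([f"{p:+d}" for p in table.positions()])
    ax.set_xlabel("position relative to cleavage site")
    ax.set_ylabel("bits")
    ax.set_ylim(0, math.log2(20))
    return ax
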