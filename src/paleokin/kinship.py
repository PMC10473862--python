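"""Modified Pairwise Mismatch Rate (MPMR) kinship estimation.

For two pseudohaploid genomes the raw pairwise mismatch rate (PMR) is
the fraction of jointly covered SNPs at which the single sampled
alleles disagree.  Because each call is one random allele per
individual, the expected PMR is ``(1 - phi) * B`` where ``phi`` is the
kinship coefficient of the pair and ``B`` the PMR of an unrelated pair
from the same population.  Dividing by an estimate of ``B`` (the cohort
median by default, assuming a mostly unrelated cohort) gives a
normalized score with population-free expectations:

==================================  =====  ==========
relationship                        phi    E[norm]
==================================  =====  ==========
same individual / monozygotic twin  1/2    0.50
parent-offspring, full sibling      1/4    0.75
half-sibling, avuncular, grandpar.  1/8    0.875
unrelated                           0      1.00
==================================  =====  ==========

Degree classes cut the score at the midpoints of adjacent expectations
(0.625, 0.8125, 0.90625).  Uncertainty comes from a delete-one block
jackknife over contiguous 20 Mb windows, robust to linkage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np

from .io_formats import PseudohaploidMatrix, chromosome_sort_key

__all__ = [
    "MISSING",
    "DEFAULT_CUTOFFS",
    "PairCounts",
    "KinshipEstimate",
    "pairwise_mismatch",
    "background_rate",
    "classify_degree",
    "jackknife_se",
    "kin_matrix",
    "build_network",
]

MISSING = 9
BLOCK_SIZE = 20_000_000  # 20 Mb jackknife windows

#: Upper bounds (exclusive) of the identical/first/second classes on the
#: normalized score; midpoints of the expected values {0.5, 0.75, 0.875, 1}.
DEFAULT_CUTOFFS: tuple[float, float, float] = (0.625, 0.8125, 0.90625)

DEGREES = ("identical/twin", "first", "second", "unrelated", "insufficient")


@dataclass(frozen=True)
class PairCounts:
    """Raw mismatch evidence for one pair, with per-block tallies."""

    pair: tuple[str, str]
    overlap: int
    mismatches: int
    block_overlap: np.ndarray
    block_mismatch: np.ndarray

    @property
    def pmr(self) -> float:
        """Raw pairwise mismatch rate; NaN when the pair shares no sites."""
        return self.mismatches / self.overlap if self.overlap else float("nan")


@dataclass(frozen=True)
class KinshipEstimate:
    """One pair's kinship summary."""

    pair: tuple[str, str]
    overlap: int
    pmr: float
    norm: float
    se: float
    degree: str


def _block_ids(matrix: PseudohaploidMatrix, block_size: int = BLOCK_SIZE) -> np.ndarray:
    """Assign each SNP to a contiguous genomic window for the jackknife."""
    keys = [
        (chromosome_sort_key(s.chromosome), (s.position - 1) // block_size)
        for s in matrix.snps
    ]
    uniq = {k: i for i, k in enumerate(sorted(set(keys)))}
    return np.fromiter((uniq[k] for k in keys), dtype=np.int64, count=len(keys))


def pairwise_mismatch(
    matrix: PseudohaploidMatrix,
    a: str,
    b: str,
    *,
    block_size: int = BLOCK_SIZE,
    block_ids: np.ndarray | None = None,
) -> PairCounts:
    """Count pseudohaploid mismatches between samples ``a`` and ``b``.

    Overlap is the number of SNPs non-missing in both; the PMR is
    mismatches/overlap, with per-block counts retained for the
    jackknife.  Zero overlap yields ``pmr = NaN`` (insufficient), never
    a division by zero.  ``block_ids`` may carry a precomputed
    :func:`_block_ids` result when evaluating many pairs of one matrix.
    """
    if a == b:
        raise ValueError("pairwise mismatch requires two distinct samples")
    ga = matrix.calls[matrix.sample_index(a)]
    gb = matrix.calls[matrix.sample_index(b)]
    bid = _block_ids(matrix, block_size) if block_ids is None else block_ids
    nblocks = int(bid.max()) + 1 if len(bid) else 0
    both = (ga != MISSING) & (gb != MISSING)
    mism = both & (ga != gb)
    return PairCounts(
        pair=tuple(sorted((a, b))),
        overlap=int(both.sum()),
        mismatches=int(mism.sum()),
        block_overlap=np.bincount(bid[both], minlength=nblocks),
        block_mismatch=np.bincount(bid[mism], minlength=nblocks),
    )


def background_rate(
    pmrs: Sequence[float],
    mode: Literal["median", "supplied"] = "median",
    supplied: float | None = None,
) -> float:
    """Background (expected-unrelated) PMR used to normalize raw rates.

    ``median`` mode takes the median of the eligible pairwise rates and
    assumes a mostly unrelated cohort; ``supplied`` passes through an
    externally known unrelated rate.
    """
    if mode == "supplied":
        if supplied is None or supplied <= 0:
            raise ValueError("supplied mode requires a positive background value")
        return float(supplied)
    eligible = [p for p in pmrs if not math.isnan(p)]
    if not eligible:
        raise ValueError("no eligible pairs to estimate the background rate")
    b = float(np.median(eligible))
    if b <= 0:
        raise ValueError("background mismatch rate is zero; cohort degenerate")
    return b


def classify_degree(
    norm: float,
    se: float | None = None,
    cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS,
) -> str:
    """Map a normalized score onto a relatedness-degree class.

    Intervals are closed below, open above: ``[0, c0)`` identical/twin,
    ``[c0, c1)`` first, ``[c1, c2)`` second, ``[c2, inf)`` unrelated.
    """
    if math.isnan(norm):
        return "insufficient"
    if norm < 0:
        raise ValueError("normalized score must be >= 0")
    c0, c1, c2 = cutoffs
    if norm < c0:
        return "identical/twin"
    if norm < c1:
        return "first"
    if norm < c2:
        return "second"
    return "unrelated"


def jackknife_se(
    block_mismatch: np.ndarray,
    block_overlap: np.ndarray,
    background: float,
) -> float:
    """Delete-one-block jackknife SE of the normalized score.

    Blocks with no overlapping sites are dropped; fewer than two
    non-empty blocks yields NaN (degree is still assigned from the
    point estimate).
    """
    block_mismatch = np.asarray(block_mismatch, dtype=float)
    block_overlap = np.asarray(block_overlap, dtype=float)
    keep = block_overlap > 0
    m, n = block_mismatch[keep], block_overlap[keep]
    g = len(n)
    if g < 2:
        return float("nan")
    total_m, total_n = m.sum(), n.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = ((total_m - m) / (total_n - n)) / background
    theta = theta[np.isfinite(theta)]
    g = len(theta)
    if g < 2:
        return float("nan")
    return float(np.sqrt((g - 1) / g * np.sum((theta - theta.mean()) ** 2)))


def kin_matrix(
    matrix: PseudohaploidMatrix,
    min_overlap: int = 1000,
    background: Literal["median", "supplied"] = "median",
    supplied_background: float | None = None,
    cutoffs: tuple[float, float, float] = DEFAULT_CUTOFFS,
) -> list[KinshipEstimate]:
    """Estimate kinship for every unordered sample pair in the matrix.

    Pairs sharing fewer than ``min_overlap`` SNPs are reported as
    ``insufficient`` and excluded from the background median.  A warning
    is emitted when more than half of the eligible pairs classify as
    related, since a contaminated median inflates everyone's apparent
    relatedness; supply an external background in that situation.
    """
    if matrix.n_samples < 2:
        raise ValueError("kinship needs at least 2 samples")
    bid = _block_ids(matrix)
    nblocks = int(bid.max()) + 1 if len(bid) else 0
    counts: list[PairCounts] = []
    nonmiss = matrix.calls != MISSING
    for ia, ib in combinations(range(matrix.n_samples), 2):
        both = nonmiss[ia] & nonmiss[ib]
        mism = both & (matrix.calls[ia] != matrix.calls[ib])
        counts.append(
            PairCounts(
                pair=tuple(sorted((matrix.samples[ia], matrix.samples[ib]))),
                overlap=int(both.sum()),
                mismatches=int(mism.sum()),
                block_overlap=np.bincount(bid[both], minlength=nblocks),
                block_mismatch=np.bincount(bid[mism], minlength=nblocks),
            )
        )

    eligible = [c.pmr for c in counts if c.overlap >= min_overlap]
    if not eligible and background == "median":
        # nothing to normalize against: every pair is insufficient
        return [
            KinshipEstimate(c.pair, c.overlap, c.pmr, float("nan"), float("nan"),
                            "insufficient")
            for c in counts
        ]
    b = background_rate(eligible, mode=background, supplied=supplied_background)

    estimates: list[KinshipEstimate] = []
    for c in counts:
        if c.overlap < min_overlap:
            estimates.append(
                KinshipEstimate(c.pair, c.overlap, c.pmr, float("nan"),
                                float("nan"), "insufficient")
            )
            continue
        norm = c.pmr / b
        se = jackknife_se(c.block_mismatch, c.block_overlap, b)
        estimates.append(
            KinshipEstimate(c.pair, c.overlap, c.pmr, norm, se,
                            classify_degree(norm, se, cutoffs))
        )

    # A contaminated median makes related pairs look unrelated after
    # normalization, so judge contamination on the raw PMR spread: anchor
    # on the upper decile (the unrelated cluster) and count pairs sitting
    # below the unrelated cutoff relative to that anchor.
    if background == "median" and eligible:
        anchor = float(np.quantile(eligible, 0.9))
        low = sum(p < cutoffs[2] * anchor for p in eligible)
        if low / len(eligible) > 0.5:
            warnings.warn(
                "more than half of the pairs look related; the median "
                "background is likely contaminated — rerun with a supplied "
                "unrelated background rate",
                stacklevel=2,
            )
    return estimates


def build_network(estimates: Iterable[KinshipEstimate]) -> nx.Graph:
    """Undirected relatedness network keeping only degree <= 2 edges.

    Nodes are all samples seen in the estimates; edges carry the degree
    class, normalized score and jackknife SE.
    """
    g = nx.Graph()
    for e in estimates:
        g.add_nodes_from(e.pair)
        if e.degree in ("identical/twin", "first", "second"):
            g.add_edge(*e.pair, degree=e.degree, norm=e.norm, se=e.se)
    return g
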