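"""Z-score-Adjusted Coverage (ZAC): ploidy, genetic sex and aneuploidy
calls from per-chromosome read counts.

The idea: at any mean coverage, the per-site read rate of a chromosome
scales with its copy number.  ZAC normalizes each chromosome's rate by
the sample's autosome-wide rate, giving a dimensionless ratio that is
1.0 for a diploid autosome regardless of coverage.  A panel of
karyotypically normal reference genomes (declared XX or XY) supplies
the expected ratio and its spread per chromosome; gonosome expectations
are stored per copy, so a single reference set serves any test
karyotype.  Copy number is the reference-copy-scaled ratio rounded to
the nearest integer; a z-score against the reference spread flags
autosomal aneuploidies.  Because everything is a ratio of rates, calls
are invariant to overall coverage, which is what lets the method work
down to ~0.01x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import AUTOSOMES, FormatError, normalize_chromosome

__all__ = [
    "DepthTable",
    "ReferenceStats",
    "PloidyCall",
    "KaryotypeCall",
    "normalize_depth",
    "build_reference_stats",
    "estimate_ploidy",
    "call_karyotype",
    "read_depth_table",
    "write_depth_table",
]

GONOSOMES = ("X", "Y")

#: Copy numbers carried by the two admissible reference karyotypes.
_REF_KARYOTYPE_COPIES: dict[str, dict[str, int]] = {
    "XX": {"X": 2, "Y": 0},
    "XY": {"X": 1, "Y": 1},
}

#: Recognized gonosomal configurations (all others -> undetermined).
_KNOWN_GONOSOMAL = {"XX", "XY", "X0", "XXY", "XYY", "XXX"}


class InsufficientDataError(ValueError):
    """Raised when coverage is too low to compute a quantity at all."""


@dataclass
class DepthTable:
    """Per-chromosome read counts for one sample over a fixed site panel.

    ``reads[c]`` is the number of reads overlapping panel sites on
    chromosome ``c``; ``sites[c]`` the number of panel sites there.
    All 22 autosomes are required; X and Y are optional but a karyotype
    call needs both.
    """

    sample: str
    reads: dict[str, int]
    sites: dict[str, int]

    def __post_init__(self) -> None:
        self.reads = {normalize_chromosome(c): int(n) for c, n in self.reads.items()}
        self.sites = {normalize_chromosome(c): int(n) for c, n in self.sites.items()}
        if set(self.reads) != set(self.sites):
            raise FormatError(f"{self.sample}: reads/sites chromosome sets differ")
        missing = [c for c in AUTOSOMES if c not in self.sites]
        if missing:
            raise FormatError(f"{self.sample}: missing autosomes {missing}")
        for c in self.sites:
            if self.sites[c] <= 0:
                raise FormatError(f"{self.sample}: chromosome {c} has no panel sites")
            if self.reads[c] < 0:
                raise FormatError(f"{self.sample}: negative read count on {c}")

    @property
    def chromosomes(self) -> list[str]:
        from .io_formats import chromosome_sort_key

        return sorted(self.sites, key=chromosome_sort_key)

    @property
    def mean_coverage(self) -> float:
        """Autosome-wide reads per site (the sample's mean coverage in x)."""
        return sum(self.reads[c] for c in AUTOSOMES) / sum(self.sites[c] for c in AUTOSOMES)


@dataclass
class ReferenceStats:
    """Per-chromosome normalized-coverage expectations from reference genomes.

    Autosomal statistics are stored on the diploid scale
    (``reference_copies=2``); X and Y are stored per copy
    (``reference_copies=1``) so XX and XY references pool into one
    expectation.
    """

    mean_ratio: dict[str, float]
    sd_ratio: dict[str, float]
    reference_copies: dict[str, int]
    n_ref: dict[str, int]

    def __post_init__(self) -> None:
        for c, m in self.mean_ratio.items():
            if m <= 0:
                raise ValueError(f"chromosome {c}: mean ratio must be > 0")
            if self.sd_ratio[c] <= 0:
                raise ValueError(f"chromosome {c}: sd must be > 0")
            if self.n_ref[c] < 2:
                raise ValueError(f"chromosome {c}: need >= 2 reference samples")


@dataclass(frozen=True)
class PloidyCall:
    """One chromosome's copy-number estimate for one sample."""

    sample: str
    chromosome: str
    ratio: float
    z: float
    copies: int
    flagged: bool
    reads: int = 0


@dataclass(frozen=True)
class KaryotypeCall:
    """Genome-wide karyotype summary assembled from per-chromosome calls."""

    sample: str
    gonosomal: str
    genetic_sex: str
    autosomal_trisomies: tuple[str, ...] = ()
    autosomal_monosomies: tuple[str, ...] = ()
    min_informative: bool = True

    @property
    def karyotype_label(self) -> str:
        """Compact label, e.g. ``XY``, ``XX+21``, ``XY-18``."""
        label = self.gonosomal
        for c in self.autosomal_trisomies:
            label += f"+{c}"
        for c in self.autosomal_monosomies:
            label += f"-{c}"
        return label


def normalize_depth(depth: DepthTable) -> dict[str, float]:
    """Per-chromosome coverage ratio, normalized by the autosomal rate.

    ``ratio_c = (reads_c / sites_c) / (sum_auto reads / sum_auto sites)``.
    The site-weighted mean over autosomes is exactly 1 by construction.
    """
    auto_reads = sum(depth.reads[c] for c in AUTOSOMES)
    auto_sites = sum(depth.sites[c] for c in AUTOSOMES)
    if auto_reads == 0:
        raise InsufficientDataError(f"{depth.sample}: zero autosomal reads")
    rate = auto_reads / auto_sites
    return {c: (depth.reads[c] / depth.sites[c]) / rate for c in depth.chromosomes}


def build_reference_stats(
    refs: Sequence[DepthTable],
    ref_karyotypes: Mapping[str, str],
) -> ReferenceStats:
    """Pool reference genomes into per-chromosome ratio expectations.

    Each reference must carry a declared normal karyotype (``XX`` or
    ``XY``).  Gonosomal ratios are divided by the declared copy number
    before pooling, so the stored X/Y expectation is per copy; XX
    references contribute nothing to Y.
    """
    if len(refs) < 2:
        raise ValueError(f"need >= 2 reference samples, got {len(refs)}")
    for r in refs:
        k = ref_karyotypes.get(r.sample)
        if k not in _REF_KARYOTYPE_COPIES:
            raise ValueError(
                f"reference {r.sample}: karyotype must be declared XX or XY, got {k!r}"
            )

    per_chrom: dict[str, list[float]] = {}
    for r in refs:
        copies = _REF_KARYOTYPE_COPIES[ref_karyotypes[r.sample]]
        ratios = normalize_depth(r)
        for c, ratio in ratios.items():
            per_chrom.setdefault(c, [])
            if c in GONOSOMES:
                n = copies[c]
                if n == 0:
                    continue  # an XX genome says nothing about per-copy Y
                per_chrom[c].append(ratio / n)
            else:
                per_chrom[c].append(ratio)

    mean_ratio: dict[str, float] = {}
    sd_ratio: dict[str, float] = {}
    reference_copies: dict[str, int] = {}
    n_ref: dict[str, int] = {}
    for c, values in per_chrom.items():
        if len(values) < 2:
            raise ValueError(f"chromosome {c}: fewer than 2 usable reference samples")
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1))
        if sd == 0:
            raise ValueError(
                f"chromosome {c}: zero variance across references; "
                "add more references or inject coverage jitter"
            )
        mean_ratio[c] = mean
        sd_ratio[c] = sd
        reference_copies[c] = 1 if c in GONOSOMES else 2
        n_ref[c] = len(values)
    return ReferenceStats(mean_ratio, sd_ratio, reference_copies, n_ref)


def _round_toward(x: float, expected: int) -> int:
    """Round to nearest non-negative integer; exact halves resolve toward
    the copy number closer to ``expected`` (conservative calling)."""
    lo = math.floor(x)
    if x - lo == 0.5:
        hi = lo + 1
        chosen = lo if abs(lo - expected) <= abs(hi - expected) else hi
    else:
        chosen = round(x)
    return max(int(chosen), 0)


def estimate_ploidy(
    sample: DepthTable,
    refs: ReferenceStats,
    z_threshold: float = 3.0,
) -> list[PloidyCall]:
    """Estimate per-chromosome copy number for one sample.

    Autosomes: ``copies = round(2 * ratio / mean_ratio)`` with z-score
    ``(ratio - mean_ratio) / sd_ratio``; a chromosome is flagged as
    aneuploid when its copy estimate departs from 2 *and* ``|z|``
    exceeds ``z_threshold``.  Gonosomes: copies from the per-copy
    expectation (``round(ratio / per_copy_mean)``, half-ties toward one
    copy); the z-score measures the residual against the estimated copy
    number and the aneuploidy flag is reserved for autosomes — gonosomal
    anomalies are read off the assembled karyotype instead.
    """
    ratios = normalize_depth(sample)
    calls: list[PloidyCall] = []
    for c, ratio in ratios.items():
        if c not in refs.mean_ratio:
            raise ValueError(f"chromosome {c} present in sample but absent from references")
        m = refs.mean_ratio[c]
        sd = refs.sd_ratio[c]
        if c in GONOSOMES:
            copies = _round_toward(ratio / m, expected=1)
            z = (ratio - copies * m) / (sd * math.sqrt(max(copies, 1)))
            flagged = False
        else:
            copies = _round_toward(2.0 * ratio / m, expected=2)
            z = (ratio - m) / sd
            flagged = copies != 2 and abs(z) > z_threshold
        calls.append(
            PloidyCall(
                sample=sample.sample,
                chromosome=c,
                ratio=ratio,
                z=z,
                copies=copies,
                flagged=flagged,
                reads=sample.reads[c],
            )
        )
    return calls


def call_karyotype(calls: Iterable[PloidyCall], min_reads: int = 100) -> KaryotypeCall:
    """Assemble a karyotype call from per-chromosome ploidy calls.

    The gonosomal genotype is the string ``"X" * nX + "Y" * nY`` (with
    ``X0`` for a single X and no Y).  When combined X+Y reads fall below
    ``min_reads`` the call is ``undetermined`` rather than a guess.
    Degenerate input never raises.
    """
    calls = list(calls)
    by_chrom = {c.chromosome: c for c in calls}
    sample = calls[0].sample if calls else ""

    trisomies = tuple(c.chromosome for c in calls if c.flagged and c.copies > 2)
    monosomies = tuple(c.chromosome for c in calls if c.flagged and c.copies < 2)

    x = by_chrom.get("X")
    y = by_chrom.get("Y")
    if x is None or y is None:
        return KaryotypeCall(sample, "undetermined", "undetermined",
                             trisomies, monosomies, min_informative=False)
    gono_reads = x.reads + y.reads
    if gono_reads < min_reads:
        return KaryotypeCall(sample, "undetermined", "undetermined",
                             trisomies, monosomies, min_informative=False)

    nx, ny = x.copies, y.copies
    if nx == 1 and ny == 0:
        gonosomal = "X0"
    else:
        gonosomal = "X" * nx + "Y" * ny
    if gonosomal not in _KNOWN_GONOSOMAL:
        gonosomal = "undetermined"

    if gonosomal == "undetermined":
        sex = "undetermined"
    elif ny >= 1:
        sex = "M"
    elif gonosomal in ("XX", "XXX"):
        sex = "F"
    else:
        sex = "undetermined"
    return KaryotypeCall(sample, gonosomal, sex, trisomies, monosomies, min_informative=True)


def read_depth_table(path: str | Path) -> list[DepthTable]:
    """Read depth TSV (sample, chrom, reads, sites) into DepthTables."""
    from .io_formats import _read_tsv

    _, rows = _read_tsv(path, ("sample", "chrom", "reads", "sites"))
    reads: dict[str, dict[str, int]] = {}
    sites: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for _lineno, row in rows:
        s = row["sample"]
        if s not in reads:
            reads[s], sites[s] = {}, {}
            order.append(s)
        c = row["chrom"]
        reads[s][c] = int(row["reads"])
        sites[s][c] = int(row["sites"])
    return [DepthTable(s, reads[s], sites[s]) for s in order]


def write_depth_table(tables: Iterable[DepthTable], path: str | Path) -> None:
    """Write DepthTables as the depth TSV dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("sample\tchrom\treads\tsites\n")
        for t in tables:
            for c in t.chromosomes:
                fh.write(f"{t.sample}\t{c}\t{t.reads[c]}\t{t.sites[c]}\n")
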