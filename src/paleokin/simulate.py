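"""Synthetic ancient-DNA data with known truth.

Three generators cover the toolkit's inputs:

* **Pedigree genotypes** — gene dropping: founder diploid genotypes are
  drawn site-wise from Hardy-Weinberg proportions at a frequency
  sampled per site, and each child inherits one uniformly chosen allele
  per parent per site.  Sites are independent (no linkage), which is
  sufficient for mismatch-rate expectations though not for IBD-segment
  methods.
* **Pseudohaploid calls** — the single-read regime of low-coverage
  shotgun data: each site is covered with probability ``min(coverage, 1)``
  and, if covered, one of the two chromosomes is sampled uniformly.
  Post-mortem deamination is modelled as C->T / G->A conversion of the
  sampled base with probability ``damage_rate`` (uniform along the
  molecule, emulating a half-UDG-treated library), plus an optional
  random allele-flip error.
* **Depth tables and pileups** — per-chromosome read counts are
  ``Poisson(sites * coverage * copies / 2)`` under a stated karyotype;
  per-site pileup depths are ``Poisson(coverage)`` with the same
  damage/error chemistry applied per read.

Everything is reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import PileupRecord, PseudohaploidMatrix, SnpRecord, VariantPanelEntry
from .zac import DepthTable

__all__ = [
    "GRCH37_LENGTHS",
    "SimulationConfig",
    "PedigreeSpec",
    "default_site_map",
    "simulate_snp_map",
    "simulate_pedigree_genotypes",
    "pseudohaploidize",
    "parse_karyotype",
    "simulate_depth_table",
    "simulate_pileup",
]

#: GRCh37 chromosome lengths in bp, used to apportion panel sites.
GRCH37_LENGTHS: dict[str, int] = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _G, _T, _A = (ord(x) for x in "CGTA")

_GONOSOME_COPIES = {
    "XX": (2, 0), "XY": (1, 1), "X0": (1, 0),
    "XXY": (2, 1), "XYY": (1, 2), "XXX": (3, 0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic-data model.

    ``coverage`` is mean per-site coverage in x units; ``damage_rate``
    the probability a sampled C (G) is read as T (A); ``error_rate`` a
    per-call random allele flip.  Defaults reflect a clean
    high-coverage library; lower the coverage and raise the damage to
    emulate ancient shotgun data (typical half-UDG residual damage is a
    few percent).
    """

    n_sites: int = 10_000
    freq_range: tuple[float, float] = (0.05, 0.95)
    coverage: float = 1.0
    damage_rate: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        for name in ("damage_rate", "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.freq_range
        if not 0 < lo <= hi < 1:
            raise ValueError("freq_range must satisfy 0 < lo <= hi < 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PedigreeSpec:
    """A pedigree as founders, matings and same-individual duplicates.

    ``matings`` are ``(parentA, parentB, child)`` triples; dizygotic
    twins are simply two children of the same mating.  ``duplicates``
    declare exact genomic copies (same individual sampled twice, or a
    monozygotic twin).  Kinship coefficients for any pair follow by the
    standard recursive (tabular) method.
    """

    founders: tuple[str, ...]
    matings: tuple[tuple[str, str, str], ...] = ()
    duplicates: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "founders", tuple(self.founders))
        object.__setattr__(self, "matings", tuple(tuple(m) for m in self.matings))
        object.__setattr__(self, "duplicates", tuple(tuple(d) for d in self.duplicates))
        self._ordered()  # validates

    def _ordered(self) -> list[str]:
        """Individuals in an order where parents precede children."""
        if len(set(self.founders)) != len(self.founders):
            raise ValueError("duplicate founder ids")
        defined = set(self.founders)
        order = list(self.founders)
        pending = list(self.matings)
        while pending:
            progress = False
            remaining = []
            for pa, pb, child in pending:
                if child in defined:
                    raise ValueError(f"individual {child!r} defined twice")
                if pa in defined and pb in defined:
                    defined.add(child)
                    order.append(child)
                    progress = True
                else:
                    remaining.append((pa, pb, child))
            if not progress:
                bad = ", ".join(m[2] for m in remaining)
                raise ValueError(f"unresolvable pedigree (cycle or unknown parent) at: {bad}")
            pending = remaining
        for src, copy in self.duplicates:
            if src not in defined:
                raise ValueError(f"duplicate source {src!r} unknown")
            if copy in defined:
                raise ValueError(f"duplicate copy id {copy!r} already used")
            defined.add(copy)
        return order

    @property
    def samples(self) -> list[str]:
        """All sample ids: founders, children, then duplicate copies."""
        return self._ordered() + [copy for _, copy in self.duplicates]

    def parents(self) -> dict[str, tuple[str, str]]:
        return {child: (pa, pb) for pa, pb, child in self.matings}

    def kinship_matrix(self) -> dict[tuple[str, str], float]:
        """Kinship coefficient phi for every ordered pair of individuals.

        Founders are assumed unrelated and non-inbred (phi(f, f) = 1/2);
        for a child ``c`` of ``(p, q)``: ``phi(c, j) = (phi(p, j) +
        phi(q, j)) / 2`` for earlier ``j`` and ``phi(c, c) =
        (1 + phi(p, q)) / 2``.  Duplicate copies share all coefficients
        with their source, and phi(source, copy) = phi(source, source).
        """
        order = self._ordered()
        par = self.parents()
        phi: dict[tuple[str, str], float] = {}
        for i, a in enumerate(order):
            if a in par:
                pa, pb = par[a]
                phi[(a, a)] = 0.5 * (1.0 + phi[tuple(sorted((pa, pb)))])
            else:
                phi[(a, a)] = 0.5
            for b in order[:i]:
                if a in par:
                    pa, pb = par[a]
                    v = 0.5 * (phi[tuple(sorted((pa, b)))] + phi[tuple(sorted((pb, b)))])
                else:
                    v = 0.0
                phi[tuple(sorted((a, b)))] = v
        for src, copy in self.duplicates:
            for other in order:
                key = tuple(sorted((src, other))) if other != src else (src, src)
                phi[tuple(sorted((copy, other)))] = phi[key]
            phi[(copy, copy)] = phi[(src, src)]
        for (a, b), v in list(phi.items()):
            phi[(b, a)] = v
        return phi

    def kinship_coefficient(self, a: str, b: str) -> float:
        return self.kinship_matrix()[(a, b)]


def default_site_map(
    total_sites: int = 1_150_000,
    include_gonosomes: bool = True,
) -> dict[str, int]:
    """Per-chromosome panel-site counts proportional to chromosome length,
    emulating a 1240k-like capture map (~1.15M sites by default)."""
    chroms = list(GRCH37_LENGTHS) if include_gonosomes else list(GRCH37_LENGTHS)[:22]
    total_len = sum(GRCH37_LENGTHS[c] for c in chroms)
    return {c: max(1, round(total_sites * GRCH37_LENGTHS[c] / total_len)) for c in chroms}


def _unique_sorted_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=int(n * 1.05) + 8))
    while len(pos) < n:
        pos = np.unique(np.concatenate([pos, rng.integers(1, length + 1, size=n)]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_snp_map(
    n_sites: int,
    rng: np.random.Generator,
    chromosomes: Sequence[str] | None = None,
) -> list[SnpRecord]:
    """Random bi-allelic site map spread over chromosomes by length."""
    chroms = list(chromosomes) if chromosomes is not None else list(GRCH37_LENGTHS)[:22]
    total_len = sum(GRCH37_LENGTHS[c] for c in chroms)
    counts = {c: max(1, round(n_sites * GRCH37_LENGTHS[c] / total_len)) for c in chroms}
    # nudge rounding drift back onto the largest chromosome
    counts[chroms[0]] += n_sites - sum(counts.values())
    snps: list[SnpRecord] = []
    i = 0
    for c in chroms:
        positions = _unique_sorted_positions(rng, counts[c], GRCH37_LENGTHS[c])
        ref_idx = rng.integers(0, 4, size=counts[c])
        alt_idx = (ref_idx + rng.integers(1, 4, size=counts[c])) % 4
        for p, r, a in zip(positions, ref_idx, alt_idx):
            snps.append(
                SnpRecord(f"snp{i}", c, int(p), chr(_BASES[r]), chr(_BASES[a]))
            )
            i += 1
    return snps


def simulate_pedigree_genotypes(
    ped: PedigreeSpec,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    snps: list[SnpRecord] | None = None,
) -> PseudohaploidMatrix:
    """Gene-drop diploid genotypes through a pedigree.

    Returns a diploid matrix (values = reference-allele dose 0/1/2,
    ``diploid=True``).  Founders are Hardy-Weinberg at a per-site
    reference-allele frequency drawn uniformly from ``cfg.freq_range``;
    children inherit one random allele per parent per site; duplicate
    copies are bit-identical rows.
    """
    if rng is None:
        rng = cfg.rng()
    if snps is None:
        snps = simulate_snp_map(cfg.n_sites, rng)
    n = len(snps)
    lo, hi = cfg.freq_range
    freqs = rng.uniform(lo, hi, size=n)

    order = ped._ordered()
    par = ped.parents()
    # two allele columns per individual: 1 = ref allele, 0 = alt allele
    alleles: dict[str, np.ndarray] = {}
    for ind in order:
        if ind in par:
            pa, pb = par[ind]
            ha = _transmit(alleles[pa], rng)
            hb = _transmit(alleles[pb], rng)
            alleles[ind] = np.stack([ha, hb], axis=1)
        else:
            alleles[ind] = (rng.random((n, 2)) < freqs[:, None]).astype(np.int8)

    samples = ped.samples
    dup = dict((copy, src) for src, copy in ped.duplicates)
    calls = np.empty((len(samples), n), dtype=np.int8)
    for i, s in enumerate(samples):
        calls[i] = alleles[dup.get(s, s)].sum(axis=1)
    return PseudohaploidMatrix(samples, snps, calls, diploid=True)


def _transmit(parent_alleles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One uniformly chosen allele per site from a parent's two."""
    pick = rng.integers(0, 2, size=parent_alleles.shape[0])
    return parent_alleles[np.arange(parent_alleles.shape[0]), pick]


def pseudohaploidize(
    diploid: PseudohaploidMatrix,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> PseudohaploidMatrix:
    """Collapse diploid genotypes to damaged single-allele calls.

    Each site is covered with probability ``min(coverage, 1)``; one
    allele is sampled uniformly from the genotype; deamination turns a
    sampled C into T (G into A) with probability ``damage_rate``; a
    random allele flip happens with probability ``error_rate``.  A
    damaged base matching neither site allele is discarded (missing),
    as a tri-allelic read would be.
    """
    if not diploid.diploid:
        raise ValueError("pseudohaploidize expects a diploid truth matrix")
    if rng is None:
        rng = cfg.rng()
    calls = diploid.calls
    shape = calls.shape
    ref_b = np.array([ord(s.ref) for s in diploid.snps], dtype=np.uint8)
    alt_b = np.array([ord(s.alt) for s in diploid.snps], dtype=np.uint8)

    covered = rng.random(shape) < min(cfg.coverage, 1.0)
    ref_sampled = rng.random(shape) < calls / 2.0
    base = np.where(ref_sampled, ref_b, alt_b)
    if cfg.damage_rate > 0:
        dmg = rng.random(shape) < cfg.damage_rate
        base = np.where(dmg & (base == _C), _T, base)
        base = np.where(dmg & (base == _G), _A, base)
    out = np.where(base == ref_b, 2, np.where(base == alt_b, 0, 9)).astype(np.int8)
    if cfg.error_rate > 0:
        err = rng.random(shape) < cfg.error_rate
        out = np.where(err & (out == 2), np.int8(0),
                       np.where(err & (out == 0), np.int8(2), out))
    out = np.where(covered, out, np.int8(9))
    return PseudohaploidMatrix(diploid.samples, diploid.snps, out)


def parse_karyotype(karyotype: str) -> dict[str, int]:
    """Expand a karyotype token into per-chromosome copy numbers.

    ``"XY"`` -> autosomes 2, X 1, Y 1; suffixes add or remove autosomal
    copies: ``"XX+21"`` is trisomy 21, ``"XY-18"`` monosomy 18.  The
    bare token ``"trisomy-21"`` means ``"XX+21"``.
    """
    k = karyotype.strip()
    if k.lower() in ("trisomy-21", "trisomy21"):
        k = "XX+21"
    gono = k
    mods: list[str] = []
    for sep in ("+", "-"):
        while sep in gono:
            idx = gono.rindex(sep)
            mods.append(gono[idx:])
            gono = gono[:idx]
    if gono not in _GONOSOME_COPIES:
        raise ValueError(f"unknown karyotype token {karyotype!r}")
    nx, ny = _GONOSOME_COPIES[gono]
    copies = {str(i): 2 for i in range(1, 23)}
    copies["X"], copies["Y"] = nx, ny
    for mod in mods:
        chrom = mod[1:]
        if chrom not in copies or chrom in ("X", "Y"):
            raise ValueError(f"unknown karyotype modifier {mod!r} in {karyotype!r}")
        copies[chrom] += 1 if mod[0] == "+" else -1
        if copies[chrom] < 0:
            raise ValueError(f"negative copy number from {karyotype!r}")
    return copies


def simulate_depth_table(
    karyotype: str,
    sites_per_chromosome: Mapping[str, int] | None = None,
    coverage: float = 0.01,
    rng: np.random.Generator | int | None = None,
    sample: str = "sim",
) -> DepthTable:
    """Poisson per-chromosome read counts under a stated karyotype.

    ``reads_c ~ Poisson(sites_c * coverage * copies_c / 2)``, so a
    diploid autosome averages ``coverage`` reads per site.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    sites = dict(sites_per_chromosome) if sites_per_chromosome else default_site_map()
    copies = parse_karyotype(karyotype)
    reads = {
        c: int(rng.poisson(sites[c] * coverage * copies.get(c, 2) / 2.0))
        for c in sites
    }
    return DepthTable(sample, reads, sites)


def simulate_pileup(
    panel: Sequence[VariantPanelEntry],
    genotypes: PseudohaploidMatrix,
    coverage: float,
    cfg: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[PileupRecord]:
    """Per-site read pileups for panel sites with damage chemistry.

    ``genotypes`` is a diploid truth matrix whose site map must contain
    every panel coordinate.  Depth per site is ``Poisson(coverage)``;
    each read samples one allele from the genotype, suffers an allele
    flip with ``error_rate`` and deamination with ``damage_rate``; reads
    damaged off both alleles stay in the total depth but support
    neither allele.
    """
    cfg = cfg or SimulationConfig()
    if rng is None:
        rng = cfg.rng()
    if not genotypes.diploid:
        raise ValueError("simulate_pileup expects a diploid truth matrix")
    coord_to_col = {
        (s.chromosome, s.position): j for j, s in enumerate(genotypes.snps)
    }
    records: list[PileupRecord] = []
    for i, sample in enumerate(genotypes.samples):
        for entry in panel:
            key = (entry.chromosome, entry.position)
            if key not in coord_to_col:
                raise ValueError(f"panel site {key} absent from the genotype site map")
            dose = int(genotypes.calls[i, coord_to_col[key]])  # ref-allele dose
            depth = int(rng.poisson(coverage))
            ref_reads = int(rng.binomial(depth, dose / 2.0)) if depth else 0
            alt_reads = depth - ref_reads
            if cfg.error_rate > 0:
                r2a = int(rng.binomial(ref_reads, cfg.error_rate))
                a2r = int(rng.binomial(alt_reads, cfg.error_rate))
                ref_reads += a2r - r2a
                alt_reads += r2a - a2r
            if cfg.damage_rate > 0:
                ref_reads, alt_reads = _damage_reads(
                    ref_reads, alt_reads, entry.ref, entry.alt, cfg.damage_rate, rng
                )
            records.append(
                PileupRecord(sample, entry.chromosome, entry.position,
                             entry.ref, entry.alt, depth, alt_reads)
            )
    return records


def _damage_reads(
    ref_reads: int,
    alt_reads: int,
    ref: str,
    alt: str,
    d: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Deaminate reads: C->T and G->A with probability d per read."""
    damaged_to = {"C": "T", "G": "A"}
    if ref in damaged_to:
        conv = int(rng.binomial(ref_reads, d))
        ref_reads -= conv
        if damaged_to[ref] == alt:
            alt_reads += conv
    if alt in damaged_to:
        conv = int(rng.binomial(alt_reads, d))
        alt_reads -= conv
        # a read damaged from alt back onto ref supports ref again
        if damaged_to[alt] == ref:
            ref_reads += conv
    return ref_reads, alt_reads
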