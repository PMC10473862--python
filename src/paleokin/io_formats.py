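"""Readers and writers for the file formats the toolkit consumes.

Genotypes travel as EIGENSTRAT ``.geno``/``.snp``/``.ind`` trios, the
de-facto interchange format of the 1240k ancient-DNA ecosystem.  Variant
panels and per-site pileup evidence are flat tab-separated tables.  All
coordinates are 1-based GRCh37 throughout; chromosome labels are
normalized on input (``chr`` prefix stripped, ``M``/``MT`` unified to
``MT``).

Pseudohaploid genotypes use the EIGENSTRAT reference-allele-count
encoding restricted to homozygous-or-missing states:

========  =================================
value     meaning
========  =================================
``0``     two doses of the alternate allele
``2``     two doses of the reference allele
``9``     missing
========  =================================

A value of ``1`` (heterozygous) cannot occur in a pseudohaploid call; on
input it is recoded to missing with a warning unless the caller opts in
to diploid data (simulator output).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "SnpRecord",
    "PseudohaploidMatrix",
    "PileupRecord",
    "VariantPanelEntry",
    "normalize_chromosome",
    "chromosome_sort_key",
    "mutation_class",
    "read_eigenstrat",
    "write_eigenstrat",
    "read_panel",
    "read_pileup",
    "write_pileup",
]

ALLELES = frozenset("ACGT")

#: Canonical chromosome order: autosomes 1..22, then X, Y, MT.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")
AUTOSOMES: tuple[str, ...] = CHROMOSOMES[:22]

_CHROM_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}

#: Unordered base pairs that constitute transitions (purine<->purine,
#: pyrimidine<->pyrimidine).  Everything else is a transversion.
_TRANSITIONS = frozenset({frozenset("AG"), frozenset("CT")})


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_chromosome(label: str) -> str:
    """Normalize a chromosome label to the canonical {1..22, X, Y, MT} set."""
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.upper() in ("M", "MT"):
        c = "MT"
    else:
        c = c.upper() if c.upper() in ("X", "Y") else c
    if c not in _CHROM_ORDER:
        raise FormatError(f"unknown chromosome label: {label!r}")
    return c


def chromosome_sort_key(chrom: str) -> int:
    """Sort key placing autosomes first, then X, Y, MT."""
    return _CHROM_ORDER[normalize_chromosome(chrom)]


def mutation_class(ref: str, alt: str) -> str:
    """Classify a substitution as ``transition`` or ``transversion``."""
    pair = frozenset((ref, alt))
    if len(pair) != 2 or not pair <= ALLELES:
        raise FormatError(f"invalid allele pair {ref!r}/{alt!r}")
    return "transition" if pair in _TRANSITIONS else "transversion"


@dataclass(frozen=True)
class SnpRecord:
    """A single bi-allelic site on the genotyping panel."""

    snp_id: str
    chromosome: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.ref not in ALLELES or self.alt not in ALLELES:
            raise FormatError(
                f"{self.snp_id}: alleles must be A/C/G/T, got {self.ref}/{self.alt}"
            )
        if self.ref == self.alt:
            raise FormatError(f"{self.snp_id}: ref and alt alleles are identical")
        if self.position < 1:
            raise FormatError(f"{self.snp_id}: position must be >= 1 (1-based)")


@dataclass(frozen=True)
class PileupRecord:
    """Read evidence for one sample at one panel coordinate."""

    sample: str
    chromosome: str
    position: int
    ref: str
    alt: str
    depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.depth < 0:
            raise FormatError(f"{self.sample} {self.chromosome}:{self.position}: depth < 0")
        if not 0 <= self.alt_depth <= self.depth:
            raise FormatError(
                f"{self.sample} {self.chromosome}:{self.position}: "
                f"alt_depth {self.alt_depth} outside [0, depth={self.depth}]"
            )


@dataclass(frozen=True)
class VariantPanelEntry:
    """One screening-panel site with its clinical annotation.

    ``mutation_class`` is derived from the alleles, never read from disk,
    so transition/transversion status can never disagree with ref/alt.
    """

    snp_id: str
    chromosome: str
    position: int
    ref: str
    alt: str
    significance: str
    condition: str
    mutation_class: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.ref not in ALLELES or self.alt not in ALLELES:
            raise FormatError(
                f"{self.snp_id}: alleles must be A/C/G/T, got {self.ref}/{self.alt}"
            )
        if self.ref == self.alt:
            raise FormatError(f"{self.snp_id}: ref == alt")
        if not self.significance:
            raise FormatError(f"{self.snp_id}: empty significance")
        object.__setattr__(self, "mutation_class", mutation_class(self.ref, self.alt))


class PseudohaploidMatrix:
    """Samples x SNPs genotype matrix in pseudohaploid {0, 2, 9} encoding.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows).
    snps
        Ordered :class:`SnpRecord` (columns).
    calls
        ``(n_samples, n_snps)`` integer array with values in {0, 2, 9}
        (or {0, 1, 2, 9} when ``diploid=True``, for simulator output).
    diploid
        Permit heterozygous ``1`` calls.  Pseudohaploid consumers must
        not be handed a diploid matrix.
    """

    def __init__(
        self,
        samples: Sequence[str],
        snps: Sequence[SnpRecord],
        calls: np.ndarray,
        *,
        diploid: bool = False,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(samples), len(snps)):
            raise FormatError(
                f"calls shape {calls.shape} does not match "
                f"{len(samples)} samples x {len(snps)} SNPs"
            )
        allowed = {0, 1, 2, 9} if diploid else {0, 2, 9}
        bad = set(np.unique(calls)) - allowed
        if bad:
            raise FormatError(
                f"genotype values {sorted(bad)} not permitted "
                f"({'diploid' if diploid else 'pseudohaploid'} encoding)"
            )
        seen: set[tuple[str, int]] = set()
        for s in snps:
            key = (s.chromosome, s.position)
            if key in seen:
                raise FormatError(f"duplicate site {s.chromosome}:{s.position}")
            seen.add(key)
        if len(set(samples)) != len(samples):
            raise FormatError("duplicate sample identifiers")
        self.samples = list(samples)
        self.snps = list(snps)
        self.calls = calls
        self.diploid = diploid

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PseudohaploidMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"<PseudohaploidMatrix {self.n_samples} samples x {self.n_snps} SNPs"
            f"{' (diploid)' if self.diploid else ''}>"
        )


def read_eigenstrat(prefix: str | Path, *, keep_diploid: bool = False) -> PseudohaploidMatrix:
    """Read an EIGENSTRAT ``.geno``/``.snp``/``.ind`` trio.

    ``.geno`` rows are SNPs and columns are samples, one character per
    genotype in {0, 1, 2, 9}.  Under the default pseudohaploid policy a
    heterozygous ``1`` is recoded to ``9`` with one summary warning;
    ``keep_diploid=True`` keeps the values (e.g. simulator truth data).

    Raises
    ------
    FormatError
        On dimension mismatches between the three files, naming the
        offending counts.
    """
    prefix = Path(prefix)
    ind_lines = _read_nonempty_lines(prefix.with_suffix(".ind"))
    samples = [ln.split()[0] for ln in ind_lines]

    snps: list[SnpRecord] = []
    for ln in _read_nonempty_lines(prefix.with_suffix(".snp")):
        parts = ln.split()
        if len(parts) < 6:
            raise FormatError(f"{prefix}.snp: expected 6 columns, got {len(parts)}: {ln!r}")
        snp_id, chrom, _gpos, pos, ref, alt = parts[:6]
        snps.append(SnpRecord(snp_id, chrom, int(pos), ref, alt))

    geno_path = prefix.with_suffix(".geno")
    if not geno_path.exists():
        raise FormatError(f"missing file: {geno_path}")
    # keep blank rows: a matrix with zero samples has empty .geno lines
    geno_lines = geno_path.read_text().splitlines()
    if len(geno_lines) != len(snps):
        raise FormatError(
            f"{prefix}: .geno has {len(geno_lines)} rows but .snp lists {len(snps)} SNPs"
        )
    calls = np.full((len(samples), len(snps)), 9, dtype=np.int8)
    for j, ln in enumerate(geno_lines):
        if len(ln) != len(samples):
            raise FormatError(
                f"{prefix}: .geno row {j + 1} has {len(ln)} columns "
                f"but .ind lists {len(samples)} samples"
            )
        calls[:, j] = np.frombuffer(ln.encode("ascii"), dtype=np.uint8) - ord("0")
    if not np.isin(calls, (0, 1, 2, 9)).all():
        raise FormatError(f"{prefix}.geno: genotype characters outside {{0,1,2,9}}")

    if not keep_diploid:
        het = calls == 1
        if het.any():
            warnings.warn(
                f"{prefix}.geno: recoded {int(het.sum())} heterozygous calls to "
                "missing under the pseudohaploid convention",
                stacklevel=2,
            )
            calls[het] = 9
    return PseudohaploidMatrix(samples, snps, calls, diploid=keep_diploid)


def write_eigenstrat(matrix: PseudohaploidMatrix, prefix: str | Path) -> None:
    """Write ``matrix`` as an EIGENSTRAT trio; round-trips bit-exactly.

    A matrix containing heterozygous calls is refused unless it was
    constructed with ``diploid=True``.
    """
    prefix = Path(prefix)
    if not matrix.diploid and (matrix.calls == 1).any():
        raise FormatError("heterozygous calls in a pseudohaploid matrix")
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".ind"), "w") as fh:
        for s in matrix.samples:
            fh.write(f"{s}\tU\tCohort\n")
    with open(prefix.with_suffix(".snp"), "w") as fh:
        for s in matrix.snps:
            fh.write(f"{s.snp_id}\t{s.chromosome}\t0.0\t{s.position}\t{s.ref}\t{s.alt}\n")
    digits = np.char.mod("%d", matrix.calls.T)
    with open(prefix.with_suffix(".geno"), "w") as fh:
        for row in digits:
            fh.write("".join(row))
            fh.write("\n")


def read_panel(path: str | Path) -> list[VariantPanelEntry]:
    """Read a variant-panel TSV (rsID, chrom, pos, ref, alt, significance, condition).

    Entries come back sorted by (chromosome, position); the mutation
    class is computed from the alleles.  Duplicate coordinates and
    non-ACGT alleles are errors.
    """
    header, rows = _read_tsv(path, ("rsID", "chrom", "pos", "ref", "alt", "significance", "condition"))
    entries: list[VariantPanelEntry] = []
    seen: set[tuple[str, int]] = set()
    for lineno, row in rows:
        try:
            e = VariantPanelEntry(
                snp_id=row["rsID"],
                chromosome=row["chrom"],
                position=int(row["pos"]),
                ref=row["ref"],
                alt=row["alt"],
                significance=row["significance"],
                condition=row["condition"],
            )
        except FormatError as err:
            raise FormatError(f"{path}:{lineno}: {err}") from None
        key = (e.chromosome, e.position)
        if key in seen:
            raise FormatError(f"{path}:{lineno}: duplicate panel site {e.chromosome}:{e.position}")
        seen.add(key)
        entries.append(e)
    entries.sort(key=lambda e: (chromosome_sort_key(e.chromosome), e.position))
    return entries


def read_pileup(path: str | Path) -> list[PileupRecord]:
    """Read a pileup TSV (sample, chrom, pos, ref, alt, depth, alt_depth)."""
    _, rows = _read_tsv(path, ("sample", "chrom", "pos", "ref", "alt", "depth", "alt_depth"))
    records: list[PileupRecord] = []
    for lineno, row in rows:
        try:
            records.append(
                PileupRecord(
                    sample=row["sample"],
                    chromosome=row["chrom"],
                    position=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    depth=int(row["depth"]),
                    alt_depth=int(row["alt_depth"]),
                )
            )
        except FormatError as err:
            raise FormatError(f"{path}:{lineno}: {err}") from None
    return records


def write_pileup(records: Iterable[PileupRecord], path: str | Path) -> None:
    """Write pileup records to TSV; inverse of :func:`read_pileup`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tpos\tref\talt\tdepth\talt_depth\n")
        for r in records:
            fh.write(
                f"{r.sample}\t{r.chromosome}\t{r.position}\t{r.ref}\t{r.alt}\t"
                f"{r.depth}\t{r.alt_depth}\n"
            )


def _read_nonempty_lines(path: Path) -> list[str]:
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def _read_tsv(path: str | Path, required: tuple[str, ...]):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing file: {path}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file (header required)")
    header = lines[0].split("\t")
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
            )
        rows.append((lineno, dict(zip(header, parts))))
    return header, rows
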