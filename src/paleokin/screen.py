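"""Damage-aware screening of pileup evidence against variant panels.

Ancient DNA carries post-mortem cytosine deamination, which manifests
as spurious C->T (and G->A) substitutions — exactly the transition
class.  A single alternate read at a transition site is therefore weak
evidence: it may be damage rather than a genotype.  The screen reports
every panel site with read evidence, then applies the retention rule
used for ancient cohorts: transition hits below an alternate-read
threshold are excluded unless the same allele is independently observed
in a second sample, or an explicit phenotype corroboration (e.g.
diagnostic skeletal features) is supplied.  Transversions cannot be
produced by deamination and are never excluded by this filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import PileupRecord, VariantPanelEntry, chromosome_sort_key

__all__ = ["VariantHit", "screen_sample", "apply_damage_filter", "summarize_report"]


@dataclass(frozen=True)
class VariantHit:
    """One sample x panel-site observation.

    ``status`` is ``no_call`` when no alternate read supports the
    variant, ``retained``/``excluded`` after the damage filter.
    """

    sample: str
    entry: VariantPanelEntry
    depth: int
    alt_depth: int
    flags: frozenset[str] = frozenset()
    status: str = "no_call"

    @property
    def allele_fraction(self) -> float:
        return self.alt_depth / self.depth if self.depth else float("nan")


def screen_sample(
    pileup: Iterable[PileupRecord],
    panel: Sequence[VariantPanelEntry],
) -> list[VariantHit]:
    """Match pileup evidence against a panel, one hit per covered site.

    Every (sample, panel site) combination with a pileup record yields a
    hit: sites with at least one alternate read become candidates
    (``retained`` until the damage filter rules on them), sites with
    reads but no alternate support are ``no_call``.  A pileup record
    whose reference allele contradicts the panel's is skipped with a
    warning — that is a coordinate or build problem, not evidence.
    """
    by_coord = {(e.chromosome, e.position): e for e in panel}
    hits: list[VariantHit] = []
    for rec in pileup:
        entry = by_coord.get((rec.chromosome, rec.position))
        if entry is None:
            continue
        if rec.ref != entry.ref:
            warnings.warn(
                f"{rec.sample} {rec.chromosome}:{rec.position}: pileup ref "
                f"{rec.ref} conflicts with panel ref {entry.ref}; site skipped",
                stacklevel=2,
            )
            continue
        status = "retained" if rec.alt_depth > 0 else "no_call"
        hits.append(
            VariantHit(
                sample=rec.sample,
                entry=entry,
                depth=rec.depth,
                alt_depth=rec.alt_depth,
                status=status,
            )
        )
    hits.sort(key=lambda h: (h.sample, chromosome_sort_key(h.entry.chromosome), h.entry.position))
    return hits


def apply_damage_filter(
    hits: Iterable[VariantHit],
    min_alt_reads: int = 2,
    cross_sample: bool = True,
    overrides: Mapping[tuple[str, str], bool] | Iterable[tuple[str, str]] | None = None,
    min_depth: int | None = None,
) -> list[VariantHit]:
    """Finalize hit status under the low-coverage-transition rule.

    A transition hit with ``alt_depth < min_alt_reads`` (optionally also
    ``depth < min_depth``) is flagged ``low_coverage_transition`` and
    excluded, unless

    * ``cross_sample`` is set and at least two samples show alternate
      reads for the same panel allele (flag ``multi_sample_corroborated``), or
    * a ``(sample, snp_id)`` phenotype override is supplied (flag
      ``phenotype_corroborated``), mirroring skeletal-evidence exceptions.

    Transversion hits are never excluded by this filter.  The function
    recomputes flags from the raw evidence, so applying it twice equals
    applying it once.
    """
    hits = list(hits)
    override_keys: set[tuple[str, str]] = set()
    if overrides:
        if isinstance(overrides, Mapping):
            override_keys = {k for k, v in overrides.items() if v}
        else:
            override_keys = set(overrides)

    support: dict[tuple[str, int, str], set[str]] = {}
    for h in hits:
        if h.alt_depth > 0:
            key = (h.entry.chromosome, h.entry.position, h.entry.alt)
            support.setdefault(key, set()).add(h.sample)

    out: list[VariantHit] = []
    for h in hits:
        if h.alt_depth == 0:
            out.append(replace(h, flags=frozenset(), status="no_call"))
            continue
        flags: set[str] = set()
        status = "retained"
        low = h.alt_depth < min_alt_reads or (min_depth is not None and h.depth < min_depth)
        if h.entry.mutation_class == "transition" and low:
            flags.add("low_coverage_transition")
            key = (h.entry.chromosome, h.entry.position, h.entry.alt)
            if cross_sample and len(support.get(key, ())) >= 2:
                flags.add("multi_sample_corroborated")
            elif (h.sample, h.entry.snp_id) in override_keys:
                flags.add("phenotype_corroborated")
            else:
                status = "excluded"
        out.append(replace(h, flags=frozenset(flags), status=status))
    return out


def summarize_report(hits: Iterable[VariantHit]) -> pd.DataFrame:
    """Roll hits up per (sample, condition): counts and strongest retained hit.

    Columns: sample, condition, retained, excluded, no_call, top_variant
    (rsID of the retained hit with most alternate reads; ties broken by
    genomic coordinate), top_alt_depth, top_allele_fraction.  Ordering
    is deterministic (sample, then condition).
    """
    rows: dict[tuple[str, str], dict] = {}
    for h in hits:
        key = (h.sample, h.entry.condition)
        row = rows.setdefault(
            key,
            {"sample": h.sample, "condition": h.entry.condition,
             "retained": 0, "excluded": 0, "no_call": 0,
             "top_variant": "", "top_alt_depth": 0, "top_allele_fraction": float("nan"),
             "_top_key": None},
        )
        row[h.status] += 1
        if h.status == "retained":
            cand = (-h.alt_depth, chromosome_sort_key(h.entry.chromosome), h.entry.position)
            if row["_top_key"] is None or cand < row["_top_key"]:
                row["_top_key"] = cand
                row["top_variant"] = h.entry.snp_id
                row["top_alt_depth"] = h.alt_depth
                row["top_allele_fraction"] = h.allele_fraction
    body = [
        {k: v for k, v in row.items() if k != "_top_key"}
        for _, row in sorted(rows.items())
        if row["retained"] + row["excluded"] + row["no_call"] > 0
    ]
    columns = ["sample", "condition", "retained", "excluded", "no_call",
               "top_variant", "top_alt_depth", "top_allele_fraction"]
    return pd.DataFrame(body, columns=columns)
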