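"""Damage-aware clinical variant screening.

Screens pileup evidence from three (synthetic) individuals against the
shipped mtDNA and clinical demonstration panels: a high-coverage LHON
mutation, a single-read transition (damage-suspect, excluded), and the
same single-read transversion in two individuals (retained).
"""

from paleokin import PileupRecord, apply_damage_filter, read_panel, screen_sample, summarize_report
from paleokin.data import panel_path

panel = read_panel(panel_path("mtdna")) + read_panel(panel_path("clinical"))

pileup = [
    # LHON-defining mtDNA variant at 48x — unambiguous
    PileupRecord("S1", "MT", 14484, "T", "C", 48, 48),
    # one alternate read at a C>T transition: could be deamination
    PileupRecord("S15", "13", 108863559, "C", "T", 1, 1),
    # one alternate read at an A>T transversion in two individuals:
    # damage cannot produce transversions, so both are kept
    PileupRecord("S6", "7", 146489606, "A", "T", 1, 1),
    PileupRecord("S45", "7", 146489606, "A", "T", 2, 1),
]

hits = apply_damage_filter(screen_sample(pileup, panel), min_alt_reads=2,
                           cross_sample=True)
for h in hits:
    frac = f"{h.allele_fraction:.2f}" if h.depth else "-"
    print(f"{h.sample:<4} {h.entry.snp_id:<12} {h.entry.mutation_class:<12}"
          f" {h.alt_depth}/{h.depth} reads (af={frac})  {h.status:<9}"
          f" {','.join(sorted(h.flags)) or '-'}")

print("\nper-condition rollup:")
print(summarize_report(hits).to_string(index=False))
print(
    "\nOnly the single-read transition is excluded: deamination mimics"
    "\nC->T, so a lone alternate read there is weak evidence unless a"
    "\nsecond sample (or a phenotype override) corroborates it."
)
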