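"""Accessors for the small data tables shipped with the package.

The variant panels are *synthetic demonstration panels*: they are
format-identical to real screening panels (ClinVar-derived clinical
sets, pigmentation SNP sets, mtDNA disease sites) but their membership
is illustrative, anchored on a handful of well-known variants.  A real
clinical panel is regenerated from a ClinVar release by keeping
single-nucleotide variants marked pathogenic/likely pathogenic and
dropping deletions, duplications, CNVs and conflicting reports; drop
the resulting TSV in and the toolkit consumes it unchanged.

``bk_cohort_sexes.tsv`` is the published sex and cultural-horizon
assignment of the Balatonkeresztúr Bronze Age individuals (plus one
Baden-culture individual), shipped as a worked input for cohort
aggregation.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["panel_path", "cohort_sexes_path", "load_cohort_sexes"]

_PANELS = {
    "clinical": "clinical_panel_synthetic.tsv",
    "pigmentation": "pigmentation_panel_synthetic.tsv",
    "mtdna": "mtdna_panel_synthetic.tsv",
}


def panel_path(name: str) -> Path:
    """Path to a shipped demonstration panel: clinical, pigmentation or mtdna."""
    if name not in _PANELS:
        raise KeyError(f"unknown panel {name!r}; available: {sorted(_PANELS)}")
    return Path(str(resources.files("paleokin") / "data" / _PANELS[name]))


def cohort_sexes_path() -> Path:
    """Path to the published cohort sex/group table."""
    return Path(str(resources.files("paleokin") / "data" / "bk_cohort_sexes.tsv"))


def load_cohort_sexes() -> pd.DataFrame:
    """Published sex and horizon labels as a DataFrame (sample, group, sex)."""
    return pd.read_csv(cohort_sexes_path(), sep="\t", dtype=str)
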