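"""End-to-end pipeline on a fully synthetic cohort.

One config drives simulation (pedigree genotypes, per-karyotype depth
tables, a planted panel variant), ploidy calling, kinship estimation,
variant screening and the cohort report.  Rerunning with the same
config reproduces identical bytes.
"""

import tempfile
from pathlib import Path

import pandas as pd

from paleokin import run_pipeline

samples = ["U1", "U2", "U3", "U4", "U5", "U6", "F1", "F2", "C1"]
config = {
    "seed": 11,
    "stages": ["simulate", "ploidy", "kinship", "screen", "report"],
    "simulate": {
        "pedigree": {"founders": samples[:8], "matings": [["F1", "F2", "C1"]]},
        "n_sites": 20_000,
        "coverage": 0.9,
        "karyotypes": dict.fromkeys(samples, "XY") | {"U2": "XX", "U4": "XX",
                                                      "U6": "XX", "F2": "XX",
                                                      "C1": "XYY"},
        "depth_coverage": 0.05,
        "panel": "clinical",
        "pileup_coverage": 6.0,
        "planted_variants": [["C1", "rs7794745", 1], ["F1", "rs7794745", 1]],
    },
    "ploidy": {"n_ref": 20, "ref_coverage": 0.1},
    "kinship": {"min_overlap": 1000},
    "screen": {"min_alt_reads": 2, "cross_sample": True},
    "report": {"groups": dict.fromkeys(samples, "demo")},
}

outdir = Path(tempfile.mkdtemp(prefix="paleokin_demo_"))
artifacts = run_pipeline(config, outdir=outdir)

kary = pd.read_csv(artifacts["karyotype"], sep="\t", dtype=str)
summary = kary[kary["chrom"] == "karyotype"]
print("karyotypes:", dict(zip(summary["sample"], summary["gonosomal"])))

edges = pd.read_csv(artifacts["network"], sep="\t")
print("kinship edges:")
print(edges.to_string(index=False))

hits = pd.read_csv(artifacts["hits"], sep="\t")
print("retained variant hits:")
print(hits[hits["status"] == "retained"][["sample", "rsID", "alt_depth", "status"]]
      .to_string(index=False))

print(f"\nall artifacts under {outdir}")
print(
    "\nEverything planted is recovered: the XYY child C1, the two"
    "\nparent-child first-degree edges, and the rs7794745 transversion"
    "\nretained in both carriers."
)
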