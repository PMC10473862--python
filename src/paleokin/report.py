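"""Cohort aggregation and the end-to-end pipeline driver.

``aggregate`` builds Table-1-style per-group summaries (sample counts,
genetic-sex counts, integer male percentage).  ``run_pipeline`` wires
the stages — synthetic-data generation, ZAC ploidy, MPMR kinship,
panel screening, cohort report — behind one declarative YAML config,
logging parameters and output digests so a rerun with the same config
reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import data as _data
from .io_formats import read_eigenstrat, read_panel, read_pileup, write_eigenstrat, write_pileup
from .kinship import build_network, kin_matrix
from .screen import apply_damage_filter, screen_sample, summarize_report
from .simulate import (
    PedigreeSpec,
    SimulationConfig,
    pseudohaploidize,
    simulate_depth_table,
    simulate_pedigree_genotypes,
    simulate_pileup,
)
from .zac import (
    build_reference_stats,
    call_karyotype,
    estimate_ploidy,
    read_depth_table,
    write_depth_table,
)

__all__ = ["CohortSummary", "aggregate", "male_percentage", "run_pipeline"]

log = logging.getLogger("paleokin")

_ALL_STAGES = ("simulate", "ploidy", "kinship", "screen", "report")


@dataclass
class CohortSummary:
    """Cohort-level rollup: sex table, kinship edges, anomalies, variants."""

    sex_table: pd.DataFrame
    kinship_edges: list[tuple] = field(default_factory=list)
    karyotype_anomalies: list[str] = field(default_factory=list)
    retained_hits: pd.DataFrame | None = None


def male_percentage(males: int, females: int) -> int | None:
    """Integer male percentage, floored; None when no determinate calls."""
    if males + females == 0:
        return None
    return 100 * males // (males + females)


def aggregate(
    sex_calls: Mapping[str, str],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Per-group genetic-sex summary plus a pooled ``ALL`` row.

    ``sex_calls`` maps sample -> {M, F, undetermined}; ``groups`` maps
    sample -> group label and must not mention unknown samples.
    Undetermined sexes are excluded from the male percentage, which is
    floored to an integer percent.
    """
    unknown = sorted(set(groups) - set(sex_calls))
    if unknown:
        raise ValueError(f"samples in group labels but without sex calls: {unknown}")
    rows = []
    labels = sorted(set(groups.values()))
    for label in labels + ["ALL"]:
        members = [s for s in groups if label == "ALL" or groups[s] == label]
        sexes = [sex_calls[s] for s in members]
        m, f = sexes.count("M"), sexes.count("F")
        und = len(sexes) - m - f
        rows.append(
            {"group": label, "n": len(members), "males": m, "females": f,
             "undetermined": und, "male_pct": male_percentage(m, f)}
        )
    return pd.DataFrame(rows, columns=["group", "n", "males", "females",
                                       "undetermined", "male_pct"])


def run_pipeline(config: str | Path | Mapping, outdir: str | Path | None = None) -> dict[str, Path]:
    """Run the enabled stages of the pipeline from a declarative config.

    The config (YAML path or mapping) names a ``seed``, the enabled
    ``stages`` and per-stage sections; every analysis stage either
    consumes the simulate stage's output or an explicit input path, and
    missing inputs are reported before any stage runs.  Returns a
    mapping of artifact names to paths.  Reruns with an identical
    config are byte-identical.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    outdir = Path(outdir or cfg.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = list(cfg.get("stages", _ALL_STAGES))
    bad = [s for s in stages if s not in _ALL_STAGES]
    if bad:
        raise ValueError(f"unknown stages {bad}; known: {list(_ALL_STAGES)}")
    sim = cfg.get("simulate", {})

    # fail-fast input validation before any stage executes
    def _needs(stage: str, key: str, sim_key: str) -> None:
        if stage in stages and key not in cfg.get(stage, {}):
            if "simulate" not in stages or sim_key not in sim:
                raise ValueError(
                    f"stage {stage!r} is enabled but has no {key!r} input and the "
                    f"simulate stage does not provide one"
                )

    _needs("ploidy", "depths", "karyotypes")
    _needs("kinship", "geno", "pedigree")
    _needs("screen", "pileup", "panel")
    if "report" in stages and "groups" not in cfg.get("report", {}):
        raise ValueError("stage 'report' is enabled but lists no group labels")

    artifacts: dict[str, Path] = {}

    if "simulate" in stages:
        _stage_simulate(sim, seed, outdir, artifacts)
    if "ploidy" in stages:
        _stage_ploidy(cfg.get("ploidy", {}), seed, outdir, artifacts)
    if "kinship" in stages:
        _stage_kinship(cfg.get("kinship", {}), outdir, artifacts)
    if "screen" in stages:
        _stage_screen(cfg.get("screen", {}), outdir, artifacts)
    if "report" in stages:
        _stage_report(cfg.get("report", {}), outdir, artifacts)

    for name, path in artifacts.items():
        if name == "geno_prefix":  # prefix of a .geno/.snp/.ind trio
            for ext in (".geno", ".snp", ".ind"):
                f = path.with_suffix(ext)
                log.info("artifact %s%s: %s sha256=%s", name, ext, f, _digest(f))
        else:
            log.info("artifact %s: %s sha256=%s", name, path, _digest(path))
    return artifacts


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _resolve_panel(name_or_path: str) -> Path:
    p = Path(name_or_path)
    return p if p.exists() else _data.panel_path(name_or_path)


def _stage_simulate(sim: Mapping, seed: int, outdir: Path, artifacts: dict) -> None:
    log.info("simulate: seed=%d", seed)
    if "pedigree" in sim:
        ped = PedigreeSpec(
            founders=tuple(sim["pedigree"].get("founders", ())),
            matings=tuple(tuple(m) for m in sim["pedigree"].get("matings", ())),
            duplicates=tuple(tuple(d) for d in sim["pedigree"].get("duplicates", ())),
        )
        scfg = SimulationConfig(
            n_sites=int(sim.get("n_sites", 10_000)),
            coverage=float(sim.get("coverage", 1.0)),
            damage_rate=float(sim.get("damage_rate", 0.0)),
            error_rate=float(sim.get("error_rate", 0.0)),
            seed=seed,
        )
        rng = np.random.default_rng([seed, 1])
        diploid = simulate_pedigree_genotypes(ped, scfg, rng=rng)
        matrix = pseudohaploidize(diploid, scfg, rng=rng)
        prefix = outdir / "simulated"
        write_eigenstrat(matrix, prefix)
        artifacts["geno_prefix"] = prefix
        log.info("simulate: wrote %d samples x %d SNPs", matrix.n_samples, matrix.n_snps)
    if "karyotypes" in sim:
        rng = np.random.default_rng([seed, 2])
        coverage = float(sim.get("depth_coverage", 0.05))
        sites = sim.get("sites_per_chromosome")
        tables = [
            simulate_depth_table(k, sites, coverage, rng=rng, sample=s)
            for s, k in sim["karyotypes"].items()
        ]
        path = outdir / "depths.tsv"
        write_depth_table(tables, path)
        artifacts["depths"] = path
    if "panel" in sim:
        rng = np.random.default_rng([seed, 3])
        panel = read_panel(_resolve_panel(sim["panel"]))
        samples = list(sim.get("pileup_samples") or sim.get("karyotypes", {"sim": None}))
        doses = np.full((len(samples), len(panel)), 2, dtype=np.int8)  # hom-ref default
        idx = {e.snp_id: j for j, e in enumerate(panel)}
        for s, rsid, alt_doses in sim.get("planted_variants", ()):
            doses[samples.index(s), idx[rsid]] = 2 - int(alt_doses)
        from .io_formats import PseudohaploidMatrix, SnpRecord

        snps = [SnpRecord(e.snp_id, e.chromosome, e.position, e.ref, e.alt) for e in panel]
        truth = PseudohaploidMatrix(samples, snps, doses, diploid=True)
        scfg = SimulationConfig(
            damage_rate=float(sim.get("damage_rate", 0.0)),
            error_rate=float(sim.get("error_rate", 0.0)),
            seed=seed,
        )
        records = simulate_pileup(panel, truth, float(sim.get("pileup_coverage", 4.0)),
                                  cfg=scfg, rng=rng)
        path = outdir / "pileup.tsv"
        write_pileup(records, path)
        artifacts["pileup"] = path
        artifacts["panel"] = _resolve_panel(sim["panel"])


def _stage_ploidy(pcfg: Mapping, seed: int, outdir: Path, artifacts: dict) -> None:
    depths_path = Path(pcfg.get("depths", artifacts.get("depths", "")))
    tables = read_depth_table(depths_path)
    n_ref = int(pcfg.get("n_ref", 20))
    ref_coverage = float(pcfg.get("ref_coverage", 0.1))
    rng = np.random.default_rng([seed, 101])
    sites = tables[0].sites
    refs, ref_karyotypes = [], {}
    for i in range(n_ref):
        k = "XX" if i % 2 == 0 else "XY"
        name = f"ref{i}"
        refs.append(simulate_depth_table(k, sites, ref_coverage, rng=rng, sample=name))
        ref_karyotypes[name] = k
    stats = build_reference_stats(refs, ref_karyotypes)
    z = float(pcfg.get("z_threshold", 3.0))
    min_reads = int(pcfg.get("min_reads", 100))
    log.info("ploidy: %d samples, %d refs at %.3fx, z=%.1f", len(tables), n_ref, ref_coverage, z)

    rows = []
    for t in tables:
        calls = estimate_ploidy(t, stats, z_threshold=z)
        kc = call_karyotype(calls, min_reads=min_reads)
        for c in calls:
            rows.append({"sample": t.sample, "chrom": c.chromosome,
                         "ratio": f"{c.ratio:.6f}", "z": f"{c.z:.4f}",
                         "copies": c.copies, "flagged": int(c.flagged),
                         "gonosomal": "", "genetic_sex": ""})
        rows.append({"sample": t.sample, "chrom": "karyotype", "ratio": "", "z": "",
                     "copies": "", "flagged": "", "gonosomal": kc.karyotype_label,
                     "genetic_sex": kc.genetic_sex})
    path = outdir / "karyotype.tsv"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    artifacts["karyotype"] = path


def _stage_kinship(kcfg: Mapping, outdir: Path, artifacts: dict) -> None:
    prefix = Path(kcfg.get("geno", artifacts.get("geno_prefix", "")))
    matrix = read_eigenstrat(prefix)
    estimates = kin_matrix(
        matrix,
        min_overlap=int(kcfg.get("min_overlap", 1000)),
        background=kcfg.get("background", "median"),
        supplied_background=kcfg.get("supplied_background"),
    )
    log.info("kinship: %d samples, %d pairs", matrix.n_samples, len(estimates))
    rows = [
        {"a": e.pair[0], "b": e.pair[1], "overlap": e.overlap,
         "pmr": f"{e.pmr:.6f}", "norm": f"{e.norm:.6f}", "se": f"{e.se:.6f}",
         "degree": e.degree}
        for e in estimates
    ]
    pairs_path = outdir / "pairs.tsv"
    pd.DataFrame(rows).to_csv(pairs_path, sep="\t", index=False)
    net = build_network(estimates)
    edges = [
        {"a": a, "b": b, "degree": d["degree"], "norm": f"{d['norm']:.6f}"}
        for a, b, d in sorted(net.edges(data=True))
    ]
    net_path = outdir / "network.tsv"
    pd.DataFrame(edges, columns=["a", "b", "degree", "norm"]).to_csv(
        net_path, sep="\t", index=False
    )
    artifacts["pairs"] = pairs_path
    artifacts["network"] = net_path


def _stage_screen(scfg: Mapping, outdir: Path, artifacts: dict) -> None:
    pileup = read_pileup(Path(scfg.get("pileup", artifacts.get("pileup", ""))))
    panel = read_panel(Path(scfg.get("panel", artifacts.get("panel", ""))))
    hits = screen_sample(pileup, panel)
    overrides = {tuple(o) for o in scfg.get("overrides", ())}
    hits = apply_damage_filter(
        hits,
        min_alt_reads=int(scfg.get("min_alt_reads", 2)),
        cross_sample=bool(scfg.get("cross_sample", True)),
        overrides=overrides,
        min_depth=scfg.get("min_depth"),
    )
    log.info("screen: %d hits over %d panel sites", len(hits), len(panel))
    rows = [
        {"sample": h.sample, "rsID": h.entry.snp_id, "chrom": h.entry.chromosome,
         "pos": h.entry.position, "ref": h.entry.ref, "alt": h.entry.alt,
         "class": h.entry.mutation_class, "condition": h.entry.condition,
         "depth": h.depth, "alt_depth": h.alt_depth,
         "flags": ",".join(sorted(h.flags)), "status": h.status}
        for h in hits
    ]
    hits_path = outdir / "hits.tsv"
    pd.DataFrame(rows).to_csv(hits_path, sep="\t", index=False)
    summary_path = outdir / "screen_summary.tsv"
    summarize_report(hits).to_csv(summary_path, sep="\t", index=False, float_format="%.4f")
    artifacts["hits"] = hits_path
    artifacts["screen_summary"] = summary_path


def _stage_report(rcfg: Mapping, outdir: Path, artifacts: dict) -> None:
    groups = dict(rcfg["groups"])
    sex_calls: dict[str, str] = {}
    if "karyotype" in artifacts:
        df = pd.read_csv(artifacts["karyotype"], sep="\t", dtype=str)
        summary = df[df["chrom"] == "karyotype"]
        sex_calls = dict(zip(summary["sample"], summary["genetic_sex"]))
    sex_calls.update(rcfg.get("sexes", {}))
    table = aggregate({s: sex_calls.get(s, "undetermined") for s in groups}, groups)
    path = outdir / "cohort.tsv"
    table.to_csv(path, sep="\t", index=False)
    artifacts["cohort"] = path
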