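"""End-to-end orchestration of the synthetic study.

Stages run in a fixed order (simulate, faers, signals, meta, mr, network,
report); each reads only the outputs of earlier stages from the run
directory, so deleting and rerunning a downstream stage reproduces its
files byte-identically under the same config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import faers, meta, mr, network, signals, synthetic
from .config import PipelineConfig, RunManifest, STAGES, file_checksum
from .errors import ConfigurationError, UndefinedStatisticError

logger = logging.getLogger(__name__)

__all__ = ["run", "run_stage"]


def run(config: PipelineConfig) -> tuple[Path, RunManifest]:
    """Execute the enabled stages in order; write a run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.seed, version=__version__
    )
    for name, path in sorted(config.inputs.items()):
        manifest.input_checksums[name] = file_checksum(path)
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        logger.info("stage %s ...", stage)
        try:
            counts = run_stage(stage, config, out)
        except Exception:
            logger.error("stage %s failed; partial outputs retained in %s", stage, out)
            raise
        manifest.record(stage, time.perf_counter() - t0, counts)
    manifest.write(out / "manifest.json")
    return out, manifest


def run_stage(stage: str, config: PipelineConfig, out: Path) -> dict:
    fn = {
        "simulate": _stage_simulate,
        "faers": _stage_faers,
        "signals": _stage_signals,
        "meta": _stage_meta,
        "mr": _stage_mr,
        "network": _stage_network,
        "report": _stage_report,
    }.get(stage)
    if fn is None:
        raise ConfigurationError(f"unknown stage {stage!r}")
    stage_dir = out / stage
    stage_dir.mkdir(parents=True, exist_ok=True)
    return fn(config, out, stage_dir)


# ---------------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, out: Path, d: Path) -> dict:
    sim = config.simulate
    seed = config.stage_seed("simulate")

    rcfg = synthetic.default_report_config(
        n_reports=sim.n_reports,
        planted_signals=[tuple(s) for s in sim.planted_signals],
        seed=seed,
    )
    rcfg.duplicate_rate = sim.duplicate_rate
    tables = synthetic.gen_reports(rcfg)
    synthetic.write_faers_tables(tables, d / "faers")

    gcfg = synthetic.GwasSimConfig(n_snps=sim.n_snps, frac_nonnull=0.002, seed=seed + 1)
    g1, g2 = synthetic.gen_gwas_pair(gcfg)
    meta.write_gwas(g1, d / "gwas1.tsv")
    meta.write_gwas(g2, d / "gwas2.tsv")

    prot_dir = d / "proteins"
    prot_dir.mkdir(exist_ok=True)
    loci_rows = []
    rng = np.random.default_rng(seed + 2)
    for i in range(sim.n_proteins):
        name = f"GBS{i + 1:03d}"
        causal = i < sim.n_causal_proteins
        beta = sim.causal_beta * float(rng.choice([-1.0, 1.0])) if causal else 0.0
        pcfg = synthetic.PqtlSimConfig(
            n_instruments=sim.instruments_per_protein,
            beta_causal=beta,
            gene_chrom=1 + i % 22,
            seed=seed + 10 + i,
        )
        exp_df, out_df, _ = synthetic.gen_pqtl_study(pcfg)
        meta.write_gwas(exp_df, prot_dir / f"{name}_exposure.tsv")
        meta.write_gwas(out_df, prot_dir / f"{name}_outcome.tsv")
        loci_rows.append(
            {
                "protein": name,
                "dataset": "panelA" if i % 2 == 0 else "panelB",
                "CHR": pcfg.gene_chrom,
                "start": pcfg.gene_start,
                "end": pcfg.gene_end,
                "true_beta": beta,
            }
        )
    pd.DataFrame(loci_rows).to_csv(d / "protein_loci.tsv", sep="\t", index=False)

    edge_df, gmt, expr = synthetic.gen_network_fixtures(
        seed=seed + 3, n_susceptibility=sim.n_proteins
    )
    edge_df.to_csv(d / "edges.tsv", sep="\t", index=False)
    network.write_gmt(gmt, d / "pathways.gmt")
    expr.to_csv(d / "expression.tsv", sep="\t")
    targets = sorted({g for g in edge_df["protein1"]} | {g for g in edge_df["protein2"]})
    drug_names = list(rcfg.drugs)
    t2d = pd.DataFrame(
        {
            "target": [t for t in targets if t.startswith("TGT")],
        }
    )
    t2d["drug"] = [drug_names[i % len(drug_names)] for i in range(len(t2d))]
    t2d.to_csv(d / "target_to_drug.tsv", sep="\t", index=False)

    return {
        "reports": int(tables["DEMO"]["caseversion"].eq(0).sum()),
        "report_rows": len(tables["DEMO"]),
        "snps": sim.n_snps,
        "proteins": sim.n_proteins,
        "edges": len(edge_df),
    }


def _reports_dir(config: PipelineConfig, out: Path) -> Path:
    if "reports_dir" in config.inputs:
        return Path(config.inputs["reports_dir"])
    return out / "simulate" / "faers"


def _stage_faers(config: PipelineConfig, out: Path, d: Path) -> dict:
    rs = faers.read_reports(_reports_dir(config, out), dialect="faers_ascii")
    roles = set(config.roles)
    if roles < set(faers.ROLE_CODES):
        # optional restriction to suspect drugs; reports left drug-less drop out
        kept = []
        for rec in rs:
            drugs = tuple((g, r) for g, r in rec.drugs if r in roles)
            if drugs:
                kept.append(replace(rec, drugs=drugs))
        rs = faers.ReportSet(records=tuple(kept), provenance=rs.provenance)
    deduped, counts = faers.deduplicate(rs)
    cases = faers.select_cases(deduped, config.event_terms)
    if len(cases) == 0:
        raise ConfigurationError("no case matches the configured event terms")
    summary = faers.descriptive_summary(cases)
    summary.to_csv(d / "table1.tsv", sep="\t", index=False)
    drugs, indis = faers.rank_drugs_and_indications(cases)
    drugs.to_csv(d / "drug_ranking.tsv", sep="\t", index=False)
    indis.to_csv(d / "indication_ranking.tsv", sep="\t", index=False)
    # the deduplicated full set feeds the signal stage denominators
    synthetic_set = pd.DataFrame(
        {
            "case_id": [r.case_id for r in deduped],
            "drugs": ["|".join(sorted({g for g, _ in r.drugs})) for r in deduped],
            "reactions": ["|".join(sorted(set(r.reactions))) for r in deduped],
        }
    )
    synthetic_set.to_csv(d / "dedup_cases.tsv", sep="\t", index=False)
    return {
        "reports_in": len(rs),
        "after_dedup": len(deduped),
        "cases": len(cases),
        **counts,
    }


def _load_dedup_cases(out: Path) -> pd.DataFrame:
    path = out / "faers" / "dedup_cases.tsv"
    if not path.exists():
        raise ConfigurationError("signals stage requires the faers stage outputs")
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def _stage_signals(config: PipelineConfig, out: Path, d: Path) -> dict:
    df = _load_dedup_cases(out)
    event_keys = {faers.normalize_term(t) for t in config.event_terms}

    has_event = np.array(
        [
            any(faers.normalize_term(r) in event_keys for r in row.split("|"))
            for row in df["reactions"]
        ]
    )
    drug_lists = [row.split("|") if row else [] for row in df["drugs"]]
    all_drugs = sorted({g for lst in drug_lists for g in lst})
    n = len(df)
    n_event = int(has_event.sum())

    th = config.thresholds
    crit = signals.CriteriaThresholds(
        min_cases=th.signal_min_cases, prr_min=th.prr_min, chi2_min=th.chi2_min
    )
    results = []
    for drug in all_drugs:
        has_drug = np.array([drug in lst for lst in drug_lists])
        a = int((has_drug & has_event).sum())
        b = int(has_drug.sum()) - a
        c = n_event - a
        dd = n - a - b - c
        try:
            res = signals.evaluate_signal(
                signals.ContingencyTable(a, b, c, dd),
                drug=drug,
                thresholds=crit,
                ebgm_z=th.ebgm_z,
            )
        except UndefinedStatisticError:
            continue
        results.append(res)

    ranked = signals.rank_signals(results, top=config.top_signals)
    ranked.to_csv(d / "signals_full.tsv", sep="\t", index=False, float_format="%.6g")
    signals.format_signal_table(ranked).to_csv(d / "table2.tsv", sep="\t", index=False)
    return {"drugs_tested": len(all_drugs), "flagged": len(ranked)}


def _stage_meta(config: PipelineConfig, out: Path, d: Path) -> dict:
    g1 = meta.read_gwas(config.inputs.get("gwas1", out / "simulate" / "gwas1.tsv"))
    g2 = meta.read_gwas(config.inputs.get("gwas2", out / "simulate" / "gwas2.tsv"))
    aligned, drop_log = meta.harmonize_variants(g1, g2)
    pooled = meta.fixed_effect_meta(aligned)
    meta.write_gwas(
        pooled.assign(EAF=np.nan, N=0)[meta.GWAS_COLUMNS], d / "meta.tsv"
    )
    drop_log.to_csv(d / "harmonization_drops.tsv", sep="\t", index=False)
    lam = meta.genomic_lambda(pooled["P"])
    loci = meta.significant_loci(pooled)
    loci.to_csv(d / "significant_loci.tsv", sep="\t", index=False)
    qq, man = meta.qq_manhattan_tables(pooled)
    qq.to_csv(d / "qq.tsv", sep="\t", index=False, float_format="%.6g")
    man.to_csv(d / "manhattan.tsv", sep="\t", index=False, float_format="%.6g")
    with open(d / "lambda.json", "w") as fh:
        json.dump({"lambda": lam.value, "n": lam.n, "low_confidence": lam.low_confidence}, fh)
        fh.write("\n")
    return {
        "snps_pooled": len(pooled),
        "dropped": len(drop_log),
        "loci": len(loci),
        "lambda": lam.value,
    }


def _stage_mr(config: PipelineConfig, out: Path, d: Path) -> dict:
    sim_dir = out / "simulate"
    loci = pd.read_csv(sim_dir / "protein_loci.tsv", sep="\t")
    th = config.thresholds
    panels = []
    outcomes = {}
    for row in loci.itertuples(index=False):
        exp_df = meta.read_gwas(sim_dir / "proteins" / f"{row.protein}_exposure.tsv")
        outcomes[row.protein] = meta.read_gwas(
            sim_dir / "proteins" / f"{row.protein}_outcome.tsv"
        )
        panels.append(
            mr.Panel(
                protein=row.protein,
                dataset=row.dataset,
                exposure=exp_df,
                locus=mr.GeneLocus(int(row.CHR), int(row.start), int(row.end), row.protein),
            )
        )

    results: list[mr.MRResult] = []
    seed = config.stage_seed("mr")
    for k, panel in enumerate(panels):
        try:
            results.append(
                mr.run_mr(
                    panel,
                    outcomes[panel.protein],
                    p_threshold=th.gwas_p,
                    f_threshold=th.f_stat,
                    r2_threshold=th.ld_r2,
                    seed=seed + k,
                )
            )
        except mr.NoInstrumentsError as exc:
            logger.info("%s", exc)
    for dataset in sorted({r.dataset for r in results}):
        group = [r for r in results if r.dataset == dataset]
        adj = mr.fdr_adjust([r.primary.p for r in group])
        for r, q in zip(group, adj):
            r.fdr_p = float(q)
    table = mr.results_table(results)
    table.to_csv(d / "mr_results.tsv", sep="\t", index=False, float_format="%.6g")
    sig = sorted(
        r.protein for r in results if r.fdr_p is not None and r.fdr_p < th.fdr and r.verdict
    )
    sets = {
        ds: sorted(
            r.protein
            for r in results
            if r.dataset == ds and r.fdr_p is not None and r.fdr_p < th.fdr and r.verdict
        )
        for ds in sorted({r.dataset for r in results})
    }
    summary = {"significant": sig, "per_dataset": sets}
    if len(sets) == 2:
        (na, sa), (nb, sb) = sets.items()
        summary.update(mr.overlap_summary(sa, sb, na, nb))
    with open(d / "mr_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"proteins": len(panels), "analyzed": len(results), "significant": len(sig)}


def _stage_network(config: PipelineConfig, out: Path, d: Path) -> dict:
    sim_dir = out / "simulate"
    net = network.load_network(sim_dir / "edges.tsv", score_threshold=config.thresholds.score)
    with open(out / "mr" / "mr_summary.json") as fh:
        sig = json.load(fh)["significant"]
    all_a = sorted(pd.read_csv(sim_dir / "protein_loci.tsv", sep="\t")["protein"])
    set_a = sig or all_a
    t2d_df = pd.read_csv(sim_dir / "target_to_drug.tsv", sep="\t")
    set_b = sorted(t2d_df["target"])
    t2d = {row.target: [row.drug] for row in t2d_df.itertuples(index=False)}
    overlap = network.cross_set_interactions(net, all_a, set_b, t2d)
    overlap.ranked.to_csv(d / "cross_degrees.tsv", sep="\t", index=False)

    gmt = network.read_gmt(sim_dir / "pathways.gmt")
    enrich = network.ora_enrichment(set_a, gmt, universe=None, keep_all=True)
    enrich.to_csv(d / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    expr = pd.read_csv(sim_dir / "expression.tsv", sep="\t", index_col=0)
    profile = network.tissue_profile(expr, set_a)
    profile.to_csv(d / "tissue_profile.tsv", sep="\t")
    with open(d / "overlap.json", "w") as fh:
        json.dump(
            {
                "cross_edges": overlap.cross_edges,
                "a_touched": overlap.a_touched,
                "b_touched": overlap.b_touched,
                "drugs": sorted(overlap.drugs),
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return {
        "edges": len(net),
        "cross_edges": overlap.cross_edges,
        "enriched_pathways": int((enrich["p_adjusted"] < 0.05).sum()),
    }


def _stage_report(config: PipelineConfig, out: Path, d: Path) -> dict:
    lines = ["# Synthetic study report", ""]
    t1 = out / "faers" / "table1.tsv"
    if t1.exists():
        lines += ["## Case characteristics", "", pd.read_csv(t1, sep="\t").to_string(index=False), ""]
    t2 = out / "signals" / "table2.tsv"
    if t2.exists():
        lines += ["## Signal ranking", "", pd.read_csv(t2, sep="\t").to_string(index=False), ""]
    lam = out / "meta" / "lambda.json"
    if lam.exists():
        lines += ["## GWAS meta-analysis", "", lam.read_text().strip(), ""]
    mrs = out / "mr" / "mr_summary.json"
    if mrs.exists():
        lines += ["## Mendelian randomization", "", mrs.read_text().strip(), ""]
    ov = out / "network" / "overlap.json"
    if ov.exists():
        lines += ["## Network overlap", "", ov.read_text().strip(), ""]
    enr = out / "network" / "enrichment.tsv"
    if enr.exists():
        lines += ["## Enrichment", "", pd.read_csv(enr, sep="\t").to_string(index=False), ""]
    (d / "report.md").write_text("\n".join(lines))
    return {"sections": sum(1 for ln in lines if ln.startswith("## "))}
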