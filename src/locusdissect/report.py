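"""Pipeline orchestration and evidence aggregation.

Runs the stages in method order — locus catalogue -> fine-mapping ->
cis-eQTL -> Mendelian randomization -> co-expression network -> peak-gene
linkage — and aggregates the per-gene evidence into a transparent
composite score: one point each for (i) a significant cis-eQTL in any
tissue, (ii) MR P <= 0.05 without HEIDI heterogeneity (HEIDI P > 0.01 or
not evaluated), (iii) a key-driver flag, (iv) an accessibility link whose
peak contains a credible-set SNP, plus a bonus point when the eQTL and MR
effect directions agree.  Candidate genes are ranked by score; a failure
in an optional stage degrades the report instead of aborting.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import atac_link, eqtl, finemap, locus_catalog, mr, network, synthetic_data

logger = logging.getLogger(__name__)

__all__ = ["EvidenceTable", "PipelineReport", "run_pipeline", "score_gene"]

ALL_STAGES = ("locus", "finemap", "eqtl", "mr", "network", "atac")
NOT_EVALUATED = "not evaluated"

#: LD-pruning threshold for MR instruments (r^2 to any kept instrument)
MR_PRUNE_R2 = 0.1
#: exposure strength (z^2) for an eQTL to become an MR instrument
MR_INSTRUMENT_Z2 = 9.0


@dataclass
class EvidenceTable:
    """Per-candidate-gene evidence and composite scores."""

    table: pd.DataFrame

    @property
    def ranking(self) -> list[str]:
        return list(self.table["gene"])


@dataclass
class PipelineReport:
    evidence: EvidenceTable
    artifacts: dict = field(default_factory=dict)
    stage_status: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        """Byte-stable JSON (sorted keys) of the evidence and stage status."""

        def _clean(obj):
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.floating, float)):
                return None if (isinstance(obj, float) and math.isnan(obj)) else float(obj)
            if isinstance(obj, (np.integer, int)):
                return int(obj)
            if isinstance(obj, (np.bool_, bool)):
                return bool(obj)
            return obj

        payload = {
            "evidence": _clean(self.evidence.table.to_dict(orient="records")),
            "stages": _clean(self.stage_status),
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def score_gene(evidence: dict) -> int:
    """Composite evidence score (0-5); missing categories contribute 0."""
    score = 0
    fdr = evidence.get("best_eqtl_fdr")
    if fdr is not None and not _is_na(fdr) and fdr <= 0.05:
        score += 1
    mr_p = evidence.get("mr_p")
    heidi_p = evidence.get("heidi_p")
    mr_ok = (
        mr_p is not None
        and not _is_na(mr_p)
        and mr_p <= 0.05
        and (heidi_p is None or _is_na(heidi_p) or heidi_p > 0.01)
    )
    if mr_ok:
        score += 1
    if evidence.get("key_driver") is True:
        score += 1
    if evidence.get("accessibility_link") is True:
        score += 1
    eb, me = evidence.get("best_eqtl_beta"), evidence.get("mr_estimate")
    if (
        eb is not None
        and me is not None
        and not _is_na(eb)
        and not _is_na(me)
        and np.sign(eb) == np.sign(me)
        and np.sign(eb) != 0
    ):
        score += 1
    return score


def _is_na(x) -> bool:
    try:
        return x is None or (isinstance(x, float) and math.isnan(x))
    except TypeError:
        return False


def _records_from_gwas(bundle: synthetic_data.StudyBundle) -> list[locus_catalog.VariantRecord]:
    """Build the locus table from the simulated GWAS cohort (logistic scan)."""
    assoc = mr.logistic_assoc(bundle.genotypes_gwas, bundle.outcome)
    pos = bundle.variants.set_index("rsid")
    records = []
    for _, row in assoc.iterrows():
        records.append(
            locus_catalog.VariantRecord(
                rsid=row["rsid"],
                chrom=str(pos.loc[row["rsid"], "chrom"]),
                pos=int(pos.loc[row["rsid"], "pos"]),
                a1="A",
                a2="G",
                beta=float(row["beta"]),
                se=float(row["se"]),
                pvalue=float(row["p"]),
                traits=("synthetic",),
            )
        )
    return records


def run_pipeline(
    config: synthetic_data.SimConfig | synthetic_data.StudyBundle | dict,
    stages: tuple[str, ...] | None = None,
    out_dir: str | Path | None = None,
) -> PipelineReport:
    """Execute the locus-dissection pipeline and rank candidate genes.

    ``config`` is a :class:`~locusdissect.synthetic_data.SimConfig` (the
    study is simulated), an already-simulated
    :class:`~locusdissect.synthetic_data.StudyBundle`, or a dict with a
    ``"simulate"`` key holding SimConfig fields.  ``stages`` subsets the
    executed stages; the locus stage is mandatory.  Optional-stage
    failures are logged and marked "not evaluated" in the report.
    """
    stages = tuple(stages) if stages is not None else ALL_STAGES
    if "locus" not in stages:
        raise ValueError("the locus stage is mandatory")
    if isinstance(config, dict):
        if "simulate" not in config:
            raise ValueError("dict config must contain a 'simulate' section with SimConfig fields")
        config = synthetic_data.SimConfig(**config["simulate"])
    bundle = synthetic_data.simulate_study(config) if isinstance(config, synthetic_data.SimConfig) else config
    cfg = bundle.cfg

    artifacts: dict = {}
    status: dict = {s: NOT_EVALUATED for s in ALL_STAGES}
    timings: dict = {}

    def _run(name: str, fn):
        if name not in stages:
            return None
        t0 = time.perf_counter()
        try:
            result = fn()
            status[name] = "ok"
            return result
        except Exception as exc:  # optional stages degrade, never abort
            logger.warning("stage %r failed: %s", name, exc)
            status[name] = f"failed: {exc}"
            return None
        finally:
            timings[name] = time.perf_counter() - t0

    # --- locus catalogue (mandatory) ------------------------------------
    records = _records_from_gwas(bundle)
    lead = locus_catalog.lead_snp(records)
    ld = locus_catalog.compute_ld(bundle.genotypes_gwas)
    annotations = {r.rsid: locus_catalog.annotate_snp(r, bundle.features) for r in records}
    artifacts["locus"] = {
        "records": records,
        "lead_snp": lead.rsid,
        "span_bp": locus_catalog.locus_span(records),
        "ld": ld,
        "annotations": annotations,
    }
    status["locus"] = "ok"

    candidates = sorted(bundle.genes[bundle.genes["chrom"].astype(str) == records[0].chrom]["gene"])

    # --- fine-mapping ----------------------------------------------------
    def _stage_finemap():
        z = np.array([r.z for r in records])
        enum = finemap.enumerate_configs(z, ld, finemap.FinemapPrior())
        single = finemap.single_causal_pips(records)
        return {"single": single, "enum": enum, "credible_set": single.credible_set}

    fm = _run("finemap", _stage_finemap)
    if fm is not None:
        artifacts["finemap"] = fm
    credible = set(fm["credible_set"]) if fm else {lead.rsid}

    # --- cis-eQTL --------------------------------------------------------
    def _stage_eqtl():
        pairs_frame = pd.DataFrame({"rsid": [r.rsid for r in records], "chrom": [r.chrom for r in records], "pos": [r.pos for r in records]})
        cis = eqtl.cis_pairs(pairs_frame, bundle.genes)
        results = {}
        for tissue, expr_df in bundle.expression.items():
            em = eqtl.ExpressionMatrix(tissue, expr_df, is_log=True)
            res = eqtl.map_eqtls(bundle.genotypes_eqtl, em, pairs=cis)
            results[tissue] = res
        return results

    eqtl_res = _run("eqtl", _stage_eqtl)
    if eqtl_res is not None:
        artifacts["eqtl"] = eqtl_res
        target = bundle.truth.target_gene
        arterial = cfg.arterial_tissues[0]
        try:
            artifacts["trait_correlation"] = eqtl.trait_correlation(
                bundle.expression[arterial].loc[target], bundle.traits
            )
        except ValueError as exc:
            logger.warning("trait correlation skipped: %s", exc)

    # --- Mendelian randomization ----------------------------------------
    def _stage_mr():
        outcome_df = pd.DataFrame(
            {"rsid": [r.rsid for r in records], "a1": [r.a1 for r in records], "a2": [r.a2 for r in records],
             "beta": [r.beta for r in records], "se": [r.se for r in records]}
        )
        results: dict[str, dict] = {}
        for gene in candidates:
            best = None
            for tissue in cfg.arterial_tissues:
                res = eqtl_res.get(tissue) if eqtl_res else None
                if res is None:
                    continue
                sub = res[res["gene"] == gene]
                if not len(sub):
                    continue
                exposure = sub.rename(columns={"beta": "beta", "se": "se"})[["rsid", "beta", "se"]].copy()
                exposure["a1"], exposure["a2"] = "A", "G"
                inst = mr.harmonize(exposure, outcome_df, ld=ld)
                strong = np.flatnonzero((inst.b_zx / inst.se_zx) ** 2 >= MR_INSTRUMENT_Z2)
                if len(strong) == 0:
                    continue
                pruned = _ld_prune(inst, strong)
                est = mr.ivw(inst.subset(pruned))
                heidi_p, heidi_n = (None, None)
                if len(strong) >= 3:
                    heidi_p, heidi_n = mr.heidi(inst.subset(list(strong)))
                entry = {"tissue": tissue, "estimate": est.estimate, "se": est.se, "p": est.pvalue,
                         "n_variants": est.n_variants, "heidi_p": heidi_p, "heidi_n": heidi_n}
                if best is None or entry["p"] < best["p"]:
                    best = entry
            if best is not None:
                results[gene] = best
        return results

    mr_res = _run("mr", _stage_mr) if eqtl_res is not None else None
    if mr_res is not None:
        artifacts["mr"] = mr_res

    # --- co-expression network and key drivers ---------------------------
    def _stage_network():
        arterial = cfg.arterial_tissues[0]
        graph = network.build_graph(bundle.expression[arterial], beta=network.DEFAULT_BETA)
        modules = network.detect_modules(graph)
        mt = network.module_trait(modules, bundle.traits) if len(modules.eigengenes.columns) else None
        kd = network.key_drivers(graph, modules) if modules.modules else None
        return {"graph": graph, "modules": modules, "module_trait": mt, "key_drivers": kd}

    net = _run("network", _stage_network)
    if net is not None:
        artifacts["network"] = net

    # --- accessibility linkage -------------------------------------------
    def _stage_atac():
        links = atac_link.peak2gene(
            bundle.accessibility, bundle.group_expression, bundle.peaks, bundle.genes
        )
        hits = atac_link.intersect_snps(records, bundle.peaks)
        linked = atac_link.snp_to_linked_genes(records, links, hits)
        return {"links": links, "intersections": hits, "snp_genes": linked}

    atac = _run("atac", _stage_atac)
    if atac is not None:
        artifacts["atac"] = atac

    # --- evidence aggregation --------------------------------------------
    rows = []
    for gene in candidates:
        ev: dict = {"gene": gene}
        if eqtl_res is not None:
            best_fdr, best_beta, best_tissue, lead_top = None, None, None, False
            for tissue, res in eqtl_res.items():
                sub = res[res["gene"] == gene]
                if not len(sub):
                    continue
                i = sub["fdr"].idxmin()
                if best_fdr is None or sub.loc[i, "fdr"] < best_fdr:
                    best_fdr = float(sub.loc[i, "fdr"])
                    best_beta = float(sub.loc[i, "beta"])
                    best_tissue = tissue
                top_var = sub.loc[sub["p"].idxmin(), "rsid"]
                if top_var == lead.rsid:
                    lead_top = True
            ev.update(best_eqtl_fdr=best_fdr, best_eqtl_beta=best_beta, best_eqtl_tissue=best_tissue,
                      lead_snp_is_top_eqtl=lead_top)
        else:
            ev.update(best_eqtl_fdr=None, best_eqtl_beta=None, best_eqtl_tissue=NOT_EVALUATED,
                      lead_snp_is_top_eqtl=None)
        g_mr = (mr_res or {}).get(gene)
        if g_mr is not None:
            ev.update(mr_estimate=g_mr["estimate"], mr_se=g_mr["se"], mr_p=g_mr["p"],
                      heidi_p=g_mr["heidi_p"], mr_tissue=g_mr["tissue"])
        else:
            ev.update(mr_estimate=None, mr_se=None, mr_p=None, heidi_p=None,
                      mr_tissue=NOT_EVALUATED if mr_res is None else "no instruments")
        if net is not None and net["key_drivers"] is not None:
            kd = net["key_drivers"]
            flagged = kd[(kd["key_driver"]) & (kd["node"].map(lambda n: n[0]) == gene)]
            ev["key_driver"] = bool(len(flagged))
            ev["key_driver_module"] = flagged.iloc[0]["module"] if len(flagged) else None
        else:
            ev["key_driver"] = None if net is None else False
            ev["key_driver_module"] = None
        if atac is not None:
            linked = atac["snp_genes"]
            ev["accessibility_link"] = any(
                gene in linked.get(rsid, {}) for rsid in credible
            )
        else:
            ev["accessibility_link"] = None
        ann = [annotations[r.rsid] for r in records]
        ev["n_snps_in_gene"] = sum(1 for g, _ in ann if g == gene)
        ev["score"] = score_gene(ev)
        rows.append(ev)

    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["score", "mr_p", "gene"],
        ascending=[False, True, True],
        na_position="last",
        kind="stable",
    ).reset_index(drop=True)
    report = PipelineReport(evidence=EvidenceTable(table), artifacts=artifacts, stage_status=status, timings=timings)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        table.to_csv(out / "evidence.tsv", sep="\t", index=False)
    return report


def _ld_prune(inst: mr.InstrumentSet, strong: np.ndarray, r2_max: float = MR_PRUNE_R2) -> list[int]:
    """Greedy LD pruning: keep instruments by descending exposure z^2,
    skipping any with r^2 above the threshold to an already-kept one."""
    z2 = (inst.b_zx / inst.se_zx) ** 2
    order = sorted(strong, key=lambda i: -z2[i])
    kept: list[int] = []
    R = inst.ld.r if inst.ld is not None else None
    for i in order:
        if R is None or all(R[i, j] ** 2 < r2_max for j in kept):
            kept.append(i)
    return kept
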