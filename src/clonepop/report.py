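"""Pipeline orchestration, configuration and the cohort summary report.

``run_pipeline`` wires the stages in dependency order (io -> clonal ->
popstats / sweeps / recomb / ancestry), writes each stage's tables under the
output directory, logs parameters, and isolates stage failures so partial
outputs survive. Enrichment annotations degrade gracefully: a missing TE BED
or gene GFF3 skips those summaries with a warning and leaves the rest of the
run untouched.

The headline descriptive number, :func:`recovery_rate`, is the released
strain's footprint in the field collection: the fraction of field isolates
that belong to the released strain's clonal group.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml

from . import ancestry as anc
from . import clonal, io_core, popstats, recomb, sweeps

log = logging.getLogger("clonepop")


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run (one YAML file)."""

    vcf: str
    meta: str
    out_dir: str
    te_bed: str | None = None
    genes_gff: str | None = None
    mat_fasta: str | None = None
    mat_exclusion: tuple | None = None        # (chrom, start, end)
    pops: list[str] = dc_field(default_factory=lambda: ["1997", "2007", "2017"])
    clonal_threshold: float = 0.998
    lineage_threshold: float = 0.99
    window: int = 5000
    ld_min_maf: float = 0.1
    ld_min_geno: float = 0.6
    ld_max_dist: int = 200_000
    ld_subsample_n: int | None = None
    sweep_grid: int = 1000
    sweep_quantile: float = 0.05
    recomb_min_snps: int = 1500
    recomb_overlap_policy: str | float = "any"
    ancestry_k: list[int] = dc_field(default_factory=lambda: [2, 3, 4, 5, 6])
    ancestry_seeds: int = 5
    ancestry_max_iter: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.vcf, self.meta):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        for p in (self.te_bed, self.genes_gff, self.mat_fasta):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not 0 < self.clonal_threshold < 1:
            raise ValueError("clonal_threshold must be in (0, 1)")
        if not 0 < self.sweep_quantile < 1:
            raise ValueError("sweep_quantile must be in (0, 1)")
        if self.window < 1 or self.sweep_grid < 1 or self.recomb_min_snps < 1:
            raise ValueError("window/grid/min_snps must be positive")

    def child_seed(self, stage: str) -> int:
        # deterministic per-stage seed so stages rerun independently
        return (self.seed * 1_000_003 + sum(map(ord, stage))) % (2**31 - 1)


def recovery_rate(assignment: clonal.CloneAssignment, meta: pd.DataFrame,
                  released_id: str) -> tuple[int, int, float]:
    """(n_clone_members, n_field_isolates, percent) for a released strain.

    Counts every member of the released strain's clonal group among the field
    collection (the released inoculum itself, flagged ``released`` in the
    metadata, is not a field collection and is excluded from both counts);
    percent is rounded to 1 decimal.
    """
    if released_id not in assignment.labels.index:
        raise KeyError(f"released strain {released_id!r} not in assignment")
    lab = assignment.labels[released_id]
    members = assignment.members(lab)
    is_field = ~meta["released"]
    n_clone = sum(1 for m in members if m in meta.index and is_field.get(m, False))
    n_total = int(is_field.sum())
    pct = round(100.0 * n_clone / n_total, 1) if n_total else 0.0
    return n_clone, n_total, pct


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return the report dictionary.

    Writes per-stage TSVs plus ``report.txt`` under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    def stage(name, fn):
        log.info("stage %s: starting", name)
        try:
            res = fn()
        except Exception as e:  # noqa: BLE001 - isolate the failing stage
            log.error("stage %s failed: %s", name, e)
            raise StageError(name, e) from e
        report["stages"][name] = "ok"
        return res

    # --- io ---------------------------------------------------------------
    def _io():
        matrix = io_core.read_vcf(config.vcf, mat_exclusion=config.mat_exclusion)
        meta = io_core.read_meta(config.meta)
        missing = set(matrix.isolate_ids) - set(meta.index)
        if missing:
            raise ValueError(f"isolates without metadata: {sorted(missing)[:5]}")
        return matrix, meta

    matrix, meta = stage("io", _io)
    report["n_isolates"] = matrix.n_isolates
    report["n_sites"] = matrix.n_sites
    pop_ids = {p: [i for i in matrix.isolate_ids
                   if str(meta.loc[i, "pop"]) == p] for p in config.pops}

    # --- clonal ------------------------------------------------------------
    def _clonal():
        idm = clonal.pairwise_identity(matrix)
        assignment = clonal.clonal_groups(idm, config.clonal_threshold)
        assignment.labels.rename_axis("isolate").reset_index().to_csv(
            out / "clones.tsv", sep="\t", index=False)
        if matrix.n_isolates >= 3:
            tree = clonal.nj_tree(idm)
            (out / "nj_tree.nwk").write_text(io_core.write_newick(tree) + "\n")
        coords, ev = clonal.pca(matrix, k=min(10, matrix.n_isolates - 1))
        pd.DataFrame(coords, index=matrix.isolate_ids,
                     columns=[f"PC{i+1}" for i in range(coords.shape[1])]
                     ).rename_axis("isolate").reset_index().to_csv(
            out / "pca.tsv", sep="\t", index=False)
        venn_tab, venn_sum = clonal.temporal_venn(assignment, meta,
                                                  tuple(config.pops))
        venn_tab.to_csv(out / "temporal_venn.tsv", sep="\t", index=False)
        return idm, assignment, venn_sum, ev

    idm, assignment, venn_sum, ev = stage("clonal", _clonal)
    report["clone_recurrence"] = venn_sum
    report["pca_explained"] = [round(float(x), 4) for x in ev[:2]]

    n_groups = sum(1 for lab in assignment.labels.unique()
                   if lab.startswith("C"))
    report["n_clonal_groups"] = n_groups
    report["n_lineages"] = int(assignment.labels.nunique())

    if config.mat_fasta:
        def _mat():
            calls = clonal.mat_type_fasta(config.mat_fasta)
            calls.rename_axis("isolate").reset_index().to_csv(
                out / "mat_types.tsv", sep="\t", index=False)
            return calls
        mat_calls = stage("mat_typing", _mat)
        report["n_heterokaryon"] = int((mat_calls == "both").sum())

    # recovery rates for released strains
    released_ids = list(meta.index[meta["released"]])
    report["recovery_rates"] = {}
    for rid in released_ids:
        if rid in assignment.labels.index:
            n_c, n_t, pct = recovery_rate(assignment, meta, rid)
            report["recovery_rates"][rid] = {"n_clone": n_c, "n_total": n_t,
                                             "percent": pct}

    # --- popstats ----------------------------------------------------------
    def _popstats():
        med_d, med_fst = {}, {}
        for p, ids in pop_ids.items():
            if len(ids) >= 4:
                d = popstats.tajimas_d(matrix, ids, window=config.window)
                d.to_csv(out / f"tajimas_d_{p}.tsv", sep="\t", index=False)
                med_d[p] = float(d["value"].median(skipna=True))
        pops = [p for p, ids in pop_ids.items() if len(ids) >= 2]
        for i in range(len(pops)):
            for j in range(i + 1, len(pops)):
                fst, med = popstats.hudson_fst(matrix, pop_ids[pops[i]],
                                               pop_ids[pops[j]],
                                               window=config.window)
                fst.to_csv(out / f"fst_{pops[i]}_{pops[j]}.tsv", sep="\t",
                           index=False)
                med_fst[f"{pops[i]}-{pops[j]}"] = med
        ld_plateau = {}
        nmin = min((len(ids) for ids in pop_ids.values() if len(ids) >= 4),
                   default=0)
        sub_n = config.ld_subsample_n or (nmin if nmin >= 4 else None)
        for p, ids in pop_ids.items():
            if sub_n and len(ids) >= sub_n:
                ld = popstats.ld_decay(matrix, ids, config.ld_min_maf,
                                       config.ld_min_geno, config.ld_max_dist,
                                       subsample_n=sub_n,
                                       seed=config.child_seed("ld"))
                ld.binned.to_csv(out / f"ld_{p}.tsv", sep="\t", index=False)
        return med_d, med_fst

    med_d, med_fst = stage("popstats", _popstats)
    report["median_tajimas_d"] = {k: round(v, 4) for k, v in med_d.items()}
    report["median_fst"] = {k: round(v, 4) for k, v in med_fst.items()}

    # --- sweeps ------------------------------------------------------------
    def _sweeps():
        bg = sweeps.background_sfs(matrix)
        clr = sweeps.clr_scan(matrix, bg, grid=config.sweep_grid)
        clr.to_csv(out / "clr_scan.tsv", sep="\t", index=False)
        sel = sweeps.top_quantile_windows(clr, q=config.sweep_quantile,
                                          window=config.sweep_grid)
        sel.to_csv(out / "selected_windows.tsv", sep="\t", index=False)
        res = {"n_selected": len(sel)}
        if config.te_bed:
            te = io_core.read_bed(config.te_bed)
            n_ov, n_tot, pct = sweeps.te_overlap_fraction(sel, te)
            res["te_overlap"] = {"n_overlap": n_ov, "n_total": n_tot,
                                 "percent": pct}
        else:
            log.warning("sweeps: no TE BED given; skipping TE enrichment")
        if config.genes_gff:
            genes = io_core.read_gff(config.genes_gff)
            n_e, n_g, pct = sweeps.effector_fraction(sel, genes)
            res["effectors"] = {"n_effector": n_e, "n_genes": n_g,
                                "percent": pct}
        else:
            log.warning("sweeps: no gene GFF3 given; skipping effector summary")
        return res

    report["sweeps"] = stage("sweeps", _sweeps)

    # --- recomb ------------------------------------------------------------
    def _recomb():
        res = {}
        for rid in released_ids:
            rmat = meta.loc[rid, "mat"]
            opp = "MAT1-1" if rmat == "MAT1-2" else "MAT1-2"
            clone_mates = set(assignment.members(assignment.labels[rid]))
            same = [i for i in matrix.isolate_ids
                    if meta.loc[i, "mat"] == rmat and i not in clone_mates
                    and i != rid]
            opps = [i for i in matrix.isolate_ids if meta.loc[i, "mat"] == opp]
            bg = recomb.background_blocks(matrix, rid, same,
                                          config.recomb_min_snps)
            counts = {}
            all_blocks = []
            for iso in opps:
                cand = recomb.candidate_blocks(
                    matrix, rid, iso, bg, config.recomb_min_snps,
                    config.recomb_overlap_policy)
                counts[iso] = len(cand)
                if len(cand):
                    cand = cand.assign(partner=iso, released=rid)
                    all_blocks.append(cand)
            if all_blocks:
                pd.concat(all_blocks, ignore_index=True).to_csv(
                    out / f"blocks_{rid}.tsv", sep="\t", index=False)
            pd.Series(counts, name="n_blocks").rename_axis("isolate")\
                .reset_index().to_csv(out / f"block_counts_{rid}.tsv",
                                      sep="\t", index=False)
            res[rid] = counts
        if len(released_ids) == 2:
            a, b = released_ids
            ca, cb = list(res[a].values()), list(res[b].values())
            if len(ca) >= 2 and len(cb) >= 2:
                t = recomb.compare_block_counts(ca, cb)
                res["test"] = {"statistic": round(t.statistic, 4),
                               "pvalue": t.pvalue, "direction": t.direction}
        return res

    report["recomb"] = stage("recomb", _recomb)

    # --- ancestry ----------------------------------------------------------
    def _ancestry():
        fits, stacked = anc.ancestry_panel(
            matrix, K_range=config.ancestry_k,
            seeds=[config.child_seed("ancestry") + s
                   for s in range(config.ancestry_seeds)],
            max_iter=config.ancestry_max_iter, meta=meta)
        stacked.to_csv(out / "ancestry_q.tsv", sep="\t", index=False)
        return {K: {"loglik": round(f.loglik, 2), "iterations": f.n_iter,
                    "converged": f.converged} for K, f in fits.items()}

    report["ancestry"] = stage("ancestry", _ancestry)

    # --- report ------------------------------------------------------------
    lines = ["clonepop pipeline report", "========================", ""]

    def emit(d, indent=0):
        for k, v in d.items():
            if isinstance(v, dict):
                lines.append("  " * indent + f"{k}:")
                emit(v, indent + 1)
            else:
                lines.append("  " * indent + f"{k}: {v}")

    emit(report)
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report
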