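"""Synthetic cohorts with the structure the downstream analyses assume.

The flagship generator, :func:`simulate_cohort`, emulates a two-decade field
survey of a clonal haploid entomopathogen at a biocontrol release site:

* ~12 chromosomes carrying dense biallelic SNPs;
* three temporal sub-populations (1997 / 2007 / 2017) built from founder
  lineages, with a configurable fraction of lineages replaced each decade and
  one lineage persisting through all epochs;
* each lineage a star genealogy — a founder haplotype plus small independent
  per-descendant divergence, so clone-mates sit above any near-1 identity
  threshold in expectation;
* two founder lineages split into deeper ancestral groups (the G1/G2 analogue)
  via group-level shared mutations, giving PCA/ancestry/F_ST structure;
* two released MAT1-2 strains that are founder representatives of their
  lineages, with clonal descendants among the field isolates;
* recombinant blocks copied verbatim from a released strain into opposite-MAT
  recipients (plus an optional decoy copy into a same-MAT background isolate,
  which the conserved-block exclusion must remove);
* a planted selective sweep, and TE compartments containing effector-enriched
  genes.

Everything is emitted as standard files (VCF, TSV, BED, GFF3, FASTA) plus
truth tables, so every downstream stage is testable without any downloads.

Neutral-equilibrium and split-population cohorts (used for calibration-style
checks: Tajima's D near 0, panmictic F_ST near 0, LD decay under
recombination) cannot come from the star-genealogy model; they are provided by
:func:`simulate_neutral` / :func:`simulate_split`, which wrap msprime's haploid
coalescent, and :func:`simulate_admixture` draws genotypes directly from an
admixture likelihood with known Q.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (GenotypeMatrix, MISSING, write_bed, write_gff, write_meta,
                      write_vcf)
from .clonal import MAT1_PROBES, MAT2_PROBES, revcomp

EPOCHS = (1997, 2007, 2017)
_NUC = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic biocontrol-site cohort.

    Defaults describe the emulated study system: a ~35-Mb genome on 12
    chromosomes, 152 field isolates over three decadal epochs, 24 founder
    lineages with ~70% decadal turnover, ~1e6 segregating SNPs, two released
    MAT1-2 strains, planted recombinant blocks and one planted sweep.
    """

    n_chromosomes: int = 12
    chrom_length: int = 2_900_000
    n_isolates_per_epoch: dict = field(
        default_factory=lambda: {1997: 50, 2007: 51, 2017: 51})
    n_founder_lineages: int = 24
    mutation_rate: float = 1.2e-3       # per bp per founder branch
    group_mutation_rate: float = 1.2e-3  # per bp per ancestral-group branch
    n_ancestral_groups: int = 2
    clone_divergence: float = 2e-4      # expected pairwise diff fraction in a clone
    replacement_fraction: float = 0.7   # lineages replaced per decadal epoch
    persistent_lineage: bool = True     # keep one lineage in every epoch pool
    released_strains: list = field(
        default_factory=lambda: [("Bb13", "MAT1-2"), ("Bb17", "MAT1-2")])
    planted_blocks: list | None = None  # None -> auto-plant; [] -> none
    sweep: tuple | None = ("chr01", None, 2e-5)  # (chrom, pos|None=TE centre, alpha)
    te_fraction: float = 0.2
    effector_fraction_in_te: float = 0.08
    effector_fraction_outside: float = 0.02
    missing_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for name in ("clone_divergence", "replacement_fraction", "te_fraction",
                     "effector_fraction_in_te", "effector_fraction_outside",
                     "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("chromosome counts/lengths must be positive")
        if self.n_founder_lineages < 2:
            raise ValueError("need at least 2 founder lineages")
        if self.mutation_rate < 0 or self.group_mutation_rate < 0:
            raise ValueError("mutation rates must be non-negative")


@dataclass
class SimOutput:
    """File paths plus in-memory truth for a simulated cohort."""

    vcf: Path
    meta_tsv: Path
    te_bed: Path
    genes_gff: Path
    mat_fasta: Path
    truth_clones: Path
    truth_blocks: Path
    truth_sweep: Path
    truth_ancestry: Path
    matrix: GenotypeMatrix
    meta: pd.DataFrame
    clone_truth: pd.Series          # isolate -> founder lineage id
    blocks: pd.DataFrame            # planted blocks with roles
    sweep: tuple | None             # (chrom, position, alpha)
    q_truth: pd.DataFrame           # isolate x ancestral-group proportions
    te_intervals: pd.DataFrame
    genes: pd.DataFrame
    mat_locus: tuple                # (chrom, start, end), 1-based closed


def expected_segregating_sites(config: SimConfig) -> float:
    """Analytic expectation of the number of emitted SNP sites.

    Mutations follow the infinite-sites model: per chromosome the founder
    branches contribute Poisson(n_lineages * mu * L) sites, the ancestral
    group branches Poisson(n_groups * group_mu * L), and each field isolate
    adds private sites at rate clone_divergence/2 per base site; totals add
    over chromosomes.
    """
    lam_base = config.chrom_length * (
        config.n_founder_lineages * config.mutation_rate
        + config.n_ancestral_groups * config.group_mutation_rate)
    n_field = sum(config.n_isolates_per_epoch.values())
    lam_c = lam_base * (1.0 + n_field * config.clone_divergence / 2.0)
    return config.n_chromosomes * lam_c


# ---------------------------------------------------------------------------
# sweep planting
# ---------------------------------------------------------------------------

def plant_sweep(matrix: GenotypeMatrix, chrom: str, position: int,
                alpha: float, seed: int = 0) -> GenotypeMatrix:
    """Overlay a hard selective sweep centred at ``position`` on ``chrom``.

    Each site at distance d escapes the sweep with probability
    1 - exp(-alpha * d); a non-escaping site is fixed for its current major
    allele in every isolate. At d = 0 the escape probability is 0, so the
    focal site is always fixed. Far sites are left untouched (escape
    probability -> 1).
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    cmask = matrix.site_mask_for_chrom(chrom)
    if not cmask.any():
        raise ValueError(f"unknown chromosome: {chrom!r}")
    pos = matrix.sites.loc[cmask, "pos"].to_numpy()
    if not (1 <= position <= pos.max() + 1):
        raise ValueError(f"sweep position {position} outside {chrom}")
    rng = np.random.default_rng(seed)
    d = np.abs(pos - position).astype(float)
    p_escape = 1.0 - np.exp(-alpha * d)
    fixed = rng.random(d.size) >= p_escape
    calls = matrix.calls.copy()
    cidx = np.flatnonzero(cmask)
    for j in cidx[fixed]:
        col = calls[:, j]
        valid = col != MISSING
        n_alt = int((col[valid] == 1).sum())
        major = 1 if n_alt * 2 >= int(valid.sum()) else 0
        col[valid] = major
    return GenotypeMatrix(calls, matrix.sites.copy(), list(matrix.isolate_ids))


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

def _epoch_pools(config: SimConfig) -> dict[int, list[int]]:
    """Founder-lineage pool per epoch, replacing ``replacement_fraction`` of
    the pool each decade (sliding window over the founder list)."""
    F = config.n_founder_lineages
    r = config.replacement_fraction
    m = max(2, int(F / (1.0 + 2.0 * r)))
    k = int(round(m * r))
    pools = {}
    for e, epoch in enumerate(EPOCHS):
        lo = min(e * k, F - m)
        pool = list(range(lo, lo + m))
        if config.persistent_lineage and 0 not in pool:
            pool = [0] + pool
        pools[epoch] = pool
    return pools


def _auto_blocks(meta: pd.DataFrame, clone_truth: pd.Series,
                 released: list[tuple[str, str]], chrom_names: list[str],
                 sites_per_chrom: dict[str, int],
                 rng: np.random.Generator) -> list[dict]:
    """Default planted blocks: candidates from each released strain into
    opposite-MAT isolates, plus one decoy also copied into a same-MAT
    background isolate (expected to be excluded downstream)."""
    blocks: list[dict] = []
    # avoid chrom 1 (sweep chromosome by default); one candidate per chromosome
    usable = [c for c in chrom_names[1:]] or chrom_names
    lengths = [1800, 2200, 1700]
    used_recipients: set[str] = set()
    ci = 0
    for rid, rmat in released:
        rlin = clone_truth[rid]
        opp = "MAT1-1" if rmat == "MAT1-2" else "MAT1-2"
        recips = [i for i in meta.index
                  if meta.loc[i, "mat"] == opp and clone_truth[i] != rlin
                  and i not in used_recipients]
        same = [i for i in meta.index
                if meta.loc[i, "mat"] == rmat and clone_truth[i] != rlin
                and not meta.loc[i, "released"] and i not in used_recipients]
        n_cand = 2 if rid == released[0][0] else 1
        for b in range(min(n_cand, len(recips))):
            chrom = usable[ci % len(usable)]
            ln = lengths[ci % len(lengths)]
            ci += 1
            ns = sites_per_chrom[chrom]
            if ln + 2 > ns:
                continue
            start = int(rng.integers(1, max(2, ns - ln - 1)))
            blocks.append(dict(donor=rid, recipient=recips[b], chrom=chrom,
                               start_idx=start, length=ln, role="candidate"))
            used_recipients.add(recips[b])
        # decoy: same range also copied into a same-MAT background isolate
        if same and blocks and blocks[-1]["donor"] == rid and rid == released[0][0]:
            d = blocks[-1]
            blocks.append(dict(donor=rid, recipient=same[0], chrom=d["chrom"],
                               start_idx=d["start_idx"], length=d["length"],
                               role="background_copy"))
            used_recipients.add(same[0])
            blocks[-2]["role"] = "candidate_excluded"
    return blocks


def _mat_marker_sequence(mat: str, rng: np.random.Generator) -> str:
    """A short locus sequence carrying the primer sites of the given idiomorph
    (forward primer verbatim, reverse primer as its reverse complement)."""
    def background(n: int) -> str:
        return "".join(rng.choice(_NUC, size=n))

    parts = [background(40)]
    if mat in ("MAT1-1", "both"):
        f, r = MAT1_PROBES
        parts += [f, background(120), revcomp(r), background(30)]
    if mat in ("MAT1-2", "both"):
        f, r = MAT2_PROBES
        parts += [f, background(120), revcomp(r), background(30)]
    parts.append(background(40))
    return "".join(parts)


def simulate_cohort(config: SimConfig, out_dir: str | Path) -> SimOutput:
    """Generate a full synthetic cohort and write all standard files.

    Identical config + seed gives byte-identical outputs. Raises if a planted
    block does not fit on its chromosome or violates the opposite-MAT rule.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    F = config.n_founder_lineages
    G = config.n_ancestral_groups
    L = config.chrom_length
    chrom_names = [f"chr{c + 1:02d}" for c in range(config.n_chromosomes)]
    group_of_lineage = np.arange(F) % G

    # --- isolates, lineages, metadata -----------------------------------
    pools = _epoch_pools(config)
    isolate_ids: list[str] = []
    lineage_of: list[int] = []
    years: list[int] = []
    released_flags: list[bool] = []

    released = list(config.released_strains)
    # balanced idiomorphs, decorrelated from the (interleaved) ancestral groups
    lineage_mat = np.array(["MAT1-1" if l % 4 in (0, 3) else "MAT1-2"
                            for l in range(F)], dtype=object)
    released_lineage: dict[str, int] = {}
    pool0 = [l for l in pools[EPOCHS[0]] if l != 0]
    for j, (rid, rmat) in enumerate(released):
        # pick lineages of alternating ancestral groups from the first pool
        cands = [l for l in pool0 if group_of_lineage[l] == (j % G)
                 and l not in released_lineage.values()]
        lin = cands[0] if cands else pool0[j % len(pool0)]
        released_lineage[rid] = lin
        lineage_mat[lin] = rmat
        isolate_ids.append(rid)
        lineage_of.append(lin)
        years.append(EPOCHS[0])
        released_flags.append(True)

    for epoch in EPOCHS:
        n = config.n_isolates_per_epoch.get(epoch, 0)
        pool = pools[epoch]
        assigned = rng.choice(pool, size=n)
        for i, lin in enumerate(assigned):
            isolate_ids.append(f"A{epoch}-{i + 1:03d}")
            lineage_of.append(int(lin))
            years.append(epoch)
            released_flags.append(False)
    # guarantee each released lineage has at least one field descendant
    for rid, lin in released_lineage.items():
        field_rows = [i for i in range(len(isolate_ids))
                      if not released_flags[i]]
        if not any(lineage_of[i] == lin for i in field_rows):
            tgt = [i for i in field_rows if years[i] == EPOCHS[0]][0]
            lineage_of[tgt] = lin

    lineage_of = np.asarray(lineage_of)
    n_iso = len(isolate_ids)
    host_orders = np.array(["LEP", "COL", "HEM", "HYM", "DIP", "ORT"])
    hosts = rng.choice(host_orders, size=n_iso,
                       p=[0.40, 0.20, 0.15, 0.10, 0.10, 0.05])
    meta = pd.DataFrame({
        "isolate": isolate_ids,
        "pop": [str(y) for y in years],
        "year": years,
        "mat": [lineage_mat[l] for l in lineage_of],
        "host": hosts,
        "released": released_flags,
    }).set_index("isolate")

    # --- sites and haplotypes (infinite-sites nested star genealogies) ---
    # Every mutation hits a fresh position on the group -> founder -> isolate
    # genealogy, so the site matrix is a perfect phylogeny: clonal cohorts
    # carry no four-gamete signal unless blocks/sweeps are planted.
    all_sites = []
    call_blocks = []
    sites_per_chrom: dict[str, int] = {}
    released_arr = np.asarray(released_flags)
    for chrom in chrom_names:
        n_group_mut = rng.poisson(G * config.group_mutation_rate * L)
        n_founder_mut = rng.poisson(F * config.mutation_rate * L)
        n_base = n_group_mut + n_founder_mut
        # per-isolate private mutations: expected pairwise clone difference
        # is clone_divergence * (#shared sites), so each descendant gets
        # Poisson(clone_divergence/2 * n_base) fresh sites
        priv_lambda = config.clone_divergence / 2.0 * n_base
        k_priv = rng.poisson(priv_lambda, size=n_iso)
        k_priv[released_arr] = 0            # released strains ARE founders
        total = int(n_base + k_priv.sum())
        if total > L:
            raise ValueError("mutation rates too high for chromosome length")
        positions = rng.choice(L, size=total, replace=False) + 1
        kind = np.zeros(n_base, dtype=np.int8)          # 0 = founder, 1 = group
        kind[rng.permutation(n_base)[:n_group_mut]] = 1
        founders_hit = rng.integers(0, F, size=n_base)
        groups_hit = rng.integers(0, G, size=n_base)

        H = np.zeros((F, n_base), dtype=np.int8)
        fm = kind == 0
        H[founders_hit[fm], np.flatnonzero(fm)] = 1
        gm = np.flatnonzero(kind == 1)
        for j in gm:
            H[group_of_lineage == groups_hit[j], j] = 1
        if G == 1 and gm.size:
            keep = H.sum(axis=0) != F      # drop sites fixed in all founders
            drop = n_base - int(keep.sum())
            H = H[:, keep]
            positions = np.delete(positions, np.flatnonzero(~keep))
            n_base -= drop
            total -= drop

        calls = np.zeros((n_iso, total), dtype=np.int8)
        calls[:, :n_base] = H[lineage_of]
        col = n_base
        for i in range(n_iso):              # private singleton sites
            calls[i, col:col + k_priv[i]] = 1
            col += k_priv[i]
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        calls = calls[:, order]

        ref = rng.choice(_NUC, size=total)
        alt_shift = rng.integers(1, 4, size=total)
        nuc_idx = np.searchsorted(_NUC, ref)
        alt = _NUC[(nuc_idx + alt_shift) % 4]
        all_sites.append(pd.DataFrame({"chrom": chrom, "pos": positions,
                                       "ref": ref, "alt": alt}))
        call_blocks.append(calls)
        sites_per_chrom[chrom] = total

    sites = pd.concat(all_sites, ignore_index=True)
    calls = np.concatenate(call_blocks, axis=1)
    chrom_offset = {}
    off = 0
    for chrom in chrom_names:
        chrom_offset[chrom] = off
        off += sites_per_chrom[chrom]

    # --- planted recombinant blocks --------------------------------------
    blocks_spec = config.planted_blocks
    if blocks_spec is None:
        blocks_spec = _auto_blocks(meta, pd.Series(lineage_of, index=isolate_ids),
                                   released, chrom_names, sites_per_chrom, rng)
    iso_index = {iid: i for i, iid in enumerate(isolate_ids)}
    protected = np.zeros_like(calls, dtype=bool)
    block_rows = []
    for b in blocks_spec:
        donor, recip = b["donor"], b["recipient"]
        chrom, start, ln = b["chrom"], int(b["start_idx"]), int(b["length"])
        role = b.get("role", "candidate")
        ns = sites_per_chrom[chrom]
        if start < 0 or start + ln > ns:
            raise ValueError(
                f"planted block {donor}->{recip} exceeds {chrom} SNP count "
                f"({start}+{ln} > {ns})")
        dmat, rmat_ = meta.loc[donor, "mat"], meta.loc[recip, "mat"]
        if role != "background_copy" and {dmat, rmat_} != {"MAT1-1", "MAT1-2"}:
            raise ValueError(
                f"planted block recipient {recip} must have MAT opposite to "
                f"donor {donor} ({dmat} vs {rmat_})")
        o = chrom_offset[chrom]
        di, ri = iso_index[donor], iso_index[recip]
        calls[ri, o + start:o + start + ln] = calls[di, o + start:o + start + ln]
        # force mismatches at the flanks so block boundaries are exact
        for edge in (start - 1, start + ln):
            if 0 <= edge < ns:
                calls[ri, o + edge] = 1 - calls[di, o + edge]
                protected[ri, o + edge] = protected[di, o + edge] = True
        protected[ri, o + start:o + start + ln] = True
        protected[di, o + start:o + start + ln] = True
        bp_start = int(sites["pos"].iloc[o + start])
        bp_end = int(sites["pos"].iloc[o + start + ln - 1])
        block_rows.append(dict(donor=donor, recipient=recip, chrom=chrom,
                               start_idx=start, end_idx=start + ln - 1,
                               n_snps=ln, start_bp=bp_start, end_bp=bp_end,
                               role=role))
    blocks_df = pd.DataFrame(block_rows, columns=[
        "donor", "recipient", "chrom", "start_idx", "end_idx", "n_snps",
        "start_bp", "end_bp", "role"])

    # --- TE compartments and genes ---------------------------------------
    te_rows, gene_rows = [], []
    n_comp = 3
    for chrom in chrom_names:
        comp_len = int(config.te_fraction * L / n_comp)
        for c in range(n_comp):
            third = L // n_comp
            lo = c * third + 1
            start = int(rng.integers(lo, max(lo + 1, lo + third - comp_len)))
            te_rows.append(dict(chrom=chrom, start=start,
                                end=min(start + comp_len - 1, L)))
        g = 0
        start = 500
        while start + 1500 <= L:
            mid = start + 750
            in_te = any(r["chrom"] == chrom and r["start"] <= mid <= r["end"]
                        for r in te_rows[-n_comp:])
            p_eff = (config.effector_fraction_in_te if in_te
                     else config.effector_fraction_outside)
            gene_rows.append(dict(chrom=chrom, start=start, end=start + 1499,
                                  strand="+", gene_id=f"{chrom}g{g + 1:04d}",
                                  effector=int(rng.random() < p_eff)))
            start += 3000
            g += 1
    te_df = pd.DataFrame(te_rows)
    genes_df = pd.DataFrame(gene_rows)

    matrix = GenotypeMatrix(calls, sites, isolate_ids)

    # --- planted sweep ----------------------------------------------------
    sweep_truth = None
    if config.sweep is not None:
        s_chrom, s_pos, s_alpha = config.sweep
        if s_pos is None:
            te0 = te_df[te_df["chrom"] == s_chrom].iloc[0]
            s_pos = int((te0["start"] + te0["end"]) // 2)
        sweep_seed = int(rng.integers(0, 2**31 - 1))
        matrix = plant_sweep(matrix, s_chrom, int(s_pos), float(s_alpha),
                             seed=sweep_seed)
        sweep_truth = (s_chrom, int(s_pos), float(s_alpha))

    # --- missing data (never inside planted blocks) ----------------------
    if config.missing_rate > 0:
        miss = rng.random(matrix.calls.shape) < config.missing_rate
        miss &= ~protected
        matrix.calls[miss] = MISSING

    # --- truth tables -----------------------------------------------------
    clone_truth = pd.Series(lineage_of, index=isolate_ids, name="lineage")
    q_truth = pd.DataFrame(
        np.eye(G)[group_of_lineage[lineage_of]],
        index=isolate_ids, columns=[f"q{g + 1}" for g in range(G)])

    # --- write files -------------------------------------------------------
    paths = SimOutput(
        vcf=out / "cohort.vcf", meta_tsv=out / "meta.tsv",
        te_bed=out / "te.bed", genes_gff=out / "genes.gff3",
        mat_fasta=out / "mat_markers.fasta",
        truth_clones=out / "truth_clones.tsv",
        truth_blocks=out / "truth_blocks.tsv",
        truth_sweep=out / "truth_sweep.tsv",
        truth_ancestry=out / "truth_ancestry.tsv",
        matrix=matrix, meta=meta, clone_truth=clone_truth, blocks=blocks_df,
        sweep=sweep_truth, q_truth=q_truth, te_intervals=te_df, genes=genes_df,
        mat_locus=(chrom_names[-1], L // 2 + 1, L // 2 + 20_000),
    )
    write_vcf(matrix, paths.vcf, contig_lengths={c: L for c in chrom_names})
    write_meta(meta, paths.meta_tsv)
    write_bed(te_df, paths.te_bed)
    write_gff(genes_df, paths.genes_gff)
    with open(paths.mat_fasta, "w") as fh:
        for iid in isolate_ids:
            seq = _mat_marker_sequence(meta.loc[iid, "mat"], rng)
            fh.write(f">{iid}\n{seq}\n")
    clone_truth.rename_axis("isolate").reset_index().to_csv(
        paths.truth_clones, sep="\t", index=False)
    blocks_df.to_csv(paths.truth_blocks, sep="\t", index=False)
    with open(paths.truth_sweep, "w") as fh:
        fh.write("chrom\tposition\talpha\n")
        if sweep_truth is not None:
            fh.write(f"{sweep_truth[0]}\t{sweep_truth[1]}\t{sweep_truth[2]}\n")
    q_truth.rename_axis("isolate").reset_index().to_csv(
        paths.truth_ancestry, sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# coalescent / analytic companions
# ---------------------------------------------------------------------------

def _matrix_from_ts(ts_list, chrom_names: list[str]) -> GenotypeMatrix:
    frames, blocks = [], []
    n = None
    for ts, chrom in zip(ts_list, chrom_names):
        pos, cols = [], []
        seen = set()
        for var in ts.variants():
            g = var.genotypes
            if g.max() > 1:
                continue  # keep biallelic only
            p = int(var.site.position) + 1
            if p in seen:
                continue
            seen.add(p)
            pos.append(p)
            cols.append(g.astype(np.int8))
        n = ts.num_samples
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                    "ref": "A", "alt": "T"}))
        blocks.append(np.stack(cols, axis=1) if cols
                      else np.zeros((n, 0), dtype=np.int8))
    sites = pd.concat(frames, ignore_index=True)
    calls = np.concatenate(blocks, axis=1)
    ids = [f"s{i + 1:03d}" for i in range(calls.shape[0])]
    return GenotypeMatrix(calls, sites, ids)


def simulate_neutral(n_isolates: int, sequence_length: float = 1e5,
                     population_size: float = 1e4, mutation_rate: float = 1e-7,
                     recombination_rate: float = 0.0, n_chromosomes: int = 1,
                     seed: int = 1) -> GenotypeMatrix:
    """Haploid neutral-equilibrium cohort from the standard coalescent."""
    import msprime

    ts_list = []
    chroms = [f"chr{c + 1:02d}" for c in range(n_chromosomes)]
    for c in range(n_chromosomes):
        ts = msprime.sim_ancestry(
            samples=n_isolates, ploidy=1, sequence_length=sequence_length,
            recombination_rate=recombination_rate,
            population_size=population_size, random_seed=seed + 7919 * c + 1)
        mts = msprime.sim_mutations(ts, rate=mutation_rate,
                                    random_seed=seed + 7919 * c + 2,
                                    model=msprime.BinaryMutationModel())
        ts_list.append(mts)
    return _matrix_from_ts(ts_list, chroms)


def simulate_split(n_per_pop: int, split_time: float,
                   sequence_length: float = 1e5, population_size: float = 1e4,
                   mutation_rate: float = 1e-7, recombination_rate: float = 0.0,
                   seed: int = 1
                   ) -> tuple[GenotypeMatrix, list[str], list[str]]:
    """Two haploid populations that split ``split_time`` generations ago.

    split_time = 0 gives a single panmictic pool split arbitrarily in two.
    Returns (matrix, ids_pop_A, ids_pop_B).
    """
    import msprime

    if split_time <= 0:
        mat = simulate_neutral(2 * n_per_pop, sequence_length, population_size,
                               mutation_rate, recombination_rate, seed=seed)
    else:
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=population_size)
        dem.add_population(name="B", initial_size=population_size)
        dem.add_population(name="anc", initial_size=population_size)
        dem.add_population_split(time=split_time, derived=["A", "B"],
                                 ancestral="anc")
        ts = msprime.sim_ancestry(
            samples={"A": n_per_pop, "B": n_per_pop}, ploidy=1,
            sequence_length=sequence_length, demography=dem,
            recombination_rate=recombination_rate, random_seed=seed + 1)
        mts = msprime.sim_mutations(ts, rate=mutation_rate,
                                    random_seed=seed + 2,
                                    model=msprime.BinaryMutationModel())
        mat = _matrix_from_ts([mts], ["chr01"])
    ids = mat.isolate_ids
    return mat, ids[:n_per_pop], ids[n_per_pop:]


def simulate_admixture(n_per_pop: int = 20, n_admixed: int = 5,
                       n_sites: int = 2000, divergence: float = 0.3,
                       admixed_q: float = 0.5, seed: int = 1
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Two ancestral gene pools with known per-isolate ancestry proportions.

    Ancestral allele frequencies differ by ``divergence`` at every site;
    pure isolates have one-hot Q, admixed isolates q = (admixed_q,
    1 - admixed_q). Genotypes are direct Bernoulli draws from the admixture
    likelihood, so estimated Q can be compared with the truth.
    """
    rng = np.random.default_rng(seed)
    f1 = rng.uniform(0.05, 0.95, size=n_sites)
    sign = rng.choice([-1.0, 1.0], size=n_sites)
    f2 = np.clip(f1 + sign * divergence, 0.02, 0.98)
    F = np.stack([f1, f2])                      # K x sites
    qs = ([(1.0, 0.0)] * n_per_pop + [(0.0, 1.0)] * n_per_pop
          + [(admixed_q, 1.0 - admixed_q)] * n_admixed)
    Q = np.asarray(qs)
    p = Q @ F                                    # isolates x sites
    calls = (rng.random(p.shape) < p).astype(np.int8)
    ids = ([f"P1-{i + 1:02d}" for i in range(n_per_pop)]
           + [f"P2-{i + 1:02d}" for i in range(n_per_pop)]
           + [f"AD-{i + 1:02d}" for i in range(n_admixed)])
    sites = pd.DataFrame({"chrom": "chr01",
                          "pos": np.arange(1, n_sites + 1) * 100,
                          "ref": "A", "alt": "T"})
    q_truth = pd.DataFrame(Q, index=ids, columns=["q1", "q2"])
    return GenotypeMatrix(calls, sites, ids), q_truth
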