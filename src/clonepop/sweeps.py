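"""Composite-likelihood-ratio (CLR) selective-sweep scan with TE/effector
enrichment summaries.

The scan contrasts, at every grid point (default 1 kb), the likelihood of the
observed derived-allele counts under a local hard-sweep model against the
genome-wide background site-frequency spectrum, in the spirit of the
SweepFinder family of tests. The sweep model is a star-genealogy
approximation: at distance d from the swept site each sampled lineage escapes
the sweep with probability p_e = 1 - exp(-alpha * d); escaped lineages
retain their pre-sweep (background) alleles — modelled as a uniformly chosen
subset of a background configuration with the site's pre-sweep derived count
— while all non-escaped lineages inherit the single sweeping haplotype's
allele. CLR(x) = 2 * [max_alpha sum_sites log P_sweep - sum_sites log P_bg],
clamped at 0; as p_e -> 1 everywhere the sweep model collapses onto the
background and the CLR is exactly 0.

Monomorphic sites present in the matrix contribute: local fixation is the
strongest footprint of a recent sweep, so the likelihood is defined over
derived counts 0..n with the invariant-class mass estimated from the data.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from .io_core import MISSING, GenotypeMatrix
from .popstats import polarize

log = logging.getLogger("clonepop")

_EPS = 1e-6
_PE_CUTOFF = 0.999  # beyond this escape probability a site is background-like


# ---------------------------------------------------------------------------
# background SFS
# ---------------------------------------------------------------------------

@dataclass
class SfsBackground:
    """Genome-wide empirical spectrum of derived-allele counts.

    ``probs[j-1]`` is the probability of derived count j in 1..n-1 over
    polymorphic sites. ``p_invariant = (p0, pn)`` is the fraction of matrix
    sites monomorphic ancestral/derived (kept separately so the scan can
    model fixation). If ``folded``, probs is symmetrised over j and n-j.
    """

    probs: np.ndarray
    n: int
    folded: bool
    p_invariant: tuple[float, float]

    def full_spectrum(self) -> np.ndarray:
        """Probability vector over derived counts 0..n (eps-floored)."""
        p0, pn = self.p_invariant
        mid = self.probs * max(1.0 - p0 - pn, 0.0)
        full = np.concatenate([[p0], mid, [pn]])
        full = np.maximum(full, _EPS)
        return full / full.sum()


def _derived_counts(matrix: GenotypeMatrix, pop: list[str] | None,
                    polarization: str) -> tuple[np.ndarray, int]:
    """Per-site derived counts rescaled to the full sample size n.

    Counts at sites with missing calls are rescaled from the non-missing
    calls (round(p_derived * n)) so all sites live on one 0..n scale.
    Unpolarizable sites are dropped.
    """
    derived, polarizable = polarize(matrix, polarization)
    calls = (matrix.calls if pop is None
             else matrix.calls[[matrix.index_of(i) for i in pop]])
    n = calls.shape[0]
    valid = calls != MISSING
    m = valid.sum(axis=0)
    dc = ((calls == derived[None, :]) & valid).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(m == n, dc,
                     np.round(dc / np.maximum(m, 1) * n)).astype(np.int64)
    j = np.where(m > 0, j, -1)
    j = np.where(polarizable, j, -1)
    return j, n


def background_sfs(matrix: GenotypeMatrix, pop: list[str] | None = None,
                   polarization: str = "reference",
                   folded: bool = False) -> SfsBackground:
    """Empirical distribution of derived counts over all polymorphic sites."""
    j, n = _derived_counts(matrix, pop, polarization)
    j = j[j >= 0]
    if j.size == 0:
        raise ValueError("no polarizable site")
    poly = j[(j > 0) & (j < n)]
    if poly.size == 0:
        raise ValueError("no polymorphic site for the background spectrum")
    counts = np.bincount(poly, minlength=n + 1)[1:n].astype(float)
    if folded:
        counts = counts + counts[::-1]
    probs = counts / counts.sum()
    p0 = float((j == 0).sum() / j.size)
    pn = float((j == n).sum() / j.size)
    return SfsBackground(probs, n, folded, (p0, pn))


# ---------------------------------------------------------------------------
# CLR scan
# ---------------------------------------------------------------------------

def _sweep_emission(n: int, pe_levels: np.ndarray, bg_full: np.ndarray
                    ) -> np.ndarray:
    """log P_sweep(observed count j | escape prob level), marginalised over
    the background configuration; shape (n_levels, n+1).

    Given pre-sweep derived count j0 ~ background: K ~ Binom(n, p_e) lineages
    escape as a uniform subset (derived among them M ~ Hypergeom(n, j0, K));
    the remaining n-K lineages carry the sweeping haplotype's allele, derived
    with probability j0/n. Observed count = M + (n-K) * Bernoulli(j0/n).
    """
    ks = np.arange(n + 1)
    out = np.zeros((pe_levels.size, n + 1))
    for li, pe in enumerate(pe_levels):
        wk = binom.pmf(ks, n, pe)
        acc = np.zeros(n + 1)
        for j0 in range(n + 1):
            pj0 = bg_full[j0]
            if pj0 <= 0:
                continue
            a = j0 / n
            dist = np.zeros(n + 1)
            for k in range(n + 1):
                if wk[k] < 1e-12:
                    continue
                ms = np.arange(max(0, k - (n - j0)), min(k, j0) + 1)
                pm = hypergeom.pmf(ms, n, j0, k)
                # sweeping haplotype ancestral: observed = m
                np.add.at(dist, ms, wk[k] * pm * (1.0 - a))
                # sweeping haplotype derived: observed = m + (n-k)
                np.add.at(dist, ms + (n - k), wk[k] * pm * a)
            acc += pj0 * dist
        out[li] = np.log(np.maximum(acc, 1e-300))
    return out


def default_alpha_grid(matrix: GenotypeMatrix, n_alphas: int = 16
                       ) -> np.ndarray:
    """Log-spaced sweep strengths spanning escape probabilities ~0.01..0.99
    at the median inter-site distance."""
    pos = matrix.sites["pos"].to_numpy()
    chrom = matrix.sites["chrom"].to_numpy()
    gaps = []
    for c in dict.fromkeys(chrom):
        p = pos[chrom == c]
        if p.size > 1:
            gaps.append(np.diff(p))
    med = float(np.median(np.concatenate(gaps))) if gaps else 1000.0
    a_min = -math.log(0.99) / med
    a_max = -math.log(0.01) / med
    return np.geomspace(a_min, a_max, n_alphas)


def clr_scan(matrix: GenotypeMatrix, background: SfsBackground,
             pop: list[str] | None = None, grid: int = 1000,
             alpha_grid: np.ndarray | None = None,
             polarization: str = "reference",
             n_pe_levels: int = 48) -> pd.DataFrame:
    """CLR at every ``grid`` bp along each chromosome.

    Returns columns chrom, pos, clr, alpha (the maximising sweep strength).
    The scan is deterministic given the matrix and the alpha grid.
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid(matrix)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size == 0:
        raise ValueError("empty alpha grid")
    n = background.n
    bg_full = background.full_spectrum()
    if background.folded:
        # symmetrise so escaped-lineage draws are polarization-agnostic
        bg_full = (bg_full + bg_full[::-1]) / 2.0

    # escape-probability levels: dense near 1 where the model flattens out
    pe_levels = np.concatenate([
        [0.0], 1.0 - np.geomspace(1.0, 1.0 - _PE_CUTOFF, n_pe_levels - 1)])
    pe_levels = np.clip(np.sort(pe_levels), 0.0, 1.0)
    logL = _sweep_emission(n, pe_levels, bg_full)          # levels x (n+1)
    log_bg = np.log(bg_full)

    j_all, _ = _derived_counts(matrix, pop, polarization)
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()

    rows = []
    for chrom in matrix.chroms:
        cmask = (chrom_arr == chrom) & (j_all >= 0)
        pos = pos_arr[cmask]
        j = j_all[cmask]
        if pos.size == 0:
            continue
        lb = log_bg[j]
        grid_pts = np.arange(grid, int(pos.max()) + grid, grid)
        for x in grid_pts:
            best = 0.0
            best_a = alpha_grid[0]
            for a in alpha_grid:
                radius = -math.log(1.0 - _PE_CUTOFF) / a
                lo = np.searchsorted(pos, x - radius)
                hi = np.searchsorted(pos, x + radius, side="right")
                if lo >= hi:
                    continue
                d = np.abs(pos[lo:hi] - x)
                pe = 1.0 - np.exp(-a * d)
                lev = np.searchsorted(pe_levels, pe, side="left")
                lev = np.clip(lev, 0, pe_levels.size - 1)
                ll = logL[lev, j[lo:hi]].sum() - lb[lo:hi].sum()
                if ll > best:
                    best, best_a = ll, a
            rows.append(dict(chrom=chrom, pos=int(x), clr=2.0 * best,
                             alpha=best_a))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quantile calling and enrichment
# ---------------------------------------------------------------------------

def top_quantile_windows(clr_points: pd.DataFrame, q: float = 0.05,
                         window: int = 1000) -> pd.DataFrame:
    """Grid windows whose CLR reaches the empirical (1-q) quantile.

    The base count is ceil(q*N); points tying the threshold value are all
    included. Each selected grid point becomes the 1-window interval it
    represents. Returns chrom, start, end, pos, clr.
    """
    N = len(clr_points)
    if N < 1.0 / q:
        raise ValueError("need at least 1/q CLR points")
    vals = clr_points["clr"].to_numpy()
    k = int(np.ceil(q * N))
    thr = np.sort(vals)[::-1][k - 1]
    sel = clr_points[vals >= thr].copy()
    if len(sel) == N and np.allclose(vals, vals[0]):
        log.warning("top_quantile_windows: all CLR values tied; selecting all")
    sel["start"] = np.maximum(sel["pos"] - window // 2 + 1, 1)
    sel["end"] = sel["pos"] + window // 2
    return sel[["chrom", "start", "end", "pos", "clr"]].reset_index(drop=True)


def te_overlap_fraction(selected: pd.DataFrame, te_intervals: pd.DataFrame
                        ) -> tuple[int, int, int]:
    """(n_overlapping, n_total, percent) of selected windows sharing >= 1 bp
    with a TE interval (1-based closed on both sides); percent rounded to
    the nearest integer."""
    n_total = len(selected)
    n_overlap = 0
    by_chrom = {c: g for c, g in te_intervals.groupby("chrom")}
    for _, w in selected.iterrows():
        g = by_chrom.get(w["chrom"])
        if g is None:
            continue
        if ((g["start"] <= w["end"]) & (g["end"] >= w["start"])).any():
            n_overlap += 1
    pct = int(round(100.0 * n_overlap / n_total)) if n_total else 0
    return n_overlap, n_total, pct


def effector_fraction(selected: pd.DataFrame, genes: pd.DataFrame
                      ) -> tuple[int, int, float]:
    """(n_effector, n_genes, percent) of genes overlapping selected windows;
    percent rounded to 2 decimals. NaN percent (with a warning) if no gene
    overlaps."""
    hit_ids = set()
    by_chrom = {c: g for c, g in selected.groupby("chrom")}
    for _, g in genes.iterrows():
        w = by_chrom.get(g["chrom"])
        if w is None:
            continue
        if ((w["start"] <= g["end"]) & (w["end"] >= g["start"])).any():
            hit_ids.add(g["gene_id"])
    in_regions = genes[genes["gene_id"].isin(hit_ids)]
    n_genes = len(in_regions)
    n_eff = int(in_regions["effector"].sum())
    if n_genes == 0:
        log.warning("effector_fraction: no gene overlaps the selected windows")
        return 0, 0, float("nan")
    return n_eff, n_genes, round(100.0 * n_eff / n_genes, 2)
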