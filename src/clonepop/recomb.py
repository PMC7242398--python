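"""Recombinant-block detection between released strains and field isolates.

A candidate crossover segment is a maximal run of consecutive SNP sites (in
site-table order, per chromosome) at which two haploid isolates carry
identical non-missing calls, at least ``min_snps`` sites long (default 1500,
roughly 5 kb at the emulated SNP density). Because a released strain cannot
outcross with isolates of its own mating type, long blocks it shares with
same-MAT non-clonal isolates are interpreted as ancestrally conserved
sequence rather than crossovers; the union of those blocks is subtracted
from the candidates found against each opposite-MAT isolate. Block counts
per opposite-MAT partner are then compared between released strains with a
two-sample t-test (Welch by default).

By default a missing call in either isolate terminates a run (conservative);
``skip_missing=True`` instead ignores sites where either isolate is missing,
so runs bridge missing data but only identical informative sites count.

A Hudson–Kaplan four-gamete R_min scan is included as a windowed
recombination signal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import MISSING, GenotypeMatrix

log = logging.getLogger("clonepop")


def _runs_from_bool(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive indices."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def identical_runs(matrix: GenotypeMatrix, isolate_a: str, isolate_b: str,
                   min_snps: int = 1500, skip_missing: bool = False
                   ) -> pd.DataFrame:
    """Maximal identical-call runs between two isolates, per chromosome.

    Returns chrom, start_idx, end_idx (per-chromosome SNP indices), start_bp,
    end_bp, n_snps for runs with n_snps >= min_snps. In ``skip_missing`` mode
    missing sites do not break runs and are not counted in n_snps.
    """
    ia = matrix.index_of(isolate_a)
    ib = matrix.index_of(isolate_b)
    a = matrix.calls[ia]
    b = matrix.calls[ib]
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    rows = []
    for chrom in matrix.chroms:
        cidx = np.flatnonzero(chrom_arr == chrom)
        ca, cb = a[cidx], b[cidx]
        pos = pos_arr[cidx]
        both = (ca != MISSING) & (cb != MISSING)
        if skip_missing:
            kept = np.flatnonzero(both)
            eq = ca[kept] == cb[kept]
            for s, e in _runs_from_bool(eq):
                n = e - s + 1
                if n >= min_snps:
                    si, ei = int(kept[s]), int(kept[e])
                    rows.append(dict(chrom=chrom, start_idx=si, end_idx=ei,
                                     start_bp=int(pos[si]), end_bp=int(pos[ei]),
                                     n_snps=n))
        else:
            eq = both & (ca == cb)
            for s, e in _runs_from_bool(eq):
                n = e - s + 1
                if n >= min_snps:
                    rows.append(dict(chrom=chrom, start_idx=int(s),
                                     end_idx=int(e), start_bp=int(pos[s]),
                                     end_bp=int(pos[e]), n_snps=n))
    return pd.DataFrame(rows, columns=["chrom", "start_idx", "end_idx",
                                       "start_bp", "end_bp", "n_snps"])


def merge_intervals(blocks: pd.DataFrame) -> pd.DataFrame:
    """Union of SNP-index intervals per chromosome (overlapping or adjacent
    intervals merge)."""
    rows = []
    for chrom, g in blocks.groupby("chrom", sort=False):
        ivs = sorted(zip(g["start_idx"], g["end_idx"]))
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                rows.append(dict(chrom=chrom, start_idx=cur_s, end_idx=cur_e))
                cur_s, cur_e = s, e
        rows.append(dict(chrom=chrom, start_idx=cur_s, end_idx=cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start_idx", "end_idx"])


def background_blocks(matrix: GenotypeMatrix, released: str,
                      same_mat_isolates: list[str], min_snps: int = 1500,
                      skip_missing: bool = False) -> pd.DataFrame:
    """Merged union of identical runs between the released strain and each
    same-MAT background isolate (ancestrally conserved regions).

    The caller must exclude the released strain's own clonal group from
    ``same_mat_isolates`` — clone mates are identical genome-wide and would
    blanket every candidate.
    """
    if not same_mat_isolates:
        log.warning("background_blocks: empty background set for %s", released)
        return pd.DataFrame(columns=["chrom", "start_idx", "end_idx"])
    parts = [identical_runs(matrix, released, iso, min_snps, skip_missing)
             for iso in same_mat_isolates]
    allb = pd.concat(parts, ignore_index=True)
    if allb.empty:
        return pd.DataFrame(columns=["chrom", "start_idx", "end_idx"])
    return merge_intervals(allb)


def candidate_blocks(matrix: GenotypeMatrix, released: str,
                     opposite_mat_isolate: str, background: pd.DataFrame,
                     min_snps: int = 1500,
                     overlap_policy: str | float = "any",
                     skip_missing: bool = False) -> pd.DataFrame:
    """Identical runs against an opposite-MAT isolate, minus conserved blocks.

    ``overlap_policy``: "any" drops a candidate sharing >= 1 SNP with the
    background; a float f in (0, 1] drops it only when the overlapping
    fraction of the candidate reaches f.
    """
    runs = identical_runs(matrix, released, opposite_mat_isolate, min_snps,
                          skip_missing)
    if runs.empty or background.empty:
        return runs
    keep = []
    bg_by_chrom = {c: g for c, g in background.groupby("chrom", sort=False)}
    for _, r in runs.iterrows():
        g = bg_by_chrom.get(r["chrom"])
        if g is None:
            keep.append(True)
            continue
        ov = (np.minimum(g["end_idx"], r["end_idx"])
              - np.maximum(g["start_idx"], r["start_idx"]) + 1).clip(lower=0)
        total = int(ov.sum())
        if overlap_policy == "any":
            keep.append(total == 0)
        else:
            keep.append(total / r["n_snps"] < float(overlap_policy))
    return runs[np.asarray(keep)].reset_index(drop=True)


@dataclass
class BlockCountResult:
    """Two-group comparison of per-partner retained block counts."""

    statistic: float
    pvalue: float
    direction: str          # "A>B", "B>A" or "equal"
    mean_a: float
    mean_b: float
    test: str


def compare_block_counts(counts_a, counts_b, test: str = "welch"
                         ) -> BlockCountResult:
    """Two-sided two-sample t-test on block counts (Welch default)."""
    a = np.asarray(list(counts_a), dtype=float)
    b = np.asarray(list(counts_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 isolates")
    ma, mb = a.mean(), b.mean()
    direction = "A>B" if ma > mb else ("B>A" if mb > ma else "equal")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if ma == mb:
            return BlockCountResult(0.0, 1.0, "equal", ma, mb, test)
        log.warning("compare_block_counts: both groups zero-variance with "
                    "different means; p reported as 0")
        return BlockCountResult(np.inf if ma > mb else -np.inf, 0.0,
                                direction, ma, mb, test)
    t, p = stats.ttest_ind(a, b, equal_var=(test == "student"))
    return BlockCountResult(float(t), float(p), direction, ma, mb, test)


# ---------------------------------------------------------------------------
# four-gamete R_min
# ---------------------------------------------------------------------------

def _incompatible_pairs(calls: np.ndarray) -> list[tuple[int, int]]:
    """Site pairs (i < j) exhibiting all four gametes over jointly
    non-missing isolates."""
    alt = calls == 1
    ref = calls == 0
    a = alt.astype(np.float32)
    r = ref.astype(np.float32)
    n11 = a.T @ a
    n00 = r.T @ r
    n10 = a.T @ r
    n01 = r.T @ a
    inc = (n11 > 0) & (n00 > 0) & (n10 > 0) & (n01 > 0)
    ii, jj = np.nonzero(np.triu(inc, k=1))
    return list(zip(ii.tolist(), jj.tolist()))


def hudson_kaplan_rmin(pairs: list[tuple[int, int]]) -> int:
    """Minimum number of recombination events explaining the incompatible
    pairs: greedy stabbing of the open intervals (i, j) from the left."""
    if not pairs:
        return 0
    ivs = sorted(pairs, key=lambda p: p[1])
    rmin = 0
    last_gap = -1
    for i, j in ivs:
        if last_gap < i:          # breakpoint gap g stabs (i,j) iff i <= g < j
            rmin += 1
            last_gap = j - 1
    return rmin


def four_gamete_rmin(matrix: GenotypeMatrix, pop: list[str] | None = None,
                     window: int = 5000) -> pd.DataFrame:
    """Hudson–Kaplan R_min per non-overlapping window.

    Returns chrom, start, end, value (R_min), n_sites. Clonal data without
    recombination gives 0 everywhere.
    """
    calls = (matrix.calls if pop is None
             else matrix.calls[[matrix.index_of(i) for i in pop]])
    if calls.shape[0] < 4:
        raise ValueError("four-gamete scan needs at least 4 isolates")
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    rows = []
    for chrom in matrix.chroms:
        cidx = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[cidx]
        start = 1
        pmax = int(pos.max())
        while start <= pmax:
            end = start + window - 1
            wmask = (pos >= start) & (pos <= end)
            widx = cidx[wmask]
            val = 0
            if widx.size >= 2:
                val = hudson_kaplan_rmin(_incompatible_pairs(calls[:, widx]))
            rows.append(dict(chrom=chrom, start=start, end=end, value=val,
                             n_sites=int(widx.size)))
            start += window
    return pd.DataFrame(rows)
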