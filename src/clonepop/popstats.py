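"""Windowed diversity and differentiation statistics for haploid cohorts.

Implements Tajima's D and Hudson's F_ST in non-overlapping genomic windows
(default 5 kb, one value per window), LD decay in r² with MAF/call-rate
pre-filters and seeded isolate subsampling, and 1-D/2-D derived-allele
frequency spectra.

Estimator choices, for haploid samples:

* π is the exact mean pairwise difference count (not a heterozygosity
  approximation), accumulated per site over jointly non-missing calls.
* F_ST is Hudson's estimator combined across sites as a ratio of averages
  (sum of per-site numerators over sum of per-site denominators), which has
  low small-sample bias; negative window values are retained. The Wright band
  [0.05, 0.15] for moderate differentiation is annotated on request.
* r² is the classic gametic correlation computed from haplotype counts over
  jointly non-missing isolates.
* Polarization defaults to reference-as-ancestral; an outgroup isolate can be
  named instead, and unpolarizable sites are skipped and counted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix, filter_sites

log = logging.getLogger("clonepop")

WRIGHT_BAND = (0.05, 0.15)  # moderate differentiation


def _pop_calls(matrix: GenotypeMatrix, pop: list[str] | None) -> np.ndarray:
    if pop is None:
        return matrix.calls
    rows = [matrix.index_of(i) for i in pop]
    return matrix.calls[rows]


def _windows(pos_max: int, window: int) -> list[tuple[int, int]]:
    out = []
    start = 1
    while start <= pos_max:
        out.append((start, start + window - 1))
        start += window
    return out


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """The normalisation constants of Tajima's D for sample size n."""
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(matrix: GenotypeMatrix, pop: list[str] | None = None,
              window: int = 5000) -> pd.DataFrame:
    """Tajima's D per non-overlapping window.

    Per window: pi = exact mean pairwise difference count, theta_W = S/a1,
    D = (pi - theta_W)/sqrt(e1*S + e2*S*(S-1)). Windows with S = 0 get NaN.
    Returns columns chrom,start,end,value,n_sites,S,n_isolates.
    """
    calls = _pop_calls(matrix, pop)
    n = calls.shape[0]
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 haploid isolates")
    k = tajima_constants(n)

    valid = calls != MISSING
    m = valid.sum(axis=0).astype(float)                  # valid calls per site
    alt = ((calls == 1) & valid).sum(axis=0).astype(float)
    poly = (alt > 0) & (alt < m)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi_site = np.where(m >= 2, alt * (m - alt) / (m * (m - 1) / 2.0), 0.0)

    rows = []
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    for chrom in matrix.chroms:
        cmask = chrom_arr == chrom
        cpos = pos_arr[cmask]
        cpi, cpoly = pi_site[cmask], poly[cmask]
        for start, end in _windows(int(cpos.max()), window):
            wmask = (cpos >= start) & (cpos <= end)
            S = int(cpoly[wmask].sum())
            if S == 0:
                D = np.nan
            else:
                pi = float(cpi[wmask].sum())
                theta = S / k["a1"]
                D = (pi - theta) / np.sqrt(k["e1"] * S + k["e2"] * S * (S - 1))
            rows.append(dict(chrom=chrom, start=start, end=end, value=D,
                             n_sites=int(wmask.sum()), S=S, n_isolates=n))
    return pd.DataFrame(rows)


def chrom_medians(window_stats: pd.DataFrame) -> pd.Series:
    """Per-chromosome median of a window statistic (NaN windows ignored)."""
    return window_stats.groupby("chrom", sort=False)["value"].median()


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------

def hudson_fst_site_terms(calls_a: np.ndarray, calls_b: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Hudson numerator/denominator (usable-site mask included)."""
    va = calls_a != MISSING
    vb = calls_b != MISSING
    n1 = va.sum(axis=0).astype(float)
    n2 = vb.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = ((calls_a == 1) & va).sum(axis=0) / np.maximum(n1, 1)
        p2 = ((calls_b == 1) & vb).sum(axis=0) / np.maximum(n2, 1)
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
               - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    usable = (n1 >= 2) & (n2 >= 2)
    return num, den, usable


def hudson_fst(matrix: GenotypeMatrix, pop_a: list[str], pop_b: list[str],
               window: int = 5000) -> tuple[pd.DataFrame, float]:
    """Windowed Hudson F_ST (ratio of averages) and its genome-wide median.

    Windows where the summed denominator is 0 (no site polymorphic across the
    pair) are NaN; negative values are retained.
    """
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValueError("both populations need n >= 2")
    ca = _pop_calls(matrix, pop_a)
    cb = _pop_calls(matrix, pop_b)
    num, den, usable = hudson_fst_site_terms(ca, cb)
    num = np.where(usable, num, 0.0)
    den = np.where(usable, den, 0.0)

    rows = []
    chrom_arr = matrix.sites["chrom"].to_numpy()
    pos_arr = matrix.sites["pos"].to_numpy()
    for chrom in matrix.chroms:
        cmask = chrom_arr == chrom
        cpos = pos_arr[cmask]
        cnum, cden = num[cmask], den[cmask]
        for start, end in _windows(int(cpos.max()), window):
            wmask = (cpos >= start) & (cpos <= end)
            sd = float(cden[wmask].sum())
            fst = float(cnum[wmask].sum()) / sd if sd > 0 else np.nan
            rows.append(dict(chrom=chrom, start=start, end=end, value=fst,
                             n_sites=int(wmask.sum()),
                             n_isolates=len(pop_a) + len(pop_b)))
    df = pd.DataFrame(rows)
    return df, float(df["value"].median(skipna=True))


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class LDResult:
    """Binned LD decay curve plus a 1-bp-resolved short-range profile."""

    binned: pd.DataFrame    # bin_lo, bin_hi, mean_r2, n_pairs
    short_range: pd.DataFrame  # distance (1..short_max bp), mean_r2, n_pairs
    n_sites_used: int
    n_isolates_used: int


def pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """r² between two haploid loci over jointly non-missing calls.

    NaN if either locus is monomorphic on the joint set.
    """
    v = (x != MISSING) & (y != MISSING)
    n = int(v.sum())
    if n == 0:
        return np.nan
    xa = (x[v] == 1)
    ya = (y[v] == 1)
    pa, pb = xa.mean(), ya.mean()
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom == 0:
        return np.nan
    pab = (xa & ya).mean()
    return float((pab - pa * pb) ** 2 / denom)


def ld_decay(matrix: GenotypeMatrix, pop: list[str] | None = None,
             min_maf: float = 0.1, min_geno: float = 0.6,
             max_dist: int = 200_000, bin_size: int = 500,
             short_max: int = 100, subsample_n: int | None = None,
             seed: int = 0) -> LDResult:
    """Mean r² versus physical distance, after site filtering and seeded
    isolate subsampling (LD is sample-size sensitive, so comparisons between
    groups should pass the same ``subsample_n``)."""
    sub = matrix if pop is None else matrix.take_isolates(pop)
    if subsample_n is not None:
        if subsample_n > sub.n_isolates:
            raise ValueError("subsample_n exceeds population size")
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(sub.n_isolates, subsample_n, replace=False))
        sub = GenotypeMatrix(sub.calls[keep], sub.sites.copy(),
                             [sub.isolate_ids[i] for i in keep])
    sub = filter_sites(sub, min_maf=min_maf, min_call_rate=min_geno)

    n_bins = int(np.ceil(max_dist / bin_size))
    bin_sum = np.zeros(n_bins)
    bin_n = np.zeros(n_bins, dtype=np.int64)
    short_sum = np.zeros(short_max)
    short_n = np.zeros(short_max, dtype=np.int64)

    chrom_arr = sub.sites["chrom"].to_numpy()
    pos_all = sub.sites["pos"].to_numpy()
    for chrom in sub.chroms:
        cidx = np.flatnonzero(chrom_arr == chrom)
        pos = pos_all[cidx]
        calls = sub.calls[:, cidx]
        alt = calls == 1
        valid = calls != MISSING
        S = pos.size
        jmax = np.searchsorted(pos, pos + max_dist, side="right")
        for i in range(S - 1):
            j0, j1 = i + 1, jmax[i]
            if j0 >= j1:
                continue
            xi_alt = alt[:, i][:, None]
            xi_val = valid[:, i][:, None]
            Yalt = alt[:, j0:j1]
            Yval = valid[:, j0:j1]
            v = xi_val & Yval
            n = v.sum(axis=0).astype(float)
            ok = n > 0
            n_s = np.maximum(n, 1)
            pa = (xi_alt & v).sum(axis=0) / n_s
            pb = (Yalt & v).sum(axis=0) / n_s
            pab = (xi_alt & Yalt & v).sum(axis=0) / n_s
            denom = pa * (1 - pa) * pb * (1 - pb)
            ok &= denom > 0
            if not ok.any():
                continue
            r2 = np.zeros_like(denom)
            r2[ok] = (pab[ok] - pa[ok] * pb[ok]) ** 2 / denom[ok]
            d = pos[j0:j1] - pos[i]
            b = np.minimum((d - 1) // bin_size, n_bins - 1)
            np.add.at(bin_sum, b[ok], r2[ok])
            np.add.at(bin_n, b[ok], 1)
            sh = ok & (d <= short_max)
            if sh.any():
                np.add.at(short_sum, d[sh] - 1, r2[sh])
                np.add.at(short_n, d[sh] - 1, 1)

    with np.errstate(invalid="ignore"):
        binned = pd.DataFrame({
            "bin_lo": np.arange(n_bins) * bin_size + 1,
            "bin_hi": (np.arange(n_bins) + 1) * bin_size,
            "mean_r2": np.where(bin_n > 0, bin_sum / np.maximum(bin_n, 1),
                                np.nan),
            "n_pairs": bin_n,
        })
        short = pd.DataFrame({
            "distance": np.arange(1, short_max + 1),
            "mean_r2": np.where(short_n > 0, short_sum / np.maximum(short_n, 1),
                                np.nan),
            "n_pairs": short_n,
        })
    return LDResult(binned, short, sub.n_sites, sub.n_isolates)


# ---------------------------------------------------------------------------
# derived-allele frequency spectra
# ---------------------------------------------------------------------------

def polarize(matrix: GenotypeMatrix, polarization: str = "reference"
             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site derived-allele code and polarizability mask.

    ``polarization`` is "reference" (reference allele taken as ancestral, so
    the derived allele is the alt) or an isolate id used as outgroup (the
    derived allele is the one the outgroup does not carry; sites where the
    outgroup is missing are unpolarizable).

    Returns (derived_allele per site in {0,1}, polarizable mask).
    """
    if polarization == "reference":
        return (np.ones(matrix.n_sites, dtype=np.int8),
                np.ones(matrix.n_sites, dtype=bool))
    out_row = matrix.calls[matrix.index_of(polarization)]
    polarizable = out_row != MISSING
    derived = np.where(out_row == 0, 1, 0).astype(np.int8)
    return derived, polarizable


@dataclass
class DafSpectrum:
    """Joint derived-allele-count spectrum for a population pair."""

    counts: np.ndarray      # (n1+1) x (n2+1)
    n_skipped: int          # unpolarizable sites

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def daf_spectrum(matrix: GenotypeMatrix, pop_a: list[str], pop_b: list[str],
                 polarization: str = "reference") -> DafSpectrum:
    """2-D derived-allele frequency spectrum between two populations.

    Cell (a, b) counts sites with derived-allele count a in pop A and b in
    pop B (counts over non-missing calls). Unpolarizable sites are skipped
    and tallied.
    """
    derived, polarizable = polarize(matrix, polarization)
    ca = _pop_calls(matrix, pop_a)
    cb = _pop_calls(matrix, pop_b)
    n1, n2 = len(pop_a), len(pop_b)
    da = ((ca == derived[None, :]) & (ca != MISSING)).sum(axis=0)
    db = ((cb == derived[None, :]) & (cb != MISSING)).sum(axis=0)
    counts = np.zeros((n1 + 1, n2 + 1), dtype=np.int64)
    np.add.at(counts, (da[polarizable], db[polarizable]), 1)
    return DafSpectrum(counts, int((~polarizable).sum()))
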