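"""Maximum-likelihood individual ancestry for haploid genotypes via EM.

The model is the classic admixture likelihood adapted to haploids: isolate i
carries admixture proportions q_i (a point on the K-simplex) and ancestral
population k has allele frequency f_kl at site l; the single allele observed
at (i, l) is Bernoulli(sum_k q_ik f_kl). The diploid binomial used by the
usual ancestry programs would double-count haploid observations, so each
locus contributes one draw:

    L = prod_i prod_l [sum_k q_ik f_kl]^g_il * [sum_k q_ik (1 - f_kl)]^(1-g_il)

with missing calls skipped. EM alternates responsibilities of the K source
populations for each observed allele with closed-form updates of Q and F.
The log-likelihood is non-decreasing by construction; F is clamped away from
{0,1} to keep logs finite. Label switching between restarts is resolved by
greedy matching on ancestral-frequency correlation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix

log = logging.getLogger("clonepop")

_F_CLAMP = 1e-6


@dataclass
class AncestryFit:
    """EM solution for one value of K."""

    Q: pd.DataFrame            # isolates x K admixture proportions
    F: np.ndarray              # K x sites ancestral allele frequencies
    loglik_trace: list[float]
    K: int
    seed: int
    n_iter: int
    converged: bool
    degenerate: bool = False   # some component carries ~no ancestry mass

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _em_once(g: np.ndarray, mask: np.ndarray, K: int, max_iter: int,
             tol: float, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray, list[float], int, bool]:
    n, L = g.shape
    Q = rng.dirichlet(np.ones(K), size=n)
    F = np.clip(rng.uniform(0.1, 0.9, size=(K, L)), _F_CLAMP, 1 - _F_CLAMP)
    g1 = (g == 1) & mask
    g0 = (g == 0) & mask
    n_obs = mask.sum(axis=1).astype(float)         # loci observed per isolate
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: P(source=k | allele), accumulated per component
        denom1 = Q @ F                              # P(g=1)
        denom0 = Q @ (1.0 - F)
        ll = float(np.log(denom1[g1]).sum() + np.log(denom0[g0]).sum())
        trace.append(ll)
        Q_new = np.zeros_like(Q)
        F_num = np.zeros_like(F)
        F_den = np.zeros_like(F)
        inv1 = np.where(g1, 1.0 / denom1, 0.0)
        inv0 = np.where(g0, 1.0 / denom0, 0.0)
        for k in range(K):
            r1 = Q[:, k:k + 1] * F[k] * inv1        # resp. at derived calls
            r0 = Q[:, k:k + 1] * (1.0 - F[k]) * inv0
            Q_new[:, k] = (r1 + r0).sum(axis=1) / n_obs
            F_num[k] = r1.sum(axis=0)
            F_den[k] = (r1 + r0).sum(axis=0)
        Q = Q_new / Q_new.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(F_den > 0, F_num / np.maximum(F_den, 1e-300), F)
        F = np.clip(F, _F_CLAMP, 1 - _F_CLAMP)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return Q, F, trace, it, converged


def fit_ancestry(matrix: GenotypeMatrix, K: int, max_iter: int = 10_000,
                 tol: float = 1e-6, seed: int = 0, n_init: int = 5
                 ) -> AncestryFit:
    """EM fit of the haploid admixture model; best of ``n_init`` restarts.

    Raises if K < 1, K > n isolates, or an isolate has no observed call.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > matrix.n_isolates:
        raise ValueError("K exceeds the number of isolates")
    g = matrix.calls
    mask = g != MISSING
    empty = np.flatnonzero(mask.sum(axis=1) == 0)
    if empty.size:
        raise ValueError(
            f"isolate(s) with no observed call: "
            f"{[matrix.isolate_ids[i] for i in empty]}")

    if K == 1:
        # closed form: F = per-site derived frequency, Q = 1
        cnt1 = ((g == 1) & mask).sum(axis=0)
        cnt0 = ((g == 0) & mask).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = cnt1 / np.maximum(cnt1 + cnt0, 1)
        f = np.clip(f, _F_CLAMP, 1 - _F_CLAMP)
        ll = float((cnt1 * np.log(f)).sum() + (cnt0 * np.log(1 - f)).sum())
        f = f[None, :]
        Q = pd.DataFrame(np.ones((matrix.n_isolates, 1)),
                         index=matrix.isolate_ids, columns=["q1"])
        return AncestryFit(Q, f, [ll], 1, seed, 0, True)

    best = None
    for r in range(n_init):
        rng = np.random.default_rng(seed + 1009 * r)
        Q, F, trace, it, conv = _em_once(g, mask, K, max_iter, tol, rng)
        if best is None or trace[-1] > best[2][-1]:
            best = (Q, F, trace, it, conv)
    Q, F, trace, it, conv = best
    # degenerate if a component carries ~no ancestry mass, or two components
    # collapsed onto the same ancestral frequencies (non-identifiable Q)
    degenerate = bool((Q.sum(axis=0) < 0.01 * matrix.n_isolates).any())
    for a in range(K):
        for b in range(a + 1, K):
            if np.abs(F[a] - F[b]).max() < 1e-2:
                degenerate = True
    if degenerate:
        log.warning("fit_ancestry: K=%d is degenerate (empty or collapsed "
                    "component)", K)
    Qdf = pd.DataFrame(Q, index=matrix.isolate_ids,
                       columns=[f"q{k + 1}" for k in range(K)])
    return AncestryFit(Qdf, F, trace, K, seed, it, conv, degenerate)


def align_components(fit: AncestryFit, reference: AncestryFit) -> AncestryFit:
    """Resolve label switching by greedy matching of ancestral-frequency rows
    to a reference fit with the same K (highest correlation first)."""
    if fit.K != reference.K:
        raise ValueError("K mismatch")
    K = fit.K
    corr = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            ca = np.corrcoef(fit.F[a], reference.F[b])[0, 1]
            corr[a, b] = -2.0 if np.isnan(ca) else ca
    perm = [-1] * K
    used_a, used_b = set(), set()
    for _ in range(K):
        best_pair, best_c = None, -np.inf
        for a in range(K):
            if a in used_a:
                continue
            for b in range(K):
                if b in used_b:
                    continue
                if corr[a, b] > best_c:
                    best_c, best_pair = corr[a, b], (a, b)
        a, b = best_pair
        perm[b] = a
        used_a.add(a)
        used_b.add(b)
    Q = fit.Q.to_numpy()[:, perm]
    F = fit.F[perm]
    Qdf = pd.DataFrame(Q, index=fit.Q.index, columns=fit.Q.columns)
    return AncestryFit(Qdf, F, fit.loglik_trace, K, fit.seed, fit.n_iter,
                       fit.converged, fit.degenerate)


def ancestry_panel(matrix: GenotypeMatrix, K_range=range(2, 7),
                   seeds=(0, 1, 2, 3, 4), max_iter: int = 10_000,
                   tol: float = 1e-6, meta: pd.DataFrame | None = None
                   ) -> tuple[dict[int, AncestryFit], pd.DataFrame]:
    """One fit per K (best over seeds, labels aligned across seeds) plus a
    stacked long-format Q table; isolates ordered by metadata ``pop`` group
    when metadata is given."""
    K_range = list(K_range)
    if not K_range:
        raise ValueError("empty K range")
    fits: dict[int, AncestryFit] = {}
    for K in K_range:
        per_seed = [fit_ancestry(matrix, K, max_iter, tol, seed=s, n_init=1)
                    for s in seeds]
        best = max(per_seed, key=lambda f: f.loglik)
        aligned = [align_components(f, best) if f is not best else f
                   for f in per_seed]
        fits[K] = max(aligned, key=lambda f: f.loglik)

    order = list(matrix.isolate_ids)
    if meta is not None:
        order = (meta.loc[order].sort_values("pop", kind="stable")
                 .index.tolist())
    stacked = []
    for K, fit in fits.items():
        q = fit.Q.loc[order]
        for k in range(K):
            stacked.append(pd.DataFrame({
                "isolate": q.index, "K": K, "component": k + 1,
                "q": q.iloc[:, k].to_numpy()}))
    return fits, pd.concat(stacked, ignore_index=True)
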