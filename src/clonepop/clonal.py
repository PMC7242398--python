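"""Clonal-lineage delineation: pairwise identity, clustering, NJ tree, PCA,
mating-type (MAT) typing and temporal clone recurrence.

The pairwise statistic is SNP-matrix identity — the fraction of jointly
non-missing biallelic SNP sites at which two haploid isolates carry the same
allele. Over a dense genome-wide site set this is an assembly-free proxy for
average nucleotide identity (ANI); clone mates sit near 1 and the clustering
threshold (default identity > 0.998 for clonal groups, > 0.99 for deeper
lineages) mirrors the ANI cut-offs used for such cohorts. Clustering is
single linkage: clonal groups are connected components of the
identity-above-threshold graph, because clonal descent produces subclades,
not centroid-shaped clusters.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .io_core import MISSING, GenotypeMatrix

log = logging.getLogger("clonepop")

# PCR primer pairs delimiting the two MAT idiomorphs; used as default probes
# for in-silico mating-type determination.
MAT1_PROBES = ("CAATTCTCCGTCATCTGCAA", "TTCTTCTGTGGCAAGGCTCT")   # MAT1-1-1
MAT2_PROBES = ("CAGACATACCATTGTGAAGCAG", "TGCTGCTCGAGGAGAGCTT")  # MAT1-2-1

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# pairwise identity
# ---------------------------------------------------------------------------

@dataclass
class IdentityMatrix:
    """Symmetric isolate x isolate SNP identity with joint-coverage counts.

    ``identity[i, j]`` is NaN where the pair shares no non-missing site.
    """

    identity: np.ndarray
    n_joint: np.ndarray
    isolate_ids: list[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.identity, index=self.isolate_ids,
                            columns=self.isolate_ids)


def pairwise_identity(matrix: GenotypeMatrix) -> IdentityMatrix:
    """identity(i,j) = #(equal non-missing calls) / #(jointly non-missing sites)."""
    if matrix.n_isolates < 2:
        raise ValueError("need at least 2 isolates")
    c = matrix.calls
    ref = (c == 0).astype(np.float32)
    alt = (c == 1).astype(np.float32)
    valid = (c != MISSING).astype(np.float32)
    equal = ref @ ref.T + alt @ alt.T
    joint = valid @ valid.T
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(joint > 0, equal / np.maximum(joint, 1), np.nan)
    np.fill_diagonal(ident, 1.0)
    if np.isnan(ident).any():
        log.warning("pairwise_identity: %d pairs have zero joint coverage",
                    int(np.isnan(ident).sum() // 2))
    return IdentityMatrix(ident, joint.astype(np.int64), list(matrix.isolate_ids))


# ---------------------------------------------------------------------------
# clonal grouping
# ---------------------------------------------------------------------------

@dataclass
class CloneAssignment:
    """Partition of isolates into clonal groups at a given identity threshold.

    Groups of >= 2 isolates are labelled C1..Ck in decreasing size order;
    singletons keep their own isolate id as label.
    """

    labels: pd.Series      # isolate -> clone label
    threshold: float

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for iso, lab in self.labels.items():
            out.setdefault(lab, []).append(iso)
        return out


def clonal_groups(idm: IdentityMatrix, threshold: float = 0.998
                  ) -> CloneAssignment:
    """Single-linkage clusters of the graph with edges identity > threshold.

    Pairs with undefined identity (no joint coverage) are treated as below
    threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    ident = np.nan_to_num(idm.identity, nan=-1.0)
    adj = csr_matrix(np.triu(ident > threshold, k=1))
    n_comp, comp = connected_components(adj, directed=False)
    sizes = np.bincount(comp, minlength=n_comp)
    order = np.argsort(-sizes[np.flatnonzero(sizes >= 2)], kind="stable")
    multi = np.flatnonzero(sizes >= 2)
    label_of_comp: dict[int, str] = {}
    for rank, ci in enumerate(multi[order]):
        label_of_comp[ci] = f"C{rank + 1}"
    labels = []
    for i, iso in enumerate(idm.isolate_ids):
        labels.append(label_of_comp.get(comp[i], iso))
    return CloneAssignment(pd.Series(labels, index=idm.isolate_ids,
                                     name="clone"), threshold)


# ---------------------------------------------------------------------------
# NJ tree
# ---------------------------------------------------------------------------

def nj_tree(idm_or_dist: IdentityMatrix | np.ndarray,
            ids: list[str] | None = None) -> TreeNode:
    """Neighbour-joining (Saitou–Nei) tree on distance = 1 - identity.

    Negative branch lengths are clamped to zero. Requires >= 3 taxa.
    """
    if isinstance(idm_or_dist, IdentityMatrix):
        dist = 1.0 - np.nan_to_num(idm_or_dist.identity, nan=0.0)
        ids = idm_or_dist.isolate_ids
    else:
        dist = np.asarray(idm_or_dist, dtype=float)
        if ids is None:
            ids = [f"t{i + 1}" for i in range(dist.shape[0])]
    if dist.shape[0] < 3:
        raise ValueError("NJ needs at least 3 taxa")
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    dm = DistanceMatrix(dist, ids)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(matrix: GenotypeMatrix, k: int = 10
        ) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the genotype matrix with allele-frequency normalisation.

    Missing calls are imputed to the site mean; each site is centred and
    scaled by 1/sqrt(p(1-p)) (the drift-variance normalisation used for SNP
    PCA). Returns (coordinates, explained_variance_fraction) with coordinates
    = top-k left singular vectors scaled by singular values.
    """
    if matrix.n_isolates < 2:
        raise ValueError("need at least 2 isolates")
    X = matrix.calls.astype(float)
    X[X == MISSING] = np.nan
    p = np.nanmean(X, axis=0)
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if not poly.any():
        raise ValueError("no polymorphic site for PCA")
    X = X[:, poly]
    p = p[poly]
    inds = np.where(np.isnan(X))
    X[inds] = np.take(p, inds[1])
    X = (X - p) / np.sqrt(p * (1.0 - p))
    rank = min(X.shape) - 1 if min(X.shape) > 1 else 1
    if k > rank:
        log.warning("pca: k=%d exceeds rank %d; truncating", k, rank)
        k = rank
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :k] * s[:k]
    total = (s ** 2).sum()
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return coords, explained


# ---------------------------------------------------------------------------
# MAT typing
# ---------------------------------------------------------------------------

def _probe_hit(probe: str, seq: str, max_mismatch: int = 1) -> bool:
    if not seq:
        return False
    for q in (probe, revcomp(probe)):
        r = edlib.align(q, seq, mode="HW", task="distance", k=max_mismatch)
        if r["editDistance"] != -1:
            return True
    return False


def mat_type(sequences: str | list[str],
             probes1: tuple[str, str] = MAT1_PROBES,
             probes2: tuple[str, str] = MAT2_PROBES,
             max_mismatch: int = 1) -> str:
    """Type the MAT idiomorph of an isolate from its sequence(s).

    Each probe (default: the four MAT PCR primers) is searched on both strands
    allowing ``max_mismatch`` edits. An idiomorph is called present when both
    of its probes hit. Returns "MAT1-1", "MAT1-2", "both" (putative
    heterokaryon) or "unknown".
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    sequences = [s for s in sequences if s]
    if not sequences:
        return "unknown"
    has1 = any(all(_probe_hit(p, s, max_mismatch) for p in probes1)
               for s in sequences)
    has2 = any(all(_probe_hit(p, s, max_mismatch) for p in probes2)
               for s in sequences)
    if has1 and has2:
        return "both"
    if has1:
        return "MAT1-1"
    if has2:
        return "MAT1-2"
    return "unknown"


def mat_type_fasta(path, **kw) -> pd.Series:
    """MAT-type every record of a (multi-)FASTA; index = record id."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = mat_type(str(rec.seq), **kw)
    return pd.Series(out, name="mat")


# ---------------------------------------------------------------------------
# temporal recurrence
# ---------------------------------------------------------------------------

def temporal_venn(assignment: CloneAssignment, meta: pd.DataFrame,
                  epochs: tuple = ("1997", "2007", "2017")
                  ) -> tuple[pd.DataFrame, dict]:
    """Epoch occupancy of each clone / divergent isolate.

    Returns (table, summary): the table has one row per clone label with the
    set of epochs it was observed in; the summary counts labels unique to one
    epoch, shared between epoch pairs, and present in all epochs.
    """
    rows = []
    for lab, members in assignment.groups().items():
        eps = sorted({str(meta.loc[m, "pop"]) for m in members
                      if str(meta.loc[m, "pop"]) in set(map(str, epochs))})
        if not eps:
            continue
        rows.append(dict(clone=lab, n_isolates=len(members),
                         epochs=",".join(eps), n_epochs=len(eps)))
    table = pd.DataFrame(rows, columns=["clone", "n_isolates", "epochs",
                                        "n_epochs"])
    summary = {
        "single_epoch": int((table["n_epochs"] == 1).sum()),
        "shared": int((table["n_epochs"] >= 2).sum()),
        "all_epochs": int((table["n_epochs"] == len(epochs)).sum()),
    }
    return table, summary
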