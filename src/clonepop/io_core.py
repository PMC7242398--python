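"""Readers/writers for standard formats and the genotype-matrix container.

Everything downstream operates on a :class:`GenotypeMatrix`: isolates x ordered
biallelic SNP sites with haploid calls in {0=ref, 1=alt, -1=missing}. The
organism is haploid, but variant callers often emit diploid-coded genotypes;
``0/0`` and ``1/1`` collapse to the haploid call and heterozygous calls become
missing (with a logged count), since a true haploid cannot be heterozygous at a
nuclear locus outside a heterokaryon.

Coordinate conventions: internal positions are 1-based (VCF/GFF native); BED is
converted from 0-based half-open on read. All sites are biallelic SNPs; sites
falling in a declared mating-type (MAT) locus interval can be excluded on read,
because the idiomorphic MAT locus does not align between opposite mating types.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from skbio import TreeNode

log = logging.getLogger("clonepop")

MISSING = -1

POP_VOCAB = {"1997", "2007", "2017", "MR1", "MR2", "NMR"}
MAT_VOCAB = {"MAT1-1", "MAT1-2", "both", "unknown"}
HOST_VOCAB = {"COL", "LEP", "HEM", "HYM", "DIP", "ORT"}
META_COLUMNS = ["isolate", "pop", "year", "mat", "host", "released"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Haploid genotype calls for isolates x ordered biallelic SNP sites.

    Attributes
    ----------
    calls:
        int8 array of shape (n_isolates, n_sites); 0=ref, 1=alt, -1=missing.
    sites:
        DataFrame with columns ``chrom, pos, ref, alt``; pos is 1-based and
        strictly increasing within each chromosome.
    isolate_ids:
        Unique isolate identifiers, row order of ``calls``.
    """

    calls: np.ndarray
    sites: pd.DataFrame
    isolate_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.isolate_ids = [str(i) for i in self.isolate_ids]
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (isolates x sites)")
        if self.calls.shape[0] != len(self.isolate_ids):
            raise ValueError("calls rows != number of isolate ids")
        if self.calls.shape[1] != len(self.sites):
            raise ValueError("calls columns != number of sites")
        if len(set(self.isolate_ids)) != len(self.isolate_ids):
            raise ValueError("isolate ids are not unique")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_isolates(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.sites["chrom"]))

    def index_of(self, isolate: str) -> int:
        try:
            return self.isolate_ids.index(isolate)
        except ValueError:
            raise KeyError(f"unknown isolate id: {isolate!r}") from None

    def take_isolates(self, ids: Sequence[str]) -> "GenotypeMatrix":
        rows = [self.index_of(i) for i in ids]
        return GenotypeMatrix(self.calls[rows], self.sites.copy(), list(ids))

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.calls[:, idx], self.sites.iloc[idx].reset_index(drop=True),
            list(self.isolate_ids),
        )

    def site_mask_for_chrom(self, chrom: str) -> np.ndarray:
        return (self.sites["chrom"] == chrom).to_numpy()

    def alt_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (#alt, #non-missing) over all isolates."""
        valid = self.calls != MISSING
        alt = ((self.calls == 1) & valid).sum(axis=0)
        return alt, valid.sum(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing calls (NaN if none)."""
        alt, n = self.alt_counts()
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def validate_sorted(self) -> None:
        chrom = self.sites["chrom"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        for c in self.chroms:
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    mat_exclusion: tuple[str, int, int] | None = None,
) -> GenotypeMatrix:
    """Parse a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained; records inside ``mat_exclusion``
    (chrom, start, end; 1-based closed) are dropped. Haploid GT ("0"/"1"/".")
    and homozygous diploid GT ("0/0", "1/1") are accepted; heterozygous diploid
    calls become missing. Drop counts are logged.
    """
    path = str(path)
    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    n = len(samples)
    if n == 0:
        raise ValueError(f"{path}: VCF contains no samples")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    dropped = {"multiallelic": 0, "non_snp": 0, "mat_locus": 0}
    n_het = 0

    for rec in vcf:
        if len(rec.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        if not rec.is_snp:
            dropped["non_snp"] += 1
            continue
        if mat_exclusion is not None:
            c, s, e = mat_exclusion
            if rec.CHROM == c and s <= rec.POS <= e:
                dropped["mat_locus"] += 1
                continue
        calls = np.full(n, MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            alleles = [a for a in gt[:-1]]  # last element is the phased flag
            if len(alleles) == 1:
                a = alleles[0]
                if a in (0, 1):
                    calls[i] = a
                elif a != -1:
                    raise ValueError(
                        f"{path}: malformed GT at {rec.CHROM}:{rec.POS} "
                        f"sample {samples[i]}: allele {a}"
                    )
            elif len(alleles) == 2:
                a, b = alleles
                if a == -1 or b == -1:
                    continue
                if a == b and a in (0, 1):
                    calls[i] = a
                elif a != b:
                    n_het += 1  # haploid organism: treat heterozygote as missing
                else:
                    raise ValueError(
                        f"{path}: malformed GT at {rec.CHROM}:{rec.POS} "
                        f"sample {samples[i]}: alleles {a}/{b}"
                    )
            else:
                raise ValueError(
                    f"{path}: malformed GT at {rec.CHROM}:{rec.POS} "
                    f"sample {samples[i]}: ploidy {len(alleles)}"
                )
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(calls)

    if not rows:
        raise ValueError(f"{path}: no biallelic SNP records retained")
    if any(v for v in dropped.values()) or n_het:
        log.info("read_vcf(%s): dropped %s; heterozygous calls set missing: %d",
                 path, dropped, n_het)

    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    calls = np.stack(rows, axis=1)
    # enforce (chrom-in-first-appearance-order, pos) sorting
    order = {c: i for i, c in enumerate(dict.fromkeys(chroms))}
    idx = np.lexsort((sites["pos"].to_numpy(),
                      sites["chrom"].map(order).to_numpy()))
    mat = GenotypeMatrix(calls[:, idx], sites.iloc[idx], samples)
    mat.validate_sorted()
    return mat


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a haploid VCF v4.2 (GT as single allele "0"/"1"/".")."""
    sites = matrix.sites
    if contig_lengths is None:
        contig_lengths = {
            c: int(sites.loc[sites["chrom"] == c, "pos"].max())
            for c in matrix.chroms
        }
    sym = np.array([".", "0", "1"])  # index by call+1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, ln in contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.isolate_ids) + "\n")
        chrom = sites["chrom"].to_numpy()
        pos = sites["pos"].to_numpy()
        ref = sites["ref"].to_numpy()
        alt = sites["alt"].to_numpy()
        gts = sym[matrix.calls + 1]  # (n_isolates, n_sites)
        for j in range(matrix.n_sites):
            fh.write(f"{chrom[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts[:, j]) + "\n")


# ---------------------------------------------------------------------------
# site filtering
# ---------------------------------------------------------------------------

def filter_sites(matrix: GenotypeMatrix, min_maf: float = 0.0,
                 min_call_rate: float = 0.0) -> GenotypeMatrix:
    """Keep sites with minor-allele frequency >= ``min_maf`` (computed on
    non-missing calls) and call rate >= ``min_call_rate``."""
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    if not 0.0 <= min_call_rate <= 1.0:
        raise ValueError("min_call_rate must be in [0, 1]")
    alt, nval = matrix.alt_counts()
    call_rate = nval / matrix.n_isolates
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nval > 0, alt / np.maximum(nval, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    keep = (maf >= min_maf) & (call_rate >= min_call_rate) & (nval > 0)
    if not keep.any():
        log.warning("filter_sites: no sites pass (min_maf=%s, min_call_rate=%s)",
                    min_maf, min_call_rate)
    return matrix.take_sites(keep)


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into 1-based closed intervals.

    Returns a DataFrame with columns ``chrom, start, end`` where a BED line
    ``chr1 0 100`` becomes start=1, end=100.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str, 1: np.int64, 2: np.int64})
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        bad = df[(df["start"] < 0) | (df["end"] <= df["start"])].iloc[0]
        raise ValueError(f"BED coordinate violation: {bad.tolist()}")
    df["start"] = df["start"] + 1  # to 1-based closed
    return df.reset_index(drop=True)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based closed intervals (chrom,start,end) as BED."""
    out = intervals.copy()
    out["start"] = out["start"] - 1
    out[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False,
                                          index=False)


def read_gff(path: str | Path) -> pd.DataFrame:
    """Read gene records from a GFF3 file (1-based closed coordinates).

    Returns columns ``chrom, start, end, strand, gene_id, effector`` where
    ``effector`` is parsed from an ``effector=1|0`` attribute (default 0).
    """
    names = ["chrom", "source", "type", "start", "end", "score", "strand",
             "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names,
                     dtype={"chrom": str})
    df = df[df["type"] == "gene"].copy()
    if (df["start"] < 1).any() or (df["end"] < df["start"]).any():
        bad = df[(df["start"] < 1) | (df["end"] < df["start"])].iloc[0]
        raise ValueError(f"GFF coordinate violation: {bad.tolist()}")

    def attr(s: str, key: str, default: str = "") -> str:
        for part in s.strip().split(";"):
            if part.startswith(key + "="):
                return part.split("=", 1)[1]
        return default

    df["gene_id"] = [attr(a, "ID", f"gene{i}") for i, a in
                     enumerate(df["attributes"])]
    df["effector"] = [int(attr(a, "effector", "0")) for a in df["attributes"]]
    return df[["chrom", "start", "end", "strand", "gene_id",
               "effector"]].reset_index(drop=True)


def write_gff(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene records (chrom,start,end,strand,gene_id,effector) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g['gene_id']};effector={int(g['effector'])}"
            fh.write(f"{g['chrom']}\tclonepop\tgene\t{int(g['start'])}\t"
                     f"{int(g['end'])}\t.\t{g.get('strand', '+')}\t.\t{attrs}\n")


def interval_overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap length in bp between two 1-based closed intervals."""
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode) -> str:
    import io as _io
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    import io as _io
    return TreeNode.read(_io.StringIO(text), format="newick")


# ---------------------------------------------------------------------------
# isolate metadata
# ---------------------------------------------------------------------------

def read_meta(path: str | Path) -> pd.DataFrame:
    """Read the isolate metadata TSV (header: isolate pop year mat host released).

    Returns a DataFrame indexed by isolate id; ``released`` is boolean.
    """
    df = pd.read_csv(path, sep="\t", dtype={"isolate": str, "pop": str,
                                            "mat": str, "host": str})
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad_pop = set(df["pop"]) - POP_VOCAB
    if bad_pop:
        raise ValueError(f"unknown pop labels: {sorted(bad_pop)}")
    bad_mat = set(df["mat"]) - MAT_VOCAB
    if bad_mat:
        raise ValueError(f"unknown mat labels: {sorted(bad_mat)}")
    df["released"] = df["released"].astype(int).astype(bool)
    if (df.loc[df["released"], "mat"] == "unknown").any():
        raise ValueError("released isolates must have a known mating type")
    return df.set_index("isolate")


def write_meta(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.reset_index() if meta.index.name == "isolate" else meta.copy()
    out["released"] = out["released"].astype(int)
    out[META_COLUMNS].to_csv(path, sep="\t", index=False)
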