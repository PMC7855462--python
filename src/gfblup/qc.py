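"""Genotype container and marker quality control.

The QC chain mirrors standard practice for an inbred diversity panel:

1. remove every marker with a missing call in any accession,
2. drop markers below a minor-allele-frequency threshold (default 0.01),
3. prune near-duplicate markers within a small physical window
   (default 50 bp, |Pearson r| >= 0.999).

The chain is order-dependent and each step is idempotent on its own output.
Genotype calls are stored as minor-allele counts in {0, 1, 2} with -1 for
missing; a fully homozygous (inbred) panel only contains 0 and 2, but
heterozygous calls are accepted everywhere for generality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyPanelError, ParseError

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Accessions x markers allele-count table with marker metadata.

    ``calls[i, j]`` is the minor-allele count of accession ``i`` at marker
    ``j`` (0, 1 or 2; -1 = missing). Positions are 1-based and strictly
    increasing within a chromosome.
    """

    accession_ids: np.ndarray  # (n,) str
    marker_ids: np.ndarray  # (m,) str
    calls: np.ndarray  # (n, m) int8
    chrom: np.ndarray  # (m,) str
    pos: np.ndarray  # (m,) int64
    _maf: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.accession_ids = np.asarray(self.accession_ids, dtype=str)
        self.marker_ids = np.asarray(self.marker_ids, dtype=str)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=str)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = self.calls.shape
        if len(self.accession_ids) != n or len(self.marker_ids) != m:
            raise ValueError("label lengths do not match call matrix shape")
        if len(self.chrom) != m or len(self.pos) != m:
            raise ValueError("marker metadata length mismatch")

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency, ignoring missing calls."""
        if self._maf is None:
            self._maf = _compute_maf(self.calls)
        return self._maf

    def has_missing(self) -> bool:
        return bool((self.calls == MISSING).any())

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the marker indices ``idx`` (order kept)."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            accession_ids=self.accession_ids,
            marker_ids=self.marker_ids[idx],
            calls=self.calls[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
        )

    def sort_markers(self) -> "GenotypeMatrix":
        """Sort markers by (chromosome, position)."""
        order = np.lexsort((self.pos, self.chrom))
        return self.take_markers(order)


def _compute_maf(calls: np.ndarray) -> np.ndarray:
    """Brute-force allele counting; folds frequencies above 0.5."""
    obs = calls != MISSING
    counted = np.where(obs, calls, 0).sum(axis=0).astype(float)
    denom = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(denom > 0, counted / denom, 0.0)
    return np.minimum(freq, 1.0 - freq)


def recode_to_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Flip markers so the counted allele is the minor one (freq <= 0.5)."""
    obs = g.calls != MISSING
    counted = np.where(obs, g.calls, 0).sum(axis=0).astype(float)
    denom = 2.0 * obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(denom > 0, counted / denom, 0.0)
    flip = freq > 0.5
    calls = g.calls.copy()
    cols = np.where(flip)[0]
    for j in cols:
        col = calls[:, j]
        m = col != MISSING
        col[m] = 2 - col[m]
    return GenotypeMatrix(g.accession_ids, g.marker_ids, calls, g.chrom, g.pos)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def load_genotypes(path: str, format: str) -> GenotypeMatrix:
    """Load genotypes from ``plink-text`` (.ped/.map), ``vcf`` or ``tsv``.

    Only biallelic sites are kept; multi-allelic VCF records are dropped
    with a logged count. The minor allele is determined per marker from the
    loaded sample.
    """
    if format == "plink-text":
        g = _load_plink_text(path)
    elif format == "vcf":
        g = _load_vcf(path)
    elif format == "tsv":
        g = _load_tsv(path)
    else:
        raise DomainError(f"unknown genotype format: {format!r}")
    return recode_to_minor(g.sort_markers())


def _load_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    marker_ids = df.columns.to_numpy(dtype=str)
    vals = df.to_numpy()
    calls = np.full(vals.shape, MISSING, dtype=np.int8)
    for code in ("0", "1", "2"):
        calls[vals == code] = int(code)
    bad = ~np.isin(vals, ["0", "1", "2", "NA"]) & ~pd.isna(vals)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"non-biallelic or invalid call {vals[i, j]!r} at marker "
            f"{marker_ids[j]!r}"
        )
    # marker id convention "chrom:pos" if it parses, else sequential positions
    chrom, pos = _marker_coords_from_ids(marker_ids)
    return GenotypeMatrix(df.index.to_numpy(dtype=str), marker_ids, calls, chrom, pos)


def _marker_coords_from_ids(marker_ids: np.ndarray):
    chrom, pos = [], []
    for k, mid in enumerate(marker_ids):
        if ":" in mid:
            c, _, p = mid.partition(":")
            try:
                pos.append(int(p))
                chrom.append(c)
                continue
            except ValueError:
                pass
        chrom.append("0")
        pos.append(k + 1)
    return np.asarray(chrom, dtype=str), np.asarray(pos, dtype=np.int64)


def _load_plink_text(path: str) -> GenotypeMatrix:
    """``path`` is the shared prefix of a .ped/.map pair."""
    mp = pd.read_csv(
        path + ".map", sep=r"\s+", header=None,
        names=["chrom", "marker_id", "cm", "pos"], dtype=str,
    )
    marker_ids = mp["marker_id"].to_numpy(dtype=str)
    chrom = mp["chrom"].to_numpy(dtype=str)
    pos = mp["pos"].astype(np.int64).to_numpy()
    m = len(marker_ids)

    accessions, rows = [], []
    with open(path + ".ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}"
                )
            accessions.append(parts[1])
            rows.append(parts[6:])
    alleles = np.asarray(rows, dtype=str).reshape(len(accessions), m, 2)

    calls = np.full((len(accessions), m), MISSING, dtype=np.int8)
    for j in range(m):
        aj = alleles[:, :, :][:, j, :]
        seen = sorted(set(aj.ravel()) - {"0"})
        if len(seen) > 2:
            raise ParseError(
                f"non-biallelic marker {marker_ids[j]!r}: alleles {seen}"
            )
        if not seen:
            continue
        counted = seen[0]  # provisional; recode_to_minor fixes orientation
        obs = (aj != "0").all(axis=1)
        calls[obs, j] = (aj[obs] == counted).sum(axis=1)
    return GenotypeMatrix(np.asarray(accessions, dtype=str), marker_ids, calls, chrom, pos)


def _load_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    accessions = np.asarray(vcf.samples, dtype=str)
    marker_ids, chrom, pos, cols = [], [], [], []
    n_multiallelic = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        gts = np.asarray(rec.genotype.array())[:, :2]
        col = np.where((gts < 0).any(axis=1), MISSING, (gts > 0).sum(axis=1))
        cols.append(col.astype(np.int8))
        marker_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
    if n_multiallelic:
        logger.warning("dropped %d multi-allelic VCF records", n_multiallelic)
    if not cols:
        raise EmptyPanelError("no biallelic records in VCF")
    g = GenotypeMatrix(
        accessions,
        np.asarray(marker_ids, dtype=str),
        np.column_stack(cols),
        np.asarray(chrom, dtype=str),
        np.asarray(pos, dtype=np.int64),
    )
    g.n_dropped_multiallelic = n_multiallelic  # type: ignore[attr-defined]
    return g


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Remove every marker with >= 1 missing call; accessions are never removed."""
    keep = np.where(~(g.calls == MISSING).any(axis=0))[0]
    if keep.size == 0:
        raise EmptyPanelError("every marker has at least one missing call")
    if keep.size == g.n_markers:
        return g
    return g.take_markers(keep)


def filter_maf(g: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Keep markers with MAF >= ``threshold`` (order preserved)."""
    if not 0.0 <= threshold <= 0.5:
        raise DomainError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    keep = np.where(g.maf >= threshold)[0]
    if keep.size == 0:
        raise EmptyPanelError(f"no marker passes MAF >= {threshold}")
    if keep.size == g.n_markers:
        return g
    return g.take_markers(keep)


def ld_prune(
    g: GenotypeMatrix, window_bp: int = 50, r_threshold: float = 0.999
) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning within a physical window.

    Scanning each chromosome in position order, a marker is removed when its
    allele counts have |Pearson r| >= ``r_threshold`` with any already-kept
    marker no more than ``window_bp`` base pairs to its left. The later
    marker (larger position) is always the one removed. Pairs on different
    chromosomes are never compared.
    """
    if window_bp <= 0:
        raise DomainError("window_bp must be positive")
    if g.has_missing():
        raise DomainError("ld_prune requires a missing-free matrix")

    calls = g.calls.astype(np.float64)
    centered = calls - calls.mean(axis=0)
    norms = np.sqrt((centered ** 2).sum(axis=0))

    keep_mask = np.zeros(g.n_markers, dtype=bool)
    for ch in np.unique(g.chrom):
        idx = np.where(g.chrom == ch)[0]
        idx = idx[np.argsort(g.pos[idx], kind="stable")]
        kept: list[int] = []
        for j in idx:
            drop = False
            for k in reversed(kept):
                if g.pos[j] - g.pos[k] > window_bp:
                    break
                if norms[j] == 0 or norms[k] == 0:
                    continue  # monomorphic: correlation undefined, keep
                r = centered[:, j] @ centered[:, k] / (norms[j] * norms[k])
                if abs(r) >= r_threshold:
                    drop = True
                    break
            if not drop:
                kept.append(j)
                keep_mask[j] = True
    keep = np.where(keep_mask)[0]
    if keep.size == g.n_markers:
        return g
    return g.take_markers(keep)


def qc_chain(
    g: GenotypeMatrix,
    maf_threshold: float = 0.01,
    window_bp: int = 50,
    r_threshold: float = 0.999,
) -> GenotypeMatrix:
    """The fixed QC order: missing-call removal, MAF filter, LD pruning."""
    return ld_prune(
        filter_maf(filter_missing(g), maf_threshold), window_bp, r_threshold
    )
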