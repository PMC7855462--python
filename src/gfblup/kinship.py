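"""Genomic relationship matrices (GRMs).

The GRM is G = W W' / m, where W is the accession x marker matrix of
centered, scaled minor-allele counts: w_i = (z_i - 2 p_i) / sqrt(2 p_i (1 - p_i)),
with p_i the allele frequency of the counted (minor) allele in the analyzed
panel. For a genomic feature, G_f is built from the feature's markers only
and G_r from the complement, each scaled by its own marker count, so that

    m_f * G_f + m_r * G_r = m * G_all        (additivity of cross-products).

For a fully inbred panel (calls in {0, 2}) the expected diagonal of G is 2,
twice the outbred value, because E[w^2] = 4 p q / (2 p q).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, EmptyPanelError, PartitionError
from .qc import GenotypeMatrix


@dataclass
class GRM:
    """Symmetric accession x accession genomic relationship matrix."""

    accession_ids: np.ndarray
    values: np.ndarray
    n_markers_used: int
    marker_subset_id: str = "ALL"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.accession_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match accession count")
        if self.n_markers_used < 1:
            raise EmptyPanelError("GRM built from zero markers")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset(self, idx: np.ndarray) -> "GRM":
        idx = np.asarray(idx)
        return GRM(
            accession_ids=np.asarray(self.accession_ids)[idx],
            values=self.values[np.ix_(idx, idx)],
            n_markers_used=self.n_markers_used,
            marker_subset_id=self.marker_subset_id,
        )


def center_scale(g: GenotypeMatrix) -> np.ndarray:
    """Centered, scaled marker matrix W; columns have mean exactly 0.

    Allele frequencies come from the supplied panel. Monomorphic markers
    must be excluded beforehand (their scaling divides by zero).
    """
    if g.has_missing():
        raise DomainError("center_scale requires a missing-free matrix")
    mono = np.where(g.maf <= 0.0)[0]
    if mono.size:
        raise DomainError(
            f"monomorphic marker(s) reach center_scale: "
            f"{', '.join(g.marker_ids[mono[:5]])}"
            + ("..." if mono.size > 5 else "")
        )
    z = g.calls.astype(np.float64)
    p = z.mean(axis=0) / 2.0  # frequency of the counted allele
    w = (z - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return w


def compute_grm(
    w: np.ndarray,
    accession_ids: np.ndarray,
    marker_subset_id: str = "ALL",
) -> GRM:
    """G = W W' / m with m the number of columns of W."""
    m = w.shape[1]
    if m == 0:
        raise EmptyPanelError("cannot build a GRM from an empty marker subset")
    values = (w @ w.T) / m
    return GRM(np.asarray(accession_ids), values, m, marker_subset_id)


def grm_from_genotypes(g: GenotypeMatrix, marker_subset_id: str = "ALL") -> GRM:
    """Convenience: center/scale then build the all-marker GRM."""
    return compute_grm(center_scale(g), g.accession_ids, marker_subset_id)


def partition_grm(
    g: GenotypeMatrix,
    feature_markers: np.ndarray,
    feature_id: str = "feature",
    w: np.ndarray | None = None,
) -> tuple[GRM, GRM]:
    """Split the panel into a feature GRM and a remainder GRM.

    ``feature_markers`` are column indices into ``g``. Each GRM is scaled by
    its own marker count; allele frequencies are those of the full panel
    (pass a precomputed ``w`` from :func:`center_scale` to avoid rescaling).
    """
    feature_markers = np.unique(np.asarray(feature_markers, dtype=np.int64))
    m = g.n_markers
    if feature_markers.size == 0:
        raise PartitionError("feature has no markers in the panel")
    if feature_markers.size >= m:
        raise PartitionError("feature covers all markers; remainder is empty")
    if feature_markers.min() < 0 or feature_markers.max() >= m:
        raise PartitionError("feature marker index out of range")
    if w is None:
        w = center_scale(g)
    mask = np.zeros(m, dtype=bool)
    mask[feature_markers] = True
    g_f = compute_grm(w[:, mask], g.accession_ids, feature_id)
    g_r = compute_grm(w[:, ~mask], g.accession_ids, f"~{feature_id}")
    return g_f, g_r
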