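"""Design-adjusted phenotypes (per-genotype BLUEs).

Replicate-level measurements from the imaging platform are adjusted with
the design model

    value = Genotype + x + y + image_position + sowing_block + error,

where Genotype is a fixed effect (cell-means coding, so the BLUEs stay on
the observed scale) and the spatial row (x), column (y), image position and
sowing block are independent random intercepts. The variance components are
estimated by the same AI-REML core used for the genomic models, with an
identity-structured covariance per factor (Z Z' kinships); the BLUE vector
is the GLS estimate of the genotype means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .mixedmodel import ModelSpec, reml_fit

logger = logging.getLogger(__name__)

RANDOM_FACTORS = ("x", "y", "image_position", "sowing_block")
REQUIRED_COLUMNS = ("accession", "replicate", "timepoint", "value")


@dataclass
class AdjustedPhenotype:
    """One BLUE per accession at one timepoint."""

    accession_ids: np.ndarray
    values: np.ndarray
    timepoint: str

    def __post_init__(self) -> None:
        self.accession_ids = np.asarray(self.accession_ids, dtype=str)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.accession_ids) != len(self.values):
            raise ValueError("label/value length mismatch")

    def align(self, accession_order) -> "AdjustedPhenotype":
        """Reorder to match a genotype panel; accessions must all be present."""
        index = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            order = np.array([index[a] for a in accession_order])
        except KeyError as exc:
            raise DomainError(f"accession {exc} has no BLUE at {self.timepoint}")
        return AdjustedPhenotype(
            self.accession_ids[order], self.values[order], self.timepoint
        )


def _validate_table(tbl: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in tbl.columns]
    if missing:
        raise DomainError(f"phenotype table lacks column(s): {missing}")
    if not np.all(np.isfinite(tbl["value"].to_numpy(float))):
        raise DomainError("phenotype values must be finite")


def fit_design_model(tbl: pd.DataFrame, timepoint: str,
                     max_iter: int = 100, tol: float = 1e-5):
    """Fit the design model at one timepoint.

    Returns ``(AdjustedPhenotype, design_variances)`` where the dict maps
    each retained random factor (plus ``"residual"``) to its REML variance
    estimate. Factors with fewer than 2 levels are dropped with a warning;
    accessions with zero observations at the timepoint are excluded (they
    are simply absent from the output).
    """
    _validate_table(tbl)
    sub = tbl[tbl["timepoint"].astype(str) == str(timepoint)]
    if sub.empty:
        raise DomainError(f"no observations at timepoint {timepoint!r}")
    accessions = np.array(sorted(sub["accession"].astype(str).unique()))
    if len(accessions) < 2:
        raise DomainError("design model needs >= 2 accessions")

    y = sub["value"].to_numpy(np.float64)
    n_obs = len(y)
    acc_codes = pd.Categorical(sub["accession"].astype(str),
                               categories=accessions).codes
    x = np.zeros((n_obs, len(accessions)))
    x[np.arange(n_obs), acc_codes] = 1.0

    kinships, retained = [], []
    for factor in RANDOM_FACTORS:
        if factor not in sub.columns:
            continue
        codes = pd.Categorical(sub[factor]).codes
        n_levels = codes.max() + 1
        if n_levels < 2:
            logger.warning("factor %s has < 2 levels at %s; dropped",
                           factor, timepoint)
            continue
        z = np.zeros((n_obs, n_levels))
        z[np.arange(n_obs), codes] = 1.0
        kinships.append(z @ z.T)
        retained.append(factor)

    # degenerate case: genotype means already fit the data exactly, so every
    # random component is zero and the GLS solution is the plain cell mean
    counts0 = np.bincount(acc_codes, minlength=len(accessions))
    sums0 = np.bincount(acc_codes, weights=y, minlength=len(accessions))
    within_ss = float(((y - (sums0 / counts0)[acc_codes]) ** 2).sum())
    if within_ss <= 1e-12 * max(float(np.var(y)) * n_obs, 1.0):
        kinships = []

    if kinships:
        fit = reml_fit(y, ModelSpec(kinships, x), max_iter=max_iter, tol=tol)
        blues = fit.beta
        variances = dict(zip(retained, fit.components))
        variances["residual"] = fit.residual
    else:
        # no random factor retained: GLS collapses to per-accession means
        counts = np.bincount(acc_codes, minlength=len(accessions))
        sums = np.bincount(acc_codes, weights=y, minlength=len(accessions))
        blues = sums / counts
        resid = y - blues[acc_codes]
        dof = max(n_obs - len(accessions), 1)
        variances = {"residual": float((resid ** 2).sum() / dof)}

    return AdjustedPhenotype(accessions, blues, str(timepoint)), variances


def summarize_variation(tbl: pd.DataFrame):
    """Per-timepoint coefficient of variation and inter-timepoint correlations.

    CV = SD / mean of the accession BLUEs x 100 (percent). Correlations are
    Pearson r between timepoint BLUE vectors over the accessions shared by
    each pair of timepoints.
    """
    _validate_table(tbl)
    timepoints = list(dict.fromkeys(tbl["timepoint"].astype(str)))
    blues = {}
    for t in timepoints:
        adj, _ = fit_design_model(tbl, t)
        series = pd.Series(adj.values, index=adj.accession_ids)
        mean = series.mean()
        if mean == 0:
            raise DomainError(f"CV undefined at {t}: mean BLUE is zero")
        blues[t] = series
    cv = pd.Series(
        {t: 100.0 * s.std(ddof=1) / s.mean() for t, s in blues.items()},
        name="cv_percent",
    )
    frame = pd.DataFrame(blues)
    corr = frame.corr(method="pearson")
    return cv, corr
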