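"""Cross-validated model comparison and the genome-wide feature scan.

Prediction accuracy is the Pearson correlation between observed adjusted
phenotypes and predicted total genomic values of each test fold, over
k-fold cross-validation repeated several times with the fold assignment
shared bit-identically between every model compared. Feature models
(GFBLUP) are compared to the all-marker GBLUP benchmark by

* a likelihood-ratio test of sigma_f^2 = 0 whose null is the mixture
  1/2 point-mass(0) + 1/2 chi-square(1) (the parameter sits on the
  boundary),
* a two-sided Wilcoxon-Mann-Whitney test on the two accuracy samples,
  with Benjamini-Hochberg FDR over the whole features x timepoints family,
* genomic heritabilities h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) and
  hf2 = sigma_f^2 / (sigma_f^2 + sigma_r^2 + sigma_e^2); records with hf2
  outside (0.01, 0.99) are flagged as over-estimated/undetermined and do
  not pass the filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, EmptyPanelError, GfblupError
from .kinship import GRM, center_scale, compute_grm, partition_grm
from .mixedmodel import (
    ModelSpec,
    VarianceFit,
    component_blups,
    predict_genomic_values,
    reml_fit,
)

logger = logging.getLogger(__name__)

#: heritability closer than this to 0 or 1 marks a fold as inestimable
H2_BOUNDARY_EPS = 1e-3
#: hf2 window outside which a feature model is filtered out
HF2_FILTER = (0.01, 0.99)
#: exact Wilcoxon enumeration below this per-sample size, else normal approx.
WILCOXON_EXACT_MAX = 12


@dataclass
class CVResult:
    """Per-fold accuracies of one model under shared splits."""

    model_id: str
    fold_accuracies: np.ndarray
    splits_seed: int
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=np.float64)

    @property
    def median(self) -> float:
        return float(np.median(self.fold_accuracies))


def make_cv_splits(n: int, k: int = 8, repeats: int = 10, seed: int = 0) -> list:
    """Deterministic k-fold splits, repeated; reused across compared models.

    Within each repeat the test folds are disjoint, cover all ``n`` indices,
    and differ in size by at most one.
    """
    if k > n:
        raise DomainError(f"k = {k} exceeds n = {n}")
    if k < 2:
        raise DomainError("k must be >= 2")
    rng = np.random.default_rng(seed)
    splits = []
    idx = np.arange(n)
    for _ in range(repeats):
        perm = rng.permutation(idx)
        folds = np.array_split(perm, k)
        for f in folds:
            test = np.sort(f)
            train = np.sort(np.setdiff1d(idx, f))
            splits.append((train, test))
    return splits


def _total_h2(fit: VarianceFit) -> float:
    denom = fit.total_genetic + fit.residual
    return fit.total_genetic / denom if denom > 0 else np.nan


def cross_validate(
    spec: ModelSpec,
    y,
    splits,
    model_id: str = "model",
    splits_seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> CVResult:
    """Refit REML per training fold, predict the test fold, record Pearson r.

    Folds whose training fit lands on a heritability boundary (total h2 at
    0 or 1, i.e. undetermined or over-estimated genomic variance) are
    discarded and counted in ``n_discarded``.
    """
    yv = np.asarray(getattr(y, "values", y), dtype=np.float64).ravel()
    accs, discarded = [], 0
    for train, test in splits:
        sub = spec.subset(train)
        fit = reml_fit(yv[train], sub, max_iter=max_iter, tol=tol)
        h2 = _total_h2(fit)
        if not np.isfinite(h2) or h2 <= H2_BOUNDARY_EPS or h2 >= 1 - H2_BOUNDARY_EPS:
            discarded += 1
            continue
        pred = predict_genomic_values(fit, spec, yv[train], train, test)
        obs = yv[test]
        if np.std(obs) == 0 or np.std(pred.total_genomic_value) == 0:
            discarded += 1
            continue
        accs.append(float(np.corrcoef(obs, pred.total_genomic_value)[0, 1]))
    if not accs:
        raise EmptyPanelError("every CV fold was discarded")
    return CVResult(model_id, np.array(accs), splits_seed, discarded)


def likelihood_ratio_test(loglik_full: float, loglik_null: float,
                          tolerance: float = 1e-6):
    """LR = 2 (l_full - l_null) against the 1/2 delta_0 + 1/2 chi2_1 mixture.

    The tested variance sits on the boundary of its parameter space, so the
    asymptotic null is the equal mixture of a point mass at zero and a
    chi-square with one degree of freedom; p = 1 at LR = 0.
    """
    if loglik_full < loglik_null - max(tolerance, 1e-12):
        raise DomainError(
            f"nesting violated: full loglik {loglik_full} < null {loglik_null}"
        )
    lr = max(2.0 * (loglik_full - loglik_null), 0.0)
    p = 1.0 if lr == 0.0 else 0.5 * float(stats.chi2.sf(lr, df=1))
    return lr, p


def compare_accuracy(cv_a: CVResult, cv_b: CVResult):
    """Medians, percent gain of a over b, and Wilcoxon-Mann-Whitney p.

    Exact enumeration is used when both samples have <= 12 values and no
    ties straddle the groups; otherwise the normal approximation with tie
    correction. The test is two-sided.
    """
    a, b = cv_a.fold_accuracies, cv_b.fold_accuracies
    if len(a) < 2 or len(b) < 2:
        raise DomainError("need >= 2 accuracies per sample")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    pct_gain = 100.0 * (med_a - med_b) / med_b if med_b > 0 else np.nan
    exact = (len(a) <= WILCOXON_EXACT_MAX and len(b) <= WILCOXON_EXACT_MAX
             and len(np.union1d(a, b)) == len(a) + len(b))
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return med_a, med_b, pct_gain, float(res.pvalue)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values over the full features x timepoints family."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def observed_scale_h2(fit: VarianceFit, grm: GRM) -> float:
    """Heritability on the accession scale: sigma_g^2 tr(G)/n over total.

    With fully inbred 0/2 coding the GRM diagonal averages ~2, so the
    model-scale component sigma_g^2 is about half the genetic variance per
    accession. This helper rescales by the mean GRM diagonal, making the
    estimate directly comparable with a simulated variance ratio
    var(g) / (var(g) + sigma_e^2).
    """
    gv = float(fit.components[0]) * float(np.mean(np.diag(grm.values)))
    denom = gv + fit.residual
    if denom <= 0:
        raise DomainError("all variance components are zero")
    return gv / denom


def heritabilities(fit: VarianceFit) -> dict:
    """h2 (single kinship) or hf2/h2 (feature + remainder) from a fit.

    For one kinship: h2 = sigma_g^2 / (sigma_g^2 + sigma_e^2). For two
    (feature first): hf2 = sigma_f^2 / (sigma_f^2 + sigma_r^2 + sigma_e^2),
    plus the total genomic h2 over all components.
    """
    total = fit.total_genetic + fit.residual
    if total <= 0:
        raise DomainError("all variance components are zero")
    out = {"h2": fit.total_genetic / total}
    if len(fit.components) >= 2:
        out["hf2"] = float(fit.components[0]) / total
    return out


# ---------------------------------------------------------------------------
# Feature scan
# ---------------------------------------------------------------------------

@dataclass
class FeatureScanRecord:
    feature_id: str
    timepoint: str
    hf2: float
    h2_gblup: float
    lr: float
    p_lrt: float
    median_r_gfblup: float
    median_r_gblup: float
    pct_gain: float
    p_wilcoxon: float
    q_fdr: float = np.nan
    n_genes: int = 0
    n_markers: int = 0
    component_correlation: float = np.nan
    n_discarded: int = 0
    informative: bool = False
    passed_filters: bool = False


def feature_scan(
    features,
    y_by_timepoint: dict,
    geno,
    splits,
    splits_seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> pd.DataFrame:
    """GFBLUP scan of every feature x timepoint against the GBLUP benchmark.

    Per record: full-data GFBLUP fit (hf2, LR vs the nested GBLUP fit and
    its mixture p-value), cross-validated accuracies on the shared splits,
    Wilcoxon comparison with the benchmark, BH-FDR over the whole scan, the
    Pearson correlation between the full-data feature and remainder BLUPs,
    and the filter flags. Features mapping to zero markers (or to all
    markers) are skipped with a report.
    """
    w = center_scale(geno)
    m = w.shape[1]
    g_all = compute_grm(w, geno.accession_ids, "ALL")

    baselines = {}
    for t, y in y_by_timepoint.items():
        yv = np.asarray(getattr(y, "values", y), dtype=np.float64).ravel()
        spec0 = ModelSpec([g_all])
        fit0 = reml_fit(yv, spec0, max_iter=max_iter, tol=tol)
        cv0 = cross_validate(spec0, yv, splits, "GBLUP", splits_seed,
                             max_iter=max_iter, tol=tol)
        baselines[t] = (yv, fit0, cv0)

    records = []
    n_skipped = 0
    for feat in features:
        if feat.n_markers == 0 or feat.n_markers >= m:
            n_skipped += 1
            continue
        g_f, g_r = partition_grm(geno, feat.marker_indices, feat.feature_id, w=w)
        spec_f = ModelSpec([g_f, g_r])
        for t, (yv, fit0, cv0) in baselines.items():
            try:
                fit_f = reml_fit(yv, spec_f, max_iter=max_iter, tol=tol)
                lr, p_lrt = likelihood_ratio_test(
                    fit_f.restricted_loglik, fit0.restricted_loglik
                )
                cv_f = cross_validate(spec_f, yv, splits, feat.feature_id,
                                      splits_seed, max_iter=max_iter, tol=tol)
                med_f, med_0, pct_gain, p_w = compare_accuracy(cv_f, cv0)
                blups = component_blups(fit_f, spec_f, yv)
                if np.std(blups[0]) > 0 and np.std(blups[1]) > 0:
                    comp_corr = float(np.corrcoef(blups[0], blups[1])[0, 1])
                else:
                    comp_corr = np.nan
            except GfblupError as exc:
                logger.warning("feature %s at %s failed: %s",
                               feat.feature_id, t, exc)
                continue
            h = heritabilities(fit_f)
            records.append(FeatureScanRecord(
                feature_id=feat.feature_id,
                timepoint=str(t),
                hf2=h.get("hf2", np.nan),
                h2_gblup=heritabilities(fit0)["h2"],
                lr=lr,
                p_lrt=p_lrt,
                median_r_gfblup=med_f,
                median_r_gblup=med_0,
                pct_gain=pct_gain,
                p_wilcoxon=p_w,
                n_genes=feat.n_genes,
                n_markers=feat.n_markers,
                component_correlation=comp_corr,
                n_discarded=cv_f.n_discarded,
            ))
    if n_skipped:
        logger.info("skipped %d feature(s) with 0 or all markers", n_skipped)
    if not records:
        raise EmptyPanelError("no feature produced a scan record")

    q = fdr_adjust([r.p_wilcoxon for r in records])
    for rec, qv in zip(records, q):
        rec.q_fdr = float(qv)
        direction = rec.median_r_gfblup > rec.median_r_gblup
        rec.informative = bool(rec.p_wilcoxon < 0.05 and direction)
        rec.passed_filters = bool(
            HF2_FILTER[0] < rec.hf2 < HF2_FILTER[1]
            and rec.p_lrt < 0.05
            and rec.p_wilcoxon < 0.05
            and direction
        )
    return pd.DataFrame([vars(r) for r in records])


def scan_summary(scan: pd.DataFrame) -> dict:
    """Scan-level associations: gain vs heritability and hf2 vs size/LR."""
    out = {}
    ok = scan[np.isfinite(scan["pct_gain"])]
    if len(ok) >= 3:
        out["cor_gain_h2"] = float(
            np.corrcoef(ok["pct_gain"], ok["h2_gblup"])[0, 1]
        ) if ok["h2_gblup"].std() > 0 else np.nan
        out["cor_hf2_ngenes"] = float(
            np.corrcoef(ok["hf2"], ok["n_genes"])[0, 1]
        ) if ok["n_genes"].std() > 0 else np.nan
        out["cor_hf2_lr"] = float(np.corrcoef(ok["hf2"], ok["lr"])[0, 1])
    return out


# ---------------------------------------------------------------------------
# Gene-set overlap and enrichment tests
# ---------------------------------------------------------------------------

def overlap_chisq(feature_genes, reference_genes, universe):
    """Chi-square (1 d.o.f., no continuity correction) on the 2x2 membership
    table (in/out feature x in/out reference) over ``universe``."""
    universe = set(universe)
    if not universe:
        raise DomainError("empty universe")
    f = set(feature_genes) & universe
    r = set(reference_genes) & universe
    a = len(f & r)
    b = len(f - r)
    c = len(r - f)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0:
        raise DomainError("empty table")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    if np.any(expected == 0):
        return 0.0, 1.0
    statistic = float(((table - expected) ** 2 / expected).sum())
    return statistic, float(stats.chi2.sf(statistic, df=1))


def fisher_enrichment(feature_genes, term_annotations: dict, universe):
    """One-sided Fisher exact enrichment per term, BH-FDR across terms.

    Returns a DataFrame (term, odds_ratio, p, q) sorted by p.
    """
    universe = set(universe)
    feature = set(feature_genes) & universe
    if not feature:
        raise DomainError("empty feature gene set")
    rows = []
    for term, genes in term_annotations.items():
        g = set(genes) & universe
        a = len(feature & g)
        b = len(feature - g)
        c = len(g - feature)
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((term, float(odds), float(p)))
    df = pd.DataFrame(rows, columns=["term", "odds_ratio", "p"])
    df["q"] = fdr_adjust(df["p"].to_numpy())
    return df.sort_values("p", ignore_index=True)
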