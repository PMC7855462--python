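"""Average-information REML for multi-kinship mixed models, and BLUP prediction.

The model is

    y = X b + sum_k u_k + e,     u_k ~ N(0, sigma_k^2 K_k),  e ~ N(0, sigma_e^2 I)

with V = sum_k sigma_k^2 K_k + sigma_e^2 I. One kinship gives GBLUP, a
feature/remainder pair gives GFBLUP, and M region kinships give MultiBLUP.
Variance components are estimated by maximizing the restricted
log-likelihood

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

with the average-information update: score_k = -1/2 [tr(P K_k) - y'P K_k P y],
AI_kl = 1/2 y'P K_k P K_l P y. A step that decreases l_R is halved (up to 10
times). Negative proposals are clamped to a small positive floor
(1e-8 x var(y)); a component stuck at the floor for 3 consecutive iterations
is fixed at 0 with a boundary flag and excluded from further updates.
Convergence is declared when the largest parameter change, on the scale of
the phenotypic variance, falls below ``tol``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
from scipy import stats

from .errors import DomainError, NumericalError, PartitionError
from .kinship import GRM
from .qc import GenotypeMatrix

logger = logging.getLogger(__name__)

#: variance floor, as a fraction of the phenotypic variance
FLOOR_FRACTION = 1e-8
#: consecutive floor hits after which a component is fixed at zero
FLOOR_PATIENCE = 3
#: maximum number of step halvings per iteration
MAX_HALVINGS = 10


@dataclass
class ModelSpec:
    """Kinships plus fixed-effect design; length-1 kinships = GBLUP."""

    kinships: list  # of GRM or (n, n) ndarray
    fixed_effects: np.ndarray | None = None  # defaults to intercept-only
    labels: list | None = None

    def kinship_values(self) -> list:
        return [k.values if isinstance(k, GRM) else np.asarray(k, float)
                for k in self.kinships]

    def design(self, n: int) -> np.ndarray:
        if self.fixed_effects is None:
            return np.ones((n, 1))
        x = np.asarray(self.fixed_effects, dtype=np.float64)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise DomainError("fixed-effects matrix is rank deficient")
        return x

    def subset(self, idx: np.ndarray) -> "ModelSpec":
        idx = np.asarray(idx)
        ks = [k[np.ix_(idx, idx)] for k in self.kinship_values()]
        x = None if self.fixed_effects is None \
            else np.asarray(self.fixed_effects)[idx]
        return ModelSpec(ks, x, self.labels)


@dataclass
class VarianceFit:
    """REML solution for one model on one phenotype vector."""

    components: np.ndarray  # one variance per kinship
    residual: float
    restricted_loglik: float
    converged: bool
    n_iterations: int
    boundary_flags: np.ndarray  # per kinship + residual, True = clamped at 0/floor
    beta: np.ndarray = field(default_factory=lambda: np.zeros(1))

    @property
    def total_genetic(self) -> float:
        return float(self.components.sum())


@dataclass
class Prediction:
    """Conditional genomic-value predictions for a test set."""

    accession_ids: np.ndarray
    per_component_values: np.ndarray  # (n_kinships, n_test)
    total_genomic_value: np.ndarray  # (n_test,)


def _as_y(y) -> np.ndarray:
    values = getattr(y, "values", y)
    arr = np.asarray(values, dtype=np.float64).ravel()
    if not np.all(np.isfinite(arr)):
        raise DomainError("phenotype vector contains non-finite values")
    return arr


def _loglik_and_terms(y, x, kinships, theta):
    """Restricted log-likelihood plus the quantities reused by the update."""
    n = len(y)
    v = theta[-1] * np.eye(n)
    for sig, k in zip(theta[:-1], kinships):
        v += sig * k
    try:
        c, low = sla.cho_factor(v, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - extreme inputs
        raise NumericalError(f"V is singular: {exc}")
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    vinv = sla.cho_solve((c, low), np.eye(n), check_finite=False)
    vinv_x = vinv @ x
    xtvix = x.T @ vinv_x
    sign, logdet_x = np.linalg.slogdet(xtvix)
    if sign <= 0:
        raise NumericalError("X'V^-1X not positive definite")
    xtvix_inv = np.linalg.inv(xtvix)
    p = vinv - vinv_x @ xtvix_inv @ vinv_x.T
    py = p @ y
    ll = -0.5 * (logdet_v + logdet_x + float(y @ py))
    beta = xtvix_inv @ (vinv_x.T @ y)
    return ll, p, py, beta


def reml_fit(
    y,
    spec: ModelSpec,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> VarianceFit:
    """AI-REML estimate of all variance components.

    Starts from an equal split of the phenotypic variance across all
    components (kinships + residual). Returns ``converged = False`` when the
    iteration budget runs out. Boundary components are fixed at zero and
    flagged; the remaining components keep updating.
    """
    y = _as_y(y)
    kinships = spec.kinship_values()
    n = len(y)
    for k in kinships:
        if k.shape != (n, n):
            raise DomainError("kinship dimension does not match phenotype length")
    x = spec.design(n)
    n_k = len(kinships)
    if n < n_k + 1 + x.shape[1]:
        raise DomainError("too few observations for the number of parameters")

    var_y = float(np.var(y, ddof=1))
    if var_y == 0.0:
        raise DomainError("phenotype has zero variance")
    floor = FLOOR_FRACTION * var_y
    # kinship diagonals differ from 1 (inbreds have diag ~2); normalize the
    # equal-split start so each component contributes ~var_y/(n_k+1)
    diag_means = np.array([np.mean(np.diag(k)) for k in kinships])
    diag_means[diag_means <= 0] = 1.0
    theta = np.empty(n_k + 1)
    theta[:-1] = var_y / (n_k + 1) / diag_means
    theta[-1] = var_y / (n_k + 1)

    active = np.ones(n_k + 1, dtype=bool)  # residual always active
    floor_streak = np.zeros(n_k + 1, dtype=int)
    flags = np.zeros(n_k + 1, dtype=bool)

    ll, p, py, beta = _loglik_and_terms(y, x, kinships, theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        act = np.where(active)[0]
        # score and AI over active parameters (residual kinship = I)
        pk_py = []  # K_j P y for active j
        score = np.empty(len(act))
        for a, j in enumerate(act):
            kj = kinships[j] if j < n_k else None
            kpy = kj @ py if kj is not None else py.copy()
            tr_pk = float((p * kj).sum()) if kj is not None else float(np.trace(p))
            score[a] = -0.5 * (tr_pk - float(py @ kpy))
            pk_py.append(kpy)
        ai = np.empty((len(act), len(act)))
        p_kpy = [p @ v for v in pk_py]
        for a in range(len(act)):
            for b in range(a, len(act)):
                ai[a, b] = ai[b, a] = 0.5 * float(pk_py[a] @ p_kpy[b])
        try:
            delta = np.linalg.solve(ai + 1e-12 * np.eye(len(act)), score)
        except np.linalg.LinAlgError:
            delta = score / (np.diag(ai) + 1e-12)
        # EM-REML update as a guaranteed-ascent fallback direction
        em_delta = np.array([
            theta[j] ** 2 * (float(py @ kpy) - (
                float((p * kinships[j]).sum()) if j < n_k else float(np.trace(p))
            )) / n
            for j, kpy in zip(act, pk_py)
        ])

        # step-halving line search on the restricted log-likelihood
        step = 1.0
        accepted = False
        full_step = False
        for attempt in range(MAX_HALVINGS + 1):
            proposal = theta.copy()
            proposal[act] = np.maximum(theta[act] + step * delta, floor)
            proposal[~active] = 0.0
            proposal[-1] = max(proposal[-1], floor)
            try:
                ll_new, p_new, py_new, beta_new = _loglik_and_terms(
                    y, x, kinships, proposal
                )
            except NumericalError:
                step *= 0.5
                continue
            if ll_new >= ll - 1e-10:
                accepted = True
                full_step = attempt == 0
                break
            step *= 0.5
        if not accepted:
            # AI direction failed entirely: try one EM step instead
            proposal = theta.copy()
            proposal[act] = np.maximum(theta[act] + em_delta, floor)
            proposal[-1] = max(proposal[-1], floor)
            try:
                ll_new, p_new, py_new, beta_new = _loglik_and_terms(
                    y, x, kinships, proposal
                )
                accepted = ll_new >= ll - 1e-10
            except NumericalError:
                accepted = False
            if not accepted:
                break  # no improving step in any direction: at the optimum

        change = np.max(np.abs(proposal - theta)) / var_y
        theta, ll, p, py, beta = proposal, ll_new, p_new, py_new, beta_new

        # boundary bookkeeping: genetic components stuck at the floor -> 0
        for j in range(n_k):
            if active[j] and theta[j] <= floor * (1 + 1e-9):
                floor_streak[j] += 1
                if floor_streak[j] >= FLOOR_PATIENCE:
                    active[j] = False
                    flags[j] = True
                    theta[j] = 0.0
                    ll, p, py, beta = _loglik_and_terms(y, x, kinships, theta)
            else:
                floor_streak[j] = 0
        flags[-1] = theta[-1] <= floor * (1 + 1e-9)

        if change < tol and full_step:
            converged = True
            break

    if not converged:
        logger.debug("AI-REML stopped without meeting tol after %d iterations", it)
        # a fit that stopped because no step improves the likelihood is at a
        # (possibly boundary) optimum; report it as converged
        converged = it < max_iter

    # final boundary normalization: a component at the floor is statistically
    # zero; report it as exactly 0 and recompute the solution without it
    comp = theta[:-1].copy()
    at_floor = comp <= floor * (1 + 1e-9)
    if at_floor.any():
        flags[:-1] |= at_floor
        comp[at_floor] = 0.0
        theta = np.append(comp, max(theta[-1], floor))
        ll, _, _, beta = _loglik_and_terms(y, x, kinships, theta)
    return VarianceFit(
        components=comp,
        residual=float(theta[-1]),
        restricted_loglik=float(ll),
        converged=bool(converged),
        n_iterations=it,
        boundary_flags=flags,
        beta=beta,
    )


def predict_genomic_values(
    fit: VarianceFit,
    spec: ModelSpec,
    y_train,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    accession_ids: np.ndarray | None = None,
) -> Prediction:
    """Predict test genomic values conditional on the training phenotypes.

    For each component k:
        g_k(test) = sigma_k^2 K_k[test, train] V_train^-1 (y_train - X b),
    with V_train built from the fitted variances on the training block.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise PartitionError("train and test sets overlap")
    y_train = _as_y(y_train)
    kinships = spec.kinship_values()
    n_tr = len(train_idx)
    x_full = spec.design(kinships[0].shape[0]) if spec.fixed_effects is not None \
        else np.ones((kinships[0].shape[0], 1))
    x_tr = x_full[train_idx]

    v = fit.residual * np.eye(n_tr)
    for sig, k in zip(fit.components, kinships):
        v += sig * k[np.ix_(train_idx, train_idx)]
    try:
        c = sla.cho_factor(v, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"training V is singular: {exc}")
    resid = y_train - x_tr @ fit.beta
    alpha = sla.cho_solve(c, resid, check_finite=False)

    per_comp = np.vstack([
        sig * (k[np.ix_(test_idx, train_idx)] @ alpha)
        for sig, k in zip(fit.components, kinships)
    ])
    ids = (np.asarray(accession_ids)[test_idx]
           if accession_ids is not None else test_idx.astype(str))
    return Prediction(ids, per_comp, per_comp.sum(axis=0))


def component_blups(fit: VarianceFit, spec: ModelSpec, y) -> np.ndarray:
    """Full-data BLUPs of every component: u_k = sigma_k^2 K_k V^-1 (y - X b)."""
    y = _as_y(y)
    kinships = spec.kinship_values()
    n = len(y)
    x = spec.design(n)
    v = fit.residual * np.eye(n)
    for sig, k in zip(fit.components, kinships):
        v += sig * k
    c = sla.cho_factor(v, lower=True, check_finite=False)
    alpha = sla.cho_solve(c, y - x @ fit.beta, check_finite=False)
    return np.vstack([sig * (k @ alpha) for sig, k in zip(fit.components, kinships)])


# ---------------------------------------------------------------------------
# Adaptive MultiBLUP region selection
# ---------------------------------------------------------------------------

@dataclass
class RegionSelection:
    """Marker groups chosen by the adaptive region scan."""

    groups: list  # list of np.ndarray of marker indices
    background: np.ndarray | None  # complement markers, None when fallback
    fallback_all: bool  # True when no window was significant


def _window_starts(length: int, window_bp: int, step: int) -> list:
    starts = []
    s = 1
    while s <= max(length - step, 1):
        starts.append(s)
        if s + window_bp - 1 >= length and len(starts) > 0 and length <= window_bp:
            break
        s += step
    return starts or [1]


def _group_ftest(y: np.ndarray, w: np.ndarray) -> float:
    """F-test p-value of the joint OLS regression of y on centered markers."""
    n = len(y)
    wc = w - w.mean(axis=0)
    keep = wc.std(axis=0) > 0
    wc = wc[:, keep]
    if wc.shape[1] == 0:
        return 1.0
    yc = y - y.mean()
    beta, _, rank, _ = np.linalg.lstsq(wc, yc, rcond=None)
    q = int(rank)
    df2 = n - q - 1
    if q == 0 or df2 <= 0:
        return 1.0
    rss1 = float(((yc - wc @ beta) ** 2).sum())
    rss0 = float((yc ** 2).sum())
    if rss1 <= 0:
        return 0.0
    f = ((rss0 - rss1) / q) / (rss1 / df2)
    return float(stats.f.sf(f, q, df2))


def multiblup_select_regions(
    g: GenotypeMatrix,
    y,
    window_bp: int = 10_000,
    overlap: float = 0.5,
    p_enter: float = 1e-5,
    p_merge_bonferroni: float = 0.05,
) -> RegionSelection:
    """Adaptive selection of region kinship groups.

    Each chromosome is tiled into windows of ``window_bp`` stepping
    ``window_bp * (1 - overlap)``. Every window's markers are jointly tested
    against the phenotype (OLS F-test); windows with p < ``p_enter`` seed
    regions, and runs of adjacent/overlapping significant windows are merged
    when the merged region's Bonferroni-adjusted p (multiplier = number of
    windows tested genome-wide) stays below ``p_merge_bonferroni``. Returns
    the region groups plus the complement background group, or the
    all-marker group when nothing is significant.
    """
    if window_bp <= 0:
        raise DomainError("window_bp must be positive")
    if not 0.0 <= overlap < 1.0:
        raise DomainError("overlap must lie in [0, 1)")
    y = _as_y(y)
    if len(y) != g.n_accessions:
        raise DomainError("phenotype length does not match accession count")
    step = max(int(round(window_bp * (1.0 - overlap))), 1)
    calls = g.calls.astype(np.float64)

    windows = []  # (chrom, start, end, marker_idx, p)
    n_windows = 0
    for ch in np.unique(g.chrom):
        cidx = np.where(g.chrom == ch)[0]
        cpos = g.pos[cidx]
        length = int(cpos.max())
        for s in _window_starts(length, window_bp, step):
            e = s + window_bp - 1
            lo = np.searchsorted(cpos, s, side="left")
            hi = np.searchsorted(cpos, e, side="right")
            midx = cidx[lo:hi]
            n_windows += 1
            if midx.size == 0:
                continue
            p = _group_ftest(y, calls[:, midx])
            windows.append((ch, s, e, midx, p))

    sig = [wdw for wdw in windows if wdw[4] < p_enter]
    if not sig:
        return RegionSelection(
            groups=[np.arange(g.n_markers)], background=None, fallback_all=True
        )

    # merge runs of overlapping/adjacent significant windows per chromosome
    groups: list = []
    sig.sort(key=lambda wdw: (wdw[0], wdw[1]))
    run = [sig[0]]
    for wdw in sig[1:]:
        same_chrom = wdw[0] == run[-1][0]
        adjacent = same_chrom and wdw[1] <= run[-1][2] + 1
        if adjacent:
            run.append(wdw)
        else:
            groups.extend(_finalize_run(run, y, calls, n_windows, p_merge_bonferroni))
            run = [wdw]
    groups.extend(_finalize_run(run, y, calls, n_windows, p_merge_bonferroni))

    selected = np.unique(np.concatenate(groups))
    background = np.setdiff1d(np.arange(g.n_markers), selected)
    return RegionSelection(groups=groups, background=background, fallback_all=False)


def _finalize_run(run, y, calls, n_windows, p_merge_bonferroni):
    """Merge a run of adjacent significant windows if the joint test allows."""
    if len(run) == 1:
        return [run[0][3]]
    merged = np.unique(np.concatenate([wdw[3] for wdw in run]))
    p_joint = _group_ftest(y, calls[:, merged])
    if p_joint * n_windows < p_merge_bonferroni:
        return [merged]
    return [wdw[3] for wdw in run]
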