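"""Admixture likelihood machinery: cluster allele frequencies, supervised
single-query ancestry estimation, locus-bootstrap standard errors, and
unsupervised joint estimation.

Model
-----
Each individual carries an ancestry vector ``q`` on the K-simplex; reference
cluster *k* is characterised by allele-B frequencies ``f_k`` over L unlinked
loci.  Genotypes are binomial: ``g_l ~ Binomial(2, pi_l)`` with
``pi_l = sum_k q_k f_kl``.  The log-likelihood of one individual is

    l(q, F) = sum_l [ log C(2, g_l) + g_l log(pi_l) + (2 - g_l) log(1 - pi_l) ]

with missing loci contributing zero.  Estimation is by EM; in *supervised*
mode reference members have their ``q`` pinned to unit vectors and only the
query's ``q`` (and, in ``joint`` mode, F) is free.  Standard errors come from
bootstrap resampling of loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from feralmix.genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: allele-frequency clamp applied everywhere a frequency is produced
EPS = 1e-6

_LOG2 = float(np.log(2.0))


@dataclass
class ReferencePanel:
    """A genotype matrix with a sample -> reference-cluster assignment.

    ``frequencies`` optionally carries the true (simulated) or previously
    estimated K x L cluster allele-frequency matrix, ordered by
    ``cluster_ids``.
    """

    genotypes: GenotypeMatrix
    cluster_of: dict[str, str]
    frequencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.genotypes.sample_ids if s not in self.cluster_of]
        if missing:
            raise ValueError(f"samples without cluster assignment: {missing[:5]}")

    @property
    def cluster_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid in self.genotypes.sample_ids:
            seen.setdefault(self.cluster_of[sid], None)
        return list(seen)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def membership_matrix(self) -> np.ndarray:
        """Boolean K x n_samples cluster membership, ordered by cluster_ids."""
        cl = self.cluster_ids
        idx = {c: k for k, c in enumerate(cl)}
        out = np.zeros((len(cl), self.genotypes.n_samples), dtype=bool)
        for i, sid in enumerate(self.genotypes.sample_ids):
            out[idx[self.cluster_of[sid]], i] = True
        return out


@dataclass
class AlleleFrequencyModel:
    """Per-cluster allele-B frequencies with observation counts."""

    cluster_ids: list[str]
    frequencies: np.ndarray  # K x L, clamped to [EPS, 1-EPS]
    counts: np.ndarray  # K x L observed allele totals (2 * called genotypes)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def n_markers(self) -> int:
        return self.frequencies.shape[1]


@dataclass
class AncestryEstimate:
    """Supervised ancestry result for one query sample."""

    sample_id: str
    cluster_ids: list[str]
    q: np.ndarray
    se: np.ndarray | None = None
    significant: np.ndarray | None = None
    n_boot: int = 0
    n_boot_failed: int = 0
    loglik: float = float("nan")
    iterations: int = 0
    converged: bool = False
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _clamp(f: np.ndarray) -> np.ndarray:
    return np.clip(f, EPS, 1.0 - EPS)


def estimate_cluster_frequencies(
    panel: ReferencePanel, pseudocount: float = 0.5
) -> AlleleFrequencyModel:
    """Empirical allele-B frequencies per reference cluster.

    ``f_kl = (allele-B count + pseudocount) / (2 n_observed + 2 pseudocount)``
    with missing genotypes excluded from the counts; the default pseudocount
    0.5 is a Jeffreys-style shrinkage toward 1/2 that keeps rare-allele
    frequencies off the boundary.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    g = panel.genotypes
    member = panel.membership_matrix()
    if not member.any(axis=1).all():
        empty = [c for c, row in zip(panel.cluster_ids, member) if not row.any()]
        raise ValueError(f"empty reference cluster(s): {empty}")
    obs = g.observed_mask()
    d = np.where(obs, g.dosage, 0).astype(np.float64)
    b_counts = member.astype(np.float64) @ d  # K x L
    totals = 2.0 * (member.astype(np.float64) @ obs.astype(np.float64))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (b_counts + pseudocount) / (totals + 2.0 * pseudocount)
    if pseudocount == 0:
        f = np.where(totals > 0, f, 0.5)
    return AlleleFrequencyModel(
        cluster_ids=panel.cluster_ids, frequencies=_clamp(f), counts=totals
    )


def log_likelihood(
    q: np.ndarray, frequencies: np.ndarray, genotypes: np.ndarray
) -> float:
    """Exact admixture binomial log-likelihood.

    Accepts a single individual (``q`` length K, ``genotypes`` length L) or a
    batch (``q`` n x K, ``genotypes`` n x L).  Missing entries contribute 0.
    """
    q = np.asarray(q, dtype=np.float64)
    F = np.asarray(frequencies, dtype=np.float64)
    g = np.asarray(genotypes)
    if np.any(F <= 0.0) or np.any(F >= 1.0):
        raise ValueError("frequencies must lie strictly inside (0, 1)")
    squeeze = q.ndim == 1
    Q = np.atleast_2d(q)
    G = np.atleast_2d(g)
    obs = G != MISSING
    gd = np.where(obs, G, 0).astype(np.float64)
    P = Q @ F
    ll = np.where(obs, gd * np.log(P) + (2.0 - gd) * np.log1p(-P), 0.0)
    ll += np.where(obs & (G == 1), _LOG2, 0.0)
    total = float(ll.sum())
    del squeeze
    return total


# ---------------------------------------------------------------------------
# supervised estimation
# ---------------------------------------------------------------------------

def _reference_counts(panel: ReferencePanel) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-cluster allele-B counts and allele totals (no pseudocount)."""
    g = panel.genotypes
    member = panel.membership_matrix().astype(np.float64)
    obs = g.observed_mask()
    d = np.where(obs, g.dosage, 0).astype(np.float64)
    return member @ d, 2.0 * (member @ obs.astype(np.float64))


def _em_supervised(
    g: np.ndarray,
    ref_b: np.ndarray,
    ref_n: np.ndarray,
    mode: str,
    pseudocount: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """EM on one query given fixed reference cluster memberships.

    ``ref_b``/``ref_n`` are K x L reference allele-B counts and allele totals;
    in joint mode F is re-estimated each sweep from reference counts plus the
    query's expected allele assignments, in fixed_frequencies mode F stays at
    the pseudocount estimate.  Returns (q, F, loglik_trace, converged); the
    trace is of the EM objective (query + reference log-likelihood in joint
    mode, query log-likelihood in fixed mode).
    """
    K, L = ref_b.shape
    obs = g != MISSING
    L_obs = int(obs.sum())
    if L_obs == 0:
        raise ValueError("query has no observed genotypes at shared markers")
    gd = np.where(obs, g, 0).astype(np.float64)

    F = _clamp((ref_b + pseudocount) / (ref_n + 2.0 * pseudocount))
    q = np.full(K, 1.0 / K)

    # reference log-likelihood terms only matter for the joint-mode objective;
    # each reference member is a pure draw from its own cluster
    def ref_loglik(Fc: np.ndarray) -> float:
        with np.errstate(invalid="ignore"):
            t = ref_b * np.log(Fc) + (ref_n - ref_b) * np.log1p(-Fc)
        return float(np.where(ref_n > 0, t, 0.0).sum())

    def query_loglik(qc: np.ndarray, Fc: np.ndarray) -> float:
        p = qc @ Fc
        return float(
            np.where(obs, gd * np.log(p) + (2.0 - gd) * np.log1p(-p), 0.0).sum()
        )

    def step(qc: np.ndarray, Fc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One EM step: E-step from (q, F), M-step for q (and F in joint)."""
        p = qc @ Fc
        with np.errstate(invalid="ignore", divide="ignore"):
            wb = np.where(obs, gd / p, 0.0)  # L
            wa = np.where(obs, (2.0 - gd) / (1.0 - p), 0.0)
        eb = qc[:, None] * Fc * wb[None, :]  # K x L expected B copies from k
        ea = qc[:, None] * (1.0 - Fc) * wa[None, :]
        qn = (eb + ea).sum(axis=1) / (2.0 * L_obs)
        qn = qn / qn.sum()
        Fn = _clamp((ref_b + eb) / (ref_n + eb + ea)) if mode == "joint" else Fc
        return qn, Fn

    def objective(qc: np.ndarray, Fc: np.ndarray) -> float:
        return query_loglik(qc, Fc) + (ref_loglik(Fc) if mode == "joint" else 0.0)

    trace = []
    converged = False
    it = 0
    while it < max_iter:
        # squared-extrapolation cycle built from two plain EM steps, with a
        # fallback to the plain result so the recorded objective trace is
        # non-decreasing either way
        q1, F1 = step(q, F)
        q2, F2 = step(q1, F1)
        it += 2
        rq, rF = q1 - q, F1 - F
        vq, vF = (q2 - q1) - rq, (F2 - F1) - rF
        v2 = float((vq**2).sum() + (vF**2).sum())
        accepted = False
        if v2 > 0:
            r2 = float((rq**2).sum() + (rF**2).sum())
            alpha = -max(1.0, np.sqrt(r2 / v2))
            qx = np.clip(q - 2.0 * alpha * rq + alpha**2 * vq, 1e-12, None)
            qx = qx / qx.sum()
            Fx = _clamp(F - 2.0 * alpha * rF + alpha**2 * vF)
            qx, Fx = step(qx, Fx)
            it += 1
            ox = objective(qx, Fx)
            if np.isfinite(ox) and ox >= objective(q2, F2):
                q, F, obj = qx, Fx, ox
                accepted = True
        if not accepted:
            q, F = q2, F2
            obj = objective(q, F)
        trace.append(obj)
        if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
            converged = True
            break
    if not np.isfinite(trace[-1]):
        raise ValueError("non-finite likelihood during supervised EM")
    return q, F, np.asarray(trace), converged


def supervised_query(
    query: np.ndarray,
    panel: ReferencePanel,
    mode: str = "joint",
    tol: float = 1e-6,
    max_iter: int = 2000,
    pseudocount: float = 0.5,
    sample_id: str = "query",
) -> AncestryEstimate:
    """Estimate one query sample's ancestry against the reference clusters.

    Reference members are pinned to their clusters (unit ancestry vectors);
    the query's ``q`` is maximised by EM from a uniform start.  In ``joint``
    mode the cluster frequencies F are co-estimated from reference members
    plus the query, mirroring supervised analyses that use both the reference
    clusters and the sample being analysed; ``fixed_frequencies`` holds F at
    the empirical cluster estimate and is the fast path.
    """
    if mode not in ("joint", "fixed_frequencies"):
        raise ValueError(f"unknown mode {mode!r}")
    if panel.n_clusters < 2:
        raise ValueError("supervised query needs K >= 2 reference clusters")
    query = np.asarray(query)
    if query.shape != (panel.genotypes.n_markers,):
        raise ValueError("query length does not match panel marker count")
    ref_b, ref_n = _reference_counts(panel)
    q, F, trace, converged = _em_supervised(
        query, ref_b, ref_n, mode, pseudocount, tol, max_iter
    )
    obs = query != MISSING
    gd = np.where(obs, query, 0).astype(np.float64)
    p = q @ F
    ll = float(
        np.where(
            obs,
            gd * np.log(p) + (2.0 - gd) * np.log1p(-p) + (query == 1) * _LOG2,
            0.0,
        ).sum()
    )
    return AncestryEstimate(
        sample_id=sample_id,
        cluster_ids=panel.cluster_ids,
        q=q,
        loglik=ll,
        iterations=len(trace),
        converged=converged,
        loglik_trace=trace,
    )


def bootstrap_standard_errors(
    query: np.ndarray,
    panel: ReferencePanel,
    n_boot: int = 100,
    seed: int | None = None,
    significance_multiplier: float = 1.0,
    mode: str = "joint",
    tol: float = 1e-6,
    max_iter: int = 2000,
    pseudocount: float = 0.5,
    sample_id: str = "query",
) -> AncestryEstimate:
    """Supervised ancestry with locus-bootstrap standard errors.

    Loci are resampled uniformly with replacement ``n_boot`` times (default
    100) and the supervised EM rerun on each replicate; ``se_k`` is the SD of
    ``q_k`` across replicates.  The reported point estimate is the full-data
    fit.  Cluster *k* is flagged significant when
    ``q_k - significance_multiplier * se_k > 0`` — the "standard error does
    not overlap zero" rule, read literally at one SE (multiplier
    configurable).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    est = supervised_query(
        query, panel, mode=mode, tol=tol, max_iter=max_iter,
        pseudocount=pseudocount, sample_id=sample_id,
    )
    query = np.asarray(query)
    ref_b, ref_n = _reference_counts(panel)
    L = query.shape[0]
    rng = np.random.default_rng(seed)
    reps = []
    failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, L, size=L)
        try:
            qb, _, _, conv = _em_supervised(
                query[idx], ref_b[:, idx], ref_n[:, idx],
                mode, pseudocount, tol, max_iter,
            )
        except ValueError:
            failed += 1
            continue
        if not conv:
            failed += 1
            continue
        reps.append(qb)
    if len(reps) < 2:
        raise ValueError("fewer than 2 successful bootstrap replicates")
    R = np.vstack(reps)
    se = R.std(axis=0, ddof=1)
    est.se = se
    est.significant = (est.q - significance_multiplier * se) > 0.0
    est.n_boot = len(reps)
    est.n_boot_failed = failed
    return est


# ---------------------------------------------------------------------------
# unsupervised estimation
# ---------------------------------------------------------------------------

def unsupervised_fit(
    g: GenotypeMatrix | np.ndarray,
    K: int,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 3,
    accelerate: bool = True,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Joint EM estimation of all samples' ancestry Q and frequencies F.

    Q rows are initialised from seeded Dirichlet(1) draws; the best of
    ``n_restarts`` runs by log-likelihood is returned as
    ``(Q, F, loglik, loglik_trace)``.  With ``accelerate`` (default) each
    cycle applies a squared-extrapolation (SQUAREM-style) step built from
    two plain EM sweeps, falling back to the plain step whenever the
    extrapolation does not improve the likelihood — so the recorded
    log-likelihood trace is non-decreasing either way.
    """
    dosage = g.dosage if isinstance(g, GenotypeMatrix) else np.asarray(g)
    n, L = dosage.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds n_samples={n}")
    obs = dosage != MISSING
    gd = np.where(obs, dosage, 0).astype(np.float64)
    L_obs = obs.sum(axis=1).astype(np.float64)
    if np.any(L_obs == 0):
        raise ValueError("a sample has no observed genotypes")

    def sweep(Q: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """One EM sweep: E-step responsibilities, M-step for Q and F."""
        P = Q @ F
        with np.errstate(invalid="ignore", divide="ignore"):
            Wb = np.where(obs, gd / P, 0.0)
            Wa = np.where(obs, (2.0 - gd) / (1.0 - P), 0.0)
        Qn = np.empty_like(Q)
        Fn = np.empty_like(F)
        for k in range(K):
            eb = Q[:, k][:, None] * F[k][None, :] * Wb  # n x L
            ea = Q[:, k][:, None] * (1.0 - F[k])[None, :] * Wa
            Qn[:, k] = (eb + ea).sum(axis=1) / (2.0 * L_obs)
            num = eb.sum(axis=0)
            den = (eb + ea).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                Fn[k] = np.where(den > 0, num / den, 0.5)
        Qn = Qn / Qn.sum(axis=1, keepdims=True)
        return Qn, _clamp(Fn)

    def project(Q: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Q = np.clip(Q, 1e-12, None)
        return Q / Q.sum(axis=1, keepdims=True), _clamp(F)

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float, np.ndarray] | None = None
    for _ in range(max(1, n_restarts)):
        Q = rng.dirichlet(np.ones(K), size=n)
        # initial F from responsibility-weighted counts under the random Q
        F = _clamp((Q.T @ gd + 0.5) / (2.0 * (Q.T @ obs.astype(np.float64)) + 1.0))
        trace: list[float] = []
        it = 0
        while it < max_iter:
            if not accelerate:
                Q, F = sweep(Q, F)
                it += 1
            else:
                Q1, F1 = sweep(Q, F)
                Q2, F2 = sweep(Q1, F1)
                it += 2
                rQ, rF = Q1 - Q, F1 - F
                vQ, vF = (Q2 - Q1) - rQ, (F2 - F1) - rF
                r2 = float((rQ**2).sum() + (rF**2).sum())
                v2 = float((vQ**2).sum() + (vF**2).sum())
                if v2 > 0:
                    alpha = -max(1.0, np.sqrt(r2 / v2))
                    Qx, Fx = project(
                        Q - 2.0 * alpha * rQ + alpha**2 * vQ,
                        F - 2.0 * alpha * rF + alpha**2 * vF,
                    )
                    # stabilise with one EM sweep from the extrapolated point
                    Qx, Fx = sweep(Qx, Fx)
                    it += 1
                    llx = log_likelihood(Qx, Fx, dosage)
                    ll2 = log_likelihood(Q2, F2, dosage)
                    if np.isfinite(llx) and llx >= ll2:
                        Q, F = Qx, Fx
                    else:
                        Q, F = Q2, F2
                else:
                    Q, F = Q2, F2
            ll = log_likelihood(Q, F, dosage)
            trace.append(ll)
            if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
                break
        run = (Q, F, trace[-1], np.asarray(trace))
        if best is None or run[2] > best[2]:
            best = run
    assert best is not None
    return best
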