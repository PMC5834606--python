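"""Admixture-proportion (ancestry) estimation and threshold classification.

Two estimators of per-sample membership coefficients q:

* a supervised maximum-likelihood estimator for K = 2 given fixed reference
  allele frequencies for the two parental lineages (the dosage at each locus
  is binomial in the mixture frequency q*p_HOL + (1-q)*p_CAL, which makes
  the log-likelihood concave in q — it is maximised exactly by bisection on
  its derivative);
* an unsupervised EM for the admixture likelihood with uncorrelated cluster
  frequencies (ADMIXTURE-style) for small K, with seeded restarts and
  optional label alignment to reference panels by frequency correlation.

Classification follows the 0.7/0.3 membership-coefficient rule: a sample is
assigned to a lineage iff that lineage's coefficient is >= 0.7, otherwise it
is ADMIXED.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .popio import GenotypeMatrix

ADMIXED = "ADMIXED"
PURE_THRESHOLD = 0.7


class AncestryError(ValueError):
    pass


@dataclasses.dataclass
class AncestryEstimate:
    """Per-sample ancestry proportions over K clusters."""

    samples: list[str]
    q: np.ndarray               # (n_samples, K), rows sum to 1
    log_likelihood: float
    n_loci: int
    converged: bool
    iterations: int
    cluster_labels: list[str] | None = None
    cluster_freqs: np.ndarray | None = None  # (K, n_loci), EM only


def _loglik_terms(dos, plo, mix):
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = dos * np.log(mix) + (plo - dos) * np.log1p(-mix)
    return ll


def supervised_q_batch(
    dosage: np.ndarray,
    ploidy: np.ndarray,
    p_cal: np.ndarray,
    p_hol: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> np.ndarray:
    """Maximum-likelihood q_HOL for each row of a dosage matrix.

    Missing dosages (< 0) and loci with a missing reference frequency are
    dropped per sample. Raises when every usable locus is uninformative
    (p_CAL == p_HOL everywhere).
    """
    dos = np.asarray(dosage, dtype=float)
    plo = np.asarray(ploidy, dtype=float)
    if dos.ndim == 1:
        dos = dos[None, :]
        plo = plo[None, :]
    ok_ref = np.isfinite(p_cal) & np.isfinite(p_hol)
    diff = np.where(ok_ref, p_hol - p_cal, 0.0)
    obs = (dos >= 0) & ok_ref[None, :]
    informative = obs & (np.abs(diff)[None, :] > 0)
    if np.any(informative.sum(axis=1) == 0):
        raise AncestryError("flat likelihood: no informative loci for some sample")
    # clip frequencies away from {0,1} so fixed loci keep a finite likelihood
    eps = 1e-9
    pc = np.clip(np.where(ok_ref, p_cal, 0.5), eps, 1 - eps)
    ph = np.clip(np.where(ok_ref, p_hol, 0.5), eps, 1 - eps)
    dcl = ph - pc

    def dll(q):
        """Derivative of the log-likelihood wrt q, per sample (vectorised)."""
        mix = pc[None, :] + q[:, None] * dcl[None, :]
        term = dcl[None, :] * (dos / mix - (plo - dos) / (1.0 - mix))
        return np.where(obs, term, 0.0).sum(axis=1)

    n = dos.shape[0]
    lo = np.zeros(n)
    hi = np.ones(n)
    d_lo = dll(lo)
    d_hi = dll(hi)
    # concave log-likelihood: boundary optima where the derivative never crosses 0
    at_lo = d_lo <= 0
    at_hi = d_hi >= 0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d_mid = dll(mid)
        go_up = d_mid > 0
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
        if np.all(hi - lo < tol):
            break
    q = 0.5 * (lo + hi)
    q[at_lo] = 0.0
    q[at_hi] = 1.0
    return q


def supervised_q(
    G: GenotypeMatrix,
    sample: str,
    ref_freqs_cal: np.ndarray,
    ref_freqs_hol: np.ndarray,
) -> AncestryEstimate:
    """Supervised K = 2 ancestry for one sample; q columns are (CAL, HOL)."""
    i = G.sample_index([sample])[0]
    q_hol = supervised_q_batch(
        G.dosage[i], G.ploidy[i], ref_freqs_cal, ref_freqs_hol
    )[0]
    dos = G.dosage[i].astype(float)
    plo = G.ploidy[i].astype(float)
    ok = (dos >= 0) & np.isfinite(ref_freqs_cal) & np.isfinite(ref_freqs_hol)
    eps = 1e-9
    mix = np.clip(
        (1 - q_hol) * ref_freqs_cal + q_hol * ref_freqs_hol, eps, 1 - eps
    )
    ll = float(np.where(ok, _loglik_terms(dos, plo, mix), 0.0).sum())
    return AncestryEstimate(
        samples=[sample],
        q=np.array([[1.0 - q_hol, q_hol]]),
        log_likelihood=ll,
        n_loci=int(ok.sum()),
        converged=True,
        iterations=0,
        cluster_labels=["CAL", "HOL"],
    )


def _em_loglik(dos, plo, obs, Q, P):
    eps = 1e-12
    mix = np.clip(Q @ P, eps, 1 - eps)
    return float(np.where(obs, _loglik_terms(dos, plo, mix), 0.0).sum())


def em_admixture(
    G: GenotypeMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    n_restarts: int = 5,
    ref_freqs: dict[str, np.ndarray] | None = None,
) -> AncestryEstimate:
    """Unsupervised EM on the admixture likelihood (uncorrelated frequencies).

    Runs ``n_restarts`` seeded restarts and keeps the best log-likelihood
    (ties broken by restart order). Loci monomorphic across all samples are
    dropped before EM. The log-likelihood is non-decreasing across
    iterations (EM guarantee; asserted in tests). When ``ref_freqs`` maps
    lineage labels to reference frequency vectors (over the original loci),
    clusters are labelled by best frequency correlation.
    """
    if K < 1:
        raise AncestryError("K must be >= 1")
    dos_all = G.dosage.astype(float)
    plo_all = G.ploidy.astype(float)
    obs_all = dos_all >= 0
    # drop monomorphic loci
    alt = np.where(obs_all, dos_all, 0.0).sum(axis=0)
    tot = np.where(obs_all, plo_all, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pbar = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    poly = np.isfinite(pbar) & (pbar > 0) & (pbar < 1)
    if not poly.any():
        raise AncestryError("no polymorphic loci")
    dos = dos_all[:, poly]
    plo = plo_all[:, poly]
    obs = obs_all[:, poly]
    dos_f = np.where(obs, dos, 0.0)
    ref_f = np.where(obs, plo - dos, 0.0)
    plo_tot = np.where(obs, plo, 0.0).sum(axis=1)
    n, m = dos.shape

    if K == 1:
        Q = np.ones((n, 1))
        P = pbar[poly][None, :]
        ll = _em_loglik(dos, plo, obs, Q, P)
        full_P = np.full((1, G.n_loci), np.nan)
        full_P[0, poly] = P[0]
        return AncestryEstimate(
            samples=list(G.samples), q=Q, log_likelihood=ll, n_loci=int(poly.sum()),
            converged=True, iterations=0, cluster_freqs=full_P,
        )

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng([int(seed) % (2**31), 17, r])
        Q = rng.dirichlet(np.ones(K), size=n)
        P = np.clip(
            pbar[poly][None, :] + rng.normal(0, 0.1, size=(K, m)), 0.01, 0.99
        )
        prev_ll = -np.inf
        converged = False
        it = 0
        eps = 1e-12
        for it in range(1, max_iter + 1):
            mix = np.clip(Q @ P, eps, 1 - eps)        # (n, m)
            cmix = 1.0 - mix
            # E-step responsibilities, accumulated as expected allele counts
            # alt copies: weight_k = Q_ik P_kl / mix ; ref copies analogous
            A = np.zeros((n, K))  # expected ancestry copies per sample/cluster
            alt_k = np.zeros((K, m))
            tot_k = np.zeros((K, m))
            for k in range(K):
                w_alt = Q[:, k : k + 1] * P[k][None, :] / mix
                w_ref = Q[:, k : k + 1] * (1.0 - P[k][None, :]) / cmix
                e_alt = dos_f * w_alt
                e_ref = ref_f * w_ref
                A[:, k] = e_alt.sum(axis=1) + e_ref.sum(axis=1)
                alt_k[k] = e_alt.sum(axis=0)
                tot_k[k] = e_alt.sum(axis=0) + e_ref.sum(axis=0)
            Q = A / np.maximum(plo_tot, eps)[:, None]
            Q = np.clip(Q, eps, None)
            Q /= Q.sum(axis=1, keepdims=True)
            P = np.clip(alt_k / np.maximum(tot_k, eps), eps, 1 - eps)
            ll = _em_loglik(dos, plo, obs, Q, P)
            if ll - prev_ll < tol and it > 1:
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
        cand = (prev_ll, r, Q, P, converged, it)
        if best is None or cand[0] > best[0]:
            best = cand
    ll, _, Q, P, converged, it = best

    labels = None
    if ref_freqs:
        full = {lab: np.asarray(f)[poly] for lab, f in ref_freqs.items()}
        labels = _align_clusters(P, full)
    full_P = np.full((K, G.n_loci), np.nan)
    full_P[:, poly] = P
    return AncestryEstimate(
        samples=list(G.samples), q=Q, log_likelihood=ll, n_loci=int(poly.sum()),
        converged=converged, iterations=it, cluster_labels=labels,
        cluster_freqs=full_P,
    )


def _align_clusters(P: np.ndarray, refs: dict[str, np.ndarray]) -> list[str]:
    """Greedy cluster -> reference-lineage labels by frequency correlation."""
    K = P.shape[0]
    labels: list[str | None] = [None] * K
    pairs = []
    for k in range(K):
        for lab, f in refs.items():
            ok = np.isfinite(f)
            if ok.sum() < 2:
                continue
            r = np.corrcoef(P[k, ok], f[ok])[0, 1]
            pairs.append((-r, k, lab))
    used_k: set[int] = set()
    used_lab: set[str] = set()
    for _, k, lab in sorted(pairs):
        if k in used_k or lab in used_lab:
            continue
        labels[k] = lab
        used_k.add(k)
        used_lab.add(lab)
    for k in range(K):
        if labels[k] is None:
            labels[k] = f"cluster{k + 1}"
    return labels  # type: ignore[return-value]


def classify_assignment(
    q: np.ndarray | Sequence[float],
    labels: Sequence[str] = ("CAL", "HOL"),
    threshold: float = PURE_THRESHOLD,
) -> str:
    """Assign a lineage iff its membership coefficient is >= threshold (0.7),
    otherwise ADMIXED (coefficients strictly inside (0.3, 0.7))."""
    q = np.asarray(q, dtype=float)
    if q.ndim != 1 or len(q) != len(labels):
        raise AncestryError("q and labels must have matching length")
    if np.any(q < -1e-9) or abs(q.sum() - 1.0) > 1e-6:
        raise AncestryError("q must be a probability vector")
    k = int(np.argmax(q))
    return labels[k] if q[k] >= threshold else ADMIXED
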