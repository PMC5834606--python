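"""Differentiation and diversity statistics.

Implements the two-population Weir & Cockerham (1984) theta estimator from
its variance components (a: among populations, b: among individuals within
populations, c: within individuals), an AMOVA phi_ST for haplotype
alignments with a label-permutation test, and the basic diversity summaries
(nucleotide diversity pi, observed/expected heterozygosity).

Conventions
-----------
* Negative theta estimates are reported, never clamped to zero.
* The multi-locus mean theta is the ratio of summed components
  sum(a) / sum(a + b + c), the standard W&C combination.
* Hemizygous (ploidy-1) calls are excluded from the diploid-based W&C
  components: at Z-linked loci F_ST uses male diploids only.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .popio import MISSING, GenotypeMatrix


class StatError(ValueError):
    pass


@dataclasses.dataclass
class AlleleFreqTable:
    """Per-group, per-locus alternate-allele frequencies with allele counts."""

    groups: list[str]
    freq: np.ndarray      # (n_groups, n_loci), NaN where no observed alleles
    n_alleles: np.ndarray  # (n_groups, n_loci) int

    def for_group(self, name: str) -> np.ndarray:
        return self.freq[self.groups.index(name)]


def allele_frequencies(
    G: GenotypeMatrix, grouping: Mapping[str, Sequence[str]]
) -> AlleleFreqTable:
    """Ploidy-aware alternate-allele frequencies per group.

    grouping maps group name -> sample ids (each sample in at most one
    group). Frequency = alt dosage sum / observed allele count; loci with
    zero observed alleles in a group get NaN frequency and count 0.
    """
    seen: dict[str, str] = {}
    for g, members in grouping.items():
        for s in members:
            if s in seen:
                raise StatError(f"sample {s!r} assigned to both {seen[s]!r} and {g!r}")
            seen[s] = g
    groups = list(grouping)
    n_g, m = len(groups), G.n_loci
    freq = np.full((n_g, m), np.nan)
    counts = np.zeros((n_g, m), dtype=np.int64)
    for gi, g in enumerate(groups):
        idx = G.sample_index(grouping[g])
        d = G.dosage[idx].astype(float)
        p = G.ploidy[idx].astype(float)
        obs = d >= 0
        alt = np.where(obs, d, 0.0).sum(axis=0)
        tot = np.where(obs, p, 0.0).sum(axis=0)
        counts[gi] = tot.astype(np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[gi] = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
    return AlleleFreqTable(groups=groups, freq=freq, n_alleles=counts)


@dataclasses.dataclass
class FstResult:
    """Per-locus W&C variance components and theta, plus the combined mean."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    theta: np.ndarray        # per-locus a/(a+b+c); NaN where a+b+c == 0
    mean_theta: float        # sum(a)/sum(a+b+c) over usable loci
    n_loci_used: int
    loci: pd.DataFrame | None = None


def _diploid_pop_summaries(G: GenotypeMatrix, idx: np.ndarray):
    """Per-locus (n, p, h) for one population, diploid calls only."""
    d = G.dosage[idx].astype(float)
    p2 = G.ploidy[idx] == 2
    obs = (d >= 0) & p2
    n = obs.sum(axis=0).astype(float)
    alt = np.where(obs, d, 0.0).sum(axis=0)
    het = np.where(obs, d == 1, False).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * np.maximum(n, 1)), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n, p, h


def wc_fst(
    G: GenotypeMatrix, popA: Sequence[str], popB: Sequence[str]
) -> FstResult:
    """Weir & Cockerham (1984) two-allele, two-population theta per locus.

    Sample sizes per population per locus are the observed non-missing
    diploid counts; the observed-heterozygosity term enters through the h
    terms of the a/b/c components. Loci where either population has fewer
    than one diploid call, or both have fewer than two in total, are NaN.
    """
    idxA = G.sample_index(popA)
    idxB = G.sample_index(popB)
    if len(idxA) < 2 or len(idxB) < 2:
        raise StatError("each population needs >= 2 samples")
    nA, pA, hA = _diploid_pop_summaries(G, idxA)
    nB, pB, hB = _diploid_pop_summaries(G, idxB)
    usable = (nA >= 1) & (nB >= 1) & (nA + nB >= 3)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (nA + nB) / r
        nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1.0)
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(np.abs(denom) > 0, a / denom, np.nan)
    ok = usable & np.isfinite(denom) & (np.abs(denom) > 0)
    mean_theta = (
        float(np.nansum(np.where(ok, a, 0.0)) / np.nansum(np.where(ok, denom, 0.0)))
        if ok.any()
        else float("nan")
    )
    return FstResult(
        a=a, b=b, c=c, theta=theta, mean_theta=mean_theta,
        n_loci_used=int(ok.sum()), loci=G.loci,
    )


# --------------------------------------------------------------------------
# AMOVA phi_ST for haplotype alignments
# --------------------------------------------------------------------------


@dataclasses.dataclass
class PhiStResult:
    phi_st: float
    sigma2_among: float
    sigma2_within: float
    p_value: float
    n_permutations: int


def hamming_matrix(seqs: Sequence[str]) -> np.ndarray:
    """Pairwise count of differing sites between equal-length sequences."""
    arr = np.array([list(s) for s in seqs])
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = (arr != arr[i]).sum(axis=1)
    return d


def _phi_from_sq(d2: np.ndarray, labels: np.ndarray):
    """phi_ST variance components from a squared-distance matrix."""
    n = len(labels)
    groups, counts = np.unique(labels, return_counts=True)
    g = len(groups)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for grp, ng in zip(groups, counts):
        idx = np.flatnonzero(labels == grp)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_among = ss_total - ss_within
    df_among, df_within = g - 1, n - g
    ms_within = ss_within / df_within
    n_prime = (n - (counts**2).sum() / n) / df_among
    sigma_a = (ss_among / df_among - ms_within) / n_prime
    sigma_w = ms_within
    tot = sigma_a + sigma_w
    phi = sigma_a / tot if tot != 0 else np.nan
    return phi, sigma_a, sigma_w


def phi_st(
    seqs: Sequence[str],
    labels: Sequence[str],
    n_perm: int = 100,
    seed: int = 0,
    distance_matrix: np.ndarray | None = None,
) -> PhiStResult:
    """AMOVA phi_ST between two groups of haplotypes with a permutation test.

    The molecular distance defaults to the number of differing sites;
    phi_ST = sigma2_among / (sigma2_among + sigma2_within). The p-value is
    the fraction of label permutations (observed configuration included)
    with phi_ST >= the observed value.
    """
    labels = np.asarray(labels)
    if n_perm < 1:
        raise StatError("n_perm must be >= 1")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) != 2:
        raise StatError(f"need exactly two groups, got {list(uniq)}")
    if counts.min() < 2:
        raise StatError("each group needs >= 2 sequences")
    if distance_matrix is None:
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise StatError("sequences must be equal length")
        distance_matrix = hamming_matrix(seqs)
    d2 = np.asarray(distance_matrix, dtype=float) ** 2
    phi_obs, s_a, s_w = _phi_from_sq(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 1  # the observed configuration counts
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        phi_p, _, _ = _phi_from_sq(d2, perm)
        if phi_p >= phi_obs - 1e-12:
            hits += 1
    return PhiStResult(
        phi_st=float(phi_obs),
        sigma2_among=float(s_a),
        sigma2_within=float(s_w),
        p_value=hits / (n_perm + 1),
        n_permutations=n_perm,
    )


# --------------------------------------------------------------------------
# Diversity summaries
# --------------------------------------------------------------------------


def nucleotide_diversity(seqs: Sequence[str]) -> float:
    """pi: mean pairwise per-site difference among haplotypes."""
    n = len(seqs)
    if n < 2:
        return 0.0
    d = hamming_matrix(seqs)
    pairs = d[np.triu_indices(n, 1)]
    return float(pairs.mean() / len(seqs[0]))


def heterozygosity(
    G: GenotypeMatrix, samples: Sequence[str]
) -> tuple[float, float]:
    """(H_o, H_e) for one group of samples.

    H_o is the fraction of heterozygous calls among observed diploid calls;
    H_e is 2p(1-p) averaged over loci with data (sample-size-uncorrected).
    """
    idx = G.sample_index(samples)
    if idx.size == 0:
        raise StatError("empty group")
    d = G.dosage[idx]
    p2 = G.ploidy[idx] == 2
    obs = (d >= 0) & p2
    n_obs = obs.sum()
    ho = float((d[obs] == 1).sum() / n_obs) if n_obs else float("nan")
    freqs = allele_frequencies(G, {"g": list(samples)}).freq[0]
    with np.errstate(invalid="ignore"):
        he_per_locus = 2.0 * freqs * (1.0 - freqs)
    he = float(np.nanmean(he_per_locus)) if np.isfinite(he_per_locus).any() else float("nan")
    return ho, he


def diversity_stats(
    G: GenotypeMatrix | None,
    grouping: Mapping[str, Sequence[str]],
    haplotypes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-group diversity table: pi (needs haplotypes), H_o and H_e (need G)."""
    rows = []
    for g, members in grouping.items():
        pi = np.nan
        if haplotypes is not None:
            seqs = [haplotypes[s] for s in members if s in haplotypes]
            if len(seqs) >= 2:
                pi = nucleotide_diversity(seqs)
        ho = he = np.nan
        if G is not None:
            ho, he = heterozygosity(G, members)
        rows.append({"group": g, "pi": pi, "H_o": ho, "H_e": he,
                     "n_samples": len(members)})
    return pd.DataFrame(rows)
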