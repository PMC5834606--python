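"""Statistical site filters for SNP matrices.

Reproduces the standard ddRAD filtering stack: per-locus missingness
thresholds, an exact Hardy–Weinberg test, positional thinning (one random
SNP kept per cluster of close positions) and windowed LD pruning on the
squared dosage correlation. Filters compose in a configured order and every
step's removed/retained counts are recorded in a :class:`FilterReport`.

The exact HWE test is the two-sided "sum of configuration probabilities
<= observed" version (not mid-p). The default significance level is 0.001.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .popio import MISSING, GenotypeMatrix


class FilterConfigError(ValueError):
    pass


@dataclasses.dataclass
class FilterStep:
    name: str
    params: dict
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclasses.dataclass
class FilterReport:
    steps: list[FilterStep] = dataclasses.field(default_factory=list)

    def add(self, name: str, params: dict, n_in: int, n_removed: int) -> None:
        self.steps.append(FilterStep(name, params, n_in, n_removed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"filter": s.name, **{f"param_{k}": v for k, v in s.params.items()},
                 "n_in": s.n_in, "n_removed": s.n_removed, "n_out": s.n_out}
                for s in self.steps
            ]
        )


def filter_by_missingness(
    G: GenotypeMatrix, max_missing_fraction: float,
    report: FilterReport | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep loci whose missing-call fraction is <= the threshold (inclusive)."""
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise FilterConfigError("max_missing_fraction must be in [0,1]")
    report = report or FilterReport()
    frac = (G.dosage == MISSING).mean(axis=0)
    keep = frac <= max_missing_fraction + 1e-12
    report.add("missingness", {"max_missing": max_missing_fraction},
               G.n_loci, int((~keep).sum()))
    return G.subset_loci(keep), report


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy–Weinberg test on diploid genotype counts.

    Conditional on the allele counts, each heterozygote count n_Aa' of the
    right parity has probability proportional to
    2**n_Aa' * n! / (n_AA'! n_Aa'! n_aa'!); the p-value sums the
    probabilities of all configurations no more probable than the observed
    one. Returns NaN when all counts are zero.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise FilterConfigError("genotype counts must be >= 0")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return float("nan")
    nA = 2 * n_AA + n_Aa
    hets = np.arange(nA % 2, min(nA, 2 * n - nA) + 1, 2)
    n_AA_all = (nA - hets) // 2
    n_aa_all = n - n_AA_all - hets
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_AA_all + 1)
        - gammaln(hets + 1)
        - gammaln(n_aa_all + 1)
    )
    logp -= np.logaddexp.reduce(logp)  # normalize over the support
    p_obs = logp[np.searchsorted(hets, n_Aa)]
    return float(np.exp(np.logaddexp.reduce(logp[logp <= p_obs + 1e-10])))


def hwe_pvalues(G: GenotypeMatrix) -> np.ndarray:
    """Per-locus exact HWE p-values from observed diploid calls.

    Hemizygous (ploidy-1) calls never enter: at Z-linked loci the test uses
    diploid (male) genotypes only.
    """
    p = np.empty(G.n_loci)
    d = G.dosage
    diploid = G.ploidy == 2
    obs = (d >= 0) & diploid
    for j in range(G.n_loci):
        col = d[obs[:, j], j]
        p[j] = hwe_exact_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return p


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Composite genotype r^2: squared Pearson correlation of dosages over
    jointly non-missing samples. NaN when either vector is constant or
    fewer than two joint observations exist."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = (a >= 0) & (b >= 0)
    if ok.sum() < 2:
        return float("nan")
    a, b = a[ok], b[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _thin_positions(
    loci: pd.DataFrame, min_bp: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean keep-mask: one random SNP per chain-linked cluster of loci
    closer than min_bp on the same scaffold."""
    keep = np.ones(len(loci), dtype=bool)
    for _, grp in loci.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        start = 0
        for i in range(1, len(idx) + 1):
            if i == len(idx) or pos[i] - pos[i - 1] > min_bp:
                if i - start > 1:  # a violating cluster
                    keep[idx[start:i]] = False
                    keep[idx[start + rng.integers(i - start)]] = True
                start = i
    return keep


def _ld_prune_mask(
    G: GenotypeMatrix, r2_threshold: float, window_bp: int
) -> np.ndarray:
    """Keep-mask for windowed LD pruning; the earlier-position SNP of a
    violating pair is kept (documented convention, not PLINK's heuristic)."""
    keep = np.ones(G.n_loci, dtype=bool)
    loci = G.loci
    for _, grp in loci.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        for ii in range(len(idx)):
            if not keep[idx[ii]]:
                continue
            jj = ii + 1
            while jj < len(idx) and pos[jj] - pos[ii] <= window_bp:
                if keep[idx[jj]]:
                    r2 = ld_r2(G.dosage[:, idx[ii]], G.dosage[:, idx[jj]])
                    if np.isfinite(r2) and r2 > r2_threshold:
                        keep[idx[jj]] = False
                jj += 1
    return keep


KNOWN_FILTERS = ("missingness", "thin_bp", "hwe", "ld_prune")


def apply_site_filters(
    G: GenotypeMatrix,
    steps: Sequence[tuple[str, dict]],
    seed: int = 0,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply an ordered list of site filters.

    ``steps`` is a sequence of (name, params) with names from
    ``missingness`` (max_missing), ``thin_bp`` (min_bp), ``hwe`` (alpha),
    ``ld_prune`` (r2_threshold, window_bp). Thinning tie-breaks use the run
    seed, so re-running with the same seed is deterministic.
    """
    rng = np.random.default_rng(seed)
    report = FilterReport()
    for name, params in steps:
        if name not in KNOWN_FILTERS:
            raise FilterConfigError(f"unknown filter {name!r}")
        n_in = G.n_loci
        if name == "missingness":
            G, report = filter_by_missingness(
                G, params.get("max_missing", 0.5), report
            )
            continue
        if name == "thin_bp":
            keep = _thin_positions(G.loci, int(params.get("min_bp", 50)), rng)
        elif name == "hwe":
            alpha = float(params.get("alpha", 0.001))
            pvals = hwe_pvalues(G)
            keep = ~(pvals < alpha)  # NaN p (no data) is retained
        else:  # ld_prune
            keep = _ld_prune_mask(
                G,
                float(params.get("r2_threshold", 0.8)),
                int(params.get("window_bp", 1000)),
            )
        report.add(name, dict(params), n_in, int((~keep).sum()))
        G = G.subset_loci(keep)
    return G, report
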