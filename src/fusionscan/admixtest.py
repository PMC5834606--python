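"""Three-population f3 admixture test with block-jackknife errors.

f3(C; A, B) averages (p_C - p_A)(p_C - p_B) over loci. A significantly
negative value indicates the target C is admixed between sources related to
A and B; drift private to C pushes the statistic positive. Standard errors
come from a delete-one-block jackknife over contiguous windows of SNPs
(blocks by SNP count, default 500), weighted for unequal block lengths, so
they are robust to linkage.

When genotype data are available, the "corrected" estimator subtracts the
target's sampling-variance term h_C/n_C per locus (h_C the unbiased
heterozygosity), so that E[f3] = 0 when C coincides with one source. The f3
values reported here are unscaled (no heterozygosity normalisation):
magnitudes are not comparable across datasets, only signs and Z-scores.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .diffstats import AlleleFreqTable, allele_frequencies
from .popio import GenotypeMatrix


class F3Error(ValueError):
    pass


@dataclasses.dataclass
class F3Result:
    f3: float
    se: float
    z: float          # NaN when SE is 0
    block_size: int
    n_blocks: int
    n_loci: int


def f3_per_locus(
    p_c: np.ndarray,
    p_a: np.ndarray,
    p_b: np.ndarray,
    n_c: np.ndarray | None = None,
    corrected: bool = False,
) -> np.ndarray:
    """Per-locus (p_C - p_A)(p_C - p_B), optionally bias-corrected.

    The correction subtracts p_C(1-p_C)/(n_C - 1) (the unbiased estimate of
    the target's allele-frequency sampling variance, n_C = allele count).
    Loci where the target frequency is 0 or 1 contribute a zero correction.
    Loci with any frequency missing are NaN (skipped downstream).
    """
    p_c = np.asarray(p_c, dtype=float)
    vals = (p_c - np.asarray(p_a, dtype=float)) * (p_c - np.asarray(p_b, dtype=float))
    if corrected:
        if n_c is None:
            raise F3Error("corrected estimator needs target allele counts")
        n_c = np.asarray(n_c, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(n_c > 1, p_c * (1.0 - p_c) / (n_c - 1.0), np.nan)
        vals = vals - corr
    return vals


def block_jackknife(
    per_locus_values: np.ndarray, block_size: int
) -> F3Result:
    """Delete-one-block jackknife mean, SE and Z over contiguous SNP blocks.

    Loci must be in genomic order; the last block may be short. Blocks are
    weighted by length (Busing-style weighted jackknife, the convention of
    the f-statistics literature); with equal blocks this reduces exactly to
    the classic delete-one formula. NaN per-locus values are dropped before
    blocking. Fewer than 2 non-empty blocks is an error.
    """
    if block_size < 1:
        raise F3Error("block_size must be >= 1")
    vals = np.asarray(per_locus_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    n = vals.size
    n_blocks = int(np.ceil(n / block_size))
    if n_blocks < 2:
        raise F3Error(f"need >= 2 blocks, got {n_blocks} ({n} usable loci)")
    total = vals.sum()
    est = total / n
    sizes = np.array(
        [min(block_size, n - j * block_size) for j in range(n_blocks)], dtype=float
    )
    block_sums = np.add.reduceat(vals, np.arange(0, n, block_size))
    loo = (total - block_sums) / (n - sizes)  # leave-one-block-out means
    g = float(n_blocks)
    h = n / sizes
    theta_jack = g * est - np.sum((1.0 - sizes / n) * loo)
    tau = h * est - (h - 1.0) * loo
    var = np.sum((tau - theta_jack) ** 2 / (h - 1.0)) / g
    se = float(np.sqrt(var))
    z = est / se if se > 0 else float("nan")
    return F3Result(
        f3=float(est), se=se, z=float(z),
        block_size=block_size, n_blocks=n_blocks, n_loci=n,
    )


def f3_test(
    G: GenotypeMatrix,
    target: Sequence[str],
    source_a: Sequence[str],
    source_b: Sequence[str],
    block_size: int = 500,
    corrected: bool = True,
) -> F3Result:
    """f3(target; source_a, source_b) from genotypes, with jackknife SE."""
    tab = allele_frequencies(
        G, {"C": list(target), "A": list(source_a), "B": list(source_b)}
    )
    vals = f3_per_locus(
        tab.freq[0], tab.freq[1], tab.freq[2],
        n_c=tab.n_alleles[0], corrected=corrected,
    )
    return block_jackknife(vals, block_size)


def f3_from_freqs(
    tab: AlleleFreqTable,
    target: str,
    source_a: str,
    source_b: str,
    block_size: int = 500,
    corrected: bool = False,
) -> F3Result:
    """f3 from a prepared allele-frequency table (loci in genomic order)."""
    vals = f3_per_locus(
        tab.for_group(target), tab.for_group(source_a), tab.for_group(source_b),
        n_c=tab.n_alleles[tab.groups.index(target)], corrected=corrected,
    )
    return block_jackknife(vals, block_size)
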