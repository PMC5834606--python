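"""Independent brute-force oracles used only by the tests.

Each oracle takes a computation route different from the library code it
checks: the Weir-Cockerham oracle goes through the allele-indicator ANOVA
mean squares rather than the frequency-form component formulas; the HWE
oracle enumerates genotype configurations in exact rational arithmetic; the
jackknife oracle is the classic equal-block delete-one transcription; the
AMOVA oracle is a plain-loop sums-of-squares transcription.
"""

from fractions import Fraction
from math import comb

import numpy as np


def wc_theta_anova(genotypes_a, genotypes_b):
    """W&C (1984) a/b/c for one biallelic locus, two populations, via the
    allele-indicator nested ANOVA. Genotypes are dosage lists (diploid).

    Returns (a, b, c). Mean squares: MSG within individuals, MSI among
    individuals within populations, MSP among populations; then
    a = (MSP - MSI)/(2 n_c), b = (MSI - MSG)/2, c = MSG.
    """
    pops = [list(genotypes_a), list(genotypes_b)]
    # allele pairs per individual
    alleles = [[(1 if d >= 1 else 0, 1 if d == 2 else 0) for d in p] for p in pops]
    n_i = [len(p) for p in pops]
    N = sum(n_i)
    r = 2
    grand = sum(a + b for p in alleles for (a, b) in p) / (2 * N)
    ssg = ssi = ssp = 0.0
    for p in alleles:
        pmean = sum(a + b for (a, b) in p) / (2 * len(p))
        ssp += 2 * len(p) * (pmean - grand) ** 2
        for (x1, x2) in p:
            imean = (x1 + x2) / 2
            ssi += 2 * (imean - pmean) ** 2
            ssg += (x1 - imean) ** 2 + (x2 - imean) ** 2
    msg = ssg / N
    msi = ssi / (N - r)
    msp = ssp / (r - 1)
    n_c = (N - sum(n * n for n in n_i) / N) / (r - 1)
    a = (msp - msi) / (2 * n_c)
    b = (msi - msg) / 2
    c = msg
    return a, b, c


def hwe_exact_enumeration(n_AA, n_Aa, n_aa):
    """Exact HWE p-value by full enumeration in rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return None
    nA = 2 * n_AA + n_Aa
    weights = {}
    for het in range(nA % 2, min(nA, 2 * n - nA) + 1, 2):
        hom_A = (nA - het) // 2
        hom_a = n - hom_A - het
        weights[het] = Fraction(
            2**het * comb(n, hom_A) * comb(n - hom_A, het), 1
        )
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_Aa]
    return sum(p for p in probs.values() if p <= p_obs)


def delete_one_jackknife(values, block_size):
    """Classic equal-block delete-one jackknife (estimate, SE).

    Requires the number of loci to be an exact multiple of block_size.
    """
    vals = np.asarray(values, dtype=float)
    n = vals.size
    assert n % block_size == 0
    g = n // block_size
    loo = np.array(
        [
            np.delete(vals, slice(j * block_size, (j + 1) * block_size)).mean()
            for j in range(g)
        ]
    )
    se = np.sqrt((g - 1) / g * np.sum((loo - loo.mean()) ** 2))
    return vals.mean(), se


def amova_phi_st(seqs, labels):
    """phi_ST by a plain-loop sums-of-squares transcription.

    Distance: number of differing sites. Two groups assumed.
    """
    n = len(seqs)
    d2 = [[sum(a != b for a, b in zip(seqs[i], seqs[j])) ** 2 for j in range(n)]
          for i in range(n)]
    groups = sorted(set(labels))
    ss_total = sum(d2[i][j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    counts = []
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        counts.append(len(idx))
        ss_within += sum(
            d2[i][j] for k, i in enumerate(idx) for j in idx[k + 1:]
        ) / len(idx)
    ss_among = ss_total - ss_within
    df_among = len(groups) - 1
    df_within = n - len(groups)
    ms_within = ss_within / df_within
    n_prime = (n - sum(c * c for c in counts) / n) / df_among
    sigma_a = (ss_among / df_among - ms_within) / n_prime
    return sigma_a / (sigma_a + ms_within)
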