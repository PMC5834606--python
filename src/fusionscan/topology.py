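"""Block-wise closest-pair topology tallies.

For three lineages, each contiguous block of SNPs votes for the pair with
the smallest mean squared allele-frequency difference; the tally of votes
over blocks summarises which pairs of lineages the genome supports as
closest. Run genome-wide versus on a high-F_ST (introgression-resistant)
subset, discordance between the two tallies is the signature of lineage
fusion: gene flow pulls the fused pair together genome-wide while resistant
loci retain the true ((CAL,CHI),HOL) history.

This distance tally is a deliberately simple surrogate for posterior
tree-set proportions from full species-tree inference ("the percentage of
trees matching each topology"); numerical agreement with such methods is
not expected, only the qualitative majority pattern.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .diffstats import AlleleFreqTable

PAIRS = (("CAL", "HOL"), ("CAL", "CHI"), ("HOL", "CHI"))


class TopologyError(ValueError):
    pass


@dataclasses.dataclass
class TopologyTally:
    """Counts/proportions of blocks in which each lineage pair is closest."""

    counts: dict[str, int]       # keys "CAL-HOL", "CAL-CHI", "HOL-CHI"
    ties: int
    block_size: int
    n_blocks: int
    subset: str

    @property
    def proportions(self) -> dict[str, float]:
        tot = sum(self.counts.values())
        return {k: (v / tot if tot else float("nan")) for k, v in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        props = self.proportions
        return pd.DataFrame(
            [
                {"pair": k, "blocks": v, "proportion": props[k]}
                for k, v in self.counts.items()
            ]
        )


def pairwise_block_distance(
    freqs: dict[str, np.ndarray], block: np.ndarray
) -> dict[str, float]:
    """Mean squared frequency difference per lineage pair over one block.

    Loci with any lineage frequency missing are excluded; an empty usable
    block raises (callers skip it).
    """
    sub = {k: np.asarray(v, dtype=float)[block] for k, v in freqs.items()}
    ok = np.ones(len(block), dtype=bool)
    for v in sub.values():
        ok &= np.isfinite(v)
    if not ok.any():
        raise TopologyError("block has no usable loci")
    out = {}
    for a, b in PAIRS:
        diff = sub[a][ok] - sub[b][ok]
        out[f"{a}-{b}"] = float(np.mean(diff**2))
    return out


def topology_tally(
    tab: AlleleFreqTable | dict[str, np.ndarray],
    block_size: int = 50,
    subset_mask: np.ndarray | None = None,
    subset_tag: str = "all",
    tie_tol: float = 0.0,
) -> TopologyTally:
    """Tally the closest pair per contiguous block of SNPs.

    ``tab`` supplies CAL/HOL/CHI frequencies in genomic order; an optional
    boolean ``subset_mask`` (e.g. F_ST > 0.2 loci, or resistant loci)
    restricts the tally. Exact ties go to a separate tie bucket, never to a
    pair. Fewer than 2 blocks is an error.
    """
    if isinstance(tab, AlleleFreqTable):
        freqs = {g: tab.for_group(g) for g in ("CAL", "HOL", "CHI")}
    else:
        freqs = {k: np.asarray(v, dtype=float) for k, v in tab.items()}
    m = len(next(iter(freqs.values())))
    idx = np.arange(m)
    if subset_mask is not None:
        idx = idx[np.asarray(subset_mask, dtype=bool)]
    n_blocks = int(np.ceil(len(idx) / block_size))
    if n_blocks < 2:
        raise TopologyError(f"need >= 2 blocks, got {n_blocks}")
    counts = {f"{a}-{b}": 0 for a, b in PAIRS}
    ties = 0
    used = 0
    for j in range(n_blocks):
        block = idx[j * block_size:(j + 1) * block_size]
        try:
            d = pairwise_block_distance(freqs, block)
        except TopologyError:
            continue
        used += 1
        dmin = min(d.values())
        winners = [k for k, v in d.items() if v <= dmin + tie_tol]
        if len(winners) == 1:
            counts[winners[0]] += 1
        else:
            ties += 1
    return TopologyTally(
        counts=counts, ties=ties, block_size=block_size,
        n_blocks=used, subset=subset_tag,
    )


def fst_subset_mask(theta: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask of loci with pairwise F_ST strictly above threshold."""
    theta = np.asarray(theta, dtype=float)
    return np.isfinite(theta) & (theta > threshold)
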