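"""Diagnostic SNP panels, mosaic genomic profiles and mitonuclear tests.

A diagnostic panel is the set of loci fixed (F_ST = 1) or strongly
differentiated (F_ST strictly above a threshold, e.g. 0.58 or 0.2) between
hand-curated pure reference groups; each panel locus is oriented by which
allele is CAL-typical. Individuals are then scored per locus as homozygous
CAL (CC), heterozygous (CH) or homozygous HOL (HH) — long-admixed mosaic
genomes show all three states, F1 hybrids are all CH. Per-sample profiles
combine four marker layers (mtDNA, Z, autosomal, diagnostic SNP) into a
categorical assignment table; samples need at least three layers present.

The mitonuclear independence (uncoupling) test is a permutation test of
whether the mtDNA lineage label predicts nuclear ancestry; after long
random interbreeding the two decouple. The classical evidence for
uncoupling is a pattern, not a test — this permutation test is this
package's own formalisation and its output says so.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ancestry import ADMIXED, classify_assignment
from .diffstats import allele_frequencies, wc_fst
from .popio import GenotypeMatrix

MISSING_LAYER = "MISSING"
LAYERS = ("mt", "Z", "auto", "SNP")


class ProfileError(ValueError):
    pass


@dataclasses.dataclass
class DiagnosticPanel:
    """Oriented panel of lineage-diagnostic loci.

    ``loci`` columns: locus_index, chrom, pos, cal_allele ("ref"/"alt"),
    theta (W&C F_ST between the pure reference groups), p_cal, p_hol.
    """

    loci: pd.DataFrame
    rule: str           # {fixed, near_fixed, fst_gt}
    threshold: float

    def __len__(self) -> int:
        return len(self.loci)


def build_diagnostic_panel(
    G: GenotypeMatrix,
    pure_cal: Sequence[str],
    pure_hol: Sequence[str],
    rule: str = "fixed",
    threshold: float = 1.0,
) -> DiagnosticPanel:
    """Select diagnostic loci between pure reference groups.

    rule="fixed": per-locus theta == 1 (complete fixation); rule="fst_gt":
    theta strictly > threshold. The CAL-typical allele is the allele at
    higher frequency in the pure CAL group; loci where the reference
    frequencies are equal are never included (orientation undefined).
    An empty panel is returned with a warning flag, not an error.
    """
    if not pure_cal or not pure_hol:
        raise ProfileError("reference groups must be non-empty")
    if set(pure_cal) & set(pure_hol):
        raise ProfileError("reference groups must be disjoint")
    fst = wc_fst(G, pure_cal, pure_hol)
    tab = allele_frequencies(G, {"CAL": list(pure_cal), "HOL": list(pure_hol)})
    p_cal, p_hol = tab.freq[0], tab.freq[1]
    theta = fst.theta
    oriented = np.isfinite(p_cal) & np.isfinite(p_hol) & (p_cal != p_hol)
    if rule == "fixed":
        sel = oriented & np.isfinite(theta) & (theta >= 1.0 - 1e-9)
    elif rule in ("fst_gt", "near_fixed"):
        sel = oriented & np.isfinite(theta) & (theta > threshold)
    else:
        raise ProfileError(f"unknown rule {rule!r}")
    idx = np.flatnonzero(sel)
    loci = G.loci.iloc[idx].copy()
    loci.insert(0, "locus_index", idx)
    loci["cal_allele"] = np.where(p_cal[idx] > p_hol[idx], "alt", "ref")
    loci["theta"] = theta[idx]
    loci["p_cal"] = p_cal[idx]
    loci["p_hol"] = p_hol[idx]
    return DiagnosticPanel(
        loci=loci.reset_index(drop=True), rule=rule,
        threshold=threshold if rule != "fixed" else 1.0,
    )


def snp_profile(
    G: GenotypeMatrix, sample: str, panel: DiagnosticPanel
) -> pd.DataFrame:
    """Score one sample at the panel loci.

    States: CC (two CAL-typical alleles), CH (heterozygous), HH (two
    HOL-typical), C/H for hemizygous single copies, "missing" for no call.
    Hemizygous states are kept distinct so female Z calls never masquerade
    as homozygous diploid evidence.
    """
    if len(panel) == 0:
        raise ProfileError("panel is empty")
    i = G.sample_index([sample])[0]
    idx = panel.loci["locus_index"].to_numpy()
    dos = G.dosage[i, idx]
    plo = G.ploidy[i, idx]
    cal_is_alt = (panel.loci["cal_allele"] == "alt").to_numpy()
    cal_copies = np.where(cal_is_alt, dos, plo - dos)
    states = np.full(len(idx), "missing", dtype=object)
    obs = dos >= 0
    dip = obs & (plo == 2)
    hemi = obs & (plo == 1)
    states[dip & (cal_copies == 2)] = "CC"
    states[dip & (cal_copies == 1)] = "CH"
    states[dip & (cal_copies == 0)] = "HH"
    states[hemi & (cal_copies == 1)] = "C"
    states[hemi & (cal_copies == 0)] = "H"
    out = panel.loci[["locus_index", "chrom", "pos"]].copy()
    out["state"] = states
    return out


def snp_profile_counts(profile: pd.DataFrame) -> dict[str, int]:
    counts = profile["state"].value_counts().to_dict()
    return {s: int(counts.get(s, 0)) for s in ("CC", "CH", "HH", "C", "H", "missing")}


def snp_layer_q_hol(profile: pd.DataFrame) -> float:
    """Fraction of HOL-typical allele copies among observed panel calls."""
    weights = {"CC": (0, 2), "CH": (1, 2), "HH": (2, 2), "C": (0, 1), "H": (1, 1)}
    hol = tot = 0
    for state, (h, t) in weights.items():
        k = int((profile["state"] == state).sum())
        hol += h * k
        tot += t * k
    return hol / tot if tot else float("nan")


def assign_mtdna(
    sequence: str, references: Mapping[str, Sequence[str]]
) -> str:
    """Nearest-reference-haplotype lineage by Hamming distance.

    ``references`` maps lineage label -> list of reference haplotypes (all
    the same length as ``sequence``). A tie across lineages returns
    "ambiguous"; a length mismatch raises.
    """
    best: dict[str, int] = {}
    for lineage, refs in references.items():
        for ref in refs:
            if len(ref) != len(sequence):
                raise ProfileError("sequence/reference length mismatch")
            d = sum(a != b for a, b in zip(sequence, ref))
            if lineage not in best or d < best[lineage]:
                best[lineage] = d
    dmin = min(best.values())
    winners = [lab for lab, d in best.items() if d == dmin]
    return winners[0] if len(winners) == 1 else "ambiguous"


def z_layer_assignment(
    G: GenotypeMatrix, sample: str, z_locus_index: int, cal_allele: str
) -> str:
    """Lineage call at one designated diagnostic Z SNP.

    Homozygotes (or hemizygotes) are assigned to the lineage of their
    allele; heterozygotes are always ADMIXED; missing calls give MISSING.
    """
    i = G.sample_index([sample])[0]
    d = G.dosage[i, z_locus_index]
    p = G.ploidy[i, z_locus_index]
    if d < 0:
        return MISSING_LAYER
    cal_copies = d if cal_allele == "alt" else p - d
    if p == 2 and cal_copies == 1:
        return ADMIXED
    return "CAL" if cal_copies == p else "HOL"


def genomic_profile(
    sample: str,
    mt_assignment: str | None,
    z_assignment: str | None,
    auto_q: Sequence[float] | None,
    snp_q: Sequence[float] | None,
    labels: Sequence[str] = ("CAL", "HOL"),
) -> dict[str, str]:
    """Combine the four marker layers into one categorical profile row.

    auto_q / snp_q are membership-coefficient vectors over ``labels`` (the
    0.7 rule applies); mt and Z assignments are passed through. Requires at
    least three non-missing layers; otherwise raises (caller logs and
    excludes the sample).
    """
    row = {
        "mt": mt_assignment if mt_assignment else MISSING_LAYER,
        "Z": z_assignment if z_assignment else MISSING_LAYER,
        "auto": classify_assignment(auto_q, labels) if auto_q is not None
        else MISSING_LAYER,
        "SNP": classify_assignment(snp_q, labels) if snp_q is not None
        else MISSING_LAYER,
    }
    present = sum(v != MISSING_LAYER for v in row.values())
    if present < 3:
        raise ProfileError(
            f"sample {sample!r} present in only {present} layers (need >= 3)"
        )
    row["sample"] = sample
    row["layers_present"] = str(present)
    return row


def profile_table(rows: Sequence[dict[str, str]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["sample", *LAYERS, "layers_present"])


def discordance_flags(table: pd.DataFrame) -> pd.Series:
    """True where the mt layer disagrees with a non-missing, non-admixed
    nuclear consensus (the mosaic 'uncoupled' signature)."""
    nuclear = table[["Z", "auto", "SNP"]]

    def _flag(row):
        mt = row["mt"]
        if mt in (MISSING_LAYER, "ambiguous"):
            return False
        calls = [c for c in nuclear.loc[row.name] if c in ("CAL", "HOL")]
        return bool(calls) and all(c != mt for c in calls)

    return table.apply(_flag, axis=1)


@dataclasses.dataclass
class UncouplingResult:
    statistic: float      # mean q_HOL difference between mt classes
    p_value: float
    n_permutations: int
    n_samples: int
    note: str = (
        "permutation test of mitonuclear independence; a formalisation "
        "introduced by this package, not a published procedure"
    )


def mitonuclear_independence_test(
    mt_labels: Sequence[str],
    nuclear_q_hol: Sequence[float],
    n_perm: int = 999,
    seed: int = 0,
    region_mask: Sequence[bool] | None = None,
) -> UncouplingResult:
    """Two-sided permutation test of mt-lineage vs nuclear ancestry.

    Statistic: difference in mean nuclear q_HOL between mt classes (HOL
    minus CAL). p-value: fraction of mt-label permutations with |statistic|
    >= |observed|, with +1 smoothing on both counts.
    """
    mt = np.asarray(mt_labels, dtype=object)
    q = np.asarray(nuclear_q_hol, dtype=float)
    if region_mask is not None:
        mask = np.asarray(region_mask, dtype=bool)
        mt, q = mt[mask], q[mask]
    ok = np.isfinite(q) & np.isin(mt, ("CAL", "HOL"))
    mt, q = mt[ok], q[ok]
    if len(q) < 10:
        raise ProfileError("need >= 10 samples with mt label and nuclear q")
    is_hol = mt == "HOL"
    if is_hol.all() or (~is_hol).all():
        raise ProfileError("both mt classes must be present")
    obs = q[is_hol].mean() - q[~is_hol].mean()
    rng = np.random.default_rng(seed)
    n_hol = int(is_hol.sum())
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(q))
        stat = q[perm[:n_hol]].mean() - q[perm[n_hol:]].mean()
        if abs(stat) >= abs(obs) - 1e-12:
            hits += 1
    return UncouplingResult(
        statistic=float(obs),
        p_value=(hits + 1) / (n_perm + 1),
        n_permutations=n_perm,
        n_samples=len(q),
    )
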