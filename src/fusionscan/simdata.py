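"""Synthetic multi-marker datasets emulating lineage fusion.

Three deeply diverged lineages — CAL (California), HOL (Holarctic) and CHI
(Chihuahuan) — with the true history ((CAL,CHI),HOL): CAL and CHI are sister
lineages, yet in ``fusion`` mode CAL and HOL interbreed along a geographic
transect, producing mosaic genomes, a logistic ancestry cline, maternally
inherited mtDNA labels whose cline centre may be displaced from the nuclear
one, sex-aware Z-linked loci (females hemizygous) and a fraction of
introgression-resistant loci that keep a sharp ancestry step. CHI is always
a fully isolated population.

Allele frequencies drift from a shared ancestor under the Balding–Nichols
beta model; the drift parameter F is the beta F, and its mapping to realized
Weir–Cockerham F_ST is approximate (validated empirically in the tests, not
assumed exact).

All randomness flows from ``SimConfig.seed`` through named substreams, so
every output is byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .popio import MISSING, LOCUS_COLUMNS, GenotypeMatrix

MODES = ("fusion", "isolation", "recent_contact")

# transect geometry: a south-north line of populations at constant longitude,
# anchored at San Diego; 1 degree latitude ~ 111.195 km of great-circle arc
_ANCHOR_LAT = 32.7157
_ANCHOR_LON = -117.1611
_KM_PER_DEG = 111.1949266


class ConfigError(ValueError):
    """Invalid simulator configuration."""


@dataclasses.dataclass
class SimConfig:
    """Parameters of the lineage-fusion simulator.

    Defaults describe a desk-scale ddRAD-like study: 2000 biallelic SNPs on a
    2000 km transect of 10 populations of 20 diploids, a nuclear cline of
    width 500 km centred mid-transect, deep HOL split (F=0.3) over a shallow
    CAL/CHI split (F=0.1), 2% missing calls, 10% Z-linked and 5%
    introgression-resistant loci.
    """

    n_loci: int = 2000
    frac_z_linked: float = 0.1
    frac_resistant: float = 0.05
    n_pops: int = 10
    samples_per_pop: int = 20
    transect_length_km: float = 2000.0
    cline_center_km: float = 1000.0
    cline_width_km: float = 500.0
    mt_cline_center_km: float = 1000.0
    F_deep: float = 0.3
    F_shallow: float = 0.1
    missing_rate: float = 0.02
    sex_ratio: float = 0.5
    seed: int = 0
    mode: str = "fusion"
    include_chi: bool = True

    def validate(self) -> None:
        for name in ("frac_z_linked", "frac_resistant", "missing_rate", "sex_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")
        for name in ("F_deep", "F_shallow"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name}={v} outside (0,1)")
        if self.cline_width_km <= 0:
            raise ConfigError("cline_width_km must be > 0")
        if self.n_loci < 1:
            raise ConfigError("n_loci must be >= 1")
        if self.frac_resistant + self.frac_z_linked > 1.0:
            raise ConfigError("frac_resistant + frac_z_linked > 1")
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}")
        if self.n_pops < 1 or self.samples_per_pop < 1:
            raise ConfigError("n_pops and samples_per_pop must be >= 1")


@dataclasses.dataclass
class LineageFreqs:
    """True per-lineage alternate-allele frequencies (length n_loci each)."""

    ancestral: np.ndarray
    cal: np.ndarray
    hol: np.ndarray
    chi: np.ndarray


@dataclasses.dataclass
class SimResult:
    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    truth: pd.DataFrame
    freqs: LineageFreqs
    resistant: np.ndarray  # boolean mask over loci


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def _balding_nichols(
    rng: np.random.Generator, parent: np.ndarray, F: float
) -> np.ndarray:
    """Drifted daughter frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F) around parent."""
    if F < 1e-12:
        return parent.copy()
    # a parent frequency that drifted all the way to 0/1 stays fixed
    interior = (parent > 0.0) & (parent < 1.0)
    safe = np.where(interior, parent, 0.5)
    a = safe * (1.0 - F) / F
    b = (1.0 - safe) * (1.0 - F) / F
    draw = rng.beta(a, b)
    return np.where(interior, draw, parent)


def draw_lineage_freqs(config: SimConfig) -> LineageFreqs:
    """Draw per-lineage frequencies under the ((CAL,CHI),HOL) history.

    Ancestral frequencies are uniform on [0.05, 0.95] (avoids a glut of
    monomorphic loci; loci that still end up monomorphic in a sample are
    retained — downstream filters must cope). HOL and the CAL/CHI internal
    ancestor drift from the root with F_deep; CAL and CHI drift from that
    internal ancestor with F_shallow.
    """
    config.validate()
    rng = _rng(config.seed, 1)
    p0 = rng.uniform(0.05, 0.95, size=config.n_loci)
    hol = _balding_nichols(rng, p0, config.F_deep)
    anc_cc = _balding_nichols(rng, p0, config.F_deep)
    cal = _balding_nichols(rng, anc_cc, config.F_shallow)
    chi = _balding_nichols(rng, anc_cc, config.F_shallow)
    return LineageFreqs(ancestral=p0, cal=cal, hol=hol, chi=chi)


def logistic_cline(d_km: np.ndarray | float, center_km: float, width_km: float):
    """Expected HOL ancestry at transect distance d.

    q(d) = 1 / (1 + exp(-4 (d - center) / width)); width is the inverse of
    the maximum slope (the standard hybrid-zone cline-width convention).
    """
    z = -4.0 * (np.asarray(d_km, dtype=float) - center_km) / width_km
    return 1.0 / (1.0 + np.exp(z))


def _locus_table(config: SimConfig, rng: np.random.Generator):
    """Place loci on synthetic scaffolds; Z loci on scafZ, autosomes on scaf_i."""
    m = config.n_loci
    n_z = int(round(config.frac_z_linked * m))
    n_auto = m - n_z
    per_scaf = 250
    rows = []
    k = 0
    scaf_idx = 1
    while k < n_auto:
        take = min(per_scaf, n_auto - k)
        pos = np.sort(rng.choice(np.arange(1, 2_000_001), size=take, replace=False))
        for p in pos:
            rows.append((f"scaf_{scaf_idx}", int(p), "A", "G", False))
        k += take
        scaf_idx += 1
    if n_z:
        pos = np.sort(rng.choice(np.arange(1, 2_000_001), size=n_z, replace=False))
        for p in pos:
            rows.append((f"scafZ", int(p), "A", "G", True))
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    z_mask = loci["z_linked"].to_numpy()
    # resistant loci are autosomal only
    auto_idx = np.flatnonzero(~z_mask)
    n_res = int(round(config.frac_resistant * m))
    res_idx = rng.choice(auto_idx, size=min(n_res, auto_idx.size), replace=False)
    resistant = np.zeros(m, dtype=bool)
    resistant[res_idx] = True
    return loci, z_mask, resistant


def simulate_fusion_dataset(config: SimConfig) -> SimResult:
    """Simulate genotypes, metadata and ground truth for one study.

    Populations sit at even spacing along the transect. Nuclear true ancestry
    follows the logistic cline (``fusion``), a hard step at the cline centre
    (``isolation``: everyone pure), or a one-generation contact in which
    admixed individuals are exactly F1 (``recent_contact``). In ``fusion``
    each autosomal allele copy is independently HOL-derived with probability
    true_q (random interbreeding); resistant loci instead take ancestry from
    a step at the cline centre (no introgression). mtDNA lineage is drawn
    per individual from a logistic cline centred at ``mt_cline_center_km``
    (in fusion mode), making mitonuclear uncoupling possible. CHI samples
    are a fully isolated population in every mode.
    """
    config.validate()
    rng_loci = _rng(config.seed, 2)
    rng_geno = _rng(config.seed, 3)
    rng_miss = _rng(config.seed, 4)
    freqs = draw_lineage_freqs(config)
    loci, z_mask, resistant = _locus_table(config, rng_loci)

    # --- samples and geography -------------------------------------------
    n_pops, spp = config.n_pops, config.samples_per_pop
    if n_pops == 1:
        dists = np.array([config.transect_length_km / 2.0])
    else:
        dists = np.linspace(0.0, config.transect_length_km, n_pops)
    pop_names = [f"P{i + 1:02d}" for i in range(n_pops)]
    sample_ids, pops, d_sample = [], [], []
    for i, pop in enumerate(pop_names):
        for j in range(spp):
            sample_ids.append(f"{pop}_s{j + 1:02d}")
            pops.append(pop)
            d_sample.append(dists[i])
    n_transect = len(sample_ids)
    if config.include_chi:
        for j in range(spp):
            sample_ids.append(f"CHI_s{j + 1:02d}")
            pops.append("CHI")
            d_sample.append(np.nan)
    n = len(sample_ids)
    m = config.n_loci
    d_sample = np.asarray(d_sample)
    is_chi = np.array([p == "CHI" for p in pops])

    female = rng_geno.random(n) < config.sex_ratio
    sex = np.where(female, "F", "M")

    # --- true ancestry ----------------------------------------------------
    q_cline = logistic_cline(d_sample[:n_transect], config.cline_center_km,
                             config.cline_width_km)
    step = (d_sample[:n_transect] >= config.cline_center_km).astype(float)
    true_q = np.zeros(n)
    f1 = np.zeros(n, dtype=bool)
    if config.mode == "fusion":
        true_q[:n_transect] = q_cline
    elif config.mode == "isolation":
        true_q[:n_transect] = step
    else:  # recent_contact: random mating for exactly one generation
        u = rng_geno.random(n_transect)
        pure_hol = u < q_cline**2
        pure_cal = u >= q_cline**2 + 2 * q_cline * (1 - q_cline)
        true_q[:n_transect] = np.where(pure_hol, 1.0, np.where(pure_cal, 0.0, 0.5))
        f1[:n_transect] = ~(pure_hol | pure_cal)

    # --- mtDNA lineage ----------------------------------------------------
    mt = np.empty(n, dtype=object)
    if config.mode == "fusion":
        q_mt = logistic_cline(d_sample[:n_transect], config.mt_cline_center_km,
                              config.cline_width_km)
        mt[:n_transect] = np.where(rng_geno.random(n_transect) < q_mt, "HOL", "CAL")
    elif config.mode == "isolation":
        mt[:n_transect] = np.where(true_q[:n_transect] > 0.5, "HOL", "CAL")
    else:
        # pure parents carry their own mtDNA; F1 mothers are a fair coin
        maternal = np.where(
            f1[:n_transect], rng_geno.random(n_transect) < 0.5,
            true_q[:n_transect] > 0.5,
        )
        mt[:n_transect] = np.where(maternal, "HOL", "CAL")
    mt[is_chi] = "CHI"

    # --- ploidy -----------------------------------------------------------
    ploidy = np.full((n, m), 2, dtype=np.int8)
    ploidy[np.ix_(female, z_mask)] = 1

    # --- per-copy lineage of origin --------------------------------------
    # qmat[i, l] = P(an allele copy of sample i at locus l is HOL-derived)
    qmat = np.repeat(true_q[:, None], m, axis=1)
    if config.mode != "isolation":
        step_full = np.zeros(n)
        step_full[:n_transect] = step
        qmat[:, resistant] = step_full[:, None]
    copy1_hol = rng_geno.random((n, m)) < qmat
    if config.mode == "recent_contact":
        # F1s: exactly one copy from each parental lineage at non-resistant loci
        copy2_hol = ~copy1_hol
        nonf1 = ~f1
        r2 = rng_geno.random((n, m)) < qmat
        copy2_hol[nonf1] = r2[nonf1]
        copy2_hol[:, resistant] = r2[:, resistant]
    else:
        copy2_hol = rng_geno.random((n, m)) < qmat

    # --- alleles ----------------------------------------------------------
    p_cal = np.broadcast_to(freqs.cal, (n, m))
    p_hol = np.broadcast_to(freqs.hol, (n, m))
    p1 = np.where(copy1_hol, p_hol, p_cal)
    p2 = np.where(copy2_hol, p_hol, p_cal)
    a1 = (rng_geno.random((n, m)) < p1).astype(np.int16)
    a2 = (rng_geno.random((n, m)) < p2).astype(np.int16)
    if is_chi.any():
        p_chi = np.broadcast_to(freqs.chi, (is_chi.sum(), m))
        a1[is_chi] = rng_geno.random((is_chi.sum(), m)) < p_chi
        a2[is_chi] = rng_geno.random((is_chi.sum(), m)) < p_chi
    dosage = a1 + np.where(ploidy == 2, a2, 0)
    dosage = dosage.astype(np.int16)

    # --- missingness ------------------------------------------------------
    if config.missing_rate > 0:
        mask = rng_miss.random((n, m)) < config.missing_rate
        dosage[mask] = MISSING

    G = GenotypeMatrix(samples=sample_ids, loci=loci, dosage=dosage, ploidy=ploidy)
    G.validate()

    metadata = pd.DataFrame(
        {
            "sample": sample_ids,
            "population": pops,
            "latitude": np.where(
                is_chi, 31.8, _ANCHOR_LAT + np.nan_to_num(d_sample) / _KM_PER_DEG
            ),
            "longitude": np.where(is_chi, -106.5, _ANCHOR_LON),
            "sex": sex,
            "mt_lineage": mt.astype(str),
        }
    )
    truth = pd.DataFrame(
        {
            "sample": sample_ids,
            "true_q_HOL": np.where(is_chi, np.nan, true_q),
            "true_mt_lineage": mt.astype(str),
            "distance_km": d_sample,
            "is_f1": f1,
        }
    )
    return SimResult(genotypes=G, metadata=metadata, truth=truth, freqs=freqs,
                     resistant=resistant)


# --- optional mtDNA haplotype sequences ----------------------------------

_BASES = np.array(list("ACGT"))


def generate_mt_haplotypes(
    config: SimConfig,
    truth: pd.DataFrame,
    seq_length: int = 400,
    n_fixed_diffs: int = 12,
) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Lineage-specific mtDNA reference sequences plus per-individual
    Poisson(1) private mutations.

    Returns (per-sample sequences, per-lineage reference haplotype lists).
    Each lineage's reference differs from the ancestral sequence at its own
    set of diagnostic sites, so references from different lineages differ at
    up to 2 * n_fixed_diffs sites.
    """
    rng = _rng(config.seed, 5)
    anc = rng.choice(_BASES, size=seq_length)
    refs: dict[str, list[str]] = {}
    ref_arrays: dict[str, np.ndarray] = {}
    sites = rng.choice(seq_length, size=3 * n_fixed_diffs, replace=False)
    for k, lineage in enumerate(("CAL", "HOL", "CHI")):
        arr = anc.copy()
        for s in sites[k * n_fixed_diffs:(k + 1) * n_fixed_diffs]:
            choices = [b for b in "ACGT" if b != arr[s]]
            arr[s] = rng.choice(choices)
        ref_arrays[lineage] = arr
        refs[lineage] = ["".join(arr)]
    seqs: dict[str, str] = {}
    for rec in truth.itertuples(index=False):
        arr = ref_arrays[rec.true_mt_lineage].copy()
        for _ in range(rng.poisson(1.0)):
            s = rng.integers(seq_length)
            choices = [b for b in "ACGT" if b != arr[s]]
            arr[s] = rng.choice(choices)
        seqs[rec.sample] = "".join(arr)
    return seqs, refs
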