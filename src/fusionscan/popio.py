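"""Reading, writing and validation of the joint data model.

The working objects of the whole analysis are a biallelic SNP dosage matrix
(:class:`GenotypeMatrix`) plus a per-sample metadata table. Genotypes travel
as VCF v4.2, metadata and truth tables as TSV, haplotype alignments as FASTA.

Conventions
-----------
* Positions are 1-based (VCF convention); any interval logic is half-open at
  the call site that uses it.
* Genotypes are unphased dosages; a phase separator ``|`` is accepted on read
  but phase is discarded.
* Z-linked loci are flagged with the INFO key ``ZL``. Females are hemizygous
  for Z (ploidy 1) and their calls are written/read as haploid.
* Missing dosage is encoded as ``-1`` in the integer matrix.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

MISSING = -1

LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt", "z_linked"]
METADATA_COLUMNS = ["sample", "population", "latitude", "longitude", "sex", "mt_lineage"]

VALID_SEXES = {"M", "F", "unknown"}


class ValidationError(ValueError):
    """Raised when an input file or joint data model violates its contract."""


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples x biallelic-loci alternate-allele dosage matrix.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (row order of ``dosage``).
    loci : pandas.DataFrame
        One row per locus with columns ``chrom, pos, ref, alt, z_linked``;
        positions are 1-based and strictly increasing within a scaffold.
    dosage : ndarray of int16, shape (n_samples, n_loci)
        Count of alternate alleles; ``-1`` is missing.
    ploidy : ndarray of int8, shape (n_samples, n_loci)
        2 for diploid calls, 1 for hemizygous (female Z) calls.
    """

    samples: list[str]
    loci: pd.DataFrame
    dosage: np.ndarray
    ploidy: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_index(self, names: Iterable[str]) -> np.ndarray:
        """Row indices for a list of sample names (raises on unknown name)."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown sample {exc.args[0]!r}") from None

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to loci selected by a boolean or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=self.loci.iloc[keep].reset_index(drop=True),
            dosage=self.dosage[:, keep].copy(),
            ploidy=self.ploidy[:, keep].copy(),
        )

    def validate(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.samples) or m != len(self.loci):
            raise ValidationError("dosage shape disagrees with samples/loci")
        if self.ploidy.shape != (n, m):
            raise ValidationError("ploidy shape disagrees with dosage")
        obs = self.dosage >= 0
        if np.any(self.dosage[obs] > self.ploidy[obs]):
            raise ValidationError("dosage exceeds ploidy at an observed call")
        for chrom, grp in self.loci.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on scaffold {chrom}"
                )


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as uncompressed VCF v4.2 (GT field only).

    Hemizygous (ploidy-1) calls are emitted as haploid genotypes; Z-linked
    loci carry the INFO flag ``ZL``.
    """
    path = Path(path)
    G.validate()
    contigs = list(dict.fromkeys(G.loci["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=fusionscan\n")
        fh.write('##INFO=<ID=ZL,Number=0,Type=Flag,Description="Z-linked locus">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.samples)
            + "\n"
        )
        dos = G.dosage
        plo = G.ploidy
        for j, rec in enumerate(G.loci.itertuples(index=False)):
            info = "ZL" if rec.z_linked else "."
            calls = []
            for i in range(G.n_samples):
                d, p = dos[i, j], plo[i, j]
                if p == 1:
                    calls.append("." if d == MISSING else str(d))
                else:
                    if d == MISSING:
                        calls.append("./.")
                    else:
                        calls.append(("0/0", "0/1", "1/1")[d])
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf_genotypes(
    path: str | Path,
    sex_map: Mapping[str, str] | None = None,
    skip_non_biallelic: bool = True,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Dosage is the count of alternate alleles; haploid calls get ploidy 1.
    Missing calls (``./.`` or ``.``) become ``-1``. Multi-allelic records and
    indels are skipped when ``skip_non_biallelic`` is true, otherwise they
    raise :class:`ValidationError`.

    Parameters
    ----------
    sex_map : mapping sample -> {"M","F","unknown"}, optional
        Required whenever the file contains Z-linked loci (INFO flag ``ZL``);
        every VCF sample must then appear in it.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    rows: list[tuple] = []
    dosages: list[np.ndarray] = []
    ploidies: list[np.ndarray] = []
    any_z = False
    for rec in vcf:
        alts = rec.alts or ()
        biallelic_snp = (
            len(alts) == 1 and len(rec.ref) == 1 and len(alts[0]) == 1
        )
        if not biallelic_snp:
            if skip_non_biallelic:
                continue
            raise ValidationError(
                f"non-biallelic or indel record at {rec.chrom}:{rec.pos}"
            )
        z = "ZL" in rec.info
        any_z = any_z or z
        d = np.empty(len(samples), dtype=np.int16)
        p = np.empty(len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s]["GT"]
            alleles = [a for a in gt if a is not None]
            p[i] = max(len(gt), 1)
            d[i] = sum(alleles) if len(alleles) == len(gt) and gt else MISSING
        rows.append((rec.chrom, rec.pos, rec.ref, alts[0], z))
        dosages.append(d)
        ploidies.append(p)
    vcf.close()
    if any_z:
        if sex_map is None:
            raise ValidationError("VCF contains Z-linked loci but no sex_map given")
        absent = [s for s in samples if s not in sex_map]
        if absent:
            raise ValidationError(
                f"samples missing from sex_map with Z-linked loci present: {absent}"
            )
    loci = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    G = GenotypeMatrix(
        samples=samples,
        loci=loci,
        dosage=np.array(dosages, dtype=np.int16).T.reshape(len(samples), len(loci)),
        ploidy=np.array(ploidies, dtype=np.int8).T.reshape(len(samples), len(loci)),
    )
    G.validate()
    return G


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    """Write the sample metadata table as TSV with header."""
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample metadata TSV.

    Required columns: sample, population, latitude, longitude, sex,
    mt_lineage. Empty mt_lineage is stored as the string ``"missing"``;
    coordinates out of [-90, 90] x [-180, 180] raise ValidationError.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample": str, "population": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValidationError(f"metadata missing columns: {missing_cols}")
    lat = pd.to_numeric(meta["latitude"], errors="coerce")
    lon = pd.to_numeric(meta["longitude"], errors="coerce")
    bad = lat.isna() | lon.isna() | (lat.abs() > 90) | (lon.abs() > 180)
    if bad.any():
        raise ValidationError(
            f"malformed coordinates for samples: {meta.loc[bad, 'sample'].tolist()}"
        )
    meta = meta.copy()
    meta["latitude"] = lat
    meta["longitude"] = lon
    meta["mt_lineage"] = meta["mt_lineage"].fillna("missing").replace("", "missing")
    bad_sex = ~meta["sex"].isin(VALID_SEXES)
    if bad_sex.any():
        raise ValidationError(
            f"invalid sex values: {sorted(meta.loc[bad_sex, 'sex'].unique())}"
        )
    if meta["sample"].duplicated().any():
        raise ValidationError("duplicate sample ids in metadata")
    return meta


def validate_joint(G: GenotypeMatrix, meta: pd.DataFrame) -> None:
    """Check that every genotyped sample has a metadata row."""
    have = set(meta["sample"])
    absent = [s for s in G.samples if s not in have]
    if absent:
        raise ValidationError(f"samples without metadata rows: {absent}")


def read_fasta_alignment(path: str | Path) -> dict[str, str]:
    """Read a FASTA haplotype alignment; all sequences must share one length."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValidationError(f"no sequences in {path}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValidationError(f"alignment has unequal sequence lengths: {lengths}")
    return seqs


def write_fasta_alignment(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
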