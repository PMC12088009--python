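"""Genotype container, VCF I/O and marker/sample quality-control filters.

The panel is stored as an ALT-allele dosage matrix (samples x markers,
values 0/1/2, missing coded as -1) together with a marker table carrying
chromosome, 1-based position and REF/ALT alleles.  Filters reproduce the
standard GBS quality-control cascade for an inbred diversity panel:
marker missingness, minor allele frequency, per-sample call rate and a
per-marker heterozygosity cap (inbred lines should be close to fully
homozygous; an excess of heterozygous calls flags paralog collapse).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel in the int8 dosage matrix


class GenotypeError(ValueError):
    """Raised for malformed or empty genotype inputs."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-marker ALT dosage matrix with marker metadata.

    Attributes
    ----------
    dosages : ndarray of int8, shape (n_samples, n_markers)
        ALT-allele counts in {0, 1, 2}; missing calls are ``MISSING`` (-1).
    sample_ids : list of str
    markers : DataFrame with columns ``chrom, pos, id, ref, alt``,
        sorted by (chrom, pos); ``chrom`` keeps its input category order.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    markers: pd.DataFrame
    skipped_records: int = 0
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise GenotypeError("dosages must be 2-D (samples x markers)")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise GenotypeError("sample_ids length does not match dosage rows")
        if len(self.markers) != m:
            raise GenotypeError("marker table length does not match dosage columns")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def observed_mask(self) -> np.ndarray:
        return self.dosages != MISSING

    def alt_freq(self) -> np.ndarray:
        """Per-marker ALT allele frequency over non-missing calls (NaN if none)."""
        obs = self.observed_mask()
        d = np.where(obs, self.dosages, 0).astype(float)
        n_obs = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, d.sum(axis=0) / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return (~self.observed_mask()).mean(axis=0)

    def het_freq(self) -> np.ndarray:
        """Heterozygote frequency (dosage==1) among non-missing calls per marker."""
        obs = self.observed_mask()
        n_obs = obs.sum(axis=0).astype(float)
        n_het = (self.dosages == 1).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, n_het / n_obs, np.nan)

    def call_rate(self) -> np.ndarray:
        """Per-sample fraction of non-missing markers."""
        return self.observed_mask().mean(axis=1)

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx], list(self.sample_ids),
            self.markers.iloc[idx], self.skipped_records,
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[idx, :], [self.sample_ids[i] for i in idx],
            self.markers, self.skipped_records,
        )

    def sort_markers(self) -> "GenotypeMatrix":
        """Stable sort by (chrom in category order, pos)."""
        chrom = self.markers["chrom"]
        if not isinstance(chrom.dtype, pd.CategoricalDtype):
            cats = pd.unique(chrom)
            chrom = pd.Categorical(chrom, categories=cats, ordered=True)
        order = np.lexsort((self.markers["pos"].to_numpy(),
                            np.asarray(pd.Categorical(chrom).codes)))
        return self.take_markers(order)


def _marker_frame(chrom, pos, ids, ref, alt) -> pd.DataFrame:
    chrom = pd.Categorical(chrom, categories=pd.unique(np.asarray(chrom)), ordered=True)
    return pd.DataFrame({
        "chrom": chrom,
        "pos": np.asarray(pos, dtype=np.int64),
        "id": list(ids),
        "ref": list(ref),
        "alt": list(alt),
    })


def read_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into an ALT-dosage matrix.

    Diploid GT fields are summed to ALT counts; any missing allele yields a
    missing dosage.  Multi-allelic and non-SNP records are skipped and the
    count retained on ``skipped_records``.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    chrom, pos, ids, ref, alt, rows = [], [], [], [], [], []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            skipped += 1
            continue
        # gts012: 0/1/2 = ALT count, 3 = missing
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.append(g)
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
    vcf.close()
    if not rows:
        raise GenotypeError(f"no biallelic SNPs found in {path}")
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", skipped)
    dos = np.stack(rows, axis=1)
    g = GenotypeMatrix(dos, samples, _marker_frame(chrom, pos, ids, ref, alt), skipped)
    return g.sort_markers()


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write the panel as a minimal VCF 4.2 text file (GT only, ./. missing)."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(np.asarray(g.markers["chrom"])):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        mk = g.markers
        for j in range(g.n_markers):
            gts = "\t".join(code[int(d)] for d in g.dosages[:, j])
            fh.write(f"{mk['chrom'].iloc[j]}\t{mk['pos'].iloc[j]}\t{mk['id'].iloc[j]}"
                     f"\t{mk['ref'].iloc[j]}\t{mk['alt'].iloc[j]}\t.\t.\t.\tGT\t{gts}\n")


def filter_markers(g: GenotypeMatrix, max_missing: float = 0.50,
                   min_maf: float = 0.05) -> GenotypeMatrix:
    """Drop markers with missingness >= ``max_missing`` or MAF < ``min_maf``.

    Both thresholds follow the GBS convention: the missingness bound is
    inclusive, the MAF bound strict, and MAF is computed on non-missing
    calls only.  Marker order is preserved.
    """
    keep = (g.missing_fraction() < max_missing) & ~(g.maf() < min_maf)
    # NaN MAF (all-missing marker) is already caught by the missingness rule
    out = g.take_markers(np.flatnonzero(keep))
    logger.info("filter_markers: %d -> %d markers", g.n_markers, out.n_markers)
    return out


def filter_samples(g: GenotypeMatrix, min_call_rate: float = 0.80) -> GenotypeMatrix:
    """Drop samples whose genotyping success is below ``min_call_rate``."""
    keep = np.flatnonzero(g.call_rate() >= min_call_rate)
    if keep.size == 0:
        raise GenotypeError("all samples removed by call-rate filter")
    out = g.take_samples(keep)
    logger.info("filter_samples: %d -> %d samples", g.n_samples, out.n_samples)
    return out


def filter_heterozygosity(g: GenotypeMatrix, max_het: float = 0.12,
                          empirical_q95: bool = False) -> GenotypeMatrix:
    """Drop markers whose heterozygote frequency exceeds ``max_het`` (strict >).

    With ``empirical_q95`` the threshold is instead the panel's own 95th
    percentile of per-marker heterozygosity, mimicking a percentile-based cap.
    """
    het = g.het_freq()
    thr = float(np.nanpercentile(het, 95)) if empirical_q95 else max_het
    keep = np.flatnonzero(~(het > thr))
    out = g.take_markers(keep)
    logger.info("filter_heterozygosity: %d -> %d markers (thr=%.4g)",
                g.n_markers, out.n_markers, thr)
    return out


def qc_report(g: GenotypeMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-marker (MAF, missingness, het rate) and per-sample (call rate) tables."""
    per_marker = g.markers[["chrom", "pos", "id"]].copy()
    per_marker["maf"] = g.maf()
    per_marker["missing_fraction"] = g.missing_fraction()
    per_marker["het_freq"] = g.het_freq()
    per_sample = pd.DataFrame({"sample": g.sample_ids, "call_rate": g.call_rate()})
    return per_marker, per_sample
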