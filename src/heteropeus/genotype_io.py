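"""Read, filter and write multi-sample SNP genotype data for an inbred panel.

The central container is :class:`GenotypeMatrix`: samples x biallelic SNP
sites with allele-dosage coding (0/1/2 alt-allele copies, ``MISSING`` = -1)
plus per-call read depth and genotype quality. Quality control follows the
standard resequencing-panel recipe: per-call thresholds (depth, GQ) mask
individual calls to missing; site-level thresholds (QUAL, missing rate)
then drop whole sites.

Coordinates are 1-based inclusive externally (VCF convention); conversion
to anything else is confined to readers/writers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

#: Sentinel for an absent per-call DP/GQ value (absent annotations pass filters).
UNKNOWN: int = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for SNP quality control.

    min_depth / min_genotype_quality apply per call (failures are masked to
    missing); min_site_quality applies to the site QUAL field and
    max_missing_rate to the fraction of missing calls after masking
    (failures drop the site).
    """

    min_depth: int = 3
    min_site_quality: float = 30.0
    min_genotype_quality: float = 5.0
    max_missing_rate: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must be in [0, 1]")
        if self.min_depth < 0 or self.min_site_quality < 0 or self.min_genotype_quality < 0:
            raise ValueError("thresholds must be >= 0")


class GenotypeMatrix:
    """Samples x biallelic-SNP-sites genotype grid.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    sites
        DataFrame with columns chrom, pos (1-based), ref, alt, qual
        (NaN = missing QUAL), sorted by (chrom, pos), no duplicates.
    dosage
        int8 array (n_samples, n_sites); alt-allele count 0/1/2 or MISSING.
    depth, gq
        Optional int32 arrays of per-call read depth / genotype quality;
        UNKNOWN (-1) where the annotation is absent.
    """

    def __init__(
        self,
        samples: list[str],
        sites: pd.DataFrame,
        dosage: np.ndarray,
        depth: np.ndarray | None = None,
        gq: np.ndarray | None = None,
    ) -> None:
        samples = list(samples)
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample identifiers")
        sites = sites.reset_index(drop=True)
        missing_cols = [c for c in SITE_COLUMNS if c not in sites.columns]
        if missing_cols:
            raise ValueError(f"sites table missing columns: {missing_cols}")
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(samples), len(sites)):
            raise ValueError(
                f"dosage shape {dosage.shape} != (n_samples={len(samples)}, n_sites={len(sites)})"
            )
        if not np.all(np.isin(dosage, [MISSING, 0, 1, 2])):
            raise ValueError("dosage values must be 0, 1, 2 or MISSING")
        if len(sites) > 1:
            key = list(zip(sites["chrom"], sites["pos"]))
            if any(key[i] >= key[i + 1] for i in range(len(key) - 1)):
                raise ValueError("sites must be sorted by (chrom, pos) without duplicates")
        if depth is None:
            depth = np.full(dosage.shape, UNKNOWN, dtype=np.int32)
        if gq is None:
            gq = np.full(dosage.shape, UNKNOWN, dtype=np.int32)
        depth = np.asarray(depth, dtype=np.int32)
        gq = np.asarray(gq, dtype=np.int32)
        if depth.shape != dosage.shape or gq.shape != dosage.shape:
            raise ValueError("depth/gq must match dosage shape")
        self.samples = samples
        self.sites = sites
        self.dosage = dosage
        self.depth = depth
        self.gq = gq
        self._sample_idx = {s: i for i, s in enumerate(samples)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_idx[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def subset_samples(self, samples: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in samples]
        return GenotypeMatrix(
            samples, self.sites.copy(), self.dosage[idx], self.depth[idx], self.gq[idx]
        )

    def take_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix with the sites selected by boolean mask or index."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            list(self.samples),
            self.sites.iloc[keep],
            self.dosage[:, keep],
            self.depth[:, keep],
            self.gq[:, keep],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and len(self.sites) == len(other.sites)
            and (self.sites[["chrom", "pos", "ref", "alt"]].values == other.sites[["chrom", "pos", "ref", "alt"]].values).all()
            and np.array_equal(self.dosage, other.dosage)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_sites} sites)"


def read_vcf(path: str, samples: list[str] | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Only biallelic single-base SNP records are kept; multiallelic and indel
    records are skipped (count logged). Absent DP/GQ FORMAT fields are
    stored as UNKNOWN and pass downstream filters. A missing site QUAL
    ('.') is stored as NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    if samples is not None:
        absent = set(samples) - set(vcf.samples)
        if absent:
            raise KeyError(f"samples not in VCF header: {sorted(absent)}")
        vcf.close()
        vcf = VCF(path, gts012=True, samples=list(samples))
        order = [vcf.samples.index(s) for s in samples]
    else:
        order = None
    names = list(samples) if samples is not None else list(vcf.samples)
    n = len(names)

    rows, dos_rows, dp_rows, gq_rows = [], [], [], []
    n_skipped = 0
    for v in vcf:
        if (
            len(v.ALT) != 1
            or len(v.REF) != 1
            or len(v.ALT[0]) != 1
            or v.REF not in "ACGT"
            or v.ALT[0] not in "ACGT"
        ):
            n_skipped += 1
            continue
        # gts012: 0/1/2 = alt dosage, 3 = unknown
        gt = np.asarray(v.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        dp = v.format("DP")
        if dp is None:
            dp = np.full(n, UNKNOWN, dtype=np.int32)
        else:
            dp = dp.reshape(-1).astype(np.int64)
            dp[dp < 0] = UNKNOWN
            dp = dp.astype(np.int32)
        gq = v.format("GQ")
        if gq is None:
            gq = np.full(n, UNKNOWN, dtype=np.int32)
        else:
            gq = gq.reshape(-1).astype(np.float64)
            gq[~np.isfinite(gq)] = UNKNOWN
            gq[gq < 0] = UNKNOWN
            gq = gq.astype(np.int32)
        if order is not None:
            gt, dp, gq = gt[order], dp[order], gq[order]
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], np.nan if v.QUAL is None else v.QUAL))
        dos_rows.append(gt)
        dp_rows.append(dp)
        gq_rows.append(gq)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    if rows:
        dosage = np.stack(dos_rows, axis=1)
        depth = np.stack(dp_rows, axis=1)
        gq_arr = np.stack(gq_rows, axis=1)
    else:
        dosage = np.empty((n, 0), dtype=np.int8)
        depth = np.empty((n, 0), dtype=np.int32)
        gq_arr = np.empty((n, 0), dtype=np.int32)
    order_idx = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[order_idx]
    return GenotypeMatrix(names, sites, dosage[:, order_idx], depth[:, order_idx], gq_arr[:, order_idx])


def filter_variants(gm: GenotypeMatrix, cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Apply SNP quality control, returning a new matrix.

    Calls failing the per-sample depth or genotype-quality threshold are
    masked to MISSING (the site survives if its missing rate stays within
    bounds); sites with QUAL below min_site_quality or missing rate above
    max_missing_rate are removed. Idempotent; the input is unmodified.
    """
    if cfg is None:
        cfg = FilterConfig()
    if gm.n_sites == 0:
        raise ValueError("cannot filter an empty genotype matrix")
    dosage = gm.dosage.copy()
    fail = ((gm.depth != UNKNOWN) & (gm.depth < cfg.min_depth)) | (
        (gm.gq != UNKNOWN) & (gm.gq < cfg.min_genotype_quality)
    )
    dosage[fail] = MISSING
    missing_rate = (dosage == MISSING).mean(axis=0)
    qual = gm.sites["qual"].to_numpy(dtype=float)
    qual_ok = np.isnan(qual) | (qual >= cfg.min_site_quality)
    keep = qual_ok & (missing_rate <= cfg.max_missing_rate)
    logger.info(
        "filter_variants: masked %d calls; kept %d / %d sites",
        int(fail.sum()),
        int(keep.sum()),
        gm.n_sites,
    )
    kept = np.flatnonzero(keep)
    return GenotypeMatrix(
        list(gm.samples),
        gm.sites.iloc[kept],
        dosage[:, kept],
        gm.depth[:, kept],
        gm.gq[:, kept],
    )


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as VCF v4.2 (uncompressed).

    Round-trips through :func:`read_vcf`: positions, alleles, dosages,
    QUAL, DP and GQ are preserved. Missing dosage is emitted as ``./.``;
    UNKNOWN depth/GQ as ``.``.
    """
    import pysam

    header = pysam.VariantHeader()
    for chrom in pd.unique(gm.sites["chrom"]):
        header.contigs.add(str(chrom))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for s in gm.samples:
        header.add_sample(s)

    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(path, "w", header=header) as out:
        for j in range(gm.n_sites):
            row = gm.sites.iloc[j]
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            qual = row["qual"]
            rec.qual = None if pd.isna(qual) else float(qual)
            for i, s in enumerate(gm.samples):
                call = rec.samples[s]
                call["GT"] = gt_codes[int(gm.dosage[i, j])]
                if gm.depth[i, j] != UNKNOWN:
                    call["DP"] = int(gm.depth[i, j])
                if gm.gq[i, j] != UNKNOWN:
                    call["GQ"] = int(gm.gq[i, j])
            out.write(rec)
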