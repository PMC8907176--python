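"""Readers/writers and shared containers for the pipeline's formats.

Coordinate convention: 1-based inclusive everywhere in memory (matching VCF
and the coordinates printed in the study this package emulates); the single
exception is BED export/import, which is 0-based half-open on disk.

Missing dosages are encoded with the sentinel ``MISSING`` (-1) and are
excluded, never imputed, by downstream statistics (local PCA mean-imputes
within its own windows, documented there).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing dosage / phase allele
MISSING: int = -1

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


def _as_site_frame(sites: pd.DataFrame) -> pd.DataFrame:
    """Validate a site table (biallelic SNPs, sorted, unique positions).

    Sorting is the caller's job because parallel per-site arrays must be
    reordered in step; constructors only verify.
    """
    sites = sites.reset_index(drop=True)
    missing = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table lacks columns {missing}")
    if len(sites) and (sites["pos"] < 1).any():
        raise ValueError("positions must be >= 1 (1-based)")
    if len(sites) > 1:
        key = list(zip(sites["chrom"], sites["pos"]))
        if any(k2 <= k1 for k1, k2 in zip(key, key[1:])):
            raise ValueError("sites must be sorted by (chrom, pos) without duplicates")
    return sites


@dataclass
class GenotypeMatrix:
    """Individual-level genotypes: dosages and (optionally) phased alleles.

    dosage: int8 array (n_samples, n_sites), alt-allele count 0/1/2 or MISSING.
    phase:  optional int8 array (n_samples, n_sites, 2) of ordered alleles
            (0=ref, 1=alt, MISSING); where present, dosage equals their sum.
    samples: DataFrame with columns id, sex ('male'/'female'/'unknown') and
            optionally line.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    dosage: np.ndarray
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sites = _as_site_frame(self.sites)
        self.samples = self.samples.reset_index(drop=True)
        if "sex" not in self.samples.columns:
            self.samples = self.samples.assign(sex="unknown")
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError("dosage shape inconsistent with samples x sites")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=np.int8)
            if self.phase.shape != (len(self.samples), len(self.sites), 2):
                raise ValueError("phase shape inconsistent")
            both = (self.phase >= 0).all(axis=2)
            implied = self.phase.clip(min=0).sum(axis=2)
            ok = ~both | (self.dosage == implied)
            if not ok.all():
                raise ValueError("dosage != sum of phase alleles at phased entries")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_samples(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, (list, tuple, set, pd.Index)):
            mask = self.samples["id"].isin(list(mask_or_ids)).to_numpy()
        else:
            mask = np.asarray(mask_or_ids, dtype=bool)
        return GenotypeMatrix(
            sites=self.sites,
            samples=self.samples.loc[mask],
            dosage=self.dosage[mask],
            phase=None if self.phase is None else self.phase[mask],
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            sites=self.sites.loc[mask],
            samples=self.samples,
            dosage=self.dosage[:, mask],
            phase=None if self.phase is None else self.phase[:, mask],
        )


@dataclass
class PoolCountTable:
    """Per-pool ref/alt read counts at biallelic SNPs (the Pool-seq substrate).

    pools: DataFrame with columns id and size (haploid chromosome count,
    e.g. 96 for a pool of 48 diploid males).
    """

    sites: pd.DataFrame
    pools: pd.DataFrame
    ref_count: np.ndarray
    alt_count: np.ndarray

    def __post_init__(self) -> None:
        self.sites = _as_site_frame(self.sites)
        self.pools = self.pools.reset_index(drop=True)
        self.ref_count = np.asarray(self.ref_count, dtype=np.int64)
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        shape = (len(self.pools), len(self.sites))
        if self.ref_count.shape != shape or self.alt_count.shape != shape:
            raise ValueError("count arrays inconsistent with pools x sites")
        if (self.ref_count < 0).any() or (self.alt_count < 0).any():
            raise ValueError("negative read counts")
        if (self.pools["size"] < 2).any():
            raise ValueError("pool haploid size must be >= 2")

    @property
    def coverage(self) -> np.ndarray:
        return self.ref_count + self.alt_count

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_sites(self, mask: np.ndarray) -> "PoolCountTable":
        mask = np.asarray(mask, dtype=bool)
        return PoolCountTable(
            sites=self.sites.loc[mask],
            pools=self.pools,
            ref_count=self.ref_count[:, mask],
            alt_count=self.alt_count[:, mask],
        )


@dataclass
class WindowTrack:
    """Non-overlapping fixed-width windowed statistic along one chromosome."""

    chrom: str
    start: np.ndarray  # 1-based inclusive
    end: np.ndarray  # 1-based inclusive
    value: np.ndarray  # float, NaN = missing

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=float)
        if not (len(self.start) == len(self.end) == len(self.value)):
            raise ValueError("window arrays differ in length")
        if len(self.start) > 1 and (self.start[1:] <= self.start[:-1]).any():
            raise ValueError("windows must be sorted")
        if (self.end < self.start).any():
            raise ValueError("window end < start")

    def __len__(self) -> int:
        return len(self.start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end, "value": self.value}
        )


@dataclass
class RegionSet:
    """Labelled genomic intervals, 1-based inclusive in memory."""

    regions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "label"])
    )

    def __post_init__(self) -> None:
        r = self.regions.reset_index(drop=True)
        for c in ["chrom", "start", "end", "label"]:
            if c not in r.columns:
                raise ValueError(f"region table lacks column {c}")
        if len(r) and (r["end"] < r["start"]).any():
            raise ValueError("region end < start")
        self.regions = r

    def __len__(self) -> int:
        return len(self.regions)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, sample_filter=None) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix, keeping biallelic SNPs only.

    Multiallelic and non-SNP records are dropped (count logged). Phase is
    captured from the genotype separator; missing genotypes map to the
    MISSING dosage sentinel.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_filter is not None:
        keep = [s for s in samples if s in set(sample_filter)]
        if not keep:
            raise ValueError("no samples left after sample_filter")
        vcf = VCF(str(path), samples=keep)
        samples = list(vcf.samples)

    rows, dosages, phases = [], [], []
    dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            dropped += 1
            continue
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        gts = rec.genotypes  # [allele0, allele1, phased_flag] per sample
        dos = np.empty(len(samples), dtype=np.int8)
        pha = np.full((len(samples), 2), MISSING, dtype=np.int8)
        for i, g in enumerate(gts):
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                dos[i] = MISSING
            else:
                dos[i] = a0 + a1
                if g[2]:  # phased
                    pha[i] = (a0, a1)
        dosages.append(dos)
        phases.append(pha)
    if dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", dropped)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    n = len(sites)
    dosage = (
        np.stack(dosages, axis=1) if n else np.zeros((len(samples), 0), dtype=np.int8)
    )
    phase = (
        np.stack(phases, axis=1)
        if n
        else np.full((len(samples), 0, 2), MISSING, dtype=np.int8)
    )
    # order arrays to match the canonical site sort
    order = sites.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    sample_df = pd.DataFrame({"id": samples, "sex": "unknown"})
    return GenotypeMatrix(
        sites=sites.iloc[order],
        samples=sample_df,
        dosage=dosage[:, order],
        phase=phase[:, order],
    )


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as a sorted VCF 4.2 file.

    Phased entries use '|', unphased '/', missing './.'.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(gm.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "\t".join(gm.samples["id"].astype(str))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j in range(gm.n_sites):
            site = gm.sites.iloc[j]
            fields = []
            for i in range(gm.n_samples):
                d = gm.dosage[i, j]
                if d == MISSING:
                    fields.append("./.")
                    continue
                if gm.phase is not None and (gm.phase[i, j] >= 0).all():
                    a0, a1 = gm.phase[i, j]
                    fields.append(f"{a0}|{a1}")
                else:
                    fields.append("0/1" if d == 1 else ("1/1" if d == 2 else "0/0"))
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\t.\t.\tGT\t"
                + "\t".join(fields)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Pool counts (sync-like TSV)
# ---------------------------------------------------------------------------

def write_pool_counts(table: PoolCountTable, path) -> None:
    """Write pool counts as TSV: header '#pool <id> <haploid size>' lines,
    then 'chrom pos ref alt ref:alt ...' per site."""
    path = Path(path)
    with path.open("w") as fh:
        for _, p in table.pools.iterrows():
            fh.write(f"#pool\t{p['id']}\t{int(p['size'])}\n")
        fh.write("#chrom\tpos\tref\talt\t" + "\t".join(table.pools["id"].astype(str)) + "\n")
        for j in range(table.n_sites):
            s = table.sites.iloc[j]
            cells = "\t".join(
                f"{table.ref_count[i, j]}:{table.alt_count[i, j]}"
                for i in range(table.n_pools)
            )
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{cells}\n")


def read_pool_counts(path) -> PoolCountTable:
    """Inverse of :func:`write_pool_counts`; malformed rows raise with row number."""
    path = Path(path)
    pool_ids, pool_sizes = [], []
    rows, counts = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#pool\t"):
                _, pid, size = line.split("\t")
                pool_ids.append(pid)
                pool_sizes.append(int(size))
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4 + len(pool_ids):
                raise ValueError(f"row {lineno}: expected {4 + len(pool_ids)} columns")
            chrom, pos, ref, alt = parts[:4]
            site_counts = []
            for cell in parts[4:]:
                try:
                    r, a = cell.split(":")
                    r, a = int(r), int(a)
                except ValueError as exc:
                    raise ValueError(f"row {lineno}: bad count cell {cell!r}") from exc
                if r < 0 or a < 0:
                    raise ValueError(f"row {lineno}: negative count")
                site_counts.append((r, a))
            rows.append((chrom, int(pos), ref, alt))
            counts.append(site_counts)
    if not pool_ids:
        raise ValueError("no '#pool' header lines found")
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    arr = np.array(counts, dtype=np.int64).reshape(len(rows), len(pool_ids), 2)
    order = sites.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    return PoolCountTable(
        sites=sites.iloc[order],
        pools=pd.DataFrame({"id": pool_ids, "size": pool_sizes}),
        ref_count=arr[order, :, 0].T,
        alt_count=arr[order, :, 1].T,
    )


# ---------------------------------------------------------------------------
# BED / JSON metadata
# ---------------------------------------------------------------------------

def write_bed(regions: RegionSet, path) -> None:
    """Export 1-based inclusive regions as 0-based half-open BED."""
    with Path(path).open("w") as fh:
        for _, r in regions.regions.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t{r['label']}\n")


def read_bed(path) -> RegionSet:
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            rows.append((chrom, start + 1, end, label))
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def write_metadata(obj: dict, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, default=str)


def read_metadata(path) -> dict:
    with Path(path).open() as fh:
        return json.load(fh)


def concat_genotype_matrices(matrices: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Concatenate matrices over sites (same samples, e.g. per-chromosome sims)."""
    first = matrices[0]
    for m in matrices[1:]:
        if not (m.samples["id"] == first.samples["id"]).all():
            raise ValueError("sample sets differ")
    sites = pd.concat([m.sites for m in matrices], ignore_index=True)
    dosage = np.concatenate([m.dosage for m in matrices], axis=1)
    if all(m.phase is not None for m in matrices):
        phase = np.concatenate([m.phase for m in matrices], axis=1)
    else:
        phase = None
    order = sites.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    return GenotypeMatrix(
        sites=sites.iloc[order],
        samples=first.samples,
        dosage=dosage[:, order],
        phase=None if phase is None else phase[:, order],
    )
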