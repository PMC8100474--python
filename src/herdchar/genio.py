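"""Genotype container, PLINK text/binary I/O, call-rate QC and LD pruning.

The universal in-memory object is :class:`GenotypeDataset`: a samples × SNPs
matrix of minor-allele dosages in {0, 1, 2} with ``MISSING`` (−1) as the
missing sentinel, plus ordered SNP and sample records.  The minor allele is
oriented once at load time over all samples pooled; ties go to the A1/first
allele.  Downstream estimators treat loci complete-case (skip the sentinel).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Missing-dosage sentinel stored in the int8 genotype matrix.
MISSING: int = -1

_NON_AUTOSOMAL = {"X", "Y", "XY", "MT", "M", "0", "23", "24", "25", "26"}


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic marker: id, autosome label, 1-based bp position, alleles."""

    id: str
    chromosome: str
    position: int
    allele_a: str = "A"
    allele_b: str = "B"

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"SNP {self.id}: position must be >= 1")


@dataclass(frozen=True)
class SampleRecord:
    """One diploid sample with a non-empty population (breed) label."""

    id: str
    population: str

    def __post_init__(self):
        if not self.population:
            raise ValueError(f"sample {self.id}: population label is empty")


@dataclass(frozen=True)
class QcReport:
    """Counts removed/kept by the call-rate filter, with thresholds used."""

    snps_removed: int
    samples_removed: int
    snps_kept: int
    samples_kept: int
    snp_call_rate: float
    sample_call_rate: float


@dataclass
class GenotypeDataset:
    """Samples × SNPs minor-allele dosage matrix with marker map and labels.

    Parameters
    ----------
    genotypes
        int8 array of shape (n_samples, n_snps); entries 0/1/2 or ``MISSING``.
    snps
        SNP records sorted by (chromosome, position).
    samples
        Sample records, one per matrix row.
    """

    genotypes: np.ndarray
    snps: list[SnpRecord]
    samples: list[SampleRecord]

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x snps)")
        if self.genotypes.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} snps"
            )
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.genotypes[~valid])
            raise ValueError(f"invalid dosage values {bad.tolist()}")
        order = [(_chrom_key(s.chromosome), s.position) for s in self.snps]
        if any(order[i] > order[i + 1] for i in range(len(order) - 1)):
            raise ValueError("SNPs must be sorted by (chromosome, position)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return list(seen)

    def population_mask(self, population: str) -> np.ndarray:
        mask = np.array([s.population == population for s in self.samples])
        if not mask.any():
            raise KeyError(f"unknown population {population!r}")
        return mask

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.snps], dtype=np.int64)

    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps])

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeDataset":
        """Row/column subset preserving record order."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeDataset(
            self.genotypes[np.ix_(si, vi)],
            [self.snps[j] for j in vi],
            [self.samples[i] for i in si],
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeDataset)
            and self.snps == other.snps
            and self.samples == other.samples
            and np.array_equal(self.genotypes, other.genotypes)
        )


def _chrom_key(chrom: str):
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


def _is_autosomal(chrom: str) -> bool:
    if chrom.upper() in _NON_AUTOSOMAL:
        return False
    try:
        return int(chrom) >= 1
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map) and binary (.bed/.bim/.fam) I/O
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # v1.00, SNP-major


def read_genotypes(path_prefix: str | Path, dialect: str = "plink-text") -> GenotypeDataset:
    """Read a PLINK fileset into a :class:`GenotypeDataset`.

    The minor allele is determined per SNP from the pooled frequency over all
    samples; ties break toward the A-allele (A1 in .bim, first allele seen in
    .ped).  Non-autosomal markers are skipped with a warning.
    """
    prefix = Path(path_prefix)
    if dialect == "plink-text":
        return _read_text(prefix)
    if dialect == "plink-binary":
        return _read_binary(prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(ds: GenotypeDataset, path_prefix: str | Path, dialect: str = "plink-text") -> None:
    """Write ``ds`` so that :func:`read_genotypes` reproduces it exactly."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "plink-text":
        _write_text(ds, prefix)
    elif dialect == "plink-binary":
        _write_binary(ds, prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_map_like(path: Path, has_alleles: bool):
    """Parse .map (4 cols) or .bim (6 cols) rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chrom, snp_id, _cm, pos = parts[0], parts[1], parts[2], parts[3]
            alleles = (parts[4], parts[5]) if has_alleles else ("A", "B")
            rows.append((chrom, snp_id, int(pos), alleles))
    return rows


def _read_text(prefix: Path) -> GenotypeDataset:
    map_rows = _read_map_like(prefix.with_suffix(".map"), has_alleles=False)
    n_snps = len(map_rows)
    samples: list[SampleRecord] = []
    allele_calls: list[list[tuple[str, str]]] = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{prefix}.ped row for {parts[1] if len(parts) > 1 else '?'}: "
                    f"expected {6 + 2 * n_snps} fields, got {len(parts)}"
                )
            samples.append(SampleRecord(id=parts[1], population=parts[0]))
            allele_calls.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_snps)]
            )
    n = len(samples)
    geno = np.full((n, n_snps), MISSING, dtype=np.int8)
    snp_records = []
    keep_cols = []
    for j, (chrom, snp_id, pos, _ab) in enumerate(map_rows):
        if not _is_autosomal(chrom):
            logger.warning("skipping non-autosomal SNP %s on chromosome %s", snp_id, chrom)
            continue
        # First pass: collect observed alleles in order of appearance.
        seen: list[str] = []
        for i in range(n):
            for a in allele_calls[i][j]:
                if a != "0" and a not in seen:
                    seen.append(a)
        if len(seen) > 2:
            raise ValueError(f"SNP {snp_id}: more than two alleles {seen}")
        a1 = seen[0] if seen else "A"
        a2 = seen[1] if len(seen) > 1 else ("B" if a1 != "B" else "A")
        counts = {a1: 0, a2: 0}
        for i in range(n):
            x, y = allele_calls[i][j]
            if x != "0":
                counts[x] += 1
            if y != "0":
                counts[y] += 1
        # Minor allele: lower pooled count, tie toward first-seen (a1).
        minor = a1 if counts[a1] <= counts[a2] else a2
        major = a2 if minor == a1 else a1
        col = len(snp_records)
        snp_records.append(SnpRecord(snp_id, chrom, pos, allele_a=minor, allele_b=major))
        keep_cols.append((j, minor))
    out = np.full((n, len(snp_records)), MISSING, dtype=np.int8)
    for col, (j, minor) in enumerate(keep_cols):
        for i in range(n):
            x, y = allele_calls[i][j]
            if x == "0" or y == "0":
                continue
            out[i, col] = (x == minor) + (y == minor)
    return GenotypeDataset(out, snp_records, samples)


def _write_text(ds: GenotypeDataset, prefix: Path) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for s in ds.snps:
            fh.write(f"{s.chromosome}\t{s.id}\t0\t{s.position}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sample in enumerate(ds.samples):
            fields = [sample.population, sample.id, "0", "0", "0", "-9"]
            row = ds.genotypes[i]
            for j, s in enumerate(ds.snps):
                g = row[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [s.allele_b, s.allele_b]
                elif g == 1:
                    fields += [s.allele_a, s.allele_b]
                else:
                    fields += [s.allele_a, s.allele_a]
            fh.write(" ".join(fields) + "\n")


def _read_binary(prefix: Path) -> GenotypeDataset:
    bim_rows = _read_map_like(prefix.with_suffix(".bim"), has_alleles=True)
    samples = []
    with open(prefix.with_suffix(".fam")) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                samples.append(SampleRecord(id=parts[1], population=parts[0]))
    n = len(samples)
    data = Path(prefix.with_suffix(".bed")).read_bytes()
    if data[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (want v1.00 SNP-major)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(data[3:], dtype=np.uint8)
    if body.size != bytes_per_snp * len(bim_rows):
        raise ValueError(
            f"{prefix}.bed: size {body.size} inconsistent with "
            f"{n} samples x {len(bim_rows)} SNPs"
        )
    if not bim_rows:
        return GenotypeDataset(np.empty((n, 0), dtype=np.int8), [], samples)
    # 2-bit codes per sample: 00=hom A1, 01=missing, 10=het, 11=hom A2.
    codes = body.reshape(len(bim_rows), bytes_per_snp)
    shifts = np.arange(4, dtype=np.uint8) * 2
    two_bit = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    two_bit = two_bit.reshape(len(bim_rows), -1)[:, :n]  # (snps, samples)
    decode = np.array([2, MISSING, 1, 0], dtype=np.int8)  # A1 dosage
    a1_dosage = decode[two_bit].T  # (samples, snps)

    snp_records = []
    cols = []
    for j, (chrom, snp_id, pos, (a1, a2)) in enumerate(bim_rows):
        if not _is_autosomal(chrom):
            logger.warning("skipping non-autosomal SNP %s on chromosome %s", snp_id, chrom)
            continue
        col = a1_dosage[:, j]
        obs = col[col != MISSING]
        a1_count = int(obs.sum())
        a2_count = int(2 * obs.size - a1_count)
        if a1_count <= a2_count:  # tie toward A1
            minor, major, dosage = a1, a2, col
        else:
            minor, major = a2, a1
            dosage = np.where(col == MISSING, MISSING, 2 - col).astype(np.int8)
        snp_records.append(SnpRecord(snp_id, chrom, pos, allele_a=minor, allele_b=major))
        cols.append(dosage)
    geno = (
        np.stack(cols, axis=1) if cols else np.empty((n, 0), dtype=np.int8)
    )
    return GenotypeDataset(geno, snp_records, samples)


def _write_binary(ds: GenotypeDataset, prefix: Path) -> None:
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in ds.snps:
            fh.write(f"{s.chromosome}\t{s.id}\t0\t{s.position}\t{s.allele_a}\t{s.allele_b}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sample in ds.samples:
            fh.write(f"{sample.population} {sample.id} 0 0 0 -9\n")
    n, m = ds.n_samples, ds.n_snps
    # Encode A1 (= stored minor-allele) dosage back to 2-bit codes.
    encode = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
    lut = np.zeros(4, dtype=np.uint8)
    for dosage, code in encode.items():
        lut[dosage % 4] = code  # MISSING=-1 -> index 3
    bytes_per_snp = (n + 3) // 4
    out = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    if m:
        codes = lut[ds.genotypes.T % 4]  # (snps, samples)
        out[:, :n] = codes
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (
        (out.reshape(m, bytes_per_snp, 4) << shifts[None, None, :])
        .sum(axis=2)
        .astype(np.uint8)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# QC and pruning
# ---------------------------------------------------------------------------

def qc_filter(
    ds: GenotypeDataset,
    snp_call_rate: float = 0.95,
    sample_call_rate: float = 0.95,
) -> tuple[GenotypeDataset, QcReport]:
    """Call-rate filter: SNPs first, then samples over the surviving SNPs.

    A SNP (sample) is removed when its fraction of non-missing calls is
    strictly below the threshold.  Removing all SNPs returns an empty dataset
    with a complete report rather than raising.
    """
    for thr in (snp_call_rate, sample_call_rate):
        if not (0 < thr <= 1):
            raise ValueError("call-rate thresholds must be in (0, 1]")
    present = ds.genotypes != MISSING
    n, m = ds.n_samples, ds.n_snps
    snp_keep = np.ones(m, dtype=bool) if n == 0 else present.mean(axis=0) >= snp_call_rate
    kept_present = present[:, snp_keep]
    if kept_present.shape[1] == 0:
        sample_keep = np.ones(n, dtype=bool)
    else:
        sample_keep = kept_present.mean(axis=1) >= sample_call_rate
    out = ds.subset(np.flatnonzero(sample_keep), np.flatnonzero(snp_keep))
    report = QcReport(
        snps_removed=int(m - snp_keep.sum()),
        samples_removed=int(n - sample_keep.sum()),
        snps_kept=int(snp_keep.sum()),
        samples_kept=int(sample_keep.sum()),
        snp_call_rate=snp_call_rate,
        sample_call_rate=sample_call_rate,
    )
    return out, report


def _pairwise_r2_dosage(g: np.ndarray, j: int, k: int) -> float:
    """Complete-case squared Pearson correlation between two dosage columns."""
    x, y = g[:, j].astype(float), g[:, k].astype(float)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return 0.0
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _maf(g: np.ndarray, j: int) -> float:
    col = g[:, j]
    obs = col[col != MISSING].astype(float)
    if obs.size == 0:
        return 0.0
    p = obs.sum() / (2 * obs.size)
    return min(p, 1 - p)


def ld_prune(
    ds: GenotypeDataset,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.2,
) -> list[int]:
    """Greedy windowed LD pruning; returns retained SNP indices in map order.

    Within each window (per chromosome), while any retained pair has
    r² > threshold, the member with the lower MAF is removed (tie: the later
    map position); the window then slides by ``step_snps``.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must be in (0, 1]")
    g = ds.genotypes
    chroms = ds.chromosomes()
    removed = np.zeros(ds.n_snps, dtype=bool)
    mafs = np.array([_maf(g, j) for j in range(ds.n_snps)])
    for chrom in dict.fromkeys(chroms.tolist()):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while True:
            window = idx[start : start + window_snps]
            if window.size >= 2:
                _prune_window(g, window, removed, mafs, r2_threshold)
            if start + window_snps >= idx.size:
                break
            start += step_snps
    return np.flatnonzero(~removed).tolist()


def _prune_window(g, window, removed, mafs, r2_threshold):
    while True:
        live = [j for j in window if not removed[j]]
        worst = None
        for a in range(len(live)):
            for b in range(a + 1, len(live)):
                r2 = _pairwise_r2_dosage(g, live[a], live[b])
                if r2 > r2_threshold:
                    worst = (live[a], live[b])
                    break
            if worst:
                break
        if worst is None:
            return
        ja, jb = worst
        # drop lower-MAF member; tie -> later map position (jb, since sorted)
        if mafs[ja] < mafs[jb]:
            removed[ja] = True
        else:
            removed[jb] = True
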