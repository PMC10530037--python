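"""SNP genotype matrices: I/O, quality filtering, naive imputation and
linkage-disequilibrium redundancy pruning.

The central container is :class:`MarkerMatrix`, an individuals x markers
dosage matrix (counts of one allele, 0/1/2, NaN for missing) together with
a physical map (chromosome, 1-based position).  Markers are kept sorted by
(chromosome, position).  All downstream kernels are built from this matrix
after imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "FilterThresholds",
    "FilterReport",
    "MapSummary",
    "read_genotypes",
    "write_genotypes",
    "filter_markers",
    "impute_naive",
    "prune_redundant",
    "map_summary",
]


class GenotypeFormatError(ValueError):
    """Raised when a genotype file cannot be parsed."""


class GenotypeValidationError(ValueError):
    """Raised when parsed genotype data violates an invariant."""


def _chrom_key(c: str):
    """Sort chromosomes numerically when possible, lexically otherwise."""
    try:
        return (0, int(c), "")
    except (TypeError, ValueError):
        return (1, 0, str(c))


@dataclass
class MarkerMatrix:
    """Biallelic SNP dosages with a physical map.

    Parameters
    ----------
    samples : list of str
        Ordered, unique sample identifiers (rows of ``dosage``).
    markers : list of str
        Ordered, unique marker identifiers (columns of ``dosage``).
    chrom, pos : arrays, one entry per marker
        Chromosome label and 1-based physical position (base pairs).
    dosage : float array, shape (n_samples, n_markers)
        Allele counts in {0, 1, 2}; ``NaN`` marks a missing call.
    pre_imputation_missing_rate : float array or None
        Per-marker fraction of missing calls recorded before imputation.
        Defaults to the missing fraction at construction time.
    """

    samples: list
    markers: list
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    pre_imputation_missing_rate: np.ndarray | None = None
    n_multiallelic_dropped: int = 0

    def __post_init__(self):
        self.samples = list(self.samples)
        self.markers = list(self.markers)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeValidationError("duplicated sample identifiers")
        if len(set(self.markers)) != len(self.markers):
            raise GenotypeValidationError("duplicated marker identifiers")
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise GenotypeValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise GenotypeValidationError("dosage values must be 0, 1, 2 or missing")
        order = sorted(
            range(len(self.markers)),
            key=lambda j: (_chrom_key(self.chrom[j]), self.pos[j], self.markers[j]),
        )
        if order != list(range(len(self.markers))):
            self._take_markers(np.asarray(order))
        if self.pre_imputation_missing_rate is None:
            self.pre_imputation_missing_rate = self.missing_rate()
        else:
            self.pre_imputation_missing_rate = np.asarray(
                self.pre_imputation_missing_rate, dtype=float
            )

    def _take_markers(self, idx: np.ndarray) -> None:
        self.markers = [self.markers[j] for j in idx]
        self.chrom = self.chrom[idx]
        self.pos = self.pos[idx]
        self.dosage = self.dosage[:, idx]
        if self.pre_imputation_missing_rate is not None:
            self.pre_imputation_missing_rate = self.pre_imputation_missing_rate[idx]

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_rate(self) -> np.ndarray:
        """Current per-marker fraction of missing calls."""
        return np.isnan(self.dosage).mean(axis=0)

    def call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_rate()

    def het_rate(self) -> np.ndarray:
        """Per-marker heterozygote fraction among non-missing calls."""
        obs = ~np.isnan(self.dosage)
        n_obs = obs.sum(axis=0)
        n_het = ((self.dosage == 1.0) & obs).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, n_het / n_obs, np.nan)

    def maf(self) -> np.ndarray:
        """Minor allele frequency from non-missing calls (folded)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def subset_markers(self, idx) -> "MarkerMatrix":
        idx = np.asarray(idx)
        return MarkerMatrix(
            samples=self.samples,
            markers=[self.markers[j] for j in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            dosage=self.dosage[:, idx].copy(),
            pre_imputation_missing_rate=self.pre_imputation_missing_rate[idx].copy(),
        )

    def subset_samples(self, sample_ids) -> "MarkerMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in sample_ids])
        return MarkerMatrix(
            samples=list(sample_ids),
            markers=self.markers,
            chrom=self.chrom,
            pos=self.pos,
            dosage=self.dosage[idx, :].copy(),
            pre_imputation_missing_rate=self.pre_imputation_missing_rate.copy(),
        )


@dataclass(frozen=True)
class FilterThresholds:
    """Marker QC thresholds: keep markers with call rate >= ``min_call_rate``,
    heterozygosity <= ``max_het_rate`` and MAF >= ``min_maf``."""

    min_call_rate: float = 0.75
    max_het_rate: float = 0.10
    min_maf: float = 0.05

    def __post_init__(self):
        for name in ("min_call_rate", "max_het_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class FilterReport:
    n_in: int
    n_fail_call_rate: int
    n_fail_het: int
    n_fail_maf: int
    n_out: int
    disposition: pd.Series  # marker id -> "pass" | failing criterion

    def to_tsv(self, path) -> None:
        self.disposition.rename("disposition").to_csv(path, sep="\t", index_label="marker")


@dataclass
class MapSummary:
    mean_adjacent_distance_kb: float  # NaN when no same-chromosome gaps exist
    max_gap_kb: float
    max_gap_chrom: str | None
    n_gaps_over: int
    gap_threshold_kb: float
    per_chrom_gaps_over: dict


# ----------------------------------------------------------------------
# Readers / writers
# ----------------------------------------------------------------------

def read_genotypes(path, format: str, map_path=None) -> MarkerMatrix:
    """Read a genotype file into a :class:`MarkerMatrix`.

    Heterozygous calls are kept as dosage 1 (conversion to missing happens
    in :func:`filter_markers`).  Multi-allelic records are dropped with a
    warning; the count is stored on ``n_multiallelic_dropped``.

    Parameters
    ----------
    format : {"vcf", "hapmap", "csv_dosage"}
    map_path : path, optional
        For ``csv_dosage``: CSV with columns marker, chrom, pos.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "hapmap":
        return _read_hapmap(path)
    if format == "csv_dosage":
        if map_path is None:
            raise ValueError("csv_dosage requires map_path (marker,chrom,pos CSV)")
        return _read_csv_dosage(path, map_path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_vcf(path) -> MarkerMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise GenotypeFormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    markers, chrom, pos, cols = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        markers.append(var.ID or f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(float)
        gt[gt == 2] = np.nan
        gt[gt == 3] = 2.0
        cols.append(gt)
    if n_multi:
        warnings.warn(f"dropped {n_multi} multi-allelic record(s)")
    dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return MarkerMatrix(samples, markers, np.array(chrom, dtype=object),
                        np.array(pos), dosage, n_multiallelic_dropped=n_multi)


_IUPAC_HET = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}


def _read_hapmap(path) -> MarkerMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise GenotypeFormatError(f"cannot parse HapMap file {path}: {exc}") from exc
    required = {"rs#", "alleles", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise GenotypeFormatError(
            f"HapMap file missing required columns {sorted(required - set(df.columns))}"
        )
    sample_cols = list(df.columns[11:])
    markers, chrom, pos, cols = [], [], [], []
    n_multi = 0
    for _, row in df.iterrows():
        alleles = [a for a in str(row["alleles"]).split("/") if a and a != "NA"]
        if len(alleles) != 2:
            n_multi += 1
            continue
        a, b = alleles
        col = np.full(len(sample_cols), np.nan)
        for i, sc in enumerate(sample_cols):
            call = str(row[sc]).upper()
            if call in ("N", "NN", "NAN", "--", "-"):
                continue
            if len(call) == 1:
                call = _IUPAC_HET.get(call, call * 2)
            n_b = sum(1 for c in call if c == b)
            n_a = sum(1 for c in call if c == a)
            if n_a + n_b == len(call):
                col[i] = n_b
        markers.append(row["rs#"])
        chrom.append(row["chrom"])
        pos.append(int(row["pos"]))
        cols.append(col)
    if n_multi:
        warnings.warn(f"dropped {n_multi} non-biallelic HapMap row(s)")
    dosage = np.column_stack(cols) if cols else np.empty((len(sample_cols), 0))
    return MarkerMatrix(sample_cols, markers, np.array(chrom, dtype=object),
                        np.array(pos), dosage, n_multiallelic_dropped=n_multi)


def _read_csv_dosage(path, map_path) -> MarkerMatrix:
    try:
        df = pd.read_csv(path, index_col=0)
        mp = pd.read_csv(map_path, dtype={"marker": str, "chrom": str})
    except Exception as exc:
        raise GenotypeFormatError(f"cannot parse dosage CSV: {exc}") from exc
    if not {"marker", "chrom", "pos"}.issubset(mp.columns):
        raise GenotypeFormatError("map CSV must have columns marker, chrom, pos")
    mp = mp.set_index("marker")
    missing = [m for m in df.columns if m not in mp.index]
    if missing:
        raise GenotypeFormatError(f"markers absent from map: {missing[:5]} ...")
    mp = mp.loc[df.columns]
    extra_cols = [c for c in mp.columns if c not in ("chrom", "pos")]
    pre = mp[extra_cols[0]].to_numpy(float) if "pre_imputation_missing_rate" in extra_cols else None
    return MarkerMatrix(
        samples=[str(s) for s in df.index],
        markers=[str(m) for m in df.columns],
        chrom=mp["chrom"].to_numpy(dtype=object),
        pos=mp["pos"].to_numpy(dtype=np.int64),
        dosage=df.to_numpy(dtype=float),
        pre_imputation_missing_rate=pre,
    )


def write_genotypes(m: MarkerMatrix, path, map_path) -> None:
    """Write CSV dosage (samples x markers) and its chrom/pos side table."""
    pd.DataFrame(m.dosage, index=m.samples, columns=m.markers).to_csv(path)
    pd.DataFrame(
        {
            "marker": m.markers,
            "chrom": m.chrom,
            "pos": m.pos,
            "pre_imputation_missing_rate": m.pre_imputation_missing_rate,
        }
    ).to_csv(map_path, index=False)


# ----------------------------------------------------------------------
# QC operations
# ----------------------------------------------------------------------

def filter_markers(
    m: MarkerMatrix, t: FilterThresholds = FilterThresholds()
) -> tuple[MarkerMatrix, FilterReport]:
    """Discard markers failing call-rate, heterozygosity or MAF thresholds,
    then convert surviving heterozygous calls to missing.

    A marker failing several criteria is attributed to the first failing
    one in the fixed order call-rate -> heterozygosity -> MAF.  The
    per-marker missing fraction *after* the het-to-missing conversion is
    recorded as ``pre_imputation_missing_rate`` (it is the missingness the
    imputer will fill).
    """
    call = m.call_rate()
    het = m.het_rate()
    maf = m.maf()
    fail_call = call < t.min_call_rate
    fail_het = (~fail_call) & (np.nan_to_num(het) > t.max_het_rate)
    fail_maf = (~fail_call) & (~fail_het) & (np.nan_to_num(maf) < t.min_maf)
    keep = ~(fail_call | fail_het | fail_maf)

    disposition = pd.Series("pass", index=pd.Index(m.markers, name="marker"), dtype=object)
    disposition[fail_call] = "call_rate"
    disposition[fail_het] = "het_rate"
    disposition[fail_maf] = "maf"
    report = FilterReport(
        n_in=m.n_markers,
        n_fail_call_rate=int(fail_call.sum()),
        n_fail_het=int(fail_het.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_out=int(keep.sum()),
        disposition=disposition,
    )
    if report.n_out == 0:
        raise GenotypeValidationError("no markers survive the QC thresholds")
    out = m.subset_markers(np.flatnonzero(keep))
    out.dosage[out.dosage == 1.0] = np.nan  # remaining heterozygotes -> missing
    out.pre_imputation_missing_rate = out.missing_rate()
    return out, report


def impute_naive(m: MarkerMatrix, method: str = "mode") -> MarkerMatrix:
    """Fill missing calls per marker from its non-missing calls.

    ``mode`` uses the most frequent dosage (ties broken toward the smaller
    dosage); ``mean_rounded`` rounds the marker mean to the nearest integer
    (half away from zero).  ``pre_imputation_missing_rate`` is preserved.
    """
    if method not in ("mode", "mean_rounded"):
        raise ValueError(f"unknown imputation method {method!r}")
    dosage = m.dosage.copy()
    miss = np.isnan(dosage)
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = [m.markers[j] for j in np.flatnonzero(all_missing)]
        raise GenotypeValidationError(f"markers with no observed calls: {bad[:5]}")
    for j in np.flatnonzero(miss.any(axis=0)):
        col = dosage[:, j]
        obs = col[~np.isnan(col)]
        if method == "mode":
            counts = [(obs == v).sum() for v in (0.0, 1.0, 2.0)]
            fill = float(np.argmax(counts))
        else:
            fill = float(np.floor(obs.mean() + 0.5))
        col[np.isnan(col)] = fill
    return replace(
        m,
        dosage=dosage,
        pre_imputation_missing_rate=m.pre_imputation_missing_rate.copy(),
    )


def prune_redundant(m: MarkerMatrix) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Remove markers in complete linkage disequilibrium (pairwise r^2 = 1).

    Columns are clustered when their dosage vectors are perfectly linearly
    related (identical, allele-flipped, or otherwise |r| = 1 within 1e-12);
    one representative per cluster is kept, chosen by lowest
    ``pre_imputation_missing_rate``, then highest MAF, then map order.
    Requires imputed (missing-free) dosages.

    Returns the pruned matrix and a cluster report (marker, cluster id,
    representative flag).
    """
    if np.isnan(m.dosage).any():
        raise GenotypeValidationError("prune_redundant requires imputed dosages")
    n, p = m.dosage.shape
    # Canonical standardized column signature: |r| = 1 iff signatures match.
    keys = []
    sd = m.dosage.std(axis=0)
    for j in range(p):
        col = m.dosage[:, j]
        if sd[j] == 0.0:
            keys.append(("const", j))  # r^2 undefined: singleton cluster
            continue
        z = (col - col.mean()) / sd[j]
        nz = z[np.abs(z) > 1e-9]
        if nz.size and nz[0] < 0:
            z = -z
        keys.append(("z", np.round(z, 9).tobytes()))
    clusters: dict = {}
    for j, key in enumerate(keys):
        clusters.setdefault(key, []).append(j)

    maf = m.maf()
    pre = m.pre_imputation_missing_rate
    keep = []
    records = []
    for cid, (key, members) in enumerate(sorted(clusters.items(), key=lambda kv: kv[1][0])):
        rep = min(
            members,
            key=lambda j: (pre[j], -maf[j], _chrom_key(m.chrom[j]), m.pos[j], m.markers[j]),
        )
        keep.append(rep)
        for j in members:
            records.append({"marker": m.markers[j], "cluster": cid,
                            "representative": j == rep})
    keep = np.sort(np.array(keep))
    report = pd.DataFrame.from_records(records)
    return m.subset_markers(keep), report


def map_summary(m: MarkerMatrix, gap_threshold_kb: float = 500.0) -> MapSummary:
    """Adjacent-marker spacing statistics, within chromosomes only."""
    gaps_bp = []
    per_chrom = {}
    max_gap = 0.0
    max_chrom = None
    for c in pd.unique(m.chrom):
        pos = np.sort(m.pos[m.chrom == c])
        if pos.size < 2:
            per_chrom[c] = 0
            continue
        g = np.diff(pos).astype(float)
        gaps_bp.append(g)
        per_chrom[c] = int((g / 1000.0 > gap_threshold_kb).sum())
        if g.max() > max_gap:
            max_gap = float(g.max())
            max_chrom = c
    if gaps_bp:
        allg = np.concatenate(gaps_bp)
        mean_kb = float(allg.mean() / 1000.0)
        n_over = int((allg / 1000.0 > gap_threshold_kb).sum())
    else:
        mean_kb, n_over = float("nan"), 0
    return MapSummary(
        mean_adjacent_distance_kb=mean_kb,
        max_gap_kb=max_gap / 1000.0,
        max_gap_chrom=max_chrom,
        n_gaps_over=n_over,
        gap_threshold_kb=gap_threshold_kb,
        per_chrom_gaps_over=per_chrom,
    )
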