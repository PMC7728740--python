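"""Genotype/phenotype containers, readers for standard formats, and marker QC.

Genotypes are biallelic SNP dosages coded 0/1/2 (count of the tracked allele;
for VCF input this is the ALT allele). Missing entries are NaN until
:func:`filter_markers` imputes them to the column mean, after which dosages may
be fractional. Phenotypes are per-sample trait values assumed pre-corrected for
non-genetic (design) effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "GenotypeFormatError",
    "read_genotypes",
    "read_phenotypes",
    "write_genotypes",
    "write_phenotypes",
    "filter_markers",
]


class GenotypeFormatError(ValueError):
    """Raised when an input file violates the genotype format contract."""


def _allele_freq(dosage: np.ndarray) -> np.ndarray:
    """Frequency of the counted allele per marker, ignoring missing entries."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(dosage, axis=0) / 2.0


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with marker metadata.

    ``dosage`` holds counts of the tracked allele in {0,1,2}, NaN for missing;
    after mean imputation entries may be real-valued. ``allele_freq`` is the
    frequency p_i of the counted allele among non-missing samples.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    allele_freq: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=int)
        n, p = self.dosage.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if not (len(self.marker_ids) == len(self.chrom) == len(self.pos) == p):
            raise ValueError("marker metadata length does not match dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if self.allele_freq is None:
            self.allele_freq = _allele_freq(self.dosage)
        else:
            self.allele_freq = np.asarray(self.allele_freq, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Row subset with allele frequencies recomputed on the kept samples."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            marker_ids=list(self.marker_ids),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            dosage=self.dosage[idx].copy(),
        )

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            marker_ids=[self.marker_ids[j] for j in idx],
            chrom=self.chrom[idx].copy(),
            pos=self.pos[idx].copy(),
            dosage=self.dosage[:, idx].copy(),
        )


@dataclass
class PhenotypeTable:
    """Per-sample pre-corrected values for one trait (optionally one environment)."""

    sample_ids: list[str]
    trait: str
    value: np.ndarray
    environment: str | None = None

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=float)
        if len(self.sample_ids) != len(self.value):
            raise ValueError("one value per sample required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in phenotype table")

    def __len__(self) -> int:
        return len(self.value)

    def aligned_to(self, G: GenotypeMatrix) -> np.ndarray:
        """Values reordered to G's samples; error on unresolvable ids."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            order = [lookup[s] for s in G.sample_ids]
        except KeyError as exc:  # pragma: no cover - message path
            raise ValueError(f"sample {exc} missing from phenotype table") from exc
        return self.value[order]

    def subset(self, idx: np.ndarray) -> "PhenotypeTable":
        idx = np.asarray(idx)
        return PhenotypeTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            trait=self.trait,
            value=self.value[idx].copy(),
            environment=self.environment,
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"NA", "NaN", "nan", ".", "./.", ""}


def _validate_dosage_frame(df: pd.DataFrame, path: str) -> np.ndarray:
    values = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        cell = df[col]
        for i, v in enumerate(cell):
            if isinstance(v, str):
                v = v.strip()
                if v in _MISSING_TOKENS:
                    continue
                try:
                    v = float(v)
                except ValueError:
                    raise GenotypeFormatError(
                        f"{path}: non-numeric dosage {v!r} at row {i + 1}, column {col!r}"
                    )
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            if v not in (0.0, 1.0, 2.0):
                raise GenotypeFormatError(
                    f"{path}: dosage {v} outside {{0,1,2}} at row {i + 1}, column {col!r}"
                )
            values[i, j] = v
    return values


def read_genotypes(path: str, format: str = "table", map_path: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from a delimited table, PLINK .raw, or VCF.

    Table dialect: first column sample id, remaining columns one marker each
    (header = marker ids), entries in {0,1,2} or NA. PLINK .raw: whitespace
    separated, first six columns (FID..PHENOTYPE) skipped, IID used as sample
    id. VCF: biallelic SNPs only; GT 0/0, 0/1, 1/1 map to ALT dosage 0, 1, 2.

    ``map_path`` optionally points to a delimited table with columns
    (marker, chrom, pos) supplying coordinates for table/.raw input.
    """
    if format == "table":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str)
        sample_ids = [str(s) for s in df.index]
        marker_ids = [str(c) for c in df.columns]
        dosage = _validate_dosage_frame(df, path)
    elif format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        if df.shape[1] < 7:
            raise GenotypeFormatError(f"{path}: PLINK .raw needs >= 7 columns")
        sample_ids = [str(s) for s in df["IID"]]
        geno = df.iloc[:, 6:]
        marker_ids = [str(c) for c in geno.columns]
        dosage = _validate_dosage_frame(geno.astype(object), path)
    elif format == "vcf":
        return _read_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    chrom = np.array(["0"] * len(marker_ids), dtype=object)
    pos = np.arange(1, len(marker_ids) + 1)
    if map_path is not None:
        mp = pd.read_csv(map_path, sep=None, engine="python", dtype={0: str})
        mp = mp.set_index(mp.columns[0])
        chrom = np.array([str(mp.loc[m].iloc[0]) for m in marker_ids], dtype=object)
        pos = np.array([int(mp.loc[m].iloc[1]) for m in marker_ids])
    return GenotypeMatrix(sample_ids, marker_ids, chrom, pos, dosage)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    marker_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise GenotypeFormatError(
                f"{path}: non-biallelic-SNP record at {rec.CHROM}:{rec.POS}"
            )
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = rec.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
        marker_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        chrom.append(str(rec.CHROM))
        pos.append(int(rec.POS))
    dosage = np.column_stack(rows) if rows else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids, marker_ids, np.array(chrom, dtype=object), np.array(pos), dosage)


def write_genotypes(G: GenotypeMatrix, path: str, map_path: str | None = None) -> None:
    """Write the table dialect (and optionally a marker map) read back by read_genotypes."""
    df = pd.DataFrame(G.dosage, index=G.sample_ids, columns=G.marker_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", na_rep="NA")
    if map_path is not None:
        pd.DataFrame({"marker": G.marker_ids, "chrom": G.chrom, "pos": G.pos}).to_csv(
            map_path, sep="\t", index=False
        )


def read_phenotypes(path: str) -> dict[str, PhenotypeTable]:
    """Read a delimited phenotype table: first column sample id, one column per trait.

    Returns one PhenotypeTable per trait column; non-numeric cells become NaN.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    sample_ids = [str(s) for s in df.index]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicated sample ids {dupes}")
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        out[str(col)] = PhenotypeTable(sample_ids, str(col), vals)
    return out


def write_phenotypes(tables: dict[str, PhenotypeTable] | PhenotypeTable, path: str) -> None:
    if isinstance(tables, PhenotypeTable):
        tables = {tables.trait: tables}
    first = next(iter(tables.values()))
    df = pd.DataFrame({t.trait: t.value for t in tables.values()}, index=first.sample_ids)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# marker QC
# ---------------------------------------------------------------------------


def filter_markers(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    missing_max: float = 0.10,
    subsample: int | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """QC filter: drop low-MAF and high-missingness markers, then mean-impute.

    Markers with MAF < ``maf_min`` (MAF = min(p, 1-p) over non-missing samples)
    or missing fraction > ``missing_max`` are removed. If ``subsample`` is
    given, a seeded uniform random subset of that many surviving markers is
    retained (input order preserved). Remaining missing dosages are imputed to
    the column mean so downstream models see a complete matrix.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= missing_max <= 1:
        raise ValueError("missing_max must be in [0, 1]")
    X = G.dosage
    miss_frac = np.mean(np.isnan(X), axis=0)
    freq = _allele_freq(X)
    maf = np.minimum(freq, 1.0 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)
    keep = np.flatnonzero((maf >= maf_min) & (miss_frac <= missing_max))
    if subsample is not None:
        if subsample > keep.size:
            raise ValueError(
                f"subsample={subsample} exceeds {keep.size} markers surviving QC"
            )
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(keep, size=subsample, replace=False))
    out = G.subset_markers(keep)
    X = out.dosage  # already a copy
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(col_mean, inds[1])
        out.allele_freq = _allele_freq(X)
    return out
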