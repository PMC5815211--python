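"""Readers, writers and in-memory containers for methylation data.

Internal coordinate convention is 0-based half-open everywhere.  The
bismark coverage dialect is 1-based inclusive on its start column, so
``pos = start - 1`` on read and ``start = pos + 1`` on write.

Containers are thin validated wrappers around pandas objects.  Sites are
identified by a two-level ``(chrom, pos)`` MultiIndex; samples by string
ids carried on the columns and described by a sample sheet with, at
minimum, the age of each sample in weeks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("admp.ioformats")

_FLOAT_FMT = "%.17g"  # lossless for float64 round trips

SITE_INDEX_NAMES = ("chrom", "pos")


def site_index(chroms: Iterable[str], positions: Iterable[int]) -> pd.MultiIndex:
    """Build the canonical (chrom, pos) site index; positions are 0-based."""
    pos = np.asarray(list(positions), dtype=np.int64)
    if (pos < 0).any():
        raise ValueError("site positions must be non-negative")
    return pd.MultiIndex.from_arrays(
        [list(chroms), pos], names=SITE_INDEX_NAMES
    )


def _check_site_index(index: pd.Index, what: str) -> None:
    if not isinstance(index, pd.MultiIndex) or tuple(index.names) != SITE_INDEX_NAMES:
        raise ValueError(f"{what} must be indexed by a (chrom, pos) MultiIndex")
    if index.has_duplicates:
        dups = index[index.duplicated()].tolist()
        raise ValueError(f"duplicate sites in {what}: {dups[:5]}")


def _check_sample_meta(meta: pd.DataFrame, samples: Sequence[str]) -> None:
    missing = [s for s in samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples absent from sample sheet: {missing}")
    if "age_weeks" not in meta.columns:
        raise ValueError("sample sheet must have an 'age_weeks' column")
    ages = meta.loc[list(samples), "age_weeks"]
    if ages.isna().any():
        bad = ages.index[ages.isna()].tolist()
        raise ValueError(f"missing age_weeks for samples: {bad}")
    if (ages < 0).any():
        bad = ages.index[ages < 0].tolist()
        raise ValueError(f"negative age_weeks for samples: {bad}")


@dataclass
class BetaMatrix:
    """Sites x samples methylation fractions with per-sample age metadata.

    ``values``: float DataFrame, rows indexed by (chrom, pos), columns are
    sample ids, entries in [0, 1] or NaN for missing.
    ``sample_meta``: DataFrame indexed by sample id with at least
    ``age_weeks``; ``species`` and ``group`` are optional annotations.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_site_index(self.values.index, "BetaMatrix")
        self.values = self.values.astype(float)
        self.values.columns = pd.Index(map(str, self.values.columns), name=None)
        self.sample_meta.index.name = "sample_id"
        v = self.values.to_numpy()
        bad = (v < 0) | (v > 1)
        if np.nansum(bad):
            i, j = np.argwhere(np.nan_to_num(bad, nan=False))[0]
            site = self.values.index[i]
            samp = self.values.columns[j]
            raise ValueError(
                f"beta value {v[i, j]!r} outside [0, 1] at site {site}, sample {samp}"
            )
        _check_sample_meta(self.sample_meta, list(self.values.columns))

    @property
    def sites(self) -> pd.MultiIndex:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def ages_weeks(self) -> np.ndarray:
        return self.sample_meta.loc[self.samples, "age_weeks"].to_numpy(float)

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values[list(samples)], self.sample_meta.loc[list(samples)])


@dataclass
class CountMatrix:
    """Per-site methylated / total read counts per sample.

    Missing cells are encoded as ``total == 0``.  ``to_beta`` collapses to
    a :class:`BetaMatrix` with NaN wherever coverage is zero.
    """

    methylated: pd.DataFrame
    total: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        _check_site_index(self.methylated.index, "CountMatrix")
        if not self.methylated.index.equals(self.total.index) or list(
            self.methylated.columns
        ) != list(self.total.columns):
            raise ValueError("methylated and total matrices must be aligned")
        self.methylated = self.methylated.astype(np.int64)
        self.total = self.total.astype(np.int64)
        for df in (self.methylated, self.total):
            df.columns = pd.Index(map(str, df.columns), name=None)
        self.sample_meta.index.name = "sample_id"
        m, t = self.methylated.to_numpy(), self.total.to_numpy()
        if (m < 0).any() or (t < 0).any():
            raise ValueError("counts must be non-negative")
        if (m > t).any():
            raise ValueError("methylated count exceeds total count")
        _check_sample_meta(self.sample_meta, list(self.methylated.columns))

    @property
    def sites(self) -> pd.MultiIndex:
        return self.methylated.index

    @property
    def samples(self) -> list[str]:
        return list(self.methylated.columns)

    def to_beta(self) -> BetaMatrix:
        t = self.total.to_numpy(float)
        m = self.methylated.to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(t > 0, m / np.where(t > 0, t, 1), np.nan)
        values = pd.DataFrame(beta, index=self.sites, columns=self.samples)
        return BetaMatrix(values, self.sample_meta)


@dataclass
class MappingTable:
    """1:1 cross-species CpG correspondences (liftOver-style output).

    Rows pair a site in genome A with a site in genome B together with the
    fraction of bases that remapped; rows below the configured minimum
    match fraction are dropped on read and counted in ``n_dropped``.
    """

    table: pd.DataFrame  # columns chrom_a, pos_a, chrom_b, pos_b, match_fraction
    min_match: float = 0.9
    n_dropped: int = 0

    COLUMNS = ("chrom_a", "pos_a", "chrom_b", "pos_b", "match_fraction")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"mapping table missing columns: {missing}")
        for side in "ab":
            keys = list(zip(self.table[f"chrom_{side}"], self.table[f"pos_{side}"]))
            if len(keys) != len(set(keys)):
                raise ValueError(f"ambiguous mapping: duplicate site on side {side!r}")
        mf = self.table["match_fraction"].to_numpy(float)
        if len(mf) and (mf < self.min_match).any():
            raise ValueError(
                f"match_fraction below the configured minimum {self.min_match}"
            )

    def sites_a(self) -> pd.MultiIndex:
        return site_index(self.table["chrom_a"], self.table["pos_a"])

    def sites_b(self) -> pd.MultiIndex:
        return site_index(self.table["chrom_b"], self.table["pos_b"])

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# provenance-aware TSV helpers

def _write_tsv(df: pd.DataFrame, path: Path | str, header: Mapping[str, object] | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="NA")


def _read_tsv(path: Path | str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], **kwargs)


# ---------------------------------------------------------------------------
# beta matrices and sample sheets

def write_beta_matrix(
    beta: BetaMatrix,
    matrix_path: Path | str,
    sample_sheet_path: Path | str,
    header: Mapping[str, object] | None = None,
) -> None:
    df = beta.values.reset_index()
    _write_tsv(df, matrix_path, header)
    write_sample_sheet(beta.sample_meta, sample_sheet_path, header)


def write_sample_sheet(
    meta: pd.DataFrame, path: Path | str, header: Mapping[str, object] | None = None
) -> None:
    df = meta.reset_index().rename(columns={meta.index.name or "index": "sample_id"})
    _write_tsv(df, path, header)


def read_sample_sheet(path: Path | str) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: sample sheet must have a sample_id column")
    return df.set_index("sample_id")


def read_beta_matrix(matrix_path: Path | str, sample_sheet_path: Path | str) -> BetaMatrix:
    df = _read_tsv(matrix_path, dtype={"chrom": str})
    for col in SITE_INDEX_NAMES:
        if col not in df.columns:
            raise ValueError(f"{matrix_path}: missing column {col!r}")
    meta = read_sample_sheet(sample_sheet_path)
    samples = [c for c in df.columns if c not in SITE_INDEX_NAMES]
    unknown = [s for s in samples if s not in meta.index]
    if unknown:
        raise ValueError(f"{matrix_path}: samples not in sheet: {unknown}")
    values = df.set_index(list(SITE_INDEX_NAMES))[samples]
    values.index = site_index(
        df["chrom"], df["pos"].astype(np.int64)
    )
    return BetaMatrix(values, meta)


# ---------------------------------------------------------------------------
# bismark coverage files

def write_bismark_cov(counts: CountMatrix, outdir: Path | str) -> dict[str, Path]:
    """One ``<sample>.cov`` per sample; zero-coverage cells are omitted."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    chroms = counts.sites.get_level_values("chrom")
    poss = counts.sites.get_level_values("pos").to_numpy()
    for sample in counts.samples:
        m = counts.methylated[sample].to_numpy()
        t = counts.total[sample].to_numpy()
        keep = t > 0
        path = outdir / f"{sample}.cov"
        with open(path, "w") as fh:
            for chrom, pos, mi, ti in zip(chroms[keep], poss[keep], m[keep], t[keep]):
                start = pos + 1  # 0-based internal -> 1-based bismark
                pct = 100.0 * mi / ti
                fh.write(f"{chrom}\t{start}\t{start}\t{_FLOAT_FMT % pct}\t{mi}\t{ti - mi}\n")
        paths[sample] = path
    return paths


def read_bismark_cov(paths: Mapping[str, Path | str], sample_sheet: pd.DataFrame) -> CountMatrix:
    """Read one coverage file per sample into an aligned count matrix.

    Sites are the union across samples, sorted by (chrom, pos); cells for
    sites a sample does not report are missing (total 0).
    """
    missing_files = [s for s in sample_sheet.index if s not in paths]
    if missing_files:
        raise ValueError(f"sample(s) in sheet without coverage file: {missing_files}")
    per_sample: dict[str, dict[tuple[str, int], tuple[int, int]]] = {}
    for sample, path in paths.items():
        records: dict[tuple[str, int], tuple[int, int]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) != 6:
                    raise ValueError(
                        f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}"
                    )
                try:
                    chrom, start = fields[0], int(fields[1])
                    n_meth, n_unmeth = int(fields[4]), int(fields[5])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from None
                records[(chrom, start - 1)] = (n_meth, n_meth + n_unmeth)
        if not records:
            log.warning("coverage file %s is empty; sample %s will be all-missing", path, sample)
        per_sample[sample] = records
    all_sites = sorted({k for recs in per_sample.values() for k in recs})
    index = site_index([c for c, _ in all_sites], [p for _, p in all_sites])
    samples = list(paths)
    meth = np.zeros((len(all_sites), len(samples)), dtype=np.int64)
    tot = np.zeros_like(meth)
    for j, sample in enumerate(samples):
        recs = per_sample[sample]
        for i, key in enumerate(all_sites):
            if key in recs:
                meth[i, j], tot[i, j] = recs[key]
    return CountMatrix(
        pd.DataFrame(meth, index=index, columns=samples),
        pd.DataFrame(tot, index=index, columns=samples),
        sample_sheet,
    )


# ---------------------------------------------------------------------------
# mapping tables

def write_mapping(mapping: MappingTable, path: Path | str, header: Mapping[str, object] | None = None) -> None:
    _write_tsv(mapping.table[list(MappingTable.COLUMNS)], path, header)


def read_mapping(path: Path | str, min_match: float = 0.9) -> MappingTable:
    """Read a site correspondence table, dropping rows below ``min_match``.

    The threshold is inclusive: a row with match_fraction exactly equal to
    ``min_match`` is retained.
    """
    df = _read_tsv(path, dtype={"chrom_a": str, "chrom_b": str})
    missing = [c for c in MappingTable.COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: mapping table missing columns {missing}")
    below = df["match_fraction"] < min_match
    n_dropped = int(below.sum())
    if n_dropped:
        log.info("dropped %d mapping rows below match_fraction %.3f", n_dropped, min_match)
    kept = df.loc[~below].reset_index(drop=True)
    return MappingTable(kept, min_match=min_match, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# BED intervals (regions, annotations, keep-lists)

def write_regions_bed(regions: pd.DataFrame, path: Path | str, header: Mapping[str, object] | None = None) -> None:
    """Regions as BED plus extra columns n_admps, gradient, min_p."""
    df = regions.copy()
    df.insert(3, "name", [f"region_{i}" for i in range(len(df))])
    _write_tsv(df[["chrom", "start", "end", "name", "n_admps", "gradient", "min_p"]], path, header)


def read_regions_bed(path: Path | str) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"chrom": str})
    return df[["chrom", "start", "end", "n_admps", "gradient", "min_p"]]


def read_bed(path: Path | str) -> pd.DataFrame:
    """Plain 3+ column BED (0-based half-open) into chrom/start/end."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, dtype={0: str}
    ).iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: BED intervals must satisfy start < end")
    return df


def write_bed(df: pd.DataFrame, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# generic site tables (truth tables, fit tables)

def write_site_table(df: pd.DataFrame, path: Path | str, header: Mapping[str, object] | None = None) -> None:
    """Write a table whose index is the (chrom, pos) site MultiIndex."""
    _check_site_index(df.index, "site table")
    _write_tsv(df.reset_index(), path, header)


def read_site_table(path: Path | str) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"chrom": str})
    idx = site_index(df["chrom"], df["pos"].astype(np.int64))
    return df.drop(columns=list(SITE_INDEX_NAMES)).set_index(idx)
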