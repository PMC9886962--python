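"""Readers/writers for the formats the pipeline touches and the core
in-memory containers.

Conventions
-----------
* Dosages count copies of the ALT allele: 0 (hom REF), 1 (het), 2 (hom ALT).
  Missing calls use the sentinel :data:`MISSING` (-1); after imputation the
  dosage matrix is float-valued and sentinel-free.
* All genomic coordinates are 1-based inclusive (VCF convention). BED input
  is converted at the boundary.
* Reading is order-preserving: individuals and loci keep file order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call in integer dosage matrices.
MISSING = -1


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci ALT-allele dosage matrix with metadata.

    Attributes
    ----------
    dosages : ndarray, shape (n_individuals, n_loci)
        Integer dosages in {0, 1, 2, MISSING}, or floats after imputation.
    loci : DataFrame with columns ``chrom, pos, ref, alt``
        One row per locus, in matrix column order.
    individuals : DataFrame with columns ``id, population, site``
        One row per individual, in matrix row order.
    """

    dosages: np.ndarray
    loci: pd.DataFrame
    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x loci)")
        n, L = self.dosages.shape
        if len(self.loci) != L:
            raise ValueError(f"{L} dosage columns but {len(self.loci)} locus records")
        if len(self.individuals) != n:
            raise ValueError(
                f"{n} dosage rows but {len(self.individuals)} individual records"
            )
        ids = self.individuals["id"]
        if ids.duplicated().any():
            raise ValueError("duplicated individual ids")
        if np.issubdtype(self.dosages.dtype, np.integer):
            bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
            if bad.any():
                raise ValueError(
                    f"dosage values outside {{0,1,2,missing}} at {bad.sum()} cells"
                )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def is_missing(self) -> np.ndarray:
        """Boolean mask of missing calls."""
        if np.issubdtype(self.dosages.dtype, np.integer):
            return self.dosages == MISSING
        return np.isnan(self.dosages)

    def allele_freqs(self) -> np.ndarray:
        """Per-locus ALT allele frequency over non-missing calls (NaN if none)."""
        d = self.dosages.astype(float)
        d[self.is_missing()] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(d, axis=0) / 2.0

    def subset(self, ind_idx=None, locus_idx=None) -> "GenotypeMatrix":
        """Row/column subset preserving order of the given indices."""
        ind_idx = np.arange(self.n_individuals) if ind_idx is None else np.asarray(ind_idx)
        locus_idx = np.arange(self.n_loci) if locus_idx is None else np.asarray(locus_idx)
        return GenotypeMatrix(
            self.dosages[np.ix_(ind_idx, locus_idx)],
            self.loci.iloc[locus_idx].reset_index(drop=True),
            self.individuals.iloc[ind_idx].reset_index(drop=True),
        )

    def locus_names(self) -> list[str]:
        return [
            f"{c}:{p}:{r}:{a}"
            for c, p, r, a in zip(
                self.loci["chrom"], self.loci["pos"], self.loci["ref"], self.loci["alt"]
            )
        ]


@dataclass
class EnvTable:
    """Site x environmental-predictor table (the explanatory matrix X).

    ``data`` is indexed by site label; every column is a numeric predictor.
    ``zones`` optionally maps site -> soil-zone label; ``units`` is free-form
    per-predictor metadata.
    """

    data: pd.DataFrame
    zones: pd.Series | None = None
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("EnvTable must not contain missing values after loading")

    @property
    def sites(self) -> list[str]:
        return list(self.data.index)

    @property
    def predictors(self) -> list[str]:
        return list(self.data.columns)

    def expand_to_individuals(self, site_labels) -> pd.DataFrame:
        """Broadcast site-level predictors to individuals by their site label.

        Individuals from sites absent from the table are not representable;
        callers should drop them first (see :func:`restrict_to_env_sites`).
        """
        missing = set(site_labels) - set(self.data.index)
        if missing:
            raise KeyError(f"sites without environmental data: {sorted(missing)}")
        return self.data.loc[list(site_labels)].reset_index(drop=True)


def restrict_to_env_sites(G: GenotypeMatrix, env: EnvTable) -> GenotypeMatrix:
    """Drop individuals whose site has no environmental record (with a warning)."""
    keep = G.individuals["site"].isin(env.data.index).to_numpy()
    if not keep.all():
        dropped = sorted(set(G.individuals.loc[~keep, "site"]))
        warnings.warn(
            f"excluding {int((~keep).sum())} individuals from sites without "
            f"environmental data: {dropped}"
        )
    return G.subset(ind_idx=np.flatnonzero(keep))


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive coordinates."""

    intervals: pd.DataFrame  # chrom, start, end, gene_id, description

    def __post_init__(self) -> None:
        iv = self.intervals
        if (iv["start"] > iv["end"]).any():
            raise ValueError("annotation interval with start > end")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, strict: bool = True) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF 4.x file.

    GT coding: 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing; phased
    separators are accepted. In strict mode a record with more than one ALT
    allele raises :class:`FormatError`; otherwise it is skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    meta = []
    for var in vcf:
        if len(var.ALT) != 1:
            msg = f"non-biallelic record {var.CHROM}:{var.POS}"
            if strict:
                raise FormatError(msg)
            warnings.warn(msg + " skipped")
            continue
        gts = var.genotype.array()  # (n, 3): allele1, allele2, phased
        a1, a2 = gts[:, 0], gts[:, 1]
        dos = np.where((a1 < 0) | (a2 < 0), MISSING, a1 + a2)
        rows.append(dos.astype(np.int8))
        meta.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    if not meta:
        raise FormatError(f"no usable biallelic records in {path}")
    loci = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"])
    individuals = pd.DataFrame(
        {"id": samples, "population": pd.NA, "site": pd.NA}
    )
    return GenotypeMatrix(np.column_stack(rows), loci, individuals)


def write_vcf(path, G: GenotypeMatrix) -> None:
    """Write a minimal VCF 4.2 with diploid GT, one ALT per record."""
    if not np.issubdtype(G.dosages.dtype, np.integer):
        raise ValueError("cannot write imputed (non-integer) dosages as GT calls")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(G.loci["chrom"]):
            length = int(G.loci.loc[G.loci["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.individuals["id"])
            + "\n"
        )
        for j, (_, loc) in enumerate(G.loci.iterrows()):
            calls = "\t".join(gt_map[int(d)] for d in G.dosages[:, j])
            fh.write(
                f"{loc.chrom}\t{loc.pos}\t.\t{loc.ref}\t{loc.alt}\t.\tPASS\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# Dosage / environment / phenotype TSV
# ---------------------------------------------------------------------------

def write_dosage_tsv(path, G: GenotypeMatrix) -> None:
    """Dosage TSV: id/population/site columns then one ``chrom:pos:ref:alt``
    column per locus; missing written as NA."""
    df = pd.DataFrame(G.dosages, columns=G.locus_names())
    if np.issubdtype(G.dosages.dtype, np.integer):
        df = df.astype(object).mask(df == MISSING, "NA")
    df.insert(0, "site", G.individuals["site"].to_numpy())
    df.insert(0, "population", G.individuals["population"].to_numpy())
    df.insert(0, "id", G.individuals["id"].to_numpy())
    df.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Read the dosage TSV written by :func:`write_dosage_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = [c for c in ("id", "population", "site") if c in df.columns]
    if "id" not in meta_cols:
        raise FormatError(f"{path}: dosage TSV needs an 'id' column")
    locus_cols = [c for c in df.columns if c not in meta_cols]
    loci_meta = []
    for c in locus_cols:
        parts = c.split(":")
        if len(parts) != 4:
            raise FormatError(f"{path}: locus column {c!r} is not chrom:pos:ref:alt")
        loci_meta.append((parts[0], int(parts[1]), parts[2], parts[3]))
    raw = df[locus_cols].to_numpy()
    dos = np.full(raw.shape, MISSING, dtype=np.int8)
    valid = {"0": 0, "1": 1, "2": 2}
    for (i, j), v in np.ndenumerate(raw):
        if isinstance(v, str) and v not in ("NA", ""):
            if v not in valid:
                raise FormatError(
                    f"{path}: line {i + 2}: dosage {v!r} not in {{0,1,2,NA}}"
                )
            dos[i, j] = valid[v]
        elif isinstance(v, str):
            pass  # NA / empty -> missing
        elif pd.isna(v):
            pass
    individuals = pd.DataFrame(
        {
            "id": df["id"],
            "population": df.get("population", pd.Series(pd.NA, index=df.index)),
            "site": df.get("site", pd.Series(pd.NA, index=df.index)),
        }
    )
    loci = pd.DataFrame(loci_meta, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(dos, loci, individuals)


def read_env_table(path) -> EnvTable:
    """Read a site-level environmental table (TSV with a ``site`` column).

    Sites with any empty cell are dropped with a warning — they cannot enter
    a regression-based association scan.
    """
    df = pd.read_csv(path, sep="\t")
    if "site" not in df.columns:
        raise FormatError(f"{path}: environment TSV needs a 'site' column")
    if df["site"].duplicated().any():
        raise FormatError(f"{path}: duplicated site labels")
    df = df.set_index("site")
    zones = None
    if "zone" in df.columns:
        zones = df.pop("zone")
    incomplete = df.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"dropping sites with missing environmental data: "
            f"{sorted(df.index[incomplete])}"
        )
        df = df.loc[~incomplete]
        if zones is not None:
            zones = zones.loc[df.index]
    df = df.apply(pd.to_numeric)
    return EnvTable(df, zones=zones)


def read_phenotypes(path) -> pd.DataFrame:
    """Per-genotype phenotype TSV keyed by ``id``; trait columns numeric."""
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise FormatError(f"{path}: phenotype TSV needs an 'id' column")
    if df["id"].duplicated().any():
        raise FormatError(f"{path}: duplicated individual ids")
    return df.set_index("id")


# ---------------------------------------------------------------------------
# Annotation (GFF3 / BED)
# ---------------------------------------------------------------------------

def read_annotation(path, feature_type: str = "gene") -> GeneAnnotation:
    """Read gene intervals from GFF3 or BED.

    GFF3 coordinates are already 1-based inclusive; BED (0-based half-open)
    is converted so that a BED line ``chr1 99 200`` becomes chr1:100-200.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed",):
        return _read_bed(path)
    return _read_gff3(path, feature_type)


def _read_bed(path) -> GeneAnnotation:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            gene_id = parts[3] if len(parts) > 3 else f"{chrom}:{start0 + 1}-{end}"
            rows.append((chrom, start0 + 1, end, gene_id, ""))
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "description"])
    )


def _read_gff3(path, feature_type: str) -> GeneAnnotation:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: line {lineno}: GFF3 needs 9 columns")
            chrom, _, ftype, start, end, _, _, _, attrs = parts
            if ftype != feature_type:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr.get("ID") or attr.get("Name") or f"{chrom}:{start}-{end}"
            rows.append(
                (chrom, int(start), int(end), gene_id, attr.get("description", ""))
            )
    if not rows:
        raise FormatError(f"{path}: no {feature_type!r} features found")
    return GeneAnnotation(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "description"])
    )
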