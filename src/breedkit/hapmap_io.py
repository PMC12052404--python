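"""Reading, validation and writing of the pipeline's file formats.

Genotypes come in as tab-delimited HapMap text: eleven fixed metadata
columns (``rs#, alleles, chrom, pos, strand, assembly#, center, protLSID,
assayLSID, panelLSID, QCcode``) followed by one column per individual.
Genotype calls are encoded either as two-letter diplotypes (``AG``) or as
single IUPAC codes (``R``); both dialects are accepted and auto-detected.
Calls are converted to alternate-allele dosages (0/1/2), with ``NN``/``N``/
``--`` treated as missing.

Breed membership is a two-column table (``ID``, ``breed``); optional
sampling geography is a four-column table (``breed``, ``Latitude``,
``Longitude``, ``Location``). Column-name matching is case-insensitive.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "HAPMAP_COLUMNS",
    "BreedkitError",
    "FormatError",
    "GenotypeParseError",
    "GenotypeMatrix",
    "BreedTable",
    "GeoTable",
    "ValidationReport",
    "read_hapmap",
    "write_hapmap",
    "read_breed_table",
    "read_geo_table",
    "validate_dataset",
    "write_newick",
    "write_table",
]

#: Sentinel for a missing dosage (NaN inside the float dosage matrix).
MISSING = float("nan")

HAPMAP_COLUMNS = (
    "rs#",
    "alleles",
    "chrom",
    "pos",
    "strand",
    "assembly#",
    "center",
    "protLSID",
    "assayLSID",
    "panelLSID",
    "QCcode",
)

_MISSING_CODES = {"NN", "N", "--", ""}

# IUPAC ambiguity codes for heterozygous diploid calls.
_IUPAC_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}


class BreedkitError(Exception):
    """Base class for all errors raised by breedkit."""


class FormatError(BreedkitError):
    """A file does not conform to its declared format."""


class GenotypeParseError(BreedkitError):
    """A genotype call could not be interpreted; carries its location."""


@dataclass
class GenotypeMatrix:
    """Individuals-by-SNPs dosage matrix with per-SNP metadata.

    ``dosages`` is an ``(n_individuals, n_snps)`` float array with entries
    in {0, 1, 2} or NaN for missing; a dosage counts copies of the
    alternate allele. ``snps`` is a DataFrame with columns
    ``id, chrom, pos, ref, alt`` (``alt`` may be None for a monomorphic
    SNP whose second allele is unknown).
    """

    individual_ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        if len(set(self.individual_ids)) != len(self.individual_ids):
            dupes = _duplicates(self.individual_ids)
            raise FormatError(f"duplicate individual IDs: {dupes}")
        ids = list(self.snps["id"])
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate SNP ids: {_duplicates(ids)}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individual_ids), len(self.snps)):
            raise FormatError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.snps)} SNPs"
            )
        finite = self.dosages[~np.isnan(self.dosages)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(finite[~np.isin(finite, (0.0, 1.0, 2.0))]))
            raise FormatError(f"dosages outside {{0,1,2,missing}}: {bad[:5]}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["id"])

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def missing_rate_per_snp(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def alt_allele_freq(self) -> np.ndarray:
        """Per-SNP alternate-allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    # -- subsetting ------------------------------------------------------
    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {v: i for i, v in enumerate(self.individual_ids)}
        unknown = [i for i in ids if i not in index]
        if unknown:
            raise KeyError(f"unknown individual ids: {unknown}")
        rows = [index[i] for i in ids]
        return GenotypeMatrix(list(ids), self.snps.copy(), self.dosages[rows])

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {v: i for i, v in enumerate(self.snps["id"])}
        unknown = [s for s in snp_ids if s not in index]
        if unknown:
            raise KeyError(f"unknown SNP ids: {unknown[:5]}")
        cols = [index[s] for s in snp_ids]
        return GenotypeMatrix(
            list(self.individual_ids),
            self.snps.iloc[cols].reset_index(drop=True),
            self.dosages[:, cols],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.snps.reset_index(drop=True).equals(other.snps.reset_index(drop=True))
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )


@dataclass
class BreedTable:
    """Mapping of individual ID to breed label."""

    table: pd.DataFrame  # columns: ID, breed

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns) != ["ID", "breed"]:
            raise FormatError(f"breed table needs columns ['ID','breed'], got {list(t.columns)}")
        t["ID"] = t["ID"].astype(str)
        t["breed"] = t["breed"].astype(str)
        dupes = t["ID"][t["ID"].duplicated()].tolist()
        if dupes:
            raise FormatError(f"duplicate IDs in breed table: {sorted(set(dupes))}")
        if (t["breed"].str.strip() == "").any():
            raise FormatError("empty breed labels in breed table")

    @property
    def ids(self) -> list[str]:
        return self.table["ID"].tolist()

    @property
    def breeds(self) -> list[str]:
        """Distinct breed labels in order of first appearance."""
        return list(dict.fromkeys(self.table["breed"]))

    def breed_of(self) -> dict[str, str]:
        return dict(zip(self.table["ID"], self.table["breed"]))

    def counts(self) -> dict[str, int]:
        return self.table["breed"].value_counts().to_dict()

    def labels_for(self, ids: Sequence[str]) -> np.ndarray:
        mapping = self.breed_of()
        missing = [i for i in ids if i not in mapping]
        if missing:
            raise KeyError(f"individuals without breed label: {missing[:5]}")
        return np.array([mapping[i] for i in ids])


@dataclass
class GeoTable:
    """Per-breed sampling coordinates."""

    table: pd.DataFrame  # columns: breed, Latitude, Longitude, Location

    def __post_init__(self) -> None:
        t = self.table
        expect = ["breed", "Latitude", "Longitude", "Location"]
        if list(t.columns) != expect:
            raise FormatError(f"geo table needs columns {expect}, got {list(t.columns)}")
        t["breed"] = t["breed"].astype(str)
        t["Latitude"] = t["Latitude"].astype(float)
        t["Longitude"] = t["Longitude"].astype(float)
        if t["breed"].duplicated().any():
            raise FormatError("duplicate breeds in geo table")
        bad_lat = t.loc[(t["Latitude"] < -90) | (t["Latitude"] > 90), "Latitude"]
        if len(bad_lat):
            raise FormatError(f"Latitude out of [-90, 90]: {bad_lat.tolist()}")
        bad_lon = t.loc[(t["Longitude"] < -180) | (t["Longitude"] > 180), "Longitude"]
        if len(bad_lon):
            raise FormatError(f"Longitude out of [-180, 180]: {bad_lon.tolist()}")

    def lookup(self, breed: str) -> dict:
        rows = self.table[self.table["breed"] == breed]
        if rows.empty:
            return {"Latitude": None, "Longitude": None, "Location": None}
        r = rows.iloc[0]
        return {
            "Latitude": float(r["Latitude"]),
            "Longitude": float(r["Longitude"]),
            "Location": r["Location"],
        }


@dataclass
class ValidationReport:
    """Cross-file consistency report (never raises; callers decide)."""

    genotyped_without_breed: list[str]
    labelled_without_genotype: list[str]
    breed_counts: dict[str, int]
    snp_missing_rate: dict[str, float]
    geo_breeds_without_samples: list[str] = field(default_factory=list)
    breeds_without_geo: list[str] = field(default_factory=list)

    @property
    def blocking_for_training(self) -> bool:
        return len(self.genotyped_without_breed) > 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "genotyped_without_breed": self.genotyped_without_breed,
                "labelled_without_genotype": self.labelled_without_genotype,
                "breed_counts": self.breed_counts,
                "snp_missing_rate": self.snp_missing_rate,
                "geo_breeds_without_samples": self.geo_breeds_without_samples,
                "breeds_without_geo": self.breeds_without_geo,
                "blocking_for_training": self.blocking_for_training,
            },
            indent=2,
        )


def _duplicates(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


# ---------------------------------------------------------------------------
# HapMap genotype parsing
# ---------------------------------------------------------------------------


def _split_call(call: str, dialect: str, where: str) -> tuple[str, str] | None:
    """Return the two allele letters of a call, or None if missing."""
    call = call.strip()
    if call.upper() in _MISSING_CODES:
        return None
    if dialect == "two-letter":
        if len(call) != 2:
            raise GenotypeParseError(f"{where}: expected two-letter call, got {call!r}")
        return call[0].upper(), call[1].upper()
    # iupac
    if len(call) != 1:
        raise GenotypeParseError(f"{where}: expected single IUPAC call, got {call!r}")
    c = call.upper()
    if c in "ACGT":
        return c, c
    if c in _IUPAC_HET:
        return _IUPAC_HET[c]
    raise GenotypeParseError(f"{where}: unknown IUPAC code {call!r}")


def _sniff_dialect(cells: Sequence[str]) -> str:
    for c in cells:
        c = c.strip()
        if c.upper() in _MISSING_CODES:
            continue
        return "two-letter" if len(c) == 2 else "iupac"
    return "two-letter"


def _parse_alleles_field(raw: str) -> tuple[str | None, str | None]:
    """Parse an ``alleles`` cell like ``A/G``; returns (ref, alt) or Nones."""
    parts = [p.strip().upper() for p in str(raw).split("/")]
    bases = [p for p in parts if len(p) == 1 and p in "ACGT"]
    if len(parts) >= 2 and len(bases) == len(parts):
        return bases[0], bases[1]
    if len(parts) == 1 and len(bases) == 1:
        return bases[0], None
    return None, None


def read_hapmap(path: str | Path, dialect: str = "auto") -> GenotypeMatrix:
    """Read a tab-delimited HapMap genotype file into a dosage matrix.

    The dosage of a call is its count of the alternate allele; the
    alternate allele is the *second* allele listed in the ``alleles``
    column. When that column is malformed the minor allele observed in
    the data stands in (ties broken by ASCII order, smaller base = ref).

    Parameters
    ----------
    path : file path
    dialect : ``two-letter``, ``iupac`` or ``auto`` (sniffed per file
        from the width of the first non-missing call).
    """
    if dialect not in ("two-letter", "iupac", "auto"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    with open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        lower = [h.strip().lower() for h in header]
        for col in HAPMAP_COLUMNS:
            if col.lower() not in lower:
                raise FormatError(f"HapMap header is missing required column {col!r}")
        n_meta = len(HAPMAP_COLUMNS)
        sample_ids = [h.strip() for h in header[n_meta:]]
        if not sample_ids:
            raise FormatError("HapMap file has no individual columns")
        col_of = {name: lower.index(name.lower()) for name in HAPMAP_COLUMNS}

        snp_rows = []
        dosage_rows = []
        file_dialect = dialect
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != n_meta + len(sample_ids):
                raise FormatError(
                    f"line {line_no}: expected {n_meta + len(sample_ids)} columns, "
                    f"got {len(cells)}"
                )
            calls = cells[n_meta:]
            if file_dialect == "auto":
                file_dialect = _sniff_dialect(calls)
            snp_id = cells[col_of["rs#"]].strip()
            ref, alt = _parse_alleles_field(cells[col_of["alleles"]])
            pairs = [
                _split_call(
                    c,
                    file_dialect,
                    f"line {line_no} (SNP {snp_id!r}), individual {sid!r}",
                )
                for c, sid in zip(calls, sample_ids)
            ]
            if ref is None:
                # infer from the observed calls: major = ref, minor = alt,
                # ties broken by ASCII order (smaller base becomes ref)
                counts: dict[str, int] = {}
                for p in pairs:
                    if p:
                        counts[p[0]] = counts.get(p[0], 0) + 1
                        counts[p[1]] = counts.get(p[1], 0) + 1
                ordered = sorted(counts, key=lambda a: (-counts[a], a))
                if not ordered:
                    ref, alt = "N", None
                else:
                    ref = ordered[0]
                    alt = ordered[1] if len(ordered) > 1 else None
            allowed = {ref} | ({alt} if alt else set())
            row = np.full(len(sample_ids), np.nan)
            for j, p in enumerate(pairs):
                if p is None:
                    continue
                bad = [a for a in p if a not in allowed]
                if bad:
                    raise GenotypeParseError(
                        f"line {line_no} (SNP {snp_id!r}), individual "
                        f"{sample_ids[j]!r}: allele {bad[0]!r} not in declared "
                        f"alleles {ref}/{alt}"
                    )
                row[j] = sum(1 for a in p if a == alt)
            try:
                pos = int(cells[col_of["pos"]])
            except ValueError as exc:
                raise FormatError(f"line {line_no}: non-integer pos") from exc
            snp_rows.append(
                {
                    "id": snp_id,
                    "chrom": str(cells[col_of["chrom"]]).strip(),
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                }
            )
            dosage_rows.append(row)

    snps = pd.DataFrame(snp_rows, columns=["id", "chrom", "pos", "ref", "alt"])
    dosages = (
        np.array(dosage_rows) if dosage_rows else np.empty((len(sample_ids), 0)).T
    )
    return GenotypeMatrix(sample_ids, snps, dosages.T if dosage_rows else np.empty((len(sample_ids), 0)))


_DOSAGE_CALL = {0: lambda r, a: r + r, 1: lambda r, a: r + a, 2: lambda r, a: a + a}


def write_hapmap(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as two-letter HapMap text (round-trips)."""
    path = Path(path)
    with open(path, "wt") as fh:
        fh.write("\t".join(HAPMAP_COLUMNS) + "\t" + "\t".join(G.individual_ids) + "\n")
        for j, snp in G.snps.iterrows():
            ref, alt = snp["ref"], snp["alt"]
            alleles = f"{ref}/{alt}" if alt else str(ref)
            meta = [
                str(snp["id"]),
                alleles,
                str(snp["chrom"]),
                str(int(snp["pos"])),
                "+",
                "NA",
                "NA",
                "NA",
                "NA",
                "NA",
                "NA",
            ]
            calls = []
            for d in G.dosages[:, j]:
                if np.isnan(d):
                    calls.append("NN")
                else:
                    calls.append(_DOSAGE_CALL[int(d)](ref, alt if alt else ref))
            fh.write("\t".join(meta + calls) + "\n")


# ---------------------------------------------------------------------------
# Breed / geography tables
# ---------------------------------------------------------------------------


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a small TSV or CSV table, sniffing the delimiter."""
    text = Path(path).read_text()
    first = text.splitlines()[0] if text.splitlines() else ""
    sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    if "\t" not in first and "," not in first:
        sep = r"\s+"
    return pd.read_csv(io.StringIO(text), sep=sep, dtype=str)


def _match_columns(df: pd.DataFrame, wanted: Sequence[str], what: str) -> pd.DataFrame:
    lower = {c.strip().lower(): c for c in df.columns}
    out = {}
    for w in wanted:
        if w.lower() not in lower:
            raise FormatError(f"{what}: missing required column {w!r}")
        out[w] = df[lower[w.lower()]]
    return pd.DataFrame(out)


def read_breed_table(path: str | Path) -> BreedTable:
    """Read the two-column (ID, breed) membership table (TSV or CSV)."""
    df = _match_columns(_read_delimited(path), ["ID", "breed"], "breed table")
    return BreedTable(df)


def read_geo_table(path: str | Path) -> GeoTable:
    """Read the per-breed (breed, Latitude, Longitude, Location) table."""
    df = _match_columns(
        _read_delimited(path), ["breed", "Latitude", "Longitude", "Location"], "geo table"
    )
    return GeoTable(df)


def validate_dataset(
    G: GenotypeMatrix, breeds: BreedTable, geo: GeoTable | None = None
) -> ValidationReport:
    """Cross-check the three inputs and summarise per-breed counts.

    Pure report: nothing raises here. A genotyped individual without a
    breed label marks the report blocking for training mode.
    """
    geno_ids = set(G.individual_ids)
    label_ids = set(breeds.ids)
    mapping = breeds.breed_of()
    labelled = [i for i in G.individual_ids if i in mapping]
    counts: dict[str, int] = {}
    for i in labelled:
        counts[mapping[i]] = counts.get(mapping[i], 0) + 1
    rates = dict(zip(G.snp_ids, (float(x) for x in G.missing_rate_per_snp())))
    report = ValidationReport(
        genotyped_without_breed=sorted(geno_ids - label_ids),
        labelled_without_genotype=sorted(label_ids - geno_ids),
        breed_counts=counts,
        snp_missing_rate=rates,
    )
    if geo is not None:
        sampled = set(counts)
        geo_breeds = set(geo.table["breed"])
        report.geo_breeds_without_samples = sorted(geo_breeds - sampled)
        report.breeds_without_geo = sorted(sampled - geo_breeds)
    return report


# ---------------------------------------------------------------------------
# Output plumbing
# ---------------------------------------------------------------------------


def write_newick(tree, path: str | Path | None = None) -> str:
    """Serialise a phylogenetic tree to Newick; optionally write to file."""
    text = tree.to_newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def write_table(rows: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write a result table as TSV."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)
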