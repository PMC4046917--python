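"""Genotype matrix container, I/O and missingness QC.

Genotypes are biallelic SNPs stored per cell as the count of the designated
alternate allele (0, 1, 2) or ``MISSING`` (-1).  The alternate allele of a
variant is the lexicographically later of its two allele symbols, so codes
are stable regardless of the order alleles are first seen in a file, and the
original string genotype (e.g. ``"AT"``) is recoverable from the per-variant
allele labels.

Three on-disk dialects are supported:

``ped_map``
    PLINK text pedigree format: a ``.ped`` file (six leading columns, then
    two allele symbols per variant; phenotype column coded 1=control,
    2=case; ``0 0`` = missing genotype) plus a ``.map`` sidecar naming the
    variants.
``matrix_tsv``
    A header row of variant ids, one row per sample with cells in
    ``{0,1,2,NA}``; phenotype in a 2-column sample/status sidecar.
``hdf5``
    Datasets ``genotypes`` (n x m int8, -1 = missing), ``variant_ids``,
    ``alleles`` (m x 2), ``phenotype``.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})


class GenotypeParseError(ValueError):
    """Raised when a genotype file does not parse under its dialect."""


@dataclass
class PhenotypeVector:
    """Binary case/control status per sample (case=1, control=0)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise ValueError("phenotype labels must be one-dimensional")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValueError(f"phenotype labels outside {{0,1}}: {sorted(bad)}")
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("need at least one case and one control")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.labels == 0))

    @property
    def case_mask(self) -> np.ndarray:
        return self.labels == 1

    @property
    def control_mask(self) -> np.ndarray:
        return self.labels == 0


@dataclass
class GenotypeMatrix:
    """Samples x variants store of categorical genotype codes.

    Parameters
    ----------
    genotypes
        ``(n_samples, m_variants)`` int8 array with cells in
        ``{0, 1, 2, MISSING}``.
    variant_ids
        Unique identifier per variant, order-stable.
    alleles
        ``(m_variants, 2)`` array of allele symbols ``(ref, alt)``; code k
        means k copies of ``alt``.  A monomorphic variant repeats its single
        observed symbol.
    """

    genotypes: np.ndarray
    variant_ids: np.ndarray
    alleles: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x variants)")
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        if self.variant_ids.size != self.genotypes.shape[1]:
            raise ValueError("variant_ids length must equal number of columns")
        if len(set(self.variant_ids)) != self.variant_ids.size:
            raise ValueError("variant_ids must be unique")
        if self.alleles is None:
            self.alleles = np.array(
                [("A", "B")] * self.genotypes.shape[1], dtype=object
            ).reshape(-1, 2)
        self.alleles = np.asarray(self.alleles, dtype=object).reshape(-1, 2)
        if self.alleles.shape[0] != self.genotypes.shape[1]:
            raise ValueError("alleles must have one (ref, alt) pair per variant")
        if any(not a or not b for a, b in self.alleles):
            raise ValueError("allele labels must be non-empty")
        codes = np.unique(self.genotypes)
        bad = set(codes.tolist()) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        self._index = {vid: j for j, vid in enumerate(self.variant_ids)}

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m_variants(self) -> int:
        return self.genotypes.shape[1]

    def column(self, variant) -> np.ndarray:
        """Genotype codes of one variant, by id (str) or positional index."""
        if isinstance(variant, (int, np.integer)):
            return self.genotypes[:, int(variant)]
        return self.genotypes[:, self.variant_index(variant)]

    def variant_index(self, variant_id) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"unknown variant id: {variant_id!r}") from None

    def genotype_string(self, variant, code: int) -> str:
        """Original string genotype for a code, e.g. code 1 with alleles
        ('A','T') -> 'AT'."""
        j = variant if isinstance(variant, (int, np.integer)) else self.variant_index(variant)
        ref, alt = self.alleles[j]
        if code == MISSING:
            return "00"
        if code not in (0, 1, 2):
            raise ValueError(f"invalid genotype code {code}")
        return "".join(sorted([ref] * (2 - code) + [alt] * code))

    def missing_per_variant(self) -> np.ndarray:
        return np.sum(self.genotypes == MISSING, axis=0)

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.genotypes[:, idx], self.variant_ids[idx], self.alleles[idx]
        )


FilterResult = collections.namedtuple("FilterResult", ["matrix", "n_removed"])


def filter_missingness(
    gm: GenotypeMatrix, max_missing_per_variant: int = 4
) -> FilterResult:
    """Drop variants with more than ``max_missing_per_variant`` missing cells.

    Returns the surviving matrix (variant order preserved, samples untouched)
    together with the number of variants removed.  Idempotent.
    """
    if max_missing_per_variant < 0:
        raise ValueError("max_missing_per_variant must be >= 0")
    keep = gm.missing_per_variant() <= max_missing_per_variant
    return FilterResult(gm.take_variants(np.flatnonzero(keep)), int(np.sum(~keep)))


# --------------------------------------------------------------------------
# ped/map


def _read_ped_map(path: Path) -> tuple[GenotypeMatrix, PhenotypeVector]:
    path = Path(path)
    if path.suffix == ".ped":
        ped_path, map_path = path, path.with_suffix(".map")
    else:
        ped_path, map_path = path.with_suffix(".ped"), path.with_suffix(".map")
    variant_ids = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise GenotypeParseError(f"{map_path}:{ln}: expected 4 columns")
            variant_ids.append(parts[1])
    m = len(variant_ids)

    rows: list[list[tuple[str, str]]] = []
    phen = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            status = parts[5]
            if status == "1":
                phen.append(0)
            elif status == "2":
                phen.append(1)
            else:
                raise GenotypeParseError(
                    f"{ped_path}:{ln}: phenotype {status!r} outside 1/2 coding"
                )
            rows.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
            )

    n = len(rows)
    geno = np.full((n, m), MISSING, dtype=np.int8)
    alleles = np.empty((m, 2), dtype=object)
    for j in range(m):
        symbols = sorted(
            {a for row in rows for a in row[j] if a != "0"}
        )
        if len(symbols) > 2:
            raise GenotypeParseError(
                f"variant {variant_ids[j]}: more than two alleles {symbols}"
            )
        if not symbols:
            symbols = ["0"]  # fully missing column; placeholder labels
        ref = symbols[0]
        alt = symbols[-1]
        alleles[j] = (ref, alt)
        for i, row in enumerate(rows):
            a, b = row[j]
            if a == "0" or b == "0":
                if a != b:
                    raise GenotypeParseError(
                        f"variant {variant_ids[j]}, sample {i + 1}: "
                        f"half-missing genotype {a}/{b}"
                    )
                continue
            for sym in (a, b):
                if sym not in (ref, alt):
                    raise GenotypeParseError(
                        f"variant {variant_ids[j]}, sample {i + 1}: "
                        f"unknown allele symbol {sym!r}"
                    )
            geno[i, j] = (a == alt) + (b == alt) if ref != alt else 0
    return GenotypeMatrix(geno, np.array(variant_ids, dtype=object), alleles), (
        PhenotypeVector(np.array(phen, dtype=np.int8))
    )


def write_ped_map(gm: GenotypeMatrix, phen: PhenotypeVector, prefix) -> None:
    """Write PLINK text ped/map (``prefix.ped`` + ``prefix.map``)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j, vid in enumerate(gm.variant_ids):
            fh.write(f"1\t{vid}\t0\t{j + 1}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(gm.n_samples):
            status = 2 if phen.labels[i] == 1 else 1
            fields = [f"FAM{i + 1}", f"IND{i + 1}", "0", "0", "0", str(status)]
            for j in range(gm.m_variants):
                code = gm.genotypes[i, j]
                if code == MISSING:
                    fields += ["0", "0"]
                else:
                    ref, alt = gm.alleles[j]
                    fields += [alt] * int(code) + [ref] * (2 - int(code))
            fh.write(" ".join(fields) + "\n")


# --------------------------------------------------------------------------
# matrix_tsv


def _read_matrix_tsv(path: Path) -> tuple[GenotypeMatrix, PhenotypeVector]:
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, comment="#", keep_default_na=False
    )
    geno = np.full(df.shape, MISSING, dtype=np.int8)
    values = df.to_numpy()
    for code in ("0", "1", "2"):
        geno[values == code] = int(code)
    unknown = ~np.isin(values, ["0", "1", "2", "NA"])
    if unknown.any():
        i, j = np.argwhere(unknown)[0]
        raise GenotypeParseError(
            f"{path}: cell ({df.index[i]}, {df.columns[j]}) has invalid "
            f"value {values[i, j]!r}"
        )
    pheno_path = path.with_suffix(".pheno.tsv")
    pdf = pd.read_csv(pheno_path, sep="\t", index_col=0, comment="#")
    pdf = pdf.reindex(df.index)
    if pdf.iloc[:, 0].isna().any():
        raise GenotypeParseError(f"{pheno_path}: missing status for some samples")
    labels = pdf.iloc[:, 0].to_numpy()
    if not np.isin(labels, [0, 1]).all():
        raise GenotypeParseError(f"{pheno_path}: status values must be 0/1")
    gm = GenotypeMatrix(
        geno,
        np.asarray(df.columns, dtype=object),
        np.array([("A", "B")] * df.shape[1], dtype=object).reshape(-1, 2),
    )
    return gm, PhenotypeVector(labels.astype(np.int8))


def write_matrix_tsv(gm: GenotypeMatrix, phen: PhenotypeVector, path) -> None:
    """Write the matrix_tsv dialect (``path`` + ``path.pheno.tsv`` sidecar)."""
    path = Path(path)
    cells = gm.genotypes.astype(object)
    cells[gm.genotypes == MISSING] = "NA"
    df = pd.DataFrame(
        cells,
        index=[f"S{i + 1}" for i in range(gm.n_samples)],
        columns=list(gm.variant_ids),
    )
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
    pdf = pd.DataFrame({"status": phen.labels.astype(int)}, index=df.index)
    pdf.index.name = "sample"
    pdf.to_csv(path.with_suffix(".pheno.tsv"), sep="\t")


# --------------------------------------------------------------------------
# hdf5


def _read_hdf5(path: Path) -> tuple[GenotypeMatrix, PhenotypeVector]:
    with h5py.File(path, "r") as fh:
        geno = fh["genotypes"][...].astype(np.int8)
        vids = np.array([v.decode() for v in fh["variant_ids"][...]], dtype=object)
        alleles = np.array(
            [[a.decode() for a in pair] for pair in fh["alleles"][...]], dtype=object
        )
        labels = fh["phenotype"][...].astype(np.int8)
    return GenotypeMatrix(geno, vids, alleles), PhenotypeVector(labels)


def write_hdf5(gm: GenotypeMatrix, phen: PhenotypeVector, path) -> None:
    """Write the HDF5 container (file-backed access for large matrices)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("genotypes", data=gm.genotypes, dtype=np.int8)
        fh.create_dataset(
            "variant_ids",
            data=np.array([str(v).encode() for v in gm.variant_ids]),
        )
        fh.create_dataset(
            "alleles",
            data=np.array(
                [[str(a).encode(), str(b).encode()] for a, b in gm.alleles]
            ),
        )
        fh.create_dataset("phenotype", data=phen.labels, dtype=np.int8)


_READERS = {"ped_map": _read_ped_map, "matrix_tsv": _read_matrix_tsv, "hdf5": _read_hdf5}


def read_genotypes(path, format: str) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Load a genotype matrix + phenotype under the named dialect.

    ``format`` is one of ``ped_map``, ``matrix_tsv``, ``hdf5``.  Sample and
    variant order are exactly the file order on every read.
    """
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(
            f"unknown format {format!r}; expected one of {sorted(_READERS)}"
        ) from None
    return reader(Path(path))
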