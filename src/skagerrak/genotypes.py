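"""Diploid microsatellite genotype tables: I/O, validation and allele frequencies.

The central container is :class:`GenotypeTable`, an individuals x loci array of
unordered diploid allele calls. Allele labels are raw fragment sizes in base
pairs (positive integers), never recoded indices, so private-allele comparisons
stay meaningful across populations. A missing genotype is always missing for
both gene copies; half-calls in input are coerced to missing with a warning.

Supported formats are GenePop (the de-facto exchange dialect for
microsatellite data) and a simple delimited table with two columns per locus,
matching how spreadsheet supplements of genotyping studies are usually laid
out.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel allele value for a missing gene copy (both copies are 0 or neither).
MISSING = 0

__all__ = [
    "MISSING",
    "GenotypeTable",
    "AlleleFrequencyTable",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "read_table",
    "write_table",
    "allele_frequencies",
]


class GenepopParseError(ValueError):
    """Raised when a GenePop file cannot be parsed; message names the line."""


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with population labels.

    Parameters
    ----------
    individuals : list of str
        Unique individual identifiers.
    populations : list of str
        Per-individual population label (sample code such as ``N_B`` or
        ``D_A``), aligned with ``individuals``.
    loci : list of str
        Ordered locus names.
    calls : ndarray of int, shape (n_individuals, n_loci, 2)
        Allele fragment sizes in bp; ``0`` in both slots marks a missing
        genotype. The pair is unordered: ``{109, 173}`` and ``{173, 109}``
        are the same call (stored sorted).
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {L} loci x 2"
            )
        if len(self.populations) != n:
            raise ValueError("populations must align with individuals")
        if (self.calls < 0).any():
            raise ValueError("allele labels must be positive integers (0 = missing)")
        # coerce half-calls (one copy missing) to fully missing
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            warnings.warn(
                f"{int(half.sum())} half-called genotype(s) coerced to missing",
                stacklevel=2,
            )
            self.calls[half] = MISSING
        # store each pair sorted so calls are order-free
        self.calls = np.sort(self.calls, axis=2)

    # -- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_order(self) -> list[str]:
        """Populations in order of first appearance (preserved in all reports)."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {p: 0 for p in self.population_order}
        for p in self.populations:
            sizes[p] += 1
        return sizes

    def pop_mask(self, population: str) -> np.ndarray:
        mask = np.asarray([p == population for p in self.populations])
        if not mask.any():
            raise KeyError(f"unknown population {population!r}")
        return mask

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask, True where the genotype is missing."""
        return self.calls[:, :, 0] == MISSING

    def typed_counts(self) -> pd.DataFrame:
        """Number of individuals successfully typed per locus (pooled)."""
        n = (~self.missing_mask()).sum(axis=0)
        return pd.DataFrame({"locus": self.loci, "n_typed": n})

    def subset(self, populations: Sequence[str]) -> "GenotypeTable":
        keep = np.asarray([p in set(populations) for p in self.populations])
        return GenotypeTable(
            [i for i, k in zip(self.individuals, keep) if k],
            [p for p, k in zip(self.populations, keep) if k],
            list(self.loci),
            self.calls[keep].copy(),
        )

    def relabel(self, mapping: Mapping[str, str]) -> "GenotypeTable":
        """Return a copy with population labels renamed via ``mapping``."""
        return GenotypeTable(
            list(self.individuals),
            [mapping.get(p, p) for p in self.populations],
            list(self.loci),
            self.calls.copy(),
        )

    def validate(self) -> None:
        if self.n_individuals == 0:
            raise ValueError("empty table")
        for p, n in self.population_sizes().items():
            if n < 1:
                raise ValueError(f"population {p} has no individuals")

    def to_dataframe(self) -> pd.DataFrame:
        """Two columns per locus (``<locus>_1``, ``<locus>_2``); 0 = missing."""
        data: dict[str, object] = {
            "individual": self.individuals,
            "population": self.populations,
        }
        for j, locus in enumerate(self.loci):
            data[f"{locus}_1"] = self.calls[:, j, 0]
            data[f"{locus}_2"] = self.calls[:, j, 1]
        return pd.DataFrame(data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


# -- GenePop dialect -----------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _decode_genepop_field(tok: str, lineno: int) -> tuple[int, int]:
    if len(tok) == 4:
        w = 2
    elif len(tok) == 6:
        w = 3
    else:
        raise GenepopParseError(
            f"line {lineno}: allele field {tok!r} is not 2x2 or 2x3 digits"
        )
    if not tok.isdigit():
        raise GenepopParseError(f"line {lineno}: non-numeric allele field {tok!r}")
    return int(tok[:w]), int(tok[w:])


def read_genepop(path: str | Path, pop_names: str = "last-id") -> GenotypeTable:
    """Read a GenePop (.gen) file into a :class:`GenotypeTable`.

    Parameters
    ----------
    path : path
        GenePop file: title line, locus names (one per line or one
        comma-separated line), ``POP`` separators, then individual lines
        ``id , a1a2 a1a2 ...`` with 2- or 3-digit allele coding.
        ``00``/``000`` encodes a missing gene copy.
    pop_names : {"last-id", "auto"}
        ``"last-id"`` names each population after the identifier of the last
        individual in its POP block (the GenePop convention); ``"auto"``
        assigns ``POP1..POPk``.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short to be GenePop")
    # locus names: either one comma-separated line or one per line until POP
    i = 1
    loci: list[str] = []
    if "," in lines[1] and not _POP_RE.match(lines[1]):
        loci = [s.strip() for s in lines[1].split(",") if s.strip()]
        i = 2
    else:
        while i < len(lines) and not _POP_RE.match(lines[i]):
            name = lines[i].strip()
            if name:
                loci.append(name)
            i += 1
    if not loci:
        raise GenepopParseError("no locus names found before first POP")

    blocks: list[list[tuple[str, list[tuple[int, int]]]]] = []
    current: list[tuple[str, list[tuple[int, int]]]] | None = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        if not raw.strip():
            continue
        if _POP_RE.match(raw):
            current = []
            blocks.append(current)
            continue
        if current is None:
            raise GenepopParseError(f"line {lineno + 1}: data before first POP")
        if "," not in raw:
            raise GenepopParseError(f"line {lineno + 1}: missing ',' after individual id")
        ident, rest = raw.split(",", 1)
        toks = rest.split()
        if len(toks) != len(loci):
            raise GenepopParseError(
                f"line {lineno + 1}: {len(toks)} allele fields for {len(loci)} loci"
            )
        calls = [_decode_genepop_field(t, lineno + 1) for t in toks]
        current.append((ident.strip(), calls))

    if not blocks:
        raise GenepopParseError("no POP blocks found")

    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    for k, block in enumerate(blocks):
        if not block:
            raise GenepopParseError(f"POP block {k + 1} is empty")
        label = block[-1][0] if pop_names == "last-id" else f"POP{k + 1}"
        for ident, calls in block:
            individuals.append(ident)
            populations.append(label)
            rows.append(calls)

    arr = np.asarray(rows, dtype=np.int64)
    return GenotypeTable(individuals, populations, loci, arr)


def write_genepop(
    table: GenotypeTable, path: str | Path, title: str = "skagerrak export", digits: int = 3
) -> None:
    """Write ``table`` in GenePop format (3-digit allele coding by default)."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    maxa = int(table.calls.max(initial=0))
    if maxa >= 10**digits:
        raise ValueError(f"allele label {maxa} does not fit {digits}-digit coding")
    out = [title]
    out.extend(table.loci)
    last_pop: str | None = None
    for i, (ident, pop) in enumerate(zip(table.individuals, table.populations)):
        if pop != last_pop:
            out.append("POP")
            last_pop = pop
        fields = [
            f"{a:0{digits}d}{b:0{digits}d}" for a, b in table.calls[i]
        ]
        out.append(f"{ident} , " + " ".join(fields))
    Path(path).write_text("\n".join(out) + "\n")


# -- delimited / spreadsheet tables --------------------------------------


def _norm_missing(v: object) -> int:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return MISSING
    s = str(v).strip()
    if s in ("", "0", "NA", "na", "NaN", "nan", "-"):
        return MISSING
    return int(float(s))


def read_table(path: str | Path, sep: str | None = None) -> GenotypeTable:
    """Read a delimited genotype table (CSV/TSV, or XLSX via openpyxl).

    Expected layout: one row per individual with columns ``individual``,
    ``population`` (case-insensitive; ``id``/``sample`` and ``pop``/
    ``location`` are accepted), then two columns per locus. Locus column
    pairs may be named ``<locus>_1``/``<locus>_2`` or simply duplicated
    ``<locus>``/``<locus>`` headers (pandas reads the second as ``<locus>.1``). Blank, ``0`` and
    ``NA`` cells are missing gene copies.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, header=0)
    else:
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, header=0, dtype=object)
    return from_dataframe(df)


def from_dataframe(df: pd.DataFrame) -> GenotypeTable:
    """Build a :class:`GenotypeTable` from a two-columns-per-locus DataFrame."""
    cols = list(df.columns)
    low = [str(c).strip().lower() for c in cols]

    def find(names: Iterable[str]) -> int | None:
        for n in names:
            if n in low:
                return low.index(n)
        return None

    i_ind = find(("individual", "id", "sample", "ind"))
    i_pop = find(("population", "pop", "location", "sample code", "code"))
    if i_ind is None or i_pop is None:
        raise ValueError(
            "could not locate individual/population columns; headers were: "
            + ", ".join(map(str, cols))
        )
    locus_cols = [j for j in range(len(cols)) if j not in (i_ind, i_pop)]
    if len(locus_cols) % 2 != 0:
        raise ValueError(
            "expected two columns per locus; headers were: " + ", ".join(map(str, cols))
        )

    loci: list[str] = []
    for k in range(0, len(locus_cols), 2):
        name = str(cols[locus_cols[k]])
        name = re.sub(r"(_1|_a|\.1)$", "", name)
        loci.append(name.strip())

    n = len(df)
    arr = np.zeros((n, len(loci), 2), dtype=np.int64)
    for k in range(len(loci)):
        c1, c2 = locus_cols[2 * k], locus_cols[2 * k + 1]
        arr[:, k, 0] = [_norm_missing(v) for v in df.iloc[:, c1]]
        arr[:, k, 1] = [_norm_missing(v) for v in df.iloc[:, c2]]

    return GenotypeTable(
        [str(v) for v in df.iloc[:, i_ind]],
        [str(v) for v in df.iloc[:, i_pop]],
        loci,
        arr,
    )


def write_table(table: GenotypeTable, path: str | Path) -> None:
    """Write the two-columns-per-locus CSV representation."""
    table.to_dataframe().to_csv(path, index=False)


# -- allele frequencies ---------------------------------------------------


@dataclass
class AlleleFrequencyTable:
    """Per (population, locus) allele frequencies and gene-copy counts.

    ``freqs[pop][locus]`` maps allele label -> relative frequency among the
    ``n_copies[pop][locus]`` successfully typed gene copies (2 per typed
    individual). A population with an all-missing locus has ``n_copies == 0``
    and an empty map; downstream statistics must treat that locus as
    undefined for the population.
    """

    populations: list[str]
    loci: list[str]
    freqs: dict[str, dict[str, dict[int, float]]]
    n_copies: dict[str, dict[str, int]] = field(repr=False)

    def freq(self, population: str, locus: str) -> dict[int, float]:
        return self.freqs[population][locus]

    def copies(self, population: str, locus: str) -> int:
        return self.n_copies[population][locus]

    def counts(self, population: str, locus: str) -> dict[int, int]:
        """Integer allele-copy counts (frequency x N, rounded)."""
        n = self.n_copies[population][locus]
        return {a: int(round(f * n)) for a, f in self.freqs[population][locus].items()}

    def alleles(self, locus: str) -> list[int]:
        """All allele labels seen at ``locus`` across populations, sorted."""
        out: set[int] = set()
        for p in self.populations:
            out.update(self.freqs[p][locus])
        return sorted(out)

    def locus_freq_vectors(self, locus: str) -> tuple[list[int], np.ndarray]:
        """(allele labels, populations x alleles frequency matrix) for a locus."""
        alleles = self.alleles(locus)
        idx = {a: j for j, a in enumerate(alleles)}
        mat = np.zeros((len(self.populations), len(alleles)))
        for i, p in enumerate(self.populations):
            for a, f in self.freqs[p][locus].items():
                mat[i, idx[a]] = f
        return alleles, mat


def allele_frequencies(table: GenotypeTable) -> AlleleFrequencyTable:
    """Tally allele copies per (population, locus) and normalize.

    Only non-missing calls contribute; each typed individual adds two gene
    copies. The result is invariant to individual order and to the order of
    the two alleles within a call.
    """
    pops = table.population_order
    freqs: dict[str, dict[str, dict[int, float]]] = {}
    ncop: dict[str, dict[str, int]] = {}
    for pop in pops:
        mask = table.pop_mask(pop)
        sub = table.calls[mask]  # (n_pop, L, 2)
        freqs[pop] = {}
        ncop[pop] = {}
        for j, locus in enumerate(table.loci):
            flat = sub[:, j, :].ravel()
            flat = flat[flat != MISSING]
            n = int(flat.size)
            ncop[pop][locus] = n
            if n == 0:
                freqs[pop][locus] = {}
                continue
            vals, counts = np.unique(flat, return_counts=True)
            freqs[pop][locus] = {
                int(a): float(c) / n for a, c in zip(vals, counts)
            }
    return AlleleFrequencyTable(pops, list(table.loci), freqs, ncop)
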