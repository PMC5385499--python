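"""Genotype data model and I/O for diploid microsatellite data.

The central container is :class:`GenotypeTable`: individuals x loci diploid
allele calls, where alleles are integer fragment sizes (bp) and each
individual belongs to exactly one sampling site.  Data are exchanged in the
GenePop text format (2- or 3-digit allele coding) with an optional CSV
sidecar of per-site metadata (seamount, region, coordinates, depth stratum,
fished/unfished flag).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = 0

METADATA_COLUMNS = [
    "site_id",
    "seamount",
    "region",
    "lat",
    "lon",
    "depth_m",
    "stratum",
    "fished",
]


class GenepopParseError(ValueError):
    """Malformed GenePop input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes with a site partition.

    Parameters
    ----------
    individuals : list of str
        Unique individual identifiers.
    loci : list of str
        Locus names.
    calls : ndarray of int, shape (n_individuals, n_loci, 2)
        Allele fragment sizes in bp; a missing genotype is ``(0, 0)``.
        Allele pairs are stored sorted so ``{a, b}`` and ``{b, a}`` compare
        equal.
    sites : ndarray of object, shape (n_individuals,)
        Site id of each individual.
    repeat_units : dict, optional
        Locus name -> repeat-unit length in bp (needed for binning and
        null-allele relabelling).
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    sites: np.ndarray
    repeat_units: dict[str, int] | None = None

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int64)
        if self.calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        self.sites = np.asarray(self.sites, dtype=object)
        if self.sites.shape != (len(self.individuals),):
            raise ValueError("sites must have one entry per individual")
        # order-independent storage of allele pairs
        self.calls = np.sort(self.calls, axis=2)
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("partial single-allele calls are not representable")
        if (self.calls < 0).any():
            raise ValueError("alleles must be positive or the all-zero missing code")

    # -- basic views ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def site_ids(self) -> list[str]:
        """Site ids in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s, None)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci); True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def site_sizes(self) -> dict[str, int]:
        return {s: int((self.sites == s).sum()) for s in self.site_ids()}

    def subset(self, index: np.ndarray) -> "GenotypeTable":
        """New table restricted to the given individual indices (in order)."""
        index = np.asarray(index)
        return GenotypeTable(
            individuals=[self.individuals[i] for i in index],
            loci=list(self.loci),
            calls=self.calls[index].copy(),
            sites=self.sites[index].copy(),
            repeat_units=dict(self.repeat_units) if self.repeat_units else None,
        )

    def site_indices(self, site: str) -> np.ndarray:
        return np.flatnonzero(self.sites == site)

    def allele_counts(self, locus: int | str, index: np.ndarray | None = None) -> dict[int, int]:
        """Counts of each allele (in genes) at a locus, optionally restricted
        to the given individuals."""
        j = self.loci.index(locus) if isinstance(locus, str) else locus
        a = self.calls[:, j, :] if index is None else self.calls[index][:, j, :]
        a = a[a != MISSING]
        vals, cnt = np.unique(a, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))

    def allele_freqs(self, locus: int | str, index: np.ndarray | None = None) -> dict[int, float]:
        counts = self.allele_counts(locus, index)
        tot = sum(counts.values())
        if tot == 0:
            return {}
        return {a: c / tot for a, c in counts.items()}

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and list(self.sites) == list(other.sites)
        )


# ---------------------------------------------------------------------------
# site metadata
# ---------------------------------------------------------------------------

def validate_site_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a site-metadata table.

    Expected columns: site_id, seamount, region, lat, lon, depth_m, stratum,
    fished.  Latitude/longitude must be valid decimal degrees, depths
    positive, site ids unique; ``fished`` is coerced to bool.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta = meta.copy()
    if meta["site_id"].duplicated().any():
        raise ValueError("duplicate site_id in metadata")
    if not meta["lat"].between(-90, 90).all():
        raise ValueError("latitude outside [-90, 90]")
    if not meta["lon"].between(-180, 180).all():
        raise ValueError("longitude outside [-180, 180]")
    if not (meta["depth_m"] > 0).all():
        raise ValueError("depth_m must be positive")
    if meta["fished"].dtype != bool:
        meta["fished"] = (
            meta["fished"]
            .astype(str)
            .str.strip()
            .str.lower()
            .map({"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False})
        )
        if meta["fished"].isna().any():
            raise ValueError("fished flag not interpretable as boolean")
    return meta


def read_site_metadata(path) -> pd.DataFrame:
    return validate_site_metadata(pd.read_csv(path))


# ---------------------------------------------------------------------------
# GenePop I/O
# ---------------------------------------------------------------------------

def _is_pop_line(line: str) -> bool:
    first = line.strip().split()
    return bool(first) and first[0].lower() == "pop"


def read_genepop(
    path_or_buffer,
    repeat_units: dict[str, int] | None = None,
    site_names: list[str] | None = None,
) -> GenotypeTable:
    """Parse a GenePop file into a :class:`GenotypeTable`.

    The allele digit width (2 or 3) is auto-detected from the genotype
    tokens and must be consistent across the file.  Each ``Pop`` block
    becomes one site; the site id is the name of the block's last
    individual (the GenePop convention) unless ``site_names`` supplies ids
    in block order.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    lines = text.splitlines()
    if not lines:
        raise GenepopParseError("empty file")

    # header: title, then locus names until the first Pop line
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _is_pop_line(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if not loci:
        raise GenepopParseError("no locus names before first Pop line", line=i)
    if i == len(lines):
        raise GenepopParseError("no Pop line found")

    individuals: list[str] = []
    calls_rows: list[list[tuple[int, int]]] = []
    block_of: list[int] = []
    block_names: list[list[str]] = []
    width: int | None = None
    n_blocks = 0

    while i < len(lines):
        assert _is_pop_line(lines[i])
        n_blocks += 1
        block_names.append([])
        i += 1
        block_start = i
        while i < len(lines) and not _is_pop_line(lines[i]):
            raw = lines[i].strip()
            lineno = i + 1
            i += 1
            if not raw:
                continue
            if "," not in raw:
                raise GenepopParseError("individual line lacks ',' separator", line=lineno)
            name, _, geno = raw.partition(",")
            name = name.strip()
            tokens = geno.split()
            if len(tokens) != len(loci):
                raise GenepopParseError(
                    f"expected {len(loci)} genotypes, found {len(tokens)}", line=lineno
                )
            row: list[tuple[int, int]] = []
            for tok in tokens:
                if not tok.isdigit() or len(tok) not in (4, 6):
                    raise GenepopParseError(
                        f"genotype token {tok!r} is not 4- or 6-digit", line=lineno
                    )
                w = len(tok) // 2
                if width is None:
                    width = w
                elif w != width:
                    raise GenepopParseError(
                        f"mixed allele digit widths ({w} vs {width})", line=lineno
                    )
                a, b = int(tok[:w]), int(tok[w:])
                if (a == 0) != (b == 0):
                    raise GenepopParseError(
                        f"partial genotype {tok!r} (one allele zero)", line=lineno
                    )
                row.append((a, b))
            individuals.append(name)
            calls_rows.append(row)
            block_of.append(n_blocks - 1)
            block_names[-1].append(name)
        if not block_names[-1]:
            raise GenepopParseError("empty Pop block", line=block_start)

    if len(set(individuals)) != len(individuals):
        dups = sorted({n for n in individuals if individuals.count(n) > 1})
        raise GenepopParseError(f"duplicate individual ids: {dups}")

    if site_names is not None:
        if len(site_names) != n_blocks:
            raise ValueError(
                f"{len(site_names)} site names supplied for {n_blocks} Pop blocks"
            )
        ids = list(site_names)
    else:
        ids = [names[-1] for names in block_names]

    calls = np.array(calls_rows, dtype=np.int64).reshape(len(individuals), len(loci), 2)
    sites = np.array([ids[b] for b in block_of], dtype=object)
    return GenotypeTable(individuals, loci, calls, sites, repeat_units=repeat_units)


def write_genepop(
    table: GenotypeTable,
    path_or_buffer,
    title: str = "coralpopgen export",
    digits: int = 3,
) -> None:
    """Write a table in GenePop format (3-digit coding by default)."""
    if table.n_loci == 0:
        raise ValueError("cannot write a table with no loci")
    limit = 10**digits - 1
    if table.calls.max(initial=0) > limit:
        raise ValueError(f"allele exceeds {limit} under {digits}-digit coding")

    buf = io.StringIO()
    buf.write(title + "\n")
    for locus in table.loci:
        buf.write(locus + "\n")
    for site in table.site_ids():
        buf.write("Pop\n")
        for i in table.site_indices(site):
            parts = [
                f"{a:0{digits}d}{b:0{digits}d}" for a, b in table.calls[i]
            ]
            buf.write(f"{table.individuals[i]} ,  " + " ".join(parts) + "\n")
    out = buf.getvalue()
    if hasattr(path_or_buffer, "write"):
        path_or_buffer.write(out)
    else:
        with open(path_or_buffer, "w") as fh:
            fh.write(out)


# ---------------------------------------------------------------------------
# allele binning and inclusion filter
# ---------------------------------------------------------------------------

def bin_alleles(table: GenotypeTable) -> GenotypeTable:
    """Snap raw fragment sizes to the repeat-unit lattice of each locus.

    The lattice anchor is the modal raw allele of the locus (smallest mode
    on ties); each allele moves to the nearest lattice point
    ``anchor + k * repeat_unit``, with exact ties resolved toward the
    anchor.  Idempotent: already-binned data are unchanged.
    """
    if not table.repeat_units:
        raise ValueError("repeat units are required for binning")
    calls = table.calls.copy()
    for j, locus in enumerate(table.loci):
        unit = table.repeat_units[locus]
        col = calls[:, j, :]
        observed = col[col != MISSING]
        if observed.size == 0:
            continue
        vals, cnt = np.unique(observed, return_counts=True)
        anchor = int(vals[np.argmax(cnt)])  # np.unique sorts: smallest mode wins ties
        q = (col.astype(float) - anchor) / unit
        k = np.where(q >= 0, np.ceil(q - 0.5), np.floor(q + 0.5))
        binned = (anchor + k.astype(np.int64) * unit)
        calls[:, j, :] = np.where(col == MISSING, MISSING, binned)
    return replace(table, calls=calls)


def filter_min_n(table: GenotypeTable, min_n: int = 12) -> GenotypeTable:
    """Drop sites whose sample size is not strictly greater than ``min_n``.

    The default reproduces the common "n > 12" inclusion rule for
    site-level statistics.  Surviving individuals keep their genotypes
    unchanged.
    """
    if min_n < 0:
        raise ValueError("min_n must be >= 0")
    sizes = table.site_sizes()
    keep_sites = {s for s, n in sizes.items() if n > min_n}
    if not keep_sites:
        raise ValueError(f"no site has n > {min_n}; nothing left to analyse")
    index = np.flatnonzero(np.isin(table.sites, list(keep_sites)))
    return table.subset(index)


def prune_metadata(meta: pd.DataFrame, table: GenotypeTable) -> pd.DataFrame:
    """Restrict a metadata table to the sites present in ``table``."""
    present = set(table.site_ids())
    return meta[meta["site_id"].isin(present)].reset_index(drop=True)
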