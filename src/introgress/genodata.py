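"""Data model and text I/O for diploid codominant (microsatellite) genotypes.

The central container is :class:`GenotypeTable`: a list of loci, each with a
registry of observed integer allele codes (fragment sizes), and a list of
samples carrying a genotype (an ordered pair of allele codes, or missing) at
every locus, plus grouping metadata (population, species, region and a
reference/learning-sample flag).

Two interchange dialects are supported, both plain whitespace-delimited text:

* the STRUCTURE dialect, with either one row per individual (two columns per
  locus) or two rows per individual (one column per locus), an optional
  popflag column, and ``-9`` (configurable) for missing alleles;
* the GENEPOP dialect, with 2- or 3-digit allele encoding, ``Pop`` block
  delimiters and ``00``/``000`` for missing alleles.

Genotypes are either fully observed or fully missing at a locus:
half-missing entries are rejected at parse time rather than coerced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "SampleRecord",
    "GenotypeTable",
    "GenotypeParseError",
    "read_structure_file",
    "write_structure_file",
    "read_genepop_file",
    "write_genepop_file",
    "read_sample_metadata",
    "attach_metadata",
    "allele_frequencies",
    "concat_tables",
]

#: Sentinel for a missing genotype at a locus.
MISSING = None

SPECIES_VALUES = ("elegans", "graellsii", "unknown")


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates the dialect contract."""


@dataclass(frozen=True)
class Locus:
    """A codominant locus with its registry of observed allele codes.

    Allele codes are opaque integers (microsatellite fragment sizes); the
    registry is ordered, unique, and never contains the missing code.
    """

    name: str
    alleles: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"duplicate allele codes at locus {self.name!r}")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


@dataclass
class SampleRecord:
    """One diploid individual: identity, grouping metadata and genotype.

    ``genotype`` maps locus name to an ``(a1, a2)`` pair of allele codes,
    or ``None`` when the locus is missing; alleles are stored in file order.
    """

    id: str
    population: str
    species: str = "unknown"
    region: str = ""
    is_reference: bool = False
    genotype: dict[str, tuple[int, int] | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.species not in SPECIES_VALUES:
            raise ValueError(
                f"species must be one of {SPECIES_VALUES}, got {self.species!r}"
            )


@dataclass
class GenotypeTable:
    """A validated multilocus genotype dataset.

    Invariants enforced at construction: every sample has an entry (possibly
    missing) for every locus, every observed allele is in its locus registry,
    sample ids are unique, and population labels are non-empty.
    """

    loci: list[Locus]
    samples: list[SampleRecord]
    missing_code: int = -9

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        ids = [s.id for s in self.samples]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate sample ids: {sorted(dup)}")
        registries = {l.name: set(l.alleles) for l in self.loci}
        for s in self.samples:
            if not s.population:
                raise ValueError(f"sample {s.id!r} has an empty population label")
            for name in names:
                g = s.genotype.get(name)
                if g is None:
                    s.genotype[name] = None
                    continue
                if len(g) != 2:
                    raise ValueError(
                        f"sample {s.id!r}, locus {name!r}: genotype must have 2 alleles"
                    )
                for a in g:
                    if a not in registries[name]:
                        raise ValueError(
                            f"sample {s.id!r}, locus {name!r}: allele {a} "
                            "not in locus registry"
                        )

    # -- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.population, None)
        return list(seen)

    def total_allele_count(self) -> int:
        """Total number of distinct alleles over all loci."""
        return sum(l.n_alleles for l in self.loci)

    def subset(self, predicate: Callable[[SampleRecord], bool]) -> "GenotypeTable":
        """New table containing the samples matching ``predicate``.

        Locus registries are kept as-is so allele indices stay comparable
        across subsets of the same parent table.
        """
        import copy

        return GenotypeTable(
            loci=list(self.loci),
            samples=[copy.deepcopy(s) for s in self.samples if predicate(s)],
            missing_code=self.missing_code,
        )

    def group_labels(self, grouping: "GroupingSpec") -> list[str]:
        """Resolve a grouping spec to one label per sample.

        ``grouping`` is a sample attribute name (``"population"``,
        ``"species"``, ``"region"``), a callable on :class:`SampleRecord`,
        or a sequence of labels aligned with ``samples``.
        """
        if callable(grouping):
            return [str(grouping(s)) for s in self.samples]
        if isinstance(grouping, str):
            return [str(getattr(s, grouping)) for s in self.samples]
        labels = [str(g) for g in grouping]
        if len(labels) != self.n_samples:
            raise ValueError("grouping sequence length does not match sample count")
        return labels

    def to_arrays(self) -> tuple[np.ndarray, list[dict[int, int]]]:
        """Integer-coded genotypes for numerical kernels.

        Returns ``(geno, allele_index)`` where ``geno`` has shape
        ``(n_samples, n_loci, 2)`` holding per-locus allele *indices*
        (position in the locus registry) with ``-1`` for missing, and
        ``allele_index[l]`` maps allele code -> index at locus ``l``.
        """
        index = [{a: i for i, a in enumerate(l.alleles)} for l in self.loci]
        geno = np.full((self.n_samples, self.n_loci, 2), -1, dtype=np.int64)
        for i, s in enumerate(self.samples):
            for j, l in enumerate(self.loci):
                g = s.genotype[l.name]
                if g is not None:
                    geno[i, j, 0] = index[j][g[0]]
                    geno[i, j, 1] = index[j][g[1]]
        return geno, index


GroupingSpec = str | Callable[[SampleRecord], str] | Sequence[str]


def concat_tables(tables: Sequence[GenotypeTable]) -> GenotypeTable:
    """Concatenate tables over a unified per-locus allele registry.

    All tables must share the same locus names in the same order; sample
    ids must be unique across the inputs.
    """
    if not tables:
        raise ValueError("need at least one table")
    names = tables[0].locus_names
    for t in tables[1:]:
        if t.locus_names != names:
            raise ValueError("tables have mismatched loci")
    registries: list[dict[int, None]] = [dict() for _ in names]
    for t in tables:
        for j, l in enumerate(t.loci):
            for a in l.alleles:
                registries[j].setdefault(a, None)
    loci = [Locus(n, tuple(sorted(reg))) for n, reg in zip(names, registries)]
    samples = [s for t in tables for s in t.samples]
    return GenotypeTable(loci=loci, samples=samples, missing_code=tables[0].missing_code)


def _build_loci(
    names: Sequence[str], genotypes: dict[str, dict[str, tuple[int, int] | None]]
) -> list[Locus]:
    """Locus registries from observed codes, in order of first appearance."""
    loci = []
    for name in names:
        seen: dict[int, None] = {}
        for g in genotypes.values():
            pair = g.get(name)
            if pair is not None:
                seen.setdefault(pair[0], None)
                seen.setdefault(pair[1], None)
        loci.append(Locus(name, tuple(seen)))
    return loci


# ---------------------------------------------------------------------------
# STRUCTURE dialect
# ---------------------------------------------------------------------------

def read_structure_file(
    path: str | Path,
    one_row_per_individual: bool = True,
    missing_code: int = -9,
    has_header: bool = True,
    has_popflag: bool = True,
) -> GenotypeTable:
    """Parse a STRUCTURE-dialect genotype file.

    Layout: an optional header row of locus names, then data rows of
    ``id population [popflag] allele...`` — two allele columns per locus in
    the one-row dialect, one per locus (two consecutive rows per individual)
    in the two-row dialect. The popflag column (0/1) maps to
    ``SampleRecord.is_reference``.
    """
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tokens = line.split()
            if tokens:
                rows.append((lineno, tokens))
    if not rows:
        raise GenotypeParseError(f"{path}: empty file")

    meta_cols = 3 if has_popflag else 2
    if has_header:
        header = rows[0][1]
        rows = rows[1:]
        locus_names = list(header)
    else:
        locus_names = None

    if not rows:
        raise GenotypeParseError(f"{path}: no data rows")

    per_locus_cols = 2 if one_row_per_individual else 1
    width = len(rows[0][1])
    n_loci, rem = divmod(width - meta_cols, per_locus_cols)
    if rem or n_loci < 1:
        raise GenotypeParseError(
            f"{path}, line {rows[0][0]}: row width {width} inconsistent with "
            f"{meta_cols} metadata columns and {per_locus_cols} column(s) per locus"
        )
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(n_loci)]
    if len(locus_names) != n_loci:
        raise GenotypeParseError(
            f"{path}: header names {len(locus_names)} loci but rows imply {n_loci}"
        )

    for lineno, tokens in rows:
        if len(tokens) != width:
            raise GenotypeParseError(
                f"{path}, line {lineno}: expected {width} columns, got {len(tokens)}"
            )

    def parse_allele(tok: str, lineno: int) -> int:
        try:
            return int(tok)
        except ValueError:
            raise GenotypeParseError(
                f"{path}, line {lineno}: non-integer allele code {tok!r}"
            ) from None

    samples: list[SampleRecord] = []
    genotypes: dict[str, dict[str, tuple[int, int] | None]] = {}

    def make_record(
        sid: str, pop: str, flag: str | None, pairs: list[tuple[int, int]], lineno: int
    ) -> None:
        if sid in genotypes:
            raise GenotypeParseError(f"{path}, line {lineno}: duplicate sample id {sid!r}")
        geno: dict[str, tuple[int, int] | None] = {}
        for name, (a1, a2) in zip(locus_names, pairs):
            n_missing = (a1 == missing_code) + (a2 == missing_code)
            if n_missing == 2:
                geno[name] = None
            elif n_missing == 1:
                raise GenotypeParseError(
                    f"{path}, line {lineno}: sample {sid!r}, locus {name!r} is "
                    "half-missing (exactly one allele equals the missing code)"
                )
            else:
                geno[name] = (a1, a2)
        genotypes[sid] = geno
        is_ref = flag is not None and flag not in ("0", "")
        samples.append(
            SampleRecord(id=sid, population=pop, is_reference=is_ref, genotype=geno)
        )

    if one_row_per_individual:
        for lineno, tokens in rows:
            sid, pop = tokens[0], tokens[1]
            flag = tokens[2] if has_popflag else None
            codes = [parse_allele(t, lineno) for t in tokens[meta_cols:]]
            pairs = [(codes[2 * j], codes[2 * j + 1]) for j in range(n_loci)]
            make_record(sid, pop, flag, pairs, lineno)
    else:
        if len(rows) % 2:
            raise GenotypeParseError(
                f"{path}: two-row dialect requires an even number of data rows"
            )
        for (ln1, t1), (ln2, t2) in zip(rows[::2], rows[1::2]):
            if t1[0] != t2[0]:
                raise GenotypeParseError(
                    f"{path}, lines {ln1}/{ln2}: row pair has mismatched ids "
                    f"{t1[0]!r} vs {t2[0]!r}"
                )
            sid, pop = t1[0], t1[1]
            flag = t1[2] if has_popflag else None
            row1 = [parse_allele(t, ln1) for t in t1[meta_cols:]]
            row2 = [parse_allele(t, ln2) for t in t2[meta_cols:]]
            pairs = list(zip(row1, row2))
            make_record(sid, pop, flag, pairs, ln1)

    loci = _build_loci(locus_names, genotypes)
    return GenotypeTable(loci=loci, samples=samples, missing_code=missing_code)


def write_structure_file(
    table: GenotypeTable,
    path: str | Path,
    one_row_per_individual: bool = True,
) -> None:
    """Write ``table`` in the STRUCTURE dialect (header + popflag column)."""
    mc = str(table.missing_code)
    lines = [" ".join(table.locus_names)]
    for s in table.samples:
        flag = "1" if s.is_reference else "0"
        meta = [s.id, s.population.replace(" ", "_"), flag]
        if one_row_per_individual:
            codes: list[str] = []
            for l in table.loci:
                g = s.genotype[l.name]
                codes += [mc, mc] if g is None else [str(g[0]), str(g[1])]
            lines.append(" ".join(meta + codes))
        else:
            for k in (0, 1):
                codes = []
                for l in table.loci:
                    g = s.genotype[l.name]
                    codes.append(mc if g is None else str(g[k]))
                lines.append(" ".join(meta + codes))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GENEPOP dialect
# ---------------------------------------------------------------------------

def read_genepop_file(path: str | Path) -> GenotypeTable:
    """Parse a GENEPOP file (2- or 3-digit encoding, ``Pop`` blocks).

    Population names are taken from the id of the first sample in each
    ``Pop`` block, following the usual GENEPOP convention. ``00``/``000``
    decodes as missing; a genotype mixing 2- and 3-digit encoding within a
    locus is rejected.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [line.rstrip("\n") for line in fh]
    if len(lines) < 3:
        raise GenotypeParseError(f"{path}: file too short for GENEPOP format")

    # line 1: title. Then locus names: one per line, or comma-separated.
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = lines[i].strip()
        if part:
            locus_names += [t.strip() for t in part.split(",") if t.strip()]
        i += 1
    if i == len(lines):
        raise GenotypeParseError(f"{path}: no 'Pop' delimiter found")
    if not locus_names:
        raise GenotypeParseError(f"{path}: no locus names before first 'Pop'")

    n_loci = len(locus_names)
    digit_width: list[int | None] = [None] * n_loci
    samples: list[SampleRecord] = []
    genotypes: dict[str, dict[str, tuple[int, int] | None]] = {}
    pop_name: str | None = None
    pop_counter = 0

    for lineno in range(i, len(lines)):
        raw = lines[lineno].strip()
        if not raw:
            continue
        if raw.lower() == "pop":
            pop_name = None
            pop_counter += 1
            continue
        if pop_counter == 0:
            raise GenotypeParseError(f"{path}, line {lineno + 1}: data before 'Pop'")
        if "," in raw:
            sid, geno_part = raw.split(",", 1)
        else:
            parts = raw.split(None, 1)
            if len(parts) != 2:
                raise GenotypeParseError(
                    f"{path}, line {lineno + 1}: cannot split id from genotypes"
                )
            sid, geno_part = parts
        sid = sid.strip()
        if pop_name is None:
            pop_name = sid
        tokens = geno_part.split()
        if len(tokens) != n_loci:
            raise GenotypeParseError(
                f"{path}, line {lineno + 1}: expected {n_loci} genotype fields, "
                f"got {len(tokens)}"
            )
        if sid in genotypes:
            raise GenotypeParseError(
                f"{path}, line {lineno + 1}: duplicate sample id {sid!r}"
            )
        geno: dict[str, tuple[int, int] | None] = {}
        for j, tok in enumerate(tokens):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenotypeParseError(
                    f"{path}, line {lineno + 1}: genotype field {tok!r} is not a "
                    "4- or 6-digit code"
                )
            w = len(tok) // 2
            if digit_width[j] is None:
                digit_width[j] = w
            elif digit_width[j] != w:
                raise GenotypeParseError(
                    f"{path}, line {lineno + 1}: locus {locus_names[j]!r} mixes "
                    f"{2 * digit_width[j]}- and {2 * w}-digit encoding"
                )
            a1, a2 = int(tok[:w]), int(tok[w:])
            if a1 == 0 and a2 == 0:
                geno[locus_names[j]] = None
            elif a1 == 0 or a2 == 0:
                raise GenotypeParseError(
                    f"{path}, line {lineno + 1}: locus {locus_names[j]!r} is "
                    "half-missing"
                )
            else:
                geno[locus_names[j]] = (a1, a2)
        genotypes[sid] = geno
        samples.append(SampleRecord(id=sid, population=pop_name, genotype=geno))

    loci = _build_loci(locus_names, genotypes)
    return GenotypeTable(loci=loci, samples=samples)


def write_genepop_file(
    table: GenotypeTable, path: str | Path, digits: int = 3, title: str = "introgress export"
) -> None:
    """Write ``table`` as a GENEPOP file, one ``Pop`` block per population."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    maxcode = 10**digits - 1
    for l in table.loci:
        for a in l.alleles:
            if not (1 <= a <= maxcode):
                raise ValueError(
                    f"allele code {a} at locus {l.name!r} does not fit "
                    f"{digits}-digit GENEPOP encoding"
                )
    lines = [title]
    lines += table.locus_names
    for pop in table.populations():
        lines.append("Pop")
        for s in table.samples:
            if s.population != pop:
                continue
            fields = []
            for l in table.loci:
                g = s.genotype[l.name]
                if g is None:
                    fields.append("0" * (2 * digits))
                else:
                    fields.append(f"{g[0]:0{digits}d}{g[1]:0{digits}d}")
            lines.append(f"{s.id} , " + " ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata CSV with columns id, population, species,
    region, is_reference (truthy as 1/0/true/false)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"id", "population", "species", "region", "is_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    return df


def attach_metadata(table: GenotypeTable, metadata: pd.DataFrame | str | Path) -> None:
    """Attach species/region/reference metadata to samples in place.

    ``metadata`` is a DataFrame (or CSV path) as produced by
    :func:`read_sample_metadata`; unknown sample ids in the table are left
    untouched, unknown ids in the metadata are ignored.
    """
    if not isinstance(metadata, pd.DataFrame):
        metadata = read_sample_metadata(metadata)
    by_id = {str(r["id"]): r for _, r in metadata.iterrows()}
    for s in table.samples:
        row = by_id.get(s.id)
        if row is None:
            continue
        if row.get("population"):
            s.population = str(row["population"])
        if row.get("species"):
            s.species = str(row["species"])
        s.region = str(row.get("region", s.region))
        flag = str(row.get("is_reference", "")).strip().lower()
        s.is_reference = flag in ("1", "true", "yes")


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class GroupFrequencies:
    """Per-group per-locus allele frequencies with gene-copy counts.

    ``freqs[group][l]`` maps allele code -> relative frequency at locus ``l``
    (empty dict when the group has no data there); ``gene_counts[group][l]``
    is the number of non-missing gene copies behind those frequencies.
    """

    locus_names: list[str]
    freqs: dict[str, list[dict[int, float]]]
    gene_counts: dict[str, list[int]]

    @property
    def groups(self) -> list[str]:
        return list(self.freqs)


def allele_frequencies(
    table: GenotypeTable,
    grouping: GroupingSpec = "population",
    groups: Iterable[str] | None = None,
) -> GroupFrequencies:
    """Tally allele frequencies per group and locus.

    Missing genotypes are excluded from the denominators; frequencies sum to
    one within every (group, locus) cell that has data. Requesting ``groups``
    that do not occur in the table raises ``ValueError``.
    """
    labels = table.group_labels(grouping)
    present: dict[str, None] = {}
    for lab in labels:
        present.setdefault(lab, None)
    if groups is None:
        use = list(present)
    else:
        use = [str(g) for g in groups]
        unknown = [g for g in use if g not in present]
        if unknown:
            raise ValueError(f"unknown group label(s): {unknown}")

    freqs: dict[str, list[dict[int, float]]] = {}
    counts: dict[str, list[int]] = {}
    for g in use:
        tallies: list[dict[int, int]] = [dict() for _ in table.loci]
        for s, lab in zip(table.samples, labels):
            if lab != g:
                continue
            for j, l in enumerate(table.loci):
                pair = s.genotype[l.name]
                if pair is None:
                    continue
                for a in pair:
                    tallies[j][a] = tallies[j].get(a, 0) + 1
        freqs[g] = []
        counts[g] = []
        for tally in tallies:
            total = sum(tally.values())
            counts[g].append(total)
            freqs[g].append(
                {a: c / total for a, c in sorted(tally.items())} if total else {}
            )
    return GroupFrequencies(locus_names=table.locus_names, freqs=freqs, gene_counts=counts)
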