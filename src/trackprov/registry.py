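"""Registry of genome builds and their chromosome-size tables.

A genome build (assembly) is the unit of build prediction: a named,
versioned reference whose chromosome lengths define which coordinates are
valid.  The registry bundles frozen chromosome-size tables for eight builds
across three species (human hg18/hg19/hg38, mouse mm9/mm10, fruit fly
dm3/dm6, plus two toy builds for fast tests) and can be extended with
user-supplied two-column ``chrom.sizes`` tables, the format emitted by
UCSC's ``fetchChromSizes``.

Lookup is case-insensitive and accepts aliases (``GRCh37`` resolves to
``hg19``).  Sequence-name normalization maps common dialect variants
(``1`` vs ``chr1``, ``MT`` vs ``chrM``, case differences) onto a build's
canonical names; anything else must match exactly.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import yaml

from .errors import (
    RegistryConflictError,
    SizesParseError,
    UnknownBuildError,
)

__all__ = [
    "GenomeBuild",
    "BuildRegistry",
    "load_registry",
    "normalize_chrom",
    "read_chrom_sizes",
    "BUNDLED_BUILDS",
]

#: id -> (species, aliases, primary-set chromosome names)
BUNDLED_BUILDS: dict[str, tuple[str, tuple[str, ...], tuple[str, ...]]] = {
    "hg18": ("Homo sapiens", ("grch36", "ncbi36"),
             tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")),
    "hg19": ("Homo sapiens", ("grch37",),
             tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")),
    "hg38": ("Homo sapiens", ("grch38",),
             tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")),
    "mm9": ("Mus musculus", ("ncbi37",),
            tuple(f"chr{i}" for i in range(1, 20)) + ("chrX", "chrY")),
    "mm10": ("Mus musculus", ("grcm38",),
             tuple(f"chr{i}" for i in range(1, 20)) + ("chrX", "chrY")),
    "dm3": ("Drosophila melanogaster", ("bdgp5", "bdgp5.25"),
            ("chr2L", "chr2R", "chr3L", "chr3R", "chr4", "chrX")),
    "dm6": ("Drosophila melanogaster", ("bdgp6",),
            ("chr2L", "chr2R", "chr3L", "chr3R", "chr4", "chrX", "chrY")),
    "toyA": ("synthetic", (), ("chr1", "chr2", "chr3")),
    "toyB": ("synthetic", (), ("chr1", "chr2", "chr3")),
}


def read_chrom_sizes(source: str | Path) -> dict[str, int]:
    """Parse a two-column ``<name>\\t<length>`` chrom.sizes table.

    Blank lines are ignored.  Raises :class:`SizesParseError` naming the
    offending line for anything else that does not parse.
    """
    path = Path(source)
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise SizesParseError(str(path), line_no, "expected <name> <length>")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise SizesParseError(
                    str(path), line_no, f"length {fields[1]!r} is not an integer"
                ) from None
            if length <= 0:
                raise SizesParseError(str(path), line_no, f"non-positive length {length}")
            if name in sizes:
                raise SizesParseError(str(path), line_no, f"duplicate sequence {name!r}")
            sizes[name] = length
    return sizes


@dataclass(frozen=True)
class GenomeBuild:
    """A named genome assembly with its chromosome-size table.

    Parameters
    ----------
    id
        Short build name, e.g. ``"hg19"``.
    species
        Binomial species name.
    aliases
        Alternative names resolving to this build (e.g. ``"grch37"``).
    chrom_sizes
        Canonical chromosome name -> length in base pairs.
    primary_set
        The chromosomes counted as autosomes + sex chromosomes; the
        universe for binning.  Always a subset of ``chrom_sizes``.
    """

    id: str
    species: str
    aliases: frozenset[str]
    chrom_sizes: Mapping[str, int]
    primary_set: tuple[str, ...]
    _lower_names: Mapping[str, str] = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        for name, length in self.chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"{self.id}: chromosome {name} has length {length}")
        missing = [c for c in self.primary_set if c not in self.chrom_sizes]
        if missing:
            raise ValueError(f"{self.id}: primary chromosomes missing from table: {missing}")
        object.__setattr__(
            self, "_lower_names", {n.lower(): n for n in self.chrom_sizes}
        )

    def length_of(self, chrom: str) -> int | None:
        """Length of *chrom* after normalization, or None if unknown."""
        canonical = normalize_chrom(chrom, self)
        return None if canonical is None else self.chrom_sizes[canonical]

    def genome_length(self, primary_only: bool = True) -> int:
        names = self.primary_set if primary_only else tuple(self.chrom_sizes)
        return sum(self.chrom_sizes[c] for c in names)


def normalize_chrom(name: str, build: GenomeBuild) -> str | None:
    """Map a raw sequence label onto *build*'s canonical chromosome name.

    Rules, deliberately minimal and auditable: exact match (case-insensitive),
    add or strip a ``chr`` prefix, and the mitochondrial synonym MT <-> chrM.
    Returns None when nothing matches — unknown is a value, not an error.
    Idempotent: normalizing a canonical name returns it unchanged.
    """
    lower = build._lower_names
    candidates = [name]
    if name.lower().startswith("chr"):
        candidates.append(name[3:])
    else:
        candidates.append("chr" + name)
    if name.upper() == "MT":
        candidates.append("chrM")
    elif name.lower() == "chrm":
        candidates.append("MT")
    for cand in candidates:
        hit = lower.get(cand.lower())
        if hit is not None:
            return hit
    return None


class BuildRegistry:
    """Case-insensitive mapping from build ids and aliases to builds."""

    def __init__(self, builds: Iterable[GenomeBuild] = ()) -> None:
        self._builds: dict[str, GenomeBuild] = {}
        self._by_name: dict[str, str] = {}  # lowercased id/alias -> id
        for build in builds:
            self.add(build)

    def add(self, build: GenomeBuild) -> None:
        names = {build.id.lower()} | {a.lower() for a in build.aliases}
        clash = names & self._by_name.keys()
        if clash:
            raise RegistryConflictError(
                f"build {build.id!r}: name(s) already registered: {sorted(clash)}"
            )
        self._builds[build.id] = build
        for name in names:
            self._by_name[name] = build.id

    def lookup(self, name: str) -> GenomeBuild:
        """Resolve an id or alias (case-insensitive) to its build."""
        build_id = self._by_name.get(name.lower())
        if build_id is None:
            raise UnknownBuildError(f"unknown genome build {name!r}")
        return self._builds[build_id]

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._by_name

    def __iter__(self) -> Iterator[GenomeBuild]:
        return iter(self._builds.values())

    def __len__(self) -> int:
        return len(self._builds)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._builds)

    def resolve_token(self, token: str) -> str | None:
        """Return the build id a scanned token refers to, if any."""
        build_id = self._by_name.get(token.lower())
        return build_id


def _bundled_builds() -> Iterator[GenomeBuild]:
    data_root = importlib.resources.files("trackprov") / "data"
    for build_id, (species, aliases, primary) in BUNDLED_BUILDS.items():
        with importlib.resources.as_file(data_root / f"{build_id}.chrom.sizes") as p:
            sizes = read_chrom_sizes(p)
        yield GenomeBuild(
            id=build_id,
            species=species,
            aliases=frozenset(aliases),
            chrom_sizes=sizes,
            primary_set=primary,
        )


def _builds_from_config(config_path: str | Path) -> Iterator[GenomeBuild]:
    """Read a registry-extension YAML config.

    Schema::

        builds:
          - id: myasm1
            species: Examplus speciosus
            aliases: [asm1]
            chrom_sizes: relative/or/absolute/path.chrom.sizes
            primary: [chr1, chr2]     # optional; default: all but chrM/MT
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        config = yaml.safe_load(fh) or {}
    for entry in config.get("builds", []):
        sizes_path = Path(entry["chrom_sizes"])
        if not sizes_path.is_absolute():
            sizes_path = config_path.parent / sizes_path
        sizes = read_chrom_sizes(sizes_path)
        primary = entry.get("primary")
        if primary is None:
            primary = [c for c in sizes if c.lower() not in ("chrm", "mt")]
        yield GenomeBuild(
            id=str(entry["id"]),
            species=str(entry.get("species", "unknown")),
            aliases=frozenset(str(a) for a in entry.get("aliases", ())),
            chrom_sizes=sizes,
            primary_set=tuple(primary),
        )


def load_registry(
    extra_tables: Mapping[str, str | Path] | None = None,
    config: str | Path | None = None,
) -> BuildRegistry:
    """Build the registry of bundled builds plus user extensions.

    Parameters
    ----------
    extra_tables
        Mapping of build id -> chrom.sizes path for quick ad-hoc additions
        (species recorded as "unknown", no aliases, primary = all non-chrM).
    config
        Path to a YAML registry-extension file (see module docs).
    """
    registry = BuildRegistry(_bundled_builds())
    if config is not None:
        for build in _builds_from_config(config):
            registry.add(build)
    if extra_tables:
        for build_id, path in extra_tables.items():
            sizes = read_chrom_sizes(path)
            primary = tuple(c for c in sizes if c.lower() not in ("chrm", "mt"))
            registry.add(
                GenomeBuild(
                    id=build_id,
                    species="unknown",
                    aliases=frozenset(),
                    chrom_sizes=sizes,
                    primary_set=primary,
                )
            )
    return registry
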