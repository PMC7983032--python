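"""Declarative resource registry, tabular readers and a local file cache.

Every input file (interaction tables, enzyme-substrate tables, complex
membership lists, annotation tables, mapping tables, ...) is described by a
:class:`ResourceDescriptor` in a YAML registry.  Loading goes through a
content-addressed cache keyed by a digest of the locator, so a build never
touches a remote source twice and remains fully reproducible offline.

Parsed rows are returned as :class:`RawRecord` objects that retain their
resource name and line number — every record in every built database can be
traced back to at least one (resource, line).
"""

from __future__ import annotations

import hashlib
import logging
import shutil
import urllib.request
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ConfigError, FormatError

log = logging.getLogger(__name__)

FORMATS = (
    "interaction_table",
    "enzsub_table",
    "complex_table",
    "annotation_table",
    "mapping_table",
    "homology_table",
    "site_homology_table",
    "sequence_fasta",
    "go_gaf",
    "expression_matrix",
)

#: Semantic fields a schema must cover, per tabular format.
MANDATORY_FIELDS = {
    "interaction_table": {"source", "target"},
    "enzsub_table": {"enzyme", "substrate", "residue_type", "residue_offset",
                     "modification"},
    "complex_table": {"components"},
    "annotation_table": {"entity"},
    "mapping_table": {"foreign", "reference"},
    "homology_table": {"group", "taxid", "refseq"},
    "site_homology_table": {"source_acc", "source_pos", "target_org",
                            "target_acc", "target_pos"},
    "go_gaf": set(),
    "sequence_fasta": set(),
    "expression_matrix": set(),
}


@dataclass
class ResourceDescriptor:
    """Declarative description of one input resource."""

    name: str
    locator: str
    format: str
    schema: dict[str, str] = field(default_factory=dict)  # column -> field
    license_tag: str = ""
    secondary_of: tuple[str, ...] = ()
    literature_curated: bool = False
    dataset: str | None = None       # network dataset tag, if interaction
    id_space: str = "uniprot"        # identifier space of entity columns
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.format not in FORMATS:
            raise ConfigError(f"unknown resource format: {self.format!r}")
        missing = MANDATORY_FIELDS.get(self.format, set()) \
            - set(self.schema.values())
        if self.schema and missing:
            raise ConfigError(
                f"resource {self.name!r}: schema misses mandatory fields "
                f"{sorted(missing)}")


@dataclass
class RawRecord:
    """One parsed line with full provenance."""

    resource: str
    fields: dict[str, str]
    line_no: int


def cache_key(locator: str) -> str:
    return hashlib.sha256(locator.encode("utf-8")).hexdigest()


def cache_path(cache_dir, locator: str) -> Path:
    digest = cache_key(locator)
    return Path(cache_dir) / digest[:2] / digest


def _fetch(locator: str, dest: Path, online: bool) -> None:
    dest.parent.mkdir(parents=True, exist_ok=True)
    src = Path(locator)
    if src.exists():
        shutil.copyfile(src, dest)
    elif online and "://" in locator:
        with urllib.request.urlopen(locator) as resp, open(dest, "wb") as out:
            shutil.copyfileobj(resp, out)
    else:
        raise IOError(f"resource not readable and not cached: {locator}")


def load_resource(desc: ResourceDescriptor, cache_dir=None,
                  online: bool = False) -> list[RawRecord]:
    """Load and parse a resource, via the cache.

    A populated cache entry is always preferred (no remote/file access); on a
    miss the locator is fetched, cached, then parsed.  Malformed lines are
    skipped with a logged count, never fatal.
    """
    if cache_dir is not None:
        entry = cache_path(cache_dir, desc.locator)
        if not entry.exists():
            _fetch(desc.locator, entry, online)
        path = entry
    else:
        path = Path(desc.locator)
        if not path.exists():
            raise IOError(f"resource file missing: {desc.name} ({path})")
    return parse_table(path, desc)


def parse_table(path, desc: ResourceDescriptor) -> list[RawRecord]:
    """Parse a tab-separated table per the descriptor's schema.

    Dialect: tab-separated, ``#`` comment lines, UTF-8, no quoting.  The first
    non-comment line is the header; columns named in the schema map to
    semantic fields.  Rows missing a mandatory field are counted and skipped.
    """
    mandatory = MANDATORY_FIELDS.get(desc.format, set())
    records: list[RawRecord] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        header = None
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                unknown = set(desc.schema) - set(header)
                if unknown:
                    raise FormatError(
                        f"{desc.name}: schema columns {sorted(unknown)} "
                        f"absent from header of {path}")
                continue
            if len(cells) != len(header):
                skipped += 1
                continue
            row = dict(zip(header, cells))
            fields = {sem: row[col] for col, sem in desc.schema.items()}
            if any(not fields.get(f, "") for f in mandatory):
                skipped += 1
                continue
            records.append(RawRecord(desc.name, fields, line_no))
    if skipped:
        log.info("%s: skipped %d malformed line(s)", desc.name, skipped)
    return records


def load_registry(path) -> list[ResourceDescriptor]:
    """Read a YAML list of resource descriptors.

    Relative locators are resolved against the registry file's directory.
    """
    base = Path(path).parent
    with open(path, encoding="utf-8") as fh:
        entries = yaml.safe_load(fh) or []
    descriptors = []
    seen = set()
    for entry in entries:
        desc = ResourceDescriptor(
            name=entry["name"],
            locator=str((base / entry["locator"]).resolve())
            if "://" not in entry["locator"] else entry["locator"],
            format=entry["format"],
            schema=entry.get("schema", {}),
            license_tag=entry.get("license_tag", ""),
            secondary_of=tuple(entry.get("secondary_of", [])),
            literature_curated=bool(entry.get("literature_curated", False)),
            dataset=entry.get("dataset"),
            id_space=entry.get("id_space", "uniprot"),
            options=entry.get("options", {}),
        )
        if desc.name in seen:
            raise ConfigError(f"duplicate resource name: {desc.name}")
        seen.add(desc.name)
        descriptors.append(desc)
    return descriptors


def resolve_secondary(registry: list[ResourceDescriptor],
                      closure: bool = False) -> list[tuple[str, str]]:
    """Report which resources are re-exports of others.

    Returns (resource, original) pairs; with ``closure`` the transitive
    closure of the secondary-of relation is included.  Pure report — used for
    evidence deduplication policies, never mutates the registry.
    """
    direct = {d.name: set(d.secondary_of) for d in registry}
    result = {(name, parent) for name, parents in direct.items()
              for parent in parents}
    if closure:
        changed = True
        while changed:
            changed = False
            for name, parent in list(result):
                for grand in direct.get(parent, ()):
                    if (name, grand) not in result:
                        result.add((name, grand))
                        changed = True
    return sorted(result)


def clear_cache(cache_dir) -> int:
    """Remove all cache entries; returns the number removed."""
    root = Path(cache_dir)
    n = 0
    if root.exists():
        for entry in root.glob("*/*"):
            entry.unlink()
            n += 1
    return n


def list_cache(cache_dir) -> list[str]:
    root = Path(cache_dir)
    return sorted(p.name for p in root.glob("*/*")) if root.exists() else []
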