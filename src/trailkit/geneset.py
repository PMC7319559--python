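"""Gene-set collections and the background universe.

A :class:`GeneSetCollection` holds named categories of gene identifiers
(e.g. GO terms, KEGG pathways) together with the background universe that
every enrichment test samples from.  Collections are exchanged in the GMT
dialect: one set per line, ``id <TAB> description <TAB> member...``.

Identifiers are compared case-sensitively after stripping surrounding
whitespace.  An optional two-column mapping table (old-id -> new-id, TSV,
no header) can be applied at load time for simple namespace translation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

logger = logging.getLogger(__name__)

#: Default category-size bounds applied by :func:`filter_by_size` callers.
#: Singleton categories carry no enrichment information and very large ones
#: are dominated by the universe itself.
DEFAULT_MIN_SIZE = 2
DEFAULT_MAX_SIZE = 1000


class GMTFormatError(ValueError):
    """Raised for malformed GMT or mapping-table input."""


@dataclass
class GeneSetCollection:
    """Named categories of gene identifiers plus a background universe.

    Attributes
    ----------
    name:
        Free-text label for the collection (e.g. the GMT file stem).
    categories:
        Maps category id to ``(display_name, members)``.
    universe:
        The background gene universe.  After :func:`harmonize`, every
        category is a subset of it.
    """

    name: str
    categories: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.categories)

    def members(self, category_id: str) -> frozenset[str]:
        return self.categories[category_id][1]

    def display_name(self, category_id: str) -> str:
        return self.categories[category_id][0]


def _load_mapping(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise GMTFormatError(
                    f"{path}: mapping line {lineno} has {len(fields)} fields, expected 2"
                )
            mapping[fields[0].strip()] = fields[1].strip()
    return mapping


def read_gmt(path: str | Path, mapping: str | Path | Mapping[str, str] | None = None) -> GeneSetCollection:
    """Read a GMT file into a :class:`GeneSetCollection`.

    Each line must have at least three tab-separated fields:
    category id, description, then one or more member identifiers.
    The universe is the union of all members (override later with
    :func:`harmonize`).

    Parameters
    ----------
    path:
        GMT file to read.
    mapping:
        Optional identifier translation: a dict or a path to a two-column
        TSV (old-id TAB new-id, no header).  Unmapped ids pass through.

    Raises
    ------
    GMTFormatError
        On a line with fewer than three fields (naming the line number),
        a duplicate category id, or a file with no categories.
    """
    if mapping is None:
        idmap: Mapping[str, str] = {}
    elif isinstance(mapping, (str, Path)):
        idmap = _load_mapping(mapping)
    else:
        idmap = mapping

    categories: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("\n").split("\t")]
            if len(fields) < 3:
                raise GMTFormatError(
                    f"{path}: line {lineno} has {len(fields)} fields, expected >= 3 "
                    "(id, description, members...)"
                )
            cid, desc = fields[0], fields[1]
            if cid in categories:
                raise GMTFormatError(f"{path}: duplicate category id {cid!r} at line {lineno}")
            members = frozenset(idmap.get(m, m) for m in fields[2:] if m)
            if not members:
                raise GMTFormatError(f"{path}: line {lineno} ({cid!r}) has no members")
            categories[cid] = (desc, members)

    if not categories:
        raise GMTFormatError(f"{path}: no categories")

    universe = frozenset().union(*(m for _, m in categories.values()))
    return GeneSetCollection(name=Path(path).stem, categories=categories, universe=universe)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    """Write a collection in the same GMT dialect that :func:`read_gmt` reads.

    Members are sorted lexicographically so output is deterministic and
    read/write round-trips membership exactly.
    """
    with open(path, "w") as fh:
        for cid, (desc, members) in coll.categories.items():
            fh.write("\t".join([cid, desc, *sorted(members)]) + "\n")


def filter_by_size(
    coll: GeneSetCollection,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> GeneSetCollection:
    """Keep categories with ``min_size <= |C ∩ U| <= max_size``.

    The universe is unchanged.  An empty result is allowed (logged as a
    warning), since downstream enrichment simply produces no records.
    """
    if not (1 <= min_size <= max_size):
        raise ValueError(f"require 1 <= min_size <= max_size, got ({min_size}, {max_size})")
    kept = {
        cid: (desc, members)
        for cid, (desc, members) in coll.categories.items()
        if min_size <= len(members & coll.universe) <= max_size
    }
    if not kept:
        logger.warning(
            "size filter (%d, %d) removed all %d categories", min_size, max_size, len(coll)
        )
    return GeneSetCollection(name=coll.name, categories=kept, universe=coll.universe)


def harmonize(coll: GeneSetCollection, universe: set[str] | frozenset[str]) -> GeneSetCollection:
    """Intersect every category with ``universe`` and adopt it as background.

    Categories that fall entirely outside the new universe are dropped with
    a warning.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    uni = frozenset(universe)
    categories: dict[str, tuple[str, frozenset[str]]] = {}
    for cid, (desc, members) in coll.categories.items():
        inter = members & uni
        if inter:
            categories[cid] = (desc, inter)
        else:
            logger.warning("category %r has no members in the new universe; dropped", cid)
    return GeneSetCollection(name=coll.name, categories=categories, universe=uni)
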