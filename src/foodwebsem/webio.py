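"""Reading, writing, validating and filtering food webs and their metadata.

A food web is a directed graph whose links point consumer -> resource.
Files come in two dialects: two-column edge lists (consumer, resource) and
labelled binary adjacency matrices (rows = resources, columns = consumers,
the common GlobalWeb layout).  Metadata is a CSV with one row per web
carrying the abiotic covariates (latitude, longitude, mean annual
temperature, ecosystem class).
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

ECOSYSTEMS = ("terrestrial", "freshwater", "marine", "estuarine")


class WebFormatError(ValueError):
    """Raised for malformed web or metadata files."""


@dataclass(frozen=True, eq=False)
class FoodWeb:
    """A directed food web; links point consumer -> resource.

    Parameters
    ----------
    web_id : str
        Identifier used to join the web with its metadata row.
    taxa : tuple of str
        Ordered, unique, non-empty taxon labels.  Order fixes iteration;
        two webs are equal when id, taxon *set* and link set agree.
    links : frozenset of (str, str)
        Feeding links as (consumer, resource) pairs.  Self-loops
        (cannibalism) are permitted.
    """

    web_id: str
    taxa: tuple[str, ...]
    links: frozenset[tuple[str, str]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodWeb):
            return NotImplemented
        return (
            self.web_id == other.web_id
            and set(self.taxa) == set(other.taxa)
            and self.links == other.links
        )

    def __hash__(self) -> int:
        return hash((self.web_id, frozenset(self.taxa), self.links))

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise WebFormatError(f"{self.web_id}: duplicate taxon labels")
        if any(not t for t in self.taxa):
            raise WebFormatError(f"{self.web_id}: empty taxon label")
        members = set(self.taxa)
        for c, r in self.links:
            if c not in members or r not in members:
                raise WebFormatError(
                    f"{self.web_id}: link ({c!r}, {r!r}) has endpoint outside taxa"
                )

    @property
    def n_species(self) -> int:
        return len(self.taxa)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def resources_of(self, taxon: str) -> set[str]:
        """Prey set of ``taxon`` (self-loops included)."""
        return {r for c, r in self.links if c == taxon}

    def consumers_of(self, taxon: str) -> set[str]:
        """Predator set of ``taxon`` (self-loops included)."""
        return {c for c, r in self.links if r == taxon}


@dataclass(frozen=True)
class WebMetadata:
    """Per-web abiotic covariates.

    ``aquatic`` is derived: 0 for terrestrial webs, 1 for freshwater,
    marine and estuarine ones.  ``temperature_C`` is ``None`` when the
    source row had no usable temperature; such records are kept but
    flagged so the study stage can apply listwise deletion.
    """

    web_id: str
    latitude: float
    longitude: float
    temperature_C: float | None
    ecosystem: str
    aquatic: int = field(init=False)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise WebFormatError(
                f"{self.web_id}: latitude {self.latitude} outside [-90, 90]"
            )
        if not -180.0 <= self.longitude <= 180.0:
            raise WebFormatError(
                f"{self.web_id}: longitude {self.longitude} outside [-180, 180]"
            )
        if self.ecosystem not in ECOSYSTEMS:
            raise WebFormatError(
                f"{self.web_id}: unknown ecosystem {self.ecosystem!r} "
                f"(expected one of {ECOSYSTEMS})"
            )
        object.__setattr__(
            self, "aquatic", 0 if self.ecosystem == "terrestrial" else 1
        )

    @property
    def temperature_missing(self) -> bool:
        return self.temperature_C is None


def _split_fields(line: str) -> list[str]:
    """Split a line on tab or comma, stripping whitespace."""
    sep = "\t" if "\t" in line else ","
    return [f.strip() for f in line.split(sep)]


def read_edgelist(path: str | Path, web_id: str | None = None) -> FoodWeb:
    """Read a food web from a two-column edge list.

    Each non-comment line is ``consumer<sep>resource`` with tab or comma
    separator; ``#`` starts a comment; an optional header line with the
    literal column names ``consumer``/``resource`` is skipped.  Duplicate
    lines are deduplicated with a logged warning count.
    """
    path = Path(path)
    if web_id is None:
        web_id = path.stem
    taxa: dict[str, None] = {}  # insertion-ordered set
    links: set[tuple[str, str]] = set()
    n_dup = 0
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if stripped.startswith("#! isolated:"):
                # directive recording a taxon with no links (see write_edgelist)
                taxa.setdefault(stripped.split(":", 1)[1].strip())
                continue
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = _split_fields(line)
            if len(fields) != 2 or not all(fields):
                raise WebFormatError(
                    f"{path}:{lineno}: expected two fields (consumer, resource), "
                    f"got {raw.rstrip()!r}"
                )
            c, r = fields
            if n_rows == 0 and (c.lower(), r.lower()) == ("consumer", "resource"):
                continue
            n_rows += 1
            if (c, r) in links:
                n_dup += 1
            links.add((c, r))
            taxa.setdefault(c)
            taxa.setdefault(r)
    if not links:
        raise WebFormatError(f"{path}: no links found")
    if n_dup:
        logger.warning("%s: %d duplicate link line(s) removed", web_id, n_dup)
    return FoodWeb(web_id=web_id, taxa=tuple(taxa), links=frozenset(links))


def write_edgelist(web: FoodWeb, path: str | Path) -> None:
    """Write ``web`` as a tab-separated edge list (consumer, resource)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# consumer\tresource\n")
        for c, r in sorted(web.links):
            fh.write(f"{c}\t{r}\n")
        # isolated taxa carry no links; record them so round-trips preserve S
        linked = {t for link in web.links for t in link}
        for t in web.taxa:
            if t not in linked:
                fh.write(f"#! isolated: {t}\n")


def read_adjacency(
    path: str | Path, web_id: str | None = None, transpose: bool = False
) -> FoodWeb:
    """Read a food web from a labelled binary adjacency matrix (CSV).

    Convention: rows are resources, columns are consumers, so
    ``cell[r][c] = 1`` means consumer *c* eats resource *r*.  Pass
    ``transpose=True`` for files using the opposite dialect.  Rectangular
    matrices are allowed (row and column label sets may differ); taxa is
    their union.
    """
    path = Path(path)
    if web_id is None:
        web_id = path.stem
    with open(path, encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh) if row and any(f.strip() for f in row)]
    if len(rows) < 2:
        raise WebFormatError(f"{path}: adjacency matrix needs labels and data")
    col_labels = [f.strip() for f in rows[0][1:]]
    taxa: dict[str, None] = {}
    links: set[tuple[str, str]] = set()
    row_labels = []
    for i, row in enumerate(rows[1:], start=2):
        label = row[0].strip()
        row_labels.append(label)
        cells = [f.strip() for f in row[1:]]
        if len(cells) != len(col_labels):
            raise WebFormatError(
                f"{path}:{i}: row has {len(cells)} cells, expected {len(col_labels)}"
            )
        for label_c, cell in zip(col_labels, cells):
            if cell not in ("0", "1"):
                raise WebFormatError(
                    f"{path}:{i}: non-binary cell {cell!r} (expected 0 or 1)"
                )
            if cell == "1":
                consumer, resource = label_c, label
                if transpose:
                    consumer, resource = resource, consumer
                links.add((consumer, resource))
    for t in (row_labels if not transpose else col_labels):
        taxa.setdefault(t)
    for t in (col_labels if not transpose else row_labels):
        taxa.setdefault(t)
    if not links:
        raise WebFormatError(f"{path}: no links found")
    return FoodWeb(web_id=web_id, taxa=tuple(taxa), links=frozenset(links))


def read_metadata(path: str | Path) -> list[WebMetadata]:
    """Read the per-web covariate table.

    CSV columns: web_id, latitude, longitude, temperature_C, ecosystem.
    Rows with an empty temperature cell are kept with
    ``temperature_C=None`` and counted in a log message.
    """
    path = Path(path)
    records: list[WebMetadata] = []
    n_missing = 0
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"web_id", "latitude", "longitude", "temperature_C", "ecosystem"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise WebFormatError(
                f"{path}: header must contain {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            raw_t = (row["temperature_C"] or "").strip()
            if raw_t == "" or raw_t.upper() in ("NA", "NAN"):
                temp: float | None = None
                n_missing += 1
            else:
                temp = float(raw_t)
                if math.isnan(temp):
                    temp = None
                    n_missing += 1
            records.append(
                WebMetadata(
                    web_id=row["web_id"].strip(),
                    latitude=float(row["latitude"]),
                    longitude=float(row["longitude"]),
                    temperature_C=temp,
                    ecosystem=row["ecosystem"].strip().lower(),
                )
            )
    if n_missing:
        logger.info("%s: %d record(s) with missing temperature", path, n_missing)
    return records


def write_metadata(records: Iterable[WebMetadata], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["web_id", "latitude", "longitude", "temperature_C", "ecosystem"])
        for m in records:
            writer.writerow(
                [
                    m.web_id,
                    f"{m.latitude:.6g}",
                    f"{m.longitude:.6g}",
                    "" if m.temperature_C is None else f"{m.temperature_C:.6g}",
                    m.ecosystem,
                ]
            )


def filter_webs(
    webs: Sequence[FoodWeb], min_species: int = 25, min_links: int = 50
) -> list[FoodWeb]:
    """Apply the study inclusion filter: keep webs with at least
    ``min_species`` taxa and ``min_links`` links (both boundaries
    inclusive).  Order is preserved; the number removed is logged."""
    kept = [
        w for w in webs if w.n_species >= min_species and w.n_links >= min_links
    ]
    removed = len(webs) - len(kept)
    if removed:
        logger.info(
            "inclusion filter (S >= %d, L >= %d) removed %d of %d webs",
            min_species, min_links, removed, len(webs),
        )
    return kept
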