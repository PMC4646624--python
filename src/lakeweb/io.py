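"""Reading and writing the plain-text interchange formats.

Three formats are supported, all delimited text with ``#`` comment lines:

* **link list** — one directed feeding link per line, two id tokens
  (consumer and resource, in either order; the orientation is always given
  explicitly, never guessed);
* **node table** — one row per taxon with columns
  ``id  name  compartment  habitat  phyto_form  ffg``;
* **adjacency matrix** — a square 0/1 matrix with a header row and an id
  column, rows = prey and columns = predators.

Property tables for the meta-analysis (columns ``web_label, class_label,
S, L, D, C``) are handled here too.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .web import FoodWeb, Taxon

__all__ = [
    "AdjacencyFormatError",
    "LinkFileFormatError",
    "ParseWarning",
    "read_adjacency",
    "read_link_list",
    "read_node_table",
    "read_property_table",
    "write_adjacency",
    "write_link_list",
    "write_node_table",
    "write_property_table",
]

NODE_COLUMNS = ["id", "name", "compartment", "habitat", "phyto_form", "ffg"]
PROPERTY_COLUMNS = ["web_label", "class_label", "S", "L", "D", "C"]


class LinkFileFormatError(ValueError):
    """A link-list line did not contain exactly two id tokens."""


class AdjacencyFormatError(ValueError):
    """An adjacency file was non-square or contained entries outside {0, 1}."""


class ParseWarning(UserWarning):
    """Recoverable irregularity while reading (duplicate link, missing metadata)."""


def read_node_table(path: str | Path, delimiter: str = "\t") -> dict[str, Taxon]:
    """Read taxon metadata keyed by id, preserving file order."""
    df = pd.read_csv(path, sep=delimiter, comment="#", dtype=str).fillna("")
    missing = [c for c in NODE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"node table {path} lacks columns {missing}")
    taxa: dict[str, Taxon] = {}
    for _, row in df.iterrows():
        t = Taxon(
            id=row["id"].strip(),
            name=row["name"].strip(),
            compartment=row["compartment"].strip() or "unknown",
            habitat=row["habitat"].strip() or "unknown",
            phyto_form=row["phyto_form"].strip() or "n/a",
            ffg=row["ffg"].strip() or "n/a",
        )
        if t.id in taxa:
            raise ValueError(f"duplicate id {t.id!r} in node table {path}")
        taxa[t.id] = t
    return taxa


def write_node_table(
    web: FoodWeb, path: str | Path, delimiter: str = "\t", header_comments: Iterable[str] = ()
) -> None:
    rows = [
        {
            "id": t.id,
            "name": t.name,
            "compartment": t.compartment,
            "habitat": t.habitat,
            "phyto_form": t.phyto_form,
            "ffg": t.ffg,
        }
        for t in web.taxa
    ]
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=NODE_COLUMNS).to_csv(fh, sep=delimiter, index=False)


def read_link_list(
    path: str | Path,
    orientation: str = "consumer_first",
    node_table: str | Path | Mapping[str, Taxon] | None = None,
    delimiter: str | None = None,
    label: str = "",
) -> FoodWeb:
    """Read a two-token-per-line link file into a FoodWeb.

    ``orientation`` says which token is the consumer: ``consumer_first`` or
    ``resource_first``.  ``delimiter=None`` splits on any whitespace.  Taxa
    appearing in links but absent from the node table are admitted with
    unknown compartment/habitat (with a warning) so structural metrics still
    run.  Duplicate links are deduplicated with a warning; a line with a
    token count other than two raises with its line number.
    """
    if orientation not in ("consumer_first", "resource_first"):
        raise ValueError(f"orientation must be consumer_first or resource_first, got {orientation!r}")
    meta: dict[str, Taxon]
    if node_table is None:
        meta = {}
    elif isinstance(node_table, Mapping):
        meta = dict(node_table)
    else:
        meta = read_node_table(node_table)

    links: set[tuple[str, str]] = set()
    order: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split(delimiter) if delimiter else line.split()
            if len(tokens) != 2:
                raise LinkFileFormatError(
                    f"{path}:{lineno}: expected 2 id tokens, found {len(tokens)}: {line!r}"
                )
            a, b = (tok.strip() for tok in tokens)
            pair = (a, b) if orientation == "consumer_first" else (b, a)
            if pair in links:
                warnings.warn(
                    f"{path}:{lineno}: duplicate link {pair}; deduplicated", ParseWarning
                )
            links.add(pair)
            for tid in pair:
                if tid not in seen:
                    seen.add(tid)
                    order.append(tid)

    taxa = list(meta.values())
    known = set(meta)
    extras = [tid for tid in order if tid not in known]
    if extras and meta:
        warnings.warn(
            f"{path}: {len(extras)} link taxa missing from node table "
            f"(e.g. {extras[:3]}); admitted with unknown metadata",
            ParseWarning,
        )
    taxa.extend(Taxon(id=tid) for tid in extras)
    return FoodWeb(taxa=taxa, links=links, label=label or str(path))


def write_link_list(
    web: FoodWeb,
    path: str | Path,
    orientation: str = "consumer_first",
    delimiter: str = "\t",
    header_comments: Iterable[str] = (),
) -> None:
    if orientation not in ("consumer_first", "resource_first"):
        raise ValueError(f"bad orientation {orientation!r}")
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        for c, r in sorted(web.links):
            pair = (c, r) if orientation == "consumer_first" else (r, c)
            fh.write(f"{pair[0]}{delimiter}{pair[1]}\n")


def write_adjacency(web: FoodWeb, path: str | Path, delimiter: str = "\t") -> None:
    """Write the prey-rows × predator-columns 0/1 matrix with id headers."""
    web.adjacency().to_csv(path, sep=delimiter, index_label="")


def read_adjacency(
    path: str | Path,
    node_table: str | Path | Mapping[str, Taxon] | None = None,
    delimiter: str = "\t",
    label: str = "",
) -> FoodWeb:
    """Read a prey × predator 0/1 matrix back into a FoodWeb.

    Round-trips :func:`write_adjacency` exactly (taxon order and link set).
    """
    df = pd.read_csv(path, sep=delimiter, comment="#", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise AdjacencyFormatError(
            f"{path}: matrix must be square with identical row/column ids "
            f"(got {df.shape[0]} rows x {df.shape[1]} cols)"
        )
    vals = df.to_numpy()
    if not ((vals == 0) | (vals == 1)).all():
        bad = sorted({v for v in vals.ravel() if v not in (0, 1)})
        raise AdjacencyFormatError(f"{path}: entries outside {{0,1}}: {bad[:5]}")

    if node_table is None:
        meta: dict[str, Taxon] = {}
    elif isinstance(node_table, Mapping):
        meta = dict(node_table)
    else:
        meta = read_node_table(node_table)
    taxa = [meta.get(tid, Taxon(id=tid)) for tid in df.index]
    links = {
        (pred, prey)
        for prey in df.index
        for pred in df.columns
        if df.at[prey, pred] == 1
    }
    return FoodWeb(taxa=taxa, links=links, label=label or str(path))


def read_property_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a cross-study web property table (web_label, class_label, S, L, D, C)."""
    df = pd.read_csv(path, sep=delimiter, comment="#")
    missing = [c for c in PROPERTY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"property table {path} lacks columns {missing}")
    df = df[PROPERTY_COLUMNS].copy()
    if df[["S", "L", "D", "C"]].isna().any().any():
        raise ValueError(f"property table {path} has missing values in S/L/D/C")
    return df


def write_property_table(
    df: pd.DataFrame, path: str | Path, delimiter: str = "\t", header_comments: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df[PROPERTY_COLUMNS].to_csv(fh, sep=delimiter, index=False)
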