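"""Food-web data model: taxa, binary directed link structure, validation, sub-webs.

A food web here is a *topological* (binary) web: a set of taxa and a set of
directed consumer→resource links, with no abundance or interaction-strength
information.  Taxa carry the annotations the lake analysis needs — a trophic
compartment (lower-trophic resource, phytoplankton, zooplankton,
macroinvertebrate, amphibian, fish), a habitat tag (pelagic / benthic / both)
used to extract pelagic sub-webs, a phytoplankton growth form (unicellular vs
colonial/filamentous, which decides edibility to zooplankton), and a
macroinvertebrate functional feeding group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

__all__ = [
    "COMPARTMENTS",
    "COMPARTMENT_LADDER",
    "EmptyWebError",
    "FoodWeb",
    "Taxon",
    "ValidationReport",
    "fishless",
    "induced_subweb",
    "pelagic",
    "validate_web",
]

#: Recognised trophic compartments, in ladder order (basal resources first).
COMPARTMENTS = (
    "lower_trophic",
    "phytoplankton",
    "zooplankton",
    "macroinvertebrate",
    "amphibian",
    "fish",
)

#: Six-step trophic ladder used by the compartment-based omnivory and
#: trophic-level-count conventions.
COMPARTMENT_LADDER = {c: i + 1 for i, c in enumerate(COMPARTMENTS)}

HABITATS = ("pelagic", "benthic", "both", "unknown")
PHYTO_FORMS = ("unicellular", "colonial_filamentous", "n/a")
FFGS = ("collector", "filterer", "shredder", "predator", "scraper", "n/a")


class EmptyWebError(ValueError):
    """A sub-web extraction kept zero taxa."""


@dataclass(frozen=True)
class Taxon:
    """A node of the web with its compartment/habitat/form annotations.

    ``compartment`` may be ``"unknown"`` for taxa read from a link list with
    no metadata; purely structural metrics still run on such webs, while
    compartment-dependent ones report "not computable".
    """

    id: str
    name: str = ""
    compartment: str = "unknown"
    habitat: str = "unknown"
    phyto_form: str = "n/a"
    ffg: str = "n/a"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS + ("unknown",):
            raise ValueError(f"unknown compartment {self.compartment!r} for taxon {self.id!r}")
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r} for taxon {self.id!r}")
        if self.phyto_form not in PHYTO_FORMS:
            raise ValueError(f"unknown phyto_form {self.phyto_form!r} for taxon {self.id!r}")
        if self.ffg not in FFGS:
            raise ValueError(f"unknown ffg {self.ffg!r} for taxon {self.id!r}")
        if self.phyto_form != "n/a" and self.compartment != "phytoplankton":
            raise ValueError(f"phyto_form set on non-phytoplankton taxon {self.id!r}")
        if self.ffg != "n/a" and self.compartment != "macroinvertebrate":
            raise ValueError(f"ffg set on non-macroinvertebrate taxon {self.id!r}")
        if self.compartment == "phytoplankton" and self.phyto_form == "n/a":
            # Unannotated phytoplankton default to the edible form; most lake
            # phytoplankton are treated as unicellular unless flagged otherwise.
            object.__setattr__(self, "phyto_form", "unicellular")


@dataclass
class FoodWeb:
    """An ordered taxon list plus a binary directed link set.

    Links are ordered pairs ``(consumer_id, resource_id)``; self-links
    (cannibalism) are permitted.  Taxon order is significant only for matrix
    IO and display.
    """

    taxa: list[Taxon]
    links: set[tuple[str, str]]
    label: str = ""

    def __post_init__(self) -> None:
        self.taxa = list(self.taxa)
        self.links = set(tuple(l) for l in self.links)
        ids = [t.id for t in self.taxa]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate taxon ids: {dupes}")
        known = set(ids)
        dangling = {i for pair in self.links for i in pair} - known
        if dangling:
            raise ValueError(f"links reference unknown taxa: {sorted(dangling)}")

    # -- basic views ---------------------------------------------------

    @property
    def S(self) -> int:
        return len(self.taxa)

    @property
    def L(self) -> int:
        return len(self.links)

    @property
    def ids(self) -> list[str]:
        return [t.id for t in self.taxa]

    def taxon(self, tid: str) -> Taxon:
        for t in self.taxa:
            if t.id == tid:
                return t
        raise KeyError(tid)

    def prey_of(self, tid: str, include_self: bool = True) -> set[str]:
        """Resources consumed by ``tid`` (outgoing links)."""
        out = {r for c, r in self.links if c == tid}
        if not include_self:
            out.discard(tid)
        return out

    def predators_of(self, tid: str, include_self: bool = True) -> set[str]:
        """Consumers of ``tid`` (incoming links)."""
        out = {c for c, r in self.links if r == tid}
        if not include_self:
            out.discard(tid)
        return out

    def basal_ids(self) -> set[str]:
        """Taxa with no resources (self-links ignored): the web's energy base."""
        return {t.id for t in self.taxa if not self.prey_of(t.id, include_self=False)}

    # -- matrix view ---------------------------------------------------

    def adjacency(self):
        """0/1 matrix with rows = prey and columns = predators.

        Entry ``(r, p)`` is 1 iff predator ``p`` eats prey ``r`` — the
        predators-as-columns convention used throughout the lake analysis.
        """
        import numpy as np
        import pandas as pd

        ids = self.ids
        idx = {tid: k for k, tid in enumerate(ids)}
        mat = np.zeros((len(ids), len(ids)), dtype=int)
        for c, r in self.links:
            mat[idx[r], idx[c]] = 1
        return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class ValidationReport:
    """Outcome of structural validation: hard errors plus advisory warnings."""

    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.errors


def validate_web(web: FoodWeb) -> ValidationReport:
    """Check structural soundness of a web; problems are reported, not raised.

    Errors: a lower-trophic (pure resource) taxon that consumes something.
    Warnings: taxa with no links at all (isolated), no basal taxon anywhere
    (every trophic-level computation will fail), unannotated taxa.
    Duplicate ids and dangling link endpoints are already rejected by the
    FoodWeb constructor, so a constructed web cannot carry them.
    """
    rep = ValidationReport()
    for t in web.taxa:
        if t.compartment == "lower_trophic" and web.prey_of(t.id):
            rep.errors.append(
                ("resource-consumes", f"lower_trophic taxon {t.id!r} has outgoing consumer links")
            )
    linked = {i for pair in web.links for i in pair}
    for t in web.taxa:
        if t.id not in linked:
            rep.warnings.append(("isolated", f"taxon {t.id!r} has no links"))
    if not web.basal_ids() and web.S > 0:
        rep.warnings.append(("no-basal", "web has no basal taxon; trophic levels are undefined"))
    untagged = [t.id for t in web.taxa if t.compartment == "unknown"]
    if untagged:
        rep.warnings.append(
            ("untagged", f"{len(untagged)} taxa lack compartment tags: {sorted(untagged)[:5]}...")
        )
    return rep


def induced_subweb(web: FoodWeb, keep: Callable[[Taxon], bool], label: str = "") -> FoodWeb:
    """Sub-web induced by the taxa satisfying ``keep``.

    Links survive iff both endpoints survive, so S and L never increase.
    """
    taxa = [t for t in web.taxa if keep(t)]
    if not taxa:
        raise EmptyWebError("predicate keeps no taxa")
    kept = {t.id for t in taxa}
    links = {(c, r) for c, r in web.links if c in kept and r in kept}
    return FoodWeb(taxa=taxa, links=links, label=label or web.label)


def fishless(web: FoodWeb) -> FoodWeb:
    """Drop all fish: the fishless variant used to compare lakes with and without fish."""
    return induced_subweb(web, lambda t: t.compartment != "fish", label=f"{web.label} (fishless)")


def pelagic(web: FoodWeb) -> FoodWeb:
    """Keep open-water taxa (habitat pelagic or both): the pelagic sub-web."""
    return induced_subweb(
        web, lambda t: t.habitat in ("pelagic", "both"), label=f"{web.label} (pelagic)"
    )
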