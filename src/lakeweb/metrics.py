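"""The 23 structural food-web properties, plus trophic-level count.

Conventions the literature leaves open are made explicit in
:class:`Conventions` and default to the choices that are arithmetically
consistent with published alpine-lake tables:

* ``averaging_set`` — MeanSWTL and MeanShortChn average over consumers only
  (``"consumers"``, default) or over all taxa (``"all"``).  Consumers-only is
  the only choice compatible with published pelagic values for webs that are
  three-quarters basal.
* ``chain_units`` — MeanShortChn on the trophic-level scale (basal = 1, so an
  obligate herbivore scores 2; ``"levels"``, default) or as a raw link count
  (herbivore = 1; ``"links"``).
* ``sd_form`` — population (divide-by-S, default) or sample standard
  deviations for GenSD/VulSD.
* ``omnivory_basis`` — prey trophic levels for omnivory/herbivory and the
  trophic-level count come from the six-compartment ladder
  (lower-trophic resources = 1 … fish = 6; ``"compartment"``, default) or
  from computed shortest trophic levels (``"computed_tl"``).

Self-links (cannibalism) count toward L, Can and the similarity sets, but are
excluded from top/intermediate/basal classification and from prey sets in
every trophic-level computation — a cannibal cannot raise its own level, and
the prey-averaged linear system stays nonsingular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from .web import COMPARTMENT_LADDER, COMPARTMENTS, FoodWeb

__all__ = [
    "Conventions",
    "MetricsReport",
    "NotComputableError",
    "TrophicLevelError",
    "TrophicLevels",
    "basic_counts",
    "compartment_fractions",
    "compute_all",
    "connectance_properties",
    "diet_classes",
    "generality_vulnerability",
    "mean_short_chain",
    "mean_swtl",
    "role_fractions",
    "trophic_level_count",
    "trophic_levels",
    "trophic_similarity",
]


class TrophicLevelError(ValueError):
    """Trophic levels are undefined (no basal taxon, or consumers cut off from one)."""


class NotComputableError(ValueError):
    """A compartment-dependent metric was asked of a web with untagged taxa."""


@dataclass(frozen=True)
class Conventions:
    averaging_set: str = "consumers"   # "consumers" | "all"
    chain_units: str = "levels"        # "levels" | "links"
    sd_form: str = "population"        # "population" | "sample"
    omnivory_basis: str = "compartment"  # "compartment" | "computed_tl"

    def __post_init__(self) -> None:
        checks = {
            "averaging_set": ("consumers", "all"),
            "chain_units": ("levels", "links"),
            "sd_form": ("population", "sample"),
            "omnivory_basis": ("compartment", "computed_tl"),
        }
        for name, allowed in checks.items():
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {getattr(self, name)!r}")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# counts and fractions


def connectance_properties(S: int, L: int) -> dict[str, float]:
    """Linkage density D = L/S, potential links Lp = S^2, connectance C = L/S^2.

    Pure count arithmetic; usable directly on published (S, L) pairs.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    return {"D": L / S, "Lp": S * S, "C": L / (S * S)}


def basic_counts(web: FoodWeb) -> tuple[int, int, float, int, float]:
    """(S, L, D, Lp, C) for a web; self-links count toward L."""
    if web.S < 1:
        raise ValueError("empty web")
    d = connectance_properties(web.S, web.L)
    return web.S, web.L, d["D"], d["Lp"], d["C"]


def role_fractions(web: FoodWeb) -> tuple[float, float, float, float]:
    """(T, I, B, Can): top / intermediate / basal fractions and cannibal fraction.

    Self-links are ignored when classifying T/I/B: a taxon whose only predator
    is itself is still top, and a pure cannibal counts as basal.
    """
    if web.S < 1:
        raise ValueError("empty web")
    top = inter = basal = can = 0
    for t in web.taxa:
        prey = web.prey_of(t.id, include_self=False)
        preds = web.predators_of(t.id, include_self=False)
        if (t.id, t.id) in web.links:
            can += 1
        if not prey:
            basal += 1
        elif preds:
            inter += 1
        else:
            top += 1
    S = web.S
    return top / S, inter / S, basal / S, can / S


def compartment_fractions(web: FoodWeb) -> dict[str, float]:
    """Per-compartment richness fractions {Sl, Sp, Sz, Sm, Sa, Sf}; sum to 1."""
    if any(t.compartment == "unknown" for t in web.taxa):
        untagged = [t.id for t in web.taxa if t.compartment == "unknown"]
        raise NotComputableError(f"taxa lack compartment tags: {sorted(untagged)[:5]}")
    codes = dict(zip(COMPARTMENTS, ["Sl", "Sp", "Sz", "Sm", "Sa", "Sf"]))
    counts = {code: 0 for code in codes.values()}
    for t in web.taxa:
        counts[codes[t.compartment]] += 1
    return {code: n / web.S for code, n in counts.items()}


# ---------------------------------------------------------------------------
# trophic levels


@dataclass
class TrophicLevels:
    """Per-taxon trophic levels on the basal-=-1 scale.

    ``shortest_tl`` is 1 + the minimum number of links down to a basal taxon;
    ``prey_averaged_tl`` solves TL_i = 1 + mean(TL of i's prey); ``swtl`` is
    the arithmetic mean of the two (the short-weighted trophic level).
    """

    shortest_tl: dict[str, float]
    prey_averaged_tl: dict[str, float]

    @property
    def swtl(self) -> dict[str, float]:
        return {
            k: (self.shortest_tl[k] + self.prey_averaged_tl[k]) / 2 for k in self.shortest_tl
        }


def trophic_levels(web: FoodWeb) -> TrophicLevels:
    """Compute shortest, prey-averaged and short-weighted trophic levels.

    Shortest levels come from a multi-source breadth-first search upward from
    the basal set; prey-averaged levels from the linear system
    ``TL_i = 1 + (1/n_i) * sum(TL_j for j in prey(i))`` with basal TL = 1.
    Self-links are excluded from prey sets.  Raises
    :class:`TrophicLevelError` if there is no basal taxon or some consumer has
    no directed path down to one (e.g. members of an isolated cycle).
    """
    basal = web.basal_ids()
    if not basal:
        raise TrophicLevelError("trophic levels undefined: web has no basal taxon")

    # distance from each taxon *down* to the basal set: BFS on reversed links
    G = nx.DiGraph()
    G.add_nodes_from(web.ids)
    G.add_edges_from((r, c) for c, r in web.links if c != r)  # resource -> consumer
    source = object()  # virtual super-source feeding every basal taxon
    G.add_edges_from((source, b) for b in basal)
    dist = {t: d - 1 for t, d in nx.single_source_shortest_path_length(G, source).items()}
    dist.pop(source, None)
    unreachable = [tid for tid in web.ids if tid not in dist]
    if unreachable:
        raise TrophicLevelError(
            f"taxa with no path to a basal resource: {sorted(unreachable)}"
        )
    shortest = {tid: 1.0 + dist[tid] for tid in web.ids}

    ids = web.ids
    idx = {tid: k for k, tid in enumerate(ids)}
    A = np.eye(len(ids))
    b = np.ones(len(ids))
    for tid in ids:
        prey = web.prey_of(tid, include_self=False)
        if prey:
            w = 1.0 / len(prey)
            for p in prey:
                A[idx[tid], idx[p]] -= w
    tl = np.linalg.solve(A, b)
    prey_avg = {tid: float(tl[idx[tid]]) for tid in ids}
    return TrophicLevels(shortest_tl=shortest, prey_averaged_tl=prey_avg)


def _averaging_ids(web: FoodWeb, conv: Conventions) -> list[str]:
    if conv.averaging_set == "all":
        return web.ids
    basal = web.basal_ids()
    return [tid for tid in web.ids if tid not in basal]


def mean_swtl(levels: TrophicLevels, web: FoodWeb, conv: Conventions = Conventions()) -> float | None:
    """Mean short-weighted trophic level (consumers-only by default)."""
    ids = _averaging_ids(web, conv)
    if not ids:
        return None
    swtl = levels.swtl
    return float(np.mean([swtl[i] for i in ids]))


def mean_short_chain(
    levels: TrophicLevels, web: FoodWeb, conv: Conventions = Conventions()
) -> float | None:
    """Mean shortest chain to a basal taxon (level scale by default)."""
    ids = _averaging_ids(web, conv)
    if not ids:
        return None
    offset = 1.0 if conv.chain_units == "links" else 0.0
    return float(np.mean([levels.shortest_tl[i] - offset for i in ids]))


# ---------------------------------------------------------------------------
# diet classes


def _prey_levels(web: FoodWeb, levels: TrophicLevels | None, conv: Conventions) -> dict[str, float]:
    if conv.omnivory_basis == "compartment":
        untagged = [t.id for t in web.taxa if t.compartment == "unknown"]
        if untagged:
            raise NotComputableError(
                f"compartment basis needs full tags; untagged: {sorted(untagged)[:5]}"
            )
        return {t.id: COMPARTMENT_LADDER[t.compartment] for t in web.taxa}
    if levels is None:
        levels = trophic_levels(web)
    return {tid: round(levels.shortest_tl[tid]) for tid in web.ids}


def diet_classes(
    web: FoodWeb,
    levels: TrophicLevels | None = None,
    conv: Conventions = Conventions(),
) -> tuple[float, float]:
    """(Herb, Omn) as fractions of all S taxa.

    A herbivore consumes only basal taxa; an omnivore consumes prey from at
    least two distinct trophic levels (levels per ``conv.omnivory_basis``).
    Self-links are excluded from prey sets.
    """
    level_of = _prey_levels(web, levels, conv)
    basal = web.basal_ids()
    herb = omn = 0
    for t in web.taxa:
        prey = web.prey_of(t.id, include_self=False)
        if not prey:
            continue
        if prey <= basal:
            herb += 1
        if len({level_of[p] for p in prey}) >= 2:
            omn += 1
    return herb / web.S, omn / web.S


def trophic_level_count(
    web: FoodWeb,
    levels: TrophicLevels | None = None,
    conv: Conventions = Conventions(),
) -> int:
    """Number of trophic levels in the web.

    Compartment basis (default): distinct rungs of the six-step ladder with at
    least one taxon present.  Computed basis: ceiling of the maximum shortest
    trophic level.
    """
    if conv.omnivory_basis == "compartment":
        untagged = [t.id for t in web.taxa if t.compartment == "unknown"]
        if untagged:
            raise NotComputableError(
                f"compartment basis needs full tags; untagged: {sorted(untagged)[:5]}"
            )
        return len({COMPARTMENT_LADDER[t.compartment] for t in web.taxa})
    if levels is None:
        levels = trophic_levels(web)
    return math.ceil(max(levels.shortest_tl.values()))


# ---------------------------------------------------------------------------
# degree heterogeneity and trophic similarity


def generality_vulnerability(
    web: FoodWeb, conv: Conventions = Conventions()
) -> tuple[float, float]:
    """(GenSD, VulSD): SDs of normalized prey and predator counts.

    Per-taxon generality ``g_i = (S/L) * |prey(i)|`` and vulnerability
    ``v_i = (S/L) * |predators(i)|`` are computed over all S taxa (zeros
    included), so both means equal 1 by construction; their standard
    deviations summarise diet- and predator-load heterogeneity.
    """
    if web.L < 1:
        raise ValueError("GenSD/VulSD undefined for a web with no links")
    scale = web.S / web.L
    g = np.array([len(web.prey_of(t.id)) for t in web.taxa], dtype=float) * scale
    v = np.array([len(web.predators_of(t.id)) for t in web.taxa], dtype=float) * scale
    ddof = 0 if conv.sd_form == "population" else 1
    return float(np.std(g, ddof=ddof)), float(np.std(v, ddof=ddof))


def trophic_similarity(web: FoodWeb) -> tuple[float, float, np.ndarray]:
    """Mean and maximum Jaccardian trophic similarity, plus the pairwise matrix.

    For an unordered pair (i, j), similarity is the number of shared predators
    plus shared prey over the number of distinct predators and prey of either
    taxon; it is 1 when the two taxa play identical trophic roles and 0 when
    they share neither predators nor prey (pairs where both taxa are fully
    isolated score 0 by convention).  A self-link makes a taxon its own
    predator and prey.
    """
    if web.S < 2:
        raise ValueError("trophic similarity needs at least 2 taxa")
    ids = web.ids
    idx = {tid: k for k, tid in enumerate(ids)}
    S = web.S
    prey = np.zeros((S, S), dtype=bool)   # prey[i, j]: i eats j
    for c, r in web.links:
        prey[idx[c], idx[r]] = True
    pred = prey.T

    def _counts(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        shared = (M.astype(int) @ M.astype(int).T).astype(float)
        sizes = M.sum(axis=1).astype(float)
        union = sizes[:, None] + sizes[None, :] - shared
        return shared, union

    sh_prey, un_prey = _counts(prey)
    sh_pred, un_pred = _counts(pred)
    num = sh_prey + sh_pred
    den = un_prey + un_pred
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    iu = np.triu_indices(S, k=1)
    pairs = sim[iu]
    return float(pairs.mean()), float(pairs.max()), sim


# ---------------------------------------------------------------------------
# assembled report


_REPORT_CODES = [
    "S", "Sl", "Sp", "Sz", "Sm", "Sa", "Sf", "L", "D", "Lp", "C",
    "T", "I", "B", "Omn", "Herb", "Can",
    "MeanSWTL", "MeanShortChn", "GenSD", "VulSD", "Sim", "MaxSim", "nTL",
]

#: Printed precision for each metric in a formatted report.
_REPORT_PRECISION = {
    "S": 0, "L": 0, "Lp": 0, "nTL": 0, "D": 1,
    "Sl": 2, "Sp": 2, "Sz": 2, "Sm": 2, "Sa": 2, "Sf": 2, "C": 2,
    "T": 2, "I": 2, "B": 2, "Omn": 2, "Herb": 2, "Can": 2,
    "MeanSWTL": 2, "MeanShortChn": 2, "GenSD": 2, "VulSD": 2, "Sim": 2, "MaxSim": 2,
}


@dataclass
class MetricsReport:
    """All structural properties of one web, with reasons for any missing ones."""

    values: dict[str, float | int | None]
    missing: dict[str, str] = field(default_factory=dict)
    label: str = ""
    conventions: Conventions = field(default_factory=Conventions)

    def __getitem__(self, code: str):
        return self.values[code]

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "conventions": self.conventions.to_dict(),
            "values": self.values,
            "missing": self.missing,
        }

    def formatted(self) -> dict[str, str]:
        """Values rendered at the precision published tables use."""
        out = {}
        for code in _REPORT_CODES:
            v = self.values.get(code)
            if v is None:
                out[code] = "NA"
            else:
                nd = _REPORT_PRECISION[code]
                out[code] = f"{v:.0f}" if nd == 0 else f"{round(float(v), nd):.{nd}f}"
        return out

    def to_table(self) -> str:
        lines = ["metric\tvalue"]
        fmt = self.formatted()
        lines += [f"{code}\t{fmt[code]}" for code in _REPORT_CODES]
        return "\n".join(lines) + "\n"


def compute_all(web: FoodWeb, conv: Conventions = Conventions()) -> MetricsReport:
    """Assemble every structural property into one report.

    Metrics whose preconditions fail (untagged compartments, no basal taxon,
    no links, fewer than 2 taxa) are reported as missing with the reason
    rather than aborting the rest of the report.
    """
    values: dict[str, float | int | None] = {c: None for c in _REPORT_CODES}
    missing: dict[str, str] = {}

    S, L, D, Lp, C = basic_counts(web)
    values.update(S=S, L=L, D=D, Lp=Lp, C=C)
    T, I, B, Can = role_fractions(web)
    values.update(T=T, I=I, B=B, Can=Can)

    try:
        values.update(compartment_fractions(web))
    except NotComputableError as e:
        for code in ("Sl", "Sp", "Sz", "Sm", "Sa", "Sf"):
            missing[code] = str(e)

    levels = None
    try:
        levels = trophic_levels(web)
        values["MeanSWTL"] = mean_swtl(levels, web, conv)
        values["MeanShortChn"] = mean_short_chain(levels, web, conv)
        if values["MeanSWTL"] is None:
            missing["MeanSWTL"] = missing["MeanShortChn"] = "web has no consumers"
    except TrophicLevelError as e:
        missing["MeanSWTL"] = missing["MeanShortChn"] = str(e)

    try:
        herb, omn = diet_classes(web, levels, conv)
        values.update(Herb=herb, Omn=omn)
    except (NotComputableError, TrophicLevelError) as e:
        missing["Herb"] = missing["Omn"] = str(e)
    try:
        values["nTL"] = trophic_level_count(web, levels, conv)
    except (NotComputableError, TrophicLevelError) as e:
        missing["nTL"] = str(e)

    try:
        gsd, vsd = generality_vulnerability(web, conv)
        values.update(GenSD=gsd, VulSD=vsd)
    except ValueError as e:
        missing["GenSD"] = missing["VulSD"] = str(e)
    try:
        sim, maxsim, _ = trophic_similarity(web)
        values.update(Sim=sim, MaxSim=maxsim)
    except ValueError as e:
        missing["Sim"] = missing["MaxSim"] = str(e)

    return MetricsReport(values=values, missing=missing, label=web.label, conventions=conv)
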