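"""Synthetic food-web generators.

Three generators:

* :func:`generate_lake_web` — a compartmented alpine-lake web assembled from
  qualitative diet rules: zooplankton graze only unicellular phytoplankton
  (colonial/filamentous forms are too large), macroinvertebrate diets follow
  their functional feeding group (collectors and filterers take fine
  detritus, shredders coarse organic material, scrapers periphyton and
  unicellular phytoplankton, predators other macroinvertebrates), amphibians
  take macroinvertebrates, and fish feed across zooplankton,
  macroinvertebrates and amphibians.  Each candidate link is retained
  independently with probability ``p_link``.
* :func:`generate_niche_web` — the one-dimensional niche model: taxa get a
  uniform niche value and a contiguous feeding range whose beta-distributed
  width is calibrated so expected connectance equals ``C_target``.
* :func:`generate_random_web` — every ordered pair (self-links included) is a
  link independently with probability ``C_target``.

All generators are seeded and reproducible; :func:`fixture_suite` returns a
set of tiny hand-verified webs with frozen expected metric values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .web import FoodWeb, Taxon

__all__ = [
    "GenerationError",
    "LakeConfig",
    "NicheConfig",
    "fixture_suite",
    "generate_lake_web",
    "generate_niche_web",
    "generate_random_web",
]


class GenerationError(ValueError):
    """A consumer compartment has no eligible resources under the config."""


#: Names of the aggregated basal resource groups, in the order they are created.
LOWER_TROPHIC_NAMES = (
    "coarse_organic_material",
    "fine_detritus",
    "macrophytes",
    "water_moss",
    "periphyton",
)

DEFAULT_FFG_MIX = {
    "collector": 0.33,
    "filterer": 0.07,
    "shredder": 0.17,
    "predator": 0.23,
    "scraper": 0.20,
}


@dataclass(frozen=True)
class LakeConfig:
    """Compartment sizes and link-rule parameters for a synthetic lake web.

    Defaults emulate a complete alpine-lake web: five aggregated basal
    resources, a phytoplankton community with roughly a third
    colonial/filamentous forms, a small zooplankton community (a fraction of
    which also preys on other zooplankton), a macroinvertebrate community
    dominated by collectors and predators, a few amphibians, and a single
    salmonid top predator.  ``p_link = 0.6`` keeps linkage density and
    connectance in the range observed for lake webs of this size (D ~ 5-8,
    C ~ 0.06-0.09).
    """

    n_lower: int = 5
    n_phyto: int = 20
    fraction_colonial: float = 0.35
    n_zoo: int = 6
    fraction_predatory_zoo: float = 0.25
    n_macro: int = 30
    ffg_mix: dict = field(default_factory=lambda: dict(DEFAULT_FFG_MIX))
    n_amphib: int = 3
    n_fish: int = 1
    p_link: float = 0.6
    allow_cannibalism: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_lower, self.n_phyto, self.n_zoo, self.n_macro, self.n_amphib, self.n_fish)
        if any(n < 0 for n in counts):
            raise ValueError("compartment counts must be >= 0")
        if self.n_lower < 1:
            raise ValueError("need at least one basal resource node")
        if not (0 < self.p_link <= 1):
            raise ValueError("p_link must be in (0, 1]")
        for name in ("fraction_colonial", "fraction_predatory_zoo"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ffg_mix and not math.isclose(sum(self.ffg_mix.values()), 1.0, abs_tol=1e-9):
            raise ValueError("ffg_mix proportions must sum to 1")


@dataclass(frozen=True)
class NicheConfig:
    S: int = 50
    C_target: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError("S must be >= 2")
        if not (0 < self.C_target < 0.5):
            raise ValueError("C_target must be in (0, 0.5)")


def _counts_from_mix(n: int, mix: dict[str, float], rng: np.random.Generator) -> dict[str, int]:
    """Split n individuals across categories by largest-remainder apportionment."""
    cats = sorted(mix)
    raw = {c: n * mix[c] for c in cats}
    counts = {c: int(math.floor(raw[c])) for c in cats}
    rem = n - sum(counts.values())
    order = sorted(cats, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:rem]:
        counts[c] += 1
    return counts


def generate_lake_web(config: LakeConfig) -> FoodWeb:
    """Assemble a compartmented lake web from the diet rules (seeded).

    Every consumer is guaranteed at least one resource: if independent
    ``p_link`` sampling left its diet empty, one eligible link is forced.  A
    consumer compartment with an empty eligible set (e.g. zooplankton when
    all phytoplankton are colonial) raises :class:`GenerationError` naming
    the starving group.
    """
    rng = np.random.default_rng(config.seed)
    taxa: list[Taxon] = []

    for i in range(config.n_lower):
        name = LOWER_TROPHIC_NAMES[i] if i < len(LOWER_TROPHIC_NAMES) else f"basal_resource_{i+1}"
        taxa.append(Taxon(id=f"lt_{name}", name=name, compartment="lower_trophic", habitat="benthic"))

    n_colonial = int(round(config.fraction_colonial * config.n_phyto))
    forms = ["colonial_filamentous"] * n_colonial + ["unicellular"] * (config.n_phyto - n_colonial)
    rng.shuffle(forms)
    for i, form in enumerate(forms):
        taxa.append(
            Taxon(id=f"ph_{i+1:02d}", compartment="phytoplankton", habitat="pelagic", phyto_form=form)
        )

    n_pred_zoo = int(round(config.fraction_predatory_zoo * config.n_zoo))
    for i in range(config.n_zoo):
        taxa.append(Taxon(id=f"zo_{i+1:02d}", compartment="zooplankton", habitat="pelagic"))
    predatory_zoo = [f"zo_{i+1:02d}" for i in range(n_pred_zoo)]

    ffg_counts = _counts_from_mix(config.n_macro, config.ffg_mix, rng) if config.n_macro else {}
    k = 0
    for ffg in sorted(ffg_counts):
        for _ in range(ffg_counts[ffg]):
            k += 1
            taxa.append(
                Taxon(id=f"mi_{k:02d}", compartment="macroinvertebrate", habitat="benthic", ffg=ffg)
            )

    for i in range(config.n_amphib):
        taxa.append(Taxon(id=f"am_{i+1:02d}", compartment="amphibian", habitat="benthic"))
    for i in range(config.n_fish):
        taxa.append(Taxon(id=f"fi_{i+1:02d}", compartment="fish", habitat="both"))

    by_comp: dict[str, list[Taxon]] = {}
    for t in taxa:
        by_comp.setdefault(t.compartment, []).append(t)
    lower_by_name = {t.name: t.id for t in by_comp.get("lower_trophic", [])}
    uni_phyto = [t.id for t in by_comp.get("phytoplankton", []) if t.phyto_form == "unicellular"]
    zoo_ids = [t.id for t in by_comp.get("zooplankton", [])]
    macro_ids = [t.id for t in by_comp.get("macroinvertebrate", [])]
    amph_ids = [t.id for t in by_comp.get("amphibian", [])]
    fish_ids = [t.id for t in by_comp.get("fish", [])]

    def lower(name: str, who: str) -> list[str]:
        if name in lower_by_name:
            return [lower_by_name[name]]
        raise GenerationError(f"{who} need {name!r} but the basal set lacks it")

    candidates: dict[str, list[str]] = {}
    for zid in zoo_ids:
        elig = list(uni_phyto)
        if zid in predatory_zoo:
            elig += [z for z in zoo_ids if z != zid]
        if not elig:
            raise GenerationError("zooplankton have no eligible resources (no unicellular phytoplankton)")
        candidates[zid] = elig
    for t in by_comp.get("macroinvertebrate", []):
        if t.ffg in ("collector", "filterer"):
            elig = lower("fine_detritus", f"{t.ffg}s")
        elif t.ffg == "shredder":
            elig = lower("coarse_organic_material", "shredders")
        elif t.ffg == "scraper":
            elig = lower("periphyton", "scrapers") + uni_phyto
        else:  # predator
            elig = [m for m in macro_ids if m != t.id]
            if config.allow_cannibalism:
                elig = elig + [t.id]
            if not elig:
                raise GenerationError("predatory macroinvertebrates have no eligible resources")
        candidates[t.id] = elig
    for aid in amph_ids:
        if not macro_ids:
            raise GenerationError("amphibians have no eligible resources (no macroinvertebrates)")
        candidates[aid] = list(macro_ids)
    for fid in fish_ids:
        elig = zoo_ids + macro_ids + amph_ids
        if config.allow_cannibalism:
            elig = elig + [f for f in fish_ids]
        if not elig:
            raise GenerationError("fish have no eligible resources")
        candidates[fid] = elig

    links: set[tuple[str, str]] = set()
    for cid in sorted(candidates):
        elig = candidates[cid]
        keep = rng.random(len(elig)) < config.p_link
        chosen = [r for r, k_ in zip(elig, keep) if k_]
        if not chosen:  # forced minimum diet: no consumer may end up basal
            chosen = [elig[rng.integers(len(elig))]]
        links.update((cid, r) for r in chosen)

    return FoodWeb(taxa=taxa, links=links, label=f"synthetic_lake(seed={config.seed})")


def generate_niche_web(config: NicheConfig, max_retries: int = 100) -> FoodWeb:
    """One-dimensional niche-model web (seeded), retried until a basal taxon exists.

    Each taxon i gets a niche value n_i ~ U(0,1) and feeding-range width
    r_i = n_i * x_i with x_i ~ Beta(1, 1/(2C) - 1), so expected connectance is
    C_target; the range centre is uniform on [r_i/2, n_i] and i eats every
    taxon whose niche value falls inside the range.
    """
    beta = 1.0 / (2.0 * config.C_target) - 1.0
    rng = np.random.default_rng(config.seed)
    for _ in range(max_retries):
        n = rng.uniform(size=config.S)
        r = n * rng.beta(1.0, beta, size=config.S)
        c = rng.uniform(r / 2.0, n)
        lo, hi = c - r / 2.0, c + r / 2.0
        eats = (n[None, :] >= lo[:, None]) & (n[None, :] <= hi[:, None])
        ids = [f"t{k:03d}" for k in range(config.S)]
        links = {(ids[i], ids[j]) for i, j in zip(*np.nonzero(eats))}
        web = FoodWeb(
            taxa=[Taxon(id=i) for i in ids], links=links,
            label=f"niche(S={config.S},C={config.C_target},seed={config.seed})",
        )
        if web.basal_ids():
            return web
    raise GenerationError(f"no basal taxon after {max_retries} retries")


def generate_random_web(config: NicheConfig) -> FoodWeb:
    """Unstructured baseline: each of the S^2 ordered pairs is a link w.p. C_target."""
    rng = np.random.default_rng(config.seed)
    ids = [f"t{k:03d}" for k in range(config.S)]
    mat = rng.random((config.S, config.S)) < config.C_target
    links = {(ids[i], ids[j]) for i, j in zip(*np.nonzero(mat))}
    return FoodWeb(
        taxa=[Taxon(id=i) for i in ids], links=links,
        label=f"random(S={config.S},C={config.C_target},seed={config.seed})",
    )


# ---------------------------------------------------------------------------
# hand-verified fixtures


@dataclass(frozen=True)
class Fixture:
    web: FoodWeb
    expected: dict


def _chain3() -> Fixture:
    taxa = [
        Taxon(id="detritus", compartment="lower_trophic", habitat="benthic"),
        Taxon(id="collector", compartment="macroinvertebrate", habitat="benthic", ffg="collector"),
        Taxon(id="trout", compartment="fish", habitat="both"),
    ]
    links = {("collector", "detritus"), ("trout", "collector")}
    expected = {
        "S": 3, "L": 2, "D": 2 / 3, "Lp": 9, "C": 2 / 9,
        "T": 1 / 3, "I": 1 / 3, "B": 1 / 3, "Can": 0.0,
        "Herb": 1 / 3, "Omn": 0.0,
        "MeanSWTL": 2.5, "MeanShortChn": 2.5,  # consumers-only, level scale
        "GenSD": math.sqrt(0.5), "VulSD": math.sqrt(0.5),
        "Sim": 0.0, "MaxSim": 0.0, "nTL": 3,
        "shortest_tl": {"detritus": 1.0, "collector": 2.0, "trout": 3.0},
        "prey_averaged_tl": {"detritus": 1.0, "collector": 2.0, "trout": 3.0},
    }
    return Fixture(FoodWeb(taxa, links, label="chain3"), expected)


def _cycle3_basal() -> Fixture:
    # A eats B, B eats C, C eats A and the basal resource R.
    taxa = [Taxon(id=i) for i in ("R", "A", "B", "C")]
    links = {("A", "B"), ("B", "C"), ("C", "A"), ("C", "R")}
    # prey-averaged: TL_C = 1 + (TL_A + 1)/2, TL_B = 1 + TL_C, TL_A = 1 + TL_B
    # => TL_A = 7, TL_B = 6, TL_C = 5
    expected = {
        "S": 4, "L": 4, "T": 0.0, "I": 3 / 4, "B": 1 / 4,
        "shortest_tl": {"R": 1.0, "C": 2.0, "B": 3.0, "A": 4.0},
        "prey_averaged_tl": {"R": 1.0, "C": 5.0, "B": 6.0, "A": 7.0},
    }
    return Fixture(FoodWeb(taxa, links, label="cycle3_basal"), expected)


def _star() -> Fixture:
    taxa = [Taxon(id=i) for i in ("hub", "b1", "b2", "b3", "b4")]
    links = {("hub", b) for b in ("b1", "b2", "b3", "b4")}
    # g = (5/4)*(4,0,0,0,0): popSD = 2.0; v = (5/4)*(0,1,1,1,1): popSD = 0.5
    expected = {"S": 5, "L": 4, "GenSD": 2.0, "VulSD": 0.5, "T": 0.2, "B": 0.8, "I": 0.0}
    return Fixture(FoodWeb(taxa, links, label="star"), expected)


def _twins() -> Fixture:
    # c1 and c2 share identical predator and prey sets -> similarity 1.
    taxa = [Taxon(id=i) for i in ("b1", "b2", "c1", "c2", "top")]
    links = {("c1", "b1"), ("c1", "b2"), ("c2", "b1"), ("c2", "b2"), ("top", "c1"), ("top", "c2")}
    expected = {"S": 5, "L": 6, "MaxSim": 1.0}
    return Fixture(FoodWeb(taxa, links, label="twins"), expected)


def _minilake() -> Fixture:
    """Six-compartment miniature lake (S = 20), diets written out by hand.

    11 of the 20 taxa consume prey from at least two rungs of the compartment
    ladder (3 zooplankton, 2 collectors, 2 scrapers, 2 predatory
    macroinvertebrates, 1 amphibian, the fish), so Omn = 0.55; the colonial
    phytoplankter has no consumers, mirroring the inedibility rule.
    """
    lt = lambda n: Taxon(id=n, name=n, compartment="lower_trophic", habitat="benthic")
    taxa = [
        lt("coarse_organic_material"), lt("fine_detritus"), lt("periphyton"),
        Taxon(id="p_uni1", compartment="phytoplankton", habitat="pelagic", phyto_form="unicellular"),
        Taxon(id="p_uni2", compartment="phytoplankton", habitat="pelagic", phyto_form="unicellular"),
        Taxon(id="p_uni3", compartment="phytoplankton", habitat="pelagic", phyto_form="unicellular"),
        Taxon(id="p_col1", compartment="phytoplankton", habitat="pelagic",
              phyto_form="colonial_filamentous"),
        Taxon(id="z1", compartment="zooplankton", habitat="pelagic"),
        Taxon(id="z2", compartment="zooplankton", habitat="pelagic"),
        Taxon(id="z3", compartment="zooplankton", habitat="pelagic"),
        Taxon(id="m_coll1", compartment="macroinvertebrate", habitat="benthic", ffg="collector"),
        Taxon(id="m_coll2", compartment="macroinvertebrate", habitat="benthic", ffg="collector"),
        Taxon(id="m_shred", compartment="macroinvertebrate", habitat="benthic", ffg="shredder"),
        Taxon(id="m_scrap1", compartment="macroinvertebrate", habitat="benthic", ffg="scraper"),
        Taxon(id="m_scrap2", compartment="macroinvertebrate", habitat="benthic", ffg="scraper"),
        Taxon(id="m_pred1", compartment="macroinvertebrate", habitat="benthic", ffg="predator"),
        Taxon(id="m_pred2", compartment="macroinvertebrate", habitat="benthic", ffg="predator"),
        Taxon(id="amp1", compartment="amphibian", habitat="benthic"),
        Taxon(id="amp2", compartment="amphibian", habitat="benthic"),
        Taxon(id="f1", compartment="fish", habitat="both"),
    ]
    links = {
        ("z1", "p_uni1"), ("z1", "fine_detritus"),
        ("z2", "p_uni2"), ("z2", "fine_detritus"),
        ("z3", "p_uni1"), ("z3", "p_uni3"), ("z3", "fine_detritus"),
        ("m_coll1", "fine_detritus"), ("m_coll1", "p_uni1"),
        ("m_coll2", "fine_detritus"), ("m_coll2", "p_uni3"),
        ("m_shred", "coarse_organic_material"),
        ("m_scrap1", "periphyton"), ("m_scrap1", "p_uni2"),
        ("m_scrap2", "periphyton"), ("m_scrap2", "p_uni2"),
        ("m_pred1", "m_coll1"), ("m_pred1", "z1"),
        ("m_pred2", "m_shred"), ("m_pred2", "z2"),
        ("amp1", "m_coll1"), ("amp1", "z1"),
        ("amp2", "m_shred"),
        ("f1", "z1"), ("f1", "z2"), ("f1", "z3"),
        ("f1", "m_pred1"), ("f1", "m_pred2"), ("f1", "m_coll1"), ("f1", "amp1"),
    }
    expected = {
        "S": 20, "L": 30,
        "Sl": 3 / 20, "Sp": 4 / 20, "Sz": 3 / 20, "Sm": 7 / 20, "Sa": 2 / 20, "Sf": 1 / 20,
        "Omn": 11 / 20,
        # herbivores = consumers whose every resource is basal: the three
        # zooplankters, both collectors, the shredder and both scrapers
        "Herb": 8 / 20,
        "nTL": 6, "nTL_fishless": 5, "MaxSim": 1.0, "Can": 0.0,
    }
    return Fixture(FoodWeb(taxa, links, label="minilake"), expected)


def _no_basal() -> Fixture:
    taxa = [Taxon(id=i) for i in ("A", "B", "C")]
    links = {("A", "B"), ("B", "C"), ("C", "A")}
    expected = {"S": 3, "L": 3, "GenSD": 0.0, "VulSD": 0.0, "no_basal": True}
    return Fixture(FoodWeb(taxa, links, label="no_basal_cycle"), expected)


def fixture_suite() -> dict[str, Fixture]:
    """Named tiny webs with hand-verified expected metric values."""
    return {
        "chain3": _chain3(),
        "cycle3_basal": _cycle3_basal(),
        "star": _star(),
        "twins": _twins(),
        "minilake": _minilake(),
        "no_basal": _no_basal(),
    }
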