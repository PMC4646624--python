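"""Published census counts for the three Gredos alpine lakes.

Taxonomic richness S and link count L for each published web variant
(pelagic sub-web, fishless variant where fish are present, complete web).
These two counts are primary observations; every derived count property
(linkage density D = L/S, potential links Lp = S^2, connectance C = L/S^2)
is recomputed from them via :func:`lakeweb.metrics.connectance_properties`,
never stored.
"""

from __future__ import annotations

__all__ = ["LAKE_CENSUS"]

#: (S, L) per (lake, variant).
LAKE_CENSUS: dict[tuple[str, str], tuple[int, int]] = {
    ("caballeros", "pelagic"): (21, 70),
    ("caballeros", "complete"): (64, 344),
    ("cimera", "pelagic"): (17, 45),
    ("cimera", "fishless"): (84, 580),
    ("cimera", "complete"): (85, 645),
    ("grande_de_gredos", "pelagic"): (43, 101),
    ("grande_de_gredos", "fishless"): (95, 498),
    ("grande_de_gredos", "complete"): (96, 534),
}
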