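"""Published summary values from the year-long two-bioreactor survey.

The study that motivates this package monitored a full-scale and a lab-scale
activated-sludge bioreactor monthly for one year and published, for each
reactor, the per-sample taxon richness at every taxonomic rank and the
per-phylum taxa-time power-law exponents. Those printed values are inputs
here: the test suite and the acceptance script recompute the published
summary statistics (means, standard deviations, dominant/rare group means)
from them with this package's own statistics code.

Only internally consistent rows are carried: the published OTU-level rows do
not reproduce their own printed averages from the printed per-sample values
and are therefore excluded from checks.
"""

from __future__ import annotations

# Per-sample richness (12 monthly samples) by rank and reactor, with the
# published mean and standard deviation (population convention).
RICHNESS_PER_SAMPLE: dict[tuple[str, str], list[int]] = {
    ("phylum", "full"): [12, 13, 13, 16, 16, 14, 16, 15, 14, 14, 15, 14],
    ("phylum", "lab"): [12, 13, 14, 15, 16, 14, 16, 15, 16, 14, 15, 14],
    ("order", "full"): [51, 53, 52, 64, 65, 61, 57, 57, 56, 50, 51, 51],
    ("order", "lab"): [49, 60, 62, 58, 66, 64, 64, 53, 57, 53, 47, 51],
    ("genus", "full"): [219, 274, 231, 278, 281, 256, 249, 237, 215, 201, 229, 205],
    ("genus", "lab"): [208, 242, 251, 267, 278, 245, 231, 205, 261, 237, 197, 223],
}

PUBLISHED_RICHNESS_SUMMARY: dict[tuple[str, str], tuple[float, float]] = {
    ("phylum", "full"): (14.3, 1.2),
    ("phylum", "lab"): (14.5, 1.2),
    ("order", "full"): (55.7, 5.1),
    ("order", "lab"): (57.0, 6.1),
    ("genus", "full"): (239.6, 26.8),
    ("genus", "lab"): (237.1, 24.4),
}

# Per-phylum TTR power-law exponents w, by reactor, with the published mean
# relative abundance (%) of each phylum.
PHYLUM_TTR: dict[str, dict[str, tuple[float, float]]] = {
    # phylum: reactor -> (mean relative abundance %, w)
    "Proteobacteria": {"full": (25.8, 0.33), "lab": (43.1, 0.34)},
    "Bacteroidetes": {"full": (41.0, 0.32), "lab": (27.1, 0.35)},
    "Acidobacteria": {"full": (11.7, 0.37), "lab": (4.6, 0.36)},
    "Chloroflexi": {"full": (1.9, 0.38), "lab": (9.0, 0.37)},
    "Verrucomicrobia": {"full": (5.6, 0.37), "lab": (8.5, 0.38)},
    "Planctomycetes": {"full": (1.8, 0.42), "lab": (1.1, 0.48)},
    "Firmicutes": {"full": (2.5, 0.42), "lab": (3.7, 0.46)},
    "Actinobacteria": {"full": (0.3, 0.41), "lab": (0.6, 0.47)},
    "Chlamydiae": {"full": (0.6, 0.46), "lab": (0.3, 0.52)},
    "Spirochaetes": {"full": (0.6, 0.46), "lab": (0.4, 0.54)},
    "Synergistetes": {"full": (0.1, 0.49), "lab": (0.1, 0.54)},
    "Fusobacteria": {"full": (0.1, 0.47), "lab": (0.1, 0.55)},
    "TM7": {"full": (0.1, 0.52), "lab": (0.1, 0.57)},
    "Euryarchaeota": {"full": (0.1, 0.53), "lab": (0.0, 0.55)},
    "OP10": {"full": (0.2, 0.51), "lab": (0.1, 0.56)},
}

# The five dominant and five rarest phyla as named in the published contrast.
# (Note: the named dominant set includes Chloroflexi although Firmicutes has
# a slightly higher printed full-scale mean abundance; the published group
# means are reproduced from the named sets.)
DOMINANT_PHYLA = (
    "Proteobacteria",
    "Bacteroidetes",
    "Acidobacteria",
    "Chloroflexi",
    "Verrucomicrobia",
)
RARE_PHYLA = ("Synergistetes", "Fusobacteria", "TM7", "Euryarchaeota", "OP10")

PUBLISHED_GROUP_MEAN_W = {
    ("dominant", "full"): 0.35,
    ("dominant", "lab"): 0.36,
    ("rare", "full"): 0.50,
    ("rare", "lab"): 0.55,
}
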