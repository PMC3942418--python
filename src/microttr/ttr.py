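"""Taxa-time relationship (TTR): accumulation curves and power-law fits.

The TTR models the growth of observed richness S with the length T of the
observation window as the power law S = c * T**w; the exponent w measures
temporal turnover (w = 0: a static community; w = 1: complete replacement
every time step). The fit is ordinary least squares of log10 S on log10 T,
mirroring the standard log-log regression used throughout the species-time
literature.

Two window schemes are offered. The default "sliding" scheme averages the
distinct-taxon count over every contiguous window of each length T, the usual
construction in macroecology; "nested" accumulates from the first sample only
and is provided for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .community_io import CommunityTable, TaxonomyMap, ValidationError

SCHEMES = ("sliding", "nested")


@dataclass
class AccumulationCurve:
    window_lengths: list[int]
    richness: list[float]
    scheme: str


@dataclass
class TTRFit:
    """Power-law fit S = c * T**w on log-log axes.

    ``w`` is the slope (turnover exponent), ``c = 10**intercept``,
    ``r_squared`` the coefficient of determination of the log-log regression.
    """

    w: float
    c: float
    r_squared: float
    curve: AccumulationCurve


@dataclass
class GroupTTRReport:
    per_group: dict[str, TTRFit]
    mean_relative_abundance: dict[str, float]
    dominant_groups: list[str]
    rare_groups: list[str]
    dominant_mean_w: float
    rare_mean_w: float
    k: int


def accumulation_curve(
    table: CommunityTable, scheme: str = "sliding"
) -> AccumulationCurve:
    """Richness S(T) versus window length T = 1..n_samples.

    sliding: S(T) is the mean, over all n-T+1 contiguous windows of length T,
    of the number of distinct taxa observed anywhere in the window.
    nested: S(T) is the distinct-taxon count of the first T samples.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"scheme must be one of {SCHEMES}")
    n = table.n_samples
    if n < 2:
        raise ValidationError("accumulation curve needs at least 2 samples")
    times = np.asarray(table.sample_times)
    if n > 1 and not np.all(np.diff(times) == 1):
        raise ValidationError("sample months must be consecutive")
    present = table.presence()
    richness: list[float] = []
    for T in range(1, n + 1):
        if scheme == "nested":
            richness.append(float(present[:T].any(axis=0).sum()))
        else:
            vals = [
                present[start : start + T].any(axis=0).sum()
                for start in range(n - T + 1)
            ]
            richness.append(float(np.mean(vals)))
    return AccumulationCurve(
        window_lengths=list(range(1, n + 1)), richness=richness, scheme=scheme
    )


def fit_power_law(curve: AccumulationCurve) -> TTRFit:
    """OLS of log10 S on log10 T; see :class:`TTRFit`.

    A perfectly constant curve has zero slope and zero residual variance; by
    convention it is reported as w = 0, r_squared = 0 with a warning rather
    than an error.
    """
    S = np.asarray(curve.richness, dtype=float)
    T = np.asarray(curve.window_lengths, dtype=float)
    if len(S) < 3:
        raise ValidationError("power-law fit needs at least 3 points")
    if np.any(S <= 0):
        raise ValidationError("all richness values must be positive for a log-log fit")
    logS = np.log10(S)
    logT = np.log10(T)
    if np.allclose(logS, logS[0]):
        warnings.warn(
            "constant accumulation curve: reporting w=0, r_squared=0 by convention",
            stacklevel=2,
        )
        return TTRFit(w=0.0, c=float(S[0]), r_squared=0.0, curve=curve)
    res = stats.linregress(logT, logS)
    return TTRFit(
        w=float(res.slope),
        c=float(10.0 ** res.intercept),
        r_squared=float(res.rvalue**2),
        curve=curve,
    )


def group_mean_relative_abundance(
    table: CommunityTable, taxonomy: TaxonomyMap, rank: str
) -> dict[str, float]:
    """Mean over samples of each rank group's relative abundance."""
    rel = table.relative_abundance()
    names = [taxonomy.name_at(t, rank) for t in table.taxon_ids]
    out: dict[str, float] = {}
    for name in dict.fromkeys(names):
        cols = [j for j, nm in enumerate(names) if nm == name]
        out[name] = float(rel[:, cols].sum(axis=1).mean())
    return out


def per_group_ttr(
    table: CommunityTable,
    taxonomy: TaxonomyMap,
    rank: str = "phylum",
    k: int = 5,
    scheme: str = "sliding",
) -> GroupTTRReport:
    """TTR exponents per taxonomic group, with dominant/rare contrasts.

    Each group keeps its member taxa at full (OTU) resolution, so within-group
    turnover drives the exponent. Groups present in fewer than 2 samples are
    not scored. ``dominant_mean_w`` / ``rare_mean_w`` average the w of the k
    groups with the highest / lowest mean relative abundance; the two sets
    must be disjoint.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    abundance = group_mean_relative_abundance(table, taxonomy, rank)
    names = [taxonomy.name_at(t, rank) for t in table.taxon_ids]
    fits: dict[str, TTRFit] = {}
    for name in dict.fromkeys(names):
        taxa = [t for t, nm in zip(table.taxon_ids, names) if nm == name]
        sub = table.select_taxa(taxa)
        n_samples_present = int((sub.counts.sum(axis=1) > 0).sum())
        if n_samples_present < 2:
            continue
        curve = accumulation_curve(sub, scheme=scheme)
        if any(s <= 0 for s in curve.richness):
            continue
        fits[name] = fit_power_law(curve)
    if len(fits) < 2:
        raise ValidationError("need at least 2 scorable groups")
    if 2 * k > len(fits):
        raise ValidationError(
            f"k={k} would overlap dominant and rare sets over {len(fits)} groups"
        )
    ranked = sorted(fits, key=lambda g: abundance[g], reverse=True)
    dominant = ranked[:k]
    rare = ranked[-k:]
    return GroupTTRReport(
        per_group=fits,
        mean_relative_abundance={g: abundance[g] for g in fits},
        dominant_groups=dominant,
        rare_groups=rare,
        dominant_mean_w=float(np.mean([fits[g].w for g in dominant])),
        rare_mean_w=float(np.mean([fits[g].w for g in rare])),
        k=k,
    )
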