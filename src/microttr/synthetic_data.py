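"""Seeded generator of synthetic community time series and covariates.

Emulates the statistical structure of a year of monthly 16S surveys from
activated-sludge bioreactors: ~15 phyla with geometrically decaying pool
mass (a handful of dominant phyla carrying most reads), thousands of OTUs
with lognormal abundance spread, month-to-month presence following a
two-state Markov chain (persistent core taxa in dominant phyla, transient
taxa in rare phyla), a seasonal temperature covariate that shifts the
log-abundance of a responsive taxon subset, and multinomial read sampling at
a fixed depth per month.

The generator is the ground truth for the property tests: persistence
controls temporal turnover (the TTR exponent w), the dominant/rare
persistence contrast produces lower w for dominant phyla, and env_coupling
controls whether forward selection can recover the seasonal covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_io import CommunityTable, TaxonomyMap, ValidationError
from .ordination import CovariateTable


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic community generator.

    Defaults mirror the two-bioreactor monitoring design: 12 monthly samples
    normalized to 13422 reads, 15 phyla (the 4 most abundant carrying most of
    the read mass), 200 OTUs per phylum, strong lognormal abundance skew, high
    persistence for dominant-phylum taxa and low persistence for rare-phylum
    taxa, and a seasonal temperature spanning 16.3-25.1 degrees C.

    The default chains are memoryless (persistence equals colonization, so a
    taxon's monthly occupancy is that common probability and months are
    exchangeable when env_coupling is 0); raising persistence above
    colonization adds month-to-month memory at the same occupancy
    col / (col + 1 - pers).
    """

    n_months: int = 12
    depth: int = 13422
    n_phyla: int = 15
    taxa_per_phylum: int = 200
    n_dominant_phyla: int = 4
    pool_abundance_decay: float = 0.8
    persistence_dominant: float = 0.89
    persistence_rare: float = 0.27
    colonization_dominant: float = 0.89
    colonization_rare: float = 0.27
    abundance_sigma: float = 1.5
    env_coupling: float = 1.0
    responsive_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.persistence_dominant,
            self.persistence_rare,
            self.colonization_dominant,
            self.colonization_rare,
            self.pool_abundance_decay,
            self.responsive_fraction,
        )
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.n_months < 2:
            raise ValidationError("n_months must be >= 2")
        if self.n_phyla < 1 or self.taxa_per_phylum < 1:
            raise ValidationError("n_phyla and taxa_per_phylum must be >= 1")
        if self.env_coupling < 0:
            raise ValidationError("env_coupling must be >= 0")
        if self.n_dominant_phyla > self.n_phyla:
            raise ValidationError("n_dominant_phyla exceeds n_phyla")


def _phylum_masses(config: SimulationConfig) -> np.ndarray:
    m = config.pool_abundance_decay ** np.arange(config.n_phyla)
    return m / m.sum()


def _build_taxonomy(config: SimulationConfig) -> tuple[list[str], np.ndarray, TaxonomyMap]:
    """Taxon ids, phylum index per taxon, and a nested synthetic lineage."""
    taxon_ids: list[str] = []
    phylum_of: list[int] = []
    entries: dict[str, dict[str, str]] = {}
    idx = 0
    for p in range(config.n_phyla):
        phylum = f"Phylum{p + 1:02d}"
        for i in range(config.taxa_per_phylum):
            tid = f"OTU{idx:05d}"
            taxon_ids.append(tid)
            phylum_of.append(p)
            entries[tid] = {
                "phylum": phylum,
                "class": f"{phylum}.c{i // 64 + 1}",
                "order": f"{phylum}.o{i // 16 + 1}",
                "family": f"{phylum}.f{i // 4 + 1}",
                "genus": f"{phylum}.g{i // 2 + 1}",
            }
            idx += 1
    return taxon_ids, np.asarray(phylum_of), TaxonomyMap(entries=entries)


def _seasonal_temperature(n_months: int) -> np.ndarray:
    """Sinusoid spanning 16.3-25.1 degrees C with a 12-month period."""
    mid, amp = (25.1 + 16.3) / 2.0, (25.1 - 16.3) / 2.0
    t = np.arange(n_months)
    return mid + amp * np.sin(2.0 * np.pi * (t - 2.0) / 12.0)


def _presence_chains(
    rng: np.random.Generator,
    persist: np.ndarray,
    colonize: np.ndarray,
    n_months: int,
) -> np.ndarray:
    """(n_months, n_taxa) boolean presence via per-taxon two-state Markov chains."""
    n_taxa = persist.shape[0]
    z = np.empty((n_months, n_taxa), dtype=bool)
    stationary = colonize / np.clip(colonize + 1.0 - persist, 1e-12, None)
    z[0] = rng.random(n_taxa) < stationary
    for t in range(1, n_months):
        u = rng.random(n_taxa)
        z[t] = np.where(z[t - 1], u < persist, u < colonize)
    return z


def _draw_counts(
    rng: np.random.Generator,
    weights: np.ndarray,
    presence: np.ndarray,
    responsive: np.ndarray,
    temp_std: np.ndarray,
    env_coupling: float,
    depth: int,
) -> np.ndarray:
    n_months = presence.shape[0]
    counts = np.empty((n_months, weights.shape[0]), dtype=np.int64)
    for t in range(n_months):
        w = weights * presence[t]
        if env_coupling > 0:
            w = w * np.exp(env_coupling * temp_std[t] * responsive)
        if w.sum() == 0:  # degenerate month: keep the heaviest taxon alive
            w = np.zeros_like(weights)
            w[int(np.argmax(weights))] = 1.0
        counts[t] = rng.multinomial(depth, w / w.sum())
    return counts


def _reactor_covariates(
    rng: np.random.Generator,
    temperature: np.ndarray,
    bod: np.ndarray,
    tn: np.ndarray,
    sample_ids: list[str],
) -> CovariateTable:
    n = temperature.shape[0]
    data = pd.DataFrame(
        {
            "BOD": bod,
            "TN": tn,
            "temperature": temperature,
            "DO": np.clip(rng.normal(3.5, 0.5, n), 0.1, None),
            "SRT": np.clip(rng.normal(8.7, 2.1, n), 0.5, None),
        },
        index=sample_ids,
    )
    groups = {"BOD": "W", "TN": "W", "temperature": "O", "DO": "O", "SRT": "O"}
    return CovariateTable(sample_ids=sample_ids, data=data, groups=groups)


def _simulate_reactor(
    config: SimulationConfig,
    rng: np.random.Generator,
    taxon_ids: list[str],
    weights: np.ndarray,
    persist: np.ndarray,
    colonize: np.ndarray,
    responsive: np.ndarray,
    temp_std: np.ndarray,
    prefix: str,
) -> CommunityTable:
    presence = _presence_chains(rng, persist, colonize, config.n_months)
    counts = _draw_counts(
        rng, weights, presence, responsive, temp_std, config.env_coupling, config.depth
    )
    return CommunityTable(
        sample_ids=[f"{prefix}{m:02d}" for m in range(1, config.n_months + 1)],
        sample_times=list(range(1, config.n_months + 1)),
        taxon_ids=list(taxon_ids),
        counts=counts,
    )


def _shared_structure(config: SimulationConfig, rng: np.random.Generator):
    taxon_ids, phylum_of, taxonomy = _build_taxonomy(config)
    masses = _phylum_masses(config)
    weights = (
        masses[phylum_of]
        / config.taxa_per_phylum
        * rng.lognormal(0.0, config.abundance_sigma, len(taxon_ids))
    )
    dominant = phylum_of < config.n_dominant_phyla
    persist = np.where(
        dominant, config.persistence_dominant, config.persistence_rare
    )
    colonize = np.where(
        dominant, config.colonization_dominant, config.colonization_rare
    )
    responsive = rng.random(len(taxon_ids)) < config.responsive_fraction
    temperature = _seasonal_temperature(config.n_months)
    temp_std = (temperature - temperature.mean()) / temperature.std()
    return taxon_ids, taxonomy, weights, persist, colonize, responsive, temperature, temp_std


def simulate_community(
    config: SimulationConfig,
) -> tuple[CommunityTable, TaxonomyMap, CovariateTable]:
    """One reactor's community time series, taxonomy, and covariates.

    Identical config (including seed) reproduces identical outputs bit for
    bit. Covariates carry wastewater (W: BOD, TN) and operational
    (O: temperature, DO, SRT) variables; the scale indicator only varies
    between reactors and is added by :func:`make_two_reactor_pair`.
    """
    rng = np.random.default_rng(config.seed)
    (taxon_ids, taxonomy, weights, persist, colonize, responsive,
     temperature, temp_std) = _shared_structure(config, rng)
    table = _simulate_reactor(
        config, rng, taxon_ids, weights, persist, colonize, responsive, temp_std, "S"
    )
    bod = rng.uniform(150.0, 288.0, config.n_months)
    tn = rng.uniform(35.9, 69.3, config.n_months)
    cov = _reactor_covariates(rng, temperature, bod, tn, table.sample_ids)
    return table, taxonomy, cov


def make_two_reactor_pair(
    config: SimulationConfig, turnover_delta: float = 0.1
) -> tuple[dict[str, tuple[CommunityTable, CovariateTable]], TaxonomyMap]:
    """Full-scale / lab-scale reactor pair sharing taxa and wastewater.

    Reactor "full" uses the config persistence; reactor "lab" lowers both
    persistence probabilities by ``turnover_delta`` (more turnover, larger
    fitted w). Wastewater covariates (group W) and the seasonal temperature
    are shared; DO and SRT are drawn per reactor; the scale indicator
    (group S) is 0 for full and 1 for lab.
    """
    if turnover_delta < 0:
        raise ValidationError("turnover_delta must be >= 0")
    if (
        config.persistence_dominant - turnover_delta < 0
        or config.persistence_rare - turnover_delta < 0
    ):
        raise ValidationError("turnover_delta drives persistence below 0")
    rng = np.random.default_rng(config.seed)
    (taxon_ids, taxonomy, weights, persist, colonize, responsive,
     temperature, temp_std) = _shared_structure(config, rng)
    bod = rng.uniform(150.0, 288.0, config.n_months)
    tn = rng.uniform(35.9, 69.3, config.n_months)
    out: dict[str, tuple[CommunityTable, CovariateTable]] = {}
    for name, prefix, delta, scale in (
        ("full", "F", 0.0, 0.0),
        ("lab", "L", turnover_delta, 1.0),
    ):
        table = _simulate_reactor(
            config,
            rng,
            taxon_ids,
            weights,
            persist - delta,
            colonize,
            responsive,
            temp_std,
            prefix,
        )
        cov = _reactor_covariates(rng, temperature, bod, tn, table.sample_ids)
        cov.data["scale"] = scale
        cov.groups["scale"] = "S"
        cov = CovariateTable(
            sample_ids=table.sample_ids, data=cov.data, groups=cov.groups
        )
        out[name] = (table, cov)
    return out, taxonomy


def stack_reactors(
    pair: dict[str, tuple[CommunityTable, CovariateTable]],
) -> tuple[CommunityTable, CovariateTable]:
    """Stack the two reactors into one 2n-sample table for CCA/VPA.

    Sample times are renumbered consecutively (they only order the rows here;
    within-reactor time series analyses use the per-reactor tables).
    """
    tables = [pair[k][0] for k in pair]
    covs = [pair[k][1] for k in pair]
    taxa = tables[0].taxon_ids
    for t in tables[1:]:
        if t.taxon_ids != taxa:
            raise ValidationError("reactors must share one taxon universe")
    counts = np.vstack([t.counts for t in tables])
    sample_ids = [sid for t in tables for sid in t.sample_ids]
    table = CommunityTable(
        sample_ids=sample_ids,
        sample_times=list(range(1, len(sample_ids) + 1)),
        taxon_ids=list(taxa),
        counts=counts,
    )
    data = pd.concat([c.data for c in covs], axis=0)
    groups = dict(covs[0].groups)
    cov = CovariateTable(sample_ids=sample_ids, data=data, groups=groups)
    return table, cov
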