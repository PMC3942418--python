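"""Moving-window community change and pairwise similarity matrices.

The moving-window statistic tracks how fast a community fingerprint drifts:
for each consecutive month pair the percent change is 100 * (1 - r), where r
is the Pearson correlation of the two samples' relative-abundance profiles.
The mean and population SD of that change series is the monthly change rate
(delta-t). The Sorensen matrix (presence/absence Dice similarity) is exported
for ordination in external tools.

Pearson similarity is computed on relative abundances over the union of taxa;
negative correlations therefore give change values above 100%, which are
reported unclamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community_io import CommunityTable, ValidationError

METRICS = ("pearson", "sorenson")


@dataclass
class SimilarityMatrix:
    sample_ids: list[str]
    values: np.ndarray
    metric: str


@dataclass
class MovingWindowResult:
    """Consecutive-month change series (percent) with mean +/- population SD."""

    change_values: list[float]
    delta_t_mean: float
    delta_t_sd: float
    sd_convention: str = "population"


def pearson_matrix(table: CommunityTable) -> SimilarityMatrix:
    """Pairwise Pearson correlation of relative-abundance profiles."""
    if table.n_taxa < 2:
        raise ValidationError("pearson similarity needs at least 2 taxa")
    rel = table.relative_abundance()
    sd = rel.std(axis=1)
    for i, s in enumerate(sd):
        if s == 0:
            raise ValidationError(
                f"sample {table.sample_ids[i]!r} has a constant profile "
                "(zero variance); Pearson correlation is undefined"
            )
    values = np.corrcoef(rel)
    values = (values + values.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        sample_ids=list(table.sample_ids), values=values, metric="pearson"
    )


def sorenson_matrix(table: CommunityTable) -> SimilarityMatrix:
    """Pairwise Sorensen-Dice similarity 2|A∩B| / (|A|+|B|) on presence sets."""
    present = table.presence()
    richness = present.sum(axis=1)
    for i, r in enumerate(richness):
        if r == 0:
            raise ValidationError(
                f"sample {table.sample_ids[i]!r} has no taxa present"
            )
    shared = (present.astype(np.int64) @ present.T.astype(np.int64)).astype(float)
    denom = richness[:, None] + richness[None, :]
    values = 2.0 * shared / denom
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        sample_ids=list(table.sample_ids), values=values, metric="sorenson"
    )


def moving_window(table: CommunityTable) -> MovingWindowResult:
    """Percent change between consecutive months and its mean +/- SD."""
    if table.n_samples < 2:
        raise ValidationError("moving-window analysis needs at least 2 samples")
    times = np.asarray(table.sample_times)
    if not np.all(np.diff(times) == 1):
        raise ValidationError("sample months must be consecutive")
    sim = pearson_matrix(table)
    changes = [
        100.0 - 100.0 * sim.values[i, i + 1] for i in range(table.n_samples - 1)
    ]
    return MovingWindowResult(
        change_values=[float(c) for c in changes],
        delta_t_mean=float(np.mean(changes)),
        delta_t_sd=float(np.std(changes)),  # population convention
    )


def write_similarity(path, sim: SimilarityMatrix) -> None:
    """Square tab-separated matrix with header row and column."""
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(sim.sample_ids) + "\n")
        for i, sid in enumerate(sim.sample_ids):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in sim.values[i]) + "\n")
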