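"""Community count tables, taxonomy maps, read QC, rarefaction, richness.

The central object is :class:`CommunityTable`, a samples x taxa matrix of
non-negative integer counts with an ordered, strictly increasing month index
per sample. Everything downstream (TTR fitting, moving-window change, CCA)
consumes this object after library-size normalization (rarefaction).

File formats are plain tab-separated text:

* count table — first row is taxon ids; each following row is
  ``sample_id <TAB> month <TAB> count ...``;
* taxonomy — header ``taxon phylum class order family genus`` (tab-separated),
  one row per taxon, every rank filled (use ``unclassified`` explicitly);
* reads — standard FASTA.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

RANKS = ("phylum", "class", "order", "family", "genus")

UNCLASSIFIED = "unclassified"


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


@dataclass
class CommunityTable:
    """Samples x taxa count matrix with ordered month labels.

    Parameters
    ----------
    sample_ids
        Ordered sample labels, unique.
    sample_times
        Month index per sample (integers, strictly increasing).
    taxon_ids
        Taxon labels, unique.
    counts
        ``(n_samples, n_taxa)`` array of non-negative integers.
    """

    sample_ids: list[str]
    sample_times: list[int]
    taxon_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D samples x taxa matrix")
        n, p = self.counts.shape
        if n < 1:
            raise ValidationError("table must contain at least one sample")
        if len(self.sample_ids) != n or len(self.sample_times) != n:
            raise ValidationError("sample_ids/sample_times length mismatch with counts")
        if len(self.taxon_ids) != p:
            raise ValidationError("taxon_ids length mismatch with counts")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.taxon_ids)) != p:
            raise ValidationError("duplicate taxon ids")
        times = np.asarray(self.sample_times)
        if n > 1 and not np.all(np.diff(times) > 0):
            raise ValidationError("sample_times must be strictly increasing")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64, copy=False)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized counts (proportions per sample)."""
        totals = self.sample_totals().astype(float)
        if np.any(totals == 0):
            bad = self.sample_ids[int(np.argmax(totals == 0))]
            raise ValidationError(f"sample {bad!r} has zero total count")
        return self.counts / totals[:, None]

    def presence(self) -> np.ndarray:
        """Boolean presence/absence matrix (count >= 1)."""
        return self.counts > 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)
        df.insert(0, "month", self.sample_times)
        return df

    def select_taxa(self, taxa: list[str]) -> "CommunityTable":
        idx = [self.taxon_ids.index(t) for t in taxa]
        return CommunityTable(
            sample_ids=list(self.sample_ids),
            sample_times=list(self.sample_times),
            taxon_ids=list(taxa),
            counts=self.counts[:, idx].copy(),
        )


@dataclass
class TaxonomyMap:
    """Taxon id -> lineage at the five ranks phylum..genus.

    Every entry must carry a non-empty name at every rank; unassignable ranks
    use the explicit label ``"unclassified"``.
    """

    entries: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for taxon, lineage in self.entries.items():
            for rank in RANKS:
                name = lineage.get(rank)
                if not name:
                    raise ValidationError(
                        f"taxon {taxon!r} missing a name at rank {rank!r}"
                    )

    def name_at(self, taxon: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}; expected one of {RANKS}")
        try:
            return self.entries[taxon][rank]
        except KeyError:
            raise ValidationError(f"taxon {taxon!r} not present in taxonomy") from None


@dataclass
class RichnessSummary:
    """Per-sample richness at one rank with mean/SD/min/max.

    SD uses the population convention (divisor ``n``).
    """

    rank: str
    per_sample: list[int]
    mean: float
    sd: float
    min: int
    max: int


@dataclass
class ReadSet:
    """Ordered list of (read id, uppercased nucleotide sequence) pairs."""

    records: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def read_fasta(path) -> ReadSet:
    """Read a FASTA file into a :class:`ReadSet`, uppercasing sequences.

    Raises a :class:`ValidationError` naming the offending line when sequence
    data appears before any header, or when read ids repeat.
    """
    with open(path) as fh:
        text = fh.read()
    seen_header = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            seen_header = True
        elif not seen_header:
            raise ValidationError(
                f"malformed FASTA: sequence data before any header at line {lineno}"
            )
    records: list[tuple[str, str]] = []
    ids: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        if rec.id in ids:
            raise ValidationError(f"duplicate read id {rec.id!r}")
        ids.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    return ReadSet(records=records)


def qc_filter(reads: ReadSet, max_ambiguous: int = 1, min_length: int = 150) -> ReadSet:
    """Quality filter: drop reads with more than ``max_ambiguous`` Ns or
    shorter than ``min_length`` bases. Order is preserved; idempotent."""
    if max_ambiguous < 0 or min_length < 0:
        raise ValidationError("qc_filter parameters must be non-negative")
    kept = [
        (rid, seq)
        for rid, seq in reads.records
        if seq.count("N") <= max_ambiguous and len(seq) >= min_length
    ]
    return ReadSet(records=kept)


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Each sample is treated as a multiset of reads and subsampled by a
    multivariate hypergeometric draw, independently per sample, driven by one
    seeded generator so the same seed reproduces the same table bit for bit.
    """
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    totals = table.sample_totals()
    for sid, total in zip(table.sample_ids, totals):
        if total < depth:
            raise ValidationError(
                f"sample {sid!r} has only {total} reads, shallower than depth {depth}"
            )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        out[i] = rng.multivariate_hypergeometric(table.counts[i], depth)
    return CommunityTable(
        sample_ids=list(table.sample_ids),
        sample_times=list(table.sample_times),
        taxon_ids=list(table.taxon_ids),
        counts=out,
    )


def collapse_to_rank(
    table: CommunityTable, taxonomy: TaxonomyMap, rank: str
) -> CommunityTable:
    """Sum counts of all taxa sharing a name at ``rank``.

    The grand total is conserved. Output taxa are the distinct rank names in
    first-appearance order. Unclassified taxa at the rank collapse into the
    single explicit ``"unclassified"`` group.
    """
    names = [taxonomy.name_at(t, rank) for t in table.taxon_ids]
    order: list[str] = []
    index: dict[str, int] = {}
    for name in names:
        if name not in index:
            index[name] = len(order)
            order.append(name)
    out = np.zeros((table.n_samples, len(order)), dtype=np.int64)
    for j, name in enumerate(names):
        out[:, index[name]] += table.counts[:, j]
    return CommunityTable(
        sample_ids=list(table.sample_ids),
        sample_times=list(table.sample_times),
        taxon_ids=order,
        counts=out,
    )


def summarize_richness(
    table: CommunityTable,
    taxonomy: TaxonomyMap | None = None,
    rank: str | None = None,
    include_unclassified: bool = True,
) -> RichnessSummary:
    """Per-sample richness at a taxonomic rank (or at taxon resolution).

    Richness is the number of taxa with count >= 1 per sample after collapsing
    to ``rank``; the ``"unclassified"`` group counts as one taxon unless
    ``include_unclassified`` is False. Mean and SD are computed over samples
    with the population SD convention (divisor ``n``).
    """
    if rank is not None:
        if taxonomy is None:
            raise ValidationError("taxonomy required when collapsing to a rank")
        work = collapse_to_rank(table, taxonomy, rank)
        label = rank
    else:
        work = table
        label = "taxon"
    present = work.presence()
    if not include_unclassified and UNCLASSIFIED in work.taxon_ids:
        present = present[:, [t != UNCLASSIFIED for t in work.taxon_ids]]
    per_sample = present.sum(axis=1)
    return RichnessSummary(
        rank=label,
        per_sample=[int(v) for v in per_sample],
        mean=float(np.mean(per_sample)),
        sd=float(np.std(per_sample)),  # population form, ddof=0
        min=int(per_sample.min()),
        max=int(per_sample.max()),
    )


def write_table(path, table: CommunityTable) -> None:
    """Write a count table in the tab-separated layout read by read_table."""
    with open(path, "w") as fh:
        fh.write("sample\tmonth\t" + "\t".join(table.taxon_ids) + "\n")
        for i, sid in enumerate(table.sample_ids):
            row = "\t".join(str(int(v)) for v in table.counts[i])
            fh.write(f"{sid}\t{table.sample_times[i]}\t{row}\n")


def read_table(path) -> CommunityTable:
    """Read a tab-separated count table (see module docstring for layout)."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 3:
        raise ValidationError("count table needs sample, month and >=1 taxon column")
    taxon_ids = list(df.columns[2:])
    sample_ids = df.iloc[:, 0].tolist()
    try:
        sample_times = [int(v) for v in df.iloc[:, 1]]
        counts = df.iloc[:, 2:].astype(np.int64).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-integer cell in count table: {exc}") from exc
    return CommunityTable(
        sample_ids=sample_ids,
        sample_times=sample_times,
        taxon_ids=taxon_ids,
        counts=counts,
    )


def write_taxonomy(path, taxonomy: TaxonomyMap) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\t" + "\t".join(RANKS) + "\n")
        for taxon, lineage in taxonomy.entries.items():
            fh.write(taxon + "\t" + "\t".join(lineage[r] for r in RANKS) + "\n")


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    expected = ["taxon", *RANKS]
    if list(df.columns) != expected:
        raise ValidationError(
            f"taxonomy header must be {expected}, got {list(df.columns)}"
        )
    if df.isna().any().any():
        raise ValidationError("taxonomy contains missing cells")
    if df["taxon"].duplicated().any():
        dup = df["taxon"][df["taxon"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate taxon id {dup!r} in taxonomy")
    entries = {
        row["taxon"]: {r: row[r] for r in RANKS} for _, row in df.iterrows()
    }
    return TaxonomyMap(entries=entries)
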