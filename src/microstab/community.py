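"""Sample filtering, rarefaction, relative abundance and core microbiota.

Processing order in the pipeline is: discard shallow samples (library
size below a read threshold), rarefy the survivors to a common depth, and
only then compute diversity statistics. The per-participant *core
microbiota* is the set of OTUs that exceed a relative-abundance detection
threshold in at least a prevalence fraction of that participant's weekly
samples; its time series is the input to interaction inference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .data_model import OtuTable, StudyMetadata, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CoreTimeSeries:
    """One participant's weekly core-OTU relative-abundance series.

    Abundances are fractions of the *whole* sample (not renormalized to the
    core) so that gLV state variables are comparable across participants.
    """

    participant_id: str
    weeks: np.ndarray
    abundances: np.ndarray
    core_otu_ids: list[str]
    detection: float
    prevalence: float

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, dtype=int)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.shape != (len(self.weeks), len(self.core_otu_ids)):
            raise ValidationError("core series shape mismatch")
        if len(self.core_otu_ids) < 1:
            raise ValidationError("core must contain at least one OTU")
        if np.any(np.diff(self.weeks) <= 0):
            raise ValidationError("weeks must be strictly increasing")
        if np.any(self.abundances < 0) or np.any(self.abundances > 1):
            raise ValidationError("abundances must lie in [0, 1]")


def filter_low_depth(table: OtuTable, min_reads: int = 5000) -> OtuTable:
    """Drop samples with fewer than ``min_reads`` total reads (strict <).

    OTUs left with zero total count afterwards are dropped too (logged).
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    depths = table.sample_sums()
    keep = depths >= min_reads
    if not keep.any():
        raise ValidationError(
            f"depth filter at {min_reads} reads removed every sample")
    kept_samples = [s for s, k in zip(table.sample_ids, keep) if k]
    sub = table.select_samples(kept_samples)
    totals = sub.counts.sum(axis=0)
    if np.any(totals == 0):
        dropped = [o for o, t in zip(sub.otu_ids, totals) if t == 0]
        logger.info("depth filter: dropping %d empty OTUs: %s",
                    len(dropped), dropped[:10])
        sub = sub.select_otus([o for o, t in zip(sub.otu_ids, totals) if t > 0])
    return sub


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Subsample every sample's reads, without replacement, to ``depth``.

    Uses a multivariate hypergeometric draw per sample (exact subsampling
    without replacement); reproducible for a fixed seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    depths = table.sample_sums()
    shallow = [s for s, d in zip(table.sample_ids, depths) if d < depth]
    if shallow:
        raise ValidationError(
            f"samples shallower than rarefaction depth {depth}: {shallow}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        row = table.counts[i]
        if depths[i] == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(out, list(table.sample_ids), list(table.otu_ids),
                    table.taxonomy)


def relative_abundance(table_or_counts) -> np.ndarray:
    """Row-normalize counts to proportions (each row sums to 1)."""
    counts = (table_or_counts.counts
              if isinstance(table_or_counts, OtuTable) else
              np.asarray(table_or_counts, dtype=float))
    sums = counts.sum(axis=1, dtype=float)
    if np.any(sums == 0):
        raise ValidationError("cannot normalize all-zero sample(s)")
    return counts / sums[:, None]


def core_microbiota(table: OtuTable, metadata: StudyMetadata,
                    participant: str, detection: float = 0.001,
                    prevalence: float = 0.85) -> CoreTimeSeries:
    """Extract one participant's core-OTU time series.

    An OTU is in the core if its relative abundance is >= ``detection``
    in at least ceil(prevalence * T) of the participant's T samples.
    """
    if not 0 < detection < 1:
        raise ValueError("detection must be in (0, 1)")
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must be in (0, 1]")
    rows = metadata.for_participant(participant)
    sample_ids = [s for s in rows["sample_id"] if s in set(table.sample_ids)]
    if len(sample_ids) < 2:
        raise ValidationError(
            f"participant {participant!r} has fewer than 2 samples in table")
    rows = rows[rows["sample_id"].isin(sample_ids)]
    sub = table.select_samples(list(rows["sample_id"]))
    rel = relative_abundance(sub)
    T = rel.shape[0]
    needed = math.ceil(prevalence * T)
    hits = (rel >= detection).sum(axis=0)
    core_mask = hits >= needed
    if not core_mask.any():
        raise ValidationError(
            f"participant {participant!r}: empty core at detection="
            f"{detection}, prevalence={prevalence}; relax the thresholds")
    core_ids = [o for o, m in zip(sub.otu_ids, core_mask) if m]
    return CoreTimeSeries(
        participant_id=participant,
        weeks=rows["week"].to_numpy(),
        abundances=rel[:, core_mask],
        core_otu_ids=core_ids,
        detection=detection,
        prevalence=prevalence,
    )
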