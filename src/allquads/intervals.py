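"""Unique-site merging and per-chromosome summary statistics.

Overlapping PQS records of different topologies describe alternative
structures at one locus; a "unique site" is a maximal connected component
of records under the >=1-shared-base overlap relation (half-open
coordinates: records touching end-to-start share no base and stay
separate).  Merging is a single left-to-right sweep over
coordinate-sorted records, O(N log N) in the number of records.

Two distinct genome-wide quantities come out of the merge: the number of
unique interstrand sites (merge restricted to the nine interstrand
classes) and the number of independent groups of any type (merge over all
ten classes).  Per-chromosome statistics additionally report the raw
intrastrand (AAAA) record count, densities per megabase of assembly
length (gaps included), and the intrastrand/interstrand ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .scanner import PQSRecord
from .topology import INTERSTRAND_CLASS_NAMES, INTRASTRAND_CLASS

__all__ = [
    "SiteGroup",
    "merge_overlapping",
    "chromosome_stats",
    "poisson_z",
    "GENOME_ROW",
]

GENOME_ROW = "genome_wide"


@dataclass
class SiteGroup:
    """A maximal set of mutually/transitively overlapping PQS records."""

    seq_id: str
    start: int
    end: int
    members: list[PQSRecord]
    classes_present: set[str]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _resolve_subset(subset: Union[None, str, Iterable[str]]) -> Optional[set[str]]:
    if subset is None or subset == "all":
        return None
    if subset in ("inter", "interstrand"):
        return set(INTERSTRAND_CLASS_NAMES)
    if subset in ("intra", "intrastrand"):
        return {INTRASTRAND_CLASS}
    if isinstance(subset, str):
        raise ValueError(f"unknown class subset {subset!r}")
    return set(subset)


def merge_overlapping(
    records: Sequence[PQSRecord],
    subset: Union[None, str, Iterable[str]] = None,
) -> list[SiteGroup]:
    """Merge records sharing >=1 base into unique sites (sweep line).

    ``subset`` filters by topology before merging: None/"all", "inter",
    "intra", or an explicit iterable of class names.  Records are sorted
    by (seq_id, start, end); a record joins the open group iff it starts
    strictly before the group's maximum end on the same sequence.
    Output groups are in coordinate order.
    """
    keep = _resolve_subset(subset)
    pool = [r for r in records if keep is None or r.topology in keep]
    pool.sort(key=lambda r: (r.seq_id, r.start, r.end))
    groups: list[SiteGroup] = []
    for r in pool:
        g = groups[-1] if groups else None
        if g is not None and g.seq_id == r.seq_id and r.start < g.end:
            g.members.append(r)
            g.end = max(g.end, r.end)
            g.classes_present.add(r.topology)
        else:
            groups.append(
                SiteGroup(
                    seq_id=r.seq_id,
                    start=r.start,
                    end=r.end,
                    members=[r],
                    classes_present={r.topology},
                )
            )
    return groups


def chromosome_stats(
    records: Sequence[PQSRecord],
    seq_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-sequence and genome-wide counts and densities.

    Rows: one per sequence in ``seq_lengths`` order plus a leading
    ``genome_wide`` row.  Columns: assembly length, unique interstrand
    site count (merged over the nine interstrand classes), intrastrand
    (AAAA) record count, densities per MB, and intra/inter ratio (NaN when
    there are no interstrand sites).  The genome-wide ratio is computed
    from the summed counts.  Raises KeyError if a record names a sequence
    absent from ``seq_lengths``.
    """
    missing = {r.seq_id for r in records} - set(seq_lengths)
    if missing:
        raise KeyError(f"records reference sequences without lengths: {sorted(missing)}")

    inter_groups = merge_overlapping(records, "inter")
    n_inter: dict[str, int] = {sid: 0 for sid in seq_lengths}
    for g in inter_groups:
        n_inter[g.seq_id] += 1
    n_intra: dict[str, int] = {sid: 0 for sid in seq_lengths}
    for r in records:
        if r.topology == INTRASTRAND_CLASS:
            n_intra[r.seq_id] += 1

    rows = []
    for sid, length in seq_lengths.items():
        rows.append((sid, length, n_inter[sid], n_intra[sid]))
    total_len = sum(seq_lengths.values())
    rows.insert(
        0, (GENOME_ROW, total_len, sum(n_inter.values()), sum(n_intra.values()))
    )
    df = pd.DataFrame(
        rows, columns=["seq_id", "length_bp", "n_interstrand_unique", "n_intrastrand"]
    ).set_index("seq_id")
    mb = df["length_bp"] / 1_000_000
    df["density_inter_per_mb"] = df["n_interstrand_unique"] / mb
    df["density_intra_per_mb"] = df["n_intrastrand"] / mb
    with np.errstate(divide="ignore", invalid="ignore"):
        df["intra_inter_ratio"] = np.where(
            df["n_interstrand_unique"] > 0,
            df["n_intrastrand"] / df["n_interstrand_unique"],
            math.nan,
        )
    return df


def poisson_z(observed: float, expected: float) -> float:
    """Asymptotic Poisson z-score, (observed - expected) / sqrt(expected)."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    return (observed - expected) / math.sqrt(expected)
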