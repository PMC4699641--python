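"""Association of PQS sites with functional interval sets.

Given a set of peaks (ChIP-seq, origins of replication, promoters, ...)
and a catalogue of quadruplex-forming sites, this module computes

* the number and fraction of peaks overlapping (>=1 shared base) at
  least one site of a chosen category,
* an upper-tail binomial test of that count against a background hit
  probability, with the enrichment ratio (observed fraction / background),
* the per-record fraction of fixed-width regions (e.g. 1-kb upstream
  sequences scanned directly from FASTA) containing a PQS,
* topology-class composition of the PQS population inside peaks versus
  genome-wide, with asymptotic Poisson z-scores per class.

The background hit probability is a closed-form length-aware null: a
peak of length w placed uniformly on the genome overlaps a merged site
of length L from w + L - 1 start positions, so p = sum(L_i + w - 1) / G
over merged sites, capped at 1, with w the median peak length.  A
Monte-Carlo alternative (uniform random re-placement of the peaks) is
provided for cross-checking.

Composition analyses deliberately count *all* overlapping PQS of
different classes (no unique-site merging): any of the overlapping
predictions could be the functional one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scanner import PQSRecord, ScanParams, DEFAULT_PARAMS, scan_all
from .topology import CLASS_NAMES, INTERSTRAND_CLASS_NAMES, INTRASTRAND_CLASS

__all__ = [
    "PeakSet",
    "EnrichmentResult",
    "peaks_with_hit",
    "background_probability",
    "background_probability_mc",
    "binomial_enrichment",
    "enrich",
    "fraction_of_features_with_pqs",
    "topology_composition",
    "records_to_intervals",
    "merge_intervals",
]

Interval = Tuple[str, int, int]


@dataclass
class PeakSet:
    """A named collection of 0-based half-open genomic intervals."""

    name: str
    intervals: list[Interval]

    def __post_init__(self) -> None:
        for sid, s, e in self.intervals:
            if e <= s:
                raise ValueError(f"empty/inverted interval {sid}:{s}-{e}")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def median_length(self) -> int:
        if not self.intervals:
            raise ValueError("empty peak set")
        return int(np.median([e - s for _, s, e in self.intervals]))


@dataclass
class EnrichmentResult:
    """Binomial enrichment of one PQS category in one peak set."""

    peak_set: str
    category: str
    n_peaks: int
    n_peaks_with_hit: int
    fraction_with_hit: float
    background_p: float
    binomial_p_upper: float
    enrichment_ratio: float


def records_to_intervals(
    records: Iterable[PQSRecord],
    category: str = "any",
) -> list[Interval]:
    """Project records of a category onto plain intervals.

    category: "any" (all ten classes), "inter"/"interstrand",
    "intra"/"intrastrand", or "class:<NAME>" for a single topology.
    """
    if category == "any":
        keep = set(CLASS_NAMES)
    elif category in ("inter", "interstrand"):
        keep = set(INTERSTRAND_CLASS_NAMES)
    elif category in ("intra", "intrastrand"):
        keep = {INTRASTRAND_CLASS}
    elif category.startswith("class:"):
        name = category.split(":", 1)[1]
        if name not in CLASS_NAMES:
            raise ValueError(f"unknown topology class {name!r}")
        keep = {name}
    else:
        raise ValueError(f"unknown category {category!r}")
    return [(r.seq_id, r.start, r.end) for r in records if r.topology in keep]


def merge_intervals(intervals: Iterable[Interval]) -> dict[str, np.ndarray]:
    """Collapse intervals into per-sequence sorted non-overlapping arrays.

    Returns seq_id -> array of shape (n, 2).  Adjacent (touching)
    intervals are kept separate only if they share no base, i.e. merging
    uses the same >=1-shared-base relation as unique-site grouping.
    """
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for sid, s, e in intervals:
        by_seq.setdefault(sid, []).append((s, e))
    out: dict[str, np.ndarray] = {}
    for sid, ivs in by_seq.items():
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[sid] = np.asarray(merged, dtype=np.int64)
    return out


def peaks_with_hit(
    peaks: PeakSet, sites: Union[Sequence[Interval], Mapping[str, np.ndarray]]
) -> int:
    """Number of peaks sharing >=1 base with at least one site.

    Each peak is counted at most once however many sites it touches; the
    definition is directional (counting sites-with-a-peak would give a
    different number).
    """
    merged = sites if isinstance(sites, Mapping) else merge_intervals(sites)
    count = 0
    for sid, s, e in peaks.intervals:
        arr = merged.get(sid)
        if arr is None or len(arr) == 0:
            continue
        # first site whose end is > peak start; it overlaps iff it starts
        # before the peak ends
        i = int(np.searchsorted(arr[:, 1], s, side="right"))
        if i < len(arr) and arr[i, 0] < e:
            count += 1
    return count


def background_probability(
    sites: Union[Sequence[Interval], Mapping[str, np.ndarray]],
    seq_lengths: Mapping[str, int],
    peak_length: int,
) -> float:
    """Probability that a uniformly placed peak overlaps >=1 merged site.

    Closed form: sum over merged sites of (site_length + peak_length - 1)
    divided by the total genome length, capped at 1.  Ignores chromosome
    edge effects, which are negligible for peaks much shorter than the
    sequences.
    """
    if peak_length < 1:
        raise ValueError("peak_length must be >= 1")
    total = sum(seq_lengths.values())
    if total <= 0:
        raise ValueError("empty genome")
    merged = sites if isinstance(sites, Mapping) else merge_intervals(sites)
    favourable = 0
    for arr in merged.values():
        if len(arr):
            favourable += int((arr[:, 1] - arr[:, 0] + peak_length - 1).sum())
    return min(1.0, favourable / total)


def background_probability_mc(
    sites: Union[Sequence[Interval], Mapping[str, np.ndarray]],
    seq_lengths: Mapping[str, int],
    peak_lengths: Sequence[int],
    n_draws: int = 1000,
    seed: Optional[int] = None,
) -> float:
    """Monte-Carlo null: fraction of uniformly re-placed peaks hitting a site.

    Draws ``n_draws`` rounds of placing every peak (cycling through
    ``peak_lengths``) on a random sequence chosen proportionally to
    length, start uniform within the sequence.
    """
    rng = np.random.default_rng(seed)
    merged = sites if isinstance(sites, Mapping) else merge_intervals(sites)
    sids = list(seq_lengths)
    lens = np.array([seq_lengths[s] for s in sids], dtype=float)
    probs = lens / lens.sum()
    hits = 0
    n_total = 0
    for _ in range(n_draws):
        for w in peak_lengths:
            sid = sids[rng.choice(len(sids), p=probs)]
            lo_max = max(0, seq_lengths[sid] - w)
            s = int(rng.integers(0, lo_max + 1))
            arr = merged.get(sid)
            n_total += 1
            if arr is not None and len(arr):
                i = int(np.searchsorted(arr[:, 1], s, side="right"))
                if i < len(arr) and arr[i, 0] < s + w:
                    hits += 1
    return hits / n_total


def binomial_enrichment(k: int, n: int, p: float) -> tuple[float, float]:
    """Upper-tail binomial test and enrichment ratio.

    Returns (P(X >= k) for X ~ Binomial(n, p), (k/n)/p).  With p = 0 and
    k > 0 the event is impossible under the null: p_upper 0, ratio inf.
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 <= p <= 1.0):
        raise ValueError("need 0 <= p <= 1")
    if p == 0.0:
        return (1.0, 0.0) if k == 0 else (0.0, math.inf)
    p_upper = float(sps.binom.sf(k - 1, n, p))
    ratio = (k / n) / p if n > 0 else math.nan
    return p_upper, ratio


def enrich(
    peaks: PeakSet,
    records: Iterable[PQSRecord],
    seq_lengths: Mapping[str, int],
    category: str = "any",
    null: str = "closed-form",
    n_draws: int = 1000,
    seed: Optional[int] = None,
) -> EnrichmentResult:
    """Full enrichment analysis of one PQS category in one peak set."""
    intervals = records_to_intervals(records, category)
    merged = merge_intervals(intervals)
    n = len(peaks)
    k = peaks_with_hit(peaks, merged)
    if null == "closed-form":
        p = background_probability(merged, seq_lengths, peaks.median_length)
    elif null == "shuffle":
        lengths = [e - s for _, s, e in peaks.intervals]
        p = background_probability_mc(
            merged, seq_lengths, lengths, n_draws=n_draws, seed=seed
        )
    else:
        raise ValueError(f"unknown null {null!r}")
    p_upper, ratio = binomial_enrichment(k, n, p)
    return EnrichmentResult(
        peak_set=peaks.name,
        category=category,
        n_peaks=n,
        n_peaks_with_hit=k,
        fraction_with_hit=k / n if n else math.nan,
        background_p=p,
        binomial_p_upper=p_upper,
        enrichment_ratio=ratio,
    )


def fraction_of_features_with_pqs(
    features: Iterable[tuple[str, str]],
    params: ScanParams = DEFAULT_PARAMS,
    category: str = "any",
) -> float:
    """Fraction of fixed-width FASTA records containing >=1 PQS of a category.

    Each record (e.g. a 1-kb upstream promoter region) is scanned
    independently; matches never span record boundaries.
    """
    n = 0
    hit = 0
    for seq_id, seq in features:
        n += 1
        recs = scan_all(seq, seq_id, params)
        if records_to_intervals(recs, category):
            hit += 1
    if n == 0:
        raise ValueError("no features supplied")
    return hit / n


def topology_composition(
    in_peak_records: Sequence[PQSRecord],
    genome_records: Sequence[PQSRecord],
) -> pd.DataFrame:
    """Topology-class composition inside peaks versus genome-wide.

    All overlapping records are counted (no unique-site merging).  For
    each class: in-peak count, fraction of all PQS in peaks, fraction of
    interstrand (DS) PQS in peaks, the genome-wide reference fractions,
    and asymptotic Poisson z-scores of the in-peak count against the
    expectation from genome-wide fractions scaled to the in-peak totals
    (negative z = depletion).  z is computed on both denominators
    (``z_all`` over all classes, ``z_ds`` over interstrand classes only,
    NaN for AAAA).  A class absent both genome-wide and in peaks gets
    z = 0 and ``degenerate`` = True.
    """
    def counts(records: Sequence[PQSRecord]) -> dict[str, int]:
        c = {name: 0 for name in CLASS_NAMES}
        for r in records:
            c[r.topology] += 1
        return c

    obs = counts(in_peak_records)
    ref = counts(genome_records)
    tot_obs = sum(obs.values())
    tot_ref = sum(ref.values())
    ds_obs = sum(obs[c] for c in INTERSTRAND_CLASS_NAMES)
    ds_ref = sum(ref[c] for c in INTERSTRAND_CLASS_NAMES)

    def z_for(name: str, denom_obs: int, denom_ref: int, ref_count: int) -> tuple[float, bool]:
        if denom_ref == 0 or ref_count == 0:
            if obs[name] == 0:
                return 0.0, True
            return math.inf, True
        expected = denom_obs * ref_count / denom_ref
        if expected == 0:
            return (0.0, True) if obs[name] == 0 else (math.inf, True)
        return (obs[name] - expected) / math.sqrt(expected), False

    rows = []
    for name in CLASS_NAMES:
        z_all, degen_all = z_for(name, tot_obs, tot_ref, ref[name])
        if name == INTRASTRAND_CLASS:
            z_ds, degen_ds = math.nan, False
            frac_ds = math.nan
            frac_ds_ref = math.nan
        else:
            z_ds, degen_ds = z_for(name, ds_obs, ds_ref, ref[name])
            frac_ds = obs[name] / ds_obs if ds_obs else math.nan
            frac_ds_ref = ref[name] / ds_ref if ds_ref else math.nan
        rows.append(
            {
                "topology": name,
                "count_in_peaks": obs[name],
                "frac_all_in_peaks": obs[name] / tot_obs if tot_obs else math.nan,
                "frac_ds_in_peaks": frac_ds,
                "frac_all_genome": ref[name] / tot_ref if tot_ref else math.nan,
                "frac_ds_genome": frac_ds_ref,
                "z_all": z_all,
                "z_ds": z_ds,
                "degenerate": degen_all or degen_ds,
            }
        )
    return pd.DataFrame(rows).set_index("topology")
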