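"""Quantification of satellite hitchhiking in phage particle sequencing.

Covers the read-count arithmetic that estimates what fraction of particles
carry a satellite concatemer instead of the helper genome, the headful copy
number implied by capsid size, alignment-based read classification
(helper / satellite / hybrid), placement of long reads on an artificial
tandem concatemer reference, and a chi-square test of whether concatemer
extremities are random (headful, pac-like) or fixed (cos-like).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np
from Bio.Seq import Seq
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PackagingCounts:
    """Per-element read tallies and reference lengths."""

    reads_helper: int
    reads_satellite: int
    len_helper: int
    len_satellite: int
    concatemer_copies: int = 1
    reads_hybrid: int = 0
    reads_unassigned: int = 0

    def __post_init__(self) -> None:
        for name in ("reads_helper", "reads_satellite", "reads_hybrid", "reads_unassigned"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.len_helper <= 0 or self.len_satellite <= 0:
            raise ValueError("reference lengths must be > 0")
        if self.concatemer_copies < 1:
            raise ValueError("concatemer_copies must be >= 1")


@dataclass
class PackagingEstimate:
    """Coverage-normalized hitchhiking estimate.

    ``hitchhiker_pct`` follows the printed two-decimal convention (depths and
    the particle equivalent rounded to two decimals, the final percentage
    truncated to an integer); ``hitchhiker_odds`` is the full-precision
    satellite:helper particle ratio and ``hitchhiker_fraction`` the implied
    fraction of particles carrying the satellite, odds / (1 + odds).
    """

    norm_helper: float
    norm_satellite: float
    particle_equiv_satellite: float
    hitchhiker_pct: int
    hitchhiker_odds: float

    @property
    def hitchhiker_fraction(self) -> float:
        return self.hitchhiker_odds / (1.0 + self.hitchhiker_odds)

    @property
    def printed_chain(self) -> tuple[float, float, float, int]:
        """(norm_helper, norm_satellite, particle_equiv, pct) as printed."""
        nh = round(self.norm_helper, 2)
        ns = round(self.norm_satellite, 2)
        pe = round(ns / (self.norm_satellite / self.particle_equiv_satellite), 2)
        return nh, ns, pe, self.hitchhiker_pct


def hitchhiker_fraction(counts: PackagingCounts) -> PackagingEstimate:
    """Coverage-normalize read counts and estimate the hitchhiked fraction.

    Depths are reads per bp of reference; the satellite depth is divided by
    the concatemer copy number to convert genome equivalents into particle
    equivalents. The integer percentage reproduces the two-decimal printed
    chain ``trunc(100 * round(round(norm_sat, 2) / copies, 2) /
    round(norm_helper, 2))``; full-precision odds are also carried.
    """
    nh = counts.reads_helper / counts.len_helper
    ns = counts.reads_satellite / counts.len_satellite
    pe = ns / counts.concatemer_copies
    odds = pe / nh if nh > 0 else float("inf")
    nh2, ns2 = round(nh, 2), round(ns, 2)
    pe2 = round(ns2 / counts.concatemer_copies, 2)
    pct = int(100.0 * pe2 / nh2) if nh2 > 0 else 100
    return PackagingEstimate(
        norm_helper=nh,
        norm_satellite=ns,
        particle_equiv_satellite=pe,
        hitchhiker_pct=pct,
        hitchhiker_odds=odds,
    )


def headful_copy_number(len_helper: int, len_satellite: int) -> int:
    """Copies of the satellite filling a helper-sized headful.

    Returns the k >= 1 minimizing |k * len_satellite - len_helper|; ties go
    to the larger k (headful packaging overshoots the capsid).
    """
    if len_helper <= 0 or len_satellite <= 0:
        raise ValueError("lengths must be > 0")
    if len_satellite > len_helper:
        raise ValueError("satellite longer than helper capsid")
    best_k = 1
    best = abs(len_satellite - len_helper)
    for k in range(2, len_helper // len_satellite + 2):
        err = abs(k * len_satellite - len_helper)
        if err <= best:
            best, best_k = err, k
    return best_k


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _infix_identity(query: str, ref: str) -> tuple[float, Optional[tuple[int, int]]]:
    """Best infix placement of query in ref on either strand.

    Returns (identity over the query, (start, end) on the forward ref)."""
    best = (0.0, None)
    for q in (query, _revcomp(query)):
        res = edlib.align(q, ref, mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        ident = 1.0 - res["editDistance"] / len(q)
        if ident > best[0]:
            loc = res["locations"][0]
            best = (ident, (loc[0], loc[1] + 1))
    return best


def classify_reads(
    reads: Sequence[str],
    helper_ref: str,
    satellite_ref: str,
    min_anchor: int = 50,
    *,
    min_identity: float = 0.70,
    len_helper: Optional[int] = None,
    len_satellite: Optional[int] = None,
    concatemer_copies: int = 1,
) -> PackagingCounts:
    """Assign each read to helper, satellite, hybrid or unassigned.

    A read is anchored to a reference when >= ``min_anchor`` of its bases
    align there at >= ``min_identity``; full-read placement is tried first and
    chimeric reads are caught by a prefix/suffix split scan. Hybrid reads
    anchor to both references. ``satellite_ref`` should tile the satellite
    unit at least twice so concatemer-junction reads place cleanly.
    """
    if not helper_ref or not satellite_ref:
        raise ValueError("references must be non-empty")
    n_h = n_s = n_hyb = n_un = 0
    for read in reads:
        ah = _anchored_bases(read, helper_ref, min_anchor, min_identity)
        as_ = _anchored_bases(read, satellite_ref, min_anchor, min_identity)
        if ah >= min_anchor and as_ >= min_anchor:
            n_hyb += 1
        elif ah >= min_anchor and ah >= as_:
            n_h += 1
        elif as_ >= min_anchor:
            n_s += 1
        else:
            n_un += 1
    return PackagingCounts(
        reads_helper=n_h,
        reads_satellite=n_s,
        reads_hybrid=n_hyb,
        reads_unassigned=n_un,
        len_helper=len_helper or len(helper_ref),
        len_satellite=len_satellite or len(satellite_ref),
        concatemer_copies=concatemer_copies,
    )


def _anchored_bases(
    read: str, ref: str, min_anchor: int, min_identity: float, grid: int = 25
) -> int:
    """Longest read segment placeable in ref at >= min_identity.

    Tries the full read, then prefix/suffix splits on a coarse grid (this is
    what catches the two halves of a chimeric read)."""
    ident, _ = _infix_identity(read, ref)
    if ident >= min_identity:
        return len(read)
    best = 0
    n = len(read)
    step = max(grid, min_anchor // 2)
    for cut in range(step, n, step):
        for part in (read[:cut], read[cut:]):
            if len(part) < min_anchor or len(part) <= best:
                continue
            ident, _ = _infix_identity(part, ref)
            if ident >= min_identity:
                best = len(part)
    return best


@dataclass
class ConcatemerRead:
    """A long read placed on an artificial tandem concatemer reference."""

    read_id: str
    start_on_ref: int
    end_on_ref: int
    unit_len: int
    n_units: int = 13
    identity: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.start_on_ref < self.end_on_ref <= self.n_units * self.unit_len):
            raise ValueError("read placement outside concatemer reference")

    @property
    def phase_start(self) -> int:
        return self.start_on_ref % self.unit_len


def map_concatemer_reads(
    long_reads: Sequence[tuple[str, str]] | Sequence[str],
    unit_seq: str,
    n_units: int = 13,
    *,
    min_identity: float = 0.70,
) -> list[ConcatemerRead]:
    """Place long reads on an ``n_units`` tandem copy of the satellite unit.

    Placement is the best infix alignment on either strand; the phase of the
    read start is its offset modulo the unit length. Reads below the identity
    floor are dropped with a logged count. Reads may be (id, seq) pairs or
    bare sequences.
    """
    if not unit_seq:
        raise ValueError("unit_seq must be non-empty")
    ref = unit_seq * n_units
    placed: list[ConcatemerRead] = []
    dropped = 0
    for i, item in enumerate(long_reads):
        read_id, seq = item if isinstance(item, tuple) else (f"read{i}", item)
        if len(seq) > len(ref):
            raise ValueError(
                f"read {read_id} ({len(seq)} bp) longer than the {n_units}-copy "
                "reference; increase n_units"
            )
        ident, loc = _infix_identity(seq, ref)
        if loc is None or ident < min_identity:
            dropped += 1
            continue
        placed.append(
            ConcatemerRead(
                read_id=read_id,
                start_on_ref=loc[0],
                end_on_ref=loc[1],
                unit_len=len(unit_seq),
                n_units=n_units,
                identity=ident,
            )
        )
    if dropped:
        logger.info("map_concatemer_reads: dropped %d reads below identity floor", dropped)
    return placed


def extremity_randomness_test(
    reads: Sequence[ConcatemerRead] | Sequence[float],
    bins: int = 20,
    *,
    unit_len: Optional[int] = None,
    alpha: float = 0.05,
) -> tuple[float, float, str]:
    """Chi-square goodness-of-fit of read-start phases against uniformity.

    Random extremities (p >= alpha) indicate headful, pac-like packaging;
    a concentrated phase distribution indicates fixed, cos-like ends.
    Accepts :class:`ConcatemerRead` objects or raw phases (then ``unit_len``
    is required). Requires at least 20 reads.
    """
    if len(reads) < 20:
        raise ValueError("need >= 20 reads for the extremity test")
    if len(reads) and isinstance(reads[0], ConcatemerRead):
        phases = np.array([r.phase_start for r in reads], dtype=float)
        unit_len = reads[0].unit_len
    else:
        if unit_len is None:
            raise ValueError("unit_len required for raw phases")
        phases = np.asarray(reads, dtype=float)
    observed, _ = np.histogram(phases, bins=bins, range=(0, unit_len))
    stat, p = stats.chisquare(observed)
    verdict = (
        "random-extremities (pac-like)" if p >= alpha else "fixed-extremities (cos-like)"
    )
    return float(stat), float(p), verdict
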