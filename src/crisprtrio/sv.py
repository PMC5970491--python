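"""Structural-variant screening and Cas9 cut-site attribution.

Per-founder SV call sets are reduced to de novo candidates by removing
calls shared between founders (reciprocal-overlap matching), calls with
weak read support, and calls on unplaced scaffold contigs.  De novo CNVs
are extracted from trio copy-number segments.  Surviving candidates are
then classified as Cas9-induced when both breakpoints fall within a small
tolerance of a pair of predicted cut sites — the signature of an inversion
or deletion created by simultaneous double-strand breaks at two guide
sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SvCall",
    "CutSitePair",
    "SvAttribution",
    "filter_sv_candidates",
    "denovo_cnv_candidates",
    "classify_cas9_sv",
    "screen_cohort_for_sv",
    "read_sv_tsv",
    "read_cn_tsv",
    "cut_site_pairs",
]

SV_TYPES = ("DEL", "DUP", "INV", "TRA")


@dataclass(frozen=True)
class SvCall:
    caller: str
    founder: str
    type: str
    contig: str
    start: int            # 0-based half-open
    end: int
    supporting_fraction: float

    def __post_init__(self) -> None:
        if self.type not in SV_TYPES:
            raise ValueError(f"unknown SV type: {self.type}")
        if self.type != "TRA" and not self.start < self.end:
            raise ValueError("start must be < end for intra-contig SVs")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CutSitePair:
    """Two Cas9 cut coordinates on one contig, c1 < c2."""

    guide_ids: tuple[str, str]
    contig: str
    c1: int
    c2: int

    def __post_init__(self) -> None:
        if not self.c1 < self.c2:
            raise ValueError("cut sites must satisfy c1 < c2")

    @property
    def gap(self) -> int:
        return self.c2 - self.c1


@dataclass(frozen=True)
class SvAttribution:
    induced: bool
    pair: CutSitePair | None = None
    offset_start: int | None = None     # sv.start - c1
    offset_end: int | None = None       # sv.end - c2
    length_deviation: int | None = None  # |sv length - pair gap|


def _reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start), ov / (b_end - b_start))


def filter_sv_candidates(
    callsets: Sequence[SvCall],
    reciprocal_overlap: float = 0.5,
    min_support: float = 0.5,
    drop_scaffolds: bool = True,
    scaffold_pattern: str = r"^scaffold",
) -> dict[str, list[SvCall]]:
    """Reduce per-founder call sets to de novo candidates.

    An SV is dropped when any *other* founder has a same-type call with
    reciprocal overlap >= the threshold (shared, hence inherited or
    artifactual), when its supporting-read fraction is below
    ``min_support``, or when it lies on a scaffold contig.  Returns
    candidates keyed by founder; the result is symmetric in founder order.
    """
    pat = re.compile(scaffold_pattern)
    by_founder: dict[str, list[SvCall]] = {}
    for sv in callsets:
        by_founder.setdefault(sv.founder, []).append(sv)
    out: dict[str, list[SvCall]] = {}
    for founder, calls in by_founder.items():
        others = [sv for sv in callsets if sv.founder != founder]
        kept = []
        for sv in calls:
            if drop_scaffolds and pat.search(sv.contig):
                continue
            if sv.supporting_fraction < min_support:
                continue
            shared = any(
                o.type == sv.type and o.contig == sv.contig
                and _reciprocal_overlap(sv.start, sv.end, o.start, o.end)
                >= reciprocal_overlap
                for o in others)
            if shared:
                continue
            kept.append(sv)
        out[founder] = kept
    return out


@dataclass(frozen=True)
class CnSegment:
    sample: str
    contig: str
    start: int
    end: int
    copy_number: int


def denovo_cnv_candidates(
    segments: Sequence[CnSegment],
    min_length: int = 1_000,
    delta: int = 1,
    min_overlap: float = 0.5,
) -> list[CnSegment]:
    """Founder copy-number segments that deviate from both parents.

    A founder segment is a candidate when, for each parent, the
    best-overlapping parental segment has reciprocal overlap >=
    ``min_overlap`` and a copy number differing by >= ``delta``.
    """
    founder_segs = [s for s in segments if s.sample == "founder"
                    and s.end - s.start >= min_length]
    parents = {
        p: [s for s in segments if s.sample == p] for p in ("father", "mother")
    }
    out = []
    for f in founder_segs:
        deviant = True
        for p_segs in parents.values():
            best, best_ov = None, 0.0
            for p in p_segs:
                if p.contig != f.contig:
                    continue
                ov = _reciprocal_overlap(f.start, f.end, p.start, p.end)
                if ov > best_ov:
                    best, best_ov = p, ov
            if best is None or best_ov < min_overlap \
                    or abs(best.copy_number - f.copy_number) < delta:
                deviant = False
                break
        if deviant:
            out.append(f)
    return out


def classify_cas9_sv(
    sv: SvCall,
    pairs: Sequence[CutSitePair],
    tolerance: int = 10,
) -> SvAttribution:
    """Attribute an SV to a pair of Cas9 cuts by breakpoint proximity.

    Induced iff the SV is an inversion or deletion on the pair's contig
    with |start - c1| <= tolerance and |end - c2| <= tolerance.
    Translocations are never attributed (no paired-cut model for them).
    """
    if sv.type not in ("INV", "DEL"):
        return SvAttribution(induced=False)
    for pair in pairs:
        if pair.contig != sv.contig:
            continue
        off1 = sv.start - pair.c1
        off2 = sv.end - pair.c2
        if abs(off1) <= tolerance and abs(off2) <= tolerance:
            return SvAttribution(
                induced=True, pair=pair, offset_start=off1, offset_end=off2,
                length_deviation=abs(sv.length - pair.gap))
    return SvAttribution(induced=False)


def screen_cohort_for_sv(
    carrier_calls: Mapping[str, bool] | Sequence[bool],
) -> tuple[int, int, float]:
    """Count carriers of a target SV across a cohort.

    ``carrier_calls`` maps animal id -> presence (or is a plain sequence of
    presence flags).  Returns (carrier count, cohort size, percentage
    rounded to 2 decimals).
    """
    flags = (list(carrier_calls.values())
             if isinstance(carrier_calls, Mapping) else list(carrier_calls))
    if not flags:
        raise ValueError("cohort is empty")
    n = len(flags)
    carriers = sum(bool(f) for f in flags)
    return carriers, n, round(100.0 * carriers / n, 2)


# ---------------------------------------------------------------------------
# I/O helpers


def read_sv_tsv(path: str) -> list[SvCall]:
    """Columns: caller, founder, type, contig, start, end, supporting_fraction."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("caller\t"):
                continue
            c = line.split("\t")
            out.append(SvCall(c[0], c[1], c[2], c[3], int(c[4]), int(c[5]),
                              float(c[6])))
    return out


def read_cn_tsv(path: str) -> list[CnSegment]:
    """Columns: sample, contig, start, end, copy_number."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("sample\t"):
                continue
            c = line.split("\t")
            out.append(CnSegment(c[0], c[1], int(c[2]), int(c[3]), int(c[4])))
    return out


def cut_site_pairs(sites, max_gap: int = 100_000) -> list[CutSitePair]:
    """All same-contig pairs of cut sites (from planted or scanned sites)
    with gap <= ``max_gap``, per guide pair."""
    by_contig: dict[str, list] = {}
    for s in sites:
        by_contig.setdefault(s.contig, []).append(s)
    pairs = []
    for contig, group in by_contig.items():
        group = sorted(group, key=lambda s: s.cut_site)
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                if a.cut_site == b.cut_site:
                    continue
                if b.cut_site - a.cut_site <= max_gap:
                    pairs.append(CutSitePair(
                        (getattr(a, "guide_id", "?"), getattr(b, "guide_id", "?")),
                        contig, a.cut_site, b.cut_site))
    return pairs
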