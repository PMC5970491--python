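"""CRISPR off-target site enumeration.

Scans a genome for loci resembling an sgRNA protospacer followed by a PAM,
counting mismatches separately in the seed (PAM-proximal) and non-seed
(PAM-distal) regions of the protospacer.  A site is accepted when its seed,
non-seed and total mismatch counts all fall within the configured limits;
the default limits (1 seed, 4 non-seed, 5 total) reproduce the common
"1 mismatch in seed, up to 4 outside" working definition of a potential
off-target, capped at five mismatches overall.

Coordinates are 0-based half-open throughout.  The cut site is the blunt
double-strand-break boundary 3 bp 5' of the PAM (between protospacer
positions 17 and 18), the standard SpCas9 geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GuideSpec",
    "OffTargetSite",
    "scan_guide",
    "cut_site",
    "overlap_fraction",
    "sites_to_bed",
    "cut_sites_to_bed",
    "load_guides_tsv",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_N_CODE = 4

# IUPAC degenerate nucleotide codes -> the set of concrete bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 (A,C,G,T -> 0..3; anything else -> 4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, _N_CODE, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass(frozen=True)
class GuideSpec:
    """An sgRNA: 20-nt protospacer (5'->3', PAM-distal first) plus PAM rule.

    ``seed_length`` counts PAM-proximal protospacer bases, i.e. the last
    ``seed_length`` characters of ``protospacer``.
    """

    id: str
    protospacer: str
    pam_pattern: str = "NGG"
    seed_length: int = 12
    gene: str = ""

    def __post_init__(self) -> None:
        proto = self.protospacer.upper()
        object.__setattr__(self, "protospacer", proto)
        object.__setattr__(self, "pam_pattern", self.pam_pattern.upper())
        if len(proto) != 20:
            raise ValueError(f"protospacer must be 20 nt, got {len(proto)}")
        if any(b not in "ACGT" for b in proto):
            raise ValueError(f"protospacer has non-ACGT base: {proto}")
        if not 1 <= self.seed_length <= 20:
            raise ValueError("seed_length must be in [1, 20]")
        if any(b not in IUPAC for b in self.pam_pattern):
            raise ValueError(f"invalid PAM pattern: {self.pam_pattern}")

    @property
    def pam_length(self) -> int:
        return len(self.pam_pattern)

    @property
    def site_length(self) -> int:
        return 20 + self.pam_length


@dataclass(frozen=True)
class OffTargetSite:
    """A genomic locus matching a guide within mismatch tolerances.

    ``start``/``end`` delimit the 20-bp protospacer interval (half-open);
    the PAM lies immediately 3' of it in the guide's orientation.
    """

    guide_id: str
    contig: str
    start: int
    end: int
    strand: str
    m_seed: int
    m_nonseed: int
    cut_site: int
    accepted: bool = True

    @property
    def m_total(self) -> int:
        return self.m_seed + self.m_nonseed


def _pam_match_vec(enc: np.ndarray, offset: int, pam_pattern: str, n_pos: int) -> np.ndarray:
    """Boolean vector: PAM match at enc[i+offset : i+offset+len(pam)] for i in [0, n_pos)."""
    ok = np.ones(n_pos, dtype=bool)
    for j, ch in enumerate(pam_pattern):
        allowed = [_BASE_CODE[b] for b in IUPAC[ch]]
        col = enc[offset + j : offset + j + n_pos]
        ok &= np.isin(col, allowed)  # genome N (code 4) never matches
    return ok


def _scan_one_strand(enc: np.ndarray, guide: GuideSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (positions, m_seed, m_nonseed) of all PAM-anchored windows."""
    L = enc.size
    span = guide.site_length
    if L < span:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    n_pos = L - span + 1
    proto = encode(guide.protospacer)
    seed_start = 20 - guide.seed_length
    m_seed = np.zeros(n_pos, dtype=np.int16)
    m_nonseed = np.zeros(n_pos, dtype=np.int16)
    for k in range(20):
        mm = enc[k : k + n_pos] != proto[k]
        if k >= seed_start:
            m_seed += mm
        else:
            m_nonseed += mm
    pam_ok = _pam_match_vec(enc, 20, guide.pam_pattern, n_pos)
    pos = np.nonzero(pam_ok)[0]
    return pos, m_seed[pos].astype(np.int64), m_nonseed[pos].astype(np.int64)


def _forward_cut(start: int) -> int:
    # blunt cut boundary 3 bp 5' of the PAM: between protospacer pos 17|18
    return start + 17


def scan_guide(
    genome: Mapping[str, str],
    guide: GuideSpec,
    max_seed_mm: int = 1,
    max_nonseed_mm: int = 4,
    max_total_mm: int = 5,
) -> list[OffTargetSite]:
    """Enumerate accepted off-target sites for ``guide`` on both strands.

    Ambiguous genome bases (N) always count as mismatches and never satisfy
    a PAM position; ``N`` in the PAM pattern matches any of A/C/G/T.
    """
    if not genome:
        raise ValueError("genome is empty")
    sites: list[OffTargetSite] = []
    for contig, seq in genome.items():
        enc = encode(seq)
        L = enc.size
        # forward strand: protospacer [p, p+20), PAM [p+20, p+23)
        pos, ms, mn = _scan_one_strand(enc, guide)
        for p, s, n in zip(pos.tolist(), ms.tolist(), mn.tolist()):
            if s <= max_seed_mm and n <= max_nonseed_mm and s + n <= max_total_mm:
                sites.append(OffTargetSite(
                    guide.id, contig, p, p + 20, "+", s, n, _forward_cut(p)))
        # reverse strand: scan the reverse complement, then map back
        rc = encode(reverse_complement(seq))
        pos, ms, mn = _scan_one_strand(rc, guide)
        for p, s, n in zip(pos.tolist(), ms.tolist(), mn.tolist()):
            if s <= max_seed_mm and n <= max_nonseed_mm and s + n <= max_total_mm:
                start = L - (p + 20)   # protospacer interval on the + coordinate
                end = L - p
                # PAM at [start-3, start); cut 3 bp inside the protospacer
                sites.append(OffTargetSite(
                    guide.id, contig, start, end, "-", s, n, start + 3))
    sites.sort(key=lambda s: (s.contig, s.start, s.strand))
    return sites


def cut_site(site: OffTargetSite) -> int:
    """Blunt-cut boundary coordinate for a site (strand-aware)."""
    if site.strand == "+":
        return _forward_cut(site.start)
    return site.start + 3


def overlap_fraction(
    sites_a: Sequence[OffTargetSite],
    sites_b: Sequence[OffTargetSite],
    slop: int = 0,
) -> float:
    """Fraction of ``sites_a`` whose protospacer interval overlaps (within
    ``slop`` bases) a same-strand site in ``sites_b``.

    Returns 0.0 with a warning for empty ``sites_a``.
    """
    if not sites_a:
        warnings.warn("overlap_fraction: empty first site list; returning 0.0")
        return 0.0
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for b in sites_b:
        by_key.setdefault((b.contig, b.strand), []).append((b.start, b.end))
    hits = 0
    for a in sites_a:
        for (s, e) in by_key.get((a.contig, a.strand), ()):
            if a.start < e + slop and s < a.end + slop:
                hits += 1
                break
    return hits / len(sites_a)


def sites_to_bed(sites: Iterable[OffTargetSite], path: str) -> None:
    """Write sites as BED6: name=guide;m_seed;m_nonseed, score=m_total."""
    with open(path, "w") as fh:
        for s in sites:
            name = f"{s.guide_id};{s.m_seed};{s.m_nonseed}"
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{name}\t{s.m_total}\t{s.strand}\n")


def cut_sites_to_bed(sites: Iterable[OffTargetSite], path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            c = cut_site(s)
            fh.write(f"{s.contig}\t{c}\t{c + 1}\t{s.guide_id}\t{s.m_total}\t{s.strand}\n")


def load_guides_tsv(path: str) -> list[GuideSpec]:
    """Read guides from TSV with columns: id, protospacer[, pam, gene]."""
    guides = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("id", "guide_id"):
                continue
            pam = parts[2] if len(parts) > 2 and parts[2] else "NGG"
            gene = parts[3] if len(parts) > 3 else ""
            guides.append(GuideSpec(id=parts[0], protospacer=parts[1],
                                    pam_pattern=pam, gene=gene))
    return guides
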