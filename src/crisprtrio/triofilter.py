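"""De novo variant filter cascade over two-caller trio VCFs.

The founder animal of each trio is screened for variants absent from both
parents.  Candidate de novo SNVs and indels are pushed through an ordered
cascade of filters — site quality, founder specificity with dual-caller
support, population-database exclusion, depth / allele-fraction checks, a
phred-scaled genotype-likelihood (PL) pattern test, strand support, and an
automated artifact screen standing in for manual curation.  The report
mirrors the per-rule survivor tables such pipelines publish: an ordered
list of (rule, description, survivor count) plus the surviving candidates
with a per-rule pass/fail trail.

Rule ids:

====  ======================================================================
R0    site QUAL >= 50 and founder depth <= 300
R1    founder carries the alt, parents called hom-ref with at most
      ``max_parent_alt_reads`` (default 1) stray alt reads, and the site
      is confirmed by the second caller
R2    drop alleles present in the population database (allele match)
R3    drop positions present in the population database (position match)
R4    founder alt fraction >= 0.25 and depth >= 3 in every trio member
R5    PL pattern: founder (>20, 0, >0); each parent (0, >20, >20)
R6    founder alt allele on both strands (>= 1 forward and >= 1 reverse read)
R7    artifact screen: no second candidate within 10 bp, not inside a
      reference homopolymer / dinucleotide run >= 8 bp
R14   R1 and R4 combined (the indel cascade collapses them into one step)
====  ======================================================================

SNVs run R0-R7; indels (2-50 bp length change) run R0, R14, R5, R7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "SampleEvidence",
    "TrioVariantRecord",
    "PopulationDb",
    "CascadeConfig",
    "CascadeReport",
    "read_trio_vcfs",
    "pl_pattern_ok",
    "database_match",
    "apply_cascade",
    "normalize_variant",
    "report_to_tsv",
    "trail_to_tsv",
    "write_candidates_vcf",
]

ROLES = ("father", "mother", "founder")

RULE_DESCRIPTIONS = {
    "R0": "Site quality >= 50 and founder depth <= 300",
    "R1": "Founder-specific and identified by the second caller",
    "R2": "Not in population database (alternative allele match)",
    "R3": "Not in population database (position match)",
    "R4": "Founder alt fraction >= 25% and depth >= 3 in all trio members",
    "R5": "PL pattern: founder (>20, 0, >0); parents (0, >20, >20)",
    "R6": "Covered by both forward and reverse alt reads in founder",
    "R7": "Artifact screen (candidate cluster / low-complexity reference)",
    "R14": "Founder-specific, dual-caller, alt fraction and depth checks",
}

DEFAULT_SNV_RULES = ("R0", "R1", "R2", "R3", "R4", "R5", "R6", "R7")
DEFAULT_INDEL_RULES = ("R0", "R14", "R5", "R7")


@dataclass(frozen=True)
class SampleEvidence:
    gt_alt_count: int | None   # 0/1/2 alt-allele dosage; None if uncalled
    dp: int
    ad_ref: int
    ad_alt: int
    adf_alt: int
    adr_alt: int
    pl: tuple[int, int, int]   # (AA, AB, BB); A=ref, B=alt


@dataclass
class TrioVariantRecord:
    """One decomposed biallelic VCF site with per-role evidence."""

    contig: str
    pos: int                   # 1-based, VCF convention
    ref: str
    alt: str
    variant_class: str         # "SNV" or "indel"
    qual: float
    samples: dict[str, SampleEvidence]
    present_in_caller2: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def founder(self) -> SampleEvidence:
        return self.samples["founder"]


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimonious representation: trim shared suffix, then shared prefix.

    Makes allele keys comparable between callers that pad indels
    differently.  (Left-alignment against the reference is unnecessary for
    keys produced by a single simulator but would slot in here.)
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _classify(ref: str, alt: str) -> str | None:
    """SNV, indel (2-50 bp net length change), or None (excluded)."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    diff = abs(len(ref) - len(alt))
    if 2 <= diff <= 50:
        return "indel"
    return None


def _pl_for_pair(pl: Sequence[int], ai: int) -> tuple[int, int, int]:
    """Extract the (0/0, 0/ai, ai/ai) PL triple and renormalize to min 0."""
    i_ab = ai * (ai + 1) // 2
    i_bb = i_ab + ai
    triple = (pl[0], pl[i_ab], pl[i_bb])
    m = min(triple)
    return (triple[0] - m, triple[1] - m, triple[2] - m)


def _decompose(rec: "pysam.VariantRecord", sample_of_role: Mapping[str, str]):
    """Yield one TrioVariantRecord per alternate allele of a VCF record."""
    if not rec.alts:
        return
    for ai, alt in enumerate(rec.alts, start=1):
        if alt is None or any(ch not in "ACGTN" for ch in alt.upper()):
            continue  # symbolic / spanning-deletion alleles
        pos, ref_n, alt_n = normalize_variant(rec.pos, rec.ref, alt)
        vclass = _classify(ref_n, alt_n)
        samples: dict[str, SampleEvidence] = {}
        ok = True
        for role in ROLES:
            s = rec.samples[sample_of_role[role]]
            try:
                gt = s["GT"]
                dp = s["DP"]
                ad = s["AD"]
                pl = s["PL"]
            except KeyError:
                ok = False
                break
            if dp is None or ad is None or pl is None or None in pl:
                ok = False
                break
            adf = s.get("ADF")
            adr = s.get("ADR")
            gt_count = (None if gt is None or None in gt
                        else sum(1 for a in gt if a == ai))
            samples[role] = SampleEvidence(
                gt_alt_count=gt_count,
                dp=int(dp),
                ad_ref=int(ad[0]),
                ad_alt=int(ad[ai]),
                adf_alt=int(adf[ai]) if adf is not None else -1,
                adr_alt=int(adr[ai]) if adr is not None else -1,
                pl=_pl_for_pair(pl, ai),
            )
        if not ok:
            yield None  # counted and skipped by the caller
            continue
        yield TrioVariantRecord(
            contig=rec.contig, pos=pos, ref=ref_n, alt=alt_n,
            variant_class=vclass if vclass is not None else "excluded",
            qual=float(rec.qual) if rec.qual is not None else 0.0,
            samples=samples)


def read_trio_vcfs(
    caller1_path: str,
    caller2_path: str,
    sample_roles: Mapping[str, str] | None = None,
) -> list[TrioVariantRecord]:
    """Parse the primary caller's trio VCF and flag dual-caller support.

    ``sample_roles`` maps role -> VCF sample name (default: samples are
    literally named father/mother/founder).  Multi-allelic records are
    decomposed into per-alternate records; 1-bp indels and alleles > 50 bp
    are excluded with a logged count.
    """
    roles = dict(sample_roles) if sample_roles else {r: r for r in ROLES}
    caller2_keys: set[tuple[str, int, str, str]] = set()
    with pysam.VariantFile(caller2_path) as vf2:
        for rec in vf2:
            for alt in rec.alts or ():
                if alt is None:
                    continue
                pos, r, a = normalize_variant(rec.pos, rec.ref, alt)
                caller2_keys.add((rec.contig, pos, r, a))

    out: list[TrioVariantRecord] = []
    n_skipped = n_excluded = 0
    with pysam.VariantFile(caller1_path) as vf1:
        names = set(vf1.header.samples)
        missing = [s for s in roles.values() if s not in names]
        if missing:
            raise ValueError(f"samples missing from caller-1 VCF: {missing}")
        for rec in vf1:
            for tv in _decompose(rec, roles):
                if tv is None:
                    n_skipped += 1
                    continue
                if tv.variant_class == "excluded":
                    n_excluded += 1
                    continue
                tv.present_in_caller2 = tv.key in caller2_keys
                out.append(tv)
    if n_skipped:
        logger.warning("skipped %d records with missing FORMAT fields", n_skipped)
    if n_excluded:
        logger.warning("excluded %d alleles outside the SNV/2-50 bp indel classes",
                       n_excluded)
    return out


# ---------------------------------------------------------------------------
# individual rules


def pl_pattern_ok(
    founder_pl: Sequence[int],
    father_pl: Sequence[int],
    mother_pl: Sequence[int],
    t_founder: int = 20,
    t_parent: int = 20,
) -> bool:
    """De novo PL pattern: founder confidently het, parents confidently
    hom-ref.

    Founder triple must be (> t_founder, 0, > 0); each parent triple must
    be (0, > t_parent, > t_parent).  All inequalities strict.
    """
    f = founder_pl
    if not (f[0] > t_founder and f[1] == 0 and f[2] > 0):
        return False
    for p in (father_pl, mother_pl):
        if not (p[0] == 0 and p[1] > t_parent and p[2] > t_parent):
            return False
    return True


class PopulationDb:
    """Population variant database: allele keys and derived position keys."""

    def __init__(self, allele_keys: Sequence[tuple[str, int, str, str]] = ()):
        self.alleles: set[tuple[str, int, str, str]] = set()
        self.positions: set[tuple[str, int]] = set()
        for key in allele_keys:
            self.add(*key)

    def add(self, contig: str, pos: int, ref: str, alt: str) -> None:
        pos, ref, alt = normalize_variant(pos, ref, alt)
        self.alleles.add((contig, pos, ref, alt))
        self.positions.add((contig, pos))

    def __len__(self) -> int:
        return len(self.alleles)

    @classmethod
    def from_vcf(cls, path: str) -> "PopulationDb":
        db = cls()
        with pysam.VariantFile(path) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    if alt:
                        db.add(rec.contig, rec.pos, rec.ref, alt)
        return db

    @classmethod
    def from_tsv(cls, path: str) -> "PopulationDb":
        """4 columns: contig, pos (1-based), ref, alt."""
        db = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[1].lower() in ("pos", "position"):
                    continue
                db.add(parts[0], int(parts[1]), parts[2], parts[3])
        return db


def database_match(record: TrioVariantRecord, db: PopulationDb,
                   mode: str = "allele") -> bool:
    if mode == "allele":
        return record.key in db.alleles
    if mode == "position":
        return (record.contig, record.pos) in db.positions
    raise ValueError(f"unknown database match mode: {mode}")


def _low_complexity(seq: str, pos0: int, run_len: int) -> bool:
    """True if pos0 lies inside a homopolymer or dinucleotide tandem run of
    total length >= run_len in ``seq`` (0-based)."""
    n = len(seq)
    if not 0 <= pos0 < n:
        return False
    for unit in (1, 2):
        a = pos0
        while a - 1 >= 0 and a - 1 + unit < n and seq[a - 1] == seq[a - 1 + unit]:
            a -= 1
        b = pos0
        while b + unit < n and seq[b] == seq[b + unit]:
            b += 1
        if (b + unit) - a >= run_len:
            return True
    return False


@dataclass
class CascadeConfig:
    """Thresholds for the filter cascade (defaults per module docstring)."""

    min_qual: float = 50.0
    max_founder_dp: int = 300
    min_alt_fraction: float = 0.25
    min_dp: int = 3
    t_founder: int = 20
    t_parent: int = 20
    min_forward: int = 1
    min_reverse: int = 1
    max_parent_alt_reads: int = 1
    cluster_bp: int = 10
    run_length: int = 8
    reference: Mapping[str, str] | None = None
    snv_rules: tuple[str, ...] = DEFAULT_SNV_RULES
    indel_rules: tuple[str, ...] = DEFAULT_INDEL_RULES


@dataclass
class CascadeReport:
    """Machine twin of a per-rule survivor table."""

    variant_class: str
    n_input: int
    steps: list[tuple[str, str, int]]                 # (rule, description, survivors)
    survivors: list[TrioVariantRecord]
    trail: dict[tuple[str, int, str, str], list[tuple[str, bool]]]

    @property
    def counts(self) -> list[int]:
        return [n for _, _, n in self.steps]


def _rule_passes(rule: str, rec: TrioVariantRecord, db: PopulationDb | None,
                 cfg: CascadeConfig) -> bool:
    f = rec.founder
    fa, mo = rec.samples["father"], rec.samples["mother"]
    if rule == "R0":
        return rec.qual >= cfg.min_qual and f.dp <= cfg.max_founder_dp
    if rule == "R1":
        founder_has_alt = (f.gt_alt_count or 0) >= 1
        parents_clean = all(
            s.gt_alt_count == 0 and s.ad_alt <= cfg.max_parent_alt_reads
            for s in (fa, mo))
        return founder_has_alt and parents_clean and rec.present_in_caller2
    if rule == "R2":
        return db is None or not database_match(rec, db, "allele")
    if rule == "R3":
        return db is None or not database_match(rec, db, "position")
    if rule == "R4":
        if any(s.dp < cfg.min_dp for s in (fa, mo, f)):
            return False
        return f.dp > 0 and f.ad_alt / f.dp >= cfg.min_alt_fraction
    if rule == "R5":
        return pl_pattern_ok(f.pl, fa.pl, mo.pl, cfg.t_founder, cfg.t_parent)
    if rule == "R6":
        return f.adf_alt >= cfg.min_forward and f.adr_alt >= cfg.min_reverse
    if rule == "R14":
        return (_rule_passes("R1", rec, db, cfg)
                and _rule_passes("R4", rec, db, cfg))
    raise ValueError(f"unknown rule: {rule}")


def _apply_r7(survivors: list[TrioVariantRecord],
              cfg: CascadeConfig) -> tuple[list[TrioVariantRecord], set]:
    """Artifact screen: drop clustered candidates and candidates inside
    low-complexity reference runs."""
    dropped: set[tuple[str, int, str, str]] = set()
    by_contig: dict[str, list[TrioVariantRecord]] = {}
    for r in survivors:
        by_contig.setdefault(r.contig, []).append(r)
    for recs in by_contig.values():
        recs.sort(key=lambda r: r.pos)
        for i, r in enumerate(recs):
            if i > 0 and r.pos - recs[i - 1].pos <= cfg.cluster_bp:
                dropped.add(r.key)
                dropped.add(recs[i - 1].key)
    if cfg.reference is not None:
        for r in survivors:
            seq = cfg.reference.get(r.contig)
            if seq is not None and _low_complexity(seq, r.pos - 1, cfg.run_length):
                dropped.add(r.key)
    kept = [r for r in survivors if r.key not in dropped]
    return kept, dropped


def _run_cascade(records: list[TrioVariantRecord], db: PopulationDb | None,
                 cfg: CascadeConfig, rules: Sequence[str],
                 variant_class: str) -> CascadeReport:
    survivors = list(records)
    steps: list[tuple[str, str, int]] = []
    trail: dict = {r.key: [] for r in records}
    for rule in rules:
        if rule == "R7":
            kept, dropped = _apply_r7(survivors, cfg)
            for r in survivors:
                trail[r.key].append((rule, r.key not in dropped))
            survivors = kept
        else:
            kept = []
            for r in survivors:
                ok = _rule_passes(rule, r, db, cfg)
                trail[r.key].append((rule, ok))
                if ok:
                    kept.append(r)
            survivors = kept
        steps.append((rule, RULE_DESCRIPTIONS[rule], len(survivors)))
    return CascadeReport(variant_class=variant_class, n_input=len(records),
                         steps=steps, survivors=survivors, trail=trail)


def apply_cascade(
    records: Sequence[TrioVariantRecord],
    db: PopulationDb | None = None,
    config: CascadeConfig | None = None,
) -> dict[str, CascadeReport]:
    """Run the SNV and indel cascades; returns {"SNV": ..., "indel": ...}.

    Survivor counts are recorded after every rule and are non-increasing.
    Empty input yields all-zero reports.
    """
    cfg = config or CascadeConfig()
    snvs = [r for r in records if r.variant_class == "SNV"]
    indels = [r for r in records if r.variant_class == "indel"]
    return {
        "SNV": _run_cascade(snvs, db, cfg, cfg.snv_rules, "SNV"),
        "indel": _run_cascade(indels, db, cfg, cfg.indel_rules, "indel"),
    }


# ---------------------------------------------------------------------------
# output


def report_to_tsv(report: CascadeReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("rule\tdescription\tsurvivors\n")
        fh.write(f"input\t{report.variant_class} records\t{report.n_input}\n")
        for rule, desc, n in report.steps:
            fh.write(f"{rule}\t{desc}\t{n}\n")


def trail_to_tsv(report: CascadeReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\trule\tpassed\n")
        for (contig, pos, ref, alt), steps in report.trail.items():
            for rule, ok in steps:
                fh.write(f"{contig}\t{pos}\t{ref}\t{alt}\t{rule}\t{int(ok)}\n")


def write_candidates_vcf(survivors: Sequence[TrioVariantRecord], path: str,
                         contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write surviving candidates as a minimal trio VCF."""
    hdr = pysam.VariantHeader()
    contigs = dict(contig_lengths or {})
    for r in survivors:
        contigs.setdefault(r.contig, r.pos + len(r.ref) + 1000)
    for name, length in contigs.items():
        hdr.add_line(f'##contig=<ID={name},length={length}>')
    hdr.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    hdr.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    hdr.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    hdr.add_line('##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Genotype likelihoods">')
    for role in ROLES:
        hdr.add_sample(role)
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), None: (None,)}
    with pysam.VariantFile(path, "w", header=hdr) as vf:
        for r in sorted(survivors, key=lambda r: (r.contig, r.pos)):
            rec = vf.new_record(contig=r.contig, start=r.pos - 1,
                                alleles=(r.ref, r.alt))
            rec.qual = r.qual
            for role in ROLES:
                s = r.samples[role]
                rec.samples[role]["GT"] = gt_of.get(s.gt_alt_count, (None,))
                rec.samples[role]["DP"] = s.dp
                rec.samples[role]["AD"] = (s.ad_ref, s.ad_alt)
                rec.samples[role]["PL"] = s.pl
            vf.write(rec)
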