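"""Synthetic trio data generator.

Produces everything the downstream analysis consumes: a random genome with
planted guide target / off-target loci, a father-mother-founder trio with
inherited variants, spontaneous de novo SNVs, Cas9 on-target edits and
(optionally) off-target-induced variants clustered around predicted cut
sites, per-sample read evidence with phred-scaled genotype likelihoods, and
the file formats of a real pipeline run: two caller VCFs, a truth table,
planted-site BED, structural-variant call-set TSVs and copy-number segment
TSVs.

The read-evidence model is deliberately simple: depth is Poisson, each read
reports the alternate allele with probability e, 1/2 or 1-e for the three
diploid genotypes (e = per-read error), strands are fair coin flips, and
PLs are the exact phred-scaled likelihoods of that emission model.  This is
analytically checkable and exercises every downstream filtering rule.

All randomness is a pure function of ``SimConfig.seed``.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pysam

from .offtarget import GuideSpec, IUPAC, reverse_complement

__all__ = [
    "SimConfig",
    "EditSpec",
    "PlantedSite",
    "TruthRow",
    "TrioVariant",
    "Evidence",
    "PlacementError",
    "generate_genome",
    "implant_guide_sites",
    "simulate_trio",
    "simulate_read_evidence",
    "emit_outputs",
    "simulate_sv_callsets",
    "simulate_cn_segments",
    "write_fasta",
]

SAMPLES = ("father", "mother", "founder")

ORIGIN_INHERITED = "inherited"
ORIGIN_SPONTANEOUS = "spontaneous_dnm"
ORIGIN_ON_TARGET = "on_target_edit"
ORIGIN_INDUCED = "offtarget_induced"


class PlacementError(RuntimeError):
    """Raised when requested features cannot be placed without collisions."""


@dataclass(frozen=True)
class EditSpec:
    """An intended on-target edit: an indel planted at a guide's cut site."""

    guide_id: str
    kind: str = "del"      # "del" or "ins"
    length: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("del", "ins"):
            raise ValueError("edit kind must be 'del' or 'ins'")
        if self.length < 1:
            raise ValueError("edit length must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated trio.

    ``mu_dnm`` is the de novo mutation rate per haploid base per generation;
    the founder receives Poisson(2 * mu_dnm * genome_length) spontaneous
    heterozygous SNVs.  ``offtarget_induced_rate`` is the per-planted-site
    probability of one induced heterozygous variant at
    cut_site + round(Normal(0, induced_distance_sd)).
    """

    genome_length: int = 1_000_000
    n_contigs: int = 1
    gc_fraction: float = 0.42
    seed: int = 0
    mu_dnm: float = 1e-8
    n_inherited: int = 100
    offtarget_induced_rate: float = 0.0
    induced_distance_sd: float = 20.0
    mean_depth: float = 25.0
    base_error: float = 0.005
    caller2_discordance: float = 0.02
    edit_config: tuple[EditSpec, ...] = ()
    plant_inversion: bool = False
    n_scaffold_contigs: int = 0
    scaffold_length: int = 5_000

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10,000")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if not 0 <= self.base_error < 0.5:
            raise ValueError("base_error must be in [0, 0.5)")
        if self.n_contigs < 1 or self.genome_length // self.n_contigs < 100:
            raise ValueError("n_contigs invalid for genome_length")
        for p in ("mu_dnm", "offtarget_induced_rate", "caller2_discordance"):
            v = getattr(self, p)
            if v < 0 or (p != "mu_dnm" and v > 1):
                raise ValueError(f"{p} out of range: {v}")
        if self.n_inherited < 0:
            raise ValueError("n_inherited must be >= 0")
        object.__setattr__(self, "edit_config", tuple(self.edit_config))


@dataclass(frozen=True)
class PlantedSite:
    """Ground-truth record of one implanted guide-matching locus."""

    site_id: str
    guide_id: str
    contig: str
    start: int            # protospacer interval, 0-based half-open
    end: int
    strand: str
    m_seed: int
    m_nonseed: int
    cut_site: int

    @property
    def m_total(self) -> int:
        return self.m_seed + self.m_nonseed


@dataclass(frozen=True)
class TruthRow:
    contig: str
    pos: int              # 0-based position of the VCF anchor base
    ref: str
    alt: str
    origin: str
    site_id: str | None = None


@dataclass
class TrioVariant:
    """One variant site with true diploid genotypes (alt-allele counts)."""

    contig: str
    pos: int              # 0-based anchor
    ref: str
    alt: str
    origin: str
    site_id: str | None
    gt: dict[str, int]    # sample -> 0/1/2 alt-allele count

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class Evidence:
    """Simulated per-sample read evidence at one biallelic site."""

    dp: int
    ad: tuple[int, int]       # (ref, alt)
    adf: tuple[int, int]      # forward-strand (ref, alt)
    adr: tuple[int, int]      # reverse-strand (ref, alt)
    pl: tuple[int, int, int]  # (AA, AB, BB), normalized to min 0


# ---------------------------------------------------------------------------
# genome


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=n, p=probs)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode("ascii")


def generate_genome(config: SimConfig) -> dict[str, str]:
    """Random genome: ``n_contigs`` primary contigs (chr1..) summing to
    ``genome_length``, plus optional decoy contigs named ``scaffold_*``."""
    rng = np.random.default_rng(config.seed)
    base = config.genome_length // config.n_contigs
    lengths = [base] * config.n_contigs
    lengths[0] += config.genome_length - base * config.n_contigs
    genome: dict[str, str] = {}
    for i, L in enumerate(lengths, start=1):
        genome[f"chr{i}"] = _random_seq(rng, L, config.gc_fraction)
    for j in range(1, config.n_scaffold_contigs + 1):
        genome[f"scaffold_{j}"] = _random_seq(rng, config.scaffold_length,
                                              config.gc_fraction)
    return genome


def write_fasta(genome: Mapping[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# site implantation


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


def _realize_pam(rng: np.random.Generator, pattern: str) -> str:
    return "".join(IUPAC[ch][rng.integers(len(IUPAC[ch]))] for ch in pattern)


def _build_site_seq(rng: np.random.Generator, guide: GuideSpec,
                    m_seed: int, m_nonseed: int) -> str:
    """Protospacer+PAM with exactly the requested mismatch counts."""
    proto = list(guide.protospacer)
    seed_start = 20 - guide.seed_length
    seed_idx = list(range(seed_start, 20))
    nonseed_idx = list(range(seed_start))
    if m_seed > len(seed_idx) or m_nonseed > len(nonseed_idx):
        raise ValueError("mismatch class exceeds region size")
    for i in rng.choice(seed_idx, size=m_seed, replace=False) if m_seed else []:
        proto[i] = _mutate_base(rng, proto[i])
    for i in rng.choice(nonseed_idx, size=m_nonseed, replace=False) if m_nonseed else []:
        proto[i] = _mutate_base(rng, proto[i])
    return "".join(proto) + _realize_pam(rng, guide.pam_pattern)


def implant_guide_sites(
    genome: Mapping[str, str],
    guide: GuideSpec,
    class_counts: Mapping[tuple[int, int], int],
    seed: int,
    min_separation: int = 200,
    max_tries: int = 10_000,
) -> tuple[dict[str, str], list[PlantedSite]]:
    """Write guide-matching loci into the genome.

    For each ``(m_seed, m_nonseed) -> count`` entry, plants that many
    protospacer+PAM occurrences (random strand, random non-overlapping
    positions on primary contigs) carrying exactly the requested seed and
    non-seed mismatch counts.  Returns the modified genome and the planted
    site records.
    """
    rng = np.random.default_rng(seed)
    work = {name: list(seq) for name, seq in genome.items()}
    primary = [c for c in genome if not c.startswith("scaffold")]
    weights = np.array([len(genome[c]) for c in primary], dtype=float)
    weights /= weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    span = guide.site_length
    planted: list[PlantedSite] = []
    counter = 0
    for (ms, mn), count in sorted(class_counts.items()):
        for _ in range(count):
            for attempt in range(max_tries):
                contig = primary[rng.choice(len(primary), p=weights)]
                L = len(genome[contig])
                if L < span + 2 * min_separation:
                    continue
                pos = int(rng.integers(min_separation, L - span - min_separation))
                lo, hi = pos - min_separation, pos + span + min_separation
                if any(s < hi and lo < e for s, e in occupied[contig]):
                    continue
                break
            else:
                raise PlacementError(
                    f"could not place site class ({ms},{mn}) after {max_tries} tries")
            strand = "+" if rng.random() < 0.5 else "-"
            site_seq = _build_site_seq(rng, guide, ms, mn)
            insert = site_seq if strand == "+" else reverse_complement(site_seq)
            work[contig][pos : pos + span] = list(insert)
            occupied[contig].append((pos, pos + span))
            if strand == "+":
                start, end = pos, pos + 20
                cut = start + 17
            else:
                start, end = pos + guide.pam_length, pos + span
                cut = start + 3
            counter += 1
            planted.append(PlantedSite(
                site_id=f"{guide.id}_site{counter}", guide_id=guide.id,
                contig=contig, start=start, end=end, strand=strand,
                m_seed=ms, m_nonseed=mn, cut_site=cut))
    return {name: "".join(chars) for name, chars in work.items()}, planted


def implant_site_at(
    genome: Mapping[str, str],
    guide: GuideSpec,
    contig: str,
    pos: int,
    strand: str = "+",
    m_seed: int = 0,
    m_nonseed: int = 0,
    seed: int = 0,
    site_id: str | None = None,
) -> tuple[dict[str, str], PlantedSite]:
    """Plant a single guide-matching locus at an explicit position.

    ``pos`` is the 0-based start of the 23-bp protospacer+PAM footprint on
    the forward strand.  Used when the geometry (e.g. an exact cut-site
    gap) must be controlled.
    """
    rng = np.random.default_rng(seed)
    span = guide.site_length
    if not 0 <= pos <= len(genome[contig]) - span:
        raise PlacementError(f"site does not fit at {contig}:{pos}")
    site_seq = _build_site_seq(rng, guide, m_seed, m_nonseed)
    insert = site_seq if strand == "+" else reverse_complement(site_seq)
    seq = genome[contig]
    new = dict(genome)
    new[contig] = seq[:pos] + insert + seq[pos + span:]
    if strand == "+":
        start, end = pos, pos + 20
        cut = start + 17
    else:
        start, end = pos + guide.pam_length, pos + span
        cut = start + 3
    site = PlantedSite(site_id=site_id or f"{guide.id}_at_{contig}_{pos}",
                       guide_id=guide.id, contig=contig, start=start, end=end,
                       strand=strand, m_seed=m_seed, m_nonseed=m_nonseed,
                       cut_site=cut)
    return new, site


# ---------------------------------------------------------------------------
# trio simulation


def _draw_positions(rng: np.random.Generator, genome: Mapping[str, str],
                    n: int, used: set[tuple[str, int]],
                    max_tries: int = 100) -> list[tuple[str, int]]:
    contigs = [c for c in genome if not c.startswith("scaffold")]
    lens = np.array([len(genome[c]) for c in contigs], dtype=float)
    probs = lens / lens.sum()
    out = []
    for _ in range(n):
        for _ in range(max_tries):
            ci = rng.choice(len(contigs), p=probs)
            contig = contigs[ci]
            pos = int(rng.integers(1, len(genome[contig]) - 1))
            if (contig, pos) not in used and genome[contig][pos] in "ACGT":
                used.add((contig, pos))
                out.append((contig, pos))
                break
        else:
            raise PlacementError("could not place variant without collision")
    return out


def simulate_trio(
    genome: Mapping[str, str],
    config: SimConfig,
    planted_sites: Sequence[PlantedSite] = (),
) -> tuple[list[TrioVariant], list[TruthRow]]:
    """Simulate true genotypes for a father-mother-founder trio.

    Parents carry ``n_inherited`` heterozygous variants at random positions,
    each transmitted to the founder by a fair Mendelian coin flip.  The
    founder additionally receives spontaneous de novo SNVs (Poisson mean
    2*mu_dnm*genome_length), the configured on-target edits, and, per
    planted site with probability ``offtarget_induced_rate``, one induced
    heterozygous SNV near the cut site.

    Returns all variant sites (including untransmitted parental ones) and
    the truth table, which lists exactly the founder's non-reference alleles.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    used: set[tuple[str, int]] = set()
    variants: list[TrioVariant] = []

    # inherited heterozygous variants, one random parent each
    for contig, pos in _draw_positions(rng, genome, config.n_inherited, used):
        ref = genome[contig][pos]
        alt = _mutate_base(rng, ref)
        parent = SAMPLES[rng.integers(2)]
        transmitted = rng.random() < 0.5
        gt = {s: 0 for s in SAMPLES}
        gt[parent] = 1
        gt["founder"] = 1 if transmitted else 0
        variants.append(TrioVariant(contig, pos, ref, alt, ORIGIN_INHERITED,
                                    None, gt))

    # spontaneous de novo SNVs in the founder
    n_dnm = rng.poisson(2.0 * config.mu_dnm * config.genome_length)
    for contig, pos in _draw_positions(rng, genome, int(n_dnm), used):
        ref = genome[contig][pos]
        alt = _mutate_base(rng, ref)
        gt = {"father": 0, "mother": 0, "founder": 1}
        variants.append(TrioVariant(contig, pos, ref, alt, ORIGIN_SPONTANEOUS,
                                    None, gt))

    # on-target edits: indels at the cut site of the guide's exact site
    exact = {s.guide_id: s for s in planted_sites if s.m_total == 0}
    for edit in config.edit_config:
        site = exact.get(edit.guide_id)
        if site is None:
            raise PlacementError(
                f"edit for guide {edit.guide_id!r} requires a planted exact site")
        contig, cut = site.contig, site.cut_site
        anchor = cut - 1
        if edit.kind == "del":
            ref = genome[contig][anchor : anchor + edit.length + 1]
            alt = ref[0]
        else:
            ref = genome[contig][anchor]
            alt = ref + _random_seq(rng, edit.length, 0.5)
        for p in range(anchor, anchor + len(ref)):
            used.add((contig, p))
        gt = {"father": 0, "mother": 0, "founder": 1}
        variants.append(TrioVariant(contig, anchor, ref, alt,
                                    ORIGIN_ON_TARGET, site.site_id, gt))

    # off-target-induced variants around planted cut sites
    for site in planted_sites:
        if rng.random() >= config.offtarget_induced_rate:
            continue
        contig = site.contig
        L = len(genome[contig])
        for _ in range(100):
            offset = int(round(rng.normal(0.0, config.induced_distance_sd)))
            pos = site.cut_site + offset
            if 1 <= pos < L - 1 and (contig, pos) not in used \
                    and genome[contig][pos] in "ACGT":
                break
        else:
            raise PlacementError(f"could not place induced variant at {site.site_id}")
        used.add((contig, pos))
        ref = genome[contig][pos]
        alt = _mutate_base(rng, ref)
        gt = {"father": 0, "mother": 0, "founder": 1}
        variants.append(TrioVariant(contig, pos, ref, alt, ORIGIN_INDUCED,
                                    site.site_id, gt))

    variants.sort(key=lambda v: (v.contig, v.pos))
    truth = [TruthRow(v.contig, v.pos, v.ref, v.alt, v.origin, v.site_id)
             for v in variants if v.gt["founder"] > 0]
    return variants, truth


# ---------------------------------------------------------------------------
# read evidence


def _phred_pl(n_alt: int, n_ref: int, base_error: float) -> tuple[int, int, int]:
    """Exact PLs for the binomial emission model, normalized to min 0."""
    e = max(base_error, 1e-12)
    p_alt = {0: e, 1: 0.5, 2: 1.0 - e}
    raw = []
    for g in (0, 1, 2):
        p = p_alt[g]
        log10_l = n_alt * math.log10(p) + n_ref * math.log10(1.0 - p)
        raw.append(round(-10.0 * log10_l))
    m = min(raw)
    return tuple(int(v - m) for v in raw)  # type: ignore[return-value]


def simulate_read_evidence(
    genotype: int,
    mean_depth: float,
    base_error: float,
    rng: np.random.Generator,
) -> Evidence:
    """Draw read evidence for a diploid genotype (0=AA, 1=AB, 2=BB).

    Depth ~ Poisson(mean_depth) truncated to >= 1; each read is the
    alternate allele with probability e, 1/2, 1-e respectively; strand is a
    fair coin per read.  PLs are exact for this emission model.
    """
    dp = 0
    while dp < 1:
        dp = int(rng.poisson(mean_depth))
    p_alt = {0: base_error, 1: 0.5, 2: 1.0 - base_error}[genotype]
    n_alt = int(rng.binomial(dp, p_alt))
    n_ref = dp - n_alt
    alt_f = int(rng.binomial(n_alt, 0.5))
    ref_f = int(rng.binomial(n_ref, 0.5))
    pl = _phred_pl(n_alt, n_ref, base_error)
    return Evidence(
        dp=dp,
        ad=(n_ref, n_alt),
        adf=(ref_f, alt_f),
        adr=(n_ref - ref_f, n_alt - alt_f),
        pl=pl,
    )


# ---------------------------------------------------------------------------
# output emission


def _vcf_header(genome: Mapping[str, str]) -> pysam.VariantHeader:
    hdr = pysam.VariantHeader()
    hdr.add_line('##source=crisprtrio-sim')
    for name, seq in genome.items():
        hdr.add_line(f'##contig=<ID={name},length={len(seq)}>')
    hdr.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    hdr.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    hdr.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    hdr.add_line('##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="Forward-strand allelic depths">')
    hdr.add_line('##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="Reverse-strand allelic depths">')
    hdr.add_line('##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">')
    for s in SAMPLES:
        hdr.add_sample(s)
    return hdr


_GT_TUPLE = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def emit_outputs(
    genome: Mapping[str, str],
    variants: Sequence[TrioVariant],
    truth: Sequence[TruthRow],
    planted_sites: Sequence[PlantedSite],
    config: SimConfig,
    outdir: str,
    founder_id: str = "founder1",
) -> dict[str, str]:
    """Simulate read evidence for every variant site and write all files.

    Writes: genome FASTA, caller-1 VCF (all records), caller-2 VCF (records
    independently dropped with probability ``caller2_discordance``), truth
    TSV, planted-site BED, SV call-set TSV and copy-number segment TSV.
    Returns a path map.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "caller1_vcf": os.path.join(outdir, "caller1.vcf"),
        "caller2_vcf": os.path.join(outdir, "caller2.vcf"),
        "truth_tsv": os.path.join(outdir, "truth.tsv"),
        "sites_bed": os.path.join(outdir, "planted_sites.bed"),
        "sv_tsv": os.path.join(outdir, "sv_calls.tsv"),
        "cn_tsv": os.path.join(outdir, "cn_segments.tsv"),
    }
    write_fasta(genome, paths["fasta"])

    order = {c: i for i, c in enumerate(genome)}
    recs = sorted(variants, key=lambda v: (order[v.contig], v.pos))
    evidence: list[dict[str, Evidence]] = []
    for v in recs:
        evidence.append({s: simulate_read_evidence(
            v.gt[s], config.mean_depth, config.base_error, rng) for s in SAMPLES})

    keep2 = rng.random(len(recs)) >= config.caller2_discordance

    for path, mask in ((paths["caller1_vcf"], None), (paths["caller2_vcf"], keep2)):
        hdr = _vcf_header(genome)
        with pysam.VariantFile(path, "w", header=hdr) as vf:
            for i, v in enumerate(recs):
                if mask is not None and not mask[i]:
                    continue
                rec = vf.new_record(
                    contig=v.contig, start=v.pos, alleles=(v.ref, v.alt))
                # site quality: phred evidence against everyone being hom-ref
                rec.qual = float(max(ev.pl[0] for ev in evidence[i].values()))
                for s in SAMPLES:
                    ev = evidence[i][s]
                    rec.samples[s]["GT"] = _GT_TUPLE[v.gt[s]]
                    rec.samples[s]["DP"] = ev.dp
                    rec.samples[s]["AD"] = ev.ad
                    rec.samples[s]["ADF"] = ev.adf
                    rec.samples[s]["ADR"] = ev.adr
                    rec.samples[s]["PL"] = ev.pl
                vf.write(rec)

    with open(paths["truth_tsv"], "w") as fh:
        fh.write("contig\tpos\tref\talt\torigin\tsite_id\n")
        for t in truth:
            fh.write(f"{t.contig}\t{t.pos + 1}\t{t.ref}\t{t.alt}\t{t.origin}\t"
                     f"{t.site_id or '.'}\n")

    with open(paths["sites_bed"], "w") as fh:
        for s in planted_sites:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.site_id}\t"
                     f"{s.m_total}\t{s.strand}\n")

    sv_rows = simulate_sv_callsets(genome, planted_sites, config, founder_id,
                                   np.random.default_rng(np.random.SeedSequence([config.seed, 3])))
    with open(paths["sv_tsv"], "w") as fh:
        fh.write("caller\tfounder\ttype\tcontig\tstart\tend\tsupporting_fraction\n")
        for row in sv_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    cn_rows = simulate_cn_segments(genome)
    with open(paths["cn_tsv"], "w") as fh:
        fh.write("sample\tcontig\tstart\tend\tcopy_number\n")
        for row in cn_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    return paths


def simulate_sv_callsets(
    genome: Mapping[str, str],
    planted_sites: Sequence[PlantedSite],
    config: SimConfig,
    founder_id: str,
    rng: np.random.Generator,
    breakpoint_offsets: tuple[int, int] = (-8, 2),
    other_founders: tuple[str, ...] = ("founder2", "founder3"),
) -> list[tuple]:
    """SV call-set rows: the planted inversion plus decoys.

    When ``plant_inversion`` is set and two exact-match sites share a
    contig, an inversion is emitted for ``founder_id`` with breakpoints at
    the two cut sites shifted by ``breakpoint_offsets`` (the asymmetric
    offsets NHEJ repair leaves around paired blunt cuts).  Decoys: a
    deletion shared by all founders, a scaffold-contig deletion, a distant
    inversion and a low-support duplication.
    """
    rows: list[tuple] = []
    founders = (founder_id,) + other_founders
    exact = [s for s in planted_sites if s.m_total == 0]
    if config.plant_inversion and len(exact) >= 2:
        by_contig: dict[str, list[PlantedSite]] = {}
        for s in exact:
            by_contig.setdefault(s.contig, []).append(s)
        pair = next((sorted(v, key=lambda s: s.cut_site)[:2]
                     for v in by_contig.values() if len(v) >= 2), None)
        if pair is not None:
            c1, c2 = pair[0].cut_site, pair[1].cut_site
            rows.append(("lumpy", founder_id, "INV", pair[0].contig,
                         c1 + breakpoint_offsets[0], c2 + breakpoint_offsets[1],
                         0.9))
    primary = [c for c in genome if not c.startswith("scaffold")]
    contig = primary[0]
    L = len(genome[contig])
    # shared deletion: identical in every founder
    s0 = int(rng.integers(0, max(1, L - 20_000)))
    for f in founders:
        rows.append(("breakdancer", f, "DEL", contig, s0, s0 + 5_000, 0.8))
    # scaffold-contig call
    scaffolds = [c for c in genome if c.startswith("scaffold")]
    if scaffolds:
        rows.append(("breakdancer", founder_id, "DEL", scaffolds[0], 100, 1_100, 0.9))
    # distant inversion, unique and well-supported but far from any cut pair
    s1 = int(rng.integers(0, max(1, L - 60_000)))
    rows.append(("lumpy", founder_id, "INV", contig, s1 + 40_000, s1 + 50_000, 0.85))
    # low-support duplication
    s2 = int(rng.integers(0, max(1, L - 30_000)))
    rows.append(("breakdancer", founder_id, "DUP", contig, s2, s2 + 2_000, 0.2))
    return rows


def simulate_cn_segments(
    genome: Mapping[str, str],
    denovo: Sequence[tuple[str, int, int, int]] = (),
    inherited: Sequence[tuple[str, str, int, int, int]] = (),
) -> list[tuple]:
    """Copy-number segment rows for the trio.

    Baseline: every sample diploid (CN 2) across each primary contig.
    ``denovo``: (contig, start, end, founder_cn) segments where the founder
    deviates and both parents stay at 2.  ``inherited``: (parent, contig,
    start, end, cn) segments shared by the named parent and the founder.
    """
    rows: list[tuple] = []
    events: dict[str, list[tuple[int, int, int]]] = {s: [] for s in SAMPLES}
    for contig, start, end, cn in denovo:
        events["founder"].append((contig, start, end, cn))  # type: ignore[arg-type]
    for parent, contig, start, end, cn in inherited:
        events[parent].append((contig, start, end, cn))  # type: ignore[arg-type]
        events["founder"].append((contig, start, end, cn))  # type: ignore[arg-type]
    for sample in SAMPLES:
        for contig, seq in genome.items():
            if contig.startswith("scaffold"):
                continue
            L = len(seq)
            evs = sorted(e for e in events[sample] if e[0] == contig)
            cursor = 0
            for c, start, end, cn in evs:  # type: ignore[misc]
                if start > cursor:
                    rows.append((sample, contig, cursor, start, 2))
                rows.append((sample, contig, start, end, cn))
                cursor = end
            if cursor < L:
                rows.append((sample, contig, cursor, L, 2))
    return rows
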