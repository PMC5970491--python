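"""Shared fixtures: small genomes, guides, a hand-built cascade fixture
and the independent brute-force off-target oracle."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from crisprtrio import GuideSpec, SimConfig, generate_genome
from crisprtrio.offtarget import IUPAC, reverse_complement


@pytest.fixture(scope="session")
def guide() -> GuideSpec:
    return GuideSpec("sg1", "GACCTTGAGCAAGTCTTACG", gene="MSTN")


@pytest.fixture(scope="session")
def small_genome() -> dict[str, str]:
    return generate_genome(SimConfig(genome_length=50_000, seed=3))


# ---------------------------------------------------------------------------
# independent brute-force off-target oracle (string comparison per position)


def brute_force_scan(genome, guide, max_seed_mm=1, max_nonseed_mm=4,
                     max_total_mm=5):
    """Per-position string-comparison scan; independent of the package's
    vectorized implementation."""
    hits = set()
    proto = guide.protospacer
    seed_start = 20 - guide.seed_length
    pam = guide.pam_pattern
    span = 20 + len(pam)
    for contig, seq in genome.items():
        seq = seq.upper()
        L = len(seq)
        for strand in "+-":
            target = seq if strand == "+" else reverse_complement(seq)
            for i in range(L - span + 1):
                ok_pam = all(target[i + 20 + j] in IUPAC[pam[j]]
                             for j in range(len(pam)))
                if not ok_pam:
                    continue
                ms = mn = 0
                for k in range(20):
                    if target[i + k] != proto[k]:
                        if k >= seed_start:
                            ms += 1
                        else:
                            mn += 1
                if ms <= max_seed_mm and mn <= max_nonseed_mm \
                        and ms + mn <= max_total_mm:
                    if strand == "+":
                        hits.add((contig, i, i + 20, "+", ms, mn))
                    else:
                        hits.add((contig, L - (i + 20), L - i, "-", ms, mn))
    return hits


@pytest.fixture(scope="session")
def brute_scan():
    return brute_force_scan


# ---------------------------------------------------------------------------
# hand-built 8-record cascade fixture


def _trio_vcf_header(contig: str, length: int) -> pysam.VariantHeader:
    hdr = pysam.VariantHeader()
    hdr.add_line(f'##contig=<ID={contig},length={length}>')
    for line in (
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">',
        '##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="ADF">',
        '##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="ADR">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="PL">',
    ):
        hdr.add_line(line)
    for s in ("father", "mother", "founder"):
        hdr.add_sample(s)
    return hdr


GOOD_FOUNDER = dict(gt=(0, 1), dp=30, ad=(15, 15), adf=(8, 8), adr=(7, 7),
                    pl=(200, 0, 180))
GOOD_PARENT = dict(gt=(0, 0), dp=30, ad=(30, 0), adf=(15, 0), adr=(15, 0),
                   pl=(0, 90, 600))


def _write_rec(vf, contig, pos1, ref, alt, founder=None, father=None,
               mother=None, qual=200.0):
    founder = {**GOOD_FOUNDER, **(founder or {})}
    father = {**GOOD_PARENT, **(father or {})}
    mother = {**GOOD_PARENT, **(mother or {})}
    rec = vf.new_record(contig=contig, start=pos1 - 1, alleles=(ref, alt))
    rec.qual = qual
    for name, data in (("father", father), ("mother", mother),
                       ("founder", founder)):
        s = rec.samples[name]
        s["GT"] = data["gt"]
        s["DP"] = data["dp"]
        s["AD"] = data["ad"]
        s["ADF"] = data["adf"]
        s["ADR"] = data["adr"]
        s["PL"] = data["pl"]
    vf.write(rec)


def build_cascade_fixture(dirpath):
    """Eight SNV records on a synthetic reference, one passing every rule
    and seven failing exactly one of R1..R7 in order.

    Returns (caller1_path, caller2_path, db_keys, reference).
    """
    import os
    rng = np.random.default_rng(99)
    # non-repetitive reference, with a homopolymer island for the R7 record
    bases = "ACGT"
    seq = list("ACGT" * 500)  # period-4: no homopolymer/dinucleotide runs
    rng.shuffle(seq)  # shuffling may create short runs; fix the R7 island after
    seq = "".join(seq)
    r7_pos = 1500  # 1-based record position; embed a 9-bp homopolymer there
    seq = seq[: r7_pos - 3] + "AAAAAAAAA" + seq[r7_pos + 6:]
    reference = {"chr1": seq}

    positions = [100, 200, 300, 400, 500, 600, 700, r7_pos]
    recs = []  # (pos, ref, alt, founder-override, father-override, in_caller2)
    for i, p in enumerate(positions):
        ref = reference["chr1"][p - 1]
        alt = "G" if ref != "G" else "C"
        recs.append([p, ref, alt, {}, {}, True])
    recs[1][5] = False                                     # fails R1 (caller 2)
    db = {("chr1", recs[2][0], recs[2][1], recs[2][2]),    # fails R2 (allele)
          ("chr1", recs[3][0], recs[3][1], "T" if recs[3][2] != "T" else "A")}
    #                                                      # fails R3 (position)
    recs[4][3] = dict(dp=11, ad=(9, 2), adf=(5, 1), adr=(4, 1))   # R4: AF < 25%
    recs[5][3] = dict(pl=(20, 0, 5))                       # fails R5 (boundary)
    recs[6][3] = dict(ad=(15, 15), adf=(8, 0), adr=(7, 15))       # fails R6
    # recs[7] sits in the homopolymer -> fails R7

    c1 = os.path.join(str(dirpath), "caller1.vcf")
    c2 = os.path.join(str(dirpath), "caller2.vcf")
    for path, keep_all in ((c1, True), (c2, False)):
        hdr = _trio_vcf_header("chr1", len(seq))
        with pysam.VariantFile(path, "w", header=hdr) as vf:
            for p, ref, alt, fo, fa, in_c2 in recs:
                if not keep_all and not in_c2:
                    continue
                _write_rec(vf, "chr1", p, ref, alt, founder=fo, father=fa)
    return c1, c2, db, reference


@pytest.fixture()
def cascade_fixture(tmp_path):
    return build_cascade_fixture(tmp_path)
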