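"""Shared fixtures: handcrafted BAM writer and simulated datasets.

The two statistical fixtures keep the multi-donor study conditions
(4 donors × 50 cells with ten fixed markers each; 8 donors × 100 cells
with one μ=0.10 heteroplasmy each; ~50× per-cell coverage, error 1e-3)
on a shortened contig so the suite stays fast; per-cell depth at every
tested position is unchanged by the shorter contig.
"""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from mitovar import (
    DonorLabels,
    MitoReference,
    SimulationConfig,
    build_matrices,
    calc_allele_frequency,
    pileup_droplet,
    pileup_well,
    simulate_dataset,
)


def write_bam(path: Path, reads: list[dict], contig: str = "chrM", length: int = 1000) -> Path:
    """Write a coordinate-sorted, indexed BAM from plain dicts.

    Each read dict: name, start (0-based), seq, and optionally qual
    (Phred ints or uniform int), cigar (string), flag, mapq, tags.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": contig, "LN": length}]}
    hdr = pysam.AlignmentHeader.from_dict(header)
    segs = []
    for r in reads:
        seg = pysam.AlignedSegment(hdr)
        seg.query_name = r["name"]
        seg.query_sequence = r["seq"]
        seg.flag = r.get("flag", 0)
        unmapped = bool(seg.flag & 0x4)
        if not unmapped:
            seg.reference_id = 0
            seg.reference_start = r["start"]
            seg.cigarstring = r.get("cigar", f"{len(r['seq'])}M")
            seg.mapping_quality = r.get("mapq", 60)
        qual = r.get("qual", 30)
        if isinstance(qual, int):
            qual = [qual] * len(r["seq"])
        seg.query_qualities = qual
        for tag, val in r.get("tags", {}).items():
            seg.set_tag(tag, val)
        segs.append((length + 1 if unmapped else r["start"], seg))
    segs.sort(key=lambda t: t[0])
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for _, seg in segs:
            bam.write(seg)
    pysam.index(str(path))
    return path


@pytest.fixture(scope="session")
def tiny_reference() -> MitoReference:
    # 1000 bp repeating ACGT with one N at position 101 (1-based)
    seq = ("ACGT" * 250)[:1000]
    seq = seq[:100] + "N" + seq[101:]
    return MitoReference(contig_name="chrM", sequence=seq)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Cheap 2-donor well-based dataset for plumbing tests."""
    cfg = SimulationConfig(
        seed=5, n_donors=2, cells_per_donor=6, reads_per_cell=400,
        reference_length=1500, read_length=100, error_rate=1e-3,
        n_germline_per_donor=3, n_heteroplasmies_per_donor=1,
    )
    return simulate_dataset(cfg, tmp_path_factory.mktemp("small"))


@pytest.fixture(scope="session")
def germline_dataset(tmp_path_factory):
    """4 donors × 50 cells, 10 exclusive fixed markers each, ~50× coverage."""
    cfg = SimulationConfig(
        seed=11, n_donors=4, cells_per_donor=50, reads_per_cell=1500,
        reference_length=3000, read_length=100, error_rate=1e-3,
        n_germline_per_donor=10, n_heteroplasmies_per_donor=0,
    )
    return simulate_dataset(cfg, tmp_path_factory.mktemp("germline"))


@pytest.fixture(scope="session")
def germline_matrices(germline_dataset):
    ds = germline_dataset
    tensors, index = pileup_well(ds.bam_paths, ds.reference)
    alt, cov = build_matrices(tensors, ds.reference, index)
    af = calc_allele_frequency(alt, cov)
    labels = DonorLabels.from_tsv(ds.labels_path)
    return alt, cov, af, index, labels


@pytest.fixture(scope="session")
def het_dataset(tmp_path_factory):
    """8 donors × 100 cells, one μ=0.10 heteroplasmy per donor, droplet layout."""
    cfg = SimulationConfig(
        seed=12, n_donors=8, cells_per_donor=100, reads_per_cell=1000,
        reference_length=2000, read_length=100, error_rate=1e-3,
        layout="droplet", n_germline_per_donor=10, n_heteroplasmies_per_donor=1,
        heteroplasmy_mean_af=0.10, heteroplasmy_dispersion=0.05,
    )
    return simulate_dataset(cfg, tmp_path_factory.mktemp("het"))


@pytest.fixture(scope="session")
def het_matrices(het_dataset):
    ds = het_dataset
    whitelist = ds.whitelist_path.read_text().split()
    tensors, index = pileup_droplet(
        ds.bam_paths[0], ds.reference, whitelist=whitelist
    )
    alt, cov = build_matrices(tensors, ds.reference, index)
    af = calc_allele_frequency(alt, cov)
    labels = DonorLabels.from_tsv(ds.labels_path)
    return alt, cov, af, index, labels
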