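"""Synthetic mitochondrial references, donor genotypes and BAM files.

The simulator builds complete, indexable test datasets with a known
truth table: a random mitochondrial-sized reference, per-donor germline
variants (fixed, AF 1) and heteroplasmies (intermediate AF, varying
cell to cell), and single-end reads written as coordinate-sorted BAMs in
either the well-based layout (one BAM per cell) or the droplet-based
layout (one BAM with CB/UB tags plus a barcode whitelist).

Generative model per cell: read count ~ Poisson(mean); read starts
uniform on the linear contig (no origin-spanning reads); for each
heteroplasmic variant the cell's own allele fraction is drawn from a
Beta distribution with the donor mean μ and dispersion ρ
(shape = μ·(1−ρ)/ρ, (1−μ)·(1−ρ)/ρ, so Var = μ(1−μ)ρ), and each covering
read carries the alternative base with that probability; germline
variants appear on every covering read; independent per-base sequencing
errors substitute a uniformly chosen different base. All randomness
flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .reference_io import BASES, MitoReference, Variant

_ACGT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the simulator; the seed is mandatory.

    Defaults emulate a well-based multi-donor experiment at full
    mitochondrial scale: 4 donors × 50 cells, ~50× per-cell coverage
    (8300 reads × 100 bp over 16,569 bp), sequencing error 1e-3, ten
    donor-exclusive germline markers and one μ=0.10 heteroplasmy per
    donor.
    """

    seed: int
    n_donors: int = 4
    cells_per_donor: int = 50
    reads_per_cell: float = 8300.0
    read_length: int = 100
    reference_length: int = 16569
    error_rate: float = 1e-3
    layout: str = "well"
    barcode_length: int = 12
    n_germline_per_donor: int = 10
    n_heteroplasmies_per_donor: int = 1
    heteroplasmy_mean_af: float = 0.10
    heteroplasmy_dispersion: float = 0.05
    base_quality: int = 30
    low_quality_fraction: float = 0.0
    low_quality_phred: int = 5
    contig: str = "chrM"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory — no implicit randomness")
        if self.reference_length < 1000:
            raise ValueError("reference_length must be >= 1000")
        if self.layout not in ("well", "droplet"):
            raise ValueError(f"unknown layout {self.layout!r}")
        for name in ("error_rate", "heteroplasmy_mean_af",
                     "heteroplasmy_dispersion", "low_quality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length > self.reference_length:
            raise ValueError("reads longer than the reference")


@dataclass
class DonorTruth:
    """Ground-truth genotype of one simulated donor."""

    donor_id: str
    germline: list[Variant] = field(default_factory=list)
    heteroplasmies: list[tuple[Variant, float, float]] = field(
        default_factory=list
    )  # (variant, mean AF μ, dispersion ρ)


@dataclass
class SimulatedDataset:
    """Paths and truth of one simulated experiment."""

    layout: str
    fasta_path: Path
    bam_paths: list[Path]  # one per cell (well) or a single barcoded BAM
    whitelist_path: Path | None
    labels_path: Path
    truth_path: Path
    cell_ids: list[str]
    cell_to_donor: dict[str, str]
    reference: MitoReference
    truth: list[DonorTruth]


def make_reference(
    config: SimulationConfig, out_fasta: str | Path | None = None
) -> MitoReference:
    """Uniform-random A/C/G/T contig from the config seed; optional FASTA."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    codes = rng.integers(0, 4, size=config.reference_length)
    sequence = _ACGT_BYTES[codes].tobytes().decode("ascii")
    ref = MitoReference(contig_name=config.contig, sequence=sequence)
    if out_fasta is not None:
        write_fasta(ref, out_fasta)
    return ref


def write_fasta(reference: MitoReference, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{reference.contig_name}\n")
        seq = reference.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    return path


def make_truth(config: SimulationConfig, reference: MitoReference) -> list[DonorTruth]:
    """Sample donor-exclusive germline and heteroplasmic variants.

    Positions are distinct across all donors and variant types; alt
    bases are uniform over the three non-reference bases.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    per_donor = config.n_germline_per_donor + config.n_heteroplasmies_per_donor
    needed = config.n_donors * per_donor
    candidates = np.array(
        [i for i, b in enumerate(reference.sequence) if b != "N"], dtype=np.int64
    )
    if needed > candidates.size:
        raise ValueError(
            f"{needed} variant positions requested but only "
            f"{candidates.size} non-N positions available"
        )
    chosen = rng.choice(candidates, size=needed, replace=False)
    truth: list[DonorTruth] = []
    k = 0
    for d in range(config.n_donors):
        donor = DonorTruth(donor_id=f"donor{d + 1}")
        for _ in range(config.n_germline_per_donor):
            donor.germline.append(_random_variant(rng, reference, int(chosen[k])))
            k += 1
        for _ in range(config.n_heteroplasmies_per_donor):
            donor.heteroplasmies.append(
                (
                    _random_variant(rng, reference, int(chosen[k])),
                    config.heteroplasmy_mean_af,
                    config.heteroplasmy_dispersion,
                )
            )
            k += 1
        truth.append(donor)
    return truth


def _random_variant(
    rng: np.random.Generator, reference: MitoReference, pos0: int
) -> Variant:
    ref_base = reference.sequence[pos0]
    alts = [b for b in BASES if b != ref_base]
    return Variant(position=pos0 + 1, ref=ref_base, alt=alts[rng.integers(0, 3)])


def _beta_params(mu: float, rho: float) -> tuple[float, float]:
    # mean mu, Var = mu (1-mu) rho; rho -> 0 degenerates to a point mass
    if rho <= 0.0:
        return np.inf, np.inf
    s = (1.0 - rho) / rho
    return mu * s, (1.0 - mu) * s


def _simulate_cell_reads(
    rng: np.random.Generator,
    ref_codes: np.ndarray,
    donor: DonorTruth,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """(starts, read_code_matrix) for one cell, starts ascending."""
    L = ref_codes.size
    rl = config.read_length
    n = int(rng.poisson(config.reads_per_cell))
    starts = np.sort(rng.integers(0, L - rl + 1, size=n))
    reads = ref_codes[starts[:, None] + np.arange(rl)[None, :]].copy()
    base_code = {b: i for i, b in enumerate(BASES)}
    for variant in donor.germline:
        pos0 = variant.position - 1
        covering = np.flatnonzero((starts <= pos0) & (pos0 < starts + rl))
        reads[covering, pos0 - starts[covering]] = base_code[variant.alt]
    for variant, mu, rho in donor.heteroplasmies:
        a, b = _beta_params(mu, rho)
        cell_af = mu if not np.isfinite(a) else float(rng.beta(a, b))
        pos0 = variant.position - 1
        covering = np.flatnonzero((starts <= pos0) & (pos0 < starts + rl))
        carry = rng.random(covering.size) < cell_af
        reads[covering[carry], pos0 - starts[covering[carry]]] = base_code[variant.alt]
    if config.error_rate > 0 and n > 0:
        n_err = rng.binomial(n * rl, config.error_rate)
        if n_err:
            flat = rng.choice(n * rl, size=n_err, replace=False)
            shift = rng.integers(1, 4, size=n_err)
            reads.reshape(-1)[flat] = (reads.reshape(-1)[flat] + shift) % 4
    return starts, reads


def _qualities(rng: np.random.Generator, shape: tuple, config: SimulationConfig) -> np.ndarray:
    quals = np.full(shape, config.base_quality, dtype=np.uint8)
    if config.low_quality_fraction > 0:
        mask = rng.random(shape) < config.low_quality_fraction
        quals[mask] = config.low_quality_phred
    return quals


def _make_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = _ACGT_BYTES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _bam_header(config: SimulationConfig) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.contig, "LN": config.reference_length}],
    }


def simulate_cells(
    reference: MitoReference,
    truth: Sequence[DonorTruth],
    config: SimulationConfig,
    out_dir: str | Path,
) -> SimulatedDataset:
    """Write the full fixture: FASTA, BAM(s)+BAI, whitelist, labels, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta_path = write_fasta(reference, out / "reference.fa")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    ref_codes = np.frombuffer(reference.sequence.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    ref_codes = lut[ref_codes]
    header = _bam_header(config)

    cell_ids: list[str] = []
    cell_to_donor: dict[str, str] = {}
    droplet_barcodes: list[str] | None = None
    if config.layout == "droplet":
        n_cells = config.n_donors * config.cells_per_donor
        droplet_barcodes = _make_barcodes(rng, n_cells, config.barcode_length)

    bam_paths: list[Path] = []
    droplet_records: list[tuple[int, pysam.AlignedSegment]] = []
    cell_counter = 0
    for donor in truth:
        for j in range(config.cells_per_donor):
            if config.layout == "well":
                cell_id = f"{donor.donor_id}_cell{j:03d}"
            else:
                cell_id = droplet_barcodes[cell_counter]
            cell_counter += 1
            cell_ids.append(cell_id)
            cell_to_donor[cell_id] = donor.donor_id
            starts, reads = _simulate_cell_reads(rng, ref_codes, donor, config)
            quals = _qualities(rng, reads.shape, config)
            if config.layout == "well":
                path = out / f"{cell_id}.bam"
                with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
                    for i in range(starts.size):
                        bam.write(
                            _segment(
                                f"{cell_id}:r{i}", starts[i], reads[i], quals[i],
                                bam.header,
                            )
                        )
                pysam.index(str(path))
                bam_paths.append(path)
            else:
                umis = [
                    _ACGT_BYTES[rng.integers(0, 4, size=8)].tobytes().decode("ascii")
                    for _ in range(starts.size)
                ]
                for i in range(starts.size):
                    seg = _segment(
                        f"{cell_id}:r{i}", starts[i], reads[i], quals[i],
                        pysam.AlignmentHeader.from_dict(header),
                    )
                    seg.set_tag("CB", cell_id)
                    seg.set_tag("UB", umis[i])
                    droplet_records.append((int(starts[i]), seg))

    whitelist_path: Path | None = None
    if config.layout == "droplet":
        droplet_records.sort(key=lambda t: t[0])
        path = out / "cells.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
            for _, seg in droplet_records:
                bam.write(seg)
        pysam.index(str(path))
        bam_paths = [path]
        whitelist_path = out / "whitelist.txt"
        whitelist_path.write_text("\n".join(cell_ids) + "\n")

    labels_path = out / "labels.tsv"
    pd.DataFrame(
        {"cell_id": cell_ids, "donor_id": [cell_to_donor[c] for c in cell_ids]}
    ).to_csv(labels_path, sep="\t", index=False)

    truth_rows = []
    for donor in truth:
        for v in donor.germline:
            truth_rows.append(
                dict(donor_id=donor.donor_id, label=v.label, position=v.position,
                     ref=v.ref, alt=v.alt, type="germline", mean_af=1.0,
                     dispersion=0.0)
            )
        for v, mu, rho in donor.heteroplasmies:
            truth_rows.append(
                dict(donor_id=donor.donor_id, label=v.label, position=v.position,
                     ref=v.ref, alt=v.alt, type="heteroplasmy", mean_af=mu,
                     dispersion=rho)
            )
    truth_path = out / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)

    return SimulatedDataset(
        layout=config.layout,
        fasta_path=fasta_path,
        bam_paths=bam_paths,
        whitelist_path=whitelist_path,
        labels_path=labels_path,
        truth_path=truth_path,
        cell_ids=cell_ids,
        cell_to_donor=cell_to_donor,
        reference=reference,
        truth=list(truth),
    )


def _segment(
    name: str,
    start: int,
    codes: np.ndarray,
    quals: np.ndarray,
    header: pysam.AlignmentHeader,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = name
    seg.query_sequence = _ACGT_BYTES[codes].tobytes().decode("ascii")
    seg.flag = 0
    seg.reference_id = 0
    seg.reference_start = int(start)
    seg.mapping_quality = 60
    seg.cigartuples = [(0, codes.size)]
    seg.query_qualities = pysam.qualitystring_to_array(
        "".join(chr(q + 33) for q in quals)
    )
    return seg


def simulate_dataset(config: SimulationConfig, out_dir: str | Path) -> SimulatedDataset:
    """Reference + truth + reads in one call (the usual entry point)."""
    reference = make_reference(config)
    truth = make_truth(config, reference)
    return simulate_cells(reference, truth, config, out_dir)


def simulate_stress_bam(
    reference: MitoReference,
    path: str | Path,
    seed: int,
    n_reads: int = 2000,
    read_length: int = 80,
    contig: str | None = None,
) -> Path:
    """A deliberately messy BAM for exercising pileup filters.

    Reads carry randomized CIGARs (soft clips, insertions, deletions,
    reference skips), per-base qualities spanning the filter threshold,
    random mapping qualities, occasional N bases, and a mix of
    secondary / supplementary / duplicate / QC-fail flags.
    """
    rng = np.random.default_rng(seed)
    contig = contig or reference.contig_name
    L = reference.length
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": contig, "LN": L}],
    }
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    records = []
    # keep the worst-case reference span (match + skip + match) inside the contig
    max_start = max(1, L - read_length - 260)
    for i in range(n_reads):
        start = int(rng.integers(0, max_start))
        cigar: list[tuple[int, int]] = []
        qlen = 0
        if rng.random() < 0.3:
            sc = int(rng.integers(1, 12))
            cigar.append((4, sc))
            qlen += sc
        m1 = int(rng.integers(10, read_length))
        cigar.append((0, m1))
        qlen += m1
        if rng.random() < 0.4:
            kind = int(rng.integers(0, 3))
            ln = int(rng.integers(1, 8))
            if kind == 0:
                cigar.append((1, ln))  # insertion
                qlen += ln
            elif kind == 1:
                cigar.append((2, ln))  # deletion
            else:
                cigar.append((3, int(rng.integers(20, 200))))  # ref skip
            m2 = int(rng.integers(5, 40))
            cigar.append((0, m2))
            qlen += m2
        if rng.random() < 0.3:
            sc = int(rng.integers(1, 12))
            cigar.append((4, sc))
            qlen += sc
        codes = rng.integers(0, 4, size=qlen)
        seq = _ACGT_BYTES[codes].tobytes().decode("ascii")
        if rng.random() < 0.15:  # sprinkle N calls
            seq_l = list(seq)
            for k in rng.choice(qlen, size=min(3, qlen), replace=False):
                seq_l[int(k)] = "N"
            seq = "".join(seq_l)
        flag = 0
        r = rng.random()
        if r < 0.05:
            flag |= 0x100  # secondary
        elif r < 0.10:
            flag |= 0x800  # supplementary
        elif r < 0.15:
            flag |= 0x400  # duplicate
        elif r < 0.20:
            flag |= 0x200  # qc fail
        elif r < 0.23:
            flag |= 0x4  # unmapped
        seg = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(header))
        seg.query_name = f"stress{i}"
        seg.query_sequence = seq
        seg.flag = flag
        if not flag & 0x4:
            seg.reference_id = 0
            seg.reference_start = start
            seg.cigartuples = cigar
            seg.mapping_quality = int(rng.integers(0, 61))
        quals = rng.integers(0, 42, size=qlen).astype(np.uint8)
        seg.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in quals)
        )
        records.append((start if not flag & 0x4 else L, seg))
    records.sort(key=lambda t: t[0])
    path = Path(path)
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for _, seg in records:
            bam.write(seg)
    pysam.index(str(path))
    return path


def split_droplet_bam(
    bam_path: str | Path,
    out_dir: str | Path,
    barcodes: Sequence[str],
    barcode_tag: str = "CB",
) -> list[Path]:
    """Split a barcoded BAM into one BAM per barcode (well-layout view).

    The per-cell files inherit reads in position order, so they remain
    coordinate-sorted; used to cross-check droplet against well pileups.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    writers: dict[str, pysam.AlignmentFile] = {}
    paths: list[Path] = []
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        header = bam.header.to_dict()
        for bc in barcodes:
            p = out / f"{bc}.bam"
            writers[bc] = pysam.AlignmentFile(str(p), "wb", header=header)
            paths.append(p)
        for read in bam.fetch(until_eof=True):
            try:
                bc = str(read.get_tag(barcode_tag))
            except KeyError:
                continue
            if bc in writers:
                writers[bc].write(read)
    for w in writers.values():
        w.close()
    for p in paths:
        pysam.index(str(p))
    return paths
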