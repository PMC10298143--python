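"""Per-cell base counting over the mitochondrial contig.

Two BAM layouts are supported:

* well-based — one coordinate-sorted, indexed BAM per cell; the cell id
  is the file stem (:func:`pileup_well`);
* droplet-based — a single BAM carrying all cells, each read tagged with
  a cell barcode (default tag ``CB``); empty droplets are removed with a
  barcode whitelist and/or a minimum read cutoff (:func:`pileup_droplet`).

Both paths tally A/C/G/T base calls per reference position into a
:class:`BaseCountTensor` per cell. Only aligned-match CIGAR operations
(M/=/X) contribute: insertions, deletions, reference skips and soft
clips are ignored, so a deletion spanning a position adds nothing to
coverage there. Base calls of N never count. Consequently the coverage
at a position is exactly the sum of the four base counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .reference_io import BASES, MitoReference

log = logging.getLogger(__name__)

#: contig spellings tried when the FASTA name is absent from a BAM header
CONTIG_ALIASES = ("chrM", "MT", "chrMT", "M")

#: read categories removed before counting; ``unmapped`` is always enforced
DEFAULT_EXCLUDE_FLAGS = frozenset(
    {"secondary", "supplementary", "duplicate", "qc_fail", "unmapped"}
)
_KNOWN_FLAGS = DEFAULT_EXCLUDE_FLAGS

_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i


@dataclass(frozen=True)
class PileupFilters:
    """Read- and base-level filters applied before counting.

    min_base_quality follows the samtools-family pileup default of
    Phred 13; mapping quality is unfiltered by default. ``max_depth``
    caps the number of counted bases per position (None = unlimited).
    ``count_overlaps_once`` keeps a single base call where the two mates
    of a pair overlap (the call with higher base quality wins).
    ``collapse_umis`` collapses reads sharing (barcode, UMI) into one
    vote per position: majority base, ties broken by summed base quality
    then alphabetically.
    """

    min_base_quality: int = 13
    min_mapping_quality: int = 0
    exclude_flags: frozenset[str] = DEFAULT_EXCLUDE_FLAGS
    max_depth: int | None = None
    count_overlaps_once: bool = False
    collapse_umis: bool = False
    umi_tag: str = "UB"

    def __post_init__(self) -> None:
        if self.min_base_quality < 0 or self.min_mapping_quality < 0:
            raise ValueError("quality thresholds must be non-negative")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be >= 1 or None")
        unknown = set(self.exclude_flags) - _KNOWN_FLAGS
        if unknown:
            raise ValueError(f"unknown exclude flags: {sorted(unknown)}")
        # unmapped reads can never be positioned; always exclude them
        object.__setattr__(
            self, "exclude_flags", frozenset(self.exclude_flags) | {"unmapped"}
        )


@dataclass
class BaseCountTensor:
    """Counts of A/C/G/T calls at every reference position for one cell.

    ``counts`` has shape (4, L) with rows ordered A, C, G, T and columns
    indexed by 0-based position; the public API speaks 1-based.
    """

    cell_id: str
    counts: np.ndarray

    def at(self, position: int) -> tuple[int, int, int, int]:
        """(n_A, n_C, n_G, n_T) at a 1-based position."""
        return tuple(int(x) for x in self.counts[:, position - 1])

    def depth(self) -> np.ndarray:
        """Counted-base coverage per position (length L)."""
        return self.counts.sum(axis=0)

    def total_bases(self) -> int:
        return int(self.counts.sum())


@dataclass
class CellIndex:
    """Ordered cell universe of a pileup run.

    ``cell_ids`` fixes the column order of all downstream matrices;
    ``total_reads`` records the passing mitochondrial reads per cell.
    """

    mode: str  # "well" | "droplet"
    cell_ids: list[str]
    total_reads: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("well", "droplet"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")


@dataclass
class CoverageTrack:
    """Aggregate depth across cells: per-position sum and mean."""

    contig_name: str
    sum_depth: np.ndarray
    mean_depth: np.ndarray
    n_cells: int


def resolve_contig(bam: pysam.AlignmentFile, reference: MitoReference) -> str:
    """Find the BAM header contig matching the loaded reference.

    The FASTA name is tried first; on a length mismatch for that exact
    name an error is raised. Otherwise the common mito aliases are tried,
    accepting only a name whose header length equals the reference's.
    """
    names = set(bam.references)
    if reference.contig_name in names:
        blen = bam.get_reference_length(reference.contig_name)
        if blen != reference.length:
            raise ValueError(
                f"contig {reference.contig_name!r}: BAM header length {blen} "
                f"!= FASTA length {reference.length}"
            )
        return reference.contig_name
    for alias in CONTIG_ALIASES:
        if alias in names and bam.get_reference_length(alias) == reference.length:
            log.info(
                "contig %r not in BAM header; using alias %r",
                reference.contig_name,
                alias,
            )
            return alias
    raise ValueError(
        f"no contig in BAM header matches {reference.contig_name!r} "
        f"(length {reference.length}); header has {sorted(names)[:8]}"
    )


def _read_passes(read: pysam.AlignedSegment, filters: PileupFilters) -> bool:
    if read.is_unmapped:
        return False
    ex = filters.exclude_flags
    if "secondary" in ex and read.is_secondary:
        return False
    if "supplementary" in ex and read.is_supplementary:
        return False
    if "duplicate" in ex and read.is_duplicate:
        return False
    if "qc_fail" in ex and read.is_qcfail:
        return False
    if read.mapping_quality < filters.min_mapping_quality:
        return False
    return True


def _read_base_calls(
    read: pysam.AlignedSegment, min_base_quality: int, length: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Filtered base calls of one read: (ref_pos0, base_code, base_qual).

    Walks the CIGAR keeping aligned matches only; drops N calls, calls
    below the quality floor and positions outside the contig.
    """
    seq = read.query_sequence
    if seq is None or read.cigartuples is None:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.astype(np.uint8), empty.astype(np.int16)
    codes = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    qualities = read.query_qualities
    quals = (
        np.asarray(qualities, dtype=np.int16)
        if qualities is not None
        else np.full(len(seq), 255, dtype=np.int16)  # '*' quality: no filter
    )
    pos_parts: list[np.ndarray] = []
    code_parts: list[np.ndarray] = []
    qual_parts: list[np.ndarray] = []
    qpos = 0
    rpos = read.reference_start
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            c = codes[qpos : qpos + ln]
            q = quals[qpos : qpos + ln]
            r = np.arange(rpos, rpos + ln, dtype=np.int64)
            keep = (c < 4) & (q >= min_base_quality) & (r >= 0) & (r < length)
            if keep.any():
                pos_parts.append(r[keep])
                code_parts.append(c[keep])
                qual_parts.append(q[keep])
            qpos += ln
            rpos += ln
        elif op in (1, 4):  # I, S consume the query
            qpos += ln
        elif op in (2, 3):  # D, N consume the reference
            rpos += ln
        # H, P consume neither
    if not pos_parts:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.astype(np.uint8), empty.astype(np.int16)
    return (
        np.concatenate(pos_parts),
        np.concatenate(code_parts),
        np.concatenate(qual_parts),
    )


class _CellTally:
    """Accumulates base calls for one cell, honouring optional modes."""

    def __init__(self, length: int, filters: PileupFilters) -> None:
        self.counts = np.zeros((4, length), dtype=np.int64)
        self._flat = self.counts.reshape(-1)
        self.length = length
        self.filters = filters
        self.n_reads = 0
        self._depth = (
            np.zeros(length, dtype=np.int64) if filters.max_depth is not None else None
        )
        # qname -> (pos, code, qual) of the mate counted first
        self._pending_mates: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        # (umi,) -> {pos: {code: [votes, qual_sum]}}
        self._umi_groups: dict[str, dict[int, dict[int, list[int]]]] = {}

    def _add(self, pos: np.ndarray, code: np.ndarray) -> None:
        if self._depth is not None:
            room = self._depth[pos] < self.filters.max_depth
            pos, code = pos[room], code[room]
            self._depth[pos] += 1
        # positions within one read are unique, so fancy-index add is safe
        self._flat[code.astype(np.int64) * self.length + pos] += 1

    def _remove(self, pos: np.ndarray, code: np.ndarray) -> None:
        self._flat[code.astype(np.int64) * self.length + pos] -= 1
        if self._depth is not None:
            self._depth[pos] -= 1

    def add_read(self, read: pysam.AlignedSegment, umi: str | None = None) -> None:
        self.n_reads += 1
        pos, code, qual = _read_base_calls(
            read, self.filters.min_base_quality, self.length
        )
        if self.filters.collapse_umis and umi is not None:
            self._add_to_umi_group(umi, pos, code, qual)
            return
        if self.filters.count_overlaps_once and read.is_paired:
            pos, code, qual = self._resolve_mate_overlap(read, pos, code, qual)
        if pos.size:
            self._add(pos, code)

    def _resolve_mate_overlap(
        self,
        read: pysam.AlignedSegment,
        pos: np.ndarray,
        code: np.ndarray,
        qual: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        qname = read.query_name or ""
        prev = self._pending_mates.pop(qname, None)
        if prev is None:
            self._pending_mates[qname] = (pos, code, qual)
            return pos, code, qual
        ppos, pcode, pqual = prev
        overlap = np.isin(pos, ppos)
        if overlap.any():
            prev_idx = {int(p): i for i, p in enumerate(ppos)}
            keep = np.ones(pos.size, dtype=bool)
            for i in np.flatnonzero(overlap):
                j = prev_idx[int(pos[i])]
                if qual[i] > pqual[j]:
                    # replace the first mate's call with the better one
                    self._remove(ppos[j : j + 1], pcode[j : j + 1])
                else:
                    keep[i] = False
            pos, code, qual = pos[keep], code[keep], qual[keep]
        return pos, code, qual

    def _add_to_umi_group(
        self, umi: str, pos: np.ndarray, code: np.ndarray, qual: np.ndarray
    ) -> None:
        group = self._umi_groups.setdefault(umi, {})
        for p, c, q in zip(pos.tolist(), code.tolist(), qual.tolist()):
            votes = group.setdefault(p, {})
            entry = votes.setdefault(c, [0, 0])
            entry[0] += 1
            entry[1] += q

    def finalise(self) -> None:
        """Resolve UMI groups into one consensus call per molecule."""
        for group in self._umi_groups.values():
            for p, votes in group.items():
                best = min(
                    votes.items(),
                    key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]),
                )[0]
                self._add(
                    np.array([p], dtype=np.int64), np.array([best], dtype=np.uint8)
                )
        self._umi_groups.clear()
        self._pending_mates.clear()


def _open_checked(path: str | Path) -> pysam.AlignmentFile:
    bam = pysam.AlignmentFile(str(path), "rb")
    if not bam.has_index():
        bam.close()
        raise ValueError(f"BAM index (.bai) missing for {path}")
    return bam


def pileup_well(
    bam_paths: Sequence[str | Path],
    reference: MitoReference,
    filters: PileupFilters | None = None,
) -> tuple[list[BaseCountTensor], CellIndex]:
    """Pile up one BAM per cell; cell ids are the file stems.

    Column order of downstream matrices follows ``bam_paths`` order.
    """
    filters = filters or PileupFilters()
    if not bam_paths:
        raise ValueError("no BAM files given")
    cell_ids = [Path(p).name.removesuffix(".bam") for p in bam_paths]
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError(f"duplicate BAM file stems in input: {cell_ids}")
    tensors: list[BaseCountTensor] = []
    totals: dict[str, int] = {}
    for path, cell_id in zip(bam_paths, cell_ids):
        with _open_checked(path) as bam:
            contig = resolve_contig(bam, reference)
            tally = _CellTally(reference.length, filters)
            for read in bam.fetch(contig):
                if not _read_passes(read, filters):
                    continue
                tally.add_read(read)
            tally.finalise()
        tensors.append(BaseCountTensor(cell_id=cell_id, counts=tally.counts))
        totals[cell_id] = tally.n_reads
    log.info(
        "well pileup: %d cells, %d passing reads",
        len(tensors),
        sum(totals.values()),
    )
    return tensors, CellIndex(mode="well", cell_ids=cell_ids, total_reads=totals)


def load_whitelist(path: str | Path) -> list[str]:
    """Read a barcode whitelist: one barcode per line, order preserved."""
    out: list[str] = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        bc = line.strip()
        if bc and bc not in seen:
            out.append(bc)
            seen.add(bc)
    if not out:
        raise ValueError(f"whitelist {path} is empty")
    return out


def pileup_droplet(
    bam_path: str | Path,
    reference: MitoReference,
    filters: PileupFilters | None = None,
    barcode_tag: str = "CB",
    whitelist: Iterable[str] | None = None,
    min_reads: int | None = None,
) -> tuple[list[BaseCountTensor], CellIndex]:
    """Pile up a single barcoded BAM, one tensor per retained barcode.

    At least one of *whitelist* / *min_reads* must be given (the paper's
    empty-droplet exclusion); when both are given the whitelist is
    applied first. Reads lacking the barcode tag are dropped. Cell order
    is the whitelist order when supplied, else lexicographic.
    """
    filters = filters or PileupFilters()
    if whitelist is None and min_reads is None:
        raise ValueError(
            "droplet mode needs a barcode whitelist and/or min_reads "
            "to exclude empty droplets"
        )
    wl_order = list(dict.fromkeys(whitelist)) if whitelist is not None else None
    wl_set = set(wl_order) if wl_order is not None else None
    tallies: dict[str, _CellTally] = {}
    n_pass = 0
    n_untagged = 0
    with _open_checked(bam_path) as bam:
        contig = resolve_contig(bam, reference)
        for read in bam.fetch(contig):
            if not _read_passes(read, filters):
                continue
            n_pass += 1
            try:
                barcode = read.get_tag(barcode_tag)
            except KeyError:
                n_untagged += 1
                continue
            barcode = str(barcode)
            if wl_set is not None and barcode not in wl_set:
                continue
            tally = tallies.get(barcode)
            if tally is None:
                tally = tallies[barcode] = _CellTally(reference.length, filters)
            umi = None
            if filters.collapse_umis:
                try:
                    umi = str(read.get_tag(filters.umi_tag))
                except KeyError:
                    umi = f"_read:{read.query_name}"  # untagged: its own molecule
            tally.add_read(read, umi=umi)
    if n_pass > 0 and n_untagged == n_pass:
        raise ValueError(
            f"tag {barcode_tag!r} never observed on any passing read — "
            "wrong --barcode-tag? (10x corrected barcodes use CB, raw CR)"
        )
    if wl_order is not None:
        missing = [bc for bc in wl_order if bc not in tallies]
        if missing:
            log.warning(
                "%d whitelist barcodes absent from BAM (first: %s)",
                len(missing),
                missing[:5],
            )
        retained = [bc for bc in wl_order if bc in tallies]
    else:
        retained = sorted(tallies)
    if min_reads is not None:
        dropped = [bc for bc in retained if tallies[bc].n_reads < min_reads]
        retained = [bc for bc in retained if tallies[bc].n_reads >= min_reads]
        log.info("min_reads=%d drops %d barcodes", min_reads, len(dropped))
    if not retained:
        raise ValueError("no barcodes retained after whitelist/min_reads filtering")
    tensors = []
    totals = {}
    for bc in retained:
        tallies[bc].finalise()
        tensors.append(BaseCountTensor(cell_id=bc, counts=tallies[bc].counts))
        totals[bc] = tallies[bc].n_reads
    log.info(
        "droplet pileup: %d barcodes retained, %d passing reads (%d untagged)",
        len(retained),
        n_pass,
        n_untagged,
    )
    return tensors, CellIndex(mode="droplet", cell_ids=retained, total_reads=totals)


def total_coverage_track(
    tensors: Sequence[BaseCountTensor], reference: MitoReference
) -> CoverageTrack:
    """Aggregate counted-base depth across cells (sum and mean per position)."""
    if not tensors:
        raise ValueError("no tensors given")
    total = np.zeros(reference.length, dtype=np.int64)
    for t in tensors:
        total += t.depth()
    return CoverageTrack(
        contig_name=reference.contig_name,
        sum_depth=total,
        mean_depth=total / len(tensors),
        n_cells=len(tensors),
    )


def write_bedgraph(
    track: CoverageTrack, path: str | Path, which: str = "sum"
) -> None:
    """Write the aggregate track as bedGraph (0-based half-open runs).

    bedGraph is the one output using 0-based coordinates, per the format
    standard; all other interfaces are 1-based.
    """
    values = track.sum_depth if which == "sum" else track.mean_depth
    with open(path, "w") as fh:
        run_start = 0
        current = values[0]
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != current:
                val = int(current) if which == "sum" else float(current)
                fh.write(f"{track.contig_name}\t{run_start}\t{i}\t{val}\n")
                if i < len(values):
                    run_start = i
                    current = values[i]
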