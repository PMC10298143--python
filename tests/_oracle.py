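"""Independent naive pileup oracle.

Pure-Python per-read CIGAR walk with no shared code with the package's
pileup engine: flags are tested via raw bit masks, bases via string
indexing, counts held in plain dicts. Used to cross-check the engine
exactly on arbitrary BAMs.
"""

from __future__ import annotations

import pysam

_SECONDARY = 0x100
_SUPPLEMENTARY = 0x800
_DUPLICATE = 0x400
_QC_FAIL = 0x200
_UNMAPPED = 0x4

# CIGAR op codes: M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_CONSUMES_QUERY = {0, 1, 4, 7, 8}
_CONSUMES_REF = {0, 2, 3, 7, 8}
_ALIGNED = {0, 7, 8}


def naive_base_counts(
    bam_path,
    contig: str,
    length: int,
    min_base_quality: int = 13,
    min_mapping_quality: int = 0,
) -> dict[int, list[int]]:
    """{0-based position: [nA, nC, nG, nT]} with default flag exclusions."""
    counts: dict[int, list[int]] = {}
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for read in bam.fetch(until_eof=True):
            flag = read.flag
            if flag & (_SECONDARY | _SUPPLEMENTARY | _DUPLICATE | _QC_FAIL | _UNMAPPED):
                continue
            if read.reference_name != contig:
                continue
            if read.mapping_quality < min_mapping_quality:
                continue
            seq = read.query_sequence
            quals = read.query_qualities
            if seq is None or read.cigartuples is None:
                continue
            qpos = 0
            rpos = read.reference_start
            for op, ln in read.cigartuples:
                if op in _ALIGNED:
                    for off in range(ln):
                        p = rpos + off
                        if p < 0 or p >= length:
                            continue
                        base = seq[qpos + off]
                        idx = base_index.get(base.upper())
                        if idx is None:
                            continue
                        q = quals[qpos + off] if quals is not None else 255
                        if q < min_base_quality:
                            continue
                        counts.setdefault(p, [0, 0, 0, 0])[idx] += 1
                if op in _CONSUMES_QUERY:
                    qpos += ln
                if op in _CONSUMES_REF:
                    rpos += ln
    return counts
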