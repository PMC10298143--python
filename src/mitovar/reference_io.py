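"""Mitochondrial reference sequences and variant nomenclature.

The mitochondrial genome is small enough (16,569 bp for the human rCRS)
that the whole contig is held in memory as a string. Variants follow the
mtDNA community convention ``{position}{ref}>{alt}`` with 1-based
coordinates, e.g. ``3243A>G``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pysam

#: canonical base ordering used for row layout and array encodings
BASES = "ACGT"

_ALLOWED = frozenset("ACGTN")
_LABEL_RE = re.compile(r"^([0-9]+)([ACGT])>([ACGT])$")


@dataclass(frozen=True)
class MitoReference:
    """A single mitochondrial contig: name, upper-cased sequence, length."""

    contig_name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"reference {self.contig_name!r} contains illegal characters: "
                f"{sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise ValueError(
                f"position {position} outside [1, {self.length}]"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True, order=True)
class Variant:
    """A single-nucleotide substitution on the mitochondrial contig.

    Ordering is (position, alt) which matches the deterministic row order
    of the alternative-allele count matrix.
    """

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be one of {BASES}: {self}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical: {self}")
        if self.position < 1:
            raise ValueError(f"positions are 1-based: {self.position}")

    @property
    def label(self) -> str:
        return f"{self.position}{self.ref}>{self.alt}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def read_reference(fasta_path: str | Path, contig: str | None = None) -> MitoReference:
    """Load the mitochondrial contig from a (optionally gzipped) FASTA.

    Parameters
    ----------
    fasta_path
        Path to a FASTA file. No faidx index is required.
    contig
        Record name to select. May be omitted only when the file holds
        exactly one record.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    names: list[str] = []
    hit: str | None = None
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            names.append(rec.name)
            if contig is not None:
                if rec.name == contig:
                    hit = rec.sequence
                    break
            else:
                if len(names) > 1:
                    raise ValueError(
                        f"{path} holds multiple records {names[:2]}...; "
                        "pass contig= to pick one"
                    )
                hit = rec.sequence
    if not names:
        raise ValueError(f"{path} contains no FASTA records")
    if hit is None:
        raise ValueError(f"contig {contig!r} not found in {path} (saw {names})")
    name = contig if contig is not None else names[0]
    return MitoReference(contig_name=name, sequence=hit.upper())


def parse_variant_label(label: str, reference: MitoReference | None = None) -> Variant:
    """Parse a ``{position}{ref}>{alt}`` label, e.g. ``3243A>G``.

    When *reference* is given, the stated ref base is validated against
    the sequence and the position against its length.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"malformed variant label: {label!r}")
    position = int(m.group(1))
    ref, alt = m.group(2), m.group(3)
    if position < 1:
        raise ValueError(f"positions are 1-based: {label!r}")
    if ref == alt:
        raise ValueError(f"ref equals alt in {label!r}")
    if reference is not None:
        if position > reference.length:
            raise ValueError(
                f"position {position} beyond reference length {reference.length}"
            )
        actual = reference.base_at(position)
        if actual != ref:
            raise ValueError(
                f"{label!r}: reference holds {actual} at {position}, not {ref}"
            )
    return Variant(position=position, ref=ref, alt=alt)


def enumerate_variants(reference: MitoReference) -> list[Variant]:
    """All possible substitutions: three per position, skipping N bases.

    Order is position ascending, then alt base A<C<G<T — the row universe
    of every alternative-allele count matrix built from this reference.
    """
    out: list[Variant] = []
    for pos0, ref in enumerate(reference.sequence):
        if ref == "N":
            continue
        for alt in BASES:
            if alt != ref:
                out.append(Variant(position=pos0 + 1, ref=ref, alt=alt))
    return out
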