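"""Gene and transcript models for cassette-exon analysis.

A gene is represented as a set of isoforms, each an ordered list of exon
intervals in 0-based half-open genomic coordinates.  From this the module
derives the feature sets used throughout the pipeline:

* **exonic parts** — the gene's exon union split at every exon boundary, so
  that each part is covered by a fixed set of transcripts (the flattening
  used for exon-level counting);
* **pseudo-transcript** — the merged union of all exons, whose gaps define
  the gene's introns;
* **exon–exon junctions** and the donor/acceptor **splice sites** they use.

It also provides the small coordinate utilities needed to reproduce printed
worked values for a cassette exon: CDS-position → codon arithmetic, peptide
span lengths, reading-frame preservation, and in-silico RT-PCR amplicon
lengths over alternative isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

Interval = tuple[int, int]

STRANDS = ("+", "-")


def _validate_exons(exons: tuple[Interval, ...]) -> None:
    if not exons:
        raise ValueError("transcript must have at least one exon")
    prev_end = None
    for start, end in exons:
        if end <= start:
            raise ValueError(f"empty or inverted exon ({start}, {end})")
        if prev_end is not None and start < prev_end:
            raise ValueError("exons must be sorted and pairwise disjoint")
        prev_end = end


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: ordered, disjoint exon intervals on a single strand.

    ``cds_start_offset`` is the 0-based offset of the first coding base
    within the *spliced* transcript, when known.
    """

    transcript_id: str
    exons: tuple[Interval, ...]
    strand: str = "+"
    cds_start_offset: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        _validate_exons(self.exons)
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")
        if self.cds_start_offset is not None and not (
            0 <= self.cds_start_offset < self.spliced_length
        ):
            raise ValueError("cds_start_offset outside spliced transcript")

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_offset(self, genomic_pos: int) -> Optional[int]:
        """Map a genomic position to its 0-based offset along the spliced
        transcript (5'→3' in transcript orientation), or None if the
        position falls outside every exon."""
        if self.strand == "+":
            acc = 0
            for s, e in self.exons:
                if s <= genomic_pos < e:
                    return acc + (genomic_pos - s)
                acc += e - s
            return None
        acc = 0
        for s, e in reversed(self.exons):
            if s <= genomic_pos < e:
                return acc + (e - 1 - genomic_pos)
            acc += e - s
        return None


@dataclass(frozen=True)
class GeneModel:
    """A gene: one or more isoforms sharing chromosome and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        if not self.transcripts:
            raise ValueError("gene must have at least one transcript")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")
        for t in self.transcripts:
            if t.strand != self.strand:
                raise ValueError(
                    f"transcript {t.transcript_id} strand differs from gene"
                )

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


@dataclass(frozen=True)
class ExonicPart:
    part_id: str
    interval: Interval
    supporting_transcripts: frozenset[str]

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass(frozen=True)
class Junction:
    """An intron excised by splicing.

    ``donor`` is the genomic start of the intron (first intronic base) and
    ``acceptor`` one past its last base, so donor < acceptor always holds;
    on the minus strand the biological donor *site* is the endpoint with
    the larger coordinate, which :meth:`donor_site` accounts for.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError("junction requires donor < acceptor")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.donor, self.acceptor, self.strand)

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.donor}-{self.acceptor}:{self.strand}"

    def donor_site(self) -> "SpliceSite":
        coord = self.donor if self.strand == "+" else self.acceptor
        return SpliceSite("donor", self.chrom, coord, self.strand)

    def acceptor_site(self) -> "SpliceSite":
        coord = self.acceptor if self.strand == "+" else self.donor
        return SpliceSite("acceptor", self.chrom, coord, self.strand)


@dataclass(frozen=True)
class SpliceSite:
    kind: str  # "donor" | "acceptor"
    chrom: str
    coordinate: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.kind not in ("donor", "acceptor"):
            raise ValueError("kind must be 'donor' or 'acceptor'")

    @property
    def id(self) -> str:
        return f"{self.kind}:{self.chrom}:{self.coordinate}:{self.strand}"


@dataclass(frozen=True)
class PrimerAnchor:
    """A PCR primer anchored by coordinate (not sequence): the 0-based
    offset of its 5' end within one exon of a reference isoform."""

    exon_index: int
    offset: int
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")


# ---------------------------------------------------------------------------
# feature derivation


def flatten_exonic_parts(gene: GeneModel) -> list[ExonicPart]:
    """Split the gene's exon union into non-overlapping exonic parts.

    The boundary set is the union of all exon start/end coordinates; every
    elementary interval between consecutive boundaries that is covered by at
    least one exon becomes one part.  Parts are numbered in ascending genomic
    order regardless of strand.
    """
    boundaries = sorted(
        {c for t in gene.transcripts for s, e in t.exons for c in (s, e)}
    )
    parts: list[ExonicPart] = []
    n = 0
    for a, b in zip(boundaries, boundaries[1:]):
        covering = frozenset(
            t.transcript_id
            for t in gene.transcripts
            if any(s <= a and b <= e for s, e in t.exons)
        )
        if covering:
            n += 1
            parts.append(ExonicPart(f"{gene.gene_id}:{n:03d}", (a, b), covering))
    return parts


def build_pseudo_transcript(gene: GeneModel) -> list[Interval]:
    """Merged union of all exon intervals of the gene, sorted.

    Strictly overlapping intervals are merged; intervals that merely abut
    are kept separate (their shared boundary yields a zero-length gap that
    :func:`derive_introns` drops).
    """
    ivs = sorted(e for t in gene.transcripts for e in t.exons)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def derive_introns(pseudo: Iterable[Interval]) -> list[Interval]:
    """Gaps between consecutive pseudo-transcript exons, in genomic order.

    Zero-length gaps (abutting exons) are dropped."""
    pseudo = list(pseudo)
    return [
        (a_end, b_start)
        for (_, a_end), (b_start, _) in zip(pseudo, pseudo[1:])
        if b_start > a_end
    ]


def enumerate_junctions(gene: GeneModel) -> dict[Junction, frozenset[str]]:
    """All exon–exon junctions of the gene with their supporting isoforms.

    One junction per consecutive exon pair per transcript, deduplicated on
    (chrom, donor, acceptor, strand); returned in genomic order."""
    support: dict[Junction, set[str]] = {}
    for t in gene.transcripts:
        for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
            j = Junction(gene.chrom, e1, s2, gene.strand)
            support.setdefault(j, set()).add(t.transcript_id)
    ordered = sorted(support, key=lambda j: (j.donor, j.acceptor))
    return {j: frozenset(support[j]) for j in ordered}


def splice_sites(junctions: Iterable[Junction]) -> list[SpliceSite]:
    """Unique donor/acceptor sites used by a set of junctions."""
    seen: dict[str, SpliceSite] = {}
    for j in junctions:
        for site in (j.donor_site(), j.acceptor_site()):
            seen.setdefault(site.id, site)
    return sorted(seen.values(), key=lambda s: (s.coordinate, s.kind))


# ---------------------------------------------------------------------------
# coordinate arithmetic


def cds_to_codon(cds_position: int) -> int:
    """1-based coding-sequence position → 1-based codon (residue) index.

    e.g. c.1084 falls in codon 362."""
    if cds_position < 1:
        raise ValueError("CDS position is 1-based and must be >= 1")
    return (cds_position - 1) // 3 + 1


def peptide_span_length(start_aa: int, end_aa: int) -> int:
    """Number of residues in an inclusive 1-based span, e.g. 338–403 → 66."""
    if start_aa > end_aa:
        raise ValueError("start_aa must be <= end_aa")
    return end_aa - start_aa + 1


def frame_preserved(skipped_length_nt: int) -> bool:
    """True iff skipping ``skipped_length_nt`` nucleotides keeps the ORF."""
    if skipped_length_nt < 0:
        raise ValueError("length must be >= 0")
    return skipped_length_nt % 3 == 0


def in_silico_amplicon(
    isoform: TranscriptModel,
    fwd: PrimerAnchor,
    rev: PrimerAnchor,
    reference: TranscriptModel,
) -> Optional[int]:
    """Predicted RT-PCR product length (nt) on ``isoform``.

    Primer anchors are defined on ``reference``; the product runs from the
    forward primer's 5' end through the reverse primer's 5' end inclusive,
    measured along the spliced molecule.  Returns None ("no product") when
    either anchor's position is absent from the isoform, e.g. a primer
    anchored inside a skipped exon.
    """
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise ValueError("expected a forward and a reverse anchor")

    def genomic(anchor: PrimerAnchor) -> int:
        try:
            s, e = reference.exons[anchor.exon_index]
        except IndexError:
            raise ValueError(
                f"anchor exon {anchor.exon_index} not in reference isoform"
            ) from None
        if anchor.offset >= e - s:
            raise ValueError("anchor offset beyond exon length")
        if reference.strand == "+":
            return s + anchor.offset
        return e - 1 - anchor.offset

    a = isoform.spliced_offset(genomic(fwd))
    b = isoform.spliced_offset(genomic(rev))
    if a is None or b is None:
        return None
    if b < a:
        raise ValueError("reverse primer lies upstream of forward primer")
    return b - a + 1


# ---------------------------------------------------------------------------
# packaged synthetic gene

#: Spanned region of the synthetic cassette-exon gene (see tyk2_like_fixture).
TYK2_LIKE_CHROM = "chr19"


def tyk2_like_fixture() -> tuple[GeneModel, PrimerAnchor, PrimerAnchor]:
    """A synthetic three-exon cassette gene modelled on the TYK2 exon 7–9
    region, with an inclusive and an exon-8-skipping isoform.

    The middle exon is 198 nt (the cassette), and the exon-7/exon-9 primer
    anchors are calibrated so the inclusive-isoform amplicon is 740 nt and
    the skipping-isoform amplicon 542 nt.  Coordinates are synthetic; no
    real genome sequence is involved.
    """
    e7, e8, e9 = (1000, 1300), (1800, 1998), (2500, 2900)
    full = TranscriptModel("TYK2like-full", (e7, e8, e9), "+", cds_start_offset=0)
    skip = TranscriptModel("TYK2like-dE8", (e7, e9), "+", cds_start_offset=0)
    gene = GeneModel("TYK2like", TYK2_LIKE_CHROM, "+", (full, skip))
    fwd = PrimerAnchor(exon_index=0, offset=60, orientation="forward")
    rev = PrimerAnchor(exon_index=2, offset=301, orientation="reverse")
    return gene, fwd, rev
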