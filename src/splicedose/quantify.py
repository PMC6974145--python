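"""Feature-level quantification of spliced-read evidence.

Turns aligned-read block lists into the five quantification levels used in
multi-resolution splicing analysis — exonic parts, introns, exon–exon
junctions (with a minimum-overhang filter), splice-site activities, and
transcript abundances — and normalizes counts to RPKM/RPM.

Counting rules
--------------
* A junction observation is the gap between two consecutive blocks of a
  read; it counts only if both flanking blocks are at least ``min_overhang``
  nucleotides long (short overhangs align unreliably).
* Exonic parts and introns use the union rule: a read increments every
  feature that any of its blocks overlaps by >= 1 nt, once per feature.
* A splice site's activity is the summed count of all junctions using it,
  so total donor activity == total acceptor activity == total junction count.
* Transcript abundances come from an EM on junction-compatibility classes,
  with each isoform's read mass proportional to abundance x number of
  informative junctions (the junction-level analogue of effective length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .gene_model import ExonicPart, Interval, Junction, SpliceSite

ReadsBySample = Mapping[str, Sequence["AlignedRead"]]


@dataclass(frozen=True)
class AlignedRead:
    """A (possibly spliced) aligned read as ordered genomic blocks; the gaps
    between consecutive blocks are the read's introns."""

    blocks: tuple[Interval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        if not self.blocks:
            raise ValueError("read must have at least one block")
        prev_end = None
        for s, e in self.blocks:
            if e <= s:
                raise ValueError(f"empty or inverted block ({s}, {e})")
            if prev_end is not None and s <= prev_end:
                raise ValueError("blocks must be sorted and disjoint")
            prev_end = e

    def gaps(self) -> list[Interval]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:])
        ]


@dataclass
class CountMatrix:
    """Feature x sample raw counts plus per-sample library sizes.

    ``library_sizes`` defaults to the column sums of counted reads; when
    supplied externally it must be at least the column sums (derived
    matrices whose rows share reads, like splice-site activities, disable
    that check)."""

    counts: pd.DataFrame
    library_sizes: pd.Series = None  # type: ignore[assignment]
    check_library: bool = True

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        else:
            self.library_sizes = pd.Series(self.library_sizes).reindex(
                self.counts.columns
            )
            if self.check_library and (
                self.library_sizes + 1e-9 < self.counts.sum(axis=0)
            ).any():
                raise ValueError("library_sizes below column sums")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class NormalizedMatrix:
    """Depth-corrected expression values: RPKM (length-normalized) or RPM."""

    values: pd.DataFrame
    unit: str
    feature_lengths: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.unit not in ("RPKM", "RPM"):
            raise ValueError("unit must be 'RPKM' or 'RPM'")
        if self.unit == "RPKM":
            if self.feature_lengths is None:
                raise ValueError("RPKM requires feature_lengths")
            self.feature_lengths = pd.Series(self.feature_lengths).reindex(
                self.values.index
            )
            if (self.feature_lengths <= 0).any():
                raise ValueError("feature lengths must be positive")


@dataclass
class PsiEstimate:
    """Percent-spliced-in summary of a cassette exon from junction counts."""

    psi: float
    inclusion_count: float
    skip_count: float
    defined: bool = True


# ---------------------------------------------------------------------------
# counting


def extract_junction_counts(
    reads_by_sample: ReadsBySample,
    min_overhang: int = 6,
    chrom: str = "chr",
    strand: str = "+",
) -> CountMatrix:
    """Count reads across each exon–exon junction, keeping only spliced
    reads whose flanking blocks both span >= ``min_overhang`` nt.

    A read with k gaps can contribute to k junctions.  Unspliced reads
    contribute nothing (but do count toward the library size)."""
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    per_sample: dict[str, dict[str, int]] = {}
    library = {}
    for sample, reads in reads_by_sample.items():
        tallies: dict[str, int] = {}
        library[sample] = len(reads)
        for read in reads:
            blocks = read.blocks
            for i, (gap_start, gap_end) in enumerate(read.gaps()):
                left = blocks[i][1] - blocks[i][0]
                right = blocks[i + 1][1] - blocks[i + 1][0]
                if left >= min_overhang and right >= min_overhang:
                    jid = Junction(chrom, gap_start, gap_end, strand).id
                    tallies[jid] = tallies.get(jid, 0) + 1
        per_sample[sample] = tallies
    counts = pd.DataFrame(per_sample).fillna(0).sort_index()
    if counts.empty:
        counts = pd.DataFrame(
            index=pd.Index([], dtype=object), columns=list(reads_by_sample)
        ).fillna(0)
    # a read with k gaps contributes k observations, so column sums may
    # legitimately exceed the read-count library size
    return CountMatrix(counts, pd.Series(library, dtype=float),
                       check_library=False)


def _count_overlaps(
    reads_by_sample: ReadsBySample,
    features: Mapping[str, Interval],
    require_block_overlap: bool = True,
) -> CountMatrix:
    per_sample: dict[str, dict[str, int]] = {}
    library = {}
    for sample, reads in reads_by_sample.items():
        tallies = {fid: 0 for fid in features}
        library[sample] = len(reads)
        for read in reads:
            for fid, (fs, fe) in features.items():
                if any(bs < fe and fs < be for bs, be in read.blocks):
                    tallies[fid] += 1
        per_sample[sample] = tallies
    counts = pd.DataFrame(per_sample, index=list(features))
    # union rule: one read can increment several features
    return CountMatrix(counts, pd.Series(library, dtype=float),
                       check_library=False)


def count_exonic_parts(
    reads_by_sample: ReadsBySample, parts: Sequence[ExonicPart]
) -> CountMatrix:
    """Union-rule counting: a read increments every part any of its blocks
    overlaps by >= 1 nt; a multi-part read counts once per part."""
    return _count_overlaps(
        reads_by_sample, {p.part_id: p.interval for p in parts}
    )


def count_introns(
    reads_by_sample: ReadsBySample,
    introns: Union[Mapping[str, Interval], Sequence[Interval]],
) -> CountMatrix:
    """Union-rule counting over intron intervals.  A spliced read whose gap
    jumps an intron does not count toward it — only block overlap counts."""
    if not isinstance(introns, Mapping):
        introns = {f"intron:{i + 1}": iv for i, iv in enumerate(introns)}
    return _count_overlaps(reads_by_sample, introns)


def splice_site_activity(
    junction_counts: CountMatrix, junctions: Mapping[str, Junction]
) -> CountMatrix:
    """Per-sample activity of each splice site = sum of the counts of all
    junctions sharing that site.

    ``junctions`` maps feature ids of ``junction_counts`` to Junction
    objects.  Conservation holds by construction: summed donor activity ==
    summed acceptor activity == total junction count."""
    unknown = set(junction_counts.feature_ids) - set(junctions)
    if unknown:
        raise KeyError(f"junction ids without a Junction object: {sorted(unknown)}")
    rows: dict[str, pd.Series] = {}
    for jid, junction in junctions.items():
        if jid not in junction_counts.counts.index:
            continue
        row = junction_counts.counts.loc[jid]
        for site in (junction.donor_site(), junction.acceptor_site()):
            rows[site.id] = rows.get(site.id, 0) + row
    activity = pd.DataFrame(rows).T.sort_index()
    activity.columns = junction_counts.counts.columns
    # every junction read appears at one donor and one acceptor, so site
    # column sums are twice the junction totals; keep the original library
    return CountMatrix(activity, junction_counts.library_sizes,
                       check_library=False)


# ---------------------------------------------------------------------------
# normalization


def rpkm(count: float, library_size: float, feature_length_nt: float) -> float:
    """Reads per kilobase of feature per million reads of library."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if feature_length_nt <= 0:
        raise ValueError("feature_length_nt must be > 0")
    return count * 1e9 / (library_size * feature_length_nt)


def rpm(count: float, library_size: float) -> float:
    """Reads per million reads of library."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return count * 1e6 / library_size


def normalize(
    matrix: CountMatrix,
    unit: str,
    feature_lengths: Optional[Mapping[str, float]] = None,
) -> NormalizedMatrix:
    """Normalize a count matrix to RPKM (needs lengths) or RPM."""
    lib = matrix.library_sizes
    if (lib <= 0).any():
        raise ValueError("library_size must be > 0 for every sample")
    if unit == "RPM":
        values = matrix.counts * 1e6 / lib
        return NormalizedMatrix(values, "RPM")
    if unit == "RPKM":
        if feature_lengths is None:
            raise ValueError("RPKM requires feature_lengths")
        lengths = pd.Series(feature_lengths).reindex(matrix.counts.index)
        if lengths.isna().any():
            missing = list(lengths.index[lengths.isna()])
            raise KeyError(f"missing feature lengths: {missing}")
        values = matrix.counts.mul(1e9).div(lib, axis=1).div(lengths, axis=0)
        return NormalizedMatrix(values, "RPKM", lengths)
    raise ValueError("unit must be 'RPKM' or 'RPM'")


# ---------------------------------------------------------------------------
# cassette-exon PSI


def estimate_psi(c78: float, c89: float, c79: float) -> PsiEstimate:
    """Percent spliced in of the cassette exon from its three junctions.

    inclusion = (c78 + c89) / 2 (the two inclusion junctions each witness
    one inclusion event), skip = c79; PSI = inclusion / (inclusion + skip).
    All-zero input is flagged undefined rather than reported as 0."""
    if min(c78, c89, c79) < 0:
        raise ValueError("junction counts must be non-negative")
    inclusion = (c78 + c89) / 2.0
    skip = float(c79)
    if inclusion + skip == 0:
        return PsiEstimate(math.nan, inclusion, skip, defined=False)
    return PsiEstimate(inclusion / (inclusion + skip), inclusion, skip)


def psi_profile(
    c78: np.ndarray, c89: np.ndarray, c79: np.ndarray
) -> np.ndarray:
    """Vectorized PSI across samples; NaN where no junction reads exist."""
    c78 = np.asarray(c78, dtype=float)
    c89 = np.asarray(c89, dtype=float)
    c79 = np.asarray(c79, dtype=float)
    inclusion = (c78 + c89) / 2.0
    denom = inclusion + c79
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(denom > 0, inclusion / denom, np.nan)
    return psi


# ---------------------------------------------------------------------------
# transcript abundance EM


@dataclass
class EMResult:
    theta: dict[str, float]
    log_likelihood: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def quantify_transcripts_em(
    class_counts: Mapping[Sequence[str], float],
    informative_junctions: Mapping[str, int],
    tol: float = 1e-8,
    max_iter: int = 500,
) -> EMResult:
    """Isoform abundances from junction-compatibility classes by EM.

    Each read class lists the isoforms it is compatible with; isoform ``k``
    with ``J_k`` informative junctions emits junction reads with mass
    proportional to ``theta_k * J_k``, so the probability of class ``c`` is
    ``sum_{k in c} theta_k J_k / sum_j theta_j J_j``.  The E-step splits
    class counts across compatible isoforms by that mass; the M-step
    recovers abundances by dividing each isoform's read share by ``J_k``
    (weight 1/J_k) and renormalizing.  Deterministic: uniform start,
    convergence when max |d theta| < ``tol`` or after ``max_iter`` rounds;
    the log-likelihood is non-decreasing across iterations.
    """
    if not class_counts:
        raise ValueError("no compatibility classes given")
    isoforms = sorted(informative_junctions)
    J = np.array([informative_junctions[k] for k in isoforms], dtype=float)
    if (J <= 0).any():
        bad = [k for k in isoforms if informative_junctions[k] <= 0]
        raise ValueError(f"isoform(s) with zero informative junctions: {bad}")
    idx = {k: i for i, k in enumerate(isoforms)}
    classes = []
    counts = []
    for members, n in class_counts.items():
        members = tuple(members)
        if not members:
            raise ValueError("empty compatibility class")
        unknown = [m for m in members if m not in idx]
        if unknown:
            raise KeyError(f"class references unknown isoform(s): {unknown}")
        classes.append(np.array([idx[m] for m in members]))
        counts.append(float(n))
    counts_arr = np.array(counts)
    total = counts_arr.sum()
    theta = np.full(len(isoforms), 1.0 / len(isoforms))

    def loglik(th: np.ndarray) -> float:
        mass = th * J
        z = mass.sum()
        ll = 0.0
        for members, n in zip(classes, counts_arr):
            if n > 0:
                ll += n * math.log(mass[members].sum() / z)
        return ll

    trace = [loglik(theta)] if total > 0 else [0.0]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mass = theta * J
        resp = np.zeros_like(theta)
        for members, n in zip(classes, counts_arr):
            m = mass[members]
            resp[members] += n * m / m.sum()
        new_theta = resp / J
        s = new_theta.sum()
        new_theta = new_theta / s if s > 0 else np.full_like(theta, 1 / len(theta))
        delta = np.abs(new_theta - theta).max()
        theta = new_theta
        trace.append(loglik(theta))
        if delta < tol:
            converged = True
            break
    return EMResult(dict(zip(isoforms, theta)), trace, it, converged)
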