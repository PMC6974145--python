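"""Synthetic two-SNP splice-QTL data with known truth.

The generator emulates the study design the analysis assumes: n diploid
individuals carry two linked SNPs (a causal variant and an LD proxy, the
rs2304256 / rs12720270 analogues) whose haplotype frequencies are solved
exactly for requested minor-allele frequencies and r².  The causal dosage
shifts cassette-exon inclusion on the logit scale,

    logit(PSI_i) = alpha + beta_g * dosage_i + pop_shift[pop_i] + eps_i,

with eps ~ Normal(0, sigma) individual noise and a two-population baseline
offset mirroring a population-of-origin covariate.  Counts are Poisson at
the feature level: the two inclusion junctions at rate depth*PSI, the
skipping junction at depth*(1-PSI), the two flanking introns at
depth*gamma_intron*(1-PSI) + baseline, and exonic parts proportional to
part length (the cassette part additionally to PSI).  The proxy SNP has no
direct effect — it associates only through LD, giving the conditional
analysis a ground truth.

Defaults are the European-like study condition: n = 200 individuals,
MAFs 0.26 / 0.17, r² = 0.50, a +1 logit inclusion effect per minor-allele
copy on a baseline of logit(0.8), and 100 expected junction-informative
reads per sample.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import formats
from .gene_model import (
    GeneModel,
    Junction,
    build_pseudo_transcript,
    derive_introns,
    flatten_exonic_parts,
    tyk2_like_fixture,
)
from .quantify import (
    AlignedRead,
    CountMatrix,
    normalize,
    quantify_transcripts_em,
    splice_site_activity,
)

#: Feature ids of the simulated count table.
JUNCTION_IDS = ("junction:e7-e8", "junction:e8-e9", "junction:e7-e9")
INTRON_IDS = ("intron:7", "intron:8")
EXON_IDS = ("exon:e7", "exon:e8", "exon:e9")


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Frequencies of the four two-locus haplotypes; lower case = major
    allele, upper case = minor."""

    f_ab: float
    f_aB: float
    f_Ab: float
    f_AB: float

    def __post_init__(self) -> None:
        freqs = (self.f_ab, self.f_aB, self.f_Ab, self.f_AB)
        if any(f < -1e-12 for f in freqs):
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(sum(freqs) - 1.0) > 1e-12:
            raise ValueError("haplotype frequencies must sum to 1")

    @property
    def maf1(self) -> float:
        return self.f_Ab + self.f_AB

    @property
    def maf2(self) -> float:
        return self.f_aB + self.f_AB

    @property
    def d(self) -> float:
        return self.f_AB - self.maf1 * self.maf2

    @property
    def r2(self) -> float:
        p1, p2 = self.maf1, self.maf2
        denom = p1 * (1 - p1) * p2 * (1 - p2)
        return self.d**2 / denom if denom > 0 else 0.0

    def as_probs(self) -> np.ndarray:
        return np.clip(
            np.array([self.f_ab, self.f_aB, self.f_Ab, self.f_AB]), 0.0, None
        )


def r2_max(maf1: float, maf2: float, sign: str = "+") -> float:
    """Largest attainable r² for two loci with the given MAFs and D sign."""
    p1, p2 = maf1, maf2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    if sign == "+":
        d_extreme = min(p1 * (1 - p2), p2 * (1 - p1))
    else:
        d_extreme = min(p1 * p2, (1 - p1) * (1 - p2))
    return d_extreme**2 / denom


def solve_haplotypes(
    maf1: float, maf2: float, r2_target: float, sign: str = "+"
) -> HaplotypeFreqs:
    """Haplotype frequencies with the requested MAFs and LD.

    D = sign * sqrt(r2 * p1 q1 p2 q2), f_AB = p1 p2 + D, remaining cells by
    the margins.  Raises when the requested r² exceeds what the MAFs allow
    (D is bounded by the smallest margin product)."""
    if not (0 < maf1 <= 0.5 and 0 < maf2 <= 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]")
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    if not 0 <= r2_target <= 1:
        raise ValueError("r2_target must lie in [0, 1]")
    attainable = r2_max(maf1, maf2, sign)
    if r2_target > attainable + 1e-12:
        raise ValueError(
            f"r² = {r2_target} infeasible for MAFs ({maf1}, {maf2}) with "
            f"D sign {sign}; attainable maximum is {attainable:.4f}"
        )
    p1, p2 = maf1, maf2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    d = math.sqrt(r2_target * denom) * (1 if sign == "+" else -1)
    f_AB = p1 * p2 + d
    f_Ab = p1 * (1 - p2) - d
    f_aB = (1 - p1) * p2 - d
    f_ab = (1 - p1) * (1 - p2) + d
    cells = [f_ab, f_aB, f_Ab, f_AB]
    cells = [0.0 if abs(x) < 1e-15 else x for x in cells]
    freqs = HaplotypeFreqs(*cells)
    assert abs(freqs.r2 - r2_target) < 1e-9
    return freqs


def sample_genotypes(
    n: int, freqs: HaplotypeFreqs, seed
) -> tuple[pd.Series, pd.Series]:
    """Diploid dosages at the two SNPs under random mating: each individual
    is two independent haplotype draws; dosage = minor-allele count."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    probs = freqs.as_probs()
    probs = probs / probs.sum()
    haps = rng.choice(4, size=(n, 2), p=probs)
    # categories: 0=ab 1=aB 2=Ab 3=AB; A on SNP1 for {2,3}, B on SNP2 for {1,3}
    d1 = np.isin(haps, (2, 3)).sum(axis=1)
    d2 = np.isin(haps, (1, 3)).sum(axis=1)
    ids = sample_ids(n)
    return (
        pd.Series(d1, index=ids, name="dosage1", dtype=float),
        pd.Series(d2, index=ids, name="dosage2", dtype=float),
    )


def sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimulationConfig:
    """Study conditions of the simulated splice-QTL experiment."""

    n: int = 200
    maf1: float = 0.26
    maf2: float = 0.17
    r2_target: float = 0.50
    ld_sign: str = "+"
    alpha: float = math.log(0.8 / 0.2)  # baseline PSI 0.8 on the logit scale
    beta_g: float = 1.0  # logit-PSI shift per minor-allele copy (causal SNP)
    sigma: float = 0.3  # individual logit-PSI noise sd
    depth: float = 100.0  # expected junction-informative reads per sample
    gamma_intron: float = 0.3  # intron signal per unit of skipping
    intron_baseline: float = 2.0  # basal intron read rate
    n_pop: int = 2
    pop_shift: tuple[float, ...] = (0.0, 0.5)
    overdispersion: float = 0.0  # gamma-Poisson extra variance; 0 = Poisson
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.maf1 <= 0.5 or not 0 < self.maf2 <= 0.5:
            raise ValueError("MAFs must lie in (0, 0.5]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if len(self.pop_shift) != self.n_pop:
            raise ValueError("pop_shift must have one entry per population")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pop_shift"] = list(d["pop_shift"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "pop_shift" in d:
            d["pop_shift"] = tuple(d["pop_shift"])
        return cls(**d)


@dataclass
class SimulatedDataset:
    sample_ids: list[str]
    genotypes: pd.DataFrame  # samples x {rs_causal, rs_proxy}, dosage 0/1/2
    counts: pd.DataFrame  # features x samples, raw integer counts
    covariates: pd.DataFrame  # samples x {pop}
    library_sizes: pd.Series
    truth: dict

    @property
    def config(self) -> SimulationConfig:
        return SimulationConfig.from_dict(self.truth["config"])


def simulate_psi(
    dosage1, pop, config: SimulationConfig, seed
) -> np.ndarray:
    """Per-individual cassette-exon inclusion under the logit-linear model."""
    rng = _as_rng(seed)
    dosage1 = np.asarray(dosage1, dtype=float)
    pop = np.asarray(pop, dtype=int)
    shift = np.asarray(config.pop_shift, dtype=float)[pop]
    eta = (
        config.alpha
        + config.beta_g * dosage1
        + shift
        + rng.normal(0.0, config.sigma, size=dosage1.shape)
    )
    psi = 1.0 / (1.0 + np.exp(-eta))
    return np.clip(psi, 1e-12, 1 - 1e-12)


def _poisson(rng: np.random.Generator, lam: np.ndarray, od: float) -> np.ndarray:
    lam = np.asarray(lam, dtype=float)
    if od > 0:
        lam = rng.gamma(shape=1.0 / od, scale=od * lam)
    return rng.poisson(lam)


def simulate_counts(
    psi: np.ndarray, config: SimulationConfig, seed
) -> pd.DataFrame:
    """Feature-level Poisson counts given per-sample PSI.

    Inclusion junctions at depth*PSI, skipping junction at depth*(1-PSI),
    flanking introns at depth*gamma_intron*(1-PSI) + baseline, exonic parts
    proportional to part length (cassette part additionally to PSI)."""
    rng = _as_rng(seed)
    psi = np.asarray(psi, dtype=float)
    d, od = config.depth, config.overdispersion
    gene, _, _ = tyk2_like_fixture()
    lengths = {
        pid: part.length
        for pid, part in zip(EXON_IDS, flatten_exonic_parts(gene))
    }
    rows = {
        "junction:e7-e8": _poisson(rng, d * psi, od),
        "junction:e8-e9": _poisson(rng, d * psi, od),
        "junction:e7-e9": _poisson(rng, d * (1 - psi), od),
        "intron:7": _poisson(
            rng, d * config.gamma_intron * (1 - psi) + config.intron_baseline, od
        ),
        "intron:8": _poisson(
            rng, d * config.gamma_intron * (1 - psi) + config.intron_baseline, od
        ),
    }
    for pid in EXON_IDS:
        rate = d * lengths[pid] / 1000.0
        if pid == "exon:e8":
            rate = rate * psi
        rows[pid] = _poisson(rng, np.broadcast_to(rate, psi.shape), od)
    counts = pd.DataFrame(rows).T
    counts.columns = sample_ids(len(psi))
    return counts.astype(int)


def simulate_dataset(config: Optional[SimulationConfig] = None) -> SimulatedDataset:
    """End-to-end simulation: haplotypes → genotypes → PSI → counts."""
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_geno, rng_pop, rng_psi, rng_counts = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    freqs = solve_haplotypes(
        config.maf1, config.maf2, config.r2_target, config.ld_sign
    )
    d_causal, d_proxy = sample_genotypes(config.n, freqs, rng_geno)
    pop = rng_pop.integers(0, config.n_pop, size=config.n)
    psi = simulate_psi(d_causal.to_numpy(), pop, config, rng_psi)
    counts = simulate_counts(psi, config, rng_counts)
    ids = sample_ids(config.n)
    genotypes = pd.DataFrame(
        {"rs_causal": d_causal.to_numpy(), "rs_proxy": d_proxy.to_numpy()},
        index=ids,
    )
    covariates = pd.DataFrame({"pop": pop}, index=ids, dtype=float)
    truth = {
        "psi": [float(x) for x in psi],
        "config": config.to_dict(),
        "haplotype_freqs": {
            "f_ab": freqs.f_ab,
            "f_aB": freqs.f_aB,
            "f_Ab": freqs.f_Ab,
            "f_AB": freqs.f_AB,
        },
    }
    return SimulatedDataset(
        ids, genotypes, counts, covariates, counts.sum(axis=0).astype(float), truth
    )


# ---------------------------------------------------------------------------
# multi-level phenotype matrices


def build_level_matrices(
    counts: pd.DataFrame, library_sizes: pd.Series
) -> dict[str, pd.DataFrame]:
    """Normalized phenotype matrices per quantification level from the
    simulated feature counts: RPM for junctions and splice sites, RPKM for
    exonic parts, introns and the whole gene, and EM transcript proportions.
    """
    gene, _, _ = tyk2_like_fixture()
    junctions = dict(enumerate_fixture_junctions(gene))
    jc = CountMatrix(counts.loc[list(JUNCTION_IDS)].copy(), library_sizes)

    junction_rpm = normalize(jc, "RPM").values

    site_counts = splice_site_activity(jc, junctions)
    site_names = {
        "donor:chr19:1300:+": "site:e7_donor",
        "acceptor:chr19:1800:+": "site:e8_acceptor",
        "donor:chr19:1998:+": "site:e8_donor",
        "acceptor:chr19:2500:+": "site:e9_acceptor",
    }
    site_rpm = normalize(site_counts, "RPM").values.rename(index=site_names)

    pseudo = build_pseudo_transcript(gene)
    intron_lengths = {
        iid: e - s for iid, (s, e) in zip(INTRON_IDS, derive_introns(pseudo))
    }
    intron_rpkm = normalize(
        CountMatrix(counts.loc[list(INTRON_IDS)].copy(), library_sizes),
        "RPKM",
        intron_lengths,
    ).values

    exon_lengths = {
        eid: part.length
        for eid, part in zip(EXON_IDS, flatten_exonic_parts(gene))
    }
    exon_rpkm = normalize(
        CountMatrix(counts.loc[list(EXON_IDS)].copy(), library_sizes),
        "RPKM",
        exon_lengths,
    ).values

    gene_length = sum(e - s for s, e in pseudo)
    gene_counts = counts.loc[list(EXON_IDS)].sum(axis=0).to_frame().T
    gene_counts.index = ["gene:TYK2like"]
    gene_rpkm = normalize(
        CountMatrix(gene_counts, library_sizes),
        "RPKM",
        {"gene:TYK2like": gene_length},
    ).values

    informative = {"TYK2like-full": 2, "TYK2like-dE8": 1}
    theta_full, theta_skip = [], []
    for s in counts.columns:
        classes = {
            ("TYK2like-full",): counts.at["junction:e7-e8", s]
            + counts.at["junction:e8-e9", s],
            ("TYK2like-dE8",): counts.at["junction:e7-e9", s],
        }
        em = quantify_transcripts_em(classes, informative)
        theta_full.append(em.theta["TYK2like-full"])
        theta_skip.append(em.theta["TYK2like-dE8"])
    transcript = pd.DataFrame(
        {"transcript:full": theta_full, "transcript:dE8": theta_skip},
        index=counts.columns,
    ).T

    return {
        "gene": gene_rpkm,
        "transcript": transcript,
        "exon": exon_rpkm,
        "junction": junction_rpm,
        "splice_site": site_rpm,
        "intron": intron_rpkm,
    }


def enumerate_fixture_junctions(gene: GeneModel) -> list[tuple[str, Junction]]:
    """Map the canonical junction feature ids onto Junction objects of the
    packaged three-exon gene."""
    e7, e8, e9 = gene.transcript("TYK2like-full").exons
    return [
        ("junction:e7-e8", Junction(gene.chrom, e7[1], e8[0], gene.strand)),
        ("junction:e8-e9", Junction(gene.chrom, e8[1], e9[0], gene.strand)),
        ("junction:e7-e9", Junction(gene.chrom, e7[1], e9[0], gene.strand)),
    ]


def emit_junction_reads(
    psi_value: float,
    n_reads: int,
    seed,
    min_overhang_range: tuple[int, int] = (3, 12),
) -> list[AlignedRead]:
    """Optional block-list read emitter for exercising the read-level
    counters: each read spans one junction of the packaged gene with random
    overhangs (some below typical filters, on purpose)."""
    rng = _as_rng(seed)
    gene, _, _ = tyk2_like_fixture()
    junctions = [j for _, j in enumerate_fixture_junctions(gene)]
    probs = np.array([psi_value / 2, psi_value / 2, 1 - psi_value])
    choices = rng.choice(3, size=n_reads, p=probs / probs.sum())
    lo, hi = min_overhang_range
    reads = []
    for c in choices:
        j = junctions[c]
        left = int(rng.integers(lo, hi + 1))
        right = int(rng.integers(lo, hi + 1))
        reads.append(
            AlignedRead(((j.donor - left, j.donor), (j.acceptor, j.acceptor + right)))
        )
    return reads


# ---------------------------------------------------------------------------
# bundle I/O

_VCF_SNPS = {
    # causal analog sits 75 nt into the cassette exon; proxy 36 nt upstream
    # of the intron/exon boundary (1-based VCF positions)
    "rs_causal": {"pos": 1876, "ref": "C", "alt": "A"},
    "rs_proxy": {"pos": 1765, "ref": "G", "alt": "A"},
}


def write_fixture_bundle(dataset: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Serialize a simulated dataset as plain-text files (VCF, GTF, TSV
    matrices, truth JSON).  Re-reading reproduces the dataset bit-exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene, _, _ = tyk2_like_fixture()
    paths = {
        "annotation": out / "annotation.gtf",
        "vcf": out / "genotypes.vcf",
        "counts": out / "counts.tsv",
        "library_sizes": out / "library_sizes.tsv",
        "covariates": out / "covariates.tsv",
        "truth": out / "truth.json",
    }
    formats.write_gtf(gene, paths["annotation"])
    meta = pd.DataFrame(_VCF_SNPS).T
    formats.write_vcf(
        dataset.genotypes,
        chrom=gene.chrom,
        positions=meta["pos"].astype(int).to_dict(),
        ref=meta["ref"].to_dict(),
        alt=meta["alt"].to_dict(),
        path=paths["vcf"],
    )
    formats.write_matrix_tsv(dataset.counts, paths["counts"])
    formats.write_matrix_tsv(
        dataset.library_sizes.to_frame("library_size").T, paths["library_sizes"]
    )
    formats.write_matrix_tsv(dataset.covariates.T, paths["covariates"])
    paths["truth"].write_text(json.dumps(dataset.truth, indent=1))
    return paths


def read_fixture_bundle(bundle_dir) -> SimulatedDataset:
    bundle = Path(bundle_dir)
    counts = formats.read_matrix_tsv(bundle / "counts.tsv").astype(int)
    library = formats.read_matrix_tsv(bundle / "library_sizes.tsv").loc[
        "library_size"
    ]
    covariates = formats.read_matrix_tsv(bundle / "covariates.tsv").T
    covariates.columns.name = None
    covariates.index.name = None
    dosages = formats.read_vcf_dosages(bundle / "genotypes.vcf")
    genotypes = pd.DataFrame(dosages)
    genotypes = genotypes[sorted(genotypes.columns)]  # canonical SNP order
    truth = json.loads((bundle / "truth.json").read_text())
    truth["config"] = dict(truth["config"])
    return SimulatedDataset(
        list(counts.columns),
        genotypes,
        counts,
        covariates,
        library.astype(float),
        truth,
    )
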